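"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`CloneTrackError` so
callers (and the CLI) can catch one base class.
"""

from __future__ import annotations


class CloneTrackError(Exception):
    """Base class for all clonetrack errors."""


# --- vocabulary ---------------------------------------------------------

class UnknownFieldError(CloneTrackError):
    """A field name that the vocabulary does not define (configuration
    error, distinct from an ordinary term rejection)."""


class ProtectionError(CloneTrackError):
    """Mutation attempted on a locked vocabulary without a valid unlock
    token."""


class DuplicateTermError(CloneTrackError):
    """Term already present in the target list."""


class ReferentialIntegrityError(CloneTrackError):
    """Removal of a term that ledger records still reference."""


class ValidationError(CloneTrackError):
    """A value rejected by the controlled vocabulary."""


# --- naming -------------------------------------------------------------

class NamingError(CloneTrackError):
    """Base for sample-name grammar errors."""


class NameFormatError(NamingError):
    """Token unusable in a designator (empty, underscore, or path-unsafe
    characters)."""


class NameParseError(NamingError):
    """Text that cannot be decomposed under the grammar."""


class WellError(NamingError):
    """Malformed or out-of-bounds well label."""


class DerivationError(NamingError):
    """Clone/sort derivation applied at the wrong level."""


class AliasError(NamingError):
    """Short alias requested for a name without a well."""


# --- ledger / lineage ---------------------------------------------------

class LookupError_(CloneTrackError):
    """Unknown sample, designator, or metadata key."""


class UniquenessError(CloneTrackError):
    """Designator or derived sample name already registered."""


class ArithmeticDomainError(CloneTrackError):
    """Non-positive stock concentration in a reagent plan."""


# --- export -------------------------------------------------------------

class SchemaError(CloneTrackError):
    """Table schema unusable for export (duplicate/empty column names)."""


class ImportError_(CloneTrackError):
    """Malformed payload during table import; message carries the locus."""


# --- workspace ----------------------------------------------------------

class WorkspaceIOError(CloneTrackError):
    """Filesystem failure while scaffolding the workspace tree."""


# --- fixtures -----------------------------------------------------------

class GenerationError(CloneTrackError):
    """Infeasible parameters for the random-history generator."""
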