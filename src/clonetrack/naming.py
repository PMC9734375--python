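"""The sample-name grammar: formatting, parsing, and derivation.

A transfection designator concatenates the transfection date (YYYYMMDD),
a fluorescent-protein token, the edited gene's token, and a guide-RNA
token with no delimiters, e.g. ``20200113mChOCT4sg2``. Derived samples
append underscore-separated suffixes: a 96-well address once a clone is
designated (``_C6``) and an auto-incrementing sort counter each time the
population is flow-sorted (``_Sort1``, ``_Sort2``, ...). Names double as
directory names, so every formatted name stays within ``[A-Za-z0-9_+]``.

Because the base name carries no delimiters, parsing is vocabulary-driven:
the fluorescent-protein token is the longest case-insensitive prefix match
against the vocabulary, the guide token is the longest suffix match, and
the residue in between is the gene. Guide tokens absent from the
vocabulary fall back to a ``letters+digits`` pattern (e.g. ``sg2``) with a
warning rather than an error, since guide lists are rarely exhaustive.
Ambiguity raises; the parser never guesses.
"""

from __future__ import annotations

import datetime as dt
import re
import warnings
from dataclasses import dataclass, replace
from typing import Optional

from .errors import (
    AliasError,
    DerivationError,
    NameFormatError,
    NameParseError,
    WellError,
)
from .vocab import Vocabulary, validate_term

#: Row/column extents of the standard multi-well plate formats.
PLATE_DIMENSIONS: dict[int, tuple[int, int]] = {
    6: (2, 3),
    12: (3, 4),
    24: (4, 6),
    48: (6, 8),
    96: (8, 12),
}

_TOKEN_RE = re.compile(r"[A-Za-z0-9+]+\Z")
_WELL_RE = re.compile(r"([A-Za-z])(\d{1,2})\Z")
_SORT_RE = re.compile(r"Sort([1-9]\d*)\Z")
# fallback guide shape: trailing lowercase letters + digits, like "sg2"
_GUIDE_FALLBACK_RE = re.compile(r"[a-z]+\d+\Z")


@dataclass(frozen=True, order=True)
class WellAddress:
    """A row-letter / column-number position on a multi-well plate."""

    row: str
    column: int
    plate_format: int = 96

    def __post_init__(self) -> None:
        if self.plate_format not in PLATE_DIMENSIONS:
            raise WellError(f"unsupported plate format {self.plate_format!r}")
        n_rows, n_cols = PLATE_DIMENSIONS[self.plate_format]
        if (
            len(self.row) != 1
            or not self.row.isalpha()
            or not self.row.isupper()
            or ord(self.row) - ord("A") >= n_rows
        ):
            raise WellError(
                f"row {self.row!r} outside A..{chr(ord('A') + n_rows - 1)} "
                f"for {self.plate_format}-well format"
            )
        if not 1 <= self.column <= n_cols:
            raise WellError(
                f"column {self.column} outside 1..{n_cols} "
                f"for {self.plate_format}-well format"
            )

    @property
    def label(self) -> str:
        """Compact label, e.g. ``"C6"``."""
        return f"{self.row}{self.column}"


def parse_well(label: str, plate_format: int = 96) -> WellAddress:
    """Parse a well label like ``"C6"`` and check it against the plate
    bounds (for 96-well: rows A–H, columns 1–12)."""
    m = _WELL_RE.match(label)
    if not m:
        raise WellError(f"malformed well label {label!r}")
    return WellAddress(m.group(1).upper(), int(m.group(2)), plate_format)


@dataclass(frozen=True)
class SampleName:
    """Parsed form of a designator: date + token triple + optional
    clone-well and sort-count suffixes."""

    date: dt.date
    fp: str
    gene: str
    guide: str
    well: Optional[WellAddress] = None
    sort_index: Optional[int] = None

    def __post_init__(self) -> None:
        for label, token in (("fp", self.fp), ("gene", self.gene), ("guide", self.guide)):
            if not token or not _TOKEN_RE.match(token):
                raise NameFormatError(
                    f"{label} token {token!r} must be non-empty and restricted "
                    "to [A-Za-z0-9+] (underscores delimit suffixes)"
                )
        if self.sort_index is not None:
            if self.sort_index < 1:
                raise NameFormatError("sort_index must be >= 1")
            if self.well is None:
                raise NameFormatError(
                    "a sorted sample must be clone-level (well required)"
                )

    @property
    def base(self) -> "SampleName":
        """The transfection designator this name derives from."""
        return replace(self, well=None, sort_index=None)

    @property
    def is_clone_level(self) -> bool:
        return self.well is not None

    def __str__(self) -> str:
        return format_name(self)


def format_name(name: SampleName) -> str:
    """Render the canonical text form: ``YYYYMMDD`` + fp + gene + guide,
    then ``_<well>`` and ``_Sort<k>`` when present."""
    text = f"{name.date:%Y%m%d}{name.fp}{name.gene}{name.guide}"
    if name.well is not None:
        text += f"_{name.well.label}"
    if name.sort_index is not None:
        text += f"_Sort{name.sort_index}"
    return text


def _match_fp(body: str, vocab: Vocabulary) -> Optional[str]:
    """Longest case-insensitive prefix of ``body`` matching a vocabulary
    fluorescent-protein token; as-entered casing is preserved."""
    candidates = sorted(vocab.terms("fluorescent_protein"), key=len, reverse=True)
    lowered = body.casefold()
    for token in candidates:
        if lowered.startswith(token.casefold()):
            return body[: len(token)]
    return None


def _match_guide(body: str, vocab: Vocabulary) -> Optional[str]:
    """Longest suffix of ``body`` matching a vocabulary guide token, else
    the trailing letters+digits run as a pattern fallback (warned)."""
    candidates = sorted(vocab.terms("guide_rna"), key=len, reverse=True)
    for token in candidates:
        if body.endswith(token):
            return token
    m = _GUIDE_FALLBACK_RE.search(body)
    if m and m.start() > 0:
        token = m.group(0)
        warnings.warn(
            f"guide token {token!r} matched by pattern, not vocabulary",
            stacklevel=3,
        )
        return token
    return None


def parse_name(text: str, vocab: Vocabulary) -> SampleName:
    """Decompose a designator back into its parts.

    Suffixes split on ``_``; the delimiter-free base decomposes as an
    8-digit date, then the vocabulary-matched fluorescent-protein prefix,
    then the guide token matched greedily from the right, with the residue
    as the gene token.
    """
    parts = text.split("_")
    base = parts[0]
    if len(base) < 9 or not base[:8].isdigit():
        raise NameParseError(f"{text!r}: base must start with an 8-digit date")
    try:
        date = dt.datetime.strptime(base[:8], "%Y%m%d").date()
    except ValueError as exc:
        raise NameParseError(f"{text!r}: invalid date digits ({exc})") from None

    body = base[8:]
    fp = _match_fp(body, vocab)
    if fp is None:
        raise NameParseError(
            f"{text!r}: no fluorescent-protein token from the vocabulary "
            f"prefixes {body!r}"
        )
    rest = body[len(fp):]
    guide = _match_guide(rest, vocab)
    if guide is None:
        raise NameParseError(f"{text!r}: no guide-RNA token terminates {rest!r}")
    gene = rest[: len(rest) - len(guide)]
    if not gene:
        raise NameParseError(f"{text!r}: empty gene token between fp and guide")

    well: Optional[WellAddress] = None
    sort_index: Optional[int] = None
    for suffix in parts[1:]:
        sort_m = _SORT_RE.match(suffix)
        if sort_m:
            if sort_index is not None:
                raise NameParseError(f"{text!r}: repeated Sort suffix")
            sort_index = int(sort_m.group(1))
        elif suffix.startswith("Sort"):
            raise NameParseError(f"{text!r}: malformed Sort suffix {suffix!r}")
        elif well is None and sort_index is None:
            well = parse_well(suffix)
        else:
            raise NameParseError(f"{text!r}: unexpected suffix {suffix!r}")
    return SampleName(date, fp, gene, guide, well, sort_index)


def derive_clone_name(base: SampleName, well: WellAddress) -> SampleName:
    """Append a well address to a transfection designator, naming the
    clone isolated at that plate position."""
    if base.well is not None or base.sort_index is not None:
        raise DerivationError(
            f"{format_name(base)!r} is already clone-level; clones derive "
            "only from base transfection designators"
        )
    return replace(base, well=well)


def derive_sort_name(current: SampleName) -> SampleName:
    """Advance the sort counter: first sort appends ``_Sort1``, each later
    sort increments the index by one."""
    if current.well is None:
        raise DerivationError(
            f"{format_name(current)!r} is not clone-level; only designated "
            "clones are sorted"
        )
    next_index = 1 if current.sort_index is None else current.sort_index + 1
    return replace(current, sort_index=next_index)


def short_alias(name: SampleName) -> str:
    """Six-digit-date clone alias, e.g. ``200113_C6`` — the compact label
    used for per-clone passage reports."""
    if name.well is None:
        raise AliasError(f"{format_name(name)!r} has no well; alias undefined")
    return f"{name.date:%y%m%d}_{name.well.label}"


def is_filesystem_safe(text: str) -> bool:
    """True when every character is in the grammar alphabet
    ``[A-Za-z0-9_+]`` (safe on POSIX and Windows)."""
    return bool(re.fullmatch(r"[A-Za-z0-9_+]+", text))


def check_fp_token(name: SampleName, vocab: Vocabulary) -> str:
    """Validate the name's fp token against the vocabulary
    (case-insensitively) and return the stored canonical spelling."""
    verdict = validate_term(vocab, "fluorescent_protein", name.fp)
    if not verdict:
        from .errors import ValidationError

        raise ValidationError(
            f"fluorescent-protein token {name.fp!r} not in vocabulary"
        )
    return verdict.canonical  # type: ignore[return-value]
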