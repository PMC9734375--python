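"""Controlled vocabularies that restrict data entry.

Mirrors the activity list and data-validation term lists of a
transfection-tracking workbook: a fixed, ordered set of activity terms
(Transfect, Passage, Sort, Freeze, ...) plus per-field term lists
(fluorescent protein, gene, guide RNA, ...) used both for validating
ledger entries and for driving the delimiter-free sample-name parser.

Vocabularies are immutable values: :func:`amend_vocabulary` returns a new
object. Edit protection is a lock flag plus a passphrase token — the
analog of spreadsheet sheet protection, an anti-accident device rather
than a security measure.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Optional

from .errors import (
    DuplicateTermError,
    ProtectionError,
    ReferentialIntegrityError,
    UnknownFieldError,
)

#: Activity terms selectable for any cell sample on any day, in canonical
#: drop-down order. "Feed w mTeSr+" keeps its idiosyncratic casing.
DEFAULT_ACTIVITIES: tuple[str, ...] = (
    "Transfect",
    "Feed w Ri",
    "Image",
    "Passage",
    "Sort",
    "Freeze",
    "Thaw",
    "Extract DNA",
    "Feed w mTeSR++Ri",
    "Feed w mTeSr+",
    "Discontinue",
    "Send out for analysis",
)

#: Field names a vocabulary may define besides the activity list.
FIELD_NAMES: tuple[str, ...] = (
    "fluorescent_protein",
    "gene",
    "guide_rna",
    "plasmid_component",
    "electroporation_program",
    "plate_format",
    "medium",
)

ACTIVITY_FIELD = "activity"

#: Fields matched case-insensitively (stored casing is canonical but the
#: user's as-entered casing is preserved where it appears in names).
CASE_INSENSITIVE_FIELDS = frozenset({"fluorescent_protein"})


@dataclass(frozen=True)
class Verdict:
    """Outcome of a term validation.

    ``canonical`` is the stored spelling of the matched term (relevant for
    case-insensitive fields); ``None`` on rejection.
    """

    accepted: bool
    canonical: Optional[str] = None

    def __bool__(self) -> bool:
        return self.accepted


@dataclass(frozen=True)
class Vocabulary:
    """Ordered, unique term lists; optionally locked against edits."""

    activities: tuple[str, ...]
    fields: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    locked: bool = False
    unlock_token: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.activities:
            raise ValueError("activities list must be non-empty")
        for label, terms in self._all_lists():
            if len(set(terms)) != len(terms):
                raise DuplicateTermError(f"duplicate terms in {label!r}")

    def _all_lists(self) -> Iterable[tuple[str, tuple[str, ...]]]:
        yield ACTIVITY_FIELD, self.activities
        yield from self.fields.items()

    def terms(self, fieldname: str) -> tuple[str, ...]:
        """Ordered term list for ``fieldname`` (or ``"activity"``)."""
        if fieldname == ACTIVITY_FIELD:
            return self.activities
        try:
            return tuple(self.fields[fieldname])
        except KeyError:
            raise UnknownFieldError(f"unknown vocabulary field {fieldname!r}") from None

    def lock(self, token: str) -> "Vocabulary":
        """Return a locked copy protected by ``token``."""
        return replace(self, locked=True, unlock_token=token)


def default_vocabulary() -> Vocabulary:
    """The vocabulary in force out of the box.

    The activity list is complete; the other field lists are seeded only
    with the tokens the reference workflow actually used (mCh, OCT4, sg2
    and the 96-well plate format) — projects extend them via vocabulary
    files rather than inheriting invented terms.
    """
    return Vocabulary(
        activities=DEFAULT_ACTIVITIES,
        fields={
            "fluorescent_protein": ("mCh",),
            "gene": ("OCT4",),
            "guide_rna": ("sg2",),
            "plasmid_component": (),
            "electroporation_program": (),
            "plate_format": ("96",),
            "medium": (),
        },
    )


def validate_term(vocab: Vocabulary, fieldname: str, term: str) -> Verdict:
    """Check ``term`` against the list for ``fieldname``.

    Fluorescent-protein matching is case-insensitive (the workbook itself
    mixes ``mCh`` and ``mCH``); every other field matches exactly. An
    unknown field name raises :class:`UnknownFieldError` — a configuration
    problem, not a term rejection.
    """
    terms = vocab.terms(fieldname)
    if fieldname in CASE_INSENSITIVE_FIELDS:
        folded = term.casefold()
        for stored in terms:
            if stored.casefold() == folded:
                return Verdict(True, stored)
        return Verdict(False)
    if term in terms:
        return Verdict(True, term)
    return Verdict(False)


def amend_vocabulary(
    vocab: Vocabulary,
    fieldname: str,
    change: Literal["add", "remove"],
    term: str,
    unlock: Optional[str] = None,
    ledger=None,
) -> Vocabulary:
    """Return a copy of ``vocab`` with ``term`` added to or removed from
    the list for ``fieldname``.

    A locked vocabulary requires the matching unlock token; the lock
    survives the amendment. Added terms go to the end of the list.
    Removal is refused while a bound ``ledger`` still references the term
    (referential integrity of the event log).
    """
    if vocab.locked and unlock != vocab.unlock_token:
        raise ProtectionError(
            "vocabulary is protected; supply the unlock token to amend it"
        )
    current = vocab.terms(fieldname)  # raises UnknownFieldError if absent

    if change == "add":
        if validate_term(vocab, fieldname, term):
            raise DuplicateTermError(f"{term!r} already in {fieldname!r}")
        new_list = current + (term,)
    elif change == "remove":
        if term not in current:
            raise UnknownFieldError(f"{term!r} not present in {fieldname!r}")
        if ledger is not None and ledger.uses_term(fieldname, term):
            raise ReferentialIntegrityError(
                f"{term!r} is referenced by ledger records and cannot be removed"
            )
        new_list = tuple(t for t in current if t != term)
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"change must be 'add' or 'remove', got {change!r}")

    if fieldname == ACTIVITY_FIELD:
        return replace(vocab, activities=new_list)
    fields = dict(vocab.fields)
    fields[fieldname] = new_list
    return replace(vocab, fields=fields)


# --- vocabulary files ---------------------------------------------------

def to_csv(vocab: Vocabulary) -> str:
    """Serialize as the two-column ``field,term`` file (RFC 4180, header
    row, the reserved field ``activity`` carrying the activity list)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n")
    writer.writerow(["field", "term"])
    for label, terms in (
        (ACTIVITY_FIELD, vocab.activities),
        *vocab.fields.items(),
    ):
        for term in terms:
            writer.writerow([label, term])
    return buf.getvalue()


def from_csv(text: str) -> Vocabulary:
    """Parse a two-column vocabulary file produced by :func:`to_csv`.

    Unlisted standard fields come back as empty lists so the parser and
    validators always find them.
    """
    reader = csv.reader(io.StringIO(text))
    header = next(reader, None)
    if header is None or [h.strip() for h in header[:2]] != ["field", "term"]:
        raise UnknownFieldError("vocabulary file must start with a 'field,term' header")
    activities: list[str] = []
    fields: dict[str, list[str]] = {name: [] for name in FIELD_NAMES}
    for row in reader:
        if not row or not any(cell.strip() for cell in row):
            continue
        label, term = row[0], row[1]
        if label == ACTIVITY_FIELD:
            activities.append(term)
        elif label in fields:
            fields[label].append(term)
        else:
            raise UnknownFieldError(f"unknown vocabulary field {label!r} in file")
    return Vocabulary(
        activities=tuple(activities),
        fields={k: tuple(v) for k, v in fields.items()},
    )
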