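"""The append-only activity ledger and transfection metadata store.

This is the Calendar/Data-worksheet pair of the tracking workbook: every
action performed on a cell sample — feeding, imaging, passaging, sorting,
freezing — becomes one immutable :class:`ActivityRecord`. Records carry a
monotonically increasing sequence number so that ``(date, seq)`` totally
orders the log even when several things happen on one day or entries are
made retroactively. Nothing is ever edited or deleted; corrections are
new records whose note references the corrected sequence number.

Each transfection additionally owns a :class:`TransfectionMetadata`
payload (the Metadata-Template worksheet): constructs, guide RNA,
electroporation program, cell counts, and a reagent plan whose volumes
the ledger computes from stock concentrations, warning when the mix
exceeds the transfection vessel.
"""

from __future__ import annotations

import copy
import datetime as dt
import io
import csv
from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Optional, Sequence

from . import vocab as vocab_mod
from .errors import (
    ArithmeticDomainError,
    LookupError_,
    UniquenessError,
    ValidationError,
)
from .lineage import DISCONTINUED, SampleRegistry
from .naming import SampleName, WellAddress, format_name, parse_name
from .reports import LEDGER_COLUMNS, ReportTable, records_table
from .vocab import Vocabulary, default_vocabulary, validate_term


@dataclass(frozen=True)
class ActivityRecord:
    """One row of the event log.

    ``warnings`` and ``planned`` are in-memory annotations (recomputed on
    replay); the serialized table carries exactly the nine canonical
    columns.
    """

    seq: int
    date: dt.date
    sample: str
    activity: str
    wells_used: Optional[int] = None
    plate_size: Optional[int] = None
    note: str = ""
    user: Optional[str] = None
    machine: Optional[str] = None
    planned: bool = False
    warnings: tuple[str, ...] = ()
    parsed_sample: Optional[SampleName] = None


class ReagentInput(NamedTuple):
    reagent: str
    stock_concentration: float  # e.g. ng/µL
    target_amount: float        # e.g. ng


@dataclass
class TransfectionMetadata:
    """Metadata-Template payload for one transfection."""

    name: SampleName
    plasmid_components: list[str] = field(default_factory=list)
    guide_rna: str = ""
    electroporation_program: str = ""
    cell_count: Optional[float] = None
    reagent_inputs: list[ReagentInput] = field(default_factory=list)
    vessel_capacity: float = 100.0  # µL
    notes: str = ""
    attachments: list[str] = field(default_factory=list)

    @property
    def designator(self) -> str:
        return format_name(self.name)


@dataclass(frozen=True)
class ReagentPlan:
    """Computed volumes for a transfection mix."""

    volumes: tuple[tuple[str, float], ...]
    total_volume: float
    warnings: tuple[str, ...]


def reagent_volumes(meta: TransfectionMetadata) -> ReagentPlan:
    """Volume of each reagent = target amount / stock concentration; warn
    when the summed volume exceeds the transfection vessel capacity."""
    volumes = []
    for reagent, stock, amount in meta.reagent_inputs:
        if stock <= 0:
            raise ArithmeticDomainError(
                f"stock concentration for {reagent!r} must be > 0, got {stock}"
            )
        volumes.append((reagent, amount / stock))
    total = sum(v for _, v in volumes)
    warnings = []
    if total > meta.vessel_capacity:
        warnings.append(
            f"total volume {total:g} exceeds vessel capacity "
            f"{meta.vessel_capacity:g}"
        )
    return ReagentPlan(tuple(volumes), total, tuple(warnings))


class Ledger:
    """Event log + metadata store + the registry they drive.

    ``capture_user``/``capture_machine`` mirror the workbook's opt-in
    recording of the user and computer identity; both default off.
    """

    def __init__(
        self,
        vocab: Optional[Vocabulary] = None,
        capture_user: bool = False,
        capture_machine: bool = False,
    ) -> None:
        self.vocab = vocab if vocab is not None else default_vocabulary()
        self.records: list[ActivityRecord] = []
        self.metadata: dict[str, TransfectionMetadata] = {}
        self.registry = SampleRegistry()
        self.capture_user = capture_user
        self.capture_machine = capture_machine

    # --- internals ------------------------------------------------------

    def _next_seq(self) -> int:
        return self.records[-1].seq + 1 if self.records else 1

    def _identity(self) -> tuple[Optional[str], Optional[str]]:
        user = machine = None
        if self.capture_user:
            import getpass

            user = getpass.getuser()
        if self.capture_machine:
            import socket

            machine = socket.gethostname()
        return user, machine

    def _validate_meta(self, meta: TransfectionMetadata) -> None:
        if not validate_term(self.vocab, "fluorescent_protein", meta.name.fp):
            raise ValidationError(
                f"fluorescent-protein token {meta.name.fp!r} not in vocabulary"
            )
        if meta.guide_rna and meta.guide_rna != meta.name.guide:
            raise ValidationError(
                f"metadata guide {meta.guide_rna!r} disagrees with the "
                f"designator's guide token {meta.name.guide!r}"
            )
        # Lists seeded empty are open: validate only against non-empty lists.
        for fieldname, terms in (
            ("guide_rna", [meta.guide_rna] if meta.guide_rna else []),
            ("electroporation_program",
             [meta.electroporation_program] if meta.electroporation_program else []),
            ("plasmid_component", meta.plasmid_components),
        ):
            if self.vocab.terms(fieldname):
                for term in terms:
                    if not validate_term(self.vocab, fieldname, term):
                        raise ValidationError(
                            f"{term!r} not in the {fieldname} vocabulary"
                        )

    # --- entry operations ----------------------------------------------

    def new_transfection(
        self, meta: TransfectionMetadata, date: Optional[dt.date] = None
    ) -> str:
        """Register a transfection: validates the metadata, appends the
        Transfect record, stores the metadata under the designator, and
        roots the sample tree. Returns the designator."""
        self._validate_meta(meta)
        designator = meta.designator
        if designator in self.registry or designator in self.metadata:
            raise UniquenessError(f"transfection {designator!r} already registered")
        when = date if date is not None else meta.name.date
        user, machine = self._identity()
        record = ActivityRecord(
            seq=self._next_seq(),
            date=when,
            sample=designator,
            activity="Transfect",
            user=user,
            machine=machine,
            parsed_sample=meta.name,
        )
        self.registry.add_root(meta.name, record.seq)
        self.records.append(record)
        self.metadata[designator] = copy.deepcopy(meta)
        return designator

    def clone_transfection_template(
        self, source_designator: str, new_date: dt.date
    ) -> TransfectionMetadata:
        """Copy an existing transfection's metadata as a template: same
        constructs and reagent plan, new date, notes and attachments
        cleared. The copy is independent of the source."""
        try:
            source = self.metadata[source_designator]
        except KeyError:
            raise LookupError_(
                f"no transfection metadata for {source_designator!r}"
            ) from None
        meta = copy.deepcopy(source)
        meta.name = replace(meta.name, date=new_date)
        meta.notes = ""
        meta.attachments = []
        return meta

    def record_activity(
        self,
        date: dt.date,
        sample: str,
        activity: str,
        wells_used: Optional[int] = None,
        plate_size: Optional[int] = None,
        note: str = "",
        new_clone_well: Optional[WellAddress] = None,
        planned: bool = False,
    ) -> ActivityRecord:
        """Append one activity entry.

        The activity must be in the vocabulary and the sample registered.
        Entries may carry any date — past, current, or future. A record
        carrying ``new_clone_well`` designates a new clone at that plate
        position; a ``Sort`` record derives the next sort name. Activities
        on a discontinued sample succeed with a warning attached (the flag
        is bookkeeping, and retrospective entries are legitimate).
        """
        if activity not in self.vocab.activities:
            raise ValidationError(f"activity {activity!r} not in vocabulary")
        node = self.registry.node(sample)
        warnings = ()
        if node.status == DISCONTINUED:
            warnings = (f"{sample!r} was discontinued before this entry",)
        user, machine = self._identity()
        record = ActivityRecord(
            seq=self._next_seq(),
            date=date,
            sample=sample,
            activity=activity,
            wells_used=wells_used,
            plate_size=plate_size,
            note=note,
            user=user,
            machine=machine,
            planned=planned,
            warnings=warnings,
            parsed_sample=node.parsed,
        )
        self.registry.apply_record(record, new_clone_well=new_clone_well)
        self.records.append(record)
        return record

    def designate_clone(
        self,
        date: dt.date,
        transfection: str,
        well: WellAddress,
        activity: str = "Image",
        note: str = "",
    ) -> str:
        """Designate a clone observed at ``well`` of a transfection's
        plate, recording the observing activity (Image by default).
        Returns the new clone's name."""
        record = self.record_activity(
            date, transfection, activity, note=note, new_clone_well=well
        )
        from .naming import derive_clone_name

        return format_name(
            derive_clone_name(self.registry.node(transfection).parsed, well)
        )

    # --- queries --------------------------------------------------------

    def filter_records(
        self, predicate: Callable[[ActivityRecord], bool]
    ) -> ReportTable:
        """Records satisfying ``predicate``, as a (date, seq)-ordered
        table; the ledger itself is unchanged."""
        hits = [r for r in self.records if predicate(r)]
        return records_table(hits, f"filter@{len(self.records)}")

    def uses_term(self, fieldname: str, term: str) -> bool:
        """Whether any record or metadata entry references ``term`` —
        the referential-integrity check behind vocabulary removal."""
        if fieldname == vocab_mod.ACTIVITY_FIELD:
            return any(r.activity == term for r in self.records)
        metas = self.metadata.values()
        if fieldname == "guide_rna":
            return any(m.guide_rna == term or m.name.guide == term for m in metas)
        if fieldname == "fluorescent_protein":
            folded = term.casefold()
            return any(m.name.fp.casefold() == folded for m in metas)
        if fieldname == "gene":
            return any(m.name.gene == term for m in metas)
        if fieldname == "plasmid_component":
            return any(term in m.plasmid_components for m in metas)
        if fieldname == "electroporation_program":
            return any(m.electroporation_program == term for m in metas)
        if fieldname == "plate_format":
            return any(str(r.plate_size) == term for r in self.records)
        return False

    # --- persistence -----------------------------------------------------

    def to_table(self) -> ReportTable:
        return records_table(self.records, f"ledger@{len(self.records)}")

    def to_csv(self) -> str:
        """The Data-worksheet analog: RFC 4180, fixed nine-column header."""
        return self.to_table().to_csv()

    def load_records_csv(self, text: str) -> None:
        """Restore records from :meth:`to_csv` output (registry state is
        persisted separately, as the samples file)."""
        reader = csv.DictReader(io.StringIO(text, newline=""))
        if reader.fieldnames is None or tuple(reader.fieldnames) != LEDGER_COLUMNS:
            raise LookupError_("malformed ledger file: bad header")
        for row in reader:
            self.records.append(
                ActivityRecord(
                    seq=int(row["seq"]),
                    date=dt.date.fromisoformat(row["date"]),
                    sample=row["sample"],
                    activity=row["activity"],
                    wells_used=int(row["wells_used"]) if row["wells_used"] else None,
                    plate_size=int(row["plate_size"]) if row["plate_size"] else None,
                    note=row["note"],
                    user=row["user"] or None,
                    machine=row["machine"] or None,
                )
            )

    def replay(self, entries: Sequence[tuple]) -> None:
        """Apply a scripted entry sequence (the fixture format): tuples of
        ``("transfect", meta, date)`` or ``("activity", kwargs-dict)``."""
        for entry in entries:
            kind = entry[0]
            if kind == "transfect":
                self.new_transfection(entry[1], entry[2])
            elif kind == "activity":
                self.record_activity(**entry[1])
            else:
                raise ValueError(f"unknown entry kind {kind!r}")
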