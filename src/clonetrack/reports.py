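"""Recomputable queries over the ledger.

All reports share one currency, the :class:`ReportTable`: an ordered
grid of optional text cells under named columns, with a provenance stamp
(the generating query and the ledger length at generation). Tables are
pure functions of their inputs — regenerating on the same ledger yields
an identical table, and regenerating on an extended ledger only appends
rows (refresh semantics).

Cells are ``Optional[str]``. Builders stringify values up front (ISO-8601
dates, decimal integers, ``true``/``false`` booleans) so every export
format round-trips the table losslessly; the empty string is normalized
to missing at construction because delimited formats cannot tell the two
apart.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, fields as dc_fields
from typing import Callable, Iterable, Optional, Sequence

import datetime as dt

from .errors import LookupError_, SchemaError, ValidationError
from .naming import short_alias

Cell = Optional[str]


def _norm(value) -> Cell:
    """Coerce a raw value to the canonical cell representation."""
    if value is None or value == "":
        return None
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, dt.date):
        return value.isoformat()
    return str(value)


@dataclass(frozen=True)
class ReportTable:
    columns: tuple[str, ...]
    rows: tuple[tuple[Cell, ...], ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns) or any(
            not c for c in self.columns
        ):
            raise SchemaError("column names must be unique and non-empty")
        for row in self.rows:
            if len(row) != len(self.columns):
                raise SchemaError(
                    f"row width {len(row)} != {len(self.columns)} columns"
                )

    @classmethod
    def build(
        cls,
        columns: Sequence[str],
        raw_rows: Iterable[Sequence],
        provenance: str = "",
    ) -> "ReportTable":
        """Construct from arbitrary values, normalizing each cell."""
        return cls(
            tuple(columns),
            tuple(tuple(_norm(v) for v in row) for row in raw_rows),
            provenance,
        )

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, name: str) -> list[Cell]:
        idx = self.columns.index(name)
        return [row[idx] for row in self.rows]

    def to_csv(self) -> str:
        """RFC 4180 rendering (also the ledger/report file format)."""
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\r\n")
        writer.writerow(self.columns)
        for row in self.rows:
            writer.writerow(["" if c is None else c for c in row])
        return buf.getvalue()

    def to_text(self) -> str:
        """Fixed-width rendering for terminals."""
        cells = [list(self.columns)] + [
            ["" if c is None else c for c in row] for row in self.rows
        ]
        widths = [max(len(r[i]) for r in cells) for i in range(len(self.columns))]
        lines = ["  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip() for r in cells]
        lines.insert(1, "  ".join("-" * w for w in widths))
        return "\n".join(lines)


# --- analysis results ---------------------------------------------------

@dataclass(frozen=True)
class AnalysisResult:
    """Offsite genomic/QC results for one designated clone."""

    clone: str
    date_sent: dt.date
    passage_at_analysis: int
    fp_copy_number: Optional[float] = None
    cnv_flag: bool = False
    insertion_site_pcr: str = ""
    extra_insertion_flag: bool = False
    phenotype_note: str = ""
    mycoplasma: str = ""
    str_markers: str = ""
    data_url: str = ""


ANALYSIS_COLUMNS = tuple(f.name for f in dc_fields(AnalysisResult))


def analysis_results_to_csv(results: Sequence[AnalysisResult]) -> str:
    return ReportTable.build(
        ANALYSIS_COLUMNS, [[getattr(r, c) for c in ANALYSIS_COLUMNS] for r in results]
    ).to_csv()


def analysis_results_from_csv(text: str) -> list[AnalysisResult]:
    reader = csv.DictReader(io.StringIO(text, newline=""))
    out = []
    for row in reader:
        out.append(
            AnalysisResult(
                clone=row["clone"],
                date_sent=dt.date.fromisoformat(row["date_sent"]),
                passage_at_analysis=int(row["passage_at_analysis"]),
                fp_copy_number=float(row["fp_copy_number"])
                if row.get("fp_copy_number")
                else None,
                cnv_flag=row.get("cnv_flag") == "true",
                insertion_site_pcr=row.get("insertion_site_pcr") or "",
                extra_insertion_flag=row.get("extra_insertion_flag") == "true",
                phenotype_note=row.get("phenotype_note") or "",
                mycoplasma=row.get("mycoplasma") or "",
                str_markers=row.get("str_markers") or "",
                data_url=row.get("data_url") or "",
            )
        )
    return out


# --- the report surface -------------------------------------------------

#: Activities relevant to passage counting and its milestones.
PASSAGE_RELEVANT = (
    "Passage",
    "Freeze",
    "Thaw",
    "Send out for analysis",
    "Extract DNA",
)


def _record_row(record) -> list:
    return [
        record.seq,
        record.date,
        record.sample,
        record.activity,
        record.wells_used,
        record.plate_size,
        record.note,
        record.user,
        record.machine,
    ]


LEDGER_COLUMNS = (
    "seq",
    "date",
    "sample",
    "activity",
    "wells_used",
    "plate_size",
    "note",
    "user",
    "machine",
)


def records_table(records: Sequence, provenance: str = "ledger") -> ReportTable:
    """Render ledger records as a table in (date, seq) order."""
    ordered = sorted(records, key=lambda r: (r.date, r.seq))
    return ReportTable.build(
        LEDGER_COLUMNS, [_record_row(r) for r in ordered], provenance
    )


def activity_report(ledger, activity: str) -> ReportTable:
    """All ledger rows for one activity term (the FreezeReport /
    DiscontinueReport / TransfectionsReport pattern)."""
    if activity not in ledger.vocab.activities:
        raise ValidationError(f"unknown activity {activity!r}")
    hits = [r for r in ledger.records if r.activity == activity]
    return records_table(
        hits, f"activity_report({activity!r})@{len(ledger.records)}"
    )


def transfection_report(ledger, registry, designator: str) -> ReportTable:
    """Every activity recorded on any sample derived from one
    transfection, in (date, seq) order."""
    members = set(registry.transfection_members(designator))
    hits = [r for r in ledger.records if r.sample in members]
    return records_table(
        hits, f"transfection_report({designator!r})@{len(ledger.records)}"
    )


def passage_table(ledger, registry, clone: str) -> ReportTable:
    """Passage-counting worksheet for one clone.

    Collects the passage-relevant records (Passage, Freeze, Thaw, plus the
    Extract DNA / Send-out milestones) for the clone's whole lineage —
    its ancestors back to the transfection and its descendant sort chain —
    and annotates each row with the running count of Passage events up to
    and including that row. The count at a Freeze/Thaw/Send-out row is the
    passage number of the sample at that moment.
    """
    lineage = set(registry.ancestors(clone)) | set(registry.descendants(clone))
    hits = sorted(
        (
            r
            for r in ledger.records
            if r.sample in lineage and r.activity in PASSAGE_RELEVANT
        ),
        key=lambda r: (r.date, r.seq),
    )
    count = 0
    rows = []
    for r in hits:
        if r.activity == "Passage":
            count += 1
        rows.append(_record_row(r) + [count])
    return ReportTable.build(
        LEDGER_COLUMNS + ("passage_count",),
        rows,
        f"passage_table({clone!r})@{len(ledger.records)}",
    )


def final_passage_count(ledger, registry, clone: str) -> int:
    table = passage_table(ledger, registry, clone)
    return int(table.rows[-1][-1]) if table.rows else 0


def clones_summary(
    ledger,
    registry,
    results: Sequence[AnalysisResult] = (),
    path_for: Optional[Callable[[str], str]] = None,
) -> ReportTable:
    """One row per designated clone, collating lineage bookkeeping with
    offsite analysis results.

    Columns: clone name and short alias, lineage status (``active`` unless
    the clone or any of its sort derivatives was discontinued), deepest
    sort reached, final passage count, the joined analysis fields, and the
    workspace location (``path_for`` maps a sample name to its storage
    path; defaults to the ancestor chain joined with ``/``).
    """
    by_clone = {}
    for res in results:
        if res.clone not in registry:
            raise LookupError_(
                f"analysis result names unregistered clone {res.clone!r}"
            )
        if registry.node(res.clone).parsed.well is None:
            raise LookupError_(f"{res.clone!r} is not clone-level")
        by_clone[res.clone] = res
    if path_for is None:
        path_for = lambda name: "/".join(registry.ancestors(name))

    analysis_cols = [c for c in ANALYSIS_COLUMNS if c != "clone"]
    rows = []
    for clone in registry.clone_level_samples():
        node = registry.node(clone)
        status = (
            "discontinued" if registry.lineage_discontinued(clone) else "active"
        )
        res = by_clone.get(clone)
        rows.append(
            [
                clone,
                short_alias(node.parsed),
                status,
                registry.max_sort_index(clone),
                final_passage_count(ledger, registry, clone),
            ]
            + [getattr(res, c) if res else None for c in analysis_cols]
            + [path_for(clone)]
        )
    return ReportTable.build(
        ("clone", "alias", "status", "n_sorts", "n_passages")
        + tuple(analysis_cols)
        + ("workspace_path",),
        rows,
        f"clones_summary@{len(ledger.records)}",
    )
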