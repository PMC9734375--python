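"""Deterministic datasets: the study replica and randomized histories.

``study_replica`` rebuilds, event by event, a dataset with the shape of
the reference use case's three OCT4 knock-in transfections: three root
designators (20200113mChOCT4sg2, 20200120mCHOCT4sg2 — its idiosyncratic
``mCH`` casing preserved — and 20200220mChOCT4sg2), fifteen designated
clones, ten of which are discontinued after imaging or early passaging,
and five survivors (aliases 200113_C6, 200120_B9, 200220_A7, 200220_C6,
200220_C10) carried through iterated sorting, passaging, freezing and
genomic analysis.

Only the aggregate shape is anchored to the reference use case; the
remaining constants here are arbitrary-but-fixed choices, not ground
truth:

* the 5/5/5 split of clones across transfections and the well labels of
  the ten discontinued clones;
* the per-clone daily scripts (feed/image/passage cadence);
* which survivors carry analysis flags: the two clones with extra
  inserted sequence downstream of the edit are 200220_C6 and 200220_C10,
  which together with 200220_A7 carry the three copy-number-variant
  flags;
* 200113_C6 is the clone needing the deepest enrichment — its sort chain
  reaches ``_Sort4`` — and carries the tendency-to-differentiate note.
* the printed alias ``2020220_A7`` has a seven-digit date; the replica
  normalizes it to the six-digit convention (``200220_A7``).

``random_history`` produces vocabulary-valid ledgers for property tests:
reproducible for a fixed seed, with every generated name parseable under
the grammar.
"""

from __future__ import annotations

import datetime as dt
import random
import string
from dataclasses import dataclass
from typing import Optional

from .errors import GenerationError
from .ledger import Ledger, ReagentInput, TransfectionMetadata
from .lineage import SampleRegistry
from .naming import PLATE_DIMENSIONS, SampleName, parse_well
from .reports import AnalysisResult, final_passage_count
from .vocab import default_vocabulary


def _base(date: dt.date, fp: str) -> SampleName:
    return SampleName(date, fp, "OCT4", "sg2")


def _meta(name: SampleName) -> TransfectionMetadata:
    return TransfectionMetadata(
        name=name,
        plasmid_components=["donor-plasmid", "nuclease-plasmid"],
        guide_rna="sg2",
        electroporation_program="CB-150",
        cell_count=1.0e6,
        reagent_inputs=[
            ReagentInput("donor-plasmid", 500.0, 2500.0),
            ReagentInput("nuclease-plasmid", 400.0, 2000.0),
        ],
        vessel_capacity=100.0,
        notes="study replica transfection",
    )


#: (transfection date, fp casing, survivor wells, discontinued wells)
_REPLICA_PLAN = (
    (dt.date(2020, 1, 13), "mCh", ("C6",), ("A2", "B3", "D4", "E5")),
    (dt.date(2020, 1, 20), "mCH", ("B9",), ("A1", "C2", "D3", "F6")),
    (dt.date(2020, 2, 20), "mCh", ("A7", "C6", "C10"), ("B2", "D8")),
)

#: Survivors carrying analysis flags (full designators derived in code).
_EXTRA_INSERTION = {"200220_C6", "200220_C10"}
_CNV = {"200220_C6", "200220_C10", "200220_A7"}
_DEEP_SORT_ALIAS = "200113_C6"


def study_replica() -> tuple[Ledger, SampleRegistry, list[AnalysisResult]]:
    """Build the study-replica ledger, its registry, and the analysis
    results for the five surviving clones. Fully deterministic."""
    ledger = Ledger(default_vocabulary())

    survivors: list[str] = []  # full clone designators in plan order
    for date, fp, kept, dropped in _REPLICA_PLAN:
        designator = ledger.new_transfection(_meta(_base(date, fp)), date)
        day = lambda n: date + dt.timedelta(days=n)
        ledger.record_activity(day(1), designator, "Feed w Ri",
                               wells_used=96, plate_size=96)
        ledger.record_activity(day(2), designator, "Feed w mTeSR++Ri")
        ledger.record_activity(day(3), designator, "Image",
                               note="screen wells for fluorescent clusters")
        clones: dict[str, str] = {}
        for well in kept + dropped:
            clones[well] = ledger.designate_clone(
                day(3), designator, parse_well(well),
                note=f"single fluorescent cluster in {well}",
            )
        for well in kept + dropped:
            ledger.record_activity(day(5), clones[well], "Passage")
        for well in dropped:
            ledger.record_activity(
                day(7), clones[well], "Discontinue",
                note="no stable fluorescent population",
            )
        for well in kept:
            clone = clones[well]
            survivors.append(clone)
            alias = f"{date:%y%m%d}_{well}"
            n_sorts = 4 if alias == _DEEP_SORT_ALIAS else 2
            current = clone
            ledger.record_activity(day(7), clone, "Passage")
            for k in range(1, n_sorts + 1):
                rec_day = 7 + 4 * k
                ledger.record_activity(day(rec_day), current, "Sort",
                                       note=f"enrichment sort {k}")
                current = f"{clone}_Sort{k}"
                ledger.record_activity(day(rec_day + 2), current, "Passage")
            ledger.record_activity(day(7 + 4 * n_sorts + 3), current, "Freeze",
                                   note="bank intermediate population")
            ledger.record_activity(day(7 + 4 * n_sorts + 5), current, "Thaw")
            ledger.record_activity(day(7 + 4 * n_sorts + 6), current, "Passage")
            ledger.record_activity(day(7 + 4 * n_sorts + 8), current,
                                   "Extract DNA")
            ledger.record_activity(day(7 + 4 * n_sorts + 9), current,
                                   "Send out for analysis",
                                   note="genomic analysis: copy number, "
                                        "insertion-site PCR, STR, mycoplasma")

    results = []
    for clone in survivors:
        node = ledger.registry.node(clone)
        alias = f"{node.parsed.date:%y%m%d}_{node.parsed.well.label}"
        send = next(
            r for r in ledger.records
            if r.activity == "Send out for analysis"
            and (r.sample == clone or r.sample.startswith(clone + "_"))
        )
        extra = alias in _EXTRA_INSERTION
        results.append(
            AnalysisResult(
                clone=clone,
                date_sent=send.date,
                passage_at_analysis=final_passage_count(
                    ledger, ledger.registry, clone
                ),
                fp_copy_number=2.0 if extra else 1.0,
                cnv_flag=alias in _CNV,
                insertion_site_pcr=(
                    "extra sequence downstream of edit" if extra
                    else "expected junction"
                ),
                extra_insertion_flag=extra,
                phenotype_note=(
                    "tendency to differentiate; required extended sorting"
                    if alias == _DEEP_SORT_ALIAS else "normal morphology"
                ),
                mycoplasma="negative",
                str_markers="match to parent line",
                data_url="/".join(ledger.registry.ancestors(clone)),
            )
        )
    return ledger, ledger.registry, results


# --- randomized histories ----------------------------------------------

@dataclass(frozen=True)
class HistoryParams:
    """Bounds for the random-history generator."""

    n_transfections: int = 2
    clones_per_transfection: int = 3
    events_per_clone: int = 6
    plate_format: int = 96
    discontinue_prob: float = 0.2
    start: dt.date = dt.date(2021, 3, 1)


_NON_SORT_EVENTS = (
    "Passage", "Feed w Ri", "Feed w mTeSR++Ri", "Feed w mTeSr+",
    "Image", "Freeze", "Thaw", "Extract DNA",
)


def random_history(
    seed: int, params: Optional[HistoryParams] = None
) -> tuple[Ledger, SampleRegistry]:
    """A reproducible, vocabulary-valid random ledger.

    Transfections get random gene tokens (guide stays ``sg2`` so names
    parse under the default vocabulary); clones receive random well
    positions and event scripts mixing feeds, passages, sorts, freezes,
    and occasional discontinuation.
    """
    p = params or HistoryParams()
    n_rows, n_cols = PLATE_DIMENSIONS.get(p.plate_format, (0, 0))
    capacity = n_rows * n_cols
    if capacity == 0:
        raise GenerationError(f"unsupported plate format {p.plate_format}")
    if p.clones_per_transfection > capacity:
        raise GenerationError(
            f"{p.clones_per_transfection} clones exceed the "
            f"{p.plate_format}-well plate capacity"
        )
    rng = random.Random(seed)
    ledger = Ledger(default_vocabulary())
    for t in range(p.n_transfections):
        date = p.start + dt.timedelta(days=30 * t + rng.randrange(10))
        gene = "".join(rng.choices(string.ascii_uppercase, k=rng.randint(3, 5)))
        name = SampleName(date, "mCh", gene, "sg2")
        designator = ledger.new_transfection(_meta(name), date)
        day = 1
        wells = [
            f"{chr(ord('A') + r)}{c + 1}"
            for r in range(n_rows) for c in range(n_cols)
        ]
        rng.shuffle(wells)
        for well in wells[: p.clones_per_transfection]:
            clone = ledger.designate_clone(
                date + dt.timedelta(days=day), designator,
                parse_well(well, p.plate_format),
            )
            current = clone
            for _ in range(p.events_per_clone):
                day += rng.randint(1, 3)
                when = date + dt.timedelta(days=day)
                if rng.random() < 0.25:
                    ledger.record_activity(when, current, "Sort")
                    node = ledger.registry.node(current).parsed
                    k = 1 if node.sort_index is None else node.sort_index + 1
                    current = f"{clone}_Sort{k}"
                else:
                    ledger.record_activity(
                        when, current, rng.choice(_NON_SORT_EVENTS)
                    )
            if rng.random() < p.discontinue_prob:
                day += 1
                ledger.record_activity(
                    date + dt.timedelta(days=day), current, "Discontinue"
                )
    return ledger, ledger.registry
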