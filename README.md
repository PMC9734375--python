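# clonetrack

Contemporaneous sample-provenance tracking for the generation of
genome-edited cell lines.

Making a clonal knock-in cell line is a long, branching process: a
transfection produces a plate of candidate wells; imaging designates
clones; each clone is passaged, flow-sorted (repeatedly) to enrich the
edited population, frozen, thawed, and finally sent for genomic analysis.
Months later, the question "what passage was this bank frozen at, and
what had been done to it by then?" must be answerable from records, not
memory. `clonetrack` is an event-sourced library + CLI for exactly that
bookkeeping: every action on every sample is one row of an append-only
ledger, and sample names themselves encode provenance.

## The data model

**Names encode provenance.** A transfection designator concatenates the
date, fluorescent-protein token, edited-gene token, and guide-RNA token:

```
20200113 mCh OCT4 sg2        →  20200113mChOCT4sg2
```

Designating a clone at well C6 appends `_C6`; each flow sort appends or
increments `_Sort<k>`:

```
20200113mChOCT4sg2 → 20200113mChOCT4sg2_C6 → 20200113mChOCT4sg2_C6_Sort1 → … → _Sort4
```

Because the base name is delimiter-free, parsing is vocabulary-driven:
the fluorescent-protein token is matched (case-insensitively) from the
left, the guide token greedily from the right, and the residue is the
gene. `parse(format(x)) = x` holds for every constructible name.

**The ledger is append-only.** Each entry has a monotone sequence
number, so `(date, seq)` totally orders the log even with retroactive or
future-dated (planned) entries. Controlled vocabularies (a fixed
activity list — Transfect, Passage, Sort, Freeze, Thaw, … — plus
per-field term lists) reject typos at entry time. Corrections are new
records; nothing is ever rewritten, and replaying the same entries
reproduces byte-identical tables.

**The registry mirrors the ledger.** Transfect/designate/sort events
grow a derivation forest; `Discontinue` flips a status flag without
deleting history. The forest maps 1:1 onto nested directories
(`root/base/base_C6/base_C6_Sort1/…`), giving every sample a
human-readable, local persistent identifier where its data lives.

**Reports are pure queries.** Per-activity tables, per-transfection
histories, a passage counter (the running count of `Passage` events over
a clone's lineage, read off at Freeze/Thaw/Send-out milestones), and a
clones summary joining lineage bookkeeping with offsite analysis
results. Everything exports losslessly to CSV (RFC 4180), XML, or JSON.

## Worked example

```python
import datetime as dt
from clonetrack import (
    Ledger, SampleName, TransfectionMetadata, parse_well,
    passage_table, clones_summary,
)

ledger = Ledger()
meta = TransfectionMetadata(
    name=SampleName(dt.date(2020, 1, 13), "mCh", "OCT4", "sg2"),
    guide_rna="sg2",
)
base = ledger.new_transfection(meta)                      # '20200113mChOCT4sg2'
clone = ledger.designate_clone(dt.date(2020, 1, 16), base, parse_well("C6"))
ledger.record_activity(dt.date(2020, 1, 18), clone, "Passage")
ledger.record_activity(dt.date(2020, 1, 20), clone, "Sort")   # → ..._C6_Sort1
ledger.record_activity(dt.date(2020, 1, 22), clone + "_Sort1", "Passage")
ledger.record_activity(dt.date(2020, 1, 24), clone + "_Sort1", "Freeze")

print(passage_table(ledger, ledger.registry, clone).to_text())
```

prints

```
seq  date        sample                       activity  wells_used  plate_size  note  user  machine  passage_count
---  ----------  ---------------------------  --------  ----------  ----------  ----  ----  -------  -------------
3    2020-01-18  20200113mChOCT4sg2_C6        Passage                                                1
5    2020-01-22  20200113mChOCT4sg2_C6_Sort1  Passage                                                2
6    2020-01-24  20200113mChOCT4sg2_C6_Sort1  Freeze                                                 2
```

— the bank frozen on Jan 24 is at passage 2, and the row's sample name
says it had been sorted once.

The same flow from the shell:

```
clonetrack transfect --date 2020-01-13 --fp mCh --gene OCT4 --guide sg2
clonetrack designate-clone 20200113mChOCT4sg2 C6 --date 2020-01-16
clonetrack sort 20200113mChOCT4sg2_C6 --date 2020-01-20
clonetrack report passages 20200113mChOCT4sg2_C6
clonetrack export --format json --out ledger.json
clonetrack workspace init /data/edits && clonetrack workspace sync
```

State lives as plain-text files (`ledger.csv`, `samples.csv`,
`vocab.csv`, `metadata.json`) in the project directory.

## The study replica

`clonetrack.study_replica()` (or `clonetrack fixture study-replica --out
DIR`) deterministically rebuilds a dataset with the shape of the
workflow's reference use case: three OCT4-knock-in transfections, 15
designated clones, 10 discontinued, and 5 survivors carried through
iterated sorting (one needing a `_Sort4` chain), freezing, and genomic
analysis — of which 2 carry an extra-insertion flag and 3 a copy-number
variant. It is the standing integration fixture for reports, exports,
and the workspace scaffold.

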