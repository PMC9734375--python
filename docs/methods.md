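# Methods

## The model

`clonetrack` treats cell-line generation as an event-sourced process.
The single source of truth is an append-only ledger of activity records
`(seq, date, sample, activity, wells_used, plate_size, note, user,
machine)`; every other structure — the sample registry, the directory
tree, every report — is a pure function of the ledger prefix (plus the
transfection metadata store and any joined analysis results). This gives
two properties the package leans on everywhere: *replay determinism*
(the same entry sequence reproduces byte-identical tables) and *refresh
semantics* (reports are regenerated, never incrementally patched).

Sequence numbers increase strictly with entry order; dates may be
retroactive or future (a planned entry carries an in-memory `planned`
flag). `(date, seq)` is the total order used by all reports. Because a
retroactively dated entry sorts before existing rows, the "refresh only
appends" property holds exactly when new entries are not back-dated;
with back-dating, regeneration is still deterministic but may interleave
rows — the price of allowing retrospective record-keeping.

## The naming grammar

A base designator is `YYYYMMDD + fp + gene + guide` with no delimiters;
suffixes `_<Well>` and `_Sort<k>` are underscore-separated. The grammar
alphabet is `[A-Za-z0-9_+]`, so every name is a valid directory name on
POSIX and Windows.

Parsing a delimiter-free concatenation requires the vocabulary: the fp
token is the longest case-insensitive prefix match against the
`fluorescent_protein` list, the guide is the longest suffix match
against `guide_rna`, and the residue between them is the gene. Two
deliberate choices:

* **fp matching is case-insensitive with as-entered casing preserved.**
  Real workbooks mix `mCh` and `mCH` in designators; treating these as
  distinct proteins would corrupt provenance, while normalizing the
  casing would corrupt the recorded names. Validation canonicalizes,
  names keep what was typed. All other fields match case-sensitively.
* **Unknown guide tokens fall back to a `lowercase-letters+digits`
  pattern** (the `sg2` shape) with a `UserWarning`, because guide lists
  are rarely exhaustive in practice. A residue that matches neither
  vocabulary nor pattern is an error — the parser never guesses.

Sort derivation is restricted to clone-level names (a well must be
present): enrichment sorting happens after clone designation, and a
chain `_C6 → _C6_Sort1 → _C6_Sort2` keeps parent/child readable off the
names. Sorting a pre-clone transfection pool is rejected.

## Registry and workspace

Ledger records drive the registry: `Transfect` roots a tree, a record
carrying a designation well derives a clone child, `Sort` derives the
next sort name from the record's sample (so the registry refuses a
second `Sort` aimed at an already-superseded name — the duplicate child
would collide), and `Discontinue` flips a status flag. Nodes are never
deleted; a clone *lineage* counts as discontinued when the clone or any
of its sort derivatives is.

The workspace mirrors the registry: each sample's directory path is its
ancestor chain, root-first, so nesting depth equals derivation depth +
1. `ensure_tree` only creates (idempotent, never touches existing
content); nothing ever moves or deletes a folder — the workspace is an
archive, and discontinued samples keep their directories. `audit`
compares the two sides: it reports registered samples without folders,
and directories sitting *where a sample folder would be* (children of
the root or of a sample folder) that no sample claims. Data directories
nested deeper inside a sample's own folder are intentionally out of
audit scope — that is the sample's data area.

## Passage counting

The passage table filters a clone's lineage records — ancestors back to
the transfection plus the descendant sort chain — to `Passage`,
`Freeze`, `Thaw`, and the `Extract DNA` / `Send out for analysis`
milestones, and annotates each row with the cumulative count of
`Passage` events so far. Counts accumulate across freeze/thaw (no
reset), and passages of the pre-designation pool count toward the
clone: the clone's culture age includes its history before designation.
A clone-only count is a one-line predicate change on the same table and
was deliberately not made a flag until someone needs it.

The clones summary emits one row per designated clone: lineage status,
deepest sort index in the subtree, final passage count, the joined
analysis-result fields (copy number, CNV flag, insertion-site PCR,
extra-insertion flag, phenotype, mycoplasma, STR, data URL), and the
workspace path.

## Vocabularies

The default activity list is the fixed twelve-term set (Transfect,
Feed w Ri, Image, Passage, Sort, Freeze, Thaw, Extract DNA,
Feed w mTeSR++Ri, Feed w mTeSr+, Discontinue, Send out for analysis),
idiosyncratic spellings included — reproducing an established list
verbatim beats prettifying it. Non-activity field lists are seeded only
with tokens the reference workflow actually used (`mCh`, `OCT4`, `sg2`,
plate format `96`); inventing a plausible-looking default vocabulary
would smuggle fiction into validated records, so projects extend via
`vocab.csv` instead. Metadata fields whose vocabulary list is empty are
treated as open (unvalidated); once a list is non-empty it is enforced.

Protection is a lock flag plus a passphrase token — an anti-accident
device modeled on spreadsheet sheet protection, with no cryptographic
pretensions. Removing a term still referenced by a bound ledger is a
referential-integrity error.

## Serialization

Report tables hold `Optional[str]` cells; builders stringify once
(ISO-8601 dates, decimal integers, `true`/`false` booleans — note the
designator keeps its own `YYYYMMDD` rendering, distinct from the
ISO dates in exports). This makes the three export formats exactly
interconvertible: CSV is RFC 4180 with CRLF and a header row; XML is
the minimal flat `records/record/field[@name]` shape; JSON is an array
of flat objects. Missing is the empty field in CSV, an absent element
in XML, `null` in JSON. Because CSV cannot distinguish missing from
empty string, the empty string is normalized to missing at table
construction. Output is byte-deterministic (stable field order, no
timestamps). Known limit: XML 1.0 cannot carry most C0 control
characters, so cells are contractually printable text plus
tab/newline/CR (carriage returns ride through XML as `&#13;`).

`pandas` was considered and rejected for the table layer: the tables
are small ordered string grids with a strict lossless round-trip
contract, and dtype inference would work against it.

The CLI persists state as plain text: `ledger.csv` (the canonical
nine-column log), `samples.csv` (the registry — this is where clone
designation wells survive a reload, since the ledger columns don't
carry them), `vocab.csv`, `metadata.json`, `results.csv`, and
`clonetrack.ini` for configuration such as `workspace.root`.

## The study replica and the random generator

`study_replica()` is a scripted, fully deterministic event log shaped
like the reference use case: three transfections (2020-01-13 `mCh`,
2020-01-20 `mCH`, 2020-02-20 `mCh`, all `OCT4`/`sg2`), five designated
clones each, feeds and imaging at day 3, ten clones discontinued after
early passaging, and five survivors (`200113_C6`, `200120_B9`,
`200220_A7`, `200220_C6`, `200220_C10`) carried through ≥2 enrichment
sorts, freeze/thaw, DNA extraction and send-out. `200113_C6` gets the
deep (`_Sort4`) chain and the differentiation-prone phenotype note;
`200220_C6` and `200220_C10` carry the extra-insertion flag and, with
`200220_A7`, the three CNV flags. Only the aggregate shape is anchored
to the documented use case; the clone split, well labels, daily cadence
and flag assignments are arbitrary-but-fixed constants documented in
the module. The replica emulates bookkeeping structure, not biology: no
well-to-well variation, instrument output, or measurement noise — so
tests passing on it certify the tracking logic, not any biological
claim.

`random_history(seed, params)` generates vocabulary-valid ledgers for
property tests (defaults: 2 transfections × 3 clones × 6 events, 96-well
plates, discontinue probability 0.2, sort probability 0.25 per event) —
sized to exercise branch/sort/discontinue interleavings cheaply, with
infeasible parameters (more clones than wells) rejected.

## Numerical and degenerate cases

The only arithmetic is the reagent plan: volume = target amount ÷ stock
concentration, exact in floats at these magnitudes; non-positive
concentrations are domain errors, an empty reagent list totals 0 with
no warnings, and a total above the vessel capacity warns rather than
errors (the bench may override). Degenerate inputs elsewhere: an empty
registry lists no samples; a transfection with no clones reports only
its own row; a passage table with no passage-relevant records is empty
and its final count is 0; activities on discontinued samples record
with a warning instead of failing, because blocking retrospective
entries would lose data to save a flag.

## Problem sizes used in checks

The bundled verification runs at desk scale, chosen to be generous for
the structures involved: grammar round-trip identity on 10⁴ randomized
names, passage-count equivalence against a brute-force filter-and-count
oracle on 10³ random histories, export round-trips on 150 randomized
tables per run, and the 106-record replica for everything integration-
shaped. The replica's CSV exports are frozen by golden checksums, so
any change to its script is a deliberate, versioned event.

## Known limitations

Single-writer by design; no concurrent ledger access. Names are local
persistent identifiers — no UUID/DOI layer. Attachments are path
references, never stored payloads. Two transfections identical in
date+fp+gene+guide cannot coexist; the registry rejects the duplicate
and the user must vary a token. No synonym/ontology mapping for
vocabulary terms, and no statistics over the summaries — at three
transfections and fifteen clones, the honest output is a table, not an
inference.
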