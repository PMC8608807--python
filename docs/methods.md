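# Methods

This note documents the models, algorithms and numerical choices behind
colstore, what the synthetic-data generator does and does not emulate,
and the limitations a user should know about.

## Data model

A *dataset* is one HDF5 file holding named tables; a *table* is a set of
equal-length named *fields* (columns). Fields come in two backings:
drive-backed fields read lazily from their HDF5 datasets; memory fields
are produced by operations (filters, gathers, arithmetic) and become
drive-backed only when explicitly written to a table. There is no
automatic spill of memory fields: the user loads one column at a time,
which is practical precisely because storage is purely column-local.

Five field kinds exist:

| kind           | storage                             | order for sorting |
|----------------|-------------------------------------|-------------------|
| numeric        | one typed 1-D array (int8..64, uint8..64, float32/64, bool) | numeric |
| timestamp      | float64 POSIX seconds, UTC          | numeric |
| categorical    | small-integer codes + code→label key | by code |
| fixed string   | `S<width>` bytes, width = UTF-8 byte capacity | bytewise |
| indexed string | int64 offsets (n+1) + one uint8 byte buffer | bytewise |

Strings are UTF-8 throughout; fixed-string width counts encoded bytes.
Indexed-string offsets are 64-bit so a value buffer may exceed 4 GiB.
String comparison is bytewise on the encoding — appropriate for the
hex-style keys these datasets use; no locale collation is attempted.

Missingness is represented uniformly as a boolean *validity* companion
(`<name>_valid`) plus a configurable in-band default, never as NaN/null:
this works identically for integer, string and categorical kinds, and
keeps every stored array a plain fixed-dtype column. Gathers through a
join map use the sentinel −1 for unmatched rows and mark them invalid.

Every field supports iteration in caller-chosen chunk lengths (default
2^20 elements); the streaming phases below are built on that contract.

## Import

Import converts CSV text to typed fields in a single pass, in chunks of
`chunk_rows` (default 2^16) rows; conversion is chunk-local, so the
resulting store is bit-identical under any chunking. The CSV dialect is
RFC 4180 (doubled-quote escaping, cells may contain separators and
newlines), UTF-8 with an optional BOM.

Per-type conversions:

* **numeric** — empty cell → `invalid_default` with flag False;
  non-empty unparseable cell → error citing the row (`strict`, the
  default) or treated as empty (`lenient`, a per-field schema flag).
  Source data of this kind is typically only minimally validated
  upstream, so the policy is the schema author's choice.
* **categorical** — every cell must be in the label→code key; a missing
  label is a row-addressed error.
* **leaky categorical** — cells in the key take their code; anything
  else takes the designated `freetext_code` (which must lie outside the
  key) and the raw text goes to an indexed-string companion. Since most
  entries are then empty, the companion costs ~8 bytes/row plus actual
  text.
* **datetime** — ISO-8601 date or datetime, interpreted as UTC (the
  sources carry no zone information; a fixed convention keeps day
  arithmetic consistent). Optionally a `<name>_day` field quantised to
  midnight UTC (`floor(t / 86400) * 86400`) and, when empties are
  allowed, a validity flag.

Export (`export_csv`) writes canonical text — invalid entries as empty
cells, floats as shortest round-tripping decimals, categoricals as
labels, timestamps as ISO — chosen so export → import is the identity
on the stored bytes; the test suite asserts this round trip.

## Sorting

`argsort_stable` produces a permutation; stability (equal keys keep
their original order) is the load-bearing property, not any particular
algorithm (numpy's stable mergesort path is used). Two compositions
build on it:

* **Multi-key** (`multi_key_argsort`): successive stable single-key
  argsorts applied from the least significant key to the most
  significant, each re-sorting the previously accumulated order. Only
  one key column is resident at a time and no row tuples are formed.
* **External** (`external_argsort`): the key is cut into chunks of
  `chunk_length`; each chunk is argsorted stably and kept as a run of
  (sorted values, original indices) — in RAM, or spilled to a temporary
  HDF5 store when a `spill_dir` is given (string runs stay in RAM). The
  merge phase holds one block-buffered cursor per run (block =
  min(chunk, 2^16) elements) and a heap keyed by
  `(value, run_index, position_in_run)`. Runs are formed left to right,
  so the heap key reproduces global stability and the output is
  bit-identical to the in-memory stable sort — a property test asserts
  this for chunk lengths down to 1. NaN keys are not supported in the
  merge phase (NaN comparisons would corrupt heap order).

Applying a permutation to a table (`sort_dataframe`) computes the
permutation once, then rewrites each field in turn, buffering one whole
source column plus one output chunk — single-column residency, which is
the scaling contract of the column-local design.

## Joins

`ordered_join_maps` walks two sorted key columns with block-buffered
cursors (sortedness is verified as a side effect, end to end) and emits
two per-output-row index maps with −1 for unmatched rows. Equal-key
runs on both sides produce their Cartesian product — SQL semantics, so
a relational database can serve as an oracle — enumerated by key, then
left occurrence, then right occurrence. Key element reads are counted
and bounded by m + n + output size (asserted in tests). `merge` applies
the maps to every requested field; unsorted keys are sorted internally
and the sort permutations composed into the maps, so both paths yield
identical row multisets. Name collisions on the right take the suffix
`_r`; key columns are written once from the preserved side. Hash joins
and full outer joins are out of scope.

## Aggregation

`compute_spans` finds the boundaries of equal-key runs in a sorted
(possibly composite) key, chunk by chunk with a carried last-key;
`apply_spans` then reduces any field over those spans in blocks of
`span_block` spans (default 2^15), using `ufunc.reduceat` for numeric
kinds. Reducers: count, min, max, sum, mean, first, last. Invalid rows
are excluded from min/max/sum/mean; `count` counts all rows; a group
with no valid entry yields the default with an output validity flag of
False (not NaN), keeping aggregation outputs typed like their inputs.
min/max on categoricals compare codes — the schema author orders codes
by severity. Results are invariant to `span_block` by construction and
by test.

`quantise_daily_max` implements the daily-report rule: rows are sorted
by (person, UTC calendar day); within each group every symptom column
takes its maximum and all other columns take the first observation of
the day (a tie-break the data does not determine; "first" is the
documented choice). The assessed columns are materialised one at a time
during this operation.

## Journalling

`journal(old, new, dest, key, old_ts, new_ts)` stably sorts both
snapshots by key, aligns key groups by an ordered merge, and compares
aligned rows over the fields common to both snapshots (fields present
in only one schema are ignored; validity companions are fields and so
participate; floats compare bitwise-or-both-NaN equal; indexed strings
by decoded value). Classification per key:

* only in old → the old row, interval `[old_ts, new_ts)` — the row was
  deleted at the new snapshot, so it must not survive a filter at
  `new_ts`;
* only in new → the new row, `[new_ts, ∞)`;
* in both, equal → one row, `[old_ts, ∞)`;
* in both, different → old row `[old_ts, new_ts)` + new row
  `[new_ts, ∞)`.

The open end is +inf in the `j_valid_to` timestamp field. These
intervals are fixed by the round-trip requirement: `snapshot_at(dest,
t)` must reproduce the snapshot live at t for both endpoints, and the
test suite asserts exactly that. The five returned counts satisfy, for
unique keys: old = only_old + updated + not_updated; new = old −
only_old + only_new; journalled = old + only_new + updated.

Duplicate keys within a snapshot are aligned positionally after the
stable sort; surplus group members are classified only-old/only-new.
Real cohort tables do contain duplicate-key rows, and no principled
pairing exists without a version column, so positional alignment is the
documented convention. `journal_many` folds a timestamp-ordered
sequence of snapshots pairwise, threading each surviving row's original
`j_valid_from` forward so long-lived rows keep their first-seen time.
The journalling step itself materialises the snapshot pair being
compared; it is not streamed.

## Synthetic data

The generator emulates the *structure* of a self-report cohort, not its
content distributions:

* **left table** (patients): 32-hex-char unique ids in shuffled order;
  an integer age with ~10% empty cells; a float height; a leaky
  severity column with ~5% free text; a fixed-width country code; an
  ISO datetime; and a notes column, present in ~35% of rows, up to 600
  bytes long (the observed maximum for free text in this kind of data),
  with a configurable fraction (default 10%) of entries containing
  commas, double quotes and newlines to stress CSV quoting.
* **right table** (assessments): per-parent child counts drawn
  Poisson(`mean_children`), mean 10 by default — the stated structure
  of the real parent/child relationship; only the mean is specified
  there, and Poisson is the natural count model for it. Children carry
  the parent id, a timestamp inside a six-month window (several per day
  possible, exercising daily quantisation), a temperature with ~10%
  empties, and two ordered symptom categoricals.
* **snapshot pairs**: `new` = `old` with ⌊removed·n⌋ rows deleted,
  ⌊added·n⌋ inserted and ⌊updated·n⌋ altered in at least one common
  field (age incremented and a marker appended to notes — both always
  produce a detectable difference), with exact bookkeeping returned as
  the journalling ground truth.

Determinism: ids are MD5 hashes of `seed:tag:index`; all draws come
from `numpy.random.default_rng(seed)` streams consumed in a fixed
order, so identical configurations produce byte-identical CSVs.

What passing tests therefore show: the engine's *mechanics* — typed
import fidelity, stability, join/aggregation correctness, journal
classification — on data with realistic key structure, missingness,
dirty categoricals and hostile CSV quoting. What they do not show:
behaviour under real-world value distributions, schema drift between
snapshots, duplicate-key semantics of any particular upstream database,
or wall-clock performance on hundred-gigabyte inputs.

## Problem sizes and verification

The test suite checks every operation against an independent oracle:
brute-force stable tuple sorts, nested-loop SQL joins, per-group
reductions (including pandas cross-checks), a per-(person, day) maximum
oracle, and the snapshot generator's planted-edit bookkeeping. The
larger end-to-end checks run at 10^5 parents with ~10^6 children for
the full workflow, 10^6 rows for the streaming/memory-contract checks
(chunk 10^4), and 10^5 elements for external-sort equivalence —
desk-scale instances chosen so the whole suite completes in a couple of
minutes while still exercising the chunked code paths many chunks deep.
`scripts/acceptance.py` reruns the pipeline at 2×10^4 parents and
reports only quantities it computes in that run.

## Known limitations

* Single-core, like the design it follows; no task scheduling or
  distribution.
* Memory fields never spill automatically; operations such as
  permutation application hold one full column in RAM.
* Join-map and journal outputs are built in memory; they scale to
  desk-size outputs, not to billion-row joins.
* NaN sort keys and locale-aware string collation are unsupported.
* No compression; no multi-dimensional values; no hash joins or full
  outer joins; no general unsorted (hash) group-by.
* HDF5 concurrency limits apply: one writer, no simultaneous readers
  of a file being written.
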