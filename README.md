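# colstore

Out-of-core, column-local curation of large keyed tabular datasets —
the kind produced by citizen-science cohort studies in which millions of
participants log daily self-reports. Data arrives as periodic CSV
snapshots with parent/child structure (a patient table, an assessment
table keyed by `patient_id`, ...); the tables quickly outgrow what
RAM-resident dataframes can hold, and successive snapshots silently
overwrite changed rows. colstore is for researchers and data engineers
who need to type, clean, link and longitudinally reconcile such tables
on a commodity machine.

## Design

Everything rests on three ideas:

1. **Pure column-local storage.** Each field (column) is stored as its
   own contiguous, typed HDF5 dataset — no row blocks, no 2-D layouts.
   Reading *k* columns costs *k* contiguous reads regardless of table
   width, and a single column fits in memory even when the table does
   not. Variable-length strings are stored as an *indexed string*
   field: one concatenated UTF-8 byte buffer plus an `int64` offset
   array of length n+1 (empty entries are repeated offsets), so storage
   is proportional to total text bytes rather than
   (longest entry) × (rows).

2. **Sorts produce permutations; work happens on sorted keys.** A sort
   yields a permutation index that is applied lazily to any number of
   columns. Multi-key sorts compose stable single-key argsorts from the
   least significant key to the most significant; columns too long for
   memory are sorted in chunks whose sorted runs are merged through a
   heap of cursors keyed by `(value, run, position)`, which preserves
   global stability. Once keys are sorted, joins become ordered merges
   in O(m + n + output) and group aggregation becomes iteration over
   *spans* — the boundaries of equal-key runs.

3. **Snapshots are journalled, not overwritten.** Two snapshots of a
   keyed table are merged into one journalled table in which every row
   version carries a validity interval `[j_valid_from, j_valid_to)`
   (open ends are +inf). A row changed between snapshots contributes
   both versions; filtering the journal at any time t reproduces the
   snapshot that was live at t.

Import is schema-driven: a JSON document assigns each CSV column one of
six conversions (`fixed_string`, `indexed_string`, `numeric`,
`categorical`, `leaky_categorical`, `datetime`), with dirty columns
*split* rather than rejected — empty numerics become a default value
plus a presence flag, and "leaky" categoricals (a closed label set
contaminated with free text) become a code column plus an
indexed-string companion holding the raw text.

## Worked example

```sh
# generate a synthetic cohort: 1000 patients, ~10 assessments each
colstore synth left  --n 1000 --seed 1 --out patients.csv
colstore synth right --left-csv patients.csv --seed 1 \
    --out assessments.csv --schema-out schema.json

# typed, streaming import into one HDF5 store
colstore import --schema schema.json \
    --input patients:patients.csv --input assessments:assessments.csv \
    --output cohort.h5
```

which prints

```
10067 rows
patients: 1000 rows
assessments: 10067 rows
```

— 1000 parents and 10,067 children (Poisson with mean 10 per parent).
Analysis then runs through the library:

```python
from colstore import Dataset, merge, quantise_daily_max, sort_dataframe

with Dataset("cohort.h5", "readwrite") as ds:
    srt = ds.create_dataframe("sorted")
    sort_dataframe(ds["assessments"], ["patient_id", "created_at"], srt)

    joined = ds.create_dataframe("joined")
    n = merge(srt, ds["patients"], joined,
              left_on="patient_id", right_on="id", how="left")
    print("joined rows:", n)

    daily = ds.create_dataframe("daily")
    nq = quantise_daily_max(srt, daily, symptoms=["fatigue", "cough"])
    print("daily rows:", nq)
```

```
joined rows: 10067
daily rows: 9796
```

Every assessment row gains its patient's attributes (the left join
preserves all 10,067 child rows), and same-day repeat reports collapse
to one row per patient per UTC day carrying each symptom's daily
maximum — 9,796 daily rows here.

Journalling two snapshots of the patient table:

```sh
colstore synth pair --n 1000 --seed 5 --removed 0.01 --added 0.02 \
    --updated 0.05 --old-out old.csv --new-out new.csv
colstore import --schema schema.json --input patients:old.csv --output old.h5
colstore import --schema schema.json --input patients:new.csv --output new.h5
colstore journal --old old.h5 --new new.h5 --output journal.h5 \
    --table patients --key id --old-ts 2020-08-01 --new-ts 2020-09-01
```

```
Rows only in old: 10
Rows only in new: 20
Rows updated: 50
Rows not updated: 940
Journalled row count: 1070
```

The counts classify every key: 10 rows disappeared, 20 appeared, 50
changed in at least one field (both versions are kept), 940 were
untouched. The journal holds 1070 rows = 1000 old + 20 new-only + 50
updated versions.

## On-disk layout

One HDF5 group per table (attribute `row_count`); one subgroup per
field with a JSON attribute `fieldtype` holding the kind and its
parameters (`width` for fixed strings, `value_type` for numerics, the
code→label `key` and optional `freetext_code` for categoricals), and a
1-D resizable dataset `values` — plus `index` (int64, length n+1) for
indexed strings. Companion fields generated by import use the suffixes
`_valid`, `_freetext` and `_day`.
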