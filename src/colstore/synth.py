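"""Deterministic synthetic data shaped like a citizen-science cohort.

Two related tables are emulated: a *left* (patient-like) table keyed by a
32-hex-character id, and a *right* (assessment-like) table in which each
parent has a Poisson-distributed number of child rows — mean 10 by
default — carrying the parent id as a foreign key. The left table
exercises every field kind: a numeric column with ~10% empty cells, a
leaky categorical with ~5% free text, an ISO datetime, a fixed-width
country code, and a long free-text column with entries up to 600 bytes.
A configurable fraction of text cells contains commas, double quotes and
newlines to stress CSV quoting.

Snapshot pairs with planted edits (removed / added / updated row
fractions) are generated together with exact bookkeeping of those edits,
so journalling results can be checked against ground truth.

All output is a deterministic function of the seed: ids are derived by
hashing ``seed:index`` and every random draw comes from one
``numpy.random.default_rng(seed)`` stream consumed in a fixed order.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np

from .journalling import JournalCounts

_WORDS = (
    "feeling tired all day slight fever and headache cough worse at night "
    "lost sense of smell appetite low back to normal today chills after "
    "walking sore throat mild fatigue persistent could not sleep muscle "
    "ache shortness of breath better than yesterday naïve café 发烧 头痛"
).split()

_SEVERITY_KEY = {"": 0, "mild": 1, "moderate": 2, "severe": 3}
_COUNTRY = ["uk", "us", "se"]
_SYMPTOM_KEY = {"none": 0, "mild": 1, "moderate": 2, "severe": 3}

_T0 = 1583020800.0  # 2020-03-01T00:00:00Z
_T1 = 1598918400.0  # 2020-09-01T00:00:00Z


@dataclass
class SynthConfig:
    """Study conditions for the generators.

    ``mean_children`` mirrors the cohort's mean of 10 assessment entries
    per patient; the change fractions plant known edits in snapshot
    pairs; ``messy_text_fraction`` controls how many text cells contain
    CSV-hostile characters.
    """
    n_left: int = 1000
    mean_children: float = 10.0
    seed: int = 0
    removed: float = 0.0
    added: float = 0.0
    updated: float = 0.0
    messy_text_fraction: float = 0.1


def _hex_id(seed: int, tag: str, i: int) -> str:
    return hashlib.md5(f"{seed}:{tag}:{i}".encode()).hexdigest()


def _iso(ts: float) -> str:
    import datetime as _dt
    return _dt.datetime.fromtimestamp(ts, tz=_dt.timezone.utc) \
        .strftime("%Y-%m-%dT%H:%M:%S")


def _text(rng: np.random.Generator, max_bytes: int, messy: bool) -> str:
    words = []
    size = 0
    target = int(rng.integers(10, max_bytes))
    while size < target:
        w = _WORDS[int(rng.integers(0, len(_WORDS)))]
        if size + len(w.encode("utf-8")) + 1 > max_bytes:
            break
        words.append(w)
        size += len(w.encode("utf-8")) + 1
    s = " ".join(words)
    if messy and s:
        pos = len(s) // 2
        s = s[:pos] + ', "quoted",\n' + s[pos:]
        s = s.encode("utf-8")[:max_bytes].decode("utf-8", "ignore")
    return s


def _left_rows(config: SynthConfig) -> list[dict]:
    rng = np.random.default_rng(config.seed)
    n = config.n_left
    ids = [_hex_id(config.seed, "L", i) for i in range(n)]
    order = rng.permutation(n)
    age_empty = rng.random(n) < 0.10
    ages = rng.integers(18, 99, n)
    heights = np.round(rng.normal(170.0, 10.0, n), 1)
    sev_choice = rng.integers(0, 4, n)
    sev_free = rng.random(n) < 0.05
    country = rng.integers(0, 3, n)
    created = _T0 + rng.random(n) * (_T1 - _T0 - 1)
    notes_present = rng.random(n) < 0.35
    notes_messy = rng.random(n) < config.messy_text_fraction
    sev_labels = ["", "mild", "moderate", "severe"]

    rows = []
    for j in range(n):
        i = int(order[j])
        if sev_free[i]:
            severity = _text(rng, 40, False) or "hard to say"
        else:
            severity = sev_labels[int(sev_choice[i])]
        notes = _text(rng, 600, bool(notes_messy[i])) \
            if notes_present[i] else ""
        rows.append({
            "id": ids[i],
            "age": "" if age_empty[i] else str(int(ages[i])),
            "height_cm": repr(float(np.float32(heights[i]))),
            "severity": severity,
            "country": _COUNTRY[int(country[i])],
            "created_at": _iso(float(np.floor(created[i]))),
            "notes": notes,
        })
    return rows


_LEFT_COLUMNS = ["id", "age", "height_cm", "severity", "country",
                 "created_at", "notes"]
_RIGHT_COLUMNS = ["id", "patient_id", "created_at", "temperature",
                  "fatigue", "cough"]


def _write_csv(path, columns, rows) -> None:
    with open(path, "w", encoding="utf-8", newline="") as f:
        w = csv.writer(f, lineterminator="\n")
        w.writerow(columns)
        for r in rows:
            w.writerow([r[c] for c in columns])


def generate_left(config: SynthConfig, path) -> list[str]:
    """Write the parent (patient-like) table as CSV; returns the ids in
    file order."""
    rows = _left_rows(config)
    _write_csv(path, _LEFT_COLUMNS, rows)
    return [r["id"] for r in rows]


def generate_right(left_ids, config: SynthConfig, path) -> int:
    """Write the child (assessment-like) table as CSV; returns the row
    count. Child counts are Poisson(``mean_children``) per parent, zero
    allowed; rows are shuffled."""
    rng = np.random.default_rng(config.seed + 1)
    counts = rng.poisson(config.mean_children, len(left_ids))
    total = int(counts.sum())
    sym_labels = list(_SYMPTOM_KEY)
    parent = np.repeat(np.arange(len(left_ids)), counts)
    created = _T0 + rng.random(total) * (_T1 - _T0 - 1)
    temp_empty = rng.random(total) < 0.10
    temps = np.round(rng.normal(36.8, 0.6, total), 1)
    fatigue = rng.integers(0, 4, total)
    cough = rng.integers(0, 4, total)
    order = rng.permutation(total)

    with open(path, "w", encoding="utf-8", newline="") as f:
        w = csv.writer(f, lineterminator="\n")
        w.writerow(_RIGHT_COLUMNS)
        for j in range(total):
            i = int(order[j])
            w.writerow([
                _hex_id(config.seed, "R", i),
                left_ids[int(parent[i])],
                _iso(float(np.floor(created[i]))),
                "" if temp_empty[i] else repr(float(np.float32(temps[i]))),
                sym_labels[int(fatigue[i])],
                sym_labels[int(cough[i])],
            ])
    return total


def generate_snapshot_pair(config: SynthConfig, old_path, new_path
                           ) -> JournalCounts:
    """Write an (old, new) snapshot pair of the left table with planted
    edits, returning their exact bookkeeping.

    ``new`` is ``old`` with ``floor(removed*n)`` rows deleted,
    ``floor(added*n)`` rows inserted and ``floor(updated*n)`` rows
    altered in at least one common field; the returned counts are the
    ground truth a journalling run must recover.
    """
    for frac in (config.removed, config.added, config.updated):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("change fractions must be within [0, 1]")
    n = config.n_left
    n_removed = int(config.removed * n)
    n_added = int(config.added * n)
    n_updated = int(config.updated * n)
    if n_removed + n_updated > n:
        raise ValueError("removed + updated fractions exceed the table")

    rows = _left_rows(config)
    _write_csv(old_path, _LEFT_COLUMNS, rows)

    rng = np.random.default_rng(config.seed + 2)
    picks = rng.permutation(n)
    removed_set = set(picks[:n_removed].tolist())
    updated_set = set(picks[n_removed:n_removed + n_updated].tolist())

    new_rows = []
    for i, r in enumerate(rows):
        if i in removed_set:
            continue
        if i in updated_set:
            r = dict(r)
            r["age"] = str((int(r["age"]) + 1) % 100) if r["age"] else "44"
            r["notes"] = (r["notes"] + " [revised]").strip()
            new_rows.append(r)
        else:
            new_rows.append(r)

    add_cfg = SynthConfig(n_left=n_added, seed=config.seed + 3,
                          messy_text_fraction=config.messy_text_fraction)
    for r in _left_rows(add_cfg):
        r = dict(r)
        r["id"] = _hex_id(config.seed, "A", len(new_rows))
        new_rows.append(r)

    order = rng.permutation(len(new_rows))
    _write_csv(new_path, _LEFT_COLUMNS, [new_rows[int(j)] for j in order])

    return JournalCounts(
        rows_only_old=n_removed,
        rows_only_new=n_added,
        rows_updated=n_updated,
        rows_not_updated=n - n_removed - n_updated,
        journalled_row_count=n + n_added + n_updated,
    )


# ---------------------------------------------------------------------------
# matching import schemas


def left_schema_dict() -> dict:
    return {"schema": {"patients": {
        "primary_keys": ["id"],
        "foreign_keys": {},
        "fields": {
            "id": {"field_type": "fixed_string", "width": 32},
            "age": {"field_type": "numeric", "value_type": "int32",
                    "invalid_default": -1, "create_flag": True},
            "height_cm": {"field_type": "numeric", "value_type": "float32",
                          "invalid_default": 0.0, "create_flag": False},
            "severity": {"field_type": "leaky_categorical",
                         "key": _SEVERITY_KEY, "freetext_code": -1},
            "country": {"field_type": "categorical",
                        "key": {c: i for i, c in enumerate(_COUNTRY)}},
            "created_at": {"field_type": "datetime", "create_day": True,
                           "optional": False},
            "notes": {"field_type": "indexed_string"},
        },
    }}}


def right_schema_dict() -> dict:
    return {"schema": {
        "patients": left_schema_dict()["schema"]["patients"],
        "assessments": {
            "primary_keys": ["id"],
            "foreign_keys": {"patient_id": "patients"},
            "fields": {
                "id": {"field_type": "fixed_string", "width": 32},
                "patient_id": {"field_type": "fixed_string", "width": 32},
                "created_at": {"field_type": "datetime", "create_day": True,
                               "optional": False},
                "temperature": {"field_type": "numeric",
                                "value_type": "float32",
                                "invalid_default": 0.0, "create_flag": True},
                "fatigue": {"field_type": "categorical",
                            "key": _SYMPTOM_KEY},
                "cough": {"field_type": "categorical", "key": _SYMPTOM_KEY},
            },
        },
    }}


def write_schema(path, which: str = "both") -> None:
    doc = right_schema_dict() if which in ("both", "right") \
        else left_schema_dict()
    with open(path, "w", encoding="utf-8") as f:
        json.dump(doc, f, indent=2, ensure_ascii=False)


def write_ground_truth(path, counts: JournalCounts) -> None:
    with open(path, "w", encoding="utf-8") as f:
        json.dump(counts.as_dict(), f, indent=2)
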