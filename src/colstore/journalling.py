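"""Journalling: merge timestamped table snapshots without losing history.

Live databases exported as periodic snapshots silently overwrite changed
rows; comparing successive snapshots is the only way to recover what
changed. :func:`journal` combines an *old* and a *new* snapshot of a
keyed table into a single journalled table in which every row version
carries a validity interval ``[j_valid_from, j_valid_to)``:

* key only in old  -> the old row, valid ``[old_ts, new_ts)`` (the row
  disappeared at the new snapshot);
* key only in new  -> the new row, valid ``[new_ts, open)``;
* key in both, all common fields equal -> a single row, ``[old_ts, open)``;
* key in both, any common field different -> the old row closed at
  ``[old_ts, new_ts)`` plus the new row ``[new_ts, open)``.

The open end is encoded as +infinity. Filtering the journalled table to
rows whose interval contains a time t (:func:`snapshot_at`) reproduces
the snapshot that was live at t.

Row comparison covers the fields common to both snapshots (validity-flag
companions are themselves fields and so take part); floats compare
bitwise-or-both-NaN equal, variable-length strings by decoded value.
Duplicate keys within a snapshot are aligned positionally after a stable
sort; group-size mismatches classify the unmatched members as
only-old / only-new.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fields as fld
from .fields import DEFAULT_CHUNK
from .sorting import multi_key_argsort

#: Open-ended validity sentinel.
OPEN_END = np.inf

_META_FIELDS = ("j_valid_from", "j_valid_to")


@dataclass
class JournalCounts:
    """Per-key classification tallies of one journalling step."""
    rows_only_old: int = 0
    rows_only_new: int = 0
    rows_updated: int = 0
    rows_not_updated: int = 0
    journalled_row_count: int = 0

    def as_dict(self) -> dict:
        return {
            "rows_only_old": self.rows_only_old,
            "rows_only_new": self.rows_only_new,
            "rows_updated": self.rows_updated,
            "rows_not_updated": self.rows_not_updated,
            "journalled_row_count": self.journalled_row_count,
        }


def common_fields(old, new) -> list[str]:
    """Field names present in both tables, journal metadata excluded,
    in the old table's order."""
    new_names = set(new.keys())
    return [n for n in old.keys()
            if n in new_names and n not in _META_FIELDS]


def _materialise(df, names):
    out = {}
    for n in names:
        f = df[n]
        out[n] = f.to_memory() if hasattr(f, "to_memory") else f
    return out


def _eq_arrays(a: fld.Field, b: fld.Field) -> np.ndarray:
    """Elementwise row equality between two equal-length columns."""
    if a.kind != b.kind:
        return np.zeros(len(a), dtype=bool)
    if a.kind == "indexed_string":
        return a.byte_entries() == b.byte_entries()
    if a.kind == "categorical" and a.key != b.key:
        return np.array([x == y for x, y in zip(a.labels(), b.labels())])
    da, db = a.data, b.data
    if da.dtype.kind == "f" and db.dtype.kind == "f":
        return (da == db) | (np.isnan(da) & np.isnan(db))
    return da == db


def _pairs_equal(old_cols: dict, new_cols: dict, old_idx: np.ndarray,
                 new_idx: np.ndarray, names) -> np.ndarray:
    """For aligned row pairs ``(old_idx[i], new_idx[i])``: are all common
    fields equal?"""
    eq = np.ones(len(old_idx), dtype=bool)
    for n in names:
        a = old_cols[n].apply_index(old_idx)
        b = new_cols[n].apply_index(new_idx)
        eq &= _eq_arrays(a, b)
        if not eq.any():
            break
    return eq


def rows_equal(old, new, old_row: int, new_row: int,
               fields=None) -> bool:
    """Full comparison of one old row against one new row over the
    common fields."""
    names = fields if fields is not None else common_fields(old, new)
    old_cols = _materialise(old, names)
    new_cols = _materialise(new, names)
    return bool(_pairs_equal(old_cols, new_cols,
                             np.array([old_row]), np.array([new_row]),
                             names)[0])


def _group_starts(sort_keys: list[np.ndarray]) -> np.ndarray:
    n = len(sort_keys[0])
    if n == 0:
        return np.array([0], dtype=np.int64)
    changed = np.zeros(n - 1, dtype=bool)
    for k in sort_keys:
        changed |= k[1:] != k[:-1]
    return np.concatenate(([0], np.flatnonzero(changed) + 1, [n]))


def journal(old, new, dest, key_fields, old_ts: float,
            new_ts: float, old_from: np.ndarray | None = None
            ) -> JournalCounts:
    """Journal two snapshots of a keyed table into ``dest``.

    Both snapshots are sorted stably by ``key_fields`` and their key
    groups aligned by an ordered merge; each key is classified as
    only-old / only-new / updated / not-updated (see module docstring)
    and the surviving row versions are written to ``dest`` sorted by
    (key, j_valid_from), with ``j_valid_from`` / ``j_valid_to`` timestamp
    fields appended. Returns the classification counts.

    ``old_from`` optionally supplies a per-row valid-from for the old
    snapshot (row order as stored); multi-snapshot folding uses it so a
    row version opened several snapshots ago keeps its original start.
    """
    key_fields = [key_fields] if isinstance(key_fields, str) \
        else list(key_fields)
    for k in key_fields:
        if k not in old or k not in new:
            raise KeyError(f"key field {k!r} missing from a snapshot")
    if not old_ts < new_ts:
        raise ValueError("old_ts must precede new_ts")

    names = common_fields(old, new)
    old_cols = _materialise(old, names)
    new_cols = _materialise(new, names)

    o_order = multi_key_argsort([old_cols[k] for k in key_fields])
    n_order = multi_key_argsort([new_cols[k] for k in key_fields])
    old_cols = {k: v.apply_index(o_order) for k, v in old_cols.items()}
    new_cols = {k: v.apply_index(n_order) for k, v in new_cols.items()}
    if old_from is None:
        o_from = np.full(len(o_order), float(old_ts))
    else:
        o_from = np.asarray(old_from, dtype=np.float64)[o_order]

    o_keys = [old_cols[k].sort_keys() for k in key_fields]
    n_keys = [new_cols[k].sort_keys() for k in key_fields]
    o_bounds = _group_starts(o_keys)
    n_bounds = _group_starts(n_keys)

    def key_at(keys, i):
        return tuple(k[i] for k in keys)

    counts = JournalCounts()
    # emitted rows: (source 0=old / 1=new, row in sorted snapshot, from, to)
    src, row, vfrom, vto = [], [], [], []
    pair_old, pair_new, pair_slot = [], [], []

    oi, ni = 0, 0
    og, ng = len(o_bounds) - 1, len(n_bounds) - 1
    while oi < og or ni < ng:
        if ni >= ng or (oi < og and
                        key_at(o_keys, o_bounds[oi]) <
                        key_at(n_keys, n_bounds[ni])):
            s, e = int(o_bounds[oi]), int(o_bounds[oi + 1])
            for r in range(s, e):
                src.append(0); row.append(r)
                vfrom.append(float(o_from[r])); vto.append(new_ts)
            counts.rows_only_old += e - s
            oi += 1
        elif oi >= og or key_at(n_keys, n_bounds[ni]) < \
                key_at(o_keys, o_bounds[oi]):
            s, e = int(n_bounds[ni]), int(n_bounds[ni + 1])
            for r in range(s, e):
                src.append(1); row.append(r)
                vfrom.append(new_ts); vto.append(OPEN_END)
            counts.rows_only_new += e - s
            ni += 1
        else:
            os_, oe = int(o_bounds[oi]), int(o_bounds[oi + 1])
            ns_, ne = int(n_bounds[ni]), int(n_bounds[ni + 1])
            m = min(oe - os_, ne - ns_)
            # old-sourced versions first (j_valid_from == old_ts), in
            # positional order; the pair's interval end is patched once
            # equality is known.
            for p in range(m):
                pair_old.append(os_ + p)
                pair_new.append(ns_ + p)
                pair_slot.append(len(src))
                src.append(0); row.append(os_ + p)
                vfrom.append(float(o_from[os_ + p])); vto.append(OPEN_END)
            for r in range(os_ + m, oe):
                src.append(0); row.append(r)
                vfrom.append(float(o_from[r])); vto.append(new_ts)
            counts.rows_only_old += oe - os_ - m
            # new-sourced versions for updated pairs are appended after
            # equality is known (placeholder slots recorded)
            for r in range(ns_ + m, ne):
                src.append(1); row.append(r)
                vfrom.append(new_ts); vto.append(OPEN_END)
            counts.rows_only_new += ne - ns_ - m
            oi += 1
            ni += 1

    pair_old = np.asarray(pair_old, dtype=np.int64)
    pair_new = np.asarray(pair_new, dtype=np.int64)
    eq = _pairs_equal(old_cols, new_cols, pair_old, pair_new, names) \
        if len(pair_old) else np.empty(0, dtype=bool)
    counts.rows_not_updated = int(eq.sum())
    counts.rows_updated = int(len(eq) - eq.sum())

    # updated pairs: close the old version and splice in the new one
    # right after it, preserving (key, j_valid_from) order.
    insertions: dict[int, int] = {}
    for p in np.flatnonzero(~eq) if len(eq) else []:
        slot = pair_slot[p]
        vto[slot] = new_ts
        insertions[slot] = int(pair_new[p])

    f_src, f_row, f_from, f_to = [], [], [], []
    for i in range(len(src)):
        f_src.append(src[i]); f_row.append(row[i])
        f_from.append(vfrom[i]); f_to.append(vto[i])
        if i in insertions:
            f_src.append(1); f_row.append(insertions[i])
            f_from.append(new_ts); f_to.append(OPEN_END)

    f_src = np.asarray(f_src, dtype=np.int64)
    f_row = np.asarray(f_row, dtype=np.int64)
    counts.journalled_row_count = len(f_src)

    old_sel = np.flatnonzero(f_src == 0)
    new_sel = np.flatnonzero(f_src == 1)
    for n in names:
        a = old_cols[n].apply_index(f_row[old_sel]) if len(old_sel) \
            else old_cols[n].apply_index(np.empty(0, dtype=np.int64))
        b = new_cols[n].apply_index(f_row[new_sel]) if len(new_sel) \
            else new_cols[n].apply_index(np.empty(0, dtype=np.int64))
        dest.write(n, _interleave(a, b, old_sel, new_sel, len(f_src)))
    dest.write("j_valid_from",
               fld.TimestampField(np.asarray(f_from, dtype=np.float64)))
    dest.write("j_valid_to",
               fld.TimestampField(np.asarray(f_to, dtype=np.float64)))
    dest.finish()
    return counts


def _interleave(a: fld.Field, b: fld.Field, a_pos, b_pos, n: int) -> fld.Field:
    """Scatter two gathered columns back into one output column."""
    take_from = np.empty(n, dtype=np.int64)
    take_from[a_pos] = np.arange(len(a_pos))
    take_from[b_pos] = len(a_pos) + np.arange(len(b_pos))
    combined = _concat_fields(a, b)
    return combined.apply_index(take_from)


def _concat_fields(a: fld.Field, b: fld.Field) -> fld.Field:
    if a.kind == "indexed_string":
        return fld.IndexedStringField.from_strings(a.tolist() + b.tolist())
    data = np.concatenate([a.data, b.data])
    if a.kind == "numeric":
        return fld.NumericField(data)
    if a.kind == "timestamp":
        return fld.TimestampField(data)
    if a.kind == "categorical":
        return fld.CategoricalField(data, a.key, freetext_code=a.freetext_code)
    if a.kind == "fixed_string":
        width = max(a.width, b.width)
        return fld.FixedStringField(data.astype(f"S{width}"), width)
    raise TypeError(f"cannot concatenate {a.kind} fields")  # pragma: no cover


def snapshot_at(journalled, ts: float) -> dict[str, fld.Field]:
    """Rows whose validity interval contains ``ts``, as memory fields
    (journal metadata dropped). With unique keys this reproduces the
    snapshot that was live at ``ts``."""
    vfrom = journalled["j_valid_from"].data
    vto = journalled["j_valid_to"].data
    mask = (vfrom <= ts) & (ts < vto)
    out = {}
    for name in journalled.keys():
        if name in _META_FIELDS:
            continue
        f = journalled[name]
        mem = f.to_memory() if hasattr(f, "to_memory") else f
        out[name] = mem.apply_filter(mask)
    return out


def journal_many(snapshots, dest, key_fields, timestamps) -> JournalCounts:
    """Fold a timestamp-ordered sequence of snapshots into one journal.

    Realised pairwise: each step journals the currently-open row versions
    against the next snapshot; closed versions accumulate. Returns the
    counts of the final step.
    """
    from .dataset import Dataset
    import tempfile
    import os as _os

    snapshots = list(snapshots)
    timestamps = list(timestamps)
    if len(snapshots) != len(timestamps) or len(snapshots) < 2:
        raise ValueError("need >= 2 snapshots with matching timestamps")
    if any(b <= a for a, b in zip(timestamps, timestamps[1:])):
        raise ValueError("timestamps must be strictly increasing")

    fd, tmp = tempfile.mkstemp(suffix=".h5", prefix="colstore-journal-")
    _os.close(fd)
    counts = JournalCounts()
    try:
        with Dataset(tmp, "write") as scratch:
            current = snapshots[0]
            closed: list[dict] = []
            step = 0
            for nxt, t0, t1 in zip(snapshots[1:], timestamps[:-1],
                                   timestamps[1:]):
                step += 1
                stage = scratch.create_dataframe(f"stage{step}")
                prev_from = current["j_valid_from"].data \
                    if "j_valid_from" in current.keys() else None
                counts = journal(current, nxt, stage, key_fields, t0, t1,
                                 old_from=prev_from)
                vto = stage["j_valid_to"].data
                open_mask = np.isinf(vto)
                closed.append({n: stage[n].to_memory()
                                   .apply_filter(~open_mask)
                               for n in stage.keys()})
                opened = scratch.create_dataframe(f"open{step}")
                for n in stage.keys():
                    opened.write(n, stage[n].to_memory()
                                 .apply_filter(open_mask))
                opened.finish()
                current = opened
            # final journal = closed versions + still-open versions
            open_cols = {n: current[n].to_memory() for n in current.keys()}
            all_names = list(open_cols.keys())
            for n in all_names:
                pieces = [c[n] for c in closed] + [open_cols[n]]
                combined = pieces[0]
                for p in pieces[1:]:
                    combined = _concat_fields_any(combined, p)
                dest.write(n, combined)
            # keep deterministic (key, j_valid_from) order
            key_fields_l = [key_fields] if isinstance(key_fields, str) \
                else list(key_fields)
            order = multi_key_argsort(
                [dest[k].to_memory() for k in key_fields_l]
                + [dest["j_valid_from"].to_memory()])
            for n in list(dest.keys()):
                dest.write(n, dest[n].to_memory().apply_index(order))
            dest.finish()
    finally:
        _os.unlink(tmp)
    counts.journalled_row_count = dest.row_count
    return counts


def _concat_fields_any(a: fld.Field, b: fld.Field) -> fld.Field:
    if len(a) == 0:
        return b
    if len(b) == 0:
        return a
    return _concat_fields(a, b)
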