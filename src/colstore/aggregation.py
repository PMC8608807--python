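"""Span-based streaming aggregation over sorted keys.

Once a table is sorted by its aggregation key, every group is a
contiguous run. *Spans* are the boundaries of those runs — an array of
strictly increasing row offsets starting at 0 and ending at n — computed
once and reused for any number of per-group reductions. Reductions stream
over blocks of spans, so only one block's worth of rows is resident at a
time and the result is invariant to the block size chosen.

Includes the daily-assessment quantisation rule: multiple reports by one
person within one UTC calendar day collapse to a single row carrying, for
each symptom column, the maximum value reported that day.
"""

from __future__ import annotations

import numpy as np

from . import fields as fld
from .fields import DEFAULT_CHUNK
from .sorting import multi_key_argsort

REDUCERS = ("count", "min", "max", "sum", "mean", "first", "last")


def compute_spans(keys, chunk_length: int = DEFAULT_CHUNK) -> np.ndarray:
    """Boundaries of equal-key runs in sorted key column(s).

    ``keys`` is a field or a list of fields (composite key, compared as a
    tuple). Returns ``boundaries`` with ``boundaries[0] == 0`` and
    ``boundaries[-1] == n``; the key is constant within
    ``[boundaries[i], boundaries[i+1])`` and changes across adjacent
    spans. Verifies the key is non-decreasing; violation raises
    ``ValueError``.
    """
    keys = keys if isinstance(keys, (list, tuple)) else [keys]
    n = len(keys[0])
    if n == 0:
        return np.array([0], dtype=np.int64)
    change_points = [0]
    carry = None  # last key tuple of the previous chunk
    for start in range(0, n, chunk_length):
        stop = min(start + chunk_length, n)
        cols = [np.asarray(k.sort_key_slice(start, stop)) for k in keys]
        # lexicographic sorted-order check + change detection, vectorised
        undecided = np.ones(stop - start - 1, dtype=bool)
        violation = np.zeros(stop - start - 1, dtype=bool)
        changed = np.zeros(stop - start - 1, dtype=bool)
        for c in cols:
            lt = c[1:] < c[:-1]
            eq = c[1:] == c[:-1]
            violation |= undecided & lt
            changed |= ~eq
            undecided &= eq
        if violation.any():
            raise ValueError("key is not sorted")
        first = tuple(c[0] for c in cols)
        if carry is not None:
            if first < carry:
                raise ValueError("key is not sorted")
            if first != carry:
                change_points.append(start)
        carry = tuple(c[-1] for c in cols)
        change_points.extend((start + 1 + np.flatnonzero(changed)).tolist())
    change_points.append(n)
    return np.asarray(change_points, dtype=np.int64)


def _reduce_block(values, bounds, reducer, valid):
    """Reduce one block of spans over materialised values.

    ``bounds`` are block-local span offsets (length groups+1). Returns
    (result array, validity array).
    """
    starts = bounds[:-1]
    counts = np.diff(bounds)
    if reducer == "count":
        return counts.astype(np.int64), np.ones(len(counts), dtype=bool)
    if reducer == "first":
        out = values[starts]
        v = valid[starts] if valid is not None else np.ones(len(starts), bool)
        return out, v
    if reducer == "last":
        out = values[bounds[1:] - 1]
        v = valid[bounds[1:] - 1] if valid is not None \
            else np.ones(len(starts), bool)
        return out, v

    if values.dtype.kind in "OSU":
        # string min/max: per-group loop (no reduceat for these dtypes)
        if reducer not in ("min", "max"):
            raise TypeError(f"{reducer!r} is not defined for string fields")
        pick = min if reducer == "min" else max
        out = np.array([pick(values[s:e].tolist())
                        for s, e in zip(bounds[:-1], bounds[1:])],
                       dtype=values.dtype)
        return out, np.ones(len(starts), dtype=bool)

    vmask = valid if valid is not None else np.ones(len(values), dtype=bool)
    nvalid = np.add.reduceat(vmask.astype(np.int64), starts)
    nvalid[counts == 0] = 0
    ok = nvalid > 0
    if reducer == "sum":
        work = np.where(vmask, values, 0)
        out = np.add.reduceat(work, starts)
        out[~ok] = 0
        return out, ok
    if reducer == "mean":
        work = np.where(vmask, values, 0).astype(np.float64)
        tot = np.add.reduceat(work, starts)
        out = np.divide(tot, nvalid, out=np.zeros(len(starts)), where=ok)
        return out, ok
    if reducer in ("min", "max"):
        if values.dtype == np.bool_:
            work = values.astype(np.int64)
        else:
            work = values
        if np.issubdtype(work.dtype, np.floating):
            fill = np.inf if reducer == "min" else -np.inf
        else:
            info = np.iinfo(work.dtype)
            fill = info.max if reducer == "min" else info.min
        work = np.where(vmask, work, fill)
        ufunc = np.minimum if reducer == "min" else np.maximum
        out = ufunc.reduceat(work, starts)
        out = np.where(ok, out, 0).astype(work.dtype)
        if values.dtype == np.bool_:
            out = out.astype(bool)
        return out, ok
    raise ValueError(f"unknown reducer {reducer!r}")


def apply_spans(spans: np.ndarray, field, reducer: str,
                valid: np.ndarray | None = None,
                span_block: int = 1 << 15):
    """One reduced value per span, streamed over blocks of spans.

    Rows whose validity flag is False are excluded from min/max/sum/mean;
    ``count`` counts all rows. A group with no valid entry yields the
    kind's default with an output validity flag of False (the result
    field's ``valid`` attribute). Results do not depend on ``span_block``.
    """
    if reducer not in REDUCERS:
        raise ValueError(f"reducer must be one of {REDUCERS}, got {reducer!r}")
    spans = np.asarray(spans, dtype=np.int64)
    n = int(spans[-1])
    if len(field) != n:
        raise ValueError(
            f"field length {len(field)} != span extent {n}")
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)

    groups = len(spans) - 1
    parts, vparts = [], []
    for g0 in range(0, groups, span_block):
        g1 = min(g0 + span_block, groups)
        r0, r1 = int(spans[g0]), int(spans[g1])
        values = np.asarray(field.slice_values(r0, r1))
        bounds = spans[g0:g1 + 1] - r0
        vblock = valid[r0:r1] if valid is not None else None
        out, ok = _reduce_block(values, bounds, reducer, vblock)
        parts.append(out)
        vparts.append(ok)
    if not parts:
        parts = [np.empty(0)]
        vparts = [np.empty(0, dtype=bool)]
    data = np.concatenate(parts)
    okall = np.concatenate(vparts)

    kind = getattr(field, "kind", "numeric")
    if reducer == "count":
        return fld.NumericField(data.astype(np.int64))
    if kind == "timestamp" and reducer in ("min", "max", "first", "last",
                                           "mean"):
        return fld.TimestampField(data, valid=okall)
    if kind == "categorical" and reducer in ("min", "max", "first", "last"):
        mem = field.to_memory() if hasattr(field, "to_memory") else field
        return fld.CategoricalField(data, mem.key, valid=okall,
                                    freetext_code=mem.freetext_code)
    if kind == "fixed_string" and reducer in ("min", "max", "first", "last"):
        return fld.FixedStringField(data)
    if kind == "indexed_string" and reducer in ("min", "max", "first", "last"):
        return fld.IndexedStringField(
            *fld.encode_indexed([b.decode("utf-8") for b in data]),
            valid=okall)
    return fld.NumericField(data, valid=okall)


def quantise_daily_max(df, dest, patient_id: str = "patient_id",
                       timestamp: str = "created_at",
                       symptoms=(), chunk_length: int = DEFAULT_CHUNK) -> int:
    """Collapse multiple same-day reports to one row per (person, day).

    Rows are sorted by ``(patient_id, day)`` where ``day`` is the UTC
    calendar day of the timestamp. Within each group every symptom column
    takes the group maximum (categorical codes are ordered by severity by
    the schema author); the timestamp and all other columns take the
    first observation of the day. A ``day`` timestamp field is written
    alongside. Returns the output row count.
    """
    for name in (patient_id, timestamp, *symptoms):
        if name not in df:
            raise KeyError(f"missing field {name!r}")
    pid = df[patient_id].to_memory()
    ts = df[timestamp].to_memory()
    day = ts.day()
    order = multi_key_argsort([pid, day])
    pid_s = pid.apply_index(order)
    day_s = day.apply_index(order)
    spans = compute_spans([pid_s, day_s], chunk_length)

    dest.write(patient_id, apply_spans(spans, pid_s, "first"))
    dest.write("day", apply_spans(spans, day_s, "first"))
    dest.write(timestamp, apply_spans(spans, ts.apply_index(order), "first"))
    symptoms = list(symptoms)
    for name in df.keys():
        if name in (patient_id, timestamp):
            continue
        col = df[name].to_memory().apply_index(order)
        reducer = "max" if name in symptoms else "first"
        vname = f"{name}_valid"
        valid = None
        if vname in df.keys() and vname != name:
            valid = df[vname].to_memory().apply_index(order) \
                .data.astype(bool)
        if name.endswith("_valid"):
            continue  # companions are re-derived below
        out = apply_spans(spans, col, reducer, valid=valid)
        dest.write(name, out)
        if out.valid is not None and valid is not None:
            dest.write(vname, fld.NumericField(out.valid))
    return dest.finish()
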