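"""Independent brute-force oracles used to validate the streaming paths."""

from __future__ import annotations

import numpy as np


def stable_tuple_argsort(columns) -> list[int]:
    """Stable lexicographic argsort of row tuples (decorate-sort)."""
    n = len(columns[0])
    rows = [tuple(c[i] for c in columns) for i in range(n)]
    return sorted(range(n), key=rows.__getitem__)


def nested_loop_join(left_keys, right_keys, how: str) -> list[tuple[int, int]]:
    """SQL join semantics by exhaustive nested loops.

    Returns (left_row, right_row) pairs with -1 for unmatched, enumerated
    by key order, then left occurrence, then right occurrence — the same
    deterministic output order the streaming implementation documents.
    """
    left_keys = list(left_keys)
    right_keys = list(right_keys)
    out = []
    keys = sorted(set(left_keys) | set(right_keys))
    for k in keys:
        li = [i for i, v in enumerate(left_keys) if v == k]
        ri = [j for j, v in enumerate(right_keys) if v == k]
        if li and ri:
            for i in li:
                for j in ri:
                    out.append((i, j))
        elif li and how == "left":
            out.extend((i, -1) for i in li)
        elif ri and how == "right":
            out.extend((-1, j) for j in ri)
    return out


def group_reduce(values, group_ids, reducer, valid=None):
    """Per-group reduction by explicit grouping (dict of lists)."""
    groups: dict = {}
    order: list = []
    for i, g in enumerate(group_ids):
        if g not in groups:
            groups[g] = []
            order.append(g)
        groups[g].append(i)
    out = []
    for g in sorted(order):
        idx = groups[g]
        rows = [values[i] for i in idx]
        ok = [True] * len(idx) if valid is None else [valid[i] for i in idx]
        live = [v for v, o in zip(rows, ok) if o]
        if reducer == "count":
            out.append(len(rows))
        elif reducer == "first":
            out.append(rows[0])
        elif reducer == "last":
            out.append(rows[-1])
        elif not live:
            out.append(None)
        elif reducer == "min":
            out.append(min(live))
        elif reducer == "max":
            out.append(max(live))
        elif reducer == "sum":
            out.append(sum(live))
        elif reducer == "mean":
            out.append(sum(live) / len(live))
        else:
            raise ValueError(reducer)
    return out


def daily_max_oracle(pids, days, symptom_values):
    """Per-(person, day) maxima of one symptom column, keyed dict."""
    out: dict = {}
    for p, d, v in zip(pids, days, symptom_values):
        k = (p, d)
        if k not in out or v > out[k]:
            out[k] = v
    return out
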