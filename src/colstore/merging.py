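"""Joins as ordered merges on sorted keys.

A join is computed once as a pair of *join maps* — per-output-row source
indices into the left and right tables, with -1 marking unmatched rows —
and the maps are then applied to as many fields as needed. When both key
columns are sorted the maps come from a single linear merge pass in
O(m + n + output) comparisons; unsorted keys are handled by sorting
internally and composing the sort permutations into the maps.

Join semantics are SQL-compatible: equal-key runs on both sides produce
their Cartesian product, enumerated by key, then left occurrence order,
then right occurrence order. Keys present only on the non-preserved side
are dropped; keys present only on the preserved side emit one row with -1
on the other map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import DEFAULT_CHUNK
from .sorting import multi_key_argsort

_HOWS = ("left", "right", "inner")


@dataclass
class JoinMap:
    """Per-output-row source indices; -1 means unmatched."""
    left_map: np.ndarray
    right_map: np.ndarray
    #: key elements read while generating the maps (linear-pass contract:
    #: at most m + n + output size).
    key_reads: int = 0

    def __len__(self) -> int:
        return len(self.left_map)


class _KeyCursor:
    """Block-buffered cursor over a (possibly multi-) key column.

    Verifies the key is non-decreasing as it streams, and counts element
    reads. Multi-field keys are compared as tuples.
    """

    def __init__(self, keys, chunk_length: int, side: str):
        self.keys = keys if isinstance(keys, (list, tuple)) else [keys]
        self.n = len(self.keys[0])
        self.chunk = max(1, chunk_length)
        self.side = side
        self.pos = 0
        self.reads = 0
        self._base = 0
        self._buf = None
        self._prev_last = None
        if self.n:
            self._load(0)

    def _load(self, start: int) -> None:
        stop = min(start + self.chunk, self.n)
        cols = [np.asarray(k.sort_key_slice(start, stop)) for k in self.keys]
        self.reads += stop - start
        if len(cols) == 1:
            buf = cols[0]
            if len(buf) > 1 and (buf[1:] < buf[:-1]).any():
                raise ValueError(f"{self.side} key is not sorted")
            first, last = buf[0], buf[-1]
        else:
            buf = np.empty(stop - start, dtype=object)
            buf[:] = list(zip(*(c.tolist() for c in cols)))
            for a, b in zip(buf[:-1], buf[1:]):
                if b < a:
                    raise ValueError(f"{self.side} key is not sorted")
            first, last = buf[0], buf[-1]
        if self._prev_last is not None and first < self._prev_last:
            raise ValueError(f"{self.side} key is not sorted")
        self._prev_last = last
        self._base = start
        self._buf = buf

    @property
    def exhausted(self) -> bool:
        return self.pos >= self.n

    def peek(self):
        off = self.pos - self._base
        if off >= len(self._buf):
            self._load(self.pos)
            off = 0
        return self._buf[off]

    def take_run(self) -> tuple[int, int]:
        """Consume the run of entries equal to the current value; return
        its (start_row, length)."""
        value = self.peek()
        start = self.pos
        while not self.exhausted and not (self.peek() != value):
            self.pos += 1
            if self.pos < self.n and self.pos - self._base >= len(self._buf):
                self._load(self.pos)
        return start, self.pos - start


def ordered_join_maps(left_key, right_key, how: str = "left",
                      chunk_length: int = DEFAULT_CHUNK) -> JoinMap:
    """Generate join maps from two sorted key columns in one linear pass.

    ``left_key`` / ``right_key`` may be single fields or lists of fields
    (composite keys). Sortedness is verified while streaming; violation
    raises ``ValueError``.
    """
    if how not in _HOWS:
        raise ValueError(f"how must be one of {_HOWS}, got {how!r}")
    lc = _KeyCursor(left_key, chunk_length, "left")
    rc = _KeyCursor(right_key, chunk_length, "right")
    lmap: list[int] = []
    rmap: list[int] = []

    while not lc.exhausted and not rc.exhausted:
        lv, rv = lc.peek(), rc.peek()
        if lv < rv:
            ls, ln = lc.take_run()
            if how == "left":
                lmap.extend(range(ls, ls + ln))
                rmap.extend([-1] * ln)
        elif rv < lv:
            rs, rn = rc.take_run()
            if how == "right":
                lmap.extend([-1] * rn)
                rmap.extend(range(rs, rs + rn))
        else:
            ls, ln = lc.take_run()
            rs, rn = rc.take_run()
            for i in range(ls, ls + ln):
                lmap.extend([i] * rn)
                rmap.extend(range(rs, rs + rn))
    if how == "left":
        while not lc.exhausted:
            ls, ln = lc.take_run()
            lmap.extend(range(ls, ls + ln))
            rmap.extend([-1] * ln)
    if how == "right":
        while not rc.exhausted:
            rs, rn = rc.take_run()
            lmap.extend([-1] * rn)
            rmap.extend(range(rs, rs + rn))
    # drain both sides so sortedness is verified end to end (stays within
    # the m + n read budget)
    for cur in (lc, rc):
        while not cur.exhausted:
            cur.take_run()

    return JoinMap(np.asarray(lmap, dtype=np.int64),
                   np.asarray(rmap, dtype=np.int64),
                   key_reads=lc.reads + rc.reads)


def _is_sorted(keys, chunk_length: int) -> bool:
    try:
        cur = _KeyCursor(keys, chunk_length, "probe")
        while not cur.exhausted:
            cur.take_run()
        return True
    except ValueError:
        return False


def _compose(perm: np.ndarray | None, jmap: np.ndarray) -> np.ndarray:
    """Map join-map entries back through a sort permutation, keeping -1."""
    if perm is None:
        return jmap
    out = jmap.copy()
    hit = jmap >= 0
    out[hit] = perm[jmap[hit]]
    return out


def merge(left, right, dest, left_on, right_on=None, how: str = "left",
          suffixes: tuple[str, str] = ("", "_r"),
          chunk_length: int = DEFAULT_CHUNK) -> int:
    """SQL-style merge of two tables into ``dest``; returns the row count.

    ``left_on`` / ``right_on`` name the key field(s); sorted keys take the
    streaming ordered-merge path directly, otherwise sort permutations are
    computed internally and composed into the maps. All fields from both
    sides are written via sentinel-aware index application; unmatched rows
    get the kind's default value plus a ``<name>_valid`` companion mask.
    Name collisions on the right side get ``suffixes[1]``; key columns are
    written once, from the preserved (or left, for inner) side.
    """
    left_on = [left_on] if isinstance(left_on, str) else list(left_on)
    right_on = left_on if right_on is None else (
        [right_on] if isinstance(right_on, str) else list(right_on))
    for k in left_on:
        if k not in left:
            raise KeyError(f"unknown left key field {k!r}")
    for k in right_on:
        if k not in right:
            raise KeyError(f"unknown right key field {k!r}")

    lperm = rperm = None
    lkeys = [left[k] for k in left_on]
    rkeys = [right[k] for k in right_on]
    if not _is_sorted(lkeys, chunk_length):
        lperm = multi_key_argsort(lkeys)
        lkeys = [k.to_memory().apply_index(lperm) for k in lkeys]
    if not _is_sorted(rkeys, chunk_length):
        rperm = multi_key_argsort(rkeys)
        rkeys = [k.to_memory().apply_index(rperm) for k in rkeys]

    jm = ordered_join_maps(lkeys, rkeys, how, chunk_length)
    lmap = _compose(lperm, jm.left_map)
    rmap = _compose(rperm, jm.right_map)

    key_from_left = how != "right"
    written = set()

    def _write(name: str, field, jmap: np.ndarray) -> None:
        mem = field.to_memory() if hasattr(field, "to_memory") else field
        out = mem.apply_index(jmap, allow_sentinel=True)
        dest.write(name, out)
        written.add(name)
        if out.valid is not None and not out.valid.all():
            from .fields import NumericField
            dest.write(f"{name}_valid", NumericField(out.valid))
            written.add(f"{name}_valid")

    # key columns once, from the preserved side
    for lk, rk in zip(left_on, right_on):
        if key_from_left:
            _write(lk, left[lk], lmap)
        else:
            _write(lk, right[rk], rmap)

    for name in left.keys():
        if name in left_on:
            continue
        _write(name, left[name], lmap)
    for name in right.keys():
        if name in right_on:
            continue
        out_name = name
        if out_name in written:
            out_name = f"{name}{suffixes[1]}"
        _write(out_name, right[name], rmap)

    return dest.finish()
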