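"""Permutation-index sorting: single key, multi-key, and larger-than-memory.

Sorting happens in two steps: a sorted index (a permutation of the row
indices) is generated first, then applied independently to each field that
needs reordering. Multi-key sorts are rephrased as successive *stable*
single-key sorts applied right-to-left, so only one key column is resident
at a time. Columns too long to sort in memory are handled by sorting
fixed-length chunks and merging the sorted runs through a heap of run
cursors; a row-index array travels with each run so the merge stays stable.
"""

from __future__ import annotations

import heapq
import os
import tempfile

import h5py
import numpy as np

from .fields import DEFAULT_CHUNK


def _sort_key_array(key):
    """Comparable numpy array for a field (or pass numpy arrays through)."""
    if isinstance(key, np.ndarray):
        return key
    return key.sort_keys()


def argsort_stable(key) -> np.ndarray:
    """Stable permutation ``order`` such that ``key[order]`` is non-decreasing.

    Equal keys keep their original relative order. Strings compare
    bytewise on their UTF-8 encoding, categoricals by code.
    """
    arr = _sort_key_array(key)
    return np.argsort(arr, kind="stable").astype(np.int64)


def multi_key_argsort(keys) -> np.ndarray:
    """Stable lexicographic sort by ``(keys[0], keys[1], ...)``.

    Implemented as a series of stable single-key argsorts from the least
    significant key to the most significant, each re-sorting the order
    accumulated so far; stability of each pass is what makes the
    composition lexicographic.
    """
    keys = list(keys)
    if not keys:
        raise ValueError("multi_key_argsort needs at least one key")
    n = len(keys[0])
    for k in keys[1:]:
        if len(k) != n:
            raise ValueError("key fields differ in length")
    order = np.arange(n, dtype=np.int64)
    for key in reversed(keys):
        arr = _sort_key_array(key)
        order = order[np.argsort(arr[order], kind="stable")]
    return order


class _RunStore:
    """Sorted runs of (value, original row index), in RAM or spilled to a
    temporary HDF5 store."""

    def __init__(self, spill_dir=None, dtype=None):
        self._mem: list[tuple[np.ndarray, np.ndarray]] = []
        self._h5 = None
        self._path = None
        if spill_dir is not None and dtype is not None \
                and dtype.kind not in "OU":
            fd, self._path = tempfile.mkstemp(
                suffix=".h5", prefix="colstore-sort-", dir=str(spill_dir))
            os.close(fd)
            self._h5 = h5py.File(self._path, "w")
            self._dtype = dtype

    def add(self, values: np.ndarray, indices: np.ndarray) -> None:
        if self._h5 is not None:
            i = len(self._h5) // 2
            self._h5.create_dataset(f"v{i}", data=values)
            self._h5.create_dataset(f"i{i}", data=indices)
        else:
            self._mem.append((values, indices))

    def __len__(self) -> int:
        return len(self._h5) // 2 if self._h5 is not None else len(self._mem)

    def read(self, run: int, start: int, stop: int):
        if self._h5 is not None:
            return self._h5[f"v{run}"][start:stop], \
                self._h5[f"i{run}"][start:stop]
        v, i = self._mem[run]
        return v[start:stop], i[start:stop]

    def run_length(self, run: int) -> int:
        if self._h5 is not None:
            return self._h5[f"v{run}"].shape[0]
        return len(self._mem[run][0])

    def close(self) -> None:
        if self._h5 is not None:
            self._h5.close()
            os.unlink(self._path)


class _RunCursor:
    """Block-buffered cursor over one sorted run."""

    __slots__ = ("store", "run", "pos", "length", "block", "_values",
                 "_indices", "_base")

    def __init__(self, store: _RunStore, run: int, block: int):
        self.store = store
        self.run = run
        self.pos = 0
        self.length = store.run_length(run)
        self.block = block
        self._base = 0
        self._values, self._indices = store.read(run, 0, min(block, self.length))

    def current(self):
        off = self.pos - self._base
        return self._values[off], self._indices[off]

    def advance(self) -> bool:
        self.pos += 1
        if self.pos >= self.length:
            return False
        if self.pos - self._base >= len(self._values):
            self._base = self.pos
            self._values, self._indices = self.store.read(
                self.run, self.pos, min(self.pos + self.block, self.length))
        return True


def external_argsort(key, chunk_length: int, spill_dir=None,
                     block_length: int | None = None) -> np.ndarray:
    """Stable argsort computed on fixed-length chunks plus a k-way merge.

    Produces output identical to :func:`argsort_stable` for every input.
    Each chunk of ``chunk_length`` key elements is sorted stably and kept
    as a run (spilled to a temporary store under ``spill_dir`` when
    given); the merge phase holds one block-buffered cursor per run and a
    heap ordered by ``(value, run_index, position_in_run)``. Runs are
    formed left to right, so that heap key reproduces global stability.
    """
    if chunk_length < 1:
        raise ValueError("chunk_length must be >= 1")
    n = len(key)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    block = block_length or max(1, min(chunk_length, 1 << 16))

    first = key.sort_key_slice(0, min(chunk_length, n))
    store = _RunStore(spill_dir, np.asarray(first).dtype)
    start = 0
    while start < n:
        stop = min(start + chunk_length, n)
        vals = first if start == 0 else key.sort_key_slice(start, stop)
        vals = np.asarray(vals)
        local = np.argsort(vals, kind="stable")
        store.add(vals[local], (start + local).astype(np.int64))
        start = stop

    if len(store) == 1:
        _, order = store.read(0, 0, n)
        store.close()
        return order

    cursors = [_RunCursor(store, r, block) for r in range(len(store))]
    heap = []
    for r, cur in enumerate(cursors):
        v, _ = cur.current()
        heap.append((v, r, cur.pos))
    heapq.heapify(heap)

    out = np.empty(n, dtype=np.int64)
    for j in range(n):
        _, r, _ = heapq.heappop(heap)
        cur = cursors[r]
        _, idx = cur.current()
        out[j] = idx
        if cur.advance():
            v, _ = cur.current()
            heapq.heappush(heap, (v, r, cur.pos))
    store.close()
    return out


def apply_permutation(field, order: np.ndarray, dest_df, name: str,
                      chunk_length: int = DEFAULT_CHUNK) -> None:
    """Write ``field[order]`` into ``dest_df[name]``, streamed by output
    chunks so at most ``chunk_length`` gathered elements are buffered."""
    n = len(order)
    if name in dest_df:
        dest_df.delete(name)
    mem = field.to_memory() if hasattr(field, "to_memory") else field
    for start in range(0, n, chunk_length):
        stop = min(start + chunk_length, n)
        dest_df.append(name, mem.apply_index(order[start:stop]))
    if n == 0:
        dest_df.append(name, mem.apply_index(order))


def sort_dataframe(df, keys, dest, chunk_length: int = DEFAULT_CHUNK) -> int:
    """Sort every field of ``df`` into ``dest`` by the named key fields.

    One permutation is computed once (stable lexicographic over the key
    tuple) and applied per-field in streamed chunks.
    """
    for k in keys:
        if k not in df:
            raise KeyError(f"unknown sort key {k!r}")
    order = multi_key_argsort([df[k] for k in keys])
    for name in df.keys():
        apply_permutation(df[name], order, dest, name, chunk_length)
    return dest.finish()
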