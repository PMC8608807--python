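"""Drive-backed datasets: HDF5 storage for tables of typed columns.

On-disk layout (documented so files are portable across implementations):

* one HDF5 group per table, carrying an integer attribute ``row_count``;
* one subgroup per field, carrying a JSON attribute ``fieldtype`` that
  records the kind plus its parameters (fixed-string ``width``, numeric
  ``value_type``, the categorical ``key`` and optional ``freetext_code``);
* a dataset ``values`` holding the column body (for indexed strings, the
  concatenated uint8 byte buffer) and, for indexed strings only, a dataset
  ``index`` of int64 offsets with length n+1.

All datasets are one-dimensional and resizable so imports can append
chunk by chunk. Each column lives in its own contiguous datasets — reading
one field never touches another field's storage, which is the property the
instrumented read log (:func:`record_reads`) lets tests assert.
"""

from __future__ import annotations

import json
from contextlib import contextmanager

import h5py
import numpy as np

from . import fields as fld
from .fields import DEFAULT_CHUNK

_read_log: list | None = None


@contextmanager
def record_reads():
    """Record every storage read as ``(field_path, start, stop, nbytes)``.

    Used to verify the column-local access contract: the bytes touched by
    reading one field belong only to that field's datasets.
    """
    global _read_log
    prev, _read_log = _read_log, []
    try:
        yield _read_log
    finally:
        _read_log = prev


def _read(ds: h5py.Dataset, start: int, stop: int) -> np.ndarray:
    out = ds[start:stop]
    if _read_log is not None:
        _read_log.append((ds.name, int(start), int(stop), int(out.nbytes)))
    return out


class Dataset:
    """A drive-backed collection of named tables (one HDF5 file)."""

    def __init__(self, path, mode: str = "read"):
        h5mode = {"read": "r", "readwrite": "a", "write": "w"}.get(mode, mode)
        self.path = str(path)
        self.mode = mode
        self._h5 = h5py.File(self.path, h5mode)

    def close(self):
        self._h5.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def create_dataframe(self, name: str) -> "DataFrame":
        if name in self._h5:
            raise ValueError(f"table {name!r} already exists")
        group = self._h5.create_group(name)
        group.attrs["row_count"] = 0
        return DataFrame(self, group)

    def __getitem__(self, name: str) -> "DataFrame":
        if name not in self._h5:
            raise KeyError(f"no table named {name!r}")
        return DataFrame(self, self._h5[name])

    def __contains__(self, name: str) -> bool:
        return name in self._h5

    def keys(self):
        return list(self._h5.keys())


class DataFrame:
    """A named table: equal-length typed fields stored column-locally."""

    def __init__(self, dataset: Dataset, group: h5py.Group):
        self.dataset = dataset
        self._group = group

    @property
    def name(self) -> str:
        return self._group.name.rsplit("/", 1)[-1]

    @property
    def row_count(self) -> int:
        return int(self._group.attrs["row_count"])

    def keys(self):
        return list(self._group.keys())

    def __contains__(self, name: str) -> bool:
        return name in self._group

    def __getitem__(self, name: str) -> "BackedField":
        if name not in self._group:
            raise KeyError(f"no field named {name!r} in table {self.name!r}")
        return BackedField(self._group[name])

    def delete(self, name: str) -> None:
        del self._group[name]

    # -- writing ---------------------------------------------------------
    def write(self, name: str, field: fld.Field) -> "BackedField":
        """Write a memory field as (or over) the named drive-backed field."""
        if name in self._group:
            del self._group[name]
        self.append(name, field)
        self._sync_row_count()
        return self[name]

    def append(self, name: str, field: fld.Field) -> None:
        """Append a memory-field chunk to the named field, creating it on
        first use. Appends concatenate bit-exactly, so an import is
        invariant to the chunking used."""
        if name in self._group:
            self._append_existing(self._group[name], field)
        else:
            self._create(name, field)

    def _sync_row_count(self) -> None:
        lengths = {name: len(self[name]) for name in self.keys()}
        if lengths:
            n = max(lengths.values())
            bad = {k: v for k, v in lengths.items() if v != n}
            if bad:
                raise ValueError(
                    f"field length mismatch in table {self.name!r}: {bad} "
                    f"vs row count {n}")
            self._group.attrs["row_count"] = n
        else:
            self._group.attrs["row_count"] = 0

    def finish(self) -> int:
        """Validate equal field lengths and set the row count."""
        self._sync_row_count()
        return self.row_count

    def _create(self, name: str, field: fld.Field) -> None:
        g = self._group.create_group(name)
        meta: dict = {"kind": field.kind}
        if field.kind == "indexed_string":
            g.create_dataset("index", data=field.index, maxshape=(None,),
                             dtype=np.int64)
            g.create_dataset("values", data=field.values, maxshape=(None,),
                             dtype=np.uint8)
        elif field.kind == "fixed_string":
            meta["width"] = field.width
            g.create_dataset("values", data=field.data, maxshape=(None,),
                             dtype=f"S{max(field.width, 1)}")
        elif field.kind == "numeric":
            meta["value_type"] = field.value_type
            g.create_dataset("values", data=field.data, maxshape=(None,))
        elif field.kind == "categorical":
            meta["key"] = {str(k): v for k, v in field.key.items()}
            if field.freetext_code is not None:
                meta["freetext_code"] = field.freetext_code
            g.create_dataset("values", data=field.data, maxshape=(None,))
        elif field.kind == "timestamp":
            g.create_dataset("values", data=field.data, maxshape=(None,),
                             dtype=np.float64)
        else:  # pragma: no cover
            raise TypeError(f"cannot store field kind {field.kind!r}")
        g.attrs["fieldtype"] = json.dumps(meta, sort_keys=True)

    def _append_existing(self, g: h5py.Group, field: fld.Field) -> None:
        meta = json.loads(g.attrs["fieldtype"])
        if meta["kind"] != field.kind:
            raise TypeError(
                f"cannot append {field.kind} chunk to {meta['kind']} field")
        if field.kind == "indexed_string":
            idx_ds, val_ds = g["index"], g["values"]
            base = int(idx_ds[-1])
            old_n = idx_ds.shape[0]
            idx_ds.resize((old_n + len(field.index) - 1,))
            idx_ds[old_n:] = field.index[1:] + base
            old_v = val_ds.shape[0]
            val_ds.resize((old_v + len(field.values),))
            if len(field.values):
                val_ds[old_v:] = field.values
        else:
            ds = g["values"]
            old_n = ds.shape[0]
            ds.resize((old_n + len(field.data),))
            if len(field.data):
                ds[old_n:] = field.data


class BackedField:
    """Lazy, drive-backed view of one stored field.

    Mirrors the memory-field API: chunked reads stream straight from the
    HDF5 datasets; structural/elementwise operations materialise via
    :meth:`to_memory` and return memory fields.
    """

    backing = "dataframe"

    def __init__(self, group: h5py.Group):
        self._group = group
        self._meta = json.loads(group.attrs["fieldtype"])

    @property
    def kind(self) -> str:
        return self._meta["kind"]

    @property
    def name(self) -> str:
        return self._group.name.rsplit("/", 1)[-1]

    def __len__(self) -> int:
        if self.kind == "indexed_string":
            return self._group["index"].shape[0] - 1
        return self._group["values"].shape[0]

    # -- streaming reads -------------------------------------------------
    def slice_values(self, start: int, stop: int):
        if self.kind == "indexed_string":
            idx = _read(self._group["index"], start, stop + 1)
            vals = _read(self._group["values"], int(idx[0]), int(idx[-1]))
            buf = vals.tobytes()
            base = int(idx[0])
            return np.array(
                [buf[int(idx[i]) - base:int(idx[i + 1]) - base]
                 for i in range(len(idx) - 1)], dtype=object)
        return _read(self._group["values"], start, stop)

    def chunks(self, chunk_length: int = DEFAULT_CHUNK):
        n = len(self)
        for start in range(0, n, chunk_length):
            yield self.slice_values(start, min(start + chunk_length, n))

    sort_key_slice = slice_values

    def sort_keys(self):
        return self.slice_values(0, len(self))

    # -- materialisation -------------------------------------------------
    def to_memory(self) -> fld.Field:
        kind = self.kind
        if kind == "indexed_string":
            index = _read(self._group["index"], 0,
                          self._group["index"].shape[0])
            values = _read(self._group["values"], 0,
                           self._group["values"].shape[0])
            return fld.IndexedStringField(index, values)
        data = _read(self._group["values"], 0, len(self))
        if kind == "fixed_string":
            return fld.FixedStringField(data, self._meta["width"])
        if kind == "numeric":
            return fld.NumericField(data)
        if kind == "categorical":
            key = {int(k): v for k, v in self._meta["key"].items()}
            return fld.CategoricalField(data, key,
                                        freetext_code=self._meta.get(
                                            "freetext_code"))
        if kind == "timestamp":
            return fld.TimestampField(data)
        raise TypeError(f"unknown stored field kind {kind!r}")  # pragma: no cover

    @property
    def data(self):
        return self.to_memory().data

    def tolist(self):
        return self.to_memory().tolist()

    def apply_filter(self, mask):
        return self.to_memory().apply_filter(mask)

    def apply_index(self, indices, allow_sentinel: bool = False):
        return self.to_memory().apply_index(indices, allow_sentinel)

    @property
    def stored_bytes(self) -> int:
        """Bytes occupied on the drive by this column's datasets."""
        total = 0
        for ds_name in self._group:
            ds = self._group[ds_name]
            total += ds.shape[0] * ds.dtype.itemsize
        return total
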