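"""Typed in-memory columns (memory fields).

A field is a single column of typed values. Five kinds exist:

* fixed-width byte strings (``FixedStringField``)
* variable-length strings stored as an offset index plus one concatenated
  byte buffer (``IndexedStringField``)
* numeric / logical values (``NumericField``)
* categorical codes with a code -> label key (``CategoricalField``)
* POSIX timestamps in float64 seconds (``TimestampField``)

Memory fields live in RAM. Writing one to a :class:`~colstore.dataset.DataFrame`
produces the drive-backed flavour of the same kind (see ``colstore.dataset``).
Every field supports filtering, index application (gather, with a -1
"unmatched" sentinel), chunked iteration and — where the kind permits —
elementwise arithmetic, logical and comparison operations.
"""

from __future__ import annotations

import numpy as np

#: Default chunk length (elements) for chunked column traversal.
DEFAULT_CHUNK = 1 << 20

_NUMERIC_TYPES = {
    "int8": np.int8, "int16": np.int16, "int32": np.int32, "int64": np.int64,
    "uint8": np.uint8, "uint16": np.uint16, "uint32": np.uint32,
    "uint64": np.uint64,
    "float32": np.float32, "float64": np.float64, "bool": np.bool_,
}


def numeric_dtype(value_type: str) -> np.dtype:
    """Resolve a value-type name (e.g. ``"float32"``) to a numpy dtype."""
    try:
        return np.dtype(_NUMERIC_TYPES[value_type])
    except KeyError:
        raise ValueError(f"unknown numeric value_type {value_type!r}") from None


def encode_indexed(strings) -> tuple[np.ndarray, np.ndarray]:
    """Encode a sequence of strings as (offset index, concatenated bytes).

    The index has length n+1 with ``index[0] == 0``; entry i occupies
    ``values[index[i]:index[i+1]]`` as UTF-8. Empty entries appear in the
    index only, as repeated offsets, so storage is ``8*(n+1)`` bytes of
    offsets plus the total text bytes — independent of the longest entry.
    """
    encoded = [s.encode("utf-8") if isinstance(s, str) else bytes(s)
               for s in strings]
    index = np.zeros(len(encoded) + 1, dtype=np.int64)
    if encoded:
        np.cumsum([len(b) for b in encoded], out=index[1:])
    values = np.frombuffer(b"".join(encoded), dtype=np.uint8).copy()
    return index, values


class Field:
    """Abstract column of typed values."""

    kind: str = "abstract"
    #: "memory" here; the dataset module overrides with "dataframe".
    backing = "memory"

    #: Optional boolean validity companion (True = value present). Gather
    #: operations with the -1 sentinel populate this on their output.
    valid: np.ndarray | None = None

    def __len__(self) -> int:  # pragma: no cover - abstract
        raise NotImplementedError

    # -- chunked access -------------------------------------------------
    def chunks(self, chunk_length: int = DEFAULT_CHUNK):
        """Yield the column's values in caller-chosen chunk lengths."""
        n = len(self)
        for start in range(0, n, chunk_length):
            yield self.slice_values(start, min(start + chunk_length, n))
        if n == 0:
            return

    def slice_values(self, start: int, stop: int):  # pragma: no cover
        raise NotImplementedError

    # -- sortable / comparable representation ---------------------------
    def sort_keys(self) -> np.ndarray:
        """A numpy array whose elementwise ``<`` matches the field's order.

        Numeric and timestamp fields compare by value, categoricals by
        code, strings bytewise on their UTF-8 encoding.
        """
        raise NotImplementedError

    def sort_key_slice(self, start: int, stop: int) -> np.ndarray:
        return self.sort_keys()[start:stop]

    # -- structural operations ------------------------------------------
    def apply_filter(self, mask) -> "Field":
        """Keep rows where ``mask`` is True, preserving order."""
        mask = np.asarray(mask, dtype=bool)
        if len(mask) != len(self):
            raise ValueError(
                f"filter length {len(mask)} != field length {len(self)}")
        out = self._take(np.flatnonzero(mask))
        if self.valid is not None:
            out.valid = self.valid[mask]
        return out

    def apply_index(self, indices, allow_sentinel: bool = False) -> "Field":
        """Gather ``out[j] = self[indices[j]]``.

        With ``allow_sentinel=True`` an index of -1 yields the kind's
        empty/default value and the output's ``valid`` mask marks the row
        unmatched; join maps rely on this.
        """
        indices = np.asarray(indices, dtype=np.int64)
        n = len(self)
        sentinel = indices == -1
        if allow_sentinel:
            bad = (indices < -1) | (indices >= n)
        else:
            bad = (indices < 0) | (indices >= n)
        if bad.any():
            raise IndexError(
                f"index {indices[bad][0]} out of range for field of length {n}")
        if n == 0:
            # only reachable when every index is the sentinel
            out = self._filled_default(len(indices))
            out.valid = np.zeros(len(indices), dtype=bool)
            return out
        safe = np.where(sentinel, 0, indices)
        out = self._take(safe)
        valid = None
        if self.valid is not None:
            valid = np.where(sentinel, False, self.valid[safe] if n else False)
        if allow_sentinel and sentinel.any():
            if valid is None:
                valid = ~sentinel
            else:
                valid = valid & ~sentinel
            out._blank(np.flatnonzero(sentinel))
        out.valid = valid
        return out

    def _take(self, idx: np.ndarray) -> "Field":  # pragma: no cover
        raise NotImplementedError

    def _filled_default(self, count: int) -> "Field":
        """A field of ``count`` rows holding the kind's empty/default."""
        raise NotImplementedError  # pragma: no cover

    def _blank(self, rows: np.ndarray) -> None:  # pragma: no cover
        """Overwrite ``rows`` with the kind's empty/default value."""
        raise NotImplementedError

    # -- elementwise ----------------------------------------------------
    def _operand(self, other, op):
        if isinstance(other, Field):
            if len(other) != len(self):
                raise ValueError("elementwise operands differ in length")
            return self._op_values(other), other
        return other, None

    def _op_values(self, other):
        raise TypeError(
            f"{self.kind} field does not support elementwise operands "
            f"of kind {other.kind}")

    def _binop(self, other, op, arithmetic: bool):
        raise TypeError(f"{self.kind} fields do not support {op!r}")

    def __add__(self, other): return self._binop(other, "+", True)
    def __sub__(self, other): return self._binop(other, "-", True)
    def __mul__(self, other): return self._binop(other, "*", True)
    def __truediv__(self, other): return self._binop(other, "/", True)
    def __and__(self, other): return self._binop(other, "&", True)
    def __or__(self, other): return self._binop(other, "|", True)
    def __eq__(self, other): return self._binop(other, "==", False)
    def __ne__(self, other): return self._binop(other, "!=", False)
    def __lt__(self, other): return self._binop(other, "<", False)
    def __gt__(self, other): return self._binop(other, ">", False)
    def __le__(self, other): return self._binop(other, "<=", False)
    def __ge__(self, other): return self._binop(other, ">=", False)

    __hash__ = None


_OPS = {
    "+": np.add, "-": np.subtract, "*": np.multiply, "/": np.true_divide,
    "&": np.bitwise_and, "|": np.bitwise_or,
    "==": np.equal, "!=": np.not_equal, "<": np.less, ">": np.greater,
    "<=": np.less_equal, ">=": np.greater_equal,
}


class _ArrayField(Field):
    """Shared machinery for fields backed by a single numpy array."""

    def __init__(self, data: np.ndarray, valid=None):
        self.data = np.asarray(data)
        self.valid = None if valid is None else np.asarray(valid, dtype=bool)

    def __len__(self) -> int:
        return len(self.data)

    def slice_values(self, start, stop):
        return self.data[start:stop]

    def sort_keys(self):
        return self.data

    def _take(self, idx):
        return type(self)(self.data[idx], **self._params())

    def _filled_default(self, count):
        return type(self)(np.zeros(count, dtype=self.data.dtype),
                          **self._params())

    def _params(self) -> dict:
        return {}


class NumericField(_ArrayField):
    """Numeric / logical column with an optional validity companion.

    Where ``valid[i]`` is False the stored value is the import-time
    default; consumers must treat the entry as missing.
    """

    kind = "numeric"

    @property
    def value_type(self) -> str:
        name = self.data.dtype.name
        return "bool" if name == "bool" else name

    def _blank(self, rows):
        self.data = self.data.copy()
        self.data[rows] = False if self.data.dtype == bool else 0

    def _op_values(self, other):
        if other.kind not in ("numeric", "timestamp"):
            return super()._op_values(other)
        return other.data

    def _binop(self, other, op, arithmetic):
        rhs = self._op_values(other) if isinstance(other, Field) else other
        result = _OPS[op](self.data, rhs)
        return NumericField(result)


class TimestampField(_ArrayField):
    """POSIX timestamps, float64 seconds since the epoch (UTC)."""

    kind = "timestamp"
    DAY = 86400.0

    def __init__(self, data, valid=None):
        super().__init__(np.asarray(data, dtype=np.float64), valid)

    def day(self) -> "TimestampField":
        """Quantise each timestamp to midnight UTC of its calendar day."""
        return TimestampField(np.floor(self.data / self.DAY) * self.DAY,
                              None if self.valid is None else self.valid)

    def _blank(self, rows):
        self.data = self.data.copy()
        self.data[rows] = 0.0

    def _op_values(self, other):
        if other.kind not in ("numeric", "timestamp"):
            return super()._op_values(other)
        return other.data

    def _binop(self, other, op, arithmetic):
        rhs = self._op_values(other) if isinstance(other, Field) else other
        result = _OPS[op](self.data, rhs)
        if arithmetic and op in ("+", "-"):
            return TimestampField(result)
        return NumericField(result)


class CategoricalField(_ArrayField):
    """Small-integer codes plus a code -> label key.

    A designated free-text code (from leaky-categorical import) may be
    absent from the key; its text lives in a companion indexed-string
    field.
    """

    kind = "categorical"

    def __init__(self, codes, key: dict, valid=None, freetext_code=None):
        super().__init__(np.asarray(codes), valid)
        self.key = {int(k): str(v) for k, v in key.items()}
        self.freetext_code = freetext_code

    def _params(self):
        return {"key": self.key, "freetext_code": self.freetext_code}

    @property
    def codes(self):
        return self.data

    def labels(self) -> list[str]:
        return [self.key.get(int(c), "") for c in self.data]

    def _blank(self, rows):
        self.data = self.data.copy()
        self.data[rows] = 0

    def _binop(self, other, op, arithmetic):
        if op not in ("==", "!=", "<", ">", "<=", ">="):
            raise TypeError(f"categorical fields do not support {op!r}")
        if isinstance(other, CategoricalField):
            rhs = other.data
        elif isinstance(other, Field):
            raise TypeError("categorical comparisons need codes or a "
                            "categorical field")
        else:
            rhs = other
        return NumericField(_OPS[op](self.data, rhs))


class FixedStringField(_ArrayField):
    """Byte strings with a fixed per-entry capacity ``width`` (UTF-8 bytes)."""

    kind = "fixed_string"

    def __init__(self, data, width: int | None = None, valid=None):
        data = np.asarray(data)
        if data.dtype.kind != "S":
            if width is None:
                raise ValueError("width required when data is not bytes")
            data = data.astype(f"S{width}")
        super().__init__(data, valid)
        self.width = int(width if width is not None else data.dtype.itemsize)
        if data.dtype.itemsize != self.width:
            self.data = data.astype(f"S{self.width}")

    @classmethod
    def from_strings(cls, strings, width: int) -> "FixedStringField":
        enc = []
        for i, s in enumerate(strings):
            b = s.encode("utf-8")
            if len(b) > width:
                raise ValueError(
                    f"row {i}: encoded entry is {len(b)} bytes, "
                    f"exceeds fixed width {width}")
            enc.append(b)
        return cls(np.array(enc, dtype=f"S{width}") if enc
                   else np.empty(0, dtype=f"S{width}"), width)

    def _params(self):
        return {"width": self.width}

    def tolist(self) -> list[str]:
        return [b.decode("utf-8") for b in self.data.tolist()]

    def _blank(self, rows):
        self.data = self.data.copy()
        self.data[rows] = b""

    def _binop(self, other, op, arithmetic):
        if op not in ("==", "!=", "<", ">", "<=", ">="):
            raise TypeError(f"fixed string fields do not support {op!r}")
        if isinstance(other, FixedStringField):
            rhs = other.data
        elif isinstance(other, (str, bytes)):
            rhs = other.encode("utf-8") if isinstance(other, str) else other
        else:
            raise TypeError("fixed string comparison needs a string operand")
        return NumericField(_OPS[op](self.data, rhs))


class IndexedStringField(Field):
    """Variable-length strings: n+1 offsets + one concatenated byte buffer."""

    kind = "indexed_string"

    def __init__(self, index, values, valid=None):
        self.index = np.asarray(index, dtype=np.int64)
        self.values = np.asarray(values, dtype=np.uint8)
        self.valid = None if valid is None else np.asarray(valid, dtype=bool)
        if len(self.index) == 0 or self.index[0] != 0:
            raise ValueError("offset index must start at 0")
        if (np.diff(self.index) < 0).any():
            raise ValueError("offset index must be non-decreasing")
        if self.index[-1] != len(self.values):
            raise ValueError("final offset must equal the value buffer length")

    @classmethod
    def from_strings(cls, strings) -> "IndexedStringField":
        return cls(*encode_indexed(strings))

    def __len__(self) -> int:
        return len(self.index) - 1

    def __getitem__(self, i: int) -> str:
        n = len(self)
        if not 0 <= i < n:
            raise IndexError(f"index {i} out of range for {n} entries")
        return bytes(self.values[self.index[i]:self.index[i + 1]]) \
            .decode("utf-8")

    def tolist(self) -> list[str]:
        return [self[i] for i in range(len(self))]

    def byte_entries(self, start: int = 0, stop: int | None = None):
        """Entries ``start:stop`` as an object array of ``bytes``."""
        stop = len(self) if stop is None else stop
        buf = self.values.tobytes()
        return np.array(
            [buf[self.index[i]:self.index[i + 1]] for i in range(start, stop)],
            dtype=object)

    def slice_values(self, start, stop):
        return self.byte_entries(start, stop)

    def sort_keys(self):
        return self.byte_entries()

    def sort_key_slice(self, start, stop):
        return self.byte_entries(start, stop)

    def _gather(self, idx: np.ndarray) -> "IndexedStringField":
        starts = self.index[idx]
        lens = self.index[idx + 1] - starts
        out_index = np.zeros(len(idx) + 1, dtype=np.int64)
        np.cumsum(lens, out=out_index[1:])
        total = int(out_index[-1])
        if total:
            inner = np.arange(total, dtype=np.int64) \
                - np.repeat(out_index[:-1], lens)
            src = np.repeat(starts, lens) + inner
            out_values = self.values[src]
        else:
            out_values = np.empty(0, dtype=np.uint8)
        return IndexedStringField(out_index, out_values)

    _take = _gather

    def _filled_default(self, count):
        return IndexedStringField.from_strings([""] * count)

    def _blank(self, rows):
        # re-encode with the blanked rows empty; gather already copied
        strings = self.tolist()
        for r in rows:
            strings[int(r)] = ""
        self.index, self.values = encode_indexed(strings)

    def apply_filter(self, mask):
        mask = np.asarray(mask, dtype=bool)
        if len(mask) != len(self):
            raise ValueError(
                f"filter length {len(mask)} != field length {len(self)}")
        out = self._gather(np.flatnonzero(mask))
        if self.valid is not None:
            out.valid = self.valid[mask]
        return out

    def _binop(self, other, op, arithmetic):
        if op not in ("==", "!="):
            raise TypeError(f"indexed string fields do not support {op!r}")
        if isinstance(other, IndexedStringField):
            if len(other) != len(self):
                raise ValueError("elementwise operands differ in length")
            rhs = other.byte_entries()
        elif isinstance(other, str):
            rhs = other.encode("utf-8")
        else:
            raise TypeError("indexed string comparison needs a string operand")
        return NumericField(_OPS[op](self.byte_entries(), rhs))

    @property
    def stored_bytes(self) -> int:
        """Bytes occupied: 8*(n+1) offsets + total text bytes, no padding."""
        return self.index.nbytes + self.values.nbytes
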