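"""Schema-driven, streaming CSV import into typed drive-backed fields.

The importer reads RFC-4180-style CSV (doubled-quote escaping, cells may
contain commas and newlines, UTF-8 with an optional BOM) in chunks of
``chunk_rows`` rows and converts each schema column to its typed field in
a single stage — the store produced is bit-identical for any chunking.

Dirty source columns are split on import rather than rejected:

* numeric columns with empty cells become a typed value column (empty ->
  a configurable default) plus an optional boolean presence flag;
* "leaky" categorical columns mixing a closed label set with free text
  become a code column (free text -> a designated code outside the key)
  plus an indexed-string companion holding the raw text;
* datetime columns become float64 POSIX-second timestamps (UTC), with an
  optional day field quantised to midnight UTC and an optional presence
  flag when empties are allowed.

The schema is JSON: ``{"schema": {<table>: {"primary_keys": [...],
"foreign_keys": {<field>: <table>}, "fields": {<name>: {"field_type":
...}}}}}``. See :func:`parse_schema` for per-type parameters.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone

import numpy as np

from . import fields as fld

FIELD_TYPES = ("fixed_string", "indexed_string", "numeric", "categorical",
               "leaky_categorical", "datetime")

#: Rows converted per chunk by default.
DEFAULT_CHUNK_ROWS = 1 << 16


class SchemaError(ValueError):
    """A structural problem in a schema file, with the offending path."""


class ImportError_(ValueError):
    """A row-addressed conversion failure during import."""


# ---------------------------------------------------------------------------
# schema descriptors


@dataclass
class FieldDescriptor:
    name: str
    field_type: str
    width: int | None = None                 # fixed_string
    value_type: str | None = None            # numeric
    invalid_default: object = 0              # numeric
    create_flag: bool = False                # numeric
    parse_mode: str = "strict"               # numeric: strict | lenient
    key: dict | None = None                  # categorical / leaky
    freetext_code: int | None = None         # leaky
    create_day: bool = False                 # datetime
    optional: bool = False                   # datetime


@dataclass
class TableDescriptor:
    name: str
    primary_keys: list = dc_field(default_factory=list)
    foreign_keys: dict = dc_field(default_factory=dict)
    fields: dict = dc_field(default_factory=dict)  # name -> FieldDescriptor


@dataclass
class SchemaDescriptor:
    tables: dict  # name -> TableDescriptor


def _parse_field(table: str, name: str, entry: dict) -> FieldDescriptor:
    path = f"schema.{table}.fields.{name}"
    if not isinstance(entry, dict) or "field_type" not in entry:
        raise SchemaError(f"{path}: missing field_type")
    ft = entry["field_type"]
    if ft not in FIELD_TYPES:
        raise SchemaError(f"{path}: unknown field_type {ft!r}")
    d = FieldDescriptor(name=name, field_type=ft)
    if ft == "fixed_string":
        if "width" not in entry:
            raise SchemaError(f"{path}: fixed_string requires width")
        d.width = int(entry["width"])
    elif ft == "numeric":
        if "value_type" not in entry:
            raise SchemaError(f"{path}: numeric requires value_type")
        d.value_type = entry["value_type"]
        try:
            fld.numeric_dtype(d.value_type)
        except ValueError as e:
            raise SchemaError(f"{path}: {e}") from None
        d.invalid_default = entry.get("invalid_default", 0)
        d.create_flag = bool(entry.get("create_flag", False))
        d.parse_mode = entry.get("parse_mode", "strict")
        if d.parse_mode not in ("strict", "lenient"):
            raise SchemaError(f"{path}: parse_mode must be strict or lenient")
    elif ft in ("categorical", "leaky_categorical"):
        if "key" not in entry or not isinstance(entry["key"], dict):
            raise SchemaError(f"{path}: {ft} requires a key mapping")
        d.key = {str(k): int(v) for k, v in entry["key"].items()}
        if ft == "leaky_categorical":
            if "freetext_code" not in entry:
                raise SchemaError(f"{path}: leaky_categorical requires "
                                  f"freetext_code")
            d.freetext_code = int(entry["freetext_code"])
            if d.freetext_code in d.key.values():
                raise SchemaError(f"{path}: freetext_code collides with key")
    elif ft == "datetime":
        d.create_day = bool(entry.get("create_day", False))
        d.optional = bool(entry.get("optional", False))
    return d


def parse_schema(text: str) -> SchemaDescriptor:
    """Parse and validate a schema JSON document.

    Checks that every field type is known with its required parameters
    present, that primary-key names exist among the fields, and that
    every foreign key references an existing table. Errors name the
    offending path.
    """
    doc = json.loads(text)
    if not isinstance(doc, dict) or "schema" not in doc \
            or not isinstance(doc["schema"], dict):
        raise SchemaError("top level must be a {'schema': {...}} dictionary")
    tables: dict[str, TableDescriptor] = {}
    for tname, tentry in doc["schema"].items():
        if not isinstance(tentry, dict) or "fields" not in tentry:
            raise SchemaError(f"schema.{tname}: missing fields")
        td = TableDescriptor(name=tname)
        td.primary_keys = list(tentry.get("primary_keys", []))
        td.foreign_keys = dict(tentry.get("foreign_keys", {}))
        for fname, fentry in tentry["fields"].items():
            td.fields[fname] = _parse_field(tname, fname, fentry)
        for pk in td.primary_keys:
            if pk not in td.fields:
                raise SchemaError(
                    f"schema.{tname}.primary_keys: {pk!r} is not a field")
        for fk in td.foreign_keys:
            if fk not in td.fields:
                raise SchemaError(
                    f"schema.{tname}.foreign_keys: {fk!r} is not a field")
        tables[tname] = td
    for tname, td in tables.items():
        for fk, ref in td.foreign_keys.items():
            if ref not in tables:
                raise SchemaError(
                    f"schema.{tname}.foreign_keys.{fk}: references "
                    f"missing table {ref!r}")
    return SchemaDescriptor(tables=tables)


def load_schema(path) -> SchemaDescriptor:
    with open(path, "r", encoding="utf-8-sig") as f:
        return parse_schema(f.read())


# ---------------------------------------------------------------------------
# converters


def convert_numeric(cells, value_type: str, invalid_default=0,
                    create_flag: bool = False, parse_mode: str = "strict",
                    row_offset: int = 0):
    """Convert text cells to a typed numeric column.

    Empty cells take ``invalid_default`` with a presence flag of False.
    Non-empty unparseable cells raise (strict, citing the row) or are
    treated as empty (lenient). Returns ``(NumericField, flags-or-None)``;
    flags are produced iff ``create_flag``.
    """
    dtype = fld.numeric_dtype(value_type)
    cells = list(cells)
    n = len(cells)
    valid = np.ones(n, dtype=bool)
    out = np.empty(n, dtype=dtype)

    def parse_one(text: str):
        if dtype == np.bool_:
            low = text.strip().lower()
            if low in ("true", "1", "t", "yes"):
                return True
            if low in ("false", "0", "f", "no"):
                return False
            raise ValueError(f"not a boolean: {text!r}")
        if dtype.kind in "iu":
            return dtype.type(int(text))
        return dtype.type(float(text))

    for i, c in enumerate(cells):
        if c == "":
            valid[i] = False
            out[i] = dtype.type(invalid_default)
            continue
        try:
            out[i] = parse_one(c)
        except (ValueError, OverflowError):
            if parse_mode == "strict":
                raise ImportError_(
                    f"row {row_offset + i}: cannot parse {c!r} as "
                    f"{value_type}") from None
            valid[i] = False
            out[i] = dtype.type(invalid_default)
    f = fld.NumericField(out)
    return f, (np.asarray(valid) if create_flag else None)


def convert_categorical(cells, key: dict, row_offset: int = 0
                        ) -> fld.CategoricalField:
    """Map each cell through the label -> code key; absent labels raise
    with the row number and value."""
    codes = np.empty(len(cells), dtype=np.int32)
    for i, c in enumerate(cells):
        try:
            codes[i] = key[c]
        except KeyError:
            raise ImportError_(
                f"row {row_offset + i}: value {c!r} not in categorical "
                f"key") from None
    return fld.CategoricalField(codes, {v: k for k, v in key.items()})


def convert_leaky_categorical(cells, key: dict, freetext_code: int):
    """Split a mixed categorical/free-text column into a code column and
    an indexed-string companion.

    Cells in the key map to their code with an empty companion entry;
    anything else takes ``freetext_code`` and the raw text goes to the
    companion (same length as the input).
    """
    if freetext_code in key.values():
        raise ValueError("freetext_code must not be a value in the key")
    codes = np.empty(len(cells), dtype=np.int32)
    texts = []
    for i, c in enumerate(cells):
        code = key.get(c)
        if code is None:
            codes[i] = freetext_code
            texts.append(c)
        else:
            codes[i] = code
            texts.append("")
    cat = fld.CategoricalField(codes, {v: k for k, v in key.items()},
                               freetext_code=freetext_code)
    return cat, fld.IndexedStringField.from_strings(texts)


_ISO_FORMATS = ("%Y-%m-%dT%H:%M:%S", "%Y-%m-%d %H:%M:%S", "%Y-%m-%d",
                "%Y-%m-%dT%H:%M:%S.%f")


def _parse_iso(text: str) -> float:
    for fmt in _ISO_FORMATS:
        try:
            dt = datetime.strptime(text, fmt)
            return dt.replace(tzinfo=timezone.utc).timestamp()
        except ValueError:
            continue
    raise ValueError(f"not an ISO-8601 date/datetime: {text!r}")


def convert_datetime(cells, create_day: bool = False, optional: bool = False,
                     row_offset: int = 0):
    """Convert ISO-8601 date/datetime cells to POSIX float64 seconds (UTC).

    Returns ``(TimestampField, day-field-or-None, flags-or-None)``. The
    day field holds midnight UTC of each entry's calendar day. Empty
    cells are allowed only when ``optional`` and yield 0.0 with a False
    flag; unparseable non-empty cells raise with the row number.
    """
    n = len(cells)
    out = np.zeros(n, dtype=np.float64)
    valid = np.ones(n, dtype=bool)
    for i, c in enumerate(cells):
        if c == "":
            if not optional:
                raise ImportError_(
                    f"row {row_offset + i}: empty datetime in a "
                    f"non-optional field")
            valid[i] = False
            continue
        try:
            out[i] = _parse_iso(c)
        except ValueError:
            raise ImportError_(f"row {row_offset + i}: {c!r} is not an "
                               f"ISO date/datetime") from None
    ts = fld.TimestampField(out)
    day = None
    if create_day:
        day = ts.day()
        if not valid.all():
            day.data[~valid] = 0.0
    return ts, day, (valid if optional else None)


def convert_fixed_string(cells, width: int, row_offset: int = 0
                         ) -> fld.FixedStringField:
    enc = np.empty(len(cells), dtype=f"S{width}")
    for i, c in enumerate(cells):
        b = c.encode("utf-8")
        if len(b) > width:
            raise ImportError_(
                f"row {row_offset + i}: entry is {len(b)} bytes, exceeds "
                f"fixed width {width}")
        enc[i] = b
    return fld.FixedStringField(enc, width)


# ---------------------------------------------------------------------------
# table import / export


def _convert_column(desc: FieldDescriptor, cells, row_offset: int
                    ) -> list[tuple[str, fld.Field]]:
    """Convert one column chunk; returns (field name, field) pairs
    including companions."""
    name = desc.name
    ft = desc.field_type
    if ft == "fixed_string":
        return [(name, convert_fixed_string(cells, desc.width, row_offset))]
    if ft == "indexed_string":
        return [(name, fld.IndexedStringField.from_strings(cells))]
    if ft == "numeric":
        value, flags = convert_numeric(
            cells, desc.value_type, desc.invalid_default, desc.create_flag,
            desc.parse_mode, row_offset)
        out = [(name, value)]
        if flags is not None:
            out.append((f"{name}_valid", fld.NumericField(flags)))
        return out
    if ft == "categorical":
        return [(name, convert_categorical(cells, desc.key, row_offset))]
    if ft == "leaky_categorical":
        cat, freetext = convert_leaky_categorical(cells, desc.key,
                                                  desc.freetext_code)
        return [(name, cat), (f"{name}_freetext", freetext)]
    if ft == "datetime":
        ts, day, flags = convert_datetime(cells, desc.create_day,
                                          desc.optional, row_offset)
        out = [(name, ts)]
        if day is not None:
            out.append((f"{name}_day", day))
        if flags is not None:
            out.append((f"{name}_valid", fld.NumericField(flags)))
        return out
    raise SchemaError(f"unknown field_type {ft!r}")  # pragma: no cover


def import_csv(table: TableDescriptor, source, dest,
               chunk_rows: int = DEFAULT_CHUNK_ROWS,
               progress=None) -> int:
    """Stream a CSV table into typed fields of ``dest``; returns the row
    count.

    ``source`` is a path or a text stream. The header must cover every
    schema field name; extra CSV columns are ignored. Rows are processed
    in chunks of ``chunk_rows``, so peak buffering per field is one
    chunk's cells; row order is preserved and the result is independent
    of the chunking.
    """
    own = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        stream = open(source, "r", encoding="utf-8-sig", newline="")
        own = True
    else:
        stream = source
    try:
        reader = csv.reader(stream)
        try:
            header = next(reader)
        except StopIteration:
            raise ImportError_("empty CSV: no header row") from None
        missing = [n for n in table.fields if n not in header]
        if missing:
            raise ImportError_(
                f"CSV header is missing schema column(s): {missing}")
        cols = {n: header.index(n) for n in table.fields}
        width = len(header)

        buffers: dict[str, list] = {n: [] for n in table.fields}
        total = 0

        def flush(row_offset: int) -> None:
            for n, desc in table.fields.items():
                for out_name, f in _convert_column(desc, buffers[n],
                                                   row_offset):
                    dest.append(out_name, f)
                buffers[n] = []

        chunk_base = 0
        for rownum, row in enumerate(reader):
            if len(row) != width:
                raise ImportError_(
                    f"row {rownum}: expected {width} cells, got {len(row)}")
            for n, ci in cols.items():
                buffers[n].append(row[ci])
            total += 1
            if total - chunk_base >= chunk_rows:
                flush(chunk_base)
                if progress is not None:
                    progress(total)
                chunk_base = total
        flush(chunk_base)
        if progress is not None:
            progress(total)
        dest.finish()
        return total
    finally:
        if own:
            stream.close()


def _format_timestamp(ts: float) -> str:
    dt = datetime.fromtimestamp(ts, tz=timezone.utc)
    if dt.hour == dt.minute == dt.second == 0 and dt.microsecond == 0:
        return dt.strftime("%Y-%m-%d")
    return dt.strftime("%Y-%m-%dT%H:%M:%S")


def export_csv(table: TableDescriptor, df, dest) -> int:
    """Write an imported table back to CSV in canonical formatting.

    Canonical means: invalid numeric/datetime entries export as empty
    cells, floats as their shortest round-tripping decimal, categoricals
    as their labels (free-text code -> the companion's raw text),
    timestamps as ISO-8601 UTC. Re-importing the file with the same
    schema reproduces the original fields exactly.
    """
    own = False
    if isinstance(dest, (str, bytes)) or hasattr(dest, "__fspath__"):
        stream = open(dest, "w", encoding="utf-8", newline="")
        own = True
    else:
        stream = dest
    try:
        writer = csv.writer(stream, lineterminator="\n")
        names = list(table.fields)
        writer.writerow(names)
        n = df.row_count
        columns = []
        for name in names:
            desc = table.fields[name]
            f = df[name].to_memory()
            if desc.field_type == "fixed_string":
                columns.append(f.tolist())
            elif desc.field_type == "indexed_string":
                columns.append(f.tolist())
            elif desc.field_type == "numeric":
                valid = df[f"{name}_valid"].data.astype(bool) \
                    if desc.create_flag and f"{name}_valid" in df.keys() \
                    else np.ones(n, dtype=bool)
                cells = []
                for v, ok in zip(f.data.tolist(), valid):
                    if not ok:
                        cells.append("")
                    elif isinstance(v, bool):
                        cells.append("True" if v else "False")
                    else:
                        cells.append(repr(v))
                columns.append(cells)
            elif desc.field_type == "categorical":
                inv = {v: k for k, v in desc.key.items()}
                columns.append([inv[int(c)] for c in f.data])
            elif desc.field_type == "leaky_categorical":
                inv = {v: k for k, v in desc.key.items()}
                freetext = df[f"{name}_freetext"].to_memory()
                cells = []
                for i, c in enumerate(f.data):
                    c = int(c)
                    cells.append(freetext[i] if c == desc.freetext_code
                                 else inv[c])
                columns.append(cells)
            elif desc.field_type == "datetime":
                valid = df[f"{name}_valid"].data.astype(bool) \
                    if desc.optional and f"{name}_valid" in df.keys() \
                    else np.ones(n, dtype=bool)
                columns.append([_format_timestamp(v) if ok else ""
                                for v, ok in zip(f.data, valid)])
        for i in range(n):
            writer.writerow([col[i] for col in columns])
        return n
    finally:
        if own:
            stream.close()
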