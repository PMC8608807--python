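"""Schema parsing and typed CSV import/export."""

import io
import json

import numpy as np
import pytest

from colstore import Dataset, parse_schema, import_csv, export_csv
from colstore.importer import (
    ImportError_,
    SchemaError,
    convert_categorical,
    convert_datetime,
    convert_leaky_categorical,
    convert_numeric,
)

SEVERITY = {"": 0, "mild": 1, "moderate": 2, "severe": 3}


def schema_doc(fields, table="t", pk=("id",), fk=None, extra_tables=None):
    doc = {"schema": {table: {
        "primary_keys": list(pk),
        "foreign_keys": fk or {},
        "fields": fields,
    }}}
    if extra_tables:
        doc["schema"].update(extra_tables)
    return json.dumps(doc)


class TestParseSchema:
    def test_minimal(self):
        s = parse_schema(schema_doc(
            {"id": {"field_type": "fixed_string", "width": 4}}))
        assert list(s.tables) == ["t"]
        assert s.tables["t"].fields["id"].width == 4

    def test_categorical_key_preserved_verbatim(self):
        s = parse_schema(schema_doc({
            "id": {"field_type": "fixed_string", "width": 4},
            "sev": {"field_type": "categorical", "key": SEVERITY}},
        ))
        assert s.tables["t"].fields["sev"].key == SEVERITY

    @pytest.mark.parametrize("fields, pk, fk, match", [
        ({"x": {"field_type": "nonesuch"}}, (), None, "field_type"),
        ({"x": {"field_type": "fixed_string"}}, (), None, "width"),
        ({"x": {"field_type": "numeric"}}, (), None, "value_type"),
        ({"x": {"field_type": "leaky_categorical", "key": {"a": 0}}},
         (), None, "freetext_code"),
        ({"x": {"field_type": "indexed_string"}}, ("missing",), None,
         "primary_keys"),
        ({"x": {"field_type": "fixed_string", "width": 2}}, (),
         {"x": "elsewhere"}, "elsewhere"),
    ])
    def test_structural_errors_name_the_path(self, fields, pk, fk, match):
        with pytest.raises(SchemaError, match=match):
            parse_schema(schema_doc(fields, pk=pk, fk=fk))

    def test_valid_foreign_key(self):
        s = parse_schema(schema_doc(
            {"pid": {"field_type": "fixed_string", "width": 4}},
            pk=(), fk={"pid": "parent"},
            extra_tables={"parent": {"fields": {
                "id": {"field_type": "fixed_string", "width": 4}}}}))
        assert s.tables["t"].foreign_keys == {"pid": "parent"}


class TestConverters:
    def test_numeric_empties_take_default_with_flag(self):
        f, valid = convert_numeric(["1.5", "", "2"], "float32", 0.0, True)
        assert f.data.tolist() == [1.5, 0.0, 2.0]
        assert f.data.dtype == np.float32
        assert valid.tolist() == [True, False, True]

    def test_numeric_int(self):
        f, valid = convert_numeric(["7"], "int32", -1, True)
        assert f.data.tolist() == [7]
        assert valid.tolist() == [True]

    def test_numeric_strict_cites_row(self):
        with pytest.raises(ImportError_, match="row 0"):
            convert_numeric(["abc"], "float32")
        with pytest.raises(ImportError_, match="row 12"):
            convert_numeric(["1", "2", "abc"], "float32", row_offset=10)

    def test_numeric_lenient_treats_junk_as_empty(self):
        f, valid = convert_numeric(["abc", "4"], "int32", -1, True,
                                   parse_mode="lenient")
        assert f.data.tolist() == [-1, 4]
        assert valid.tolist() == [False, True]

    def test_leaky_categorical_split(self):
        key = {"mild": 0, "moderate": 1, "severe": 2}
        cat, freetext = convert_leaky_categorical(
            ["mild", "dunno, tired", "severe"], key, -1)
        assert cat.data.tolist() == [0, -1, 2]
        assert freetext.tolist() == ["", "dunno, tired", ""]

    def test_leaky_all_in_key_gives_empty_companion_buffer(self):
        cat, freetext = convert_leaky_categorical(
            ["mild", "severe"], {"mild": 0, "severe": 2}, -1)
        assert len(freetext.values) == 0
        assert freetext.tolist() == ["", ""]

    def test_leaky_all_free_text(self):
        cat, freetext = convert_leaky_categorical(
            ["x", "y"], {"mild": 0}, -1)
        assert cat.data.tolist() == [-1, -1]
        assert freetext.tolist() == ["x", "y"]

    def test_categorical_strict(self):
        key = {"": 0, "mild": 1, "moderate": 2, "severe": 3}
        assert convert_categorical(["severe", "mild"], key) \
            .data.tolist() == [3, 1]
        assert convert_categorical([""], key).data.tolist() == [0]
        with pytest.raises(ImportError_, match="unknown"):
            convert_categorical(["unknown"], key)

    def test_datetime_epoch_and_day(self):
        ts, day, valid = convert_datetime(["1970-01-01T00:00:00"])
        assert ts.data.tolist() == [0.0]
        ts, day, valid = convert_datetime(["1970-01-02T13:45:00"],
                                          create_day=True)
        assert day.data.tolist() == [86400.0]

    def test_datetime_optional_empty(self):
        ts, day, valid = convert_datetime(["", "1970-01-01"], optional=True)
        assert valid.tolist() == [False, True]
        assert ts.data.tolist() == [0.0, 0.0]

    def test_datetime_errors(self):
        with pytest.raises(ImportError_, match="row 1"):
            convert_datetime(["1970-01-01", "not a date"])
        with pytest.raises(ImportError_):
            convert_datetime([""], optional=False)


MIXED_SCHEMA = schema_doc({
    "id": {"field_type": "fixed_string", "width": 8},
    "temp": {"field_type": "numeric", "value_type": "float32",
             "invalid_default": 0.0, "create_flag": True},
    "sev": {"field_type": "leaky_categorical", "key": SEVERITY,
            "freetext_code": -1},
    "when": {"field_type": "datetime", "create_day": True,
             "optional": True},
    "note": {"field_type": "indexed_string"},
})

MIXED_CSV = (
    "id,temp,sev,when,note\n"
    "a1,36.5,mild,2020-03-01T10:00:00,\n"
    'a2,,"feels odd, tired",2020-03-01,"a,\nb"\n'
    "a3,38.25,severe,,plain\n"
)


class TestImportCsv:
    def _import(self, ds, csv_text, chunk_rows=1000, schema=MIXED_SCHEMA):
        table = parse_schema(schema).tables["t"]
        df = ds.create_dataframe("t")
        n = import_csv(table, io.StringIO(csv_text), df, chunk_rows)
        return n, df

    def test_companion_expansion(self, store):
        n, df = self._import(store, MIXED_CSV)
        assert n == 3
        assert set(df.keys()) == {"id", "temp", "temp_valid", "sev",
                                  "sev_freetext", "when", "when_day",
                                  "when_valid", "note"}
        assert df["temp"].data.tolist() == pytest.approx([36.5, 0.0, 38.25])
        assert df["temp_valid"].data.tolist() == [True, False, True]
        assert df["sev"].data.tolist() == [1, -1, 3]
        assert df["sev_freetext"].tolist() == ["", "feels odd, tired", ""]
        assert df["when_valid"].data.tolist() == [True, True, False]

    def test_quoted_comma_and_newline_stay_one_cell(self, store):
        n, df = self._import(store, MIXED_CSV)
        assert df["note"].tolist() == ["", "a,\nb", "plain"]

    def test_header_only_gives_zero_rows(self, store):
        n, df = self._import(store, "id,temp,sev,when,note\n")
        assert n == 0
        assert df.row_count == 0
        assert all(len(df[f]) == 0 for f in df.keys())

    def test_missing_header_column_rejected(self, store):
        with pytest.raises(ImportError_, match="note"):
            self._import(store, "id,temp,sev,when\na,1,mild,2020-01-01\n")

    def test_ragged_row_cites_row_number(self, store):
        bad = "id,temp,sev,when,note\na1,1,mild,2020-01-01,x\na2,2,mild\n"
        with pytest.raises(ImportError_, match="row 1"):
            self._import(store, bad)

    def test_extra_csv_columns_ignored(self, store):
        csv_text = ("junk,id,temp,sev,when,note\n"
                    "zz,a1,1,mild,2020-01-01,x\n")
        n, df = self._import(store, csv_text)
        assert n == 1
        assert df["id"].tolist() == ["a1"]

    def test_bom_tolerated(self, tmp_path):
        p = tmp_path / "bom.csv"
        p.write_bytes("﻿id,temp,sev,when,note\na,1,mild,,x\n"
                      .encode("utf-8"))
        with Dataset(tmp_path / "bom.h5", "write") as ds:
            table = parse_schema(MIXED_SCHEMA).tables["t"]
            df = ds.create_dataframe("t")
            assert import_csv(table, p, df) == 1


def _store_bytes(df):
    out = {}
    for name in df.keys():
        f = df[name]
        if f.kind == "indexed_string":
            out[name] = (f.to_memory().index.tobytes(),
                         f.to_memory().values.tobytes())
        else:
            out[name] = f.data.tobytes()
    return out


def test_chunk_size_invariance(tmp_path):
    table = parse_schema(MIXED_SCHEMA).tables["t"]
    results = {}
    for chunk_rows in (1, 7, 1000):
        with Dataset(tmp_path / f"c{chunk_rows}.h5", "write") as ds:
            df = ds.create_dataframe("t")
            import_csv(table, io.StringIO(MIXED_CSV), df, chunk_rows)
            results[chunk_rows] = _store_bytes(df)
    assert results[1] == results[7] == results[1000]


def test_export_then_reimport_is_lossless(tmp_path):
    table = parse_schema(MIXED_SCHEMA).tables["t"]
    with Dataset(tmp_path / "a.h5", "write") as ds:
        df = ds.create_dataframe("t")
        import_csv(table, io.StringIO(MIXED_CSV), df)
        buf = io.StringIO()
        export_csv(table, df, buf)
        with Dataset(tmp_path / "b.h5", "write") as ds2:
            df2 = ds2.create_dataframe("t")
            import_csv(table, io.StringIO(buf.getvalue()), df2)
            assert _store_bytes(df) == _store_bytes(df2)


def test_long_text_storage_proportional_to_content(tmp_path):
    rows = 2000
    long_note = "y" * 600
    lines = ["id,temp,sev,when,note"]
    for i in range(rows):
        note = long_note if i == 0 else ""
        lines.append(f"a{i},1.0,mild,2020-01-01,{note}")
    table = parse_schema(MIXED_SCHEMA).tables["t"]
    with Dataset(tmp_path / "long.h5", "write") as ds:
        df = ds.create_dataframe("t")
        import_csv(table, io.StringIO("\n".join(lines) + "\n"), df)
        stored = df["note"].stored_bytes
    assert stored == 8 * (rows + 1) + 600
    assert stored < 600 * rows / 10
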