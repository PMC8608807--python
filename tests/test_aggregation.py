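"""Span computation and streaming per-group reduction."""

import numpy as np
import pytest

from colstore import apply_spans, compute_spans, quantise_daily_max
from colstore.fields import (
    CategoricalField,
    FixedStringField,
    IndexedStringField,
    NumericField,
    TimestampField,
)
from _oracles import group_reduce, daily_max_oracle

DAY = 86400.0


class TestComputeSpans:
    def test_example(self):
        sp = compute_spans(NumericField(np.array([1, 1, 2, 3, 3])))
        assert sp.tolist() == [0, 2, 3, 5]

    def test_all_equal(self):
        assert compute_spans(NumericField(np.full(7, 4))).tolist() == [0, 7]

    def test_empty(self):
        assert compute_spans(
            NumericField(np.empty(0, np.int64))).tolist() == [0]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="not sorted"):
            compute_spans(NumericField(np.array([2, 1])))
        with pytest.raises(ValueError, match="not sorted"):
            compute_spans(NumericField(np.array([1, 3, 2])), chunk_length=2)

    def test_composite_key_group_count_matches_distinct_tuples(self, rng):
        ids = np.sort(rng.integers(0, 20, 500))
        days = np.empty(500, np.int64)
        # second key sorted within first-key runs
        sp = compute_spans(NumericField(ids))
        for s, e in zip(sp[:-1], sp[1:]):
            days[s:e] = np.sort(rng.integers(0, 5, e - s))
        spans = compute_spans([NumericField(ids), NumericField(days)],
                              chunk_length=61)
        distinct = len(set(zip(ids.tolist(), days.tolist())))
        assert len(spans) - 1 == distinct

    def test_composite_unsorted_second_key_rejected(self):
        with pytest.raises(ValueError, match="not sorted"):
            compute_spans([NumericField(np.array([1, 1, 2])),
                           NumericField(np.array([2, 1, 1]))])

    def test_chunk_size_invariance(self, rng):
        v = np.sort(rng.integers(0, 40, 1000))
        f = NumericField(v)
        base = compute_spans(f).tolist()
        for chunk in (1, 3, 97, 1000, 4096):
            assert compute_spans(f, chunk_length=chunk).tolist() == base


class TestApplySpans:
    def test_max_example(self):
        out = apply_spans(np.array([0, 2, 3, 5]),
                          NumericField(np.array([4, 6, 1, 9, 2])), "max")
        assert out.data.tolist() == [6, 1, 9]

    def test_count_gives_span_lengths(self, rng):
        v = np.sort(rng.integers(0, 10, 200))
        spans = compute_spans(NumericField(v))
        out = apply_spans(spans, NumericField(v), "count")
        assert out.data.tolist() == np.diff(spans).tolist()
        assert out.data.sum() == 200  # conservation

    @pytest.mark.parametrize("reducer",
                             ["count", "min", "max", "sum", "mean",
                              "first", "last"])
    def test_matches_groupby_oracle(self, reducer):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(1, 300))
            gids = np.sort(rng.integers(0, 12, n))
            values = rng.integers(-50, 50, n).astype(np.float64)
            valid = rng.random(n) < 0.8
            spans = compute_spans(NumericField(gids))
            out = apply_spans(spans, NumericField(values), reducer,
                              valid=valid)
            oracle = group_reduce(values.tolist(), gids.tolist(), reducer,
                                  valid.tolist())
            for got, ok, want in zip(out.data.tolist(),
                                     (out.valid if out.valid is not None
                                      else np.ones(len(out.data), bool)),
                                     oracle):
                if want is None:
                    assert not ok
                else:
                    assert got == pytest.approx(want)

    def test_pandas_cross_check(self, rng):
        import pandas as pd
        gids = np.sort(rng.integers(0, 25, 2000))
        values = rng.normal(size=2000)
        spans = compute_spans(NumericField(gids))
        got = apply_spans(spans, NumericField(values), "mean")
        want = pd.Series(values).groupby(gids).mean()
        assert got.data.tolist() == pytest.approx(want.tolist())

    def test_sum_equals_mean_times_valid_count(self, rng):
        gids = np.sort(rng.integers(0, 8, 500))
        values = rng.normal(size=500)
        valid = rng.random(500) < 0.7
        spans = compute_spans(NumericField(gids))
        s = apply_spans(spans, NumericField(values), "sum", valid=valid)
        m = apply_spans(spans, NumericField(values), "mean", valid=valid)
        nv = apply_spans(spans, NumericField(valid.astype(np.int64)), "sum")
        for sv, mv, ok, k in zip(s.data, m.data, m.valid, nv.data):
            if ok:
                assert sv == pytest.approx(mv * k, rel=1e-9)

    def test_all_invalid_group_mean_is_invalid(self):
        spans = np.array([0, 2, 4])
        out = apply_spans(spans, NumericField(np.array([1.0, 2, 3, 4])),
                          "mean", valid=np.array([False, False, True, True]))
        assert out.valid.tolist() == [False, True]
        assert out.data[1] == pytest.approx(3.5)

    def test_streaming_block_invariance(self, rng):
        gids = np.sort(rng.integers(0, 30, 700))
        values = rng.integers(0, 9, 700)
        spans = compute_spans(NumericField(gids))
        base = apply_spans(spans, NumericField(values), "sum").data.tolist()
        for block in (1, 2, 7, 1 << 15):
            assert apply_spans(spans, NumericField(values), "sum",
                               span_block=block).data.tolist() == base

    def test_string_and_categorical_reducers(self):
        spans = np.array([0, 2, 4])
        strings = IndexedStringField.from_strings(["b", "a", "z", "z"])
        assert apply_spans(spans, strings, "min").tolist() == ["a", "z"]
        assert apply_spans(spans, strings, "first").tolist() == ["b", "z"]
        cat = CategoricalField(np.array([0, 2, 1, 1]),
                               {0: "none", 1: "mild", 2: "severe"})
        out = apply_spans(spans, cat, "max")
        assert out.data.tolist() == [2, 1]
        assert out.key == cat.key

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_spans(np.array([0, 3]), NumericField(np.arange(2)), "sum")
        with pytest.raises(ValueError):
            apply_spans(np.array([0, 2]), NumericField(np.arange(2)), "nope")


class TestQuantiseDailyMax:
    def _assessments(self, store, pids, ts, fatigue, temp=None,
                     temp_valid=None):
        df = store.create_dataframe("assessments")
        df.write("patient_id", FixedStringField.from_strings(pids, 8))
        df.write("created_at", TimestampField(ts))
        df.write("fatigue", NumericField(np.asarray(fatigue)))
        if temp is not None:
            df.write("temperature", NumericField(np.asarray(temp)))
            df.write("temperature_valid",
                     NumericField(np.asarray(temp_valid, dtype=bool)))
        df.finish()
        return df

    def test_same_day_reports_collapse_to_max(self, store):
        df = self._assessments(store, ["p"] * 3,
                               [100.0, 5000.0, 20000.0], [0, 2, 1])
        out = store.create_dataframe("daily")
        n = quantise_daily_max(df, out, symptoms=["fatigue"])
        assert n == 1
        assert out["fatigue"].data.tolist() == [2]
        assert out["day"].data.tolist() == [0.0]
        assert out["created_at"].data.tolist() == [100.0]  # first of day

    def test_one_report_per_day_is_identity(self, store):
        ts = [0.5 * DAY, 1.5 * DAY, 2.5 * DAY]
        df = self._assessments(store, ["p"] * 3, ts, [1, 0, 2])
        out = store.create_dataframe("daily")
        assert quantise_daily_max(df, out, symptoms=["fatigue"]) == 3
        assert out["fatigue"].data.tolist() == [1, 0, 2]
        assert out["created_at"].data.tolist() == ts

    def test_matches_per_patient_day_oracle(self, store, rng):
        n = 2000
        pids = [f"p{int(i):03d}" for i in rng.integers(0, 50, n)]
        ts = rng.uniform(0, 30, n) * DAY
        fatigue = rng.integers(0, 4, n)
        df = self._assessments(store, pids, ts, fatigue)
        out = store.create_dataframe("daily")
        quantise_daily_max(df, out, symptoms=["fatigue"])
        days = (np.floor(ts / DAY) * DAY).tolist()
        oracle = daily_max_oracle(pids, days, fatigue.tolist())
        assert out.row_count == len(oracle)
        got = dict(zip(zip(out["patient_id"].tolist(),
                           out["day"].data.tolist()),
                       out["fatigue"].data.tolist()))
        assert got == oracle
        # output sorted by (patient, day)
        keys = list(zip(out["patient_id"].tolist(),
                        out["day"].data.tolist()))
        assert keys == sorted(keys)

    def test_invalid_entries_ignored_in_max(self, store):
        df = self._assessments(store, ["p", "p"], [0.0, 1.0], [0, 1],
                               temp=[39.0, 37.0], temp_valid=[False, True])
        out = store.create_dataframe("daily")
        quantise_daily_max(df, out, symptoms=["fatigue", "temperature"])
        assert out["temperature"].data.tolist() == [37.0]

    def test_missing_field_rejected(self, store):
        df = self._assessments(store, ["p"], [0.0], [0])
        with pytest.raises(KeyError):
            quantise_daily_max(df, store.create_dataframe("daily"),
                               symptoms=["nonexistent"])
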