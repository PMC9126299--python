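import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from scdropout import (CountTable, DataError, GeneList, LowExpressorParams,
                       UsageError, count_sums, coverage_analysis,
                       coverage_percent, low_expressor_set, matched_filter,
                       reference_lower_limit, tf_detection_table)


def _table(values, samples=None, label=""):
    values = np.asarray(values)
    return CountTable(pd.DataFrame(
        values, index=[f"g{i}" for i in range(values.shape[0])],
        columns=samples or [f"s{j}" for j in range(values.shape[1])]),
        label=label)


def _sums(d):
    return pd.Series(d, dtype=float)


class TestCountSums:
    def test_sum_across_named_replicates(self):
        t = _table([[2, 3, 5]], samples=["a", "b", "c"])
        assert count_sums(t, ["a", "b", "c"]).iloc[0] == 10
        assert count_sums(t, ["b"]).iloc[0] == 3

    def test_empty_subset_rejected(self):
        with pytest.raises(UsageError):
            count_sums(_table([[1, 2]]), [])

    def test_unknown_replicate_rejected(self):
        with pytest.raises(UsageError):
            count_sums(_table([[1, 2]]), ["nope"])


class TestLowExpressorSet:
    def test_hand_enumeration(self):
        # cutoff = 1% of 1000 = 10: b in; c above; d undetected
        low = low_expressor_set(_sums({"a": 1000, "b": 9, "c": 50, "d": 0}),
                                LowExpressorParams())
        assert set(low) == {"b"}

    def test_upper_boundary_inclusive(self):
        low = low_expressor_set(_sums({"a": 1000, "b": 10}),
                                LowExpressorParams())
        assert set(low) == {"b"}

    def test_all_equal_sums_empty_window(self):
        low = low_expressor_set(_sums({"a": 500, "b": 500, "c": 500}),
                                LowExpressorParams())
        assert len(low) == 0

    @given(st.lists(st.integers(0, 10_000), min_size=2, max_size=30),
           st.floats(0.005, 0.5))
    def test_window_grows_with_max_fraction(self, values, frac):
        sums = _sums({f"g{i}": v for i, v in enumerate(values)})
        if not (sums >= 1).any():
            return
        narrow = low_expressor_set(sums, LowExpressorParams(max_fraction=frac))
        wide = low_expressor_set(
            sums, LowExpressorParams(max_fraction=min(1.0, frac * 2)))
        assert set(narrow) <= set(wide)

    def test_all_zero_rejected(self):
        with pytest.raises(DataError):
            low_expressor_set(_sums({"a": 0, "b": 0}), LowExpressorParams())


class TestCoveragePercent:
    @pytest.mark.parametrize("low,detected,expected", [
        ({"a"}, {"a", "b", "c"}, 33.3),
        ({"a", "b"}, {"a", "b"}, 100.0),
        (set(), {"a", "b"}, 0.0),
    ])
    def test_arithmetic_and_bounds(self, low, detected, expected):
        assert coverage_percent(low, detected) == expected

    def test_low_must_be_subset(self):
        with pytest.raises(DataError):
            coverage_percent({"x"}, {"a"})

    def test_empty_detected_rejected(self):
        with pytest.raises(DataError):
            coverage_percent(set(), set())


class TestMatchedFilter:
    def test_inclusive_boundary(self):
        kept = matched_filter(_sums({"a": 200, "b": 106, "c": 105}), 106)
        assert set(kept.index) == {"a", "b"}

    def test_limit_one_is_identity_on_detected(self):
        sums = _sums({"a": 5, "b": 1, "c": 300})
        assert set(matched_filter(sums, 1).index) == {"a", "b", "c"}

    def test_reference_derived_limit(self):
        # a reference whose smallest detected per-replicate signal is 106
        ref = _table([[823_127], [106], [0]], label="ref")
        limit = reference_lower_limit(ref, LowExpressorParams(
            use_raw_sums=True))
        assert limit == 106

    def test_limit_above_max_empties_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            kept = matched_filter(_sums({"a": 5}), 10)
        assert kept.empty
        assert any("removed every gene" in r.message for r in caplog.records)


class TestFilterMonotonicityTheorem:
    def test_on_random_instances(self, rng):
        """Coverage never rises under a matched filter with limit between
        the detection floor and the low-expressor cutoff; equality holds
        iff no low expressor falls below the limit."""
        params = LowExpressorParams(use_raw_sums=True)
        for _ in range(200):
            n = int(rng.integers(5, 60))
            sums = pd.Series(rng.integers(0, 5000, size=n).astype(float),
                             index=[f"g{i}" for i in range(n)])
            detected = sums.index[sums >= 1]
            if len(detected) == 0:
                continue
            det_sums = sums.loc[detected]
            cutoff = 0.01 * det_sums.max()
            low = det_sums.index[det_sums <= cutoff]
            unfiltered = len(low) / len(detected)
            limit = rng.uniform(1.0, max(cutoff, 1.0))
            kept = matched_filter(det_sums, limit)
            if kept.empty:
                continue
            filtered = len(low.intersection(kept.index)) / len(kept)
            assert filtered <= unfiltered + 1e-12
            removed_low = (det_sums.loc[low] < limit).sum()
            if removed_low == 0:
                assert filtered == pytest.approx(unfiltered)
            elif len(low) < len(detected):
                assert filtered < unfiltered


class TestCoverageAnalysis:
    def test_self_match_leaves_pooled_coverage_unchanged(self):
        t = _table([[1000, 900], [9, 12], [50, 40], [3, 1]], label="D")
        rep = coverage_analysis({"D": t}, "D",
                                LowExpressorParams(use_raw_sums=True))
        pooled = rep.per_dataset["D"]["pooled"]
        assert pooled["coverage_filtered"] == pytest.approx(
            pooled["coverage_unfiltered"])

    def test_null_filter_gives_p_half(self):
        # reference floor of 1 removes nothing anywhere
        ref = _table([[1, 1], [40, 50], [900, 1100]], label="R")
        rep = coverage_analysis({"R": ref}, "R",
                                LowExpressorParams(use_raw_sums=True))
        t = rep.per_dataset["R"]["t_test"]
        assert t["statistic"] == 0.0
        assert t["p"] == 0.5

    def test_single_replicate_omits_t_test(self, caplog):
        t = _table([[100], [5], [1]], label="one")
        with caplog.at_level("WARNING"):
            rep = coverage_analysis({"one": t}, "one",
                                    LowExpressorParams(use_raw_sums=True))
        assert "t_test" not in rep.per_dataset["one"]


class TestTFDetection:
    def _ids(self, n, prefix):
        return [f"{prefix}{i}" for i in range(n)]

    def test_published_detected_percentages(self):
        tf_ids = self._ids(1393, "tf") + self._ids(487, "ptf")
        tf_list = GeneList(tf_ids, label="TF")
        bulk = self._ids(1393, "tf") + self._ids(14_160 - 1393, "bg")
        pseudo = self._ids(487, "ptf") + self._ids(6847 - 487, "pg")
        _, frac, test = tf_detection_table(bulk, pseudo, tf_list,
                                           "bulk", "pseudobulk")
        assert frac == {"bulk": 9.8, "pseudobulk": 7.1}
        assert test is not None

    def test_published_deg_percentage(self):
        tf_list = GeneList(self._ids(63, "tf"), label="TF")
        degs = self._ids(63, "tf") + self._ids(310 - 63, "bg")
        _, frac, _ = tf_detection_table(degs, self._ids(10, "x"), tf_list,
                                        "bulk", "other")
        assert frac["bulk"] == 20.3

    def test_degenerate_no_tf_flagged(self, caplog):
        tf_list = GeneList(["tf_absent"], label="TF")
        with caplog.at_level("WARNING"):
            table, frac, test = tf_detection_table(
                ["a", "b"], ["c"], tf_list)
        assert frac == {"A": 0.0, "B": 0.0}
        assert test is None

    def test_empty_gene_set_rejected(self):
        with pytest.raises(DataError):
            tf_detection_table([], ["a"], GeneList(["tf1"]))
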