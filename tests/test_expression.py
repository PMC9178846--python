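"""Normalization, TPM, the expressed-gene filter, sample correlation and
the qPCR relative-expression utility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import heterosiskit as hk


def _counts(data, samples=None):
    df = pd.DataFrame(data)
    df.index = [f"g{i}" for i in range(len(df))]
    if samples:
        df.columns = samples
    return df


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        c = _counts({"a": [10, 100, 7], "b": [10, 100, 7]})
        assert hk.compute_size_factors(c).tolist() == [1.0, 1.0]

    def test_doubled_library_splits_symmetrically(self):
        c = _counts({"a": [10, 100], "b": [20, 200]})
        sf = hk.compute_size_factors(c)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2), abs=1e-4)
        assert sf["b"] == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_single_sample_gets_factor_one(self):
        c = _counts({"a": [5, 9, 14]})
        assert hk.compute_size_factors(c)["a"] == 1.0

    def test_scale_equivariance_of_factor_ratios(self):
        # tripling one library triples its factor relative to every other
        # sample (the geometric-mean reference absorbs a common c^(1/n))
        rng = np.random.default_rng(0)
        c = _counts(rng.integers(1, 1000, size=(50, 4)))
        sf = hk.compute_size_factors(c)
        c2 = c.copy()
        c2.iloc[:, 0] *= 3
        sf2 = hk.compute_size_factors(c2)
        ratios = (sf2 / sf2.iloc[0]) / (sf / sf.iloc[0])
        assert ratios.iloc[1:].tolist() == pytest.approx([1 / 3] * 3, rel=1e-9)

    def test_no_universally_detected_gene_is_an_error(self):
        c = _counts({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="size factors"):
            hk.compute_size_factors(c)


class TestTPM:
    def test_single_gene_sample_is_a_million(self):
        c = _counts({"a": [17]})
        tpm = hk.compute_tpm(c, pd.Series({"g0": 500}))
        assert tpm.loc["g0", "a"] == pytest.approx(1e6)

    def test_length_rate_shares(self):
        c = _counts({"a": [30, 30]})
        tpm = hk.compute_tpm(c, pd.Series({"g0": 1000, "g1": 2000}))
        assert tpm["a"].tolist() == pytest.approx([666666.666667, 333333.333333])

    def test_all_zero_sample_is_all_zero(self):
        c = _counts({"a": [0, 0]})
        tpm = hk.compute_tpm(c, pd.Series({"g0": 100, "g1": 100}))
        assert (tpm["a"] == 0).all()

    def test_columns_sum_to_a_million(self, small_triplet):
        counts, _, _ = small_triplet
        lengths = hk.simulate_gene_lengths(list(counts.index), seed=9)
        tpm = hk.compute_tpm(counts, lengths)
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-3)

    def test_missing_length_is_keyed_error(self):
        c = _counts({"a": [1, 1]})
        with pytest.raises(KeyError, match="g1"):
            hk.compute_tpm(c, pd.Series({"g0": 100}))


class TestExpressedFilter:
    @staticmethod
    def _sheet(n_groups=1, reps=3):
        rows = []
        for g in range(n_groups):
            for r in range(reps):
                rows.append({"sample_id": f"s{g}_{r}", "cross": "X",
                             "role": f"role{g}", "timepoint": "T1", "replicate": r})
        return pd.DataFrame(rows)

    def test_boundary_sum_31_is_expressed_30_is_not(self):
        sheet = self._sheet()
        c = _counts(
            {"s0_0": [10, 10], "s0_1": [10, 10], "s0_2": [11, 10]},
        )
        expressed = hk.filter_expressed(c, sheet, threshold=30)
        assert "g0" in expressed and "g1" not in expressed

    def test_any_group_passing_suffices(self):
        sheet = self._sheet(n_groups=2)
        c = _counts(
            {"s0_0": [0], "s0_1": [0], "s0_2": [0],
             "s1_0": [20], "s1_1": [10], "s1_2": [10]},
        )
        assert "g0" in hk.filter_expressed(c, sheet)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(0, 40), min_size=3, max_size=3),
           st.integers(0, 20))
    def test_adding_counts_is_monotone(self, reps, extra):
        sheet = self._sheet()
        base = _counts({f"s0_{i}": [reps[i]] for i in range(3)})
        more = base.copy()
        more.iloc[0, 0] += extra
        in_base = "g0" in hk.filter_expressed(base, sheet)
        in_more = "g0" in hk.filter_expressed(more, sheet)
        assert in_more or not in_base


class TestSampleCorrelation:
    def test_duplicated_sample_correlates_perfectly(self):
        tpm = _counts({"a": [1.0, 5, 9], "b": [1.0, 5, 9]})
        corr = hk.sample_correlation_matrix(tpm)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_reflected_sample_anticorrelates(self):
        x = np.array([1.0, 5, 9])
        tpm = _counts({"a": x, "b": 2 * x.mean() - x})
        corr = hk.sample_correlation_matrix(tpm)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_direct_pearson_formula(self):
        rng = np.random.default_rng(1)
        tpm = _counts(rng.random((100, 2)), samples=["a", "b"])
        corr = hk.sample_correlation_matrix(tpm)
        expected = stats.pearsonr(tpm["a"], tpm["b"]).statistic
        assert corr.loc["a", "b"] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(corr, corr.T) and (np.diag(corr) == 1).all()

    def test_zero_variance_sample_flagged_nan(self):
        tpm = _counts({"a": [1.0, 2, 3], "b": [4.0, 4, 4]})
        corr = hk.sample_correlation_matrix(tpm)
        assert np.isnan(corr.loc["a", "b"]) and corr.loc["b", "b"] == 1.0


class TestQpcr:
    def test_zero_ddct_is_unity(self):
        t = pd.Series({"cal": 20.0, "s1": 21.0})
        r = pd.Series({"cal": 15.0, "s1": 16.0})
        rel = hk.qpcr_relative_expression(t, r, "cal")
        assert rel["cal"] == 1.0 and rel["s1"] == 1.0

    def test_two_cycles_higher_is_quarter(self):
        t = pd.Series({"cal": 20.0, "s1": 22.0})
        r = pd.Series({"cal": 15.0, "s1": 15.0})
        assert hk.qpcr_relative_expression(t, r, "cal")["s1"] == pytest.approx(0.25)

    def test_negative_ddct_doubles(self):
        t = pd.Series({"cal": 20.0, "s1": 19.0})
        r = pd.Series({"cal": 15.0, "s1": 15.0})
        assert hk.qpcr_relative_expression(t, r, "cal")["s1"] == pytest.approx(2.0)

    def test_missing_calibrator_is_keyed_error(self):
        t = pd.Series({"s1": 19.0})
        with pytest.raises(KeyError, match="cal"):
            hk.qpcr_relative_expression(t, t, "cal")
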