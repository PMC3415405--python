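import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import silhouette_score

from chdsig.diffexp import (
    anova,
    de_select,
    expected_null_count,
    merge_decision,
    pca_scores,
    pooled_variance_ttest,
    pvalue_uniformity,
)
from chdsig.errors import DataError

from conftest import make_matrix, make_sheet


def _matrix_from_groups(*group_values, n_probes=1):
    """Build a 1-probe matrix (replicated to n_probes) and matching sheet."""
    values, assignment = [], {}
    for gi, vals in enumerate(group_values):
        for vi, v in enumerate(vals):
            assignment[f"G{gi}S{vi}"] = f"G{gi}"
            values.append(v)
    m = make_matrix(
        np.tile(np.asarray(values, dtype=float), (n_probes, 1)),
        samples=list(assignment),
    )
    return m, make_sheet(assignment)


class TestPooledVarianceTtest:
    def test_identical_groups_give_t0_p1(self):
        m, sheet = _matrix_from_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        out = pooled_variance_ttest(m, sheet, "G0", "G1")
        assert out["t"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)
        assert out["ratio"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_example(self):
        # A=(1,2,3), B=(4,5,6): s2=1, t=-3/sqrt(2/3), df=4
        m, sheet = _matrix_from_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        out = pooled_variance_ttest(m, sheet, "G0", "G1")
        assert out["s2"].iloc[0] == pytest.approx(1.0)
        assert out["df"].iloc[0] == 4
        assert out["t"].iloc[0] == pytest.approx(-3.674234614174767)
        assert out["p"].iloc[0] == pytest.approx(0.0213116, abs=1e-6)

    def test_matches_scipy_on_two_groups(self, rng):
        a, b = rng.normal(size=(1, 8)), rng.normal(0.5, 1.0, size=(1, 6))
        m, sheet = _matrix_from_groups(a[0], b[0])
        out = pooled_variance_ttest(m, sheet, "G0", "G1")
        t_ref, p_ref = stats.ttest_ind(a[0], b[0], equal_var=True)
        assert out["t"].iloc[0] == pytest.approx(t_ref)
        assert out["p"].iloc[0] == pytest.approx(p_ref)

    def test_global_variance_pools_all_groups(self, rng):
        groups = [rng.normal(size=5), rng.normal(size=7), rng.normal(size=6)]
        m, sheet = _matrix_from_groups(*groups)
        out = pooled_variance_ttest(
            m, sheet, "G0", "G1", variance_groups=["G0", "G1", "G2"]
        )
        s2_manual = sum((len(g) - 1) * np.var(g, ddof=1) for g in groups) / sum(
            len(g) - 1 for g in groups
        )
        assert out["s2"].iloc[0] == pytest.approx(s2_manual)
        assert out["df"].iloc[0] == sum(len(g) - 1 for g in groups)

    def test_zero_variance_unequal_means_is_error(self):
        m, sheet = _matrix_from_groups([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(DataError):
            pooled_variance_ttest(m, sheet, "G0", "G1")

    def test_zero_variance_equal_means_flagged(self):
        m, sheet = _matrix_from_groups([1.0, 1.0], [1.0, 1.0])
        out = pooled_variance_ttest(m, sheet, "G0", "G1")
        assert bool(out["zero_variance"].iloc[0])
        assert out["p"].iloc[0] == 1.0

    def test_contrast_groups_must_be_in_variance_groups(self):
        m, sheet = _matrix_from_groups([1.0, 2.0], [3.0, 4.0], [5.0, 6.0])
        with pytest.raises(DataError):
            pooled_variance_ttest(m, sheet, "G0", "G1", variance_groups=["G1", "G2"])


class TestAnova:
    def test_identical_groups_give_f0_p1(self):
        m, sheet = _matrix_from_groups([1.0, 2.0], [1.0, 2.0], [1.0, 2.0])
        out = anova(m, sheet, ["G0", "G1", "G2"])
        # SSB = 0 here; F is 0 with p = 1 up to float noise
        assert out["F"].iloc[0] == pytest.approx(0.0, abs=1e-20)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_hand_anova_table(self):
        # groups (1,2),(3,4),(5,6): SSB=16, MSB=8, SSW=1.5, MSW=0.5 -> F=16
        m, sheet = _matrix_from_groups([1.0, 2.0], [3.0, 4.0], [5.0, 6.0])
        out = anova(m, sheet, ["G0", "G1", "G2"])
        f_ref, p_ref = stats.f_oneway([1, 2], [3, 4], [5, 6])
        assert f_ref == pytest.approx(16.0)
        assert out["F"].iloc[0] == pytest.approx(f_ref)
        assert out["p"].iloc[0] == pytest.approx(p_ref)
        assert (out["df_between"].iloc[0], out["df_within"].iloc[0]) == (2, 3)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_two_group_f_equals_t_squared(self, seed):
        rng = np.random.default_rng(seed)
        m, sheet = _matrix_from_groups(
            rng.normal(size=5), rng.normal(size=4), n_probes=3
        )
        f = anova(m, sheet, ["G0", "G1"])
        t = pooled_variance_ttest(m, sheet, "G0", "G1")
        np.testing.assert_allclose(f["F"], t["t"] ** 2, atol=1e-10)
        np.testing.assert_allclose(f["p"], t["p"], atol=1e-10)


class TestExpectedNullCount:
    def test_published_value(self):
        assert expected_null_count(11224, 0.01) == 112

    def test_zero_tests(self):
        assert expected_null_count(0, 0.5) == 0

    def test_exact_arithmetic(self):
        assert expected_null_count(1000, 0.05) == 50

    def test_invalid_alpha(self):
        with pytest.raises(DataError):
            expected_null_count(10, 1.5)


class TestMergeDecision:
    @staticmethod
    def _pvals(m, n_low, alpha=0.01):
        return np.concatenate([np.full(n_low, alpha / 2), np.full(m - n_low, 0.6)])

    def test_deficit_triggers_merge(self):
        d = merge_decision(self._pvals(11224, 33), alpha=0.01)
        assert d.expected_count == 112
        assert d.observed_count == 33
        assert d.merged is True

    def test_excess_blocks_merge(self):
        d = merge_decision(self._pvals(11224, 249), alpha=0.01)
        assert d.merged is False

    def test_empty_input_is_error(self):
        with pytest.raises(DataError):
            merge_decision([])

    def test_binomial_diagnostic(self):
        d = merge_decision(self._pvals(1000, 2), alpha=0.01)
        assert d.binomial_p == pytest.approx(stats.binom.cdf(2, 1000, 0.01))

    def test_ecdf_curve(self):
        d = merge_decision([0.2, 0.1, 0.4], alpha=0.05)
        assert list(d.ecdf_curve["p"]) == [0.1, 0.2, 0.4]
        assert list(d.ecdf_curve["ecdf"]) == pytest.approx([1 / 3, 2 / 3, 1.0])

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_monotone_adding_small_pvalues_never_flips_to_merged(self, data):
        base = data.draw(
            st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=5, max_size=40)
        )
        alpha = 0.1
        before = merge_decision(base, alpha=alpha)
        extra = data.draw(
            st.lists(st.floats(0.0, 0.099), min_size=1, max_size=20)
        )
        after = merge_decision(base + extra, alpha=alpha)
        assert after.observed_count == before.observed_count + len(extra)
        # adding sub-threshold p-values raises D at least as fast as E,
        # so "not merged" can never flip to "merged"
        if not before.merged:
            assert not after.merged


class TestPcaScores:
    def test_duplicate_samples_get_identical_scores(self, rng):
        x = rng.normal(size=(30, 5))
        x = np.column_stack([x, x[:, 0]])  # duplicate first sample
        scores, _, _ = pca_scores(make_matrix(x), n_components=2)
        np.testing.assert_allclose(
            scores.iloc[0].to_numpy(), scores.iloc[-1].to_numpy(), atol=1e-9
        )

    def test_explained_variance_bounded_by_total(self, rng):
        x = rng.normal(size=(40, 8))
        m = make_matrix(x)
        _, explained, ratio = pca_scores(m, n_components=3)
        centered = x - x.mean(axis=1, keepdims=True)
        total = (centered**2).sum() / (x.shape[1] - 1)
        assert explained.sum() <= total + 1e-9
        assert ratio.sum() <= 1.0 + 1e-12

    def test_planted_axis_separates_groups(self, rng):
        # two groups with a strong mean shift on half the transcripts
        n_genes, per_group = 60, 10
        x = rng.normal(size=(n_genes, 2 * per_group), scale=0.3)
        x[: n_genes // 2, :per_group] += 3.0
        scores, _, _ = pca_scores(make_matrix(x), n_components=2)
        labels = [0] * per_group + [1] * per_group
        sil = silhouette_score(scores[["PC1"]].to_numpy(), labels)
        assert sil > 0.5

    def test_too_many_components_rejected(self, rng):
        m = make_matrix(rng.normal(size=(10, 4)))
        with pytest.raises(DataError):
            pca_scores(m, n_components=5)

    def test_deterministic_signs(self, rng):
        m = make_matrix(rng.normal(size=(25, 6)))
        s1, _, _ = pca_scores(m, 3)
        s2, _, _ = pca_scores(m, 3)
        pd.testing.assert_frame_equal(s1, s2)


class TestDeSelect:
    def test_all_ones_empty(self):
        assert len(de_select(pd.Series([1.0, 1.0]), 0.05)) == 0

    def test_threshold_is_strict(self):
        out = de_select(pd.Series({"a": 0.04, "b": 0.06, "c": 0.05}), 0.05)
        assert list(out) == ["a"]


def test_pvalue_uniformity_flags_nonuniform(rng):
    stat_u, p_u = pvalue_uniformity(rng.uniform(size=2000))
    stat_n, p_n = pvalue_uniformity(rng.uniform(0, 0.5, size=2000))
    assert p_u > 0.01
    assert p_n < 1e-10
    assert stat_n > stat_u
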