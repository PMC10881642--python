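"""Regional metabolism statistics: scaling, effect sizes, ANCOVA, abnormality."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fdgpattern.regional import (
    ancova_region,
    bonferroni_adjust,
    cohens_d,
    composite_means,
    effect_size_correlation,
    global_mean_scale,
    regional_effect_table,
    subject_abnormality,
)
from fdgpattern.synthetic import SyntheticCohortSpec, default_pattern, simulate_cohort


class TestGlobalMeanScale:
    def test_equal_volumes(self):
        np.testing.assert_allclose(global_mean_scale([1, 2, 3]), [0.5, 1.0, 1.5])

    def test_weighted_mean(self):
        out = global_mean_scale([1, 3], volumes=[3, 1])
        np.testing.assert_allclose(out, [1 / 1.5, 3 / 1.5])

    def test_constant_vector(self):
        np.testing.assert_allclose(global_mean_scale([7.0] * 5), 1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            global_mean_scale([1.0, 0.0])
        with pytest.raises(ValueError):
            global_mean_scale([1.0, 2.0], volumes=[1.0, -1.0])


class TestCompositeMeans:
    def test_unit_profile(self, atlas):
        cm = composite_means(np.ones(77), atlas)
        np.testing.assert_allclose(cm.to_numpy(), 1.0)
        assert set(cm.index) == set(atlas.composites)

    def test_two_member_equal_volume(self, atlas):
        v = np.ones(77)
        v[atlas.index_of("insula_L")] = 1.0
        v[atlas.index_of("insula_R")] = 3.0
        assert composite_means(v, atlas)["insula"] == pytest.approx(2.0)

    def test_volume_weighting(self, atlas):
        vols = list(atlas.volumes)
        vols[atlas.index_of("insula_L")] = 3000.0
        vols[atlas.index_of("insula_R")] = 1000.0
        weighted_atlas = dataclasses.replace(atlas, volumes=tuple(vols))
        v = np.ones(77)
        v[atlas.index_of("insula_L")] = 1.0
        v[atlas.index_of("insula_R")] = 3.0
        assert composite_means(v, weighted_atlas)["insula"] == pytest.approx(1.5)


class TestCohensD:
    def test_identical_groups(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_value(self):
        # pooled variance 1.6667, pooled SD 1.2910, d = -2/1.2910
        assert cohens_d([1, 2, 3, 4], [3, 4, 5, 6]) == pytest.approx(-1.5492, abs=1e-4)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [1, 2, 3])
        with pytest.raises(ValueError):
            cohens_d([2, 2, 2], [2, 2, 2])  # zero pooled SD

    @settings(derandomize=True, max_examples=25)
    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=8),
        st.lists(st.floats(-50, 50), min_size=3, max_size=8),
        st.floats(0.1, 5),
        st.floats(-10, 10),
    )
    def test_antisymmetry_and_affine_invariance(self, a, b, scale, shift):
        a, b = np.asarray(a), np.asarray(b)
        if a.std(ddof=1) + b.std(ddof=1) == 0:
            return
        d = cohens_d(a, b)
        assert cohens_d(b, a) == pytest.approx(-d, abs=1e-9)
        assert cohens_d(scale * a + shift, scale * b + shift) == pytest.approx(d, abs=1e-7)


def _anova_contrast_oracle(y, group, ga, gb):
    """Pairwise contrast p from a plain one-way ANOVA via pooled residual MSE."""
    levels = sorted(set(group))
    n = len(y)
    resid = np.concatenate([y[group == g] - y[group == g].mean() for g in levels])
    mse = (resid**2).sum() / (n - len(levels))
    na, nb = (group == ga).sum(), (group == gb).sum()
    t = (y[group == ga].mean() - y[group == gb].mean()) / np.sqrt(mse * (1 / na + 1 / nb))
    return 2 * stats.t.sf(abs(t), n - len(levels))


class TestAncova:
    def test_constant_covariates_reduce_to_anova(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            y = rng.standard_normal(24)
            group = np.repeat(np.array(["A", "B", "C"]), 8)
            res = ancova_region(y, group, age=np.full(24, 70.0), sex=np.full(24, "F"))
            for (ga, gb), p in res.contrasts.items():
                assert p == pytest.approx(_anova_contrast_oracle(y, group, ga, gb), abs=1e-10)

    def test_separated_groups(self):
        y = np.concatenate([np.random.default_rng(1).normal(0, 0.1, 10), np.full(10, 10.0) + 0.01 * np.arange(10)])
        group = np.repeat(np.array(["A", "B"]), 10)
        res = ancova_region(y, group)
        assert res.contrasts[("A", "B")] < 1e-6

    def test_adjusted_means_remove_age_confound(self):
        """A pure age effect with unbalanced ages is absorbed by the covariate."""
        rng = np.random.default_rng(2)
        age = np.concatenate([rng.normal(60, 2, 30), rng.normal(80, 2, 30)])
        y = 0.05 * age + rng.normal(0, 0.01, 60)
        group = np.repeat(np.array(["A", "B"]), 30)
        with_cov = ancova_region(y, group, age=age)
        without = ancova_region(y, group)
        assert without.contrasts[("A", "B")] < 1e-6  # confounded
        assert with_cov.contrasts[("A", "B")] > 0.001  # adjusted away

    def test_error_paths(self):
        y = np.arange(6.0)
        with pytest.raises(ValueError, match="n < 2"):
            ancova_region(y, np.array(["A"] * 5 + ["B"]))
        with pytest.raises(ValueError, match="2 groups"):
            ancova_region(y, np.array(["A"] * 6))


class TestBonferroni:
    def test_examples(self):
        np.testing.assert_allclose(bonferroni_adjust([0.0005], m=77), [0.0385])
        np.testing.assert_allclose(bonferroni_adjust([0.5], m=77), [1.0])
        np.testing.assert_allclose(bonferroni_adjust([0.02, 0.3], m=1), [0.02, 0.3])

    def test_bad_p(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2])


class TestEffectSizeCorrelation:
    def test_identity_and_sign(self):
        a = np.random.default_rng(3).normal(size=77)
        res = effect_size_correlation(a, a)
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(1.0)
        res = effect_size_correlation(a, -a)
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(-1.0)

    def test_independent_vectors_near_null(self):
        rng = np.random.default_rng(4)
        null95 = np.quantile([stats.pearsonr(rng.normal(size=77), rng.normal(size=77))[0] ** 2 for _ in range(500)], 0.95)
        below = 0
        for _ in range(100):
            r2 = effect_size_correlation(rng.normal(size=77), rng.normal(size=77))["r2"]
            below += r2 < null95
        assert below >= 90

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            effect_size_correlation(np.ones(77), np.arange(77.0))


class TestSubjectAbnormality:
    def test_at_control_mean(self, atlas):
        mu, sd = np.ones(77), np.full(77, 0.1)
        res = subject_abnormality(np.ones(77), mu, sd, atlas)
        assert not res["abnormal"]
        np.testing.assert_allclose(res["z"], 0.0)

    def test_boundary_closed(self):
        mu, sd = np.ones(3), np.full(3, 0.1)
        v = np.array([1.0, 1.0, 1.2])  # exactly +2 SD in one region
        res = subject_abnormality(v, mu, sd)
        assert res["flags"][2]
        assert res["abnormal"]

    def test_control_tail_rate(self):
        rng = np.random.default_rng(5)
        mu, sd = np.full(77, 1.0), np.full(77, 0.3)
        flags = [
            subject_abnormality(rng.normal(1.0, 0.3, size=77), mu, sd)["flags"].mean()
            for _ in range(500)
        ]
        assert np.mean(flags) == pytest.approx(2 * stats.norm.sf(2), abs=0.01)

    def test_zero_sd(self):
        with pytest.raises(ValueError):
            subject_abnormality(np.ones(3), np.ones(3), np.zeros(3))


class TestEffectTable:
    def test_planted_pattern_sign_recovery(self, atlas, default_cohort):
        """Cohen's d signs follow the planted pattern for strongly-shifted regions."""
        table = regional_effect_table(default_cohort)
        pattern = default_pattern(atlas)
        strong = np.abs(pattern) > np.median(np.abs(pattern))
        d = table["cohens_d_DLB_DATPOS_vs_HC"].to_numpy()
        agree = (np.sign(d[strong]) == np.sign(pattern[strong])).mean()
        assert agree >= 0.9

    def test_table_shape_and_bonferroni_columns(self, small_cohort):
        table = regional_effect_table(small_cohort)
        assert len(table) == 77
        assert ((table.filter(like="p_bonferroni") >= table.filter(like="p_raw").to_numpy()).all()).all()
        assert (table.filter(like="p_bonferroni") <= 1.0 + 1e-12).all().all()
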