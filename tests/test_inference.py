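import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from diametric.exceptions import ValidationError
from diametric.inference import (
    PermutationConfig,
    TfceParams,
    covariate_correlation,
    fdr_adjust,
    median_split_compare,
    paired_ttest,
    permutation_test,
    rm_anova,
    tfce_enhance,
)

STRUCTURE6 = ndimage.generate_binary_structure(3, 1)


def brute_force_tfce(pos, H=2.0, E=0.5, dh_steps=4000):
    """Independent oracle: per-threshold summation on a fine fixed grid."""
    out = np.zeros_like(pos, dtype=float)
    vmax = float(pos.max(initial=0.0))
    if vmax <= 0:
        return out
    dh = vmax / dh_steps
    for a in np.arange(0.0, vmax, dh):
        supra = pos > a
        if not supra.any():
            break
        lab, _ = ndimage.label(supra, structure=STRUCTURE6)
        sizes = np.bincount(lab.ravel()).astype(float)
        sizes[0] = 0.0
        w = (np.minimum(pos, a + dh) ** (H + 1) - a ** (H + 1)) / (H + 1)
        out += np.where(supra, (sizes**E)[lab] * w, 0.0)
    return out


class TestTfce:
    def test_single_voxel_matches_analytic_integral(self):
        stat = np.zeros((8, 8, 8))
        stat[4, 4, 4] = 2.0
        enhanced = tfce_enhance(stat, TfceParams())
        # e(h) = 1 for all h < v: integral = v^(H+1) / (H+1) = v^3 / 3
        assert enhanced[4, 4, 4] == pytest.approx(2.0**3 / 3.0, rel=1e-10)

    def test_uniform_zero_map_stays_zero(self):
        assert np.all(tfce_enhance(np.zeros((6, 6, 6)), TfceParams()) == 0)

    def test_scaling_map_never_decreases_enhancement(self, rng):
        m = np.maximum(ndimage.gaussian_filter(
            rng.standard_normal((10, 10, 10)), 1.5), 0)
        e1 = tfce_enhance(m, TfceParams())
        e2 = tfce_enhance(2.0 * m, TfceParams())
        assert np.all(e2 >= e1 - 1e-12)

    def test_negative_tail_enhanced_antisymmetrically(self, rng):
        m = ndimage.gaussian_filter(rng.standard_normal((10, 10, 10)), 1.5)
        assert np.allclose(tfce_enhance(-m, TfceParams()),
                           -tfce_enhance(m, TfceParams()))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            m = np.maximum(ndimage.gaussian_filter(
                rng.standard_normal((10, 10, 10)), 1.5), 0)
            e = tfce_enhance(m, TfceParams())
            b = brute_force_tfce(m)
            assert np.max(np.abs(e - b)) / b.max() < 0.01


class TestPermutationTest:
    def test_identical_groups_yield_large_p(self):
        x = np.arange(10.0)
        res = permutation_test(
            x, x.copy(), paired=True,
            config=PermutationConfig(n_permutations=200, seed=1),
        )
        assert res.p >= 0.5

    def test_exact_enumeration_granularity_n4(self):
        left = np.array([1.0, 2.0, 3.0, 4.0])
        right = left + np.array([0.5, -0.2, 0.3, 0.1])
        res = permutation_test(
            left, right, paired=True,
            config=PermutationConfig(n_permutations=100, seed=0),
        )
        assert res.exact
        assert res.n_permutations == 16
        assert (res.p * 16) == pytest.approx(round(res.p * 16))

    def test_deterministic_under_seed(self, rng):
        left = rng.standard_normal(12)
        right = rng.standard_normal(12)
        cfg = PermutationConfig(n_permutations=300, seed=7)
        a = permutation_test(left, right, paired=False, config=cfg)
        b = permutation_test(left, right, paired=False, config=cfg)
        assert a.p == b.p
        assert a.stat == b.stat

    def test_true_effect_detected_unpaired(self, rng):
        left = rng.standard_normal(20)
        right = rng.standard_normal(20) + 2.0
        res = permutation_test(
            left, right, paired=False,
            config=PermutationConfig(n_permutations=500, seed=2),
        )
        assert res.p < 0.01

    def test_map_test_with_tfce_flags_signal_region(self, rng):
        shape = (8, 8, 8)
        left = rng.standard_normal((8,) + shape)
        right = rng.standard_normal((8,) + shape)
        right[:, 2:5, 2:5, 2:5] += 3.0
        res = permutation_test(
            left, right, paired=True,
            config=PermutationConfig(n_permutations=200, seed=3),
            tfce=TfceParams(n_steps=50),
        )
        # the signal cluster's peak survives max-TFCE FWE correction;
        # voxels far from it do not
        assert res.p_fwe[2:5, 2:5, 2:5].min() < 0.05
        assert res.p_fwe[6:, 6:, 6:].min() > 0.2
        assert res.clusters is not None and len(res.clusters) >= 1

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            permutation_test(np.ones(2), np.ones(2), paired=True)


class TestRmAnova:
    @staticmethod
    def closed_form_chi2(wide: np.ndarray) -> float:
        """Balanced-design ML likelihood-ratio statistic in closed form:
        chi2 = n (k-1) ln(SSW_null / SSW_full), where SSW are the
        within-subject residual sums of squares with and without the
        condition effect."""
        n, k = wide.shape
        subj = wide.mean(axis=1, keepdims=True)
        cond = wide.mean(axis=0, keepdims=True)
        grand = wide.mean()
        ssw_full = ((wide - subj - cond + grand) ** 2).sum()
        ssw_null = ((wide - subj) ** 2).sum()
        return n * (k - 1) * np.log(ssw_null / ssw_full)

    @staticmethod
    def _long(wide):
        df = pd.DataFrame(wide, columns=["rsBase", "Med", "rsPost"])
        df["subject"] = [f"S{i}" for i in range(len(df))]
        return df.melt(id_vars="subject", var_name="condition",
                       value_name="value")

    def test_all_equal_values_give_zero_chi2(self):
        wide = np.full((5, 3), 1.7)
        res = rm_anova(self._long(wide))
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_matches_closed_form_on_random_data(self, rng):
        for _ in range(10):
            wide = (
                rng.normal(0, 1.5, (16, 1))
                + rng.normal(0, 0.5, (1, 3))
                + rng.normal(0, 1.0, (16, 3))
            )
            res = rm_anova(self._long(wide))
            assert res.chi2 == pytest.approx(
                self.closed_form_chi2(wide), abs=1e-4
            )

    def test_invariant_to_per_subject_constant(self, rng):
        # subject intercepts keep the variance estimate off the sigma_b=0
        # boundary, where the random intercept absorbs any added constant
        wide = rng.normal(0, 1.5, (10, 1)) + rng.normal(0, 1, (10, 3))
        shifted = wide + rng.normal(0, 5, (10, 1))
        a = rm_anova(self._long(wide))
        b = rm_anova(self._long(shifted))
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-4)

    def test_designed_effect_detected(self, rng):
        """Condition effect of two residual SDs is reliably detected."""
        hits = 0
        for _ in range(20):
            wide = (
                rng.normal(0, 1.0, (16, 1))
                + np.array([[0.0, 2.0, 0.0]])
                + rng.normal(0, 1.0, (16, 3))
            )
            res = rm_anova(self._long(wide))
            hits += res.p < 0.05
        assert hits >= 18

    def test_incomplete_subjects_dropped_with_warning(self, rng):
        long = self._long(rng.normal(0, 1, (6, 3)))
        long = long.drop(long[(long.subject == "S0")
                              & (long.condition == "Med")].index)
        with pytest.warns(UserWarning, match="incomplete"):
            res = rm_anova(long)
        assert res.n_subjects == 5

    def test_tukey_table_has_all_pairs(self, rng):
        res = rm_anova(self._long(rng.normal(0, 1, (8, 3))))
        assert len(res.tukey) == 3
        assert ((res.tukey["p"] >= 0) & (res.tukey["p"] <= 1)).all()


class TestCovariateCorrelation:
    def test_self_correlation_is_one(self):
        v = np.arange(10.0)
        res = covariate_correlation(v, 3.0 * v + 1.0, n_permutations=200)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 201, abs=1e-9)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            covariate_correlation(np.arange(6.0), np.ones(6))

    def test_parametric_p_matches_scipy(self, rng):
        from scipy import stats

        v = rng.standard_normal(15)
        c = rng.standard_normal(15)
        res = covariate_correlation(v, c, method="parametric")
        ref = stats.pearsonr(v, c)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_dose_dependent_truth_sign_recovered(self):
        """When practice hours scale the generator's cross-network
        correlation, the estimated hours-FC correlation carries the
        truth's sign."""
        from diametric.studies import null_design
        from diametric.synth import generate_cohort
        from diametric.falff import falff_series  # noqa: F401 (chain import)

        design = null_design(n_em=8, n_volumes=200)
        design.n_hc = 1
        design.hours_modulate_cross_r = 0.3  # more hours -> less anticorrelated
        signs = []
        for seed in range(5):
            cohort = generate_cohort(design, seed)
            em = cohort.table.sessions(group="EM", condition="rsBase")
            hours = em.set_index("subject")["meditation_hours"]
            truth = {
                t["subject"]: t["cross_network_r"]
                for t in cohort.truth["runs"]
                if t["condition"] == "rsBase" and t["group"] == "EM"
            }
            subs = sorted(truth)
            res = covariate_correlation(
                np.array([truth[s] for s in subs]),
                hours[subs].values,
                method="parametric",
            )
            signs.append(np.sign(res.r))
        assert np.mean(np.array(signs) > 0) >= 0.8


class TestMedianSplit:
    def test_even_split_around_median(self, rng):
        hours = np.array([10.0, 20.0, 30.0, 40.0])
        res = median_split_compare(
            rng.standard_normal(4), hours, rng.standard_normal(5)
        )
        assert res.median == 25.0
        assert res.n_ties == 0
        assert len(res.tukey) == 3

    def test_ties_assigned_to_lower_group(self, rng):
        hours = np.array([10.0, 20.0, 20.0, 40.0, 50.0])
        res = median_split_compare(
            rng.standard_normal(5), hours, rng.standard_normal(5)
        )
        assert res.n_ties == 2  # both 20 h subjects sit at the median

    def test_degenerate_split_rejected(self, rng):
        with pytest.raises(ValidationError, match="degenerate"):
            median_split_compare(
                rng.standard_normal(4), np.full(4, 100.0),
                rng.standard_normal(4),
            )

    def test_dose_pattern_separates_low_from_high(self, rng):
        """Mirrors a dose-dependent trait pattern: the low-practice group
        differs from controls while the high-practice group does not."""
        hc = rng.normal(0.13, 0.05, 17)
        em_low = rng.normal(-0.20, 0.05, 8)
        em_high = rng.normal(0.10, 0.05, 8)
        hours = np.concatenate([np.linspace(100, 1000, 8),
                                np.linspace(1300, 3000, 8)])
        res = median_split_compare(
            np.concatenate([em_low, em_high]), hours, hc
        )
        tk = res.tukey.set_index(["left", "right"])["p"]
        assert tk[("HC", "EM_low")] < 0.05
        assert tk[("HC", "EM_high")] > 0.05


class TestPairedT:
    def test_df_is_n_minus_one(self, rng):
        res = paired_ttest(rng.standard_normal(16), rng.standard_normal(16))
        assert res.df == 15


class TestFdr:
    def test_hand_computed_bh_example(self):
        assert np.allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_hand_bh_on_random_p(self, rng):
        p = rng.uniform(size=9)
        # hand BH: p_(i) * m / i, cumulative min from the largest rank
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        hand = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(hand, 1.0)
        assert np.allclose(fdr_adjust(p), out)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_adjust([0.5, 1.2])
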