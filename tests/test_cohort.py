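"""Group-level statistics: Bland-Altman identities and worked example,
ICC(3,1) oracles, ANCOVA, paired tests, and the K_i regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bbbdce import (
    bland_altman,
    group_compare_ancova,
    icc_single_measure_consistency,
    make_cohort,
    paired_compare,
    regress_ki,
)


class TestBlandAltman:
    def test_worked_example_limits_of_agreement(self):
        """A pair sample with n = 25, mean difference -0.00384 and SD 0.04033
        yields upper LoA 0.07520, lower LoA -0.08288 and width 0.15809."""
        d = _pairs_with_moments(25, -0.00384, 0.04033)
        res = bland_altman(d, np.zeros_like(d))
        assert res.n == 25
        assert res.mean_diff == pytest.approx(-0.00384, abs=1e-10)
        assert res.sd_diff == pytest.approx(0.04033, abs=1e-10)
        assert res.loa_upper == pytest.approx(0.07520, abs=5e-5)
        assert res.loa_lower == pytest.approx(-0.08288, abs=5e-5)
        assert res.loa_width == pytest.approx(0.15809, abs=5e-5)

    def test_worked_example_loa_confidence_intervals(self):
        """The t(24)-based CIs of the limits, with SE = sqrt(3 s^2 / n),
        recomputed against an independent t-quantile path."""
        d = _pairs_with_moments(25, -0.00384, 0.04033)
        res = bland_altman(d, np.zeros_like(d))
        assert res.ci_upper_loa[0] == pytest.approx(0.04637, abs=5e-5)
        assert res.ci_upper_loa[1] == pytest.approx(0.10404, abs=5e-5)
        assert res.ci_lower_loa[0] == pytest.approx(-0.11172, abs=5e-5)
        assert res.ci_lower_loa[1] == pytest.approx(-0.05405, abs=5e-5)
        # independent quantile: numerically invert the t CDF by bisection
        from scipy.optimize import brentq

        t975 = brentq(lambda q: stats.t.cdf(q, 24) - 0.975, 0.0, 10.0)
        se = np.sqrt(3 * res.sd_diff**2 / res.n)
        assert res.ci_upper_loa[1] - res.loa_upper == pytest.approx(t975 * se, rel=1e-8)

    def test_identical_pairs_collapse(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning, match="zero variance"):
            res = bland_altman(x, x)
        assert res.mean_diff == 0.0
        assert res.sd_diff == 0.0
        assert res.loa_upper == res.loa_lower == 0.0

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=40),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_loa_identities_hold_exactly(self, diffs, seed):
        d = np.asarray(diffs) + np.random.default_rng(seed).normal(0, 1e-3, len(diffs))
        res = bland_altman(d, np.zeros_like(d))
        assert res.loa_width == pytest.approx(3.92 * res.sd_diff, rel=1e-12, abs=1e-15)
        assert res.loa_upper == pytest.approx(res.mean_diff + 1.96 * res.sd_diff, rel=1e-12)
        assert res.loa_upper - res.loa_lower == pytest.approx(res.loa_width, rel=1e-9, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


def _pairs_with_moments(n: int, mean: float, sd: float) -> np.ndarray:
    """Construct differences with exactly the requested sample mean and
    (n-1)-denominator SD."""
    base = np.random.default_rng(0).normal(size=n)
    base = (base - base.mean()) / base.std(ddof=1)
    return mean + sd * base


class TestIcc:
    def test_identical_columns_give_one(self):
        x = np.tile(np.array([1.0, 2.0, 3.0, 4.0])[:, None], (1, 2))
        assert icc_single_measure_consistency(x).icc == pytest.approx(1.0)

    def test_consistency_is_shift_invariant(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 9.0])
        m = np.column_stack([x, x + 3.7])
        res = icc_single_measure_consistency(m)
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_matches_sums_of_squares_oracle(self):
        """ICC(3,1) equals a brute-force oracle computing the two-way ANOVA
        mean squares with explicit double loops, to 1e-10."""
        rng = np.random.default_rng(17)
        x = rng.normal(size=(6, 2))
        res = icc_single_measure_consistency(x)
        n, k = x.shape
        grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
        ss_rows = 0.0
        for i in range(n):
            row_mean = sum(x[i][j] for j in range(k)) / k
            ss_rows += k * (row_mean - grand) ** 2
        ss_cols = 0.0
        for j in range(k):
            col_mean = sum(x[i][j] for i in range(n)) / n
            ss_cols += n * (col_mean - grand) ** 2
        ss_tot = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
        msr = ss_rows / (n - 1)
        mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
        icc_oracle = (msr - mse) / (msr + (k - 1) * mse)
        assert res.icc == pytest.approx(icc_oracle, abs=1e-10)
        assert res.msr == pytest.approx(msr, abs=1e-10)
        assert res.mse == pytest.approx(mse, abs=1e-10)

    def test_agrees_with_pingouin_icc3(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(23)
        x = rng.normal(size=(12, 2))
        res = icc_single_measure_consistency(x)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile(["a", "b"], 12),
                "score": x.ravel(),
            }
        )
        tbl = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        row = tbl[tbl["Type"].isin(["ICC3", "ICC(C,1)"])].iloc[0]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-10)
        ci_col = "CI95" if "CI95" in tbl.columns else "CI95%"
        lo, hi = row[ci_col]
        assert res.ci[0] == pytest.approx(lo, abs=5e-3)
        assert res.ci[1] == pytest.approx(hi, abs=5e-3)

    def test_monotone_decrease_with_added_noise(self):
        """Averaged over an ensemble, ICC falls as independent noise of
        growing SD corrupts the second method."""
        rng = np.random.default_rng(99)
        base = rng.normal(0, 1, size=30)
        mean_icc = []
        for sd in (0.1, 0.5, 1.0, 2.0):
            vals = [
                icc_single_measure_consistency(
                    np.column_stack([base, base + rng.normal(0, sd, 30)])
                ).icc
                for _ in range(40)
            ]
            mean_icc.append(np.mean(vals))
        assert np.all(np.diff(mean_icc) < 0)

    def test_missing_cells_rejected(self):
        x = np.ones((4, 2))
        x[1, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            icc_single_measure_consistency(x)


class TestAncova:
    @staticmethod
    def _table(ki_hc, ki_ms, age_hc, age_ms):
        rows = []
        for g, kis, ages in (("HC", ki_hc, age_hc), ("RRMS", ki_ms, age_ms)):
            for i, (k, a) in enumerate(zip(kis, ages)):
                rows.append({"group": g, "ki": k, "age": a})
        return pd.DataFrame(rows)

    def test_null_case_nonsignificant(self):
        rng = np.random.default_rng(4)
        ki = rng.normal(0.02, 0.03, 26)
        ages = rng.normal(35, 10, 26)
        t = self._table(ki[:13], ki[13:], ages[:13], ages[13:])
        res = group_compare_ancova(t)
        assert res.p_group > 0.05
        assert res.partial_eta_sq < 0.15

    def test_marginal_means_equal_raw_means_when_ages_balanced(self):
        ki_hc = [0.01, 0.02, 0.03, 0.04]
        ki_ms = [0.05, 0.06, 0.07, 0.08]
        ages = [30.0, 35.0, 40.0, 45.0]
        res = group_compare_ancova(self._table(ki_hc, ki_ms, ages, ages))
        assert res.emm["HC"] == pytest.approx(np.mean(ki_hc), abs=1e-10)
        assert res.emm["RRMS"] == pytest.approx(np.mean(ki_ms), abs=1e-10)

    def test_zero_variance_covariate_reduces_to_anova(self):
        rng = np.random.default_rng(8)
        ki = rng.normal(0, 1, 20)
        t = self._table(ki[:10], ki[10:], [40.0] * 10, [40.0] * 10)
        res = group_compare_ancova(t)
        f_oneway = stats.f_oneway(ki[:10], ki[10:])
        assert res.p_group == pytest.approx(f_oneway.pvalue, abs=1e-10)

    def test_single_group_rejected(self):
        t = pd.DataFrame({"group": ["HC"] * 5, "ki": np.arange(5.0), "age": np.arange(5.0) + 30})
        with pytest.raises(ValueError):
            group_compare_ancova(t)

    def test_power_on_cohort_generator_effect(self):
        """A true group difference of 0.042 (zero age effect, group SDs
        ~0.038) is detected at n = 13+12 in roughly two-thirds of
        replicates; the patient group's higher ages cost some power through
        the group-age collinearity in the ANCOVA."""
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            table, _ = make_cohort(
                seed=10_000 + rep,
                ki_mean={"HC": 0.003, "RRMS": 0.045},
                method_sd=0.0,
            )
            res = group_compare_ancova(table[table["method"] == "roi"])
            hits += res.p_group < 0.05
        # measured power 0.65 under these exact conditions; bound 3 MC
        # standard errors below
        assert hits / n_rep >= 0.55


class TestPairedCompare:
    def test_statistic_matches_exhaustive_sign_permutation_oracle(self):
        """At n = 6 with distinct signed ranks the exact Wilcoxon statistic
        and p-value equal full enumeration over all 2^6 sign assignments."""
        a = np.array([3.1, 5.2, 1.9, 7.4, 2.2, 9.0])
        b = np.array([2.0, 6.0, 1.0, 5.0, 4.0, 3.5])
        stat, p = paired_compare(a, b, test="wilcoxon")
        d = a - b
        ranks = stats.rankdata(np.abs(d))
        n = d.size
        total = n * (n + 1) / 2
        wplus = float(ranks[d > 0].sum())
        w_obs = min(wplus, total - wplus)
        dist = np.array(
            [
                sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product([0, 1], repeat=n)
            ]
        )
        p_oracle = float(np.mean(np.minimum(dist, total - dist) <= w_obs))
        assert stat == pytest.approx(w_obs)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_grey_vs_white_matter_difference_detected(self):
        """Paired GM/WM K_i values generated with a true difference at n=13
        are detected by the Wilcoxon test."""
        rng = np.random.default_rng(31)
        wm = rng.normal(0.020, 0.015, 13)
        gm = wm + rng.normal(0.025, 0.010, 13)
        _, p = paired_compare(gm, wm, test="wilcoxon")
        assert p < 0.05

    def test_degenerate_identical_samples_raise(self):
        x = np.arange(6.0)
        with pytest.raises(ValueError, match="zero"):
            paired_compare(x, x, test="wilcoxon")

    def test_paired_t_matches_scipy(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=(2, 10))
        stat, p = paired_compare(a, b, test="paired_t")
        ref = stats.ttest_rel(a, b)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestRegressKi:
    @staticmethod
    def _table(n=26, seed=6):
        rng = np.random.default_rng(seed)
        cbv = rng.uniform(1.0, 4.0, n)
        cbf = rng.uniform(20.0, 60.0, n)
        tissue = (np.arange(n) % 2).astype(float)
        return pd.DataFrame({"cbv": cbv, "cbf": cbf, "tissue": tissue})

    def test_exact_linear_relation_recovered(self):
        t = self._table()
        t["ki"] = 0.036 * t["cbv"]
        model = regress_ki(t)
        assert model.rsquared == pytest.approx(1.0, abs=1e-12)
        assert model.params["cbv"] == pytest.approx(0.036, abs=1e-12)
        assert model.params["cbf"] == pytest.approx(0.0, abs=1e-12)
        assert model.params["tissue"] == pytest.approx(0.0, abs=1e-12)

    def test_pure_noise_has_low_r_squared(self):
        t = self._table()
        t["ki"] = np.random.default_rng(77).normal(size=len(t))
        assert regress_ki(t).rsquared < 0.2

    def test_coefficients_match_normal_equations_oracle(self):
        t = self._table()
        rng = np.random.default_rng(15)
        t["ki"] = 0.02 * t["cbv"] - 1e-4 * t["cbf"] + 0.01 * t["tissue"] + rng.normal(0, 0.01, len(t))
        model = regress_ki(t)
        x = np.column_stack([np.ones(len(t)), t["cbv"], t["cbf"], t["tissue"]])
        beta = np.linalg.solve(x.T @ x, x.T @ t["ki"].to_numpy())
        np.testing.assert_allclose(model.params.to_numpy(), beta, atol=1e-10)

    def test_collinear_design_flagged(self):
        t = self._table()
        t["tissue"] = 2.0 * t["cbv"]  # tissue perfectly predicted by CBV
        t["ki"] = 0.03 * t["cbv"]
        with pytest.raises(ValueError, match="collinear"):
            regress_ki(t)
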