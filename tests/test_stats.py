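import numpy as np
import pandas as pd
import pytest

import focalindex as fx
from focalindex.errors import CollinearityError, UndefinedCorrelationError, UndefinedKappaError


class TestPearsonWithCI:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = fx.pearson_with_ci(x, 2 * x + 1)
        assert np.isclose(res.r, 1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        assert np.isclose(fx.pearson_with_ci(x, -x).r, -1.0)

    def test_monte_carlo_sampling_distribution(self):
        # bivariate normal, rho = 0.67, n = 36: the mean sample r over many
        # replicates sits within +-0.03 of rho (small negative bias of r)
        rng = np.random.default_rng(123)
        rho, n, reps = 0.67, 36, 2000
        rs = []
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            rs.append(fx.pearson_with_ci(x, y).r)
        assert abs(np.mean(rs) - rho) < 0.03

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            fx.pearson_with_ci(np.ones(10), np.arange(10.0))

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        a = fx.pearson_with_ci(x, y)
        b = fx.pearson_with_ci(3 * x + 2, 0.5 * y - 7)
        assert np.isclose(a.r, b.r)
        assert np.isclose(a.ci_low, b.ci_low) and np.isclose(a.ci_high, b.ci_high)

    def test_ci_brackets_r_and_shrinks_with_n(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(200)
        y = 0.5 * x + rng.standard_normal(200)
        small = fx.pearson_with_ci(x[:20], y[:20])
        large = fx.pearson_with_ci(x, y)
        assert small.ci_low < small.r < small.ci_high
        assert (large.ci_high - large.ci_low) < (small.ci_high - small.ci_low)

    def test_spearman_option_is_rank_based(self):
        x = np.arange(20.0)
        y = np.exp(x)  # monotone but nonlinear
        res = fx.pearson_with_ci(x, y, method="spearman")
        assert np.isclose(res.r, 1.0)


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert fx.cohen_kappa(fx.RaterTable(10, 0, 0, 10)).kappa == 1.0

    def test_reported_rater_table(self):
        # 37 scans: 35 both-diffuse, 1 split, 1 both-focal
        res = fx.cohen_kappa(fx.RaterTable(35, 1, 0, 1))
        assert np.isclose(res.kappa, 70 / 107)
        assert res.ci_high <= 1.0  # truncation

    def test_independent_raters_score_zero(self):
        assert abs(fx.cohen_kappa(fx.RaterTable(4, 4, 4, 4)).kappa) < 1e-12

    def test_transpose_invariance(self):
        a = fx.cohen_kappa(fx.RaterTable(20, 3, 5, 9))
        b = fx.cohen_kappa(fx.RaterTable(20, 5, 3, 9))
        assert np.isclose(a.kappa, b.kappa)

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(UndefinedKappaError):
            fx.cohen_kappa(fx.RaterTable(12, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(UndefinedKappaError):
            fx.RaterTable(-1, 2, 3, 4)


class TestSensitivityRegression:
    def _table(self, y, peep, rr, vt):
        return pd.DataFrame(
            {
                "focal_index": y,
                "peep_cmH2O": peep,
                "rr_per_min": rr,
                "vt_per_pbw_ml_kg": vt,
            }
        )

    def test_noiseless_coefficient_recovery(self):
        rng = np.random.default_rng(7)
        peep = rng.uniform(5, 15, 30)
        rr = rng.uniform(12, 30, 30)
        vt = rng.uniform(5, 9, 30)
        y = 3.0 * peep - 2.0 * rr + 5.0
        res = fx.sensitivity_regression(self._table(y, peep, rr, vt))
        assert np.isclose(res.params["peep_cmH2O"], 3.0)
        assert np.isclose(res.params["rr_per_min"], -2.0)
        assert np.isclose(res.params["vt_per_pbw_ml_kg"], 0.0, atol=1e-8)
        assert np.isclose(res.params["intercept"], 5.0)
        assert np.isclose(res.r_squared, 1.0)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(8)
        t = self._table(
            rng.uniform(0, 200, 36),
            rng.uniform(5, 15, 36),
            rng.uniform(12, 30, 36),
            rng.uniform(5, 9, 36),
        )
        a = fx.sensitivity_regression(t)
        b = fx.sensitivity_regression(t.sample(frac=1.0, random_state=1))
        assert np.isclose(a.r_squared, b.r_squared)
        for k in a.params:
            assert np.isclose(a.params[k], b.params[k])

    def test_collinear_design_names_offenders(self):
        rng = np.random.default_rng(9)
        peep = rng.uniform(5, 15, 36)
        t = self._table(rng.uniform(0, 200, 36), peep, 2 * peep, rng.uniform(5, 9, 36))
        with pytest.raises(CollinearityError, match="peep_cmH2O"):
            fx.sensitivity_regression(t)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(10)
        peep = rng.uniform(5, 15, 36)
        rr = rng.uniform(12, 30, 36)
        vt = rng.uniform(5, 9, 36)
        y = 100 + 2 * peep + rng.normal(0, 20, 36)
        res = fx.sensitivity_regression(self._table(y, peep, rr, vt))
        fitted = (
            res.params["intercept"]
            + res.params["peep_cmH2O"] * peep
            + res.params["rr_per_min"] * rr
            + res.params["vt_per_pbw_ml_kg"] * vt
        )
        resid = y - fitted
        for col in (np.ones(36), peep, rr, vt):
            assert abs(resid @ col) < 1e-6 * np.abs(y).sum()

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(11)
        t = self._table(rng.normal(size=4), rng.normal(size=4), rng.normal(size=4), rng.normal(size=4))
        with pytest.raises(ValueError):
            fx.sensitivity_regression(t)
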