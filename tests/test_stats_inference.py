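import math

import numpy as np
import pytest
from scipy import optimize

from demotif.core_model import Dataset, ProteinRecord
from demotif.stats_inference import (fisher_exact_two_sided, fit_logistic,
                                     fit_logistic_xy, lrt_pvalue, odds_ratio,
                                     phospho_contingency)


def neg_loglik(beta, X, y):
    eta = X @ beta
    return -np.sum(y * eta - np.logaddexp(0.0, eta))


def direct_ml_fit(X, y):
    """Independent optimizer oracle for the logistic likelihood."""
    res = optimize.minimize(
        neg_loglik, np.zeros(X.shape[1]), args=(X, y),
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 50000,
                 "maxfev": 50000})
    return res.x


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by integer hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    p_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w <= p_obs:
            total += w
    return total / math.comb(n, c1)


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        X = np.ones((10, 1))
        y = np.array([1] * 5 + [0] * 5, dtype=float)
        res = fit_logistic_xy(X, y)
        assert res.coefficients[0] == pytest.approx(0.0, abs=1e-10)
        assert res.converged

    def test_saturated_binary_predictor_slope_ln9(self):
        # x=1: 6 secretory / 2 non; x=0: 2 secretory / 6 non
        x = np.array([1] * 8 + [0] * 8, dtype=float)
        y = np.array([1] * 6 + [0] * 2 + [1] * 2 + [0] * 6, dtype=float)
        X = np.column_stack([np.ones(16), x])
        res = fit_logistic_xy(X, y)
        assert res.coefficients[1] == pytest.approx(math.log(9.0), abs=1e-8)

    def test_complete_separation_flagged(self):
        x = np.linspace(-1, 1, 20)
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones(20), x])
        with pytest.warns(RuntimeWarning):
            res = fit_logistic_xy(X, y)
        assert res.separation_detected

    def test_single_class_error(self):
        X = np.ones((5, 1))
        with pytest.raises(ValueError):
            fit_logistic_xy(X, np.ones(5))

    def test_too_few_rows_error(self):
        X = np.column_stack([np.ones(3), np.eye(3)])
        with pytest.raises(ValueError):
            fit_logistic_xy(X, np.array([0, 1, 0.0]))

    def test_matches_direct_maximization(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(20, 51))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            beta_true = rng.normal(scale=0.8, size=3)
            p = 1 / (1 + np.exp(-(X @ beta_true)))
            y = (rng.random(n) < p).astype(float)
            if y.sum() in (0, n):
                continue
            res = fit_logistic_xy(X, y)
            if res.separation_detected:
                continue
            oracle = direct_ml_fit(X, y)
            assert np.max(np.abs(res.coefficients - oracle)) < 1e-4

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        n = 60
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(float)
        X1 = np.column_stack([np.ones(n), x])
        X2 = np.column_stack([np.ones(n), 10.0 * x])
        r1 = fit_logistic_xy(X1, y)
        r2 = fit_logistic_xy(X2, y)
        assert r2.coefficients[1] == pytest.approx(r1.coefficients[1] / 10,
                                                   rel=1e-6)
        assert r2.wald_z[1] == pytest.approx(r1.wald_z[1], abs=1e-8)
        assert r2.lrt_p == pytest.approx(r1.lrt_p, abs=1e-8)

    def test_loglik_at_least_null(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = (rng.random(40) < 0.4).astype(float)
        res = fit_logistic_xy(X, y)
        assert res.loglik >= res.loglik_null - 1e-10

    def test_odds_ratios_exp_of_coefficients(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        y = (rng.random(50) < 0.5).astype(float)
        res = fit_logistic_xy(X, y)
        assert np.allclose(res.odds_ratios, np.exp(res.coefficients))

    def test_design_row_interface(self):
        from demotif.hypothesis_engine import DesignRow
        rng = np.random.default_rng(11)
        rows = [DesignRow(f"p{i}", int(rng.random() < 0.5),
                          float(rng.normal()), float(rng.normal()),
                          int(rng.random() < 0.5), 0)
                for i in range(40)]
        res = fit_logistic(rows, case_id=3)
        assert res.case_id == 3
        assert res.names == ["intercept", "H", "C", "order"]

    def test_ridge_rescues_separation(self):
        x = np.linspace(-1, 1, 20)
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones(20), x])
        res = fit_logistic_xy(X, y, ridge=1.0)
        assert res.converged and not res.separation_detected


class TestLRT:
    def test_zero_deviance(self):
        assert lrt_pvalue(-10.0, -10.0, 1) == pytest.approx(1.0)

    def test_chi2_quantiles(self):
        # chi-square(1) critical values at 0.05 and 0.01
        assert lrt_pvalue(0.0, -3.841 / 2, 1) == pytest.approx(0.05,
                                                               abs=5e-4)
        assert lrt_pvalue(0.0, -6.635 / 2, 1) == pytest.approx(0.01,
                                                               abs=5e-5)

    def test_negative_deviance_error(self):
        with pytest.raises(ValueError):
            lrt_pvalue(-5.0, -1.0, 1)

    def test_df_zero_error(self):
        with pytest.raises(ValueError):
            lrt_pvalue(0.0, 0.0, 0)


class TestOddsRatio:
    def test_eight(self):
        res = odds_ratio((10, 5, 2, 8))
        assert res.odds_ratio == pytest.approx(8.0)
        assert not res.correction_applied

    def test_symmetric_table_is_one(self):
        assert odds_ratio((5, 5, 5, 5)).odds_ratio == pytest.approx(1.0)

    def test_haldane_anscombe(self):
        res = odds_ratio((3, 0, 2, 4))
        assert res.correction_applied
        assert res.odds_ratio == pytest.approx((3.5 * 4.5) / (0.5 * 2.5))

    def test_ci_brackets_point_estimate(self):
        res = odds_ratio((10, 5, 2, 8))
        lo, hi = res.or_ci_95
        assert lo < res.odds_ratio < hi

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            odds_ratio((0, 0, 0, 0))

    def test_negative_cell_error(self):
        with pytest.raises(ValueError):
            odds_ratio((1, -1, 2, 3))


class TestFisherExact:
    def test_34_over_70(self):
        assert fisher_exact_two_sided((3, 1, 1, 3)) == \
            pytest.approx(34 / 70, rel=1e-9)

    def test_2_over_70(self):
        assert fisher_exact_two_sided((0, 4, 4, 0)) == \
            pytest.approx(2 / 70, rel=1e-9)

    def test_modal_symmetric_table(self):
        assert fisher_exact_two_sided((2, 2, 2, 2)) == pytest.approx(1.0)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 9, size=4)
            if a + b + c + d == 0:
                continue
            got = fisher_exact_two_sided((a, b, c, d))
            assert got == pytest.approx(fisher_oracle(a, b, c, d),
                                        rel=1e-7)

    def test_matches_scipy(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b + c + d == 0:
                continue
            got = fisher_exact_two_sided((a, b, c, d))
            ref = fisher_exact([[a, b], [c, d]]).pvalue
            assert got == pytest.approx(ref, rel=1e-6)


class TestPhosphoContingency:
    def build_dataset(self):
        # 3/4 secretory with a phospho-context motif, 1/4 non-secretory
        recs = []
        with_motif = "AADSEAA"    # DXE with S
        without = "AADAEAADEA"    # DE present, no phospho context
        for i in range(3):
            recs.append(ProteinRecord(f"s{i}", with_motif + "DE",
                                      label="secretory"))
        recs.append(ProteinRecord("s3", without, label="secretory"))
        recs.append(ProteinRecord("n0", with_motif + "DE",
                                  label="non_secretory"))
        for i in range(1, 4):
            recs.append(ProteinRecord(f"n{i}", without,
                                      label="non_secretory"))
        return Dataset(records=recs)

    def test_toy_table_and_p(self):
        res = phospho_contingency(self.build_dataset())
        assert res.table == (3, 1, 1, 3)
        assert res.fisher_p_two_sided == pytest.approx(34 / 70, rel=1e-9)

    def test_degenerate_column_correction(self):
        recs = [ProteinRecord(f"p{i}", "AADSEAA",
                              label="secretory" if i < 2 else "non_secretory")
                for i in range(4)]
        res = phospho_contingency(Dataset(records=recs))
        assert res.correction_applied

    def test_kind_restriction_changes_table(self):
        ds = Dataset(records=[
            ProteinRecord("a", "AASDEAA", label="secretory"),    # XDE only
            ProteinRecord("b", "AADSEAA", label="non_secretory"),  # DXE only
        ])
        all_kinds = phospho_contingency(ds)
        dxe_only = phospho_contingency(ds, kinds=["DXE"])
        assert all_kinds.table == (1, 1, 0, 0)
        assert dxe_only.table == (0, 1, 1, 0)

    def test_empty_dataset_error(self):
        with pytest.raises(ValueError):
            phospho_contingency(Dataset(records=[]))
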