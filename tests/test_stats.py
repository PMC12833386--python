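"""Statistical layer: VIF screen, backward elimination, diagnostics,
Hommel correction, ICC."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from spinedvc.stats import (
    backward_fit,
    hommel_adjust,
    icc_absolute,
    model_diagnostics,
    vif_screen,
)


def closed_testing_hommel(p: np.ndarray) -> np.ndarray:
    """Brute-force closed testing with Simes intersection tests.

    Adjusted p_i = max over all subsets S containing i of the Simes p-value
    of S; this is the defining construction the step-up shortcut implements.
    """
    m = len(p)
    adj = np.zeros(m)
    for i in range(m):
        worst = 0.0
        for r in range(1, m + 1):
            for S in itertools.combinations(range(m), r):
                if i not in S:
                    continue
                ps = np.sort(p[list(S)])
                k = len(ps)
                simes = np.min(k * ps / np.arange(1, k + 1))
                worst = max(worst, simes)
        adj[i] = min(1.0, worst)
    return adj


def holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)[::-1]
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank, idx in enumerate(order):
        running = min(running, (rank + 1) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


class TestVifScreen:
    def test_orthogonal_predictors_all_kept(self, rng):
        n = 40
        base = rng.standard_normal((n, 3))
        q, _ = np.linalg.qr(base)
        table = pd.DataFrame(q, columns=["a", "b", "c"])
        retained, ledger = vif_screen(table, ["a", "b", "c"])
        assert retained == ["a", "b", "c"]
        assert ledger == []

    def test_vif_matches_direct_r2_oracle(self, rng):
        # correlated triple: VIF_j must equal 1/(1-R2_j) from an independent
        # full regression of predictor j on the others
        n = 60
        x1 = rng.standard_normal(n)
        x2 = 0.7 * x1 + 0.5 * rng.standard_normal(n)
        x3 = rng.standard_normal(n)
        table = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        import statsmodels.api as sm
        vifs_oracle = {}
        for j, name in enumerate(["x1", "x2", "x3"]):
            others = [c for c in table.columns if c != name]
            res = sm.OLS(table[name], sm.add_constant(table[others])).fit()
            vifs_oracle[name] = 1.0 / (1.0 - res.rsquared)
        # none exceed 10 here, so the screen keeps everything; check via the
        # screen's own threshold mechanics with a tight threshold instead
        retained, ledger = vif_screen(table, list(table.columns),
                                      threshold=max(vifs_oracle.values()) - 1e-9)
        dropped = ledger[0]["predictor"]
        assert dropped == max(vifs_oracle, key=vifs_oracle.get)

    def test_perfect_collinearity_ledgered_as_infinite(self, rng):
        n = 30
        x = rng.standard_normal(n)
        table = pd.DataFrame({"x": x, "y": 2 * x, "z": rng.standard_normal(n)})
        retained, ledger = vif_screen(table, ["x", "y", "z"])
        assert "z" in retained and len(retained) == 2
        assert "infinite" in ledger[0]["reason"]


class TestBackwardFit:
    def test_single_strong_predictor_f_equals_t_squared(self, rng):
        n = 30
        x = rng.standard_normal(n)
        y = 2.0 * x + 0.3 * rng.standard_normal(n)
        table = pd.DataFrame({"x": x, "y": y})
        m = backward_fit(table, "y", ["x"], p_out=0.10)
        assert m.retained == ["x"]
        t = m.coef["x"] / m.se["x"]
        assert m.f_value == pytest.approx(t ** 2, rel=1e-9)

    def test_p_out_one_keeps_full_model(self, rng):
        n = 25
        table = pd.DataFrame(rng.standard_normal((n, 4)),
                             columns=["a", "b", "c", "y"])
        m = backward_fit(table, "y", ["a", "b", "c"], p_out=1.0)
        assert set(m.retained) == {"a", "b", "c"}

    def test_pure_noise_with_tiny_p_out_is_intercept_only(self, rng):
        n = 25
        table = pd.DataFrame(rng.standard_normal((n, 4)),
                             columns=["a", "b", "c", "y"])
        m = backward_fit(table, "y", ["a", "b", "c"], p_out=1e-6)
        assert m.intercept_only
        assert m.retained == []

    def test_bias_vanishes_as_noise_shrinks(self):
        from spinedvc.phantom import make_synthetic_cohort
        betas = {"ap_ratio": 5.0, "age": -0.4}
        biases = []
        for noise in (2.0, 0.2, 0.02):
            errs = []
            for k in range(10):
                table, _ = make_synthetic_cohort(30, betas, noise, seed=500 + k)
                m = backward_fit(table, "outcome", ["ap_ratio", "age", "bmi"],
                                 p_out=0.10)
                errs.append(abs(m.coef.get("ap_ratio", 0.0) - 5.0))
            biases.append(np.mean(errs))
        assert biases[2] < biases[1] < biases[0]


class TestDiagnostics:
    def test_gaussian_residuals_usually_pass(self):
        from spinedvc.phantom import make_synthetic_cohort
        passes = 0
        n_rep = 30
        for k in range(n_rep):
            table, _ = make_synthetic_cohort(15, {"age": 1.0}, 1.0, seed=200 + k)
            m = backward_fit(table, "outcome", ["age", "bmi"], p_out=1.0)
            d = model_diagnostics(m)
            passes += (not d["excluded"])
        assert passes >= 0.8 * n_rep

    def test_variance_proportional_to_fitted_is_flagged(self, rng):
        flagged = 0
        n_rep = 20
        for k in range(n_rep):
            r = np.random.default_rng(300 + k)
            x = r.uniform(1, 10, 60)
            y = 3.0 * x + r.standard_normal(60) * (0.8 * x)
            table = pd.DataFrame({"x": x, "y": y})
            m = backward_fit(table, "y", ["x"], p_out=1.0)
            d = model_diagnostics(m)
            flagged += (not d["homoscedasticity_ok"])
        assert flagged > n_rep / 2

    def test_constant_residuals_pass_both(self, rng):
        x = rng.standard_normal(20)
        table = pd.DataFrame({"x": x, "y": 2 * x + 1})
        m = backward_fit(table, "y", ["x"], p_out=1.0)
        d = model_diagnostics(m)
        assert d["normality_ok"] and d["homoscedasticity_ok"]
        assert not d["excluded"]


class TestHommel:
    def test_single_p_unchanged(self):
        assert hommel_adjust([0.03]) == pytest.approx([0.03])

    def test_all_ones_stay_one(self):
        assert np.allclose(hommel_adjust([1.0] * 5), 1.0)

    def test_matches_closed_testing_oracle(self, rng):
        for _ in range(60):
            m = int(rng.integers(2, 5))
            p = rng.uniform(0, 1, size=m)
            assert np.allclose(hommel_adjust(p), closed_testing_hommel(p),
                               atol=1e-12)

    def test_dominance_between_holm_and_hochberg(self, rng):
        # Hommel's closed test is uniformly more powerful than Hochberg's
        # shortcut, which in turn dominates Holm: adjusted p-values obey
        # Hommel <= Hochberg <= Holm elementwise, and all are >= raw p
        for _ in range(40):
            p = rng.uniform(0, 1, size=int(rng.integers(2, 7)))
            h = hommel_adjust(p)
            assert np.all(h <= hochberg(p) + 1e-12)
            assert np.all(hochberg(p) <= holm(p) + 1e-12)
            assert np.all(h >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hommel_adjust([0.2, 1.4])


def icc21_oracle(mat: np.ndarray) -> float:
    """ICC(2,1) from the two-way ANOVA mean squares, computed directly."""
    k, n = mat.shape
    grand = mat.mean()
    ms_rows = k * ((mat.mean(axis=0) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((mat.mean(axis=1) - grand) ** 2).sum() / (k - 1)
    resid = mat - mat.mean(axis=0) - mat.mean(axis=1)[:, None] + grand
    ms_err = (resid ** 2).sum() / ((n - 1) * (k - 1))
    return ((ms_rows - ms_err)
            / (ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n))


class TestICC:
    def test_identical_raters_give_one(self):
        mat = np.tile([3.0, 5.0, 4.0, 2.0, 4.5], (3, 1))
        res = icc_absolute(mat)
        assert res.estimate == pytest.approx(1.0)

    def test_constant_offset_penalised_by_absolute_agreement(self, rng):
        base = rng.uniform(1, 5, size=8)
        mat = np.stack([base, base + 1.0])
        res = icc_absolute(mat)
        assert res.estimate < 1.0
        # consistency would be perfect; absolute agreement must not be
        assert res.estimate == pytest.approx(icc21_oracle(mat), abs=1e-9)

    def test_random_matrix_matches_anova_oracle(self, rng):
        for _ in range(10):
            mat = rng.uniform(1, 5, size=(3, 9))
            res = icc_absolute(mat)
            assert res.estimate == pytest.approx(icc21_oracle(mat), abs=1e-9)
            assert res.ci_lower <= res.estimate <= res.ci_upper
            assert res.estimate <= 1.0

    def test_zero_between_subject_variance_degenerate(self):
        mat = np.array([[2.0, 2.0, 2.0], [3.0, 3.0, 3.0]])
        assert icc_absolute(mat).degenerate

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute(np.ones((1, 5)))
        with pytest.raises(ValueError):
            icc_absolute(np.ones((2, 2)))
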