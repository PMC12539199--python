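"""Univariable MR estimators against their definitions and independent oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from metabomr.uvmr import (
    MODE_GRID_POINTS,
    UnivariableMR,
    _ratio_weights,
    _weighted_median_point,
    egger,
    ivw_mre,
    run_univariable,
    wald_ratio,
    weighted_median,
    weighted_mode,
)

from conftest import make_harmonized, random_harmonized


class TestWald:
    def test_arithmetic(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.theta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_zero_outcome(self):
        assert wald_ratio(1.0, 0.1, 0.0, 0.1).theta == 0.0

    def test_zero_exposure_beta_errors(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.1, 0.05, 0.1)


class TestIVW:
    def test_perfect_collinearity(self):
        h = make_harmonized([1, 2], [0.1, 0.1], [0.5, 1.0], [0.1, 0.1])
        est = ivw_mre(h)
        assert est.theta == pytest.approx(0.5)
        assert est.q == pytest.approx(0.0, abs=1e-20)
        assert est.se == pytest.approx(0.0, abs=1e-12)

    def test_single_variant_rejected(self):
        h = make_harmonized([1.0], [0.1], [0.5], [0.1])
        with pytest.raises(ValueError):
            ivw_mre(h)

    def test_matches_wls_oracle(self):
        h = make_harmonized(
            [0.08, 0.12, 0.10], [0.01, 0.01, 0.01],
            [0.050, 0.055, 0.070], [0.010, 0.012, 0.009],
        )
        est = ivw_mre(h)
        w = 1 / h.by_se**2
        fit = sm.WLS(h.by, h.bx[:, None], weights=w).fit()
        assert est.theta == pytest.approx(fit.params[0], abs=1e-10)
        assert est.se == pytest.approx(fit.bse[0], abs=1e-10)

    def test_mre_scale_not_floored(self):
        # nearly exact fit -> residual scale << 1 -> MRE se below fixed-effect se
        h = make_harmonized(
            [0.1, 0.2, 0.3], [0.01] * 3,
            [0.05, 0.1, 0.15001], [0.05] * 3,
        )
        est = ivw_mre(h)
        fixed_se = 1 / np.sqrt(np.sum(h.bx**2 / h.by_se**2))
        assert est.se < fixed_se


class TestEgger:
    def test_exact_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_harmonized(bx, [0.01] * 4, 0.1 + 0.5 * bx, [0.05] * 4)
        est = egger(h)
        assert est.egger_intercept == pytest.approx(0.1, abs=1e-12)
        assert est.theta == pytest.approx(0.5, abs=1e-12)

    def test_orientation_invariance(self):
        bx = np.array([0.1, -0.2, 0.3, 0.4])
        by = 0.1 * np.sign(bx) + 0.5 * bx
        h1 = make_harmonized(bx, [0.01] * 4, by, [0.05] * 4)
        h2 = make_harmonized(-bx, [0.01] * 4, -by, [0.05] * 4)
        e1, e2 = egger(h1), egger(h2)
        assert e1.theta == pytest.approx(e2.theta)
        assert e1.egger_intercept == pytest.approx(e2.egger_intercept)

    def test_matches_wls_oracle_with_floor(self, rng):
        h = random_harmonized(rng, 6)
        flip = np.sign(h.bx)
        bx, by = h.bx * flip, h.by * flip
        w = 1 / h.by_se**2
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=w).fit()
        scale_factor = np.sqrt(max(fit.scale, 1.0) / fit.scale)
        est = egger(h)
        assert est.theta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert est.se == pytest.approx(fit.bse[1] * scale_factor, abs=1e-10)

    def test_too_few_or_degenerate(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.05] * 2)
        with pytest.raises(ValueError):
            egger(h)
        h = make_harmonized([0.1, 0.1, -0.1], [0.01] * 3, [0.1, 0.1, -0.1], [0.05] * 3)
        with pytest.raises(ValueError, match="unidentifiable"):
            egger(h)


class TestWeightedMedian:
    def test_all_ratios_equal(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.15], [0.05] * 3)
        assert weighted_median(h, n_boot=10, seed=0).theta == pytest.approx(0.5)

    def test_equal_weight_interpolation(self):
        # ratios (1, 2, 3) with equal weights: s = (1/6, 1/2, 5/6), theta = 2
        h = make_harmonized([1, 1, 1], [1e-9] * 3, [1, 2, 3], [1.0] * 3)
        assert weighted_median(h, n_boot=10, seed=0).theta == pytest.approx(2.0)

    def test_matches_definition_bruteforce(self, rng):
        """Independent recomputation of the interpolation definition."""
        h = random_harmonized(rng, 5)
        r, w = _ratio_weights(h.bx, h.bx_se, h.by, h.by_se)
        order = np.argsort(r)
        r_s, w_s = r[order], w[order]
        s = (np.cumsum(w_s) - w_s / 2) / w_s.sum()
        below = np.where(s < 0.5)[0][-1]
        frac = (0.5 - s[below]) / (s[below + 1] - s[below])
        expected = r_s[below] + frac * (r_s[below + 1] - r_s[below])
        assert weighted_median(h, n_boot=10, seed=0).theta == pytest.approx(expected, abs=1e-12)

    def test_bootstrap_seeded(self, rng):
        h = random_harmonized(rng, 6)
        a = weighted_median(h, n_boot=200, seed=42)
        b = weighted_median(h, n_boot=200, seed=42)
        assert a.se == b.se


class TestWeightedMode:
    def test_all_ratios_equal(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.15], [0.05] * 3)
        est = weighted_mode(h, n_boot=10, seed=0)
        assert est.theta == pytest.approx(0.5)
        assert est.se == 0.0

    def test_majority_cluster_wins(self):
        bx = np.ones(5)
        by = np.array([0.50, 0.51, 0.49, 0.50, 3.0])
        h = make_harmonized(bx, [0.01] * 5, by, [0.05] * 5)
        est = weighted_mode(h, n_boot=10, seed=0)
        assert abs(est.theta - 0.5) < 0.1

    def test_matches_dense_grid_oracle(self, rng):
        """Brute-force density maximization at 10x grid resolution."""
        h = random_harmonized(rng, 6)
        r, w = _ratio_weights(h.bx, h.bx_se, h.by, h.by_se)
        wmean = np.average(r, weights=w)
        wsd = np.sqrt(np.average((r - wmean) ** 2, weights=w))
        med = _weighted_median_point(r, w)
        wmad = _weighted_median_point(np.abs(r - med), w) / 0.6744897501960817
        spread = min(wsd, wmad) if wmad > 0 else wsd
        bw = 0.9 * spread * len(r) ** (-0.2)
        grid = np.linspace(r.min() - 3 * bw, r.max() + 3 * bw, MODE_GRID_POINTS * 10)
        dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / bw) ** 2)).sum(1)
        oracle = grid[np.argmax(dens)]
        est = weighted_mode(h, n_boot=10, seed=0)
        coarse_step = (grid[-1] - grid[0]) / (MODE_GRID_POINTS - 1)
        assert abs(est.theta - oracle) <= coarse_step


class TestDispatch:
    def test_one_snp_wald_only(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.02])
        out = run_univariable(h)
        assert [e.method for e in out] == ["wald"]

    def test_two_snp_ivw_only(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        out = run_univariable(h)
        assert [e.method for e in out] == ["ivw_mre"]

    def test_three_plus_full_suite(self, rng):
        h = random_harmonized(rng, 10)
        out = run_univariable(h, n_boot=20, seed=0)
        assert [e.method for e in out] == [
            "ivw_mre", "egger", "weighted_median", "weighted_mode"
        ]

    def test_empty_errors(self):
        h = make_harmonized([], [], [], [])
        with pytest.raises(ValueError):
            run_univariable(h)


@given(c=st.floats(min_value=0.1, max_value=10.0))
@settings(max_examples=20, deadline=None)
def test_scale_equivariance(c):
    """Scaling outcome betas and SEs by c scales every theta and se by c."""
    rng = np.random.default_rng(7)
    h = random_harmonized(rng, 6)
    h_scaled = make_harmonized(h.bx, h.bx_se, c * h.by, c * h.by_se)
    for fn in (ivw_mre, egger):
        a, b = fn(h), fn(h_scaled)
        assert b.theta == pytest.approx(c * a.theta, rel=1e-9)
        assert b.se == pytest.approx(c * a.se, rel=1e-9)
    a = weighted_median(h, n_boot=50, seed=3)
    b = weighted_median(h_scaled, n_boot=50, seed=3)
    assert b.theta == pytest.approx(c * a.theta, rel=1e-9)
    assert b.se == pytest.approx(c * a.se, rel=1e-6)


def test_estimator_consistency_on_planted_effect():
    """With 100 valid instruments and n=50,000 per panel, every estimator's
    theta lands within 3 SEs of the planted effect."""
    from metabomr.synthetic import SimulationConfig, generate_study
    from metabomr.sumstats import harmonize, select_instruments

    cfg = SimulationConfig(
        seed=77, n_samples_per_panel=50_000, n_instruments_x=100,
        n_mediators=0, gamma=(), delta=(), tau_direct=0.3, subtype_scales={},
        confounder_effect_d=0.0, age_effect_d=0.0,
    )
    bundle = generate_study(cfg, include_lowpower=False, include_observational=False)
    instruments = select_instruments(bundle.exposures["adiposity"], 5e-9)
    h = harmonize(instruments, bundle.outcomes["cancer_overall"])
    for est in run_univariable(h, n_boot=100, seed=3):
        assert abs(est.theta - 0.3) < 3 * max(est.se, 0.02), est.method


def test_model_results_surface(rng):
    h = random_harmonized(rng, 8)
    results = UnivariableMR(h, outcome_binary=True).fit(n_boot=20, seed=0)
    frame = results.to_frame()
    assert set(frame["method"]) == {"ivw_mre", "egger", "weighted_median", "weighted_mode"}
    assert "odds_ratio" in frame.columns
    ivw = results["ivw_mre"]
    assert ivw.ci_low <= ivw.theta <= ivw.ci_high
    text = results.summary()
    assert "ivw_mre" in text and "Egger intercept" in text
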