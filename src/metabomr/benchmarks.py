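"""Monte-Carlo benchmark harnesses over the synthetic study generator.

Each harness repeatedly generates a study under fixed conditions, runs the
pipeline's own estimators, and summarizes operating characteristics against
the generator's recorded ground truth: type-1 error of the IVW-MRE model
under the global null, recovery of a planted exposure->outcome log-odds
ratio, the robust-estimator contract under directional pleiotropy,
attenuation recovery across planted mediated proportions, and the
calibration of the off-target enrichment null.

These drive both the test suite and the reproduction script; per-replicate
seeds are spawned deterministically from one master seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from .mvmr import direct_effect_scan
from .offtarget import TraitCatalogue, enrichment_scan
from .sumstats import harmonize, select_instruments
from .synthetic import (
    EXPOSURE_ID,
    OUTCOME_ID,
    CatalogueConfig,
    SimulationConfig,
    compute_sumstats,
    generate_catalogue,
    generate_study,
    make_truth,
    simulate_cohort,
)
from .triangulate import TriangulationConfig, run_triangulation
from .uvmr import egger, ivw_mre, weighted_median

__all__ = [
    "spawn_seeds",
    "ivw_null_calibration",
    "effect_recovery",
    "robust_estimator_contract",
    "attenuation_recovery",
    "offtarget_calibration",
]


def spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds below 2^31."""
    rng = np.random.default_rng(master_seed)
    return rng.integers(0, 2**31 - 1, size=n)


def _two_panel_ivw(config: SimulationConfig, p_threshold: float,
                   n_exposure: int | None = None):
    """Exposure and outcome panels -> harmonized set -> IVW-MRE estimate.

    ``n_exposure`` lets the exposure GWAS run at a larger sample size than
    the outcome GWAS, as is typical of the continuous-trait side.
    """
    exp_cfg = config if n_exposure is None else replace(config, n_samples_per_panel=n_exposure)
    exp = compute_sumstats(simulate_cohort(exp_cfg, "exposure"), EXPOSURE_ID)
    out = compute_sumstats(simulate_cohort(config, "outcome"), OUTCOME_ID)
    instruments = select_instruments(exp, p_threshold, allow_empty=True)
    if len(instruments) < 3:
        return None
    return harmonize(instruments, out)


def ivw_null_calibration(
    n_reps: int = 1000,
    seed: int = 0,
    n_samples: int = 20_000,
    n_instruments: int = 50,
    alpha: float = 0.05,
) -> dict:
    """Type-1 error of IVW-MRE under the global null with valid instruments.

    Every instrument is a genuine exposure instrument; the outcome carries
    no exposure, mediator or pleiotropic genetic effect.  Returns the
    rejection rate at ``alpha`` over the replicates.
    """
    seeds = spawn_seeds(seed, n_reps)
    rejected, used = 0, 0
    for s in seeds:
        cfg = SimulationConfig(
            seed=int(s), n_samples_per_panel=n_samples,
            n_instruments_x=n_instruments, n_mediators=0, gamma=(), delta=(),
            tau_direct=0.0, subtype_scales={},
        )
        h = _two_panel_ivw(cfg, p_threshold=5e-8)
        if h is None:
            continue
        used += 1
        if ivw_mre(h).pval < alpha:
            rejected += 1
    return {"rejection_rate": rejected / used, "n_reps": used, "alpha": alpha}


def effect_recovery(
    n_reps: int = 200,
    seed: int = 0,
    tau: float = 0.59,
    n_instruments: int = 100,
    n_exposure: int = 100_000,
    n_outcome: int = 10_000,
    instrument_scale: float = 0.06,
) -> dict:
    """Recovery of a planted exposure->outcome log-odds effect by IVW-MRE.

    The default planted effect, log(1.8) ~ 0.59 per SD, matches the scale of
    an adiposity->cancer odds ratio of 1.8.  The exposure GWAS runs at a much
    larger sample size than the case-control outcome GWAS (as in practice)
    so weak-instrument dilution stays negligible; the outcome has no
    non-genetic covariate effects, isolating the estimator's behaviour.
    Reports the mean estimate, the mean odds ratio, and 95% CI coverage of
    the planted value.  A marginal-logistic outcome GWAS carries an
    intrinsic non-collapsibility attenuation of a few percent, which is part
    of what the coverage measures.
    """
    seeds = spawn_seeds(seed, n_reps)
    thetas, covered = [], []
    for s in seeds:
        cfg = SimulationConfig(
            seed=int(s), n_samples_per_panel=n_outcome,
            n_instruments_x=n_instruments, n_mediators=0, gamma=(), delta=(),
            tau_direct=tau, subtype_scales={},
            instrument_effect_scale=instrument_scale,
            confounder_effect_d=0.0, age_effect_d=0.0,
        )
        h = _two_panel_ivw(cfg, p_threshold=5e-9, n_exposure=n_exposure)
        if h is None:
            continue
        est = ivw_mre(h)
        thetas.append(est.theta)
        covered.append(est.ci_low <= tau <= est.ci_high)
    thetas = np.asarray(thetas)
    return {
        "planted_log_or": tau,
        "mean_estimate": float(thetas.mean()),
        "mean_or": float(np.exp(thetas).mean()),
        "bias": float(thetas.mean() - tau),
        "coverage": float(np.mean(covered)),
        "mc_se": float(thetas.std(ddof=1) / np.sqrt(len(thetas))),
        "n_reps": len(thetas),
    }


def robust_estimator_contract(
    n_reps: int = 200,
    seed: int = 0,
    tau: float = 0.3,
    invalid_fraction: float = 0.3,
    pleiotropy_mean: float = 0.08,
    n_instruments: int = 100,
    n_exposure: int = 50_000,
    n_outcome: int = 20_000,
    instrument_scale: float = 0.06,
) -> dict:
    """Weighted median vs IVW under directional pleiotropy; Egger intercept.

    ``invalid_fraction`` of the instruments carry a directional (oriented to
    the exposure-raising allele) pleiotropic outcome effect of mean
    ``pleiotropy_mean`` log-odds per allele.  Reports the fraction of
    replicates where |weighted-median bias| < |IVW bias|, and the mean Egger
    intercept against the planted per-instrument mean pleiotropy.
    """
    seeds = spawn_seeds(seed, n_reps)
    ivw_bias, wm_bias, intercepts = [], [], []
    for s in seeds:
        cfg = SimulationConfig(
            seed=int(s), n_samples_per_panel=n_outcome,
            n_instruments_x=n_instruments, n_mediators=0, gamma=(), delta=(),
            tau_direct=tau, invalid_fraction=invalid_fraction,
            pleiotropy_mean=pleiotropy_mean, pleiotropy_sd=0.02,
            instrument_effect_scale=instrument_scale,
            subtype_scales={},
        )
        h = _two_panel_ivw(cfg, p_threshold=5e-9, n_exposure=n_exposure)
        if h is None:
            continue
        ivw_bias.append(ivw_mre(h).theta - tau)
        wm_bias.append(weighted_median(h, n_boot=50, seed=int(s) % 10_000).theta - tau)
        intercepts.append(egger(h).egger_intercept)
    ivw_bias = np.asarray(ivw_bias)
    wm_bias = np.asarray(wm_bias)
    intercepts = np.asarray(intercepts)
    planted_mean_pleiotropy = invalid_fraction * pleiotropy_mean
    return {
        "median_beats_ivw_fraction": float(np.mean(np.abs(wm_bias) < np.abs(ivw_bias))),
        "mean_ivw_bias": float(ivw_bias.mean()),
        "mean_wm_bias": float(wm_bias.mean()),
        "egger_intercept_mean": float(intercepts.mean()),
        "egger_intercept_mc_se": float(intercepts.std(ddof=1) / np.sqrt(len(intercepts))),
        "planted_mean_pleiotropy": planted_mean_pleiotropy,
        "n_reps": len(ivw_bias),
    }


def _attenuation_config(seed: int, mediated_prop: float, tau_total: float,
                        n_samples: int, n_instruments_x: int,
                        n_instruments_m: int) -> SimulationConfig:
    gamma = 0.5
    delta = mediated_prop * tau_total / gamma
    tau_direct = (1.0 - mediated_prop) * tau_total
    return SimulationConfig(
        seed=seed, n_samples_per_panel=n_samples,
        n_instruments_x=n_instruments_x, n_instruments_per_m=n_instruments_m,
        n_mediators=1, gamma=gamma, delta=delta, tau_direct=tau_direct,
        subtype_scales={},
    )


def attenuation_recovery(
    mediated_props: tuple[float, ...] = (0.0, 0.5, 1.0),
    n_reps: int = 200,
    seed: int = 0,
    tau_total: float = 0.4,
    n_samples: int = 20_000,
    n_instruments_x: int = 50,
    n_instruments_m: int = 15,
    check_chain_every: int = 10,
) -> dict:
    """Attenuation-fraction recovery across planted mediated proportions.

    For each planted mediated proportion, a single-mediator study is
    generated and the attenuation fraction 1 - theta_direct/theta_total is
    measured via the two-exposure MVMR scan (ungated, so the zero-mediation
    scenario is measurable).  Every ``check_chain_every``-th replicate
    additionally runs the full gated screening pipeline and asserts the
    stage subset-chain invariant.
    """
    out: dict[str, dict] = {}
    for prop in mediated_props:
        seeds = spawn_seeds(seed + int(prop * 1000), n_reps)
        fractions = []
        chain_checked = 0
        for i, s in enumerate(seeds):
            cfg = _attenuation_config(int(s), prop, tau_total, n_samples,
                                      n_instruments_x, n_instruments_m)
            bundle = generate_study(cfg, include_lowpower=False,
                                    include_observational=False)
            exp_inst = select_instruments(bundle.exposures[EXPOSURE_ID], 5e-8)
            med_inst = select_instruments(bundle.mediators["metabolite_001"], 5e-8)
            # total effect from the same (main) exposure GWAS, as in Part I
            h_total = harmonize(exp_inst, bundle.outcomes[OUTCOME_ID])
            total = ivw_mre(h_total)
            _, rows = direct_effect_scan(
                exp_inst, bundle.exposures[EXPOSURE_ID],
                {"metabolite_001": (med_inst, bundle.mediators["metabolite_001"])},
                bundle.outcomes[OUTCOME_ID],
                theta_total=total,
            )
            row = rows[0]
            if row.attenuation is not None:
                fractions.append(row.attenuation)
            if i % check_chain_every == 0:
                report = run_triangulation(
                    bundle, TriangulationConfig(n_boot=50, seed=int(s) % 10_000,
                                                use_observational=False),
                )
                report.validate_chain()  # raises on violation
                chain_checked += 1
        fractions = np.asarray(fractions)
        out[f"mediated_{prop:g}"] = {
            "planted": prop,
            "mean_attenuation": float(fractions.mean()),
            "mc_se": float(fractions.std(ddof=1) / np.sqrt(len(fractions))),
            "n_reps": int(len(fractions)),
            "chain_runs_checked": chain_checked,
        }
    return out


def offtarget_calibration(
    n_catalogues: int = 50,
    seed: int = 0,
    n_mediators: int = 55,
    n_signal: int = 5,
    n_iter: int = 100,
    pit_trait: str = "height",
) -> dict:
    """Null calibration and planted-enrichment detection of the phenome scan.

    Exchangeable background catalogues: the randomized PIT of the observed
    count within the null redraws should be uniform, tested by
    Kolmogorov-Smirnov on one PIT value per catalogue draw (values within a
    catalogue share the same redraws and are not independent, so only one
    trait's value enters per draw).  The pool is ten times the signal set,
    as in a screening study where most of the panel is not implicated, so
    redraws overlap little.  A catalogue with planted associations on the
    signal instruments should give the minimal empirical p, 1/(n_iter + 1).
    """
    base = SimulationConfig(
        seed=seed, n_samples_per_panel=500, n_instruments_x=5,
        n_instruments_per_m=8, n_mediators=n_mediators,
        gamma=0.0, delta=0.0, tau_direct=0.0, subtype_scales={},
    )
    truth = make_truth(base)
    instruments = {m: list(v) for m, v in truth.mediator_instrument_effects.items()}
    mediators = list(instruments)
    signal, pool = mediators[:n_signal], mediators[n_signal:]

    rng = np.random.default_rng(seed)
    pit = []
    for c in range(n_catalogues):
        cat = TraitCatalogue(
            generate_catalogue(truth, CatalogueConfig(seed=seed * 1000 + c))
        )
        res = enrichment_scan(signal, pool, instruments, cat,
                              n_iter=n_iter, seed=seed * 7919 + c)
        null = res.null_counts[pit_trait].to_numpy()
        obs = float(res.observed_counts[pit_trait])
        # randomized PIT: uniform under exchangeability despite discreteness
        greater = int((null > obs).sum())
        ties = int((null == obs).sum())
        pit.append((greater + rng.random() * (ties + 1)) / (n_iter + 1))
    ks = stats.kstest(np.asarray(pit), "uniform")

    planted_cfg = CatalogueConfig(
        seed=seed + 1, planted_traits=["height"], planted_mediators=signal
    )
    cat = TraitCatalogue(generate_catalogue(truth, planted_cfg))
    res = enrichment_scan(signal, pool, instruments, cat, n_iter=n_iter, seed=seed)
    return {
        "ks_pvalue": float(ks.pvalue),
        "ks_statistic": float(ks.statistic),
        "n_pit_values": len(pit),
        "planted_empirical_p": float(res.empirical_p["height"]),
        "min_possible_p": 1.0 / (n_iter + 1),
    }
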