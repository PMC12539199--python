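"""Synthetic GWAS study generator with a known mediation structure.

Simulates individual-level cohorts in which an adiposity-like exposure X
raises (or lowers) a panel of metabolite-like mediators M, which together
with a direct effect of X determine a binary disease outcome D on the
log-odds scale:

    X   = sum_j a_j G_j + confounding + noise          (standardized, SD units)
    M_m = gamma_m X + sum_j b_mj G'_mj + confounding + noise   (SD units)
    D   ~ Bernoulli(expit(alpha + tau_direct X + sum_m delta_m M_m
                          + pleiotropy + confounding))

Each GWAS "panel" (exposure, mediator, outcome, observational) is drawn from
a distinct random substream of one master seed, emulating non-overlapping
study samples; the genetic architecture (variants, allele codes, planted
effects) is shared across panels.  Cohorts are reduced to per-variant
summary statistics by plain linear or logistic regression, and the planted
effect sizes are recorded as ground truth for use as an estimation oracle.

Effects are all in SD units (traits are population-standardized by
construction) or log-odds per SD, so estimator output is directly
comparable with the recorded truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy import stats

from ._regression import per_variant_linear, per_variant_logistic
from .sumstats import VariantAssociation

__all__ = [
    "SimulationConfig",
    "CatalogueConfig",
    "SyntheticTruth",
    "Cohort",
    "StudyBundle",
    "simulate_cohort",
    "compute_sumstats",
    "generate_study",
    "generate_catalogue",
]

PANELS = {
    "exposure": 1,
    "mediator": 2,
    "outcome": 3,
    "observational": 4,
    "exposure_lowpower": 5,
}

EXPOSURE_ID = "adiposity"
OUTCOME_ID = "cancer_overall"
SUBTYPE_IDS = ("cancer_endometrioid", "cancer_non_endometrioid")

# Non-palindromic allele pairs only, so harmonization of generated studies is
# lossless; palindromic handling is exercised by hand-built fixtures.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


def _as_vector(value, n: int, name: str) -> np.ndarray:
    if value is None:
        raise ValueError(f"{name} must be set")
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(n, float(arr[0]))
    if arr.size != n:
        raise ValueError(f"{name} must have length n_mediators={n}, got {arr.size}")
    return arr


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic triangulation study.

    Defaults describe a well-powered two-sample design: 20,000 individuals
    per panel, 100 exposure instruments jointly explaining roughly 30% of
    exposure variance, 15 instruments per mediator explaining roughly 30% of
    each mediator's variance, and a 10% baseline outcome prevalence.
    ``gamma`` (X->M, SD/SD), ``delta`` (M->D, log-odds/SD) and ``tau_direct``
    (X->D, log-odds/SD) set the mediation structure; scalars broadcast over
    mediators.
    """

    seed: int = 0
    n_samples_per_panel: int = 20_000
    n_instruments_x: int = 100
    n_instruments_per_m: int = 15
    n_mediators: int = 3
    maf_range: tuple[float, float] = (0.1, 0.4)
    instrument_effect_scale: float = 0.09       # SD units per allele (exposure)
    mediator_instrument_scale: float = 0.24     # SD units per allele (mediators)
    instrument_effect_distribution: str = "uniform"  # magnitude law: uniform | fixed | normal
    gamma: float | Sequence[float] = 0.3        # X -> M, SD/SD
    delta: float | Sequence[float] = 0.2        # M -> D, log-odds/SD
    tau_direct: float = 0.1                     # X -> D, log-odds/SD
    invalid_fraction: float = 0.0
    pleiotropy_mean: float = 0.0                # log-odds per allele
    pleiotropy_sd: float = 0.0
    baseline_prevalence: float = 0.1
    confounder_effect_x: float = 0.3            # U -> X, SD units
    confounder_effect_m: float = 0.2            # U -> M, SD units
    confounder_effect_d: float = 0.3            # U -> D, log-odds
    age_effect_d: float = 0.03                  # per year, log-odds
    lowpower_fraction: float = 0.25             # n fraction for the low-powered exposure panel
    subtype_scales: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            # (delta scale, tau scale, prevalence scale)
            "cancer_endometrioid": (1.0, 1.0, 0.5),
            "cancer_non_endometrioid": (1.5, 1.5, 0.25),
        }
    )

    def __post_init__(self) -> None:
        self.gamma = _as_vector(self.gamma, self.n_mediators, "gamma")
        self.delta = _as_vector(self.delta, self.n_mediators, "delta")
        self.validate()

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.01 < lo < hi < 0.5):
            raise ValueError("maf_range must lie within (0.01, 0.5)")
        if self.n_samples_per_panel < 500:
            raise ValueError("n_samples_per_panel must be >= 500")
        for name in ("invalid_fraction", "baseline_prevalence", "lowpower_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("instrument_effect_scale", "mediator_instrument_scale",
                     "tau_direct", "pleiotropy_mean", "pleiotropy_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (np.all(np.isfinite(self.gamma)) and np.all(np.isfinite(self.delta))):
            raise ValueError("gamma and delta must be finite")
        if self.n_mediators < 0 or self.n_instruments_x < 1:
            raise ValueError("need >= 1 exposure instrument and >= 0 mediators")
        if self.instrument_effect_distribution not in ("uniform", "fixed", "normal"):
            raise ValueError(
                "instrument_effect_distribution must be 'uniform', 'fixed' or 'normal'"
            )

    @property
    def mediator_ids(self) -> list[str]:
        return [f"metabolite_{m + 1:03d}" for m in range(self.n_mediators)]


@dataclass
class SyntheticTruth:
    """Planted effect sizes: the acceptance oracle for the whole pipeline."""

    instrument_effects: dict[str, float]                 # per-allele effect on X, SD units
    mediator_instrument_effects: dict[str, dict[str, float]]
    gamma: np.ndarray
    delta: np.ndarray
    tau_direct: float
    tau_total: float
    pleiotropy: dict[str, float]                         # per-allele log-odds on D
    subtype_truth: dict[str, dict] = field(default_factory=dict)
    mediator_ids: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "instrument_effects": self.instrument_effects,
            "mediator_instrument_effects": self.mediator_instrument_effects,
            "gamma": list(map(float, self.gamma)),
            "delta": list(map(float, self.delta)),
            "tau_direct": self.tau_direct,
            "tau_total": self.tau_total,
            "pleiotropy": self.pleiotropy,
            "subtype_truth": self.subtype_truth,
            "mediator_ids": self.mediator_ids,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class Cohort:
    """One simulated panel: genotypes, measured traits, covariates."""

    panel: str
    genotypes: np.ndarray             # (n, V), values in {0, 1, 2}
    variants: pd.DataFrame            # variant_id, effect_allele, other_allele, maf
    phenotypes: pd.DataFrame
    measured: list[str]               # trait columns observable on this panel

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]


@dataclass
class StudyBundle:
    """All inputs to a triangulation run, plus ground truth."""

    exposures: dict[str, list[VariantAssociation]]
    exposures_lowpower: dict[str, list[VariantAssociation]]
    mediators: dict[str, list[VariantAssociation]]
    outcomes: dict[str, list[VariantAssociation]]
    cohort: pd.DataFrame | None
    truth: SyntheticTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# genetic architecture (shared across panels)


@dataclass
class _Genetics:
    variants: pd.DataFrame
    maf: np.ndarray
    a: np.ndarray                # (Jx,), per-allele effect on X
    b: np.ndarray                # (K, P) per-allele effects on each mediator
    pleio: np.ndarray            # (Jx,), per-allele log-odds on D
    x_slice: slice
    m_slices: list[slice]


def _draw_genetics(config: SimulationConfig) -> _Genetics:
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    jx, k, p = config.n_instruments_x, config.n_mediators, config.n_instruments_per_m
    V = jx + k * p
    maf = rng.uniform(*config.maf_range, size=V)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=V)
    ids, eas, oas = [], [], []
    for v in range(V):
        if v < jx:
            ids.append(f"rsX{v + 1:04d}")
        else:
            m, j = divmod(v - jx, p)
            ids.append(f"rsM{m + 1:03d}_{j + 1:03d}")
        ea, oa = _ALLELE_PAIRS[pair_idx[v]]
        eas.append(ea)
        oas.append(oa)
    variants = pd.DataFrame(
        {"variant_id": ids, "effect_allele": eas, "other_allele": oas, "maf": maf}
    )
    dist = config.instrument_effect_distribution
    if dist == "uniform":
        # magnitudes spread +/-50% around the scale: predictable instrument
        # strength with enough exposure-beta variation to identify an
        # Egger-type slope
        a = rng.uniform(0.5, 1.5, size=jx) * config.instrument_effect_scale
        a *= rng.choice([-1.0, 1.0], size=jx)
        b = rng.uniform(0.5, 1.5, size=(k, p)) * config.mediator_instrument_scale
        b *= rng.choice([-1.0, 1.0], size=(k, p))
    elif dist == "fixed":
        a = config.instrument_effect_scale * rng.choice([-1.0, 1.0], size=jx)
        b = config.mediator_instrument_scale * rng.choice([-1.0, 1.0], size=(k, p))
    else:
        a = rng.normal(0.0, config.instrument_effect_scale, size=jx)
        b = rng.normal(0.0, config.mediator_instrument_scale, size=(k, p))
    n_invalid = int(np.floor(config.invalid_fraction * jx + 0.5))
    invalid_idx = rng.choice(jx, size=n_invalid, replace=False) if n_invalid else np.array([], int)
    pleio = np.zeros(jx)
    if n_invalid:
        # directional pleiotropy is oriented to the exposure-raising allele,
        # so a positive mean biases ratio estimates upward
        draws = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n_invalid)
        pleio[invalid_idx] = np.sign(a[invalid_idx]) * draws
    m_slices = [slice(jx + m * p, jx + (m + 1) * p) for m in range(k)]
    return _Genetics(variants, maf, a, b, pleio, slice(0, jx), m_slices)


def _het(maf: np.ndarray) -> np.ndarray:
    return 2.0 * maf * (1.0 - maf)


def make_truth(config: SimulationConfig) -> SyntheticTruth:
    """Ground truth implied by the config (deterministic given the seed)."""
    g = _draw_genetics(config)
    tau_total = config.tau_direct + float(np.dot(config.gamma, config.delta))
    ids = g.variants["variant_id"].to_numpy()
    subtype = {}
    for name, (ds, ts, _ps) in config.subtype_scales.items():
        delta_s = config.delta * ds
        tau_s = config.tau_direct * ts
        subtype[name] = {
            "delta": list(map(float, delta_s)),
            "tau_direct": float(tau_s),
            "tau_total": float(tau_s + np.dot(config.gamma, delta_s)),
        }
    return SyntheticTruth(
        instrument_effects={ids[j]: float(g.a[j]) for j in range(config.n_instruments_x)},
        mediator_instrument_effects={
            mid: {ids[s][j]: float(g.b[m, j]) for j in range(config.n_instruments_per_m)}
            for m, (mid, s) in enumerate(zip(config.mediator_ids, g.m_slices))
        },
        gamma=np.array(config.gamma, dtype=float),
        delta=np.array(config.delta, dtype=float),
        tau_direct=float(config.tau_direct),
        tau_total=float(tau_total),
        pleiotropy={ids[j]: float(g.pleio[j]) for j in range(config.n_instruments_x)
                    if g.pleio[j] != 0.0},
        subtype_truth=subtype,
        mediator_ids=config.mediator_ids,
    )


def _solve_intercept(lp: np.ndarray, prevalence: float) -> float:
    def f(alpha: float) -> float:
        return float(np.mean(expit(alpha + lp)) - prevalence)

    lo, hi = -40.0, 40.0
    if f(lo) > 0 or f(hi) < 0:
        raise RuntimeError("prevalence solver failed to bracket the intercept")
    return float(brentq(f, lo, hi, xtol=1e-10))


def simulate_cohort(config: SimulationConfig, panel: str) -> Cohort:
    """Draw one panel's individual-level data.

    The genetic architecture is identical across panels; genotypes, noise
    and covariates come from a panel-specific substream, so panels behave as
    non-overlapping samples of the same population.  Two calls with the same
    seed and panel return identical cohorts.
    """
    if panel not in PANELS:
        raise ValueError(f"unknown panel {panel!r}; one of {sorted(PANELS)}")
    g = _draw_genetics(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(PANELS[panel],)))
    n = config.n_samples_per_panel
    if panel == "exposure_lowpower":
        n = max(500, int(n * config.lowpower_fraction))

    G = rng.binomial(2, g.maf, size=(n, len(g.maf))).astype(float)
    Gc = G - 2.0 * g.maf  # center at the population mean

    U = rng.normal(size=n)
    age = rng.normal(56.0, 8.0, size=n)
    centre = pd.Categorical.from_codes(rng.integers(0, 10, size=n),
                                       categories=[f"centre_{i:02d}" for i in range(10)])

    het = _het(g.maf)
    expl_x = float(np.sum(g.a**2 * het[g.x_slice]))
    var_budget_x = 1.0 - expl_x - config.confounder_effect_x**2
    if var_budget_x <= 0:
        raise ValueError("exposure variance budget exceeded; lower instrument_effect_scale")
    X = (
        Gc[:, g.x_slice] @ g.a
        + config.confounder_effect_x * U
        + rng.normal(scale=math.sqrt(var_budget_x), size=n)
    )

    M = np.empty((n, config.n_mediators))
    cu, cm = config.confounder_effect_x, config.confounder_effect_m
    for m in range(config.n_mediators):
        s = g.m_slices[m]
        expl_m = float(np.sum(g.b[m] ** 2 * het[s]))
        gamma_m = float(config.gamma[m])
        var_budget_m = 1.0 - gamma_m**2 - expl_m - cm**2 - 2.0 * gamma_m * cm * cu
        if var_budget_m <= 0:
            raise ValueError(f"mediator {m} variance budget exceeded")
        M[:, m] = (
            gamma_m * X
            + Gc[:, s] @ g.b[m]
            + cm * U
            + rng.normal(scale=math.sqrt(var_budget_m), size=n)
        )

    lp_shared = (
        config.tau_direct * X
        + M @ config.delta
        + Gc[:, g.x_slice] @ g.pleio
        + config.confounder_effect_d * U
        + config.age_effect_d * (age - 56.0)
    )
    alpha = _solve_intercept(lp_shared, config.baseline_prevalence)
    D = rng.binomial(1, expit(alpha + lp_shared))

    pheno = {EXPOSURE_ID: X}
    for m, mid in enumerate(config.mediator_ids):
        pheno[mid] = M[:, m]
    pheno[OUTCOME_ID] = D
    for name, (ds, ts, ps) in config.subtype_scales.items():
        lp_s = (
            ts * config.tau_direct * X
            + M @ (config.delta * ds)
            + Gc[:, g.x_slice] @ g.pleio
            + config.confounder_effect_d * U
            + config.age_effect_d * (age - 56.0)
        )
        alpha_s = _solve_intercept(lp_s, config.baseline_prevalence * ps)
        pheno[name] = rng.binomial(1, expit(alpha_s + lp_s))

    pheno["age"] = age
    pheno["centre"] = centre
    pheno["confounder"] = U

    if panel == "observational":
        # diagnosis ages: most cases are diagnosed after assessment
        # (incident); a quarter carry a pre-assessment (prevalent) record.
        diag = np.full(n, np.nan)
        cases = np.flatnonzero(D == 1)
        prevalent = rng.random(len(cases)) < 0.25
        diag[cases[~prevalent]] = age[cases[~prevalent]] + rng.uniform(1, 10, (~prevalent).sum())
        diag[cases[prevalent]] = np.maximum(
            age[cases[prevalent]] - rng.uniform(1, 5, prevalent.sum()), 20.0
        )
        pheno["age_at_assessment"] = age
        pheno["age_at_diagnosis"] = diag

    phenotypes = pd.DataFrame(pheno)
    measured = {
        "exposure": [EXPOSURE_ID],
        "exposure_lowpower": [EXPOSURE_ID],
        "mediator": list(config.mediator_ids),
        "outcome": [OUTCOME_ID, *config.subtype_scales],
        "observational": list(phenotypes.columns),
    }[panel]
    return Cohort(panel, G, g.variants, phenotypes, measured)


def compute_sumstats(cohort: Cohort, trait: str) -> list[VariantAssociation]:
    """Reduce a cohort to per-variant summary statistics for one trait.

    Continuous traits use per-variant simple linear regression; binary
    traits use per-variant logistic regression, giving betas on the
    log-odds scale.  The effect allele is the counted allele.  Monomorphic
    variants are emitted with beta 0 and infinite SE so downstream selection
    excludes them.
    """
    if trait not in cohort.measured:
        raise KeyError(f"trait {trait!r} not measured on panel {cohort.panel!r}")
    y = cohort.phenotypes[trait].to_numpy(dtype=float)
    values = set(np.unique(y))
    if values <= {0.0, 1.0}:
        beta, se = per_variant_logistic(cohort.genotypes, y)
    else:
        beta, se = per_variant_linear(cohort.genotypes, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(np.isfinite(se) & (se > 0), beta / se, 0.0)
    pval = 2 * stats.norm.sf(np.abs(z))
    pval = np.where(np.isfinite(se), np.clip(pval, np.nextafter(0, 1), 1.0), 1.0)
    eaf = cohort.genotypes.mean(axis=0) / 2.0
    eaf = np.clip(eaf, 1e-6, 1 - 1e-6)
    n = cohort.n
    records = []
    v = cohort.variants
    for j in range(len(v)):
        records.append(
            VariantAssociation(
                variant_id=v["variant_id"].iat[j],
                effect_allele=v["effect_allele"].iat[j],
                other_allele=v["other_allele"].iat[j],
                eaf=float(eaf[j]),
                beta=float(beta[j]),
                se=float(se[j]),
                pval=float(pval[j]),
                n=n,
                trait_id=trait,
            )
        )
    return records


def generate_study(config: SimulationConfig, include_lowpower: bool = True,
                   include_observational: bool = True) -> StudyBundle:
    """Generate a full study bundle from disjoint panels.

    Exposure, mediator and outcome summary statistics each come from their
    own panel; subtype outcomes are measured on the outcome panel with their
    own planted delta/tau scalings; the observational panel provides the
    individual-level cohort table.
    """
    exp_cohort = simulate_cohort(config, "exposure")
    exposures = {EXPOSURE_ID: compute_sumstats(exp_cohort, EXPOSURE_ID)}

    exposures_lowpower: dict[str, list[VariantAssociation]] = {}
    if include_lowpower:
        low_cohort = simulate_cohort(config, "exposure_lowpower")
        exposures_lowpower[EXPOSURE_ID] = compute_sumstats(low_cohort, EXPOSURE_ID)

    med_cohort = simulate_cohort(config, "mediator")
    mediators = {mid: compute_sumstats(med_cohort, mid) for mid in config.mediator_ids}

    out_cohort = simulate_cohort(config, "outcome")
    outcomes = {OUTCOME_ID: compute_sumstats(out_cohort, OUTCOME_ID)}
    for name in config.subtype_scales:
        outcomes[name] = compute_sumstats(out_cohort, name)

    cohort_df = None
    if include_observational:
        obs = simulate_cohort(config, "observational")
        cohort_df = obs.phenotypes.copy()

    return StudyBundle(
        exposures=exposures,
        exposures_lowpower=exposures_lowpower,
        mediators=mediators,
        outcomes=outcomes,
        cohort=cohort_df,
        truth=make_truth(config),
        config=config,
    )


# ---------------------------------------------------------------------------
# phenome catalogue


@dataclass
class CatalogueConfig:
    """Layout of the synthetic trait-association catalogue.

    ``traits`` maps trait name to domain.  Background associations are
    planted exchangeably: each (variant, trait) pair receives a row with
    probability ``background_assoc_prob`` and a p-value drawn log-uniformly
    over ``background_p_exponents`` decades, so sub-threshold background
    hits occur at the same rate for every metabolite's instruments.
    ``planted_mediators`` instruments additionally receive associations with
    every trait in ``planted_traits`` at ``planted_p``, far below any
    plausible threshold.
    """

    seed: int = 0
    traits: dict[str, str] = field(
        default_factory=lambda: {
            "height": "anthropometric",
            "body fat percentage": "anthropometric",
            "waist circumference": "anthropometric",
            "HDL cholesterol": "lipid",
            "LDL cholesterol": "lipid",
            "triglycerides": "lipid",
            "total cholesterol": "lipid",
            "apolipoprotein B": "lipid",
            "red blood cell count": "blood cell",
            "platelet count": "blood cell",
            "lymphocyte count": "blood cell",
            "mean corpuscular volume": "blood cell",
            "glucose": "glycaemic",
            "HbA1c": "glycaemic",
            "C-reactive protein": "inflammation",
        }
    )
    background_assoc_prob: float = 0.15
    background_p_exponents: tuple[float, float] = (-20.0, -1.0)
    planted_traits: list[str] = field(default_factory=list)
    planted_mediators: list[str] = field(default_factory=list)
    planted_p: float = 1e-30


def generate_catalogue(truth: SyntheticTruth, config: CatalogueConfig) -> pd.DataFrame:
    """Build a PhenoScanner-like lookup table for all study instruments.

    Returns a DataFrame with columns variant_id, trait, domain, pval and
    unique (variant, trait) pairs.  With no planted mediators the catalogue
    is background-only and exchangeable across metabolites.
    """
    rng = np.random.default_rng(config.seed)
    variant_ids = list(truth.instrument_effects)
    for mid in truth.mediator_ids:
        variant_ids.extend(truth.mediator_instrument_effects[mid])
    trait_names = list(config.traits)
    rows: dict[tuple[str, str], dict] = {}
    lo, hi = config.background_p_exponents
    for vid in variant_ids:
        hit = rng.random(len(trait_names)) < config.background_assoc_prob
        exponents = rng.uniform(lo, hi, size=len(trait_names))
        for t_idx in np.flatnonzero(hit):
            t = trait_names[t_idx]
            rows[(vid, t)] = {
                "variant_id": vid,
                "trait": t,
                "domain": config.traits[t],
                "pval": float(10.0 ** exponents[t_idx]),
            }
    for mid in config.planted_mediators:
        if mid not in truth.mediator_instrument_effects:
            raise KeyError(f"unknown mediator {mid!r} in planted_mediators")
        for vid in truth.mediator_instrument_effects[mid]:
            for t in config.planted_traits:
                rows[(vid, t)] = {
                    "variant_id": vid,
                    "trait": t,
                    "domain": config.traits.get(t, "planted"),
                    "pval": config.planted_p,
                }
    df = pd.DataFrame(
        list(rows.values()), columns=["variant_id", "trait", "domain", "pval"]
    )
    return df.sort_values(["variant_id", "trait"], ignore_index=True)
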