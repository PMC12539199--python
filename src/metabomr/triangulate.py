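"""Sequential mediation-screening pipeline (Parts I-IV).

Part I estimates the exposure's effect on each disease outcome (MR, with the
observational arm in parallel); exposures pass on IVW p < 0.05 with
sign-consistent sensitivity estimators.  Part II screens the exposure
against the mediator panel at a Bonferroni threshold.  Part III tests the
passing mediators against each outcome at uncorrected p < 0.05 under the
mediation direction rule (the product of the exposure->mediator and
mediator->outcome signs must match the exposure->outcome sign).  Part IV
fits a two-exposure multivariable MR per surviving mediator and reports the
attenuation of the exposure's direct effect.

Every entity entering a stage receives exactly one audited decision with a
reason code, and the stage pass-sets form a subset chain by construction,
asserted on every run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import observational as obs
from .mvmr import direct_effect_scan
from .sumstats import (
    EmptyInstrumentSetError,
    InstrumentSet,
    harmonize,
    select_instruments,
)
from .synthetic import StudyBundle
from .uvmr import MREstimate, ivw_mre, run_univariable, wald_ratio

__all__ = [
    "TriangulationConfig",
    "FilterDecision",
    "TriangulationReport",
    "part1_exposure_outcome",
    "part2_exposure_mediators",
    "part3_mediators_outcome",
    "part4_attenuation",
    "run_triangulation",
]

# reason codes
PASSED = "passed"
P_ABOVE_THRESHOLD = "p_above_threshold"
SIGN_DISCORDANT_METHODS = "sign_discordant_methods"
SIGN_DISCORDANT_ARMS = "sign_discordant_arms"
DIRECTION_INCONSISTENT = "direction_inconsistent_mediation"
INSUFFICIENT_INSTRUMENTS = "insufficient_instruments"


@dataclass
class TriangulationConfig:
    """Thresholds and options for one screening run.

    The shipped defaults are the screening rules used throughout: 0.05 at
    Part I, Bonferroni 0.05/(panel size) at Part II, uncorrected 0.05 at
    Part III; instruments at p < 5e-9 for the adiposity-like exposure and
    p < 5e-8 for metabolite-like mediators, clumped at r^2 < 0.001.
    """

    p_part1: float = 0.05
    part2_alpha: float = 0.05
    part2_panel_size: int | None = None   # None -> number of mediators tested
    p_part3: float = 0.05
    instrument_p_exposure: float = 5e-9
    instrument_p_mediator: float = 5e-8
    r2_threshold: float = 0.001
    n_boot: int = 1000
    seed: int = 0
    use_observational: bool = True
    covariates: tuple[str, ...] = ("age", "centre")

    def validate(self) -> None:
        for name in ("p_part1", "part2_alpha", "p_part3",
                     "instrument_p_exposure", "instrument_p_mediator", "r2_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        return d

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class FilterDecision:
    stage: str
    entity: str
    passed: bool
    reason_code: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TriangulationReport:
    part1: pd.DataFrame
    part2: pd.DataFrame
    part3: pd.DataFrame
    attenuation: pd.DataFrame
    decisions: list[FilterDecision]
    passes: dict[str, list[str]]
    provenance: dict

    def decisions_frame(self) -> pd.DataFrame:
        return pd.DataFrame([d.to_dict() for d in self.decisions])

    def validate_chain(self) -> None:
        """Assert part4 entities <= part3 passes <= part2 passes (by mediator)."""

        def mediators(stage: str) -> set[str]:
            return {e.split("|")[1] for e in self.passes.get(stage, []) if "|" in e}

        p2, p3, p4 = mediators("part2"), mediators("part3"), mediators("part4")
        if not p3 <= p2:
            raise AssertionError(f"part3 passes {p3 - p2} missing from part2")
        if not p4 <= p3:
            raise AssertionError(f"part4 entities {p4 - p3} missing from part3")

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "passes": self.passes,
            "decisions": [d.to_dict() for d in self.decisions],
            "part1": self.part1.to_dict(orient="records"),
            "part2": self.part2.to_dict(orient="records"),
            "part3": self.part3.to_dict(orient="records"),
            "attenuation": self.attenuation.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=1, sort_keys=True, default=str)

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self.part1.to_csv(out / "part1_estimates.tsv", sep="\t", index=False)
        self.part2.to_csv(out / "part2_estimates.tsv", sep="\t", index=False)
        self.part3.to_csv(out / "part3_estimates.tsv", sep="\t", index=False)
        self.attenuation.to_csv(out / "part4_attenuation.tsv", sep="\t", index=False)
        with open(out / "decisions.log", "w") as fh:
            for d in self.decisions:
                fh.write(f"{d.stage}\t{d.entity}\t{'PASS' if d.passed else 'FAIL'}\t{d.reason_code}\n")


def _signs_consistent(estimates: list[MREstimate]) -> bool:
    """All available sensitivity estimators share the IVW estimate's sign."""
    ivw = next(e for e in estimates if e.method in ("ivw_mre", "wald"))
    ref = np.sign(ivw.theta)
    return all(np.sign(e.theta) == ref for e in estimates)


def _estimate_pair(
    instruments: InstrumentSet,
    outcome_records,
    n_boot: int,
    seed: int,
):
    """Harmonize and run the dispatch; returns (estimates, harmonized)."""
    h = harmonize(instruments, outcome_records)
    return run_univariable(h, n_boot=n_boot, seed=seed), h


def _cohort_incident(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach incident-case status and drop prevalent cases."""
    df = cohort.copy()
    if "age_at_diagnosis" in df.columns:
        status = obs.define_incident_cases(df["age_at_assessment"], df["age_at_diagnosis"])
        df["status"] = status
        df = df[df["status"] != obs.PREVALENT].copy()
        df["incident"] = (df["status"] == obs.INCIDENT).astype(float)
    else:
        df["incident"] = df.iloc[:, 0] * np.nan
    return df


def part1_exposure_outcome(
    bundle: StudyBundle, config: TriangulationConfig
) -> tuple[pd.DataFrame, list[FilterDecision], dict[str, InstrumentSet]]:
    """MR of each exposure on each outcome, with the observational arm in parallel."""
    rows, decisions = [], []
    instrument_sets: dict[str, InstrumentSet] = {}
    cohort = None
    if config.use_observational and bundle.cohort is not None:
        cohort = _cohort_incident(bundle.cohort)
    for exp_id, exp_records in bundle.exposures.items():
        try:
            instruments = select_instruments(
                exp_records, config.instrument_p_exposure,
                r2_threshold=config.r2_threshold,
            )
        except EmptyInstrumentSetError:
            for out_id in bundle.outcomes:
                decisions.append(
                    FilterDecision("part1", f"{exp_id}|{out_id}", False, INSUFFICIENT_INSTRUMENTS)
                )
            continue
        instrument_sets[exp_id] = instruments
        for out_id, out_records in bundle.outcomes.items():
            entity = f"{exp_id}|{out_id}"
            try:
                estimates, _ = _estimate_pair(instruments, out_records, config.n_boot, config.seed)
            except EmptyInstrumentSetError:
                decisions.append(FilterDecision("part1", entity, False, INSUFFICIENT_INSTRUMENTS))
                continue
            for e in estimates:
                rows.append({**e.to_dict(or_scale=True), "arm": "mr", "mean_f": instruments.mean_f})
            ivw = estimates[0]
            if ivw.pval >= config.p_part1:
                decisions.append(FilterDecision("part1", entity, False, P_ABOVE_THRESHOLD))
            elif not _signs_consistent(estimates):
                decisions.append(FilterDecision("part1", entity, False, SIGN_DISCORDANT_METHODS))
            else:
                decisions.append(FilterDecision("part1", entity, True, PASSED))
            if cohort is not None and "incident" in cohort and out_id == list(bundle.outcomes)[0]:
                work = cohort.copy()
                work[exp_id] = obs.irnt(work[exp_id])
                res = obs.fit_logistic(
                    work, y="incident", x=exp_id,
                    covariates=list(config.covariates), model_tag="age_centre",
                )
                res.outcome = out_id
                rows.append(
                    {
                        "exposure": exp_id, "outcome": out_id, "method": "observational_logistic",
                        "theta": res.estimate, "se": res.se, "ci_low": res.ci_low,
                        "ci_high": res.ci_high, "pval": res.pval, "n_snp": None,
                        "odds_ratio": res.odds_ratio, "arm": "observational",
                    }
                )
    return pd.DataFrame(rows), decisions, instrument_sets


def part2_exposure_mediators(
    bundle: StudyBundle,
    config: TriangulationConfig,
    exposure_instruments: dict[str, InstrumentSet],
    passing_exposures: list[str],
) -> tuple[pd.DataFrame, list[FilterDecision], dict[str, MREstimate]]:
    """Exposure -> mediator screen at the Bonferroni discovery threshold."""
    rows, decisions = [], []
    estimates_by_entity: dict[str, MREstimate] = {}
    panel = config.part2_panel_size or len(bundle.mediators)
    threshold = config.part2_alpha / max(panel, 1)

    obs_scan = None
    if config.use_observational and bundle.cohort is not None:
        cohort = _cohort_incident(bundle.cohort)
        work = cohort.copy()
        for exp_id in passing_exposures:
            work[exp_id] = obs.irnt(work[exp_id])
        for mid in bundle.mediators:
            if mid in work:
                work[mid] = obs.irnt(work[mid])
        obs_scan = {
            exp_id: obs.metabolome_scan(
                work, exposure=exp_id,
                mediators=[m for m in bundle.mediators if m in work],
                covariates=list(config.covariates),
            ).set_index("mediator")
            for exp_id in passing_exposures
        }

    for exp_id in passing_exposures:
        instruments = exposure_instruments[exp_id]
        for mid, med_records in bundle.mediators.items():
            entity = f"{exp_id}|{mid}"
            try:
                h = harmonize(instruments, med_records)
                est = ivw_mre(h) if h.n_snp >= 2 else wald_ratio(
                    h.bx[0], h.bx_se[0], h.by[0], h.by_se[0]
                )
                est.exposure_id, est.outcome_id = exp_id, mid
            except (EmptyInstrumentSetError, ZeroDivisionError):
                decisions.append(FilterDecision("part2", entity, False, INSUFFICIENT_INSTRUMENTS))
                continue
            estimates_by_entity[entity] = est
            row = {**est.to_dict(), "arm": "mr", "threshold": threshold}
            obs_est = None
            if obs_scan is not None and mid in obs_scan[exp_id].index:
                obs_est = float(obs_scan[exp_id].loc[mid, "estimate"])
                row["observational_estimate"] = obs_est
                row["observational_pval"] = float(obs_scan[exp_id].loc[mid, "pval"])
            rows.append(row)
            if est.pval >= threshold:
                decisions.append(FilterDecision("part2", entity, False, P_ABOVE_THRESHOLD))
            elif obs_est is not None and np.sign(obs_est) != np.sign(est.theta):
                decisions.append(FilterDecision("part2", entity, False, SIGN_DISCORDANT_ARMS))
            else:
                decisions.append(FilterDecision("part2", entity, True, PASSED))
    return pd.DataFrame(rows), decisions, estimates_by_entity


def part3_mediators_outcome(
    bundle: StudyBundle,
    config: TriangulationConfig,
    part1_ivw: dict[str, MREstimate],
    part2_estimates: dict[str, MREstimate],
    part2_passes: list[str],
) -> tuple[pd.DataFrame, list[FilterDecision], dict[str, InstrumentSet]]:
    """Mediator -> outcome step under the mediation direction rule.

    Pass requires uncorrected p < 0.05 and the triple-sign rule:
    sign(exposure->mediator) * sign(mediator->outcome) must equal
    sign(exposure->outcome) for that outcome.
    """
    rows, decisions = [], []
    mediator_instruments: dict[str, InstrumentSet] = {}
    for entity in part2_passes:
        exp_id, mid = entity.split("|")
        gamma_hat = part2_estimates[entity].theta
        try:
            m_instruments = select_instruments(
                bundle.mediators[mid], config.instrument_p_mediator,
                r2_threshold=config.r2_threshold,
            )
            mediator_instruments[mid] = m_instruments
        except EmptyInstrumentSetError:
            for out_id in bundle.outcomes:
                decisions.append(
                    FilterDecision("part3", f"{exp_id}|{mid}|{out_id}", False,
                                   INSUFFICIENT_INSTRUMENTS)
                )
            continue
        for out_id, out_records in bundle.outcomes.items():
            entity3 = f"{exp_id}|{mid}|{out_id}"
            total_key = f"{exp_id}|{out_id}"
            if total_key not in part1_ivw:
                decisions.append(FilterDecision("part3", entity3, False, INSUFFICIENT_INSTRUMENTS))
                continue
            try:
                h = harmonize(m_instruments, out_records)
                est = ivw_mre(h) if h.n_snp >= 2 else wald_ratio(
                    h.bx[0], h.bx_se[0], h.by[0], h.by_se[0]
                )
                est.exposure_id, est.outcome_id = mid, out_id
            except (EmptyInstrumentSetError, ZeroDivisionError):
                decisions.append(FilterDecision("part3", entity3, False, INSUFFICIENT_INSTRUMENTS))
                continue
            rows.append({**est.to_dict(or_scale=True), "arm": "mr",
                         "mean_f": m_instruments.mean_f})
            total_sign = np.sign(part1_ivw[total_key].theta)
            if est.pval >= config.p_part3:
                decisions.append(FilterDecision("part3", entity3, False, P_ABOVE_THRESHOLD))
            elif np.sign(gamma_hat) * np.sign(est.theta) != total_sign:
                decisions.append(FilterDecision("part3", entity3, False, DIRECTION_INCONSISTENT))
            else:
                decisions.append(FilterDecision("part3", entity3, True, PASSED))
    return pd.DataFrame(rows), decisions, mediator_instruments


def part4_attenuation(
    bundle: StudyBundle,
    config: TriangulationConfig,
    part1_ivw: dict[str, MREstimate],
    part3_passes: list[str],
    mediator_instruments: dict[str, InstrumentSet],
) -> tuple[pd.DataFrame, list[FilterDecision]]:
    """Per-mediator MVMR of the exposure's direct effect, with attenuation."""
    rows, decisions = [], []
    # lower-powered exposure instruments protect mediator conditional strength
    by_outcome: dict[tuple[str, str], list[str]] = {}
    for entity in part3_passes:
        exp_id, mid, out_id = entity.split("|")
        by_outcome.setdefault((exp_id, out_id), []).append(mid)
    for (exp_id, out_id), mids in by_outcome.items():
        exp_records = (
            bundle.exposures_lowpower.get(exp_id) or bundle.exposures[exp_id]
        )
        try:
            exp_instruments = select_instruments(
                exp_records, config.instrument_p_exposure, r2_threshold=config.r2_threshold
            )
        except EmptyInstrumentSetError:
            # fall back to the main exposure GWAS instruments
            exp_instruments = select_instruments(
                bundle.exposures[exp_id], config.instrument_p_exposure,
                r2_threshold=config.r2_threshold,
            )
        mediators = {
            mid: (mediator_instruments[mid], bundle.mediators[mid]) for mid in mids
        }
        _, att_rows = direct_effect_scan(
            exp_instruments, exp_records, mediators, bundle.outcomes[out_id],
            theta_total=part1_ivw[f"{exp_id}|{out_id}"],
        )
        for r in att_rows:
            entity4 = f"{exp_id}|{r.mediator_id}|{out_id}"
            ok = r.flag is None or r.flag == "undefined_ratio"
            decisions.append(
                FilterDecision("part4", entity4, ok,
                               PASSED if ok else INSUFFICIENT_INSTRUMENTS)
            )
            rows.append({"exposure": exp_id, **r.to_dict()})
    return pd.DataFrame(rows), decisions


def run_triangulation(bundle: StudyBundle, config: TriangulationConfig | None = None) -> TriangulationReport:
    """Execute Parts I-IV in order with short-circuiting and a full audit trail.

    Deterministic given the bundle and config (all seeds live in the
    config); rerunning with the same inputs yields an identical report body.
    """
    config = config or TriangulationConfig()
    config.validate()
    empty = pd.DataFrame()

    part1_df, d1, exp_instruments = part1_exposure_outcome(bundle, config)
    decisions = list(d1)
    passes = {"part1": [d.entity for d in d1 if d.passed]}
    part1_ivw: dict[str, MREstimate] = {}
    if not part1_df.empty:
        for _, row in part1_df[(part1_df["arm"] == "mr")
                               & (part1_df["method"].isin(["ivw_mre", "wald"]))].iterrows():
            part1_ivw[f"{row['exposure']}|{row['outcome']}"] = MREstimate(
                method=row["method"], theta=row["theta"], se=row["se"],
                pval=row["pval"], n_snp=int(row["n_snp"]),
                exposure_id=row["exposure"], outcome_id=row["outcome"],
            )

    provenance = {
        "config": config.to_dict(),
        "config_digest": config.digest,
        "seed": config.seed,
        "n_mediators": len(bundle.mediators),
        "outcomes": list(bundle.outcomes),
    }

    passing_exposures = sorted({e.split("|")[0] for e in passes["part1"]})
    if not passing_exposures:
        provenance["short_circuit"] = "part1"
        report = TriangulationReport(part1_df, empty, empty, empty, decisions, passes, provenance)
        report.validate_chain()
        return report

    part2_df, d2, part2_estimates = part2_exposure_mediators(
        bundle, config, exp_instruments, passing_exposures
    )
    decisions += d2
    passes["part2"] = [d.entity for d in d2 if d.passed]
    if not passes["part2"]:
        provenance["short_circuit"] = "part2"
        report = TriangulationReport(part1_df, part2_df, empty, empty, decisions, passes, provenance)
        report.validate_chain()
        return report

    part3_df, d3, mediator_instruments = part3_mediators_outcome(
        bundle, config, part1_ivw, part2_estimates, passes["part2"]
    )
    decisions += d3
    passes["part3"] = [d.entity for d in d3 if d.passed]
    if not passes["part3"]:
        provenance["short_circuit"] = "part3"
        report = TriangulationReport(part1_df, part2_df, part3_df, empty, decisions, passes, provenance)
        report.validate_chain()
        return report

    att_df, d4 = part4_attenuation(
        bundle, config, part1_ivw, passes["part3"], mediator_instruments
    )
    decisions += d4
    passes["part4"] = [d.entity for d in d4 if d.passed]
    report = TriangulationReport(part1_df, part2_df, part3_df, att_df, decisions, passes, provenance)
    report.validate_chain()
    return report
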