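"""GWAS summary statistics: I/O, instrument selection, clumping and harmonization.

The atoms here are per-variant association records (beta, SE, p, effect
allele, frequency, N) for a single trait.  Instrument selection applies a
p-value threshold followed by greedy LD clumping; harmonization aligns an
exposure instrument set with outcome records on a shared effect allele,
which is what every MR estimator consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "InstrumentSet",
    "HarmonizedSet",
    "MVHarmonizedSet",
    "PalindromePolicy",
    "SumstatsError",
    "EmptyInstrumentSetError",
    "read_sumstats",
    "write_sumstats",
    "records_to_frame",
    "frame_to_records",
    "select_instruments",
    "harmonize",
    "harmonize_multi",
]

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical TSV column order
SUMSTATS_COLUMNS = [
    "variant_id", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n", "trait_id",
]


class SumstatsError(ValueError):
    """Malformed summary-statistics input."""


class EmptyInstrumentSetError(SumstatsError):
    """No variant survived selection or harmonization."""


@dataclass
class VariantAssociation:
    """One variant's summary statistics for one trait.

    ``beta`` is in SD units for continuous traits and log-odds for binary
    traits; ``se`` is on the same scale.  ``eaf`` is the effect-allele
    frequency and may be ``None`` when the source did not report it.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int
    trait_id: str

    def validate(self) -> None:
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise SumstatsError(
                f"{self.variant_id}: alleles must be single bases in ACGT "
                f"(got {self.effect_allele}/{self.other_allele}); indels and "
                "multi-allelic sites are not supported"
            )
        if self.effect_allele == self.other_allele:
            raise SumstatsError(f"{self.variant_id}: alleles must differ")
        if not math.isfinite(self.beta):
            raise SumstatsError(f"{self.variant_id}: non-finite beta")
        # se == inf flags a monomorphic variant; negative or zero is invalid
        if not self.se > 0:
            raise SumstatsError(f"{self.variant_id}: se must be > 0 (got {self.se})")
        if not (0 < self.pval <= 1):
            raise SumstatsError(f"{self.variant_id}: pval must be in (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise SumstatsError(f"{self.variant_id}: eaf must be in (0, 1) or missing")
        if self.n <= 0:
            raise SumstatsError(f"{self.variant_id}: n must be positive")

    @property
    def is_palindromic(self) -> bool:
        """A/T or G/C allele pairs are strand-ambiguous."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele

    @property
    def f_statistic(self) -> float:
        return (self.beta / self.se) ** 2


@dataclass
class InstrumentSet:
    """Selected, approximately independent instruments for one trait."""

    trait_id: str
    variants: list[VariantAssociation]
    p_threshold: float
    r2_threshold: float

    @property
    def mean_f(self) -> float:
        """Mean F-statistic (beta/se)^2 over retained instruments."""
        return float(np.mean([v.f_statistic for v in self.variants]))

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def __len__(self) -> int:
        return len(self.variants)


# Harmonization actions, one per input variant
KEPT = "kept"
FLIPPED = "flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_INCOMPATIBLE = "dropped_incompatible"
DROPPED_MISSING = "dropped_missing"


@dataclass
class PalindromePolicy:
    """How to treat strand-ambiguous (A/T, G/C) variants.

    ``drop_all`` discards every palindromic pair.  Otherwise a palindromic
    pair is dropped when either study's EAF is missing or falls inside the
    ambiguity window, and oriented by allele frequency when both EAFs are
    informative (same side of 0.5 -> same strand).
    """

    drop_all: bool = False
    eaf_window: tuple[float, float] = (0.42, 0.58)

    def ambiguous(self, eaf: float | None) -> bool:
        lo, hi = self.eaf_window
        return eaf is None or (lo < eaf < hi)


@dataclass
class HarmonizedSet:
    """Exposure/outcome betas aligned to shared effect alleles.

    Arrays are one entry per retained variant.  ``actions`` accounts for
    every input variant exactly once.
    """

    variant_ids: list[str]
    bx: np.ndarray
    bx_se: np.ndarray
    by: np.ndarray
    by_se: np.ndarray
    actions: dict[str, str]
    exposure_id: str = ""
    outcome_id: str = ""

    @property
    def n_snp(self) -> int:
        return len(self.variant_ids)

    def __post_init__(self) -> None:
        self.bx = np.asarray(self.bx, dtype=float)
        self.bx_se = np.asarray(self.bx_se, dtype=float)
        self.by = np.asarray(self.by, dtype=float)
        self.by_se = np.asarray(self.by_se, dtype=float)
        lens = {len(self.bx), len(self.bx_se), len(self.by), len(self.by_se), len(self.variant_ids)}
        if len(lens) != 1:
            raise ValueError("harmonized vectors must share one length")


@dataclass
class MVHarmonizedSet:
    """Multivariable variant: K exposure-beta columns aligned to one outcome."""

    variant_ids: list[str]
    exposure_ids: list[str]
    bx: np.ndarray       # (L, K)
    bx_se: np.ndarray    # (L, K)
    by: np.ndarray       # (L,)
    by_se: np.ndarray    # (L,)
    actions: dict[str, str] = field(default_factory=dict)

    @property
    def n_snp(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_ids)


# ---------------------------------------------------------------------------
# I/O


def records_to_frame(records: Iterable[VariantAssociation]) -> pd.DataFrame:
    rows = [
        {
            "variant_id": r.variant_id,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "eaf": np.nan if r.eaf is None else r.eaf,
            "beta": r.beta,
            "se": r.se,
            "pval": r.pval,
            "n": r.n,
            "trait_id": r.trait_id,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=SUMSTATS_COLUMNS)


def frame_to_records(df: pd.DataFrame, validate: bool = True) -> list[VariantAssociation]:
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        eaf = getattr(row, "eaf", np.nan)
        rec = VariantAssociation(
            variant_id=str(row.variant_id),
            effect_allele=str(row.effect_allele).upper(),
            other_allele=str(row.other_allele).upper(),
            eaf=None if pd.isna(eaf) else float(eaf),
            beta=float(row.beta),
            se=float(row.se),
            pval=float(row.pval),
            n=int(row.n),
            trait_id=str(row.trait_id),
        )
        if validate:
            try:
                rec.validate()
            except SumstatsError as exc:
                raise SumstatsError(f"row {i}: {exc}") from None
        records.append(rec)
    return records


def read_sumstats(path, column_map: Mapping[str, str] | None = None) -> list[VariantAssociation]:
    """Read a summary-statistics TSV into validated records.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    column_map
        Optional mapping from canonical field name to the file's column name
        (e.g. ``{"variant_id": "SNP"}``); unmapped fields use canonical names.

    Raises
    ------
    SumstatsError
        On a missing mandatory column, an unparseable numeric, a row
        violating field invariants (reported with its row number), or a
        duplicate variant id within the trait.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    colmap = dict(column_map or {})
    rename = {colmap.get(k, k): k for k in SUMSTATS_COLUMNS}
    df = df.rename(columns=rename)
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns and c != "eaf"]
    if missing:
        raise SumstatsError(f"{path}: missing mandatory column(s) {missing}")
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    for col in ("eaf", "beta", "se", "pval"):
        try:
            # astype(float) round-trips exactly; pd.to_numeric's parser does not
            df[col] = df[col].astype(float)
        except (ValueError, TypeError) as exc:
            raise SumstatsError(f"{path}: unparseable numeric in column {col}: {exc}") from None
    try:
        df["n"] = df["n"].astype(float).astype(int)
    except (ValueError, TypeError) as exc:
        raise SumstatsError(f"{path}: unparseable n: {exc}") from None
    records = frame_to_records(df[SUMSTATS_COLUMNS])
    seen: dict[tuple[str, str], int] = {}
    for i, rec in enumerate(records):
        key = (rec.trait_id, rec.variant_id)
        if key in seen:
            raise SumstatsError(
                f"{path}: duplicate variant_id {rec.variant_id} for trait "
                f"{rec.trait_id} (rows {seen[key]} and {i})"
            )
        seen[key] = i
    return records


def write_sumstats(records: Sequence[VariantAssociation], path) -> None:
    # shortest exact float representation, so write -> read round-trips
    records_to_frame(records).to_csv(
        path, sep="\t", index=False, float_format=lambda x: repr(float(x))
    )


# ---------------------------------------------------------------------------
# Instrument selection


def select_instruments(
    records: Sequence[VariantAssociation],
    p_threshold: float,
    ld_info: pd.DataFrame | str | None = "assume-independent",
    r2_threshold: float = 0.001,
    allow_empty: bool = False,
) -> InstrumentSet:
    """Select genome-wide significant instruments and greedily clump them.

    Clumping repeatedly takes the smallest-p unclaimed variant and discards
    all unclaimed variants with r^2 >= ``r2_threshold`` against it.  Ties at
    equal p break lexicographically by variant id for determinism.

    ``ld_info`` is either ``"assume-independent"`` (or ``None``: no variant
    pair is in LD) or a DataFrame with columns ``id_a``, ``id_b``, ``r2``.
    """
    if not records:
        raise EmptyInstrumentSetError("no input records")
    trait_id = records[0].trait_id
    candidates = [r for r in records if r.pval <= p_threshold and math.isfinite(r.se)]
    if not candidates:
        if allow_empty:
            return InstrumentSet(trait_id, [], p_threshold, r2_threshold)
        raise EmptyInstrumentSetError(
            f"{trait_id}: no variant passes p <= {p_threshold:g}"
        )

    ld: dict[str, set[str]] = {}
    if isinstance(ld_info, pd.DataFrame):
        strong = ld_info[ld_info["r2"] >= r2_threshold]
        for a, b in zip(strong["id_a"], strong["id_b"]):
            ld.setdefault(str(a), set()).add(str(b))
            ld.setdefault(str(b), set()).add(str(a))

    candidates.sort(key=lambda r: (r.pval, r.variant_id))
    retained: list[VariantAssociation] = []
    discarded: set[str] = set()
    for rec in candidates:
        if rec.variant_id in discarded:
            continue
        retained.append(rec)
        discarded |= ld.get(rec.variant_id, set())
    return InstrumentSet(trait_id, retained, p_threshold, r2_threshold)


# ---------------------------------------------------------------------------
# Harmonization


def _match_orientation(exp: VariantAssociation, out: VariantAssociation) -> str | None:
    """Return 'same', 'swapped' or None (incompatible), allowing strand flips.

    Palindromic pairs are resolved by the caller via allele frequency; for
    them a strand flip is indistinguishable from an allele swap so this
    function only reports the nominal orientation.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    oea, ooa = out.effect_allele, out.other_allele
    if (ea, oa) == (oea, ooa):
        return "same"
    if (ea, oa) == (ooa, oea):
        return "swapped"
    cea, coa = _COMPLEMENT[oea], _COMPLEMENT[ooa]
    if (ea, oa) == (cea, coa):
        return "same"
    if (ea, oa) == (coa, cea):
        return "swapped"
    return None


def _harmonize_pair(
    exp: VariantAssociation,
    out: VariantAssociation,
    policy: PalindromePolicy,
) -> tuple[str, float | None]:
    """Resolve one exposure/outcome pair to (action, aligned outcome beta)."""
    orientation = _match_orientation(exp, out)
    if orientation is None:
        return DROPPED_INCOMPATIBLE, None
    if exp.is_palindromic:
        if policy.drop_all or policy.ambiguous(exp.eaf) or policy.ambiguous(out.eaf):
            return DROPPED_PALINDROMIC, None
        # Frequencies on the same side of 0.5 imply the same counted allele.
        same_side = (exp.eaf - 0.5) * (out.eaf - 0.5) > 0
        return (KEPT, out.beta) if same_side else (FLIPPED, -out.beta)
    if orientation == "same":
        return KEPT, out.beta
    return FLIPPED, -out.beta


def harmonize(
    exposure: InstrumentSet,
    outcome_records: Sequence[VariantAssociation],
    palindrome_policy: PalindromePolicy | None = None,
    allow_empty: bool = False,
) -> HarmonizedSet:
    """Align outcome records to the exposure instruments' effect alleles.

    Same-allele pairs are kept; swapped pairs get the outcome beta
    sign-flipped; palindromic pairs follow ``palindrome_policy``;
    incompatible allele pairs and variants absent from the outcome are
    dropped with a per-variant reason (proxy lookup is out of scope).
    """
    policy = palindrome_policy or PalindromePolicy()
    by_id = {r.variant_id: r for r in outcome_records}
    ids, bx, bx_se, by, by_se = [], [], [], [], []
    actions: dict[str, str] = {}
    for exp in exposure.variants:
        out = by_id.get(exp.variant_id)
        if out is None:
            actions[exp.variant_id] = DROPPED_MISSING
            continue
        action, beta = _harmonize_pair(exp, out, policy)
        actions[exp.variant_id] = action
        if beta is None:
            continue
        ids.append(exp.variant_id)
        bx.append(exp.beta)
        bx_se.append(exp.se)
        by.append(beta)
        by_se.append(out.se)
    if not ids and not allow_empty:
        raise EmptyInstrumentSetError(
            f"no variant survived harmonization of {exposure.trait_id} "
            f"against {outcome_records[0].trait_id if outcome_records else '<empty>'}"
        )
    return HarmonizedSet(
        variant_ids=ids,
        bx=np.array(bx), bx_se=np.array(bx_se),
        by=np.array(by), by_se=np.array(by_se),
        actions=actions,
        exposure_id=exposure.trait_id,
        outcome_id=outcome_records[0].trait_id if outcome_records else "",
    )


def harmonize_multi(
    instrument_sets: Sequence[InstrumentSet],
    exposure_records: Mapping[str, Sequence[VariantAssociation]],
    outcome_records: Sequence[VariantAssociation],
    palindrome_policy: PalindromePolicy | None = None,
) -> MVHarmonizedSet:
    """Build the K-column exposure matrix for multivariable MR.

    The instrument list is the union of each exposure's selected instruments;
    a variant is retained only when it has a summary-statistics record in
    *every* exposure GWAS and in the outcome (intersection on availability —
    absent betas are never fabricated as zeros).  All betas are aligned to
    the first exposure GWAS's effect allele for each variant.
    """
    policy = palindrome_policy or PalindromePolicy()
    exposure_ids = [s.trait_id for s in instrument_sets]
    union_ids: list[str] = []
    seen: set[str] = set()
    for s in instrument_sets:
        for v in s.variants:
            if v.variant_id not in seen:
                seen.add(v.variant_id)
                union_ids.append(v.variant_id)

    lookups = {
        tid: {r.variant_id: r for r in exposure_records[tid]} for tid in exposure_ids
    }
    out_lookup = {r.variant_id: r for r in outcome_records}

    ids: list[str] = []
    bx_rows, bx_se_rows, by, by_se = [], [], [], []
    actions: dict[str, str] = {}
    for vid in union_ids:
        recs = [lookups[tid].get(vid) for tid in exposure_ids]
        out = out_lookup.get(vid)
        if any(r is None for r in recs) or out is None:
            actions[vid] = DROPPED_MISSING
            continue
        ref = recs[0]
        row_b, row_se = [ref.beta], [ref.se]
        ok = True
        for other in recs[1:]:
            action, beta = _harmonize_pair(ref, other, policy)
            if beta is None:
                actions[vid] = action
                ok = False
                break
            row_b.append(beta)
            row_se.append(other.se)
        if not ok:
            continue
        action, beta_out = _harmonize_pair(ref, out, policy)
        if beta_out is None:
            actions[vid] = action
            continue
        actions[vid] = action
        ids.append(vid)
        bx_rows.append(row_b)
        bx_se_rows.append(row_se)
        by.append(beta_out)
        by_se.append(out.se)
    if not ids:
        raise EmptyInstrumentSetError("no variant survived multivariable harmonization")
    return MVHarmonizedSet(
        variant_ids=ids,
        exposure_ids=exposure_ids,
        bx=np.array(bx_rows, dtype=float),
        bx_se=np.array(bx_se_rows, dtype=float),
        by=np.array(by, dtype=float),
        by_se=np.array(by_se, dtype=float),
        actions=actions,
    )
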