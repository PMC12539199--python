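"""Off-target phenome scan against a local trait-association catalogue.

Compares the catalogued trait-association profile of the instruments for
"signal" metabolites (those implicated as intermediates) with an iterated
null built by redrawing the same number of metabolites at random from the
non-implicated pool and pooling their instruments.  The redraw unit is the
metabolite — its whole instrument set moves together — which preserves the
per-metabolite correlation structure of instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitCatalogue",
    "EnrichmentResult",
    "count_associations",
    "enrichment_scan",
    "top_traits_report",
]


@dataclass
class TraitCatalogue:
    """Variant -> (trait, domain, p) lookup table.

    Wraps a DataFrame with columns variant_id, trait, domain, pval; the
    (variant, trait) pairs must be unique and p-values in (0, 1].
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"variant_id", "trait", "domain", "pval"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"catalogue missing column(s) {sorted(missing)}")
        p = self.table["pval"]
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("catalogue p-values must be in (0, 1]")
        if self.table.duplicated(["variant_id", "trait"]).any():
            raise ValueError("catalogue (variant, trait) pairs must be unique")

    @classmethod
    def read_tsv(cls, path) -> "TraitCatalogue":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def hits(self, p_threshold: float) -> pd.DataFrame:
        """Rows passing the strict p < threshold rule."""
        return self.table[self.table["pval"] < p_threshold]

    @property
    def traits(self) -> list[str]:
        return sorted(self.table["trait"].unique())

    @property
    def domains(self) -> dict[str, str]:
        return dict(zip(self.table["trait"], self.table["domain"]))


def count_associations(
    variant_ids: Sequence[str],
    catalogue: TraitCatalogue,
    p_threshold: float = 1e-10,
) -> tuple[pd.Series, pd.Series]:
    """Count instruments associated with each trait and domain.

    A variant counts once per trait when any catalogue row for that
    (variant, trait) has p strictly below the threshold; domain counts
    aggregate distinct variants over the domain's traits.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    if len(variant_ids) == 0:
        raise ValueError("empty instrument list")
    hits = catalogue.hits(p_threshold)
    hits = hits[hits["variant_id"].isin(set(variant_ids))]
    trait_counts = (
        hits.groupby("trait")["variant_id"].nunique()
        .reindex(catalogue.traits, fill_value=0)
    )
    domains = sorted(catalogue.table["domain"].unique())
    domain_counts = (
        hits.groupby("domain")["variant_id"].nunique()
        .reindex(domains, fill_value=0)
    )
    return trait_counts, domain_counts


@dataclass
class EnrichmentResult:
    """Observed vs redrawn-null association profiles."""

    traits: list[str]
    observed_counts: pd.Series
    observed_proportions: pd.Series
    null_counts: pd.DataFrame           # (n_iter, traits)
    null_mean: pd.Series
    null_sd: pd.Series
    null_mean_proportion: pd.Series
    empirical_p: pd.Series
    domain_observed: pd.Series
    domain_null_mean: pd.Series
    domain_empirical_p: pd.Series
    n_signal_instruments: int
    n_iter: int
    p_threshold: float
    signal_mediators: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": self.traits,
                "observed_count": self.observed_counts.values,
                "observed_proportion": self.observed_proportions.values,
                "null_mean": self.null_mean.values,
                "null_sd": self.null_sd.values,
                "null_mean_proportion": self.null_mean_proportion.values,
                "empirical_p": self.empirical_p.values,
            }
        )


def enrichment_scan(
    signal_mediators: Sequence[str],
    pool_mediators: Sequence[str],
    instruments_by_mediator: Mapping[str, Sequence[str]],
    catalogue: TraitCatalogue,
    p_threshold: float = 1e-10,
    n_iter: int = 100,
    seed: int = 0,
) -> EnrichmentResult:
    """Compare signal-metabolite instruments to an iterated random null.

    Each iteration draws ``len(signal_mediators)`` metabolites uniformly
    without replacement from the pool (disjoint from the signal set) and
    pools their instruments; per-trait empirical p is the add-one rank of
    the observed count within the null draws,
    ``(1 + #{null >= observed}) / (n_iter + 1)``.  Counts are reported
    alongside proportions of the instrument-set size, which absorb any
    instrument-count imbalance between draws.
    """
    signal = list(signal_mediators)
    pool = list(pool_mediators)
    if set(signal) & set(pool):
        raise ValueError("signal and pool mediator sets must be disjoint")
    if len(pool) < len(signal):
        raise ValueError("pool must be at least as large as the signal set")

    def pooled(mediators: Sequence[str]) -> list[str]:
        out: list[str] = []
        for m in mediators:
            out.extend(instruments_by_mediator[m])
        return out

    signal_instruments = pooled(signal)
    observed, domain_observed = count_associations(signal_instruments, catalogue, p_threshold)

    rng = np.random.default_rng(seed)
    traits = catalogue.traits
    domains = list(domain_observed.index)
    null = np.zeros((n_iter, len(traits)), dtype=int)
    null_dom = np.zeros((n_iter, len(domains)), dtype=int)
    null_sizes = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        draw = rng.choice(pool, size=len(signal), replace=False)
        instruments = pooled(draw)
        null_sizes[it] = len(instruments)
        tc, dc = count_associations(instruments, catalogue, p_threshold)
        null[it] = tc.values
        null_dom[it] = dc.values

    null_df = pd.DataFrame(null, columns=traits)
    emp_p = pd.Series(
        (1 + (null >= observed.values[None, :]).sum(axis=0)) / (n_iter + 1), index=traits
    )
    emp_p_dom = pd.Series(
        (1 + (null_dom >= domain_observed.values[None, :]).sum(axis=0)) / (n_iter + 1),
        index=domains,
    )
    null_props = null / null_sizes[:, None]
    return EnrichmentResult(
        traits=traits,
        observed_counts=observed,
        observed_proportions=observed / len(signal_instruments),
        null_counts=null_df,
        null_mean=null_df.mean(),
        null_sd=null_df.std(ddof=1),
        null_mean_proportion=pd.Series(null_props.mean(axis=0), index=traits),
        empirical_p=emp_p,
        domain_observed=domain_observed,
        domain_null_mean=pd.Series(null_dom.mean(axis=0), index=domains),
        domain_empirical_p=emp_p_dom,
        n_signal_instruments=len(signal_instruments),
        n_iter=n_iter,
        p_threshold=p_threshold,
        signal_mediators=signal,
    )


def top_traits_report(result: EnrichmentResult, k: int = 30) -> pd.DataFrame:
    """Traits ranked by observed-minus-null proportion excess.

    Ties break by empirical p (ascending), then trait name.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = result.to_frame()
    if df.empty:
        return df
    df["excess_proportion"] = df["observed_proportion"] - df["null_mean_proportion"]
    df = df.sort_values(
        ["excess_proportion", "empirical_p", "trait"],
        ascending=[False, True, True],
        ignore_index=True,
    )
    return df.head(k)
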