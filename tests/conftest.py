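import numpy as np
import pytest

from metabomr.sumstats import HarmonizedSet, VariantAssociation


def make_record(vid="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.01,
                pval=1e-10, n=10_000, trait="trait_a") -> VariantAssociation:
    return VariantAssociation(vid, ea, oa, eaf, beta, se, pval, n, trait)


def make_harmonized(bx, bx_se, by, by_se, exposure="x", outcome="y") -> HarmonizedSet:
    bx = np.asarray(bx, float)
    return HarmonizedSet(
        variant_ids=[f"rs{i}" for i in range(len(bx))],
        bx=bx, bx_se=np.asarray(bx_se, float),
        by=np.asarray(by, float), by_se=np.asarray(by_se, float),
        actions={f"rs{i}": "kept" for i in range(len(bx))},
        exposure_id=exposure, outcome_id=outcome,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


def random_harmonized(rng, n=8):
    bx = rng.normal(0.1, 0.03, n)
    bx = np.where(np.abs(bx) < 0.02, 0.05, bx)
    return make_harmonized(
        bx,
        rng.uniform(0.005, 0.02, n),
        0.4 * bx + rng.normal(0, 0.02, n),
        rng.uniform(0.01, 0.05, n),
    )
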