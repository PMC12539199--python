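"""Synthetic study generator: determinism, truth bookkeeping, effect recovery."""

import numpy as np
import pytest

from metabomr.sumstats import frame_to_records, records_to_frame
from metabomr.synthetic import (
    CatalogueConfig,
    SimulationConfig,
    compute_sumstats,
    generate_catalogue,
    generate_study,
    make_truth,
    simulate_cohort,
)


def small_config(**kw):
    base = dict(
        seed=5, n_samples_per_panel=2_000, n_instruments_x=20,
        n_instruments_per_m=6, n_mediators=2, subtype_scales={},
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_invalid_maf_range(self):
        with pytest.raises(ValueError):
            small_config(maf_range=(0.001, 0.4))

    def test_vector_length_enforced(self):
        with pytest.raises(ValueError):
            small_config(gamma=(0.1, 0.2, 0.3))

    def test_scalar_broadcast(self):
        cfg = small_config(gamma=0.25)
        assert np.allclose(cfg.gamma, [0.25, 0.25])


class TestTruth:
    def test_tau_total_identity(self):
        cfg = small_config(n_mediators=2, gamma=(0.3, 0.2), delta=(0.5, 0.1), tau_direct=0.1)
        truth = make_truth(cfg)
        assert truth.tau_total == 0.1 + 0.3 * 0.5 + 0.2 * 0.1  # exact bookkeeping
        assert truth.tau_total == truth.tau_direct + float(np.dot(truth.gamma, truth.delta))

    def test_invalid_fraction_bookkeeping(self):
        cfg = small_config(invalid_fraction=0.3, pleiotropy_mean=0.05, pleiotropy_sd=0.0)
        truth = make_truth(cfg)
        assert len(truth.pleiotropy) == int(np.floor(0.3 * 20 + 0.5))


class TestSimulateCohort:
    def test_determinism(self):
        cfg = small_config()
        a = simulate_cohort(cfg, "exposure")
        b = simulate_cohort(cfg, "exposure")
        assert np.array_equal(a.genotypes, b.genotypes)
        assert a.phenotypes.equals(b.phenotypes)

    def test_panels_disjoint_substreams(self):
        cfg = small_config()
        a = simulate_cohort(cfg, "exposure")
        b = simulate_cohort(cfg, "outcome")
        assert not np.array_equal(a.genotypes, b.genotypes)
        # but identical genetic architecture
        assert a.variants.equals(b.variants)

    def test_genotype_values_and_binary_outcome(self):
        cfg = small_config()
        c = simulate_cohort(cfg, "outcome")
        assert set(np.unique(c.genotypes)) <= {0.0, 1.0, 2.0}
        assert set(np.unique(c.phenotypes["cancer_overall"])) <= {0, 1}

    def test_global_null_no_association(self):
        cfg = SimulationConfig(
            seed=9, n_samples_per_panel=20_000, n_instruments_x=10,
            n_mediators=0, gamma=(), delta=(), tau_direct=0.0,
            invalid_fraction=0.0, subtype_scales={},
            confounder_effect_d=0.0, age_effect_d=0.0,
        )
        c = simulate_cohort(cfg, "observational")
        from metabomr.observational import fit_logistic

        res = fit_logistic(c.phenotypes, "cancer_overall", "adiposity")
        assert abs(res.estimate) < 3 * res.se

    def test_prevalence_targeted(self):
        cfg = small_config(baseline_prevalence=0.2, n_samples_per_panel=20_000)
        c = simulate_cohort(cfg, "outcome")
        assert c.phenotypes["cancer_overall"].mean() == pytest.approx(0.2, abs=0.02)


class TestComputeSumstats:
    def test_planted_effect_recovered(self):
        """Per-variant betas converge to planted per-allele effects."""
        cfg = SimulationConfig(
            seed=2, n_samples_per_panel=50_000, n_instruments_x=5,
            n_mediators=0, gamma=(), delta=(), subtype_scales={},
        )
        cohort = simulate_cohort(cfg, "exposure")
        truth = make_truth(cfg)
        records = {r.variant_id: r for r in compute_sumstats(cohort, "adiposity")}
        for vid, a in truth.instrument_effects.items():
            rec = records[vid]
            assert abs(rec.beta - a) < 4 * rec.se

    def test_permutation_invariance(self):
        cfg = small_config()
        cohort = simulate_cohort(cfg, "exposure")
        ref = compute_sumstats(cohort, "adiposity")
        perm = np.random.default_rng(0).permutation(cohort.n)
        cohort.genotypes = cohort.genotypes[perm]
        cohort.phenotypes = cohort.phenotypes.iloc[perm].reset_index(drop=True)
        after = compute_sumstats(cohort, "adiposity")
        for a, b in zip(ref, after):
            assert a.beta == pytest.approx(b.beta, rel=1e-9)
            assert a.se == pytest.approx(b.se, rel=1e-9)

    def test_zero_case_binary_trait_errors(self):
        cfg = small_config()
        cohort = simulate_cohort(cfg, "outcome")
        cohort.phenotypes["cancer_overall"] = 0
        with pytest.raises(ValueError):
            compute_sumstats(cohort, "cancer_overall")

    def test_unmeasured_trait_rejected(self):
        cfg = small_config()
        cohort = simulate_cohort(cfg, "exposure")
        with pytest.raises(KeyError):
            compute_sumstats(cohort, "cancer_overall")

    def test_monomorphic_flagged(self):
        cfg = small_config()
        cohort = simulate_cohort(cfg, "exposure")
        cohort.genotypes[:, 0] = 0.0
        rec = compute_sumstats(cohort, "adiposity")[0]
        assert rec.beta == 0.0 and rec.se == np.inf


class TestGenerateStudy:
    def test_round_trip_and_schema(self, tmp_path):
        cfg = small_config()
        bundle = generate_study(cfg)
        frame = records_to_frame(bundle.exposures["adiposity"])
        back = frame_to_records(frame)
        assert back == bundle.exposures["adiposity"]
        assert set(bundle.mediators) == {"metabolite_001", "metabolite_002"}
        assert "cancer_overall" in bundle.outcomes
        assert bundle.cohort is not None
        assert "age_at_diagnosis" in bundle.cohort

    def test_subtypes_present_with_own_truth(self):
        cfg = SimulationConfig(seed=5, n_samples_per_panel=2_000, n_instruments_x=20,
                               n_instruments_per_m=6, n_mediators=1)
        bundle = generate_study(cfg, include_lowpower=False, include_observational=False)
        assert set(bundle.outcomes) == {
            "cancer_overall", "cancer_endometrioid", "cancer_non_endometrioid"
        }
        sub = bundle.truth.subtype_truth["cancer_non_endometrioid"]
        assert sub["tau_total"] != bundle.truth.tau_total

    def test_seed_changes_betas_not_schema(self):
        a = generate_study(small_config(seed=1), include_lowpower=False,
                           include_observational=False)
        b = generate_study(small_config(seed=2), include_lowpower=False,
                           include_observational=False)
        assert [r.variant_id for r in a.exposures["adiposity"]] == [
            r.variant_id for r in b.exposures["adiposity"]
        ]
        assert any(
            x.beta != y.beta
            for x, y in zip(a.exposures["adiposity"], b.exposures["adiposity"])
        )


class TestCatalogue:
    def test_background_only_without_planting(self):
        truth = make_truth(small_config())
        cat = generate_catalogue(truth, CatalogueConfig(seed=0))
        assert (cat["pval"] > 1e-25).all()

    def test_planted_mediators_all_instruments_hit(self):
        truth = make_truth(small_config())
        cfg = CatalogueConfig(seed=0, planted_traits=["height"],
                              planted_mediators=["metabolite_001"])
        cat = generate_catalogue(truth, cfg)
        planted_variants = set(truth.mediator_instrument_effects["metabolite_001"])
        hits = cat[(cat["trait"] == "height") & (cat["pval"] < 1e-10)]
        assert planted_variants <= set(hits["variant_id"])

    def test_unique_pairs(self):
        truth = make_truth(small_config())
        cat = generate_catalogue(truth, CatalogueConfig(seed=3))
        assert not cat.duplicated(["variant_id", "trait"]).any()
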