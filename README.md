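# metabomr

Does excess adiposity raise cancer risk *through* the circulating
metabolome? `metabomr` is a toolkit for triangulating that question with
genetic and observational evidence: two-sample Mendelian randomization (MR)
of an adiposity-like exposure, a panel of metabolite-like mediators, and a
binary disease outcome; multivariable MR for direct-effect attenuation; a
parallel observational cohort arm; a four-part sequential mediation screen
with auditable filter decisions; and a phenome-catalogue scan for
off-target instrument effects. A synthetic study generator with recorded
ground truth makes the whole pipeline testable without restricted data.

It is aimed at genetic epidemiologists who want the screening logic of an
adiposity–metabolome–cancer analysis as reusable, tested code, and at
methodologists who want a bench for MR mediation estimators with known
truth.

## The statistics at the core

With harmonized per-variant summary statistics (exposure betas β̂ₓⱼ,
outcome betas β̂ᵧⱼ, SEs σⱼ), the univariable causal effect θ is estimated
by the Wald ratio (1 instrument), the inverse-variance-weighted
multiplicative random-effects model (IVW-MRE, ≥ 2),

    θ̂ = Σ wⱼ β̂ₓⱼ β̂ᵧⱼ / Σ wⱼ β̂ₓⱼ²,   wⱼ = 1/σᵧⱼ²,
    se(θ̂) = sqrt( (Q/(L−1)) / Σ wⱼ β̂ₓⱼ² ),   Q = Cochran's statistic,

and, with ≥ 3 instruments, by MR-Egger (free intercept = mean directional
pleiotropy), the weighted median and the weighted mode. Multivariable MR
regresses β̂ᵧ on K exposure-beta columns jointly (direct effects), with
per-exposure conditional F-statistics for instrument strength and the
adapted heterogeneity statistic Q_A whose weights absorb exposure-beta
uncertainty. The sequential screen passes an exposure at IVW p < 0.05 with
sign-consistent sensitivity estimators (Part I), mediators at Bonferroni
p < 0.05/panel (Part II) and uncorrected p < 0.05 with a triple-sign
mediation-direction rule (Part III), and reports the MVMR attenuation
1 − θ̂_direct/θ̂_total per mediator (Part IV). Details and conventions are
in [docs/methods.md](docs/methods.md).

## Worked example

Generate a synthetic study in which the exposure affects the outcome only
through the first of two mediators (γ₁ = 0.5 SD/SD, δ₁ = 0.8 log-odds/SD,
no direct effect, so the planted total effect is 0.4 log-odds per SD), then
estimate the exposure → outcome leg:

```python
from metabomr import (SimulationConfig, generate_study,
                      select_instruments, harmonize, UnivariableMR)

cfg = SimulationConfig(seed=29, n_samples_per_panel=20_000,
                       n_instruments_x=60, n_instruments_per_m=15,
                       n_mediators=2, gamma=(0.5, 0.0), delta=(0.8, 0.0),
                       tau_direct=0.0, subtype_scales={})
bundle = generate_study(cfg)                      # disjoint GWAS panels + truth
print(bundle.truth.tau_total)                     # 0.4

instruments = select_instruments(bundle.exposures["adiposity"], 5e-9)
h = harmonize(instruments, bundle.outcomes["cancer_overall"])
print(UnivariableMR(h, outcome_binary=True).fit(n_boot=200, seed=1).summary())
```

prints

```
Univariable two-sample MR
  exposure: adiposity   outcome: cancer_overall   n_snp: 48

method               theta        se                  ci95           p
ivw_mre             0.3507    0.0580      (0.2370, 0.4644)    1.49e-09
                  OR 1.420 (1.267, 1.591)
egger               0.6732    0.2917      (0.1015, 1.2449)       0.021
                  OR 1.961 (1.107, 3.473)
weighted_median     0.3357    0.0748      (0.1891, 0.4823)    7.18e-06
                  OR 1.399 (1.208, 1.620)
weighted_mode       0.0926    0.1755     (-0.2513, 0.4366)       0.598
                  OR 1.097 (0.778, 1.547)
  Egger intercept: -0.0353 (se 0.0313, p 0.259)
  Cochran Q: 59.67 (p 0.102)
```

Forty-eight of the 60 planted instruments survive selection at p < 5×10⁻⁹
(mean F ≈ 88). All four estimators agree in sign and the IVW estimate
(0.35, OR 1.42 per SD) sits below the planted 0.40 by the few percent of
non-collapsibility attenuation that marginal logistic GWAS betas carry; the
Egger intercept is compatible with zero, as it should be with no planted
pleiotropy. `run_triangulation(bundle)` runs the full four-part screen on
the same bundle and, here, carries exactly `metabolite_001` through every
stage, with an attenuation fraction of 0.89.

A command-line interface mirrors the library
(`metabomr simulate | mr | mvmr | triangulate | offtarget`).

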