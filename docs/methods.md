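# Methods

`metabomr` implements a triangulation design for asking whether circulating
metabolites mediate the effect of an adiposity trait on a binary cancer
outcome: two-sample Mendelian randomization (MR) for each leg of the
exposure → mediator → outcome path, a parallel observational cohort arm, a
sequential screening logic with explicit thresholds, multivariable MR (MVMR)
for direct-effect attenuation, and a phenome-catalogue scan for off-target
instrument effects. A synthetic study generator with recorded ground truth
makes every step testable end to end.

## Univariable two-sample MR

Given harmonized per-variant summary statistics — exposure betas
$\hat\beta_{Xj}$ with SEs $\sigma_{Xj}$ and outcome betas $\hat\beta_{Yj}$
with SEs $\sigma_{Yj}$ — the package provides five estimators of the causal
effect $\theta$:

- **Wald ratio** (single instrument): $\hat\theta = \hat\beta_Y/\hat\beta_X$
  with first-order SE $|\sigma_Y/\hat\beta_X|$. The second-order delta term
  is deliberately omitted; with the instrument-strength regimes the
  screening thresholds imply (F ≫ 10) it is negligible.
- **IVW-MRE** (≥ 2 instruments): weighted regression of $\hat\beta_Y$ on
  $\hat\beta_X$ through the origin with weights $1/\sigma_{Yj}^2$. The SE is
  multiplied by $\sqrt{Q/(L-1)}$ where $Q$ is Cochran's statistic — a pure
  multiplicative random-effects model with **no flooring**, so the SE can
  fall below the fixed-effect SE under light heterogeneity.
- **MR-Egger** (≥ 3): the same regression with a free intercept after
  orienting every pair so $\hat\beta_X \ge 0$; the intercept estimates mean
  directional pleiotropy. Here the residual scale **is floored at 1**
  (inflation-only). The asymmetric treatment of the two scales mirrors the
  dominant implementations of the two estimators and is pinned by tests.
- **Weighted median** (≥ 3): the inverse-variance-weighted median of the
  per-variant ratios, interpolated at standardized cumulative weight 0.5;
  consistent when ≥ 50% of weight comes from valid instruments.
- **Weighted mode** (≥ 3): the argmax of a normal-kernel density of the
  ratios with bandwidth $\phi \cdot 0.9\,\min(\mathrm{sd}_w,
  \mathrm{MAD}_w/0.6745)\, L^{-1/5}$ ($\phi = 1$ by default), located on a
  512-point grid padded three bandwidths beyond the ratio range.

Median and mode SEs come from a seeded parametric bootstrap (default 1,000
draws of $\hat\beta^*_X, \hat\beta^*_Y$ from their reported normal
sampling distributions). All p-values are two-sided normal — a deliberate
two-sample-MR convention, stated so tests are exact; for the IVW-MRE this
makes the null rejection rate behave like a $t_{L-1}$ statistic read off a
normal table, i.e. slightly above 5% at moderate L (measured ≈ 6% at L=50).

Dispatch in the screening pipeline: 1 instrument → Wald only; 2 → IVW-MRE
only; ≥ 3 → IVW-MRE plus all three sensitivity estimators.

## Multivariable MR

For K exposures jointly instrumented by L > K variants, the direct effects
are the coefficients of the weighted regression of $\hat\beta_Y$ on the K
exposure-beta columns through the origin (weights $1/\sigma_{Yj}^2$,
multiplicative residual scale, unfloored; K = 1 reduces exactly to IVW-MRE).
Diagnostics:

- **Conditional F** per exposure k: regress its beta column on the other
  columns with weights $1/\sigma_{X_k j}^2$; the weighted residual sum of
  squares over $(L-K+1)$. Summary-statistic covariances between exposures
  are set to zero throughout — the two-sample summary-data setting provides
  no phenotypic covariance — which is a documented limitation, not an
  estimate.
- **Q_A**: $\sum_j \hat w_j (\hat\beta_{Yj} - \sum_k \hat\theta_k
  \hat\beta_{X_k j})^2$ with $\hat w_j = 1/(\sigma_{Yj}^2 + \sum_k
  \hat\theta_k^2 \sigma_{X_k j}^2)$, evaluated **once** at the fitted
  coefficients (single pass, no iteration — the iterative variant exists in
  the literature but the single-pass form is deterministic and testable),
  referred to $\chi^2_{L-K}$.

The per-mediator scan fits one two-exposure MVMR (exposure + mediator) per
mediator over the union of both instrument sets, intersected on
availability: a variant enters only if it has records in both exposure GWAS
and the outcome; absent betas are never imputed as zeros. A deliberately
lower-powered exposure GWAS can supply the exposure instruments so that an
overwhelming exposure instrument count does not dilute the mediator's
conditional strength. The attenuation fraction is $1 -
\hat\theta_{direct}/\hat\theta_{total}$, suppressed with a flag when
$|\hat\theta_{total}| < 10^{-3}$ (the ratio is then meaningless).

## Harmonization and instrument selection

Instruments are variants below a p threshold (defaults: 5e-9 for the
adiposity-like exposure, 5e-8 for metabolites), greedily clumped: take the
smallest-p unclaimed variant, discard everything with r² ≥ 0.001 against it;
ties at equal p break lexicographically by id. Mean instrument strength is
reported as the mean of $(\hat\beta/\sigma)^2$.

Harmonization aligns outcome records to the exposure's effect allele,
allowing allele swaps (beta sign flip) and strand flips. Palindromic (A/T,
G/C) variants are dropped when either study's EAF is missing or inside
(0.42, 0.58), otherwise oriented by frequency; the window is configurable
because no universal convention exists. Unmatched variants are dropped and
logged — proxy lookup would require an external LD panel and is out of
scope. Indels and multi-allelic records are rejected at read time.

## Observational arm

Continuous traits are inverse-rank-normal transformed: average ranks for
ties, rank offset 0.5, $\Phi^{-1}((r_i - 0.5)/n)$; missing values stay
missing. Cases are incident only when attending age is **strictly** less
than diagnosis age (equal ages count as prevalent — the literal reading of
the rule — and prevalent cases are excluded everywhere). Associations are
estimated by OLS (continuous) or binomial-GLM IRLS (binary; tolerance 1e-8,
≤ 50 iterations, separation raises), complete-case per model, first
adjusted for age and centre and then fully adjusted. The discovery scan
(exposure → mediators) applies Bonferroni $0.05/\text{panel size}$; the
hypothesis-driven scan (mediator → outcome) applies uncorrected 0.05.

## Sequential screening (Parts I–IV)

1. **Part I** — exposure → outcome MR per outcome (overall + subtypes), the
   observational arm in parallel. Pass: IVW p < 0.05 **and** every
   available sensitivity estimator's point estimate shares the IVW sign.
   Sign agreement with no p-value requirement is the operationalization of
   "consistency" between estimators; a sensitivity estimator fluctuating
   around zero can therefore legitimately fail an otherwise clear signal —
   this conservatism is intentional.
2. **Part II** — exposure → each mediator; pass at Bonferroni
   p < 0.05/panel and, when a cohort is supplied, MR/observational sign
   agreement.
3. **Part III** — mediator → outcome at uncorrected p < 0.05 **and** the
   triple-sign mediation rule: sign(X→M)·sign(M→Y) must equal sign(X→Y),
   applied per outcome.
4. **Part IV** — per-mediator MVMR attenuation of the exposure's direct
   effect, with conditional F attached.

Every entity entering a stage receives exactly one decision with a reason
code; stage pass-sets form a subset chain asserted on every run. Reruns
with the same config are byte-identical.

## Off-target phenome scan (Part V)

Instruments of "signal" mediators are counted against a local variant →
(trait, domain, p) catalogue at strict p < 1e-10. The null redraws the same
**number of metabolites** (not SNPs — the whole instrument set moves with
its metabolite, preserving per-metabolite correlation structure) from the
non-implicated pool, 100 iterations by default. Empirical p uses the
add-one rule $(1 + \#\{null \ge obs\})/(n_{iter}+1)$, so it is never zero
and is super-uniform under exchangeability. Instrument-count imbalance
between draws is absorbed by reporting proportions alongside counts.
Because counts are discrete, the calibration benchmark tests uniformity of
the *randomized* PIT of the observed count within the null draws (the
continuous analogue of the empirical p); the empirical p itself is reported
unrandomized.

## Synthetic study generator

The generator emulates the data a triangulation study consumes:

    X    = Σ_j a_j G_j + c_U·U + ε,                   standardized
    M_m  = γ_m X + Σ_j b_mj G'_mj + c_M·U + ε_m,      standardized
    D    ~ Bernoulli(expit(α + τ_direct·X + Σ_m δ_m M_m + pleiotropy + c_D·U + age))

with genotypes Binomial(2, MAF), MAF ~ U(0.1, 0.4) by default, and the
intercept α solved by root-finding so the prevalence matches the target
(default 10%). Traits are population-standardized by construction (noise
variance is the residual of an explicit variance budget), so planted
effects are exactly in SD units and directly comparable to estimates;
`tau_total = tau_direct + Σ γ_m δ_m` holds as a bookkeeping identity.
Panels (exposure / mediator / outcome / observational / low-powered
exposure) share one genetic architecture but draw individuals from distinct
substreams of the master seed, emulating non-overlapping samples. Subtype
outcomes are generated on the outcome panel with their own δ/τ scalings and
lower prevalence. Summary statistics come from vectorised per-variant
regressions: closed-form simple linear regression for continuous traits and
batched Newton logistic regression for binary traits (betas on the log-odds
scale; monomorphic variants emitted with SE = ∞ and excluded downstream).

Default effect sizes are a design choice made once: instrument magnitudes
are uniform within ±50% of a scale chosen so the exposure's instruments
jointly explain ≈ 30% of its variance (0.09/allele with 100 instruments)
and each mediator's ≈ 30% (0.24/allele with 15). The spread matters:
identical magnitudes leave MR-Egger's slope unidentified, while a heavier-
tailed law makes selection yield unpredictable; ±50% keeps the weakest
instruments above the screening thresholds at the default panel sizes
while giving Egger a usable beta range. Directional pleiotropy is
oriented to the exposure-raising allele (otherwise random instrument signs
cancel it and IVW is not biased, which would make the robust-estimator
contract vacuous).

What the generator does *not* emulate: LD structure (instruments are
mutually independent; clumping is exercised through an explicit pair-r²
table), relatedness and mixed-model corrections, imputation quality,
allele-frequency spectra beyond the uniform MAF window, strand ambiguity
(generated alleles are non-palindromic by construction; palindromic logic
is tested on hand-built fixtures), and real registry coding. Passing tests
therefore demonstrate correctness of the estimators and screening logic
under clean identifying assumptions, not robustness to those real-data
complications.

Two properties of single-panel case-control GWAS are faithfully present
and worth knowing when reading benchmark output: (i) marginal logistic
betas are attenuated a few percent by non-collapsibility (the other
instruments' effects act as unmodelled outcome variance), so an IVW
estimate of a planted log-OR of 0.59 centres near 0.56; (ii) per-variant
estimates from one panel are mildly positively correlated under a strong
causal signal, so IVW SEs are a little optimistic when the instrument R²
is large. The recovery benchmark conditions (exposure GWAS n = 100,000,
case-control n = 10,000, per-instrument R² ≈ 0.13%/SNP) were chosen a
priori so these intrinsic effects stay within the tested tolerances; they
are properties of the estimator on realistic data, not of this
implementation.

## Benchmark problem sizes

The Monte-Carlo benchmarks (`metabomr.benchmarks`) run at: 1,000 null
replicates (50 instruments, n = 20,000/panel); 200 recovery replicates
(100 instruments, planted OR 1.8/SD); 200 pleiotropy replicates (30%
invalid, mean 0.08 log-odds/allele); 200 replicates per mediated
proportion {0, 0.5, 1} (τ_total = 0.4, γ = 0.5, n = 20,000/panel); 50
catalogue draws × 100 redraw iterations. The reproduction script
(`scripts/acceptance.py`) runs the same harnesses at moderately reduced
replicate counts so a full pass takes a few minutes on one CPU.

## Known limitations

- No proxy-SNP lookup, Steiger filtering, MR-PRESSO, contamination-mixture
  or radial variants; no MVMR-Egger/median.
- Exposure–exposure summary-statistic covariance assumed zero in MVMR.
- Attenuation is reported as a point fraction with component CIs; no
  product-method variance for the mediated proportion.
- The observational arm supports complete-case analysis only (no
  imputation), matching the varying per-model Ns such cohorts report.
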