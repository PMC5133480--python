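# Methods

## Joint model

The package models two adjusted quantitative phenotypes — systolic blood
pressure (SBP_adj, mmHg) and one expression trait (GE_adj) — jointly,
conditional on a single-variant dosage g ∈ {0, 1, 2}. The margins are
Gaussian linear regressions on dosage,

    SBP_adj = α0 + α1 g + ε,    ε  ~ N(0, σ1²),
    GE_adj  = β0 + β1 g + ε′,   ε′ ~ N(0, σ2²),

and the joint distribution couples them through a copula:
F(y1, y2 | g) = C_ψ(F1(y1|g), F2(y2|g)). The dependence parameters ψ do not
enter the margins, so α1 and β1 keep their marginal interpretation while the
joint likelihood shares information between the phenotypes. That sharing is
where the power gain over univariate OLS comes from: when the residual
dependence is appreciable, the observed information for α1 is larger and the
Wald statistic α̂1/SE(α̂1) more powerful, at identical point estimates on
average.

## The copula family

C_ψ is the two-parameter Archimedean (BB1) family with generator
g(t) = (t^−φ − 1)^θ, φ > 0, θ ≥ 1:

    C(u, v) = {[(u^−φ − 1)^θ + (v^−φ − 1)^θ]^(1/θ) + 1}^(−1/φ).

It contains Clayton (θ = 1) and Gumbel–Hougaard (φ → 0) and has both tail
coefficients free: λ_L = 2^(−1/(θφ)), λ_U = 2 − 2^(1/θ). The model-implied
Kendall's τ is 1 − 2/(θ(φ+2)); the implementation validates this closed
form against the integral definition τ = 4∬C dC − 1 (by Gauss–Legendre
quadrature of the equivalent identity τ = 1 − 4∬ C_u C_v) in the test suite
rather than assuming it.

The family only expresses positive association. Negative dependence is
handled by rotations: reflecting one argument (90°/270°, flipping the sign
of τ) or both (180°, the survival copula). Rotation is selected during
fitting from the sign of the residual empirical τ, with 90° vs 270° resolved
by maximized log-likelihood; 180° is available but not auto-selected, since
the unrotated family already covers positive dependence with both tail
orientations reachable through (φ, θ).

Numerics: the generator overflows double precision well inside the
parameter box, so the CDF, density (the analytic mixed partial ∂²C/∂u∂v)
and conditional CDF are all evaluated in log space via `log(expm1(·))` /
`logaddexp` identities. Pseudo-observations are clamped to
[1e−10, 1 − 1e−10] before density evaluation because residual-based inputs
can touch the boundary. The density algebra is unit-tested against a
finite-difference mixed partial of the CDF and against adaptive quadrature
of the density over the unit square.

## Estimation and inference

All eight parameters are estimated by joint maximum likelihood (not
two-stage IFM), initialized from OLS margins and a τ-inverted copula start.
The optimizer is bounded L-BFGS-B over
(α0, α1, log σ1, β0, β1, log σ2, log φ, log(θ − 1 + 10⁻⁶)) with
φ ∈ [10⁻⁴, 50], θ ∈ [1, 50] (covering |τ| up to ≈ 0.99), objective
tolerance 1e−8, at most 500 iterations, and three perturbed restarts on
failure. The θ start is floored at 1.05: exactly at θ = 1 the log(θ−1)
coordinate has a vanishing gradient and the optimizer could never leave the
Clayton slice.

Standard errors come from the inverse observed information, computed as a
central-difference Hessian (relative step 10⁻⁴) in the transformed space —
where the domain is a box and θ − h < 1 can never be evaluated — and mapped
to the natural scale by the delta method. If the Hessian is not positive
definite the covariance falls back to the outer product of per-observation
scores, and the fit is flagged. Fits with φ̂ or θ̂ at the box boundary are
flagged `boundary`; no profile correction is applied because the inferential
targets are α1 and β1, not ψ.

Wald tests use the standard-normal reference for the copula model and the
exact t(n−2) reference for univariate OLS; part of any power difference
between the two models is therefore the reference distribution itself, and
the rest is the SE. Model comparison uses AIC = 2k − 2ℓ with k = 8 (copula),
7 (bivariate normal) and 6 (working independence). With identical
regressors in both margin equations the bivariate-normal MLE of the
coefficients equals per-equation OLS with the residual moment matrix as the
error-covariance MLE, so that reference fit is closed-form.

## Phenotype adjustment

Antihypertensive treatment lowers observed SBP, so a treated individual's
measurement right-censors the true value. The adjustment fits a
right-censored Gaussian regression of observed SBP on age, sex and smoking
(medication is the censoring indicator, not a covariate): untreated
observations contribute the normal density, treated ones contribute
P(true > observed | covariates). σ is estimated on the log scale; the
quasi-Newton solution is polished with Newton steps on the analytic
gradient until the first-order condition holds to ≈ 1e−9. The adjusted SBP
is observed − fitted for the untreated, and for the treated the
truncated-normal mean E[true | true > observed] − fitted
= σ·φ(z)/(1 − Φ(z)), always positive, with the MLE σ̂ plugged in.
Expression traits are residualized by OLS on age, sex, smoking and
medication; constant covariate columns (e.g. nobody treated) are dropped
rather than left to break the rank check. Samples missing any of SBP,
covariates or expression are dropped before adjustment (complete-case).

Two regime caveats, measured in the test suite:

- The truncated-mean imputation uses only the bound information
  "true > observed". When medication effects are small and nearly
  homogeneous (reduction SD well below σ), the lowered observation itself
  still ranks individuals better than the imputation, and the naive
  residual beats the censored adjustment in correlation with the true
  residual and in MSE. With heterogeneous response (reduction SD on the
  order of σ) the censored adjustment wins on both, and it keeps the
  covariate coefficients essentially unbiased in every regime while plain
  OLS does not.
- Because treatment is assigned preferentially at high latent SBP and
  medication enters the expression regressions, the adjusted-scale
  dependence is attenuated relative to the latent copula (τ = 0.30 latent →
  ≈ 0.20 adjusted under the default generator). The null is exactly
  preserved — variant effects are tested, not τ — but effective dependence,
  and hence the copula model's power edge, is smaller than the nominal τ.

## Scan conventions

Dosage counts the in-sample minor allele per variant (flipping ALT counts
when ALT is the major allele), so effect signs refer to the minor allele and
MAF ≤ 0.5 by construction. Filters: biallelic, non-monomorphic in the
analysis sample (assessed after missingness handling), ≥ 3 minor-allele
copies (at n = 81 this implies MAF ≥ 3/162 ≈ 0.0185), and missing-call
fraction ≤ 20% (strict exclusion above). Gene windows are ±5 kb with
inclusive boundaries on 1-based coordinates; BED input (0-based half-open)
is normalized on load. Per pair, samples missing that variant's call are
dropped rather than imputed. BH adjustment is applied separately to the
four test families (copula/univariate × α1/β1), mirroring separately
reported columns rather than one pooled family. Per-pair failures are
logged and reported as NaN rows, never fatal to the scan. Q-Q series use
the (i − 0.5)/m plotting positions on the −log10 scale and are written as
TSV (no plot images; any plotting tool can consume the series).

## Synthetic-data generator

The generator encodes the study conditions the package targets, chosen once:

- n = 81 analysis samples (the WGS-complete subset size of the motivating
  cohort); MAF 0.2 for single-pair studies; genotypes Binomial(2, MAF)
  (Hardy–Weinberg), independent across variants (no LD).
- Covariates: age ~ U(30, 70), sex ~ Bernoulli(0.5), smoking ~
  Bernoulli(0.25). SBP covariate effects (120, 0.5, −3, 2) mmHg with
  σ1 = 15 mmHg; expression effects (0, 0.01, −0.2, 0.2, 0.1) with σ2 = 1
  on the normalized-expression scale.
- Residual dependence: (u1, u2) drawn from the copula by the
  conditional-distribution method — u2 inverts ∂C/∂u1 by 70 vectorized
  bisection iterations (final interval < 1e−20). Default target τ = 0.2,
  the magnitude at which the motivating analyses sit.
- Medication: treatment probability logistic in standardized latent SBP
  (slope 1.5) with marginal fraction 0.3; treated observed SBP is the true
  value minus a Gamma(2, 5) reduction (mean 10 mmHg, always positive, so
  observed < true holds by construction).
- Every stream (genotypes, covariates, copula draws, censoring) derives
  from one integer seed through named SeedSequence spawns; replicate
  studies use per-replicate children of the study seed.

The multi-gene fixture writer lays genes on 20 kb spans 100 kb apart,
draws variant positions within ±8 kb of each span (so some fall outside the
±5 kb windows), spans the allele-frequency spectrum including ALT-major
sites, and gives a ~5% subset of variants > 20% missingness — every filter
is exercised. Expression per gene is coupled to the shared SBP latent
through the conditional copula, making transcripts conditionally
independent given SBP.

What the generator does not emulate: linkage disequilibrium between
variants, pedigree/relatedness structure, non-Gaussian margins,
multi-visit phenotypes, and genotyping error beyond random missingness.
Passing tests therefore demonstrate the estimator's and pipeline's
correctness under the assumed structure, not robustness to those features.

## Study sizes used in the validation suite

Type-I error: 1000 null replicates of the full pipeline at n = 81, τ = 0.2,
checked against the 95% binomial band around 0.05. Parameter recovery:
200 replicates at n = 2000 (all eight parameters within 3 Monte-Carlo SEs).
Coverage: 500 replicates at n = 500, τ = 0.3 (94–95% observed). Power/SE
ordering: 500 replicates at n = 200 with α1 = 3.7 mmHg (≈ 50% univariate
power) at τ = 0.4 and τ = 0. AIC preference: 200 replicates at n = 500,
τ = 0.3. These sizes give Monte-Carlo error comfortably inside each check's
tolerance while keeping the suite quick on a single CPU.

## Known limitations

- Wald inference on ψ itself is not provided (and near the θ = 1 boundary
  would be irregular); only α1/β1 are inferential targets.
- The copula family is single-signed; rotation handles negative dependence
  globally but cannot express dependence whose sign varies across the
  distribution.
- The univariate reference df and the treated-fraction/reduction regime
  caveats above.
- Gene-based multimarker tests, relatedness correction and annotation
  retrieval are out of scope; annotations are a file input.
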