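"""Synthetic studies with the statistical structure the joint model assumes.

The generator emulates the kind of data the method targets: Hardy-Weinberg
genotypes, a latent systolic blood pressure and one expression trait per
gene coupled through the two-parameter copula on the residual scale,
non-genetic covariates (age, sex, smoking), medication assignment that is
more likely at high latent SBP, and a strictly positive treatment reduction
so a treated individual's observed SBP right-censors the true value.

Defaults mirror the study conditions of the motivating application: n = 81
analysis samples, SBP residual scale 15 mmHg, Kendall's tau around 0.2
between the adjusted phenotypes, 30% treated.

Two harnesses, :func:`type1_error_study` and :func:`power_study`, run the
full pipeline (simulate -> medication adjustment -> expression residuals ->
copula and univariate fits) over replicates to measure empirical rejection
rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .copula import CopulaParams, _base_conditional_cdf, apply_rotation, init_params_from_tau
from .model import FitOptions, fit_joint_copula, fit_reference_models, fit_univariate
from .phenotypes import (
    GE_COVARIATES,
    SBP_COVARIATES,
    adjust_expression,
    adjust_sbp,
    drop_constant_columns,
    fit_censored_regression,
    records_to_design,
)

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "Type1Result",
    "PowerResult",
    "simulate_genotypes",
    "sample_copula",
    "simulate_study",
    "adjust_simulated_study",
    "type1_error_study",
    "power_study",
    "simulate_scan_fixture",
    "write_vcf",
]

# fixed covariate effects of the generator (SBP on the mmHg scale)
SBP_EFFECTS = {"intercept": 120.0, "age": 0.5, "sex": -3.0, "smoking": 2.0}
GE_EFFECTS = {"intercept": 0.0, "age": 0.01, "sex": -0.2, "smoking": 0.2, "medication": 0.1}
# slope of the logistic treatment-assignment model in standardized latent SBP
TREATMENT_SLOPE = 1.5


@dataclass
class SimulationConfig:
    """Free quantities of one simulated study."""

    n: int = 81
    maf: float = 0.2
    alpha1: float = 0.0  # SNV effect on SBP, mmHg per minor-allele copy
    beta1: float = 0.0  # SNV effect on expression, units per copy
    sigma1: float = 15.0  # SBP residual SD, mmHg
    sigma2: float = 1.0  # expression residual SD
    tau: float = 0.2  # target Kendall's tau between the phenotype residuals
    copula: CopulaParams | None = None  # overrides tau when given
    treated_fraction: float = 0.3
    med_reduction_shape: float = 2.0  # Gamma reduction, mean shape*scale = 10 mmHg
    med_reduction_scale: float = 5.0
    missing_rate: float = 0.0
    replicates: int = 1000
    seed: int = 2025
    nominal_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if self.n < 10:
            raise ValueError("n must be at least 10")
        if not 0 <= self.treated_fraction < 1:
            raise ValueError("treated_fraction must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")

    def copula_params(self) -> CopulaParams:
        if self.copula is not None:
            return self.copula
        return init_params_from_tau(self.tau)


@dataclass
class SimulatedStudy:
    """One synthetic study with its generating truth retained."""

    pheno: pd.DataFrame  # sample_id, sbp, medication, age, sex, smoking
    expression: pd.DataFrame  # index sample_id, one column per transcript
    dosage: np.ndarray  # minor-allele dosage, NaN = missing
    true_sbp: np.ndarray
    truth: dict


@dataclass
class Type1Result:
    rates: dict
    band: tuple[float, float]
    nominal_alpha: float
    n_replicates: int
    n_effective: int


@dataclass
class PowerResult:
    power: dict
    mean_se: dict
    nominal_alpha: float
    n_replicates: int
    n_effective: int


def _rng(seed_or_rng):
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_genotypes(n, maf, missing_rate=0.0, seed=None):
    """Hardy-Weinberg minor-allele dosages, Binomial(2, maf), NaN = missing."""
    if not 0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5] (maf = 0 is monomorphic)")
    rng = _rng(seed)
    d = rng.binomial(2, maf, size=n).astype(float)
    if missing_rate > 0:
        d[rng.random(n) < missing_rate] = np.nan
    return d


def sample_copula(n, params: CopulaParams, seed=None):
    """Draw n pairs from the copula by the conditional-distribution method.

    u1 is uniform; u2 solves dC/du1(u1, u2) = p by bisection on the base
    copula (70 iterations, interval below 1e-20), then the rotation is
    applied to the pair.
    """
    rng = _rng(seed)
    u1 = rng.uniform(size=n)
    p = rng.uniform(size=n)
    lo = np.full(n, 1e-12)
    hi = np.full(n, 1.0 - 1e-12)
    for _ in range(70):
        mid = 0.5 * (lo + hi)
        h = _base_conditional_cdf(mid, u1, params.phi, params.theta)
        take_hi = h < p
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    u2 = 0.5 * (lo + hi)
    if not (np.all(np.isfinite(u2)) and np.all((u2 > 0) & (u2 < 1))):
        raise FloatingPointError("conditional inversion failed; check copula parameters")
    return apply_rotation(u1, u2, params.rotation)


def _simulate_covariates(n, rng):
    return pd.DataFrame({
        "age": rng.uniform(30.0, 70.0, n),
        "sex": rng.integers(0, 2, n),
        "smoking": (rng.random(n) < 0.25).astype(int),
    })


def simulate_study(config: SimulationConfig, seed=None) -> SimulatedStudy:
    """Generate one single-variant, single-gene study.

    Latent phenotypes: y1 = covariate effects + alpha1*g + sigma1*Phi^-1(u1)
    and analogously y2, with (u1, u2) drawn from the configured copula.
    Treatment probability is logistic in standardized latent SBP with the
    configured marginal fraction; treated individuals' observed SBP is the
    true value minus a Gamma-distributed positive reduction.
    """
    cfg = config
    if seed is None:
        root = np.random.SeedSequence(cfg.seed)
    elif isinstance(seed, np.random.SeedSequence):
        root = seed
    else:
        root = np.random.SeedSequence(seed)
    geno_rng, cov_rng, cop_rng, cens_rng = map(np.random.default_rng, root.spawn(4))
    n = cfg.n

    # redraw a by-chance-monomorphic genotype vector (relevant at tiny n*maf)
    for _ in range(100):
        dosage = simulate_genotypes(n, cfg.maf, cfg.missing_rate, geno_rng)
        obs = dosage[~np.isnan(dosage)]
        if obs.size >= 3 and np.unique(obs).size > 1:
            break
    cov = _simulate_covariates(n, cov_rng)
    params = cfg.copula_params()
    u1, u2 = sample_copula(n, params, cop_rng)

    from scipy.special import ndtri

    g_eff = np.nan_to_num(dosage, nan=0.0)  # missing calls do not alter the phenotype
    xb1 = (SBP_EFFECTS["intercept"] + SBP_EFFECTS["age"] * cov["age"].to_numpy()
           + SBP_EFFECTS["sex"] * cov["sex"].to_numpy()
           + SBP_EFFECTS["smoking"] * cov["smoking"].to_numpy())
    true_sbp = xb1 + cfg.alpha1 * g_eff + cfg.sigma1 * ndtri(u1)

    if cfg.treated_fraction > 0:
        z = (true_sbp - true_sbp.mean()) / max(true_sbp.std(), 1e-12)
        logit0 = math.log(cfg.treated_fraction / (1.0 - cfg.treated_fraction))
        p_treat = 1.0 / (1.0 + np.exp(-(logit0 + TREATMENT_SLOPE * z)))
        treated = (cens_rng.random(n) < p_treat).astype(int)
    else:
        treated = np.zeros(n, dtype=int)
    sbp_obs = true_sbp.copy()
    idx = treated == 1
    if idx.any():
        reduction = cens_rng.gamma(cfg.med_reduction_shape, cfg.med_reduction_scale,
                                   idx.sum())
        sbp_obs[idx] = true_sbp[idx] - reduction

    xb2 = (GE_EFFECTS["intercept"] + GE_EFFECTS["age"] * cov["age"].to_numpy()
           + GE_EFFECTS["sex"] * cov["sex"].to_numpy()
           + GE_EFFECTS["smoking"] * cov["smoking"].to_numpy()
           + GE_EFFECTS["medication"] * treated)
    ge = xb2 + cfg.beta1 * g_eff + cfg.sigma2 * ndtri(u2)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    pheno = pd.DataFrame({
        "sample_id": sample_ids, "sbp": sbp_obs, "medication": treated,
        "age": cov["age"], "sex": cov["sex"], "smoking": cov["smoking"],
    })
    expression = pd.DataFrame({"T_G1": ge}, index=pd.Index(sample_ids, name="sample_id"))
    truth = {
        "alpha1": cfg.alpha1, "beta1": cfg.beta1, "sigma1": cfg.sigma1,
        "sigma2": cfg.sigma2, "copula": params, "u1": u1, "u2": u2,
        "xb_sbp": xb1, "xb_ge": xb2,
    }
    return SimulatedStudy(pheno=pheno, expression=expression, dosage=dosage,
                          true_sbp=true_sbp, truth=truth)


def adjust_simulated_study(study: SimulatedStudy):
    """Run the medication/covariate adjustment pipeline on a simulated study.

    Returns (sbp_adj, ge_adj DataFrame, tobit fit), row-aligned with the
    study's samples.
    """
    pheno = study.pheno
    X_sbp = records_to_design(pheno, SBP_COVARIATES)
    treated = pheno["medication"].to_numpy()
    fit = fit_censored_regression(X_sbp, pheno["sbp"].to_numpy(), treated)
    sbp_adj = adjust_sbp(fit, X_sbp, pheno["sbp"].to_numpy(), treated)
    X_ge = drop_constant_columns(records_to_design(pheno, GE_COVARIATES))
    ge_adj = adjust_expression(study.expression.to_numpy(), X_ge)
    ge_adj = pd.DataFrame(ge_adj, index=study.expression.index,
                          columns=study.expression.columns)
    return sbp_adj, ge_adj, fit


def _binomial_band(alpha, replicates):
    half = 1.96 * math.sqrt(alpha * (1.0 - alpha) / replicates)
    return (alpha - half, alpha + half)


def _replicate_pvalues(cfg: SimulationConfig, child_seed):
    """One replicate of the full pipeline; returns p-values and SEs per model."""
    study = simulate_study(cfg, seed=child_seed)
    sbp_adj, ge_adj, _ = adjust_simulated_study(study)
    ok = ~np.isnan(study.dosage)
    g = study.dosage[ok]
    y1 = sbp_adj[ok]
    y2 = ge_adj.iloc[:, 0].to_numpy()[ok]
    uni1 = fit_univariate(y1, g)
    uni2 = fit_univariate(y2, g)
    jf = fit_joint_copula(y1, y2, g)
    if not jf.converged:
        return None
    return {
        "p_alpha1_copula": jf.wald_alpha1[1], "p_beta1_copula": jf.wald_beta1[1],
        "p_alpha1_univariate": uni1.p, "p_beta1_univariate": uni2.p,
        "se_alpha1_copula": jf.se_alpha1, "se_alpha1_univariate": uni1.se,
        "se_beta1_copula": jf.se_beta1, "se_beta1_univariate": uni2.se,
        "alpha1_copula": jf.margins.alpha1, "alpha1_univariate": uni1.slope,
    }


def type1_error_study(config: SimulationConfig) -> Type1Result:
    """Empirical type-I error of the copula and univariate Wald tests.

    Requires null effects in the config; runs ``replicates`` single-pair
    pipelines and reports rejection fractions at ``nominal_alpha`` together
    with the 95% binomial band around the nominal level.
    """
    if config.alpha1 != 0 or config.beta1 != 0:
        raise ValueError("type-I error study requires alpha1 = beta1 = 0")
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.replicates)
    results = [r for r in (_replicate_pvalues(config, c) for c in children)
               if r is not None]
    m = len(results)
    a = config.nominal_alpha
    rates = {}
    for key in ("p_alpha1_copula", "p_beta1_copula",
                "p_alpha1_univariate", "p_beta1_univariate"):
        rates[key.replace("p_", "")] = float(
            np.mean([r[key] < a for r in results])) if m else math.nan
    return Type1Result(rates=rates, band=_binomial_band(a, config.replicates),
                       nominal_alpha=a, n_replicates=config.replicates,
                       n_effective=m)


def power_study(config: SimulationConfig) -> PowerResult:
    """Empirical power and mean reported SEs under nonzero variant effects."""
    if config.alpha1 == 0 and config.beta1 == 0:
        raise ValueError("power study requires a nonzero alpha1 or beta1")
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.replicates)
    results = [r for r in (_replicate_pvalues(config, c) for c in children)
               if r is not None]
    m = len(results)
    a = config.nominal_alpha
    power = {}
    mean_se = {}
    for key in ("p_alpha1_copula", "p_beta1_copula",
                "p_alpha1_univariate", "p_beta1_univariate"):
        power[key.replace("p_", "")] = float(
            np.mean([r[key] < a for r in results])) if m else math.nan
    for key in ("se_alpha1_copula", "se_alpha1_univariate",
                "se_beta1_copula", "se_beta1_univariate"):
        mean_se[key] = float(np.mean([r[key] for r in results])) if m else math.nan
    return PowerResult(power=power, mean_se=mean_se, nominal_alpha=a,
                       n_replicates=config.replicates, n_effective=m)


# ---------------------------------------------------------------------------
# multi-gene scan fixtures


def write_vcf(path, chrom, positions, ids, alt_dosage, sample_ids):
    """Write a minimal VCFv4.2 with GT-only diploid genotypes.

    ``alt_dosage`` is (n_variants, n_samples) counting ALT alleles, NaN for
    missing calls.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in sample_ids) + "\n")
        for pos, vid, row in zip(positions, ids, alt_dosage):
            gts = "\t".join("./." if np.isnan(d) else gt_map[int(d)] for d in row)
            fh.write(f"{chrom}\t{int(pos)}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def simulate_scan_fixture(out_dir, n_genes=50, variants_per_gene=100, n=81,
                          tau=0.2, seed=2025, missing_high_fraction=0.05,
                          maf_range=(0.01, 0.5)):
    """Write a complete synthetic study (VCF + TSVs) consumable by the scan.

    Genes are laid out on chromosome 19-like coordinates with 20 kb spans;
    variant positions are drawn within +/- 8 kb of each span so that some
    fall outside the +/- 5 kb analysis windows.  A fraction of variants get
    heavy missingness (> 20%) and allele frequencies span the spectrum so
    every filter is exercised.  Expression for each gene is copula-coupled
    to the shared SBP latent via conditional sampling.  Returns the paths
    and the generating-truth table.
    """
    import os

    root = np.random.SeedSequence(seed)
    geno_rng, cov_rng, cop_rng, cens_rng = map(np.random.default_rng, root.spawn(4))
    sample_ids = [f"S{i:04d}" for i in range(n)]
    chrom = "19"

    cov = _simulate_covariates(n, cov_rng)
    params = init_params_from_tau(tau)
    from scipy.special import ndtri

    u1 = cop_rng.uniform(size=n)
    xb1 = (SBP_EFFECTS["intercept"] + SBP_EFFECTS["age"] * cov["age"].to_numpy()
           + SBP_EFFECTS["sex"] * cov["sex"].to_numpy()
           + SBP_EFFECTS["smoking"] * cov["smoking"].to_numpy())
    true_sbp = xb1 + 15.0 * ndtri(u1)
    z = (true_sbp - true_sbp.mean()) / true_sbp.std()
    p_treat = 1.0 / (1.0 + np.exp(-(math.log(0.3 / 0.7) + TREATMENT_SLOPE * z)))
    treated = (cens_rng.random(n) < p_treat).astype(int)
    sbp_obs = true_sbp.copy()
    if treated.any():
        sbp_obs[treated == 1] -= cens_rng.gamma(2.0, 5.0, int(treated.sum()))

    # expression per gene: u2 | u1 via conditional inversion, GE covariates added
    xb2 = (GE_EFFECTS["age"] * cov["age"].to_numpy()
           + GE_EFFECTS["sex"] * cov["sex"].to_numpy()
           + GE_EFFECTS["smoking"] * cov["smoking"].to_numpy()
           + GE_EFFECTS["medication"] * treated)
    expr = {}
    genes = []
    positions, vids, dosages, truth_rows = [], [], [], []
    span = 20_000
    gap = 100_000
    for j in range(n_genes):
        gene_id = f"G{j + 1}"
        start = 1_000_000 + j * gap
        end = start + span
        genes.append((chrom, start, end, gene_id, f"T_{gene_id}"))
        p = cop_rng.uniform(size=n)
        lo = np.full(n, 1e-12); hi = np.full(n, 1 - 1e-12)
        for _ in range(70):
            mid = 0.5 * (lo + hi)
            h = _base_conditional_cdf(mid, u1, params.phi, params.theta)
            lo = np.where(h < p, mid, lo)
            hi = np.where(h < p, hi, mid)
        u2 = 0.5 * (lo + hi)
        expr[f"T_{gene_id}"] = xb2 + 1.0 * ndtri(u2)

        for k in range(variants_per_gene):
            pos = int(geno_rng.integers(start - 8000, end + 8000 + 1))
            alt_freq = float(geno_rng.uniform(*maf_range))
            if geno_rng.random() < 0.5:  # sometimes ALT is the major allele
                alt_freq = 1.0 - alt_freq
            d = geno_rng.binomial(2, alt_freq, size=n).astype(float)
            miss = (missing_high_fraction and geno_rng.random() < missing_high_fraction)
            rate = geno_rng.uniform(0.21, 0.35) if miss else geno_rng.uniform(0.0, 0.15)
            d[geno_rng.random(n) < rate] = np.nan
            positions.append(pos)
            vids.append(f"v{j + 1}_{k + 1}")
            dosages.append(d)
            truth_rows.append({"variant_id": vids[-1], "chrom": chrom, "pos": pos,
                               "gene_id": gene_id, "alt_freq": alt_freq,
                               "missing_rate_drawn": rate})

    order = np.argsort(positions, kind="stable")
    positions = [positions[i] for i in order]
    vids = [vids[i] for i in order]
    dosages = [dosages[i] for i in order]

    os.makedirs(out_dir, exist_ok=True)
    vcf_path = os.path.join(out_dir, "study.vcf")
    write_vcf(vcf_path, chrom, positions, vids, np.array(dosages), sample_ids)
    pheno = pd.DataFrame({"sample_id": sample_ids, "sbp": sbp_obs,
                          "medication": treated, "age": cov["age"],
                          "sex": cov["sex"], "smoking": cov["smoking"]})
    pheno_path = os.path.join(out_dir, "phenotypes.tsv")
    pheno.to_csv(pheno_path, sep="\t", index=False)
    expr_df = pd.DataFrame(expr, index=pd.Index(sample_ids, name="sample_id"))
    expr_path = os.path.join(out_dir, "expression.tsv")
    expr_df.to_csv(expr_path, sep="\t")
    genes_df = pd.DataFrame(genes, columns=["chrom", "start", "end", "gene_id",
                                            "transcript_id"])
    genes_path = os.path.join(out_dir, "genes.tsv")
    genes_df.to_csv(genes_path, sep="\t", index=False)
    truth = pd.DataFrame(truth_rows)
    truth_path = os.path.join(out_dir, "truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)
    return {"vcf": vcf_path, "phenotypes": pheno_path, "expression": expr_path,
            "genes": genes_path, "truth": truth_path}
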