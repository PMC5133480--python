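"""Genome scan: variant loading, filtering, gene windows, per-pair model fits.

The scan pairs every retained variant with every gene whose +/- 5 kb window
(inclusive) contains it, fits the joint copula model and the univariate,
working-independence and bivariate-normal references for each (variant,
gene) pair, and reports Wald p-values with Benjamini-Hochberg adjustment
applied separately per test family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .model import (
    FitOptions,
    empirical_kendall_tau,
    fit_joint_copula,
    fit_reference_models,
    fit_univariate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "GeneAnnotation",
    "StudyData",
    "ScanConfig",
    "ScanResult",
    "load_genotype_dosages",
    "load_gene_annotations",
    "variant_from_dosage",
    "filter_variants",
    "map_variants_to_genes",
    "run_scan",
    "bh_adjust",
    "qq_points",
]


@dataclass
class VariantRecord:
    """One variant with minor-allele dosages for the analysis sample.

    ``dosage`` counts copies of the in-sample minor allele (NaN = missing
    call), so ``maf <= 0.5`` by construction and the sign of a fitted effect
    refers to the minor allele.
    """

    chrom: str
    pos: int
    id: str
    dosage: np.ndarray
    maf: float
    n_minor_copies: int
    missing_fraction: float
    biallelic: bool = True


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene span (1-based, inclusive) and the expression column it maps to."""

    chrom: str
    start: int
    end: int
    gene_id: str
    transcript_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass
class StudyData:
    """Aligned inputs for one scan."""

    sample_ids: list[str]
    variants: list[VariantRecord]
    genes: list[GeneAnnotation]
    sbp_adj: np.ndarray
    ge_adj: pd.DataFrame  # samples x transcripts, index aligned to sample_ids


@dataclass
class ScanConfig:
    window_bp: int = 5000
    min_copies: int = 3
    max_missing: float = 0.20
    alpha: float = 0.05
    n_min: int = 20
    fit_options: FitOptions = field(default_factory=FitOptions)


@dataclass
class ScanResult:
    """Per-(variant, gene) association table plus filter bookkeeping."""

    table: pd.DataFrame
    n_variants_input: int
    n_variants_kept: int
    n_pairs: int


def variant_from_dosage(chrom, pos, vid, dosage, biallelic=True) -> VariantRecord:
    """Build a VariantRecord from a counted-allele dosage vector.

    Flips to the minor allele if the counted allele has frequency > 0.5.
    """
    d = np.asarray(dosage, dtype=float)
    obs = ~np.isnan(d)
    n_obs = int(obs.sum())
    if n_obs > 0:
        freq = float(np.nansum(d) / (2.0 * n_obs))
        if freq > 0.5:
            d = np.where(obs, 2.0 - d, np.nan)
            freq = 1.0 - freq
    else:
        freq = 0.0
    return VariantRecord(
        chrom=str(chrom), pos=int(pos), id=str(vid), dosage=d,
        maf=freq, n_minor_copies=int(np.nansum(d)),
        missing_fraction=1.0 - n_obs / d.size, biallelic=biallelic,
    )


def load_genotype_dosages(vcf_path, sample_ids) -> list[VariantRecord]:
    """Read diploid genotypes from a VCF into minor-allele dosage records.

    Missing calls are preserved as NaN.  Multiallelic records are kept but
    flagged ``biallelic=False`` (counting the first ALT) so that
    :func:`filter_variants` can drop them.  Requested samples absent from the
    VCF raise with the missing names listed.
    """
    from cyvcf2 import VCF

    sample_ids = [str(s) for s in sample_ids]
    vcf = VCF(str(vcf_path))
    absent = [s for s in sample_ids if s not in vcf.samples]
    if absent:
        raise ValueError(f"samples not present in VCF: {absent}")
    vcf.set_samples(sample_ids)
    order = [vcf.samples.index(s) for s in sample_ids]

    records = []
    n_malformed = 0
    for v in vcf:
        try:
            gts = v.genotypes
            raw = np.full(len(gts), np.nan)
            for i, gt in enumerate(gts):
                a, b = gt[0], gt[1]
                if a >= 0 and b >= 0:
                    # counts ALT alleles; collapses any non-first ALT of a
                    # multiallelic record (those are filtered out anyway)
                    raw[i] = float(min(a, 1) + min(b, 1))
            raw = raw[order]
            records.append(
                variant_from_dosage(v.CHROM, v.POS, v.ID or f"{v.CHROM}:{v.POS}",
                                    raw, biallelic=(len(v.ALT) == 1))
            )
        except Exception:  # pragma: no cover - defensive
            n_malformed += 1
            logger.warning("skipping malformed VCF record near %s:%s", v.CHROM, v.POS)
    if n_malformed:
        logger.warning("skipped %d malformed VCF records", n_malformed)
    return records


def load_gene_annotations(path) -> list[GeneAnnotation]:
    """Gene annotation table.

    TSV with header (chrom, start, end, gene_id, transcript_id) is read as
    1-based inclusive; a ``.bed`` file (0-based half-open, columns chrom,
    start, end, gene_id, score, strand, transcript_id or gene_id reused) is
    normalized to 1-based inclusive.
    """
    path = str(path)
    if path.endswith(".bed"):
        df = pd.read_csv(path, sep="\t", header=None)
        genes = []
        for row in df.itertuples(index=False):
            gene_id = str(row[3])
            transcript = str(row[6]) if len(row) > 6 else gene_id
            genes.append(GeneAnnotation(chrom=str(row[0]), start=int(row[1]) + 1,
                                        end=int(row[2]), gene_id=gene_id,
                                        transcript_id=transcript))
        return genes
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "gene_id", "transcript_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene annotation table is missing columns: {sorted(missing)}")
    return [
        GeneAnnotation(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
                       gene_id=str(r.gene_id), transcript_id=str(r.transcript_id))
        for r in df.itertuples(index=False)
    ]


def filter_variants(variants, n_samples=None, min_copies=3, max_missing=0.20):
    """Apply the scan's variant filters.

    Keeps biallelic, non-monomorphic variants with at least ``min_copies``
    copies of the minor allele and a missing-call fraction of at most
    ``max_missing`` (strict exclusion above the threshold).  The filters
    commute; counts are logged.
    """
    kept = []
    for v in variants:
        if not v.biallelic:
            continue
        if v.missing_fraction > max_missing + 1e-12:
            continue
        obs = v.dosage[~np.isnan(v.dosage)]
        if obs.size == 0 or np.unique(obs).size < 2:
            continue
        if v.n_minor_copies < min_copies:
            continue
        kept.append(v)
    logger.info("filter_variants: kept %d of %d variants", len(kept), len(variants))
    return kept


def map_variants_to_genes(variants, genes, window_bp=5000):
    """(variant, gene) pairs with the variant inside the gene's +/- window.

    Boundaries are inclusive: a variant exactly ``window_bp`` past the gene
    end is paired.  A variant may pair with several overlapping or nearby
    genes.
    """
    pairs = []
    for g in genes:
        lo = g.start - window_bp
        hi = g.end + window_bp
        for v in variants:
            if v.chrom == g.chrom and lo <= v.pos <= hi:
                pairs.append((v, g))
    return pairs


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def qq_points(pvalues):
    """Expected and observed -log10 p-value series for a uniform Q-Q plot.

    Expected values use the plotting positions (i - 0.5)/m; both series are
    returned in increasing order.  Zero p-values are clamped to the smallest
    positive double with a warning.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-values of exactly 0 clamped for the -log10 scale")
        p = np.maximum(p, np.finfo(float).tiny)
    m = p.size
    observed = np.sort(-np.log10(p))
    expected = np.sort(-np.log10((np.arange(1, m + 1) - 0.5) / m))
    return expected, observed


def run_scan(study: StudyData, config: ScanConfig | None = None) -> ScanResult:
    """Fit all models for every mapped (variant, gene) pair.

    Per pair, samples with a missing call at the variant are dropped
    (complete-case); monomorphic-after-missingness and too-small pairs are
    reported with NaN results and a convergence flag, never fatally.  BH
    adjustment is applied separately to the four test families
    (copula/univariate x alpha1/beta1).
    """
    config = config or ScanConfig()
    kept = filter_variants(study.variants, len(study.sample_ids),
                           config.min_copies, config.max_missing)
    pairs = map_variants_to_genes(kept, study.genes, config.window_bp)
    logger.info("run_scan: %d pairs from %d kept variants x %d genes",
                len(pairs), len(kept), len(study.genes))

    rows = []
    for v, g in pairs:
        row = {
            "variant_id": v.id, "chrom": v.chrom, "pos": v.pos, "maf": v.maf,
            "gene_id": g.gene_id, "transcript_id": g.transcript_id,
            "n_used": np.nan, "converged": False, "boundary": False,
            "alpha1_copula": np.nan, "se_alpha1_copula": np.nan, "p_alpha1_copula": np.nan,
            "beta1_copula": np.nan, "se_beta1_copula": np.nan, "p_beta1_copula": np.nan,
            "alpha1_univariate": np.nan, "se_alpha1_univariate": np.nan,
            "p_alpha1_univariate": np.nan,
            "beta1_univariate": np.nan, "se_beta1_univariate": np.nan,
            "p_beta1_univariate": np.nan,
            "model_tau": np.nan, "empirical_tau": np.nan,
            "aic_copula": np.nan, "aic_independence": np.nan, "aic_bvn": np.nan,
        }
        try:
            ok = ~np.isnan(v.dosage)
            gdose = v.dosage[ok]
            y1 = study.sbp_adj[ok]
            y2 = study.ge_adj[g.transcript_id].to_numpy()[ok]
            n_used = int(ok.sum())
            row["n_used"] = n_used
            uni1 = fit_univariate(y1, gdose)
            uni2 = fit_univariate(y2, gdose)
            row.update(
                alpha1_univariate=uni1.slope, se_alpha1_univariate=uni1.se,
                p_alpha1_univariate=uni1.p,
                beta1_univariate=uni2.slope, se_beta1_univariate=uni2.se,
                p_beta1_univariate=uni2.p,
            )
            tau, _ = empirical_kendall_tau(y1 - uni1.intercept - uni1.slope * gdose,
                                           y2 - uni2.intercept - uni2.slope * gdose)
            row["empirical_tau"] = tau
            ref = fit_reference_models(y1, y2, gdose)
            row["aic_independence"] = ref.independence_aic
            row["aic_bvn"] = ref.bvn_aic
            jf = fit_joint_copula(y1, y2, gdose, config.fit_options)
            row.update(
                converged=jf.converged, boundary=jf.boundary,
                model_tau=jf.model_tau, aic_copula=jf.aic,
                alpha1_copula=jf.margins.alpha1, se_alpha1_copula=jf.se_alpha1,
                p_alpha1_copula=jf.wald_alpha1[1],
                beta1_copula=jf.margins.beta1, se_beta1_copula=jf.se_beta1,
                p_beta1_copula=jf.wald_beta1[1],
            )
        except (ValueError, FloatingPointError) as exc:
            logger.warning("pair (%s, %s) failed: %s", v.id, g.gene_id, exc)
        rows.append(row)

    table = pd.DataFrame(rows)
    for col in ("p_alpha1_copula", "p_beta1_copula",
                "p_alpha1_univariate", "p_beta1_univariate"):
        adj = np.full(len(table), np.nan)
        mask = table[col].notna().to_numpy()
        if mask.any():
            adj[mask] = bh_adjust(table.loc[mask, col].to_numpy())
        table[col.replace("p_", "padj_")] = adj
    return ScanResult(table=table, n_variants_input=len(study.variants),
                      n_variants_kept=len(kept), n_pairs=len(pairs))
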