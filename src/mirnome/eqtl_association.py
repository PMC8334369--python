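"""Windowed cis miR-eQTL scan and SNV-trait association testing.

SNV-miRNA pairs are enumerated inside a +/-100 kb window around each
miRNA gene (0-based half-open, left edge inclusive), filtered for common
variants (MAF strictly > 0.1, Hardy-Weinberg p reported but not used for
exclusion), tested by linear regression of normalized expression on
minor-allele dosage with fetal sex and gestational age as cofactors, and
BH-corrected across the whole scan. Trait associations use linear or
logistic additive models; cohort-level results are pooled by
inverse-variance fixed-effect meta-analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, FeatureAnnotation, GenotypeMatrix, SampleTable
from .stats_core import bh_adjust, fixed_effect_meta, hwe_exact, linear_fit, logistic_fit

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "enumerate_pairs",
    "maf_hwe_filter",
    "eqtl_scan",
    "trait_association",
    "meta_across_cohorts",
]


@dataclass(frozen=True)
class WindowSpec:
    """Symmetric flank (bp) extending from gene start and end."""

    flank: int = 100_000

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be non-negative")


def enumerate_pairs(
    geno: GenotypeMatrix, mirnas: FeatureAnnotation, window: WindowSpec = WindowSpec()
) -> list[tuple[str, str]]:
    """All (snv_id, mirna_id) pairs with the SNV inside the flanked gene span.

    Inclusion rule (internal 0-based half-open coordinates): same
    chromosome and ``gene_start - flank <= snv_pos < gene_end + flank``.
    """
    pairs: list[tuple[str, str]] = []
    ann = mirnas.table
    snv_by_chrom: dict[str, np.ndarray] = {}
    for c in pd.unique(geno.chrom):
        snv_by_chrom[c] = np.where(geno.chrom == c)[0]
    for fid, row in ann.iterrows():
        idx = snv_by_chrom.get(row.chrom)
        if idx is None:
            continue
        pos = geno.pos[idx]
        hit = (pos >= row.start - window.flank) & (pos < row.end + window.flank)
        pairs.extend((geno.snv_ids[i], fid) for i in idx[hit])
    return pairs


def maf_hwe_filter(
    geno: GenotypeMatrix, maf_min: float = 0.1, hwe_alpha: float | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Retain common SNVs and report Hardy-Weinberg exact p per variant.

    MAF is computed on non-missing dosages and must be strictly greater
    than ``maf_min``. HWE is reported for every retained SNV; variants are
    additionally excluded on HWE only when ``hwe_alpha`` is given.
    """
    maf = geno.maf()
    hwe_p = np.ones(geno.n_snvs)
    for i in range(geno.n_snvs):
        n_major, n_het, n_minor = geno.genotype_counts(i)
        if n_major + n_het + n_minor > 0:
            hwe_p[i] = hwe_exact(n_major, n_het, n_minor).p_value
    keep = maf > maf_min
    if hwe_alpha is not None:
        keep &= hwe_p >= hwe_alpha
    report = pd.DataFrame(
        {"snv_id": geno.snv_ids, "maf": maf, "hwe_p": hwe_p, "retained": keep}
    )
    return geno.subset(keep), report


def _covariate_columns(meta: SampleTable, samples: list[str], covariates) -> np.ndarray:
    cols = []
    for cov in covariates:
        if cov == "fetal_sex":
            cols.append((meta.table.loc[samples, "fetal_sex"] == "XY").to_numpy(float))
        elif cov == "gestational_days":
            cols.append(meta.table.loc[samples, "gestational_days"].to_numpy(float))
        else:
            cols.append(meta.table.loc[samples, cov].to_numpy(float))
    return np.column_stack(cols) if cols else np.empty((len(samples), 0))


def eqtl_scan(
    expr: CountMatrix,
    geno: GenotypeMatrix,
    meta: SampleTable,
    pairs: list[tuple[str, str]],
    covariates: tuple[str, ...] = ("fetal_sex", "gestational_days"),
    min_n: int = 10,
    log1p: bool = False,
) -> pd.DataFrame:
    """Linear regression of expression on dosage for each enumerated pair.

    Missing genotypes are dropped per test (complete-case); pairs with
    fewer than ``min_n`` complete cases or a constant dosage are skipped
    with a log entry. BH correction spans every test actually performed
    in the scan; results are sorted by FDR.
    """
    if expr.kind not in ("normalized", "cpm"):
        raise ValueError("eQTL scan expects normalized expression")
    samples = [s for s in expr.values.columns if s in set(geno.sample_ids) and s in set(meta.sample_ids)]
    if len(samples) < min_n:
        raise ValueError(f"only {len(samples)} samples shared across inputs")
    geno_col = {s: i for i, s in enumerate(geno.sample_ids)}
    col_idx = np.array([geno_col[s] for s in samples])
    snv_row = {s: i for i, s in enumerate(geno.snv_ids)}
    covs = _covariate_columns(meta, samples, covariates)
    maf = geno.maf()
    hwe_cache: dict[int, float] = {}

    records = []
    n_skipped = 0
    for snv_id, mirna_id in pairs:
        if snv_id not in snv_row:
            continue
        if mirna_id not in expr.values.index:
            raise ValueError(f"expression row missing for paired miRNA {mirna_id!r}")
        i = snv_row[snv_id]
        dosage = geno.dosages[i, col_idx]
        ok = ~np.isnan(dosage)
        if ok.sum() < min_n:
            logger.info("skipping %s-%s: %d complete cases", snv_id, mirna_id, int(ok.sum()))
            n_skipped += 1
            continue
        d = dosage[ok]
        if np.ptp(d) == 0:
            logger.info("skipping %s-%s: constant dosage", snv_id, mirna_id)
            n_skipped += 1
            continue
        y = expr.values.loc[mirna_id, samples].to_numpy(float)[ok]
        if log1p:
            y = np.log1p(y)
        X = np.column_stack([d, covs[ok]])
        fit = linear_fit(y, X)
        if i not in hwe_cache:
            row = geno.dosages[i]
            hwe_cache[i] = hwe_exact(
                int(np.sum(row == 0)), int(np.sum(row == 1)), int(np.sum(row == 2))
            ).p_value
        records.append(
            (
                snv_id,
                mirna_id,
                int(ok.sum()),
                fit.coefficients[1],
                fit.standard_errors[1],
                fit.p_values[1],
                float(maf[i]),
                hwe_cache[i],
            )
        )
    if n_skipped:
        logger.warning("eqtl_scan: skipped %d of %d pairs", n_skipped, len(pairs))
    out = pd.DataFrame(
        records,
        columns=["snv_id", "mirna_id", "n_used", "beta", "se", "p_value", "maf", "hwe_p"],
    )
    out["fdr"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out.sort_values(["fdr", "p_value", "snv_id", "mirna_id"], kind="mergesort").reset_index(
        drop=True
    )


def trait_association(
    meta: SampleTable,
    geno: GenotypeMatrix,
    traits: list[str] | None = None,
    covariates: tuple[str, ...] = ("fetal_sex", "gestational_days"),
    min_n: int = 10,
) -> pd.DataFrame:
    """Additive-model SNV-trait association for every SNV x trait combination.

    Continuous traits use linear regression, binary (0/1) traits logistic
    regression; both adjust for the covariates. BH correction spans all
    tests performed.
    """
    if traits is None:
        traits = meta.trait_names
    samples = [s for s in meta.sample_ids if s in set(geno.sample_ids)]
    geno_col = {s: i for i, s in enumerate(geno.sample_ids)}
    col_idx = np.array([geno_col[s] for s in samples])
    covs = _covariate_columns(meta, samples, covariates)
    records = []
    for trait in traits:
        values = meta.table.loc[samples, trait].to_numpy(float)
        observed = ~np.isnan(values)
        uniq = np.unique(values[observed])
        binary = np.all(np.isin(uniq, (0.0, 1.0)))
        if binary and uniq.size < 2:
            raise ValueError(f"trait {trait!r} has a single class")
        for i, snv_id in enumerate(geno.snv_ids):
            dosage = geno.dosages[i, col_idx]
            ok = observed & ~np.isnan(dosage)
            if ok.sum() < min_n or np.ptp(dosage[ok]) == 0:
                continue
            X = np.column_stack([dosage[ok], covs[ok]])
            y = values[ok]
            if binary:
                if np.unique(y).size < 2:
                    continue
                fit = logistic_fit(y, X)
                if not fit.converged:
                    continue
                model = "logistic"
            else:
                fit = linear_fit(y, X)
                model = "linear"
            records.append(
                (
                    snv_id,
                    trait,
                    model,
                    int(ok.sum()),
                    fit.coefficients[1],
                    fit.standard_errors[1],
                    fit.p_values[1],
                    ",".join(covariates),
                )
            )
    out = pd.DataFrame(
        records,
        columns=["snv_id", "trait", "model", "n_used", "beta", "se", "p_value", "covariates"],
    )
    out["fdr"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out.sort_values(["fdr", "p_value", "snv_id", "trait"], kind="mergesort").reset_index(
        drop=True
    )


def meta_across_cohorts(cohort_results: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect meta-analysis of per-cohort association results.

    Each input table needs columns snv_id, trait, beta, se. Only
    (snv, trait) pairs present in every cohort are pooled; BH correction
    spans the pooled pairs.
    """
    if not cohort_results:
        raise ValueError("no cohort results supplied")
    keys = None
    indexed = []
    for df in cohort_results:
        missing = {"snv_id", "trait", "beta", "se"} - set(df.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        d = df.set_index(["snv_id", "trait"])
        indexed.append(d)
        keys = set(d.index) if keys is None else keys & set(d.index)
    records = []
    for snv_id, trait in sorted(keys):
        betas = [d.loc[(snv_id, trait), "beta"] for d in indexed]
        ses = [d.loc[(snv_id, trait), "se"] for d in indexed]
        res = fixed_effect_meta(betas, ses)
        records.append(
            (snv_id, trait, res.n_studies, res.pooled_beta, res.pooled_se, res.z, res.p_value)
        )
    out = pd.DataFrame(
        records,
        columns=["snv_id", "trait", "n_studies", "pooled_beta", "pooled_se", "z", "p_value"],
    )
    out["fdr"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out
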