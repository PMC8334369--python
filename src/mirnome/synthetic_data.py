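"""Synthetic cohort generator with ground truth.

Builds complete in-silico inputs for every pipeline stage: NB-distributed
miRNA and gene counts over three trimesters plus term clinical subgroups,
planted gestational-dynamics patterns and PE shifts, genomically
clustered miRNA blocks, genes with planted positive/negative latent
correlation to miRNAs, Hardy-Weinberg genotypes with additive cis effects
on miRNA expression, and continuous/binary pregnancy traits. A
``TruthRecord`` captures every planted parameter so downstream stages can
be tested for recovery without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CountMatrix,
    FeatureAnnotation,
    GenotypeMatrix,
    SampleTable,
    TargetMap,
    write_annotation,
    write_counts,
    write_genotypes_vcf,
    write_sample_table,
    write_target_map,
)

__all__ = ["SimConfig", "TruthRecord", "SimBundle", "simulate_cohort", "export_fixture"]

# default mix of the nine dynamics patterns (first transition - second transition)
DEFAULT_PATTERN_PROPORTIONS = {
    "Down-Down": 0.072,
    "Down-NoChange": 0.161,
    "Down-Up": 0.067,
    "Up-Up": 0.084,
    "Up-NoChange": 0.098,
    "Up-Down": 0.062,
    "NoChange-Down": 0.130,
    "NoChange-Up": 0.091,
    "NoChange-NoChange": 0.235,
}

GESTATIONAL_DAY_RANGES = {"1": (51, 81), "2": (108, 140), "term": (260, 291)}


@dataclass
class SimConfig:
    """All knobs of the simulator; ``seed`` is mandatory."""

    seed: int
    n_t1: int = 5
    n_t2: int = 7
    n_term_per_group: int = 8
    n_mirnas: int = 50
    n_genes: int = 300
    n_snvs: int = 100
    pattern_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_PROPORTIONS)
    )
    log2fc_range: tuple[float, float] = (-4.91, 2.84)
    min_abs_log2fc: float = 1.0
    pe_demir_fraction: float = 0.16
    dispersion: float = 0.05
    per_feature_dispersion: bool = False
    library_size_range: tuple[float, float] = (0.6, 1.6)
    cluster_block_sizes: dict[str, int] = field(
        default_factory=lambda: {"C19MC": 8, "C14MC": 8, "miR371_373": 2}
    )
    # (snv_index, mirna_index, beta on the natural-log mean per minor allele, maf)
    eqtl_specs: list[tuple[int, int, float, float]] = field(default_factory=list)
    # (gene_index, mirna_index, direction +1/-1, strength in (0, 1])
    corr_specs: list[tuple[int, int, int, float]] = field(default_factory=list)
    # (trait_name, snv_index, effect per minor allele)
    trait_specs: list[tuple[str, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(self.pattern_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"pattern proportions sum to {total}, expected 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for _, _, _, maf in self.eqtl_specs:
            if not 0 < maf <= 0.5:
                raise ValueError(f"eQTL MAF {maf} outside (0, 0.5]")
        for snv, mirna, _, _ in self.eqtl_specs:
            if snv >= self.n_snvs or mirna >= self.n_mirnas:
                raise ValueError("eQTL spec indexes out of range")
        for gene, mirna, direction, strength in self.corr_specs:
            if gene >= self.n_genes or mirna >= self.n_mirnas:
                raise ValueError("correlation spec indexes out of range")
            if direction not in (-1, 1) or not 0 < strength <= 1:
                raise ValueError("correlation spec needs direction +-1 and strength in (0, 1]")
        if sum(self.cluster_block_sizes.values()) > self.n_mirnas:
            raise ValueError("cluster blocks exceed the number of miRNAs")


@dataclass
class TruthRecord:
    """Planted parameters for every simulated feature."""

    mirna_truth: pd.DataFrame  # pattern, log2fc_1, log2fc_2, pe_log2fc, dispersion
    eqtl_truth: pd.DataFrame  # snv_id, mirna_id, beta, maf
    corr_truth: pd.DataFrame  # gene_id, mirna_id, direction, strength
    trait_truth: pd.DataFrame  # trait, snv_id, effect
    library_scales: pd.Series


@dataclass
class SimBundle:
    mirna_counts: CountMatrix
    gene_counts: CountMatrix
    samples: SampleTable
    mirna_annotation: FeatureAnnotation
    genotypes: GenotypeMatrix
    targets: TargetMap
    truth: TruthRecord


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean, alpha) with variance mean + alpha * mean^2 via gamma-Poisson."""
    mean = np.maximum(mean, 1e-12)
    alpha = np.broadcast_to(alpha, mean.shape)
    lam = np.where(
        alpha > 1e-10,
        rng.gamma(shape=1.0 / np.maximum(alpha, 1e-10), scale=np.maximum(alpha, 1e-10) * mean),
        mean,
    )
    return rng.poisson(lam)


def _sample_frame(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    sexes = ["XX", "XY"]
    i = 0

    def add(prefix, n, trimester, group):
        nonlocal i
        lo, hi = GESTATIONAL_DAY_RANGES[trimester]
        for j in range(n):
            rows.append(
                {
                    "sample_id": f"{prefix}{j + 1:02d}",
                    "trimester": trimester,
                    "gestational_days": int(rng.integers(lo, hi + 1)),
                    "fetal_sex": sexes[i % 2],
                    "group": group,
                }
            )
            i += 1

    add("T1_", cfg.n_t1, "1", "T1")
    add("T2_", cfg.n_t2, "2", "T2")
    for group in ("NORM", "PE", "GD", "SGA", "LGA"):
        add(f"{group}_", cfg.n_term_per_group, "term", group)
    df = pd.DataFrame(rows).set_index("sample_id")

    term = df["trimester"] == "term"
    n_term = int(term.sum())
    trait_means = {
        "birth_weight": (3600, 450),
        "birth_length": (51, 2),
        "head_circumference": (35, 1.5),
        "chest_circumference": (34, 2),
        "placental_weight": (550, 120),
    }
    for trait, (mu, sd) in trait_means.items():
        vals = np.full(len(df), np.nan)
        vals[term.to_numpy()] = rng.normal(mu, sd, n_term)
        df[trait] = vals
    df["pe_diagnosis"] = np.where(term, (df["group"] == "PE").astype(float), np.nan)
    df["gd_diagnosis"] = np.where(term, (df["group"] == "GD").astype(float), np.nan)
    return df


def _mirna_annotation(cfg: SimConfig, rng: np.random.Generator) -> FeatureAnnotation:
    ids = [f"mir{i + 1:03d}" for i in range(cfg.n_mirnas)]
    chroms, starts, clusters = [], [], []
    block_chrom = {"C19MC": "chr19", "C14MC": "chr14", "miR371_373": "chr19"}
    block_base = {"C19MC": 1_000_000, "C14MC": 5_000_000, "miR371_373": 3_000_000}
    i = 0
    for cluster, size in cfg.cluster_block_sizes.items():
        for j in range(size):
            chroms.append(block_chrom.get(cluster, "chr1"))
            starts.append(block_base.get(cluster, 1_000_000) + j * 2_000)
            clusters.append(cluster)
            i += 1
    autosomes = [f"chr{c}" for c in range(1, 23)]
    while i < cfg.n_mirnas:
        chroms.append(autosomes[int(rng.integers(0, len(autosomes)))])
        starts.append(int(rng.integers(1_000_000, 50_000_000)))
        clusters.append("other")
        i += 1
    df = pd.DataFrame(
        {
            "feature_id": ids,
            "chrom": chroms,
            "start": starts,
            "end": [s + 90 for s in starts],
            "strand": ["+" if k % 2 == 0 else "-" for k in range(cfg.n_mirnas)],
            "cluster": clusters,
        }
    ).set_index("feature_id")
    return FeatureAnnotation(table=df)


def _draw_log2fc(rng: np.random.Generator, direction: str, cfg: SimConfig) -> float:
    lo, hi = cfg.log2fc_range
    if direction == "Up":
        return float(rng.uniform(cfg.min_abs_log2fc, max(hi, cfg.min_abs_log2fc + 0.1)))
    if direction == "Down":
        return float(rng.uniform(min(lo, -cfg.min_abs_log2fc - 0.1), -cfg.min_abs_log2fc))
    return 0.0


def simulate_cohort(cfg: SimConfig) -> SimBundle:
    """Generate one full cohort; byte-identical for a fixed config/seed."""
    rng = np.random.default_rng(cfg.seed)
    samples = _sample_frame(cfg, rng)
    sample_ids = list(samples.index)
    n_samples = len(sample_ids)
    annotation = _mirna_annotation(cfg, rng)
    mirna_ids = annotation.feature_ids
    gene_ids = [f"gene{i + 1:04d}" for i in range(cfg.n_genes)]

    # --- planted dynamics patterns and PE shifts
    pattern_names = list(cfg.pattern_proportions)
    probs = np.array([cfg.pattern_proportions[p] for p in pattern_names])
    patterns = rng.choice(pattern_names, size=cfg.n_mirnas, p=probs / probs.sum())
    fc1 = np.array([_draw_log2fc(rng, p.split("-")[0], cfg) for p in patterns])
    fc2 = np.array([_draw_log2fc(rng, p.split("-")[1], cfg) for p in patterns])

    n_pe = int(round(cfg.pe_demir_fraction * cfg.n_mirnas))
    pe_idx = rng.choice(cfg.n_mirnas, size=n_pe, replace=False)
    pe_fc = np.zeros(cfg.n_mirnas)
    pe_fc[pe_idx] = rng.uniform(1.0, 2.0, n_pe) * rng.choice([-1.0, 1.0], n_pe)

    # --- genotypes (HWE by construction)
    snv_ids = [f"snv{i + 1:04d}" for i in range(cfg.n_snvs)]
    snv_chrom = np.empty(cfg.n_snvs, dtype=object)
    snv_pos = np.zeros(cfg.n_snvs, dtype=int)
    mafs = rng.uniform(0.1, 0.5, cfg.n_snvs)
    autosomes = [f"chr{c}" for c in range(1, 23)]
    for i in range(cfg.n_snvs):
        snv_chrom[i] = autosomes[int(rng.integers(0, len(autosomes)))]
        snv_pos[i] = int(rng.integers(1_000_000, 50_000_000))
    for snv_i, mirna_i, _beta, maf in cfg.eqtl_specs:
        snv_chrom[snv_i] = annotation.table.iloc[mirna_i]["chrom"]
        snv_pos[snv_i] = int(annotation.table.iloc[mirna_i]["start"]) + 10_000
        mafs[snv_i] = maf
    dosages = (
        rng.binomial(1, mafs[:, None], (cfg.n_snvs, n_samples))
        + rng.binomial(1, mafs[:, None], (cfg.n_snvs, n_samples))
    ).astype(float)
    # keep the cohort minor-allele coding convention: flip SNVs whose
    # empirical alt frequency drifted above 0.5
    minor_is_alt = dosages.mean(axis=1) / 2.0 <= 0.5
    dosages[~minor_is_alt] = 2.0 - dosages[~minor_is_alt]
    refs = np.array(["A"] * cfg.n_snvs)
    alts = np.array(["G"] * cfg.n_snvs)
    genotypes = GenotypeMatrix(
        snv_ids=snv_ids,
        chrom=snv_chrom,
        pos=snv_pos,
        ref=refs,
        alt=alts,
        sample_ids=sample_ids,
        dosages=dosages,
        minor_is_alt=minor_is_alt,
    )

    # --- miRNA means: baseline x trimester multipliers x PE shift x eQTL effect
    base = np.exp(rng.normal(np.log(800.0), 1.0, cfg.n_mirnas))
    base = np.maximum(base, 80.0)
    tri = samples["trimester"].to_numpy()
    mult = np.ones((cfg.n_mirnas, n_samples))
    mult[:, tri == "2"] = 2.0 ** fc1[:, None]
    mult[:, tri == "term"] = 2.0 ** (fc1 + fc2)[:, None]
    is_pe = (samples["group"] == "PE").to_numpy()
    mult[:, is_pe] *= 2.0 ** pe_fc[:, None]
    log_mu = np.log(base)[:, None] + np.log(mult)
    for snv_i, mirna_i, beta, _maf in cfg.eqtl_specs:
        log_mu[mirna_i] += beta * dosages[snv_i]

    if cfg.per_feature_dispersion:
        alpha_mirna = rng.lognormal(np.log(cfg.dispersion), 0.5, cfg.n_mirnas)
    else:
        alpha_mirna = np.full(cfg.n_mirnas, cfg.dispersion)
    scales = rng.uniform(*cfg.library_size_range, n_samples)
    mirna_mu = np.exp(log_mu) * scales[None, :]
    mirna_counts = _nb_draw(rng, mirna_mu, alpha_mirna[:, None])

    # --- genes: latent signal from a planted miRNA profile plus noise
    gene_base = np.exp(rng.normal(np.log(500.0), 0.8, cfg.n_genes))
    gene_base = np.maximum(gene_base, 80.0)
    gene_log = np.log(gene_base)[:, None] + rng.normal(0.0, 0.3, (cfg.n_genes, n_samples))
    amplitude = 1.5
    for gene_i, mirna_i, direction, strength in cfg.corr_specs:
        # latent = the miRNA profile as realized in the counts, so planted
        # pairs stay rank-correlated even for flat-pattern miRNAs
        latent = np.log1p(mirna_counts[mirna_i] / scales)
        z = (latent - latent.mean()) / max(latent.std(), 1e-12)
        noise = rng.normal(0.0, 1.0, n_samples)
        signal = strength * direction * z + np.sqrt(max(1.0 - strength**2, 0.0)) * noise
        gene_log[gene_i] = np.log(gene_base[gene_i]) + amplitude * signal
    gene_mu = np.exp(gene_log) * scales[None, :]
    gene_counts = _nb_draw(rng, gene_mu, cfg.dispersion)

    # --- traits with optional SNV effects
    for trait, snv_i, effect in cfg.trait_specs:
        if trait not in samples.columns:
            raise ValueError(f"trait spec names unknown trait {trait!r}")
        col = samples[trait].to_numpy(float)
        if set(np.unique(col[~np.isnan(col)])) <= {0.0, 1.0}:
            # binary: re-draw with a logistic dosage effect
            eta = -1.5 + effect * dosages[snv_i]
            draw = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))).astype(float)
            col = np.where(np.isnan(col), np.nan, draw)
        else:
            col = col + effect * dosages[snv_i]
        samples[trait] = col

    # --- target map: planted correlation partners plus random padding
    targets: dict[str, set[str]] = {}
    for gene_i, mirna_i, _d, _s in cfg.corr_specs:
        targets.setdefault(mirna_ids[mirna_i], set()).add(gene_ids[gene_i])
    for mirna_i in range(cfg.n_mirnas):
        n_extra = min(int(rng.integers(5, 16)), cfg.n_genes)
        extra = rng.choice(cfg.n_genes, size=n_extra, replace=False)
        targets.setdefault(mirna_ids[mirna_i], set()).update(gene_ids[g] for g in extra)

    truth = TruthRecord(
        mirna_truth=pd.DataFrame(
            {
                "pattern": patterns,
                "log2fc_1": fc1,
                "log2fc_2": fc2,
                "pe_log2fc": pe_fc,
                "dispersion": alpha_mirna,
            },
            index=pd.Index(mirna_ids, name="feature_id"),
        ),
        eqtl_truth=pd.DataFrame(
            [
                (snv_ids[s], mirna_ids[m], beta, maf)
                for s, m, beta, maf in cfg.eqtl_specs
            ],
            columns=["snv_id", "mirna_id", "beta", "maf"],
        ),
        corr_truth=pd.DataFrame(
            [
                (gene_ids[g], mirna_ids[m], d, s)
                for g, m, d, s in cfg.corr_specs
            ],
            columns=["gene_id", "mirna_id", "direction", "strength"],
        ),
        trait_truth=pd.DataFrame(
            [(t, snv_ids[s], e) for t, s, e in cfg.trait_specs],
            columns=["trait", "snv_id", "effect"],
        ),
        library_scales=pd.Series(scales, index=sample_ids, name="library_scale"),
    )
    return SimBundle(
        mirna_counts=CountMatrix(
            values=pd.DataFrame(mirna_counts, index=mirna_ids, columns=sample_ids), kind="raw"
        ),
        gene_counts=CountMatrix(
            values=pd.DataFrame(gene_counts, index=gene_ids, columns=sample_ids), kind="raw"
        ),
        samples=SampleTable(table=samples),
        mirna_annotation=annotation,
        genotypes=genotypes,
        targets=TargetMap(targets=targets),
        truth=truth,
    )


def export_fixture(bundle: SimBundle, directory) -> dict[str, Path]:
    """Write every bundle component in its standard on-disk format."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_counts": directory / "mirna_counts.tsv",
        "gene_counts": directory / "gene_counts.tsv",
        "samples": directory / "samples.tsv",
        "mirna_annotation": directory / "mirna_annotation.bed",
        "genotypes": directory / "genotypes.vcf",
        "targets": directory / "targets.tsv",
        "truth": directory / "truth.json",
    }
    write_counts(bundle.mirna_counts, paths["mirna_counts"])
    write_counts(bundle.gene_counts, paths["gene_counts"])
    write_sample_table(bundle.samples, paths["samples"])
    write_annotation(bundle.mirna_annotation, paths["mirna_annotation"])
    write_genotypes_vcf(bundle.genotypes, paths["genotypes"])
    write_target_map(bundle.targets, paths["targets"])
    truth = bundle.truth
    payload = {
        "mirna_truth": truth.mirna_truth.reset_index().to_dict(orient="list"),
        "eqtl_truth": truth.eqtl_truth.to_dict(orient="list"),
        "corr_truth": truth.corr_truth.to_dict(orient="list"),
        "trait_truth": truth.trait_truth.to_dict(orient="list"),
        "library_scales": truth.library_scales.to_dict(),
    }
    paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return paths
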