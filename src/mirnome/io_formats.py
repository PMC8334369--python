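"""Readers and writers for all on-disk artifacts the pipeline touches.

All genomic coordinates are held internally as 0-based half-open
intervals. Conversions happen only at format boundaries: BED is native,
GFF3 and VCF are 1-based and converted on read/write. Malformed input is
rejected with an informative error, never silently repaired (the single
documented exception: multi-allelic VCF records are skipped with a
warning).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COUNT_KINDS = ("raw", "normalized", "cpm")
TRIMESTERS = ("1", "2", "term")
SEXES = ("XX", "XY")
GROUPS = ("NORM", "PE", "GD", "SGA", "LGA", "T1", "T2")
CLUSTERS = ("C19MC", "C14MC", "miR371_373", "other")

__all__ = [
    "CountMatrix",
    "SampleTable",
    "FeatureAnnotation",
    "GenotypeMatrix",
    "TargetMap",
    "read_counts",
    "write_counts",
    "read_sample_table",
    "write_sample_table",
    "read_annotation",
    "write_annotation",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_target_map",
    "write_target_map",
    "read_gmt",
    "write_results",
]


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dup[:5]}")


@dataclass
class CountMatrix:
    """Feature x sample expression grid with aligned identifiers.

    ``values`` is a DataFrame indexed by feature id with sample ids as
    columns. ``kind`` is one of raw / normalized / cpm; raw matrices must
    hold non-negative integers.
    """

    values: pd.DataFrame
    kind: str = "raw"

    def __post_init__(self) -> None:
        if self.kind not in COUNT_KINDS:
            raise ValueError(f"unknown count kind {self.kind!r}")
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("count matrix must be numeric")
        if np.isnan(arr).any():
            raise ValueError("count matrix contains missing values")
        if (arr < 0).any():
            raise ValueError("count matrix contains negative values")
        if self.kind == "raw" and not np.allclose(arr, np.round(arr)):
            raise ValueError("raw count matrix must contain integers")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SampleTable:
    """Per-sample metadata: trimester, gestational age, sex, clinical group
    and any number of additional trait columns (real or 0/1)."""

    table: pd.DataFrame

    REQUIRED = ("trimester", "gestational_days", "fetal_sex", "group")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        tri = self.table["trimester"].astype(str)
        bad = sorted(set(tri) - set(TRIMESTERS))
        if bad:
            raise ValueError(f"unknown trimester values: {bad}")
        self.table["trimester"] = tri
        days = self.table["gestational_days"]
        if ((days < 30) | (days > 320)).any():
            raise ValueError("gestational_days outside the plausible 30-320 range")
        bad = sorted(set(self.table["fetal_sex"]) - set(SEXES))
        if bad:
            raise ValueError(f"unknown fetal_sex values: {bad}")
        bad = sorted(set(self.table["group"]) - set(GROUPS))
        if bad:
            raise ValueError(f"unknown group values: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in self.REQUIRED]

    def labels(self, scheme: str) -> pd.Series:
        """Sample labels under a grouping scheme: 'trimester' or 'group'."""
        if scheme not in ("trimester", "group"):
            raise ValueError("scheme must be 'trimester' or 'group'")
        return self.table[scheme].astype(str)


@dataclass
class FeatureAnnotation:
    """Genomic intervals (0-based half-open) plus cluster labels."""

    table: pd.DataFrame  # index: feature_id; columns chrom,start,end,strand,cluster

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "feature ids")
        for col in ("chrom", "start", "end", "strand", "cluster"):
            if col not in self.table.columns:
                raise ValueError(f"annotation missing column {col!r}")
        if (self.table["start"] >= self.table["end"]).any():
            bad = self.table.index[self.table["start"] >= self.table["end"]]
            raise ValueError(f"start >= end for features: {list(bad[:5])}")
        bad = sorted(set(self.table["strand"]) - {"+", "-", "."})
        if bad:
            raise ValueError(f"unknown strand values: {bad}")
        bad = sorted(set(self.table["cluster"]) - set(CLUSTERS))
        if bad:
            raise ValueError(f"unknown cluster labels: {bad}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class GenotypeMatrix:
    """SNV x sample minor-allele dosages.

    ``dosages`` is float with values in {0, 1, 2} and NaN for missing;
    the coding counts the minor allele as observed in the loaded cohort.
    ``minor_is_alt`` records the original ref/alt orientation per SNV.
    """

    snv_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray  # 0-based
    ref: np.ndarray
    alt: np.ndarray
    sample_ids: list[str]
    dosages: np.ndarray
    minor_is_alt: np.ndarray = None

    def __post_init__(self) -> None:
        _check_unique(self.snv_ids, "SNV ids")
        _check_unique(self.sample_ids, "sample ids")
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=int)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.snv_ids), len(self.sample_ids)):
            raise ValueError("dosage grid shape mismatch")
        vals = self.dosages[~np.isnan(self.dosages)]
        if not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if self.minor_is_alt is None:
            self.minor_is_alt = np.ones(len(self.snv_ids), dtype=bool)

    @property
    def n_snvs(self) -> int:
        return len(self.snv_ids)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNV over non-missing samples."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(self.dosages, axis=1) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def genotype_counts(self, i: int) -> tuple[int, int, int]:
        """(n homozygous major, n heterozygous, n homozygous minor)."""
        row = self.dosages[i]
        return (
            int(np.sum(row == 0)),
            int(np.sum(row == 1)),
            int(np.sum(row == 2)),
        )

    def subset(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            snv_ids=[self.snv_ids[i] for i in np.where(keep)[0]]
            if keep.dtype == bool
            else [self.snv_ids[i] for i in keep],
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            ref=np.asarray(self.ref)[keep],
            alt=np.asarray(self.alt)[keep],
            sample_ids=self.sample_ids,
            dosages=self.dosages[keep],
            minor_is_alt=self.minor_is_alt[keep],
        )


@dataclass
class TargetMap:
    """miRNA id -> set of target gene ids (empty sets are not stored)."""

    targets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [m for m, g in self.targets.items() if not g]
        if empty:
            raise ValueError(f"empty target sets for: {empty[:5]}")

    def __getitem__(self, mirna: str) -> set[str]:
        return self.targets[mirna]

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.targets

    def __len__(self) -> int:
        return len(self.targets)


# ---------------------------------------------------------------------------
# counts


def read_counts(path, kind: str = "raw") -> CountMatrix:
    """Read a TSV count matrix (first column feature id, header = samples)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: header must name at least one sample")
        sample_ids = header[1:]
        features: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            features.append(parts[0])
            try:
                vals = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric count") from exc
            if any(v < 0 for v in vals):
                raise ValueError(f"{path}:{lineno}: negative count")
            if kind == "raw" and any(v != int(v) for v in vals):
                raise ValueError(f"{path}:{lineno}: non-integer raw count")
            rows.append(vals)
    dup = pd.Index(features)
    if dup.has_duplicates:
        offender = dup[dup.duplicated()][0]
        raise ValueError(f"{path}: duplicated feature id {offender!r}")
    values = pd.DataFrame(rows, index=features, columns=sample_ids)
    if kind == "raw":
        values = values.astype(int)
    return CountMatrix(values=values, kind=kind)


def write_counts(cm: CountMatrix, path) -> None:
    df = cm.values
    if cm.kind != "raw":
        df = df.map(lambda v: float(f"{v:.10g}"))
    df.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# sample metadata


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"trimester": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    return SampleTable(table=df)


def write_sample_table(st: SampleTable, path) -> None:
    st.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# annotation


def read_annotation(path, format: str = "BED") -> FeatureAnnotation:
    """Read feature intervals from BED6(+1) or GFF3.

    BED is 0-based half-open (native); GFF3 1-based inclusive records are
    converted on read. Cluster labels come from BED column 7 or the GFF3
    ``cluster`` attribute and default to ``other``.
    """
    path = Path(path)
    records = []
    if format.upper() == "BED":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ValueError(f"{path}:{lineno}: expected >= 6 BED fields")
                chrom, start, end, name, _score, strand = parts[:6]
                cluster = parts[6] if len(parts) > 6 and parts[6] else "other"
                start, end = int(start), int(end)
                if start >= end:
                    raise ValueError(f"{path}:{lineno}: start >= end")
                records.append((name, chrom, start, end, strand, cluster))
    elif format.upper() == "GFF3":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ValueError(f"{path}:{lineno}: expected 9 GFF3 fields")
                chrom, _src, _type, start, end, _score, strand, _phase, attrs = parts
                start, end = int(start) - 1, int(end)  # to 0-based half-open
                if start >= end:
                    raise ValueError(f"{path}:{lineno}: end < start after conversion")
                attr = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                )
                name = attr.get("ID") or attr.get("Name")
                if name is None:
                    raise ValueError(f"{path}:{lineno}: record lacks ID/Name attribute")
                cluster = attr.get("cluster", "other")
                records.append((name, chrom, start, end, strand, cluster))
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    df = pd.DataFrame(
        records, columns=["feature_id", "chrom", "start", "end", "strand", "cluster"]
    ).set_index("feature_id")
    return FeatureAnnotation(table=df)


def write_annotation(ann: FeatureAnnotation, path) -> None:
    """Write annotation as BED6+1 (cluster label in column 7)."""
    with Path(path).open("w") as fh:
        for fid, row in ann.table.iterrows():
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{fid}\t.\t{row.strand}\t{row.cluster}\n"
            )


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read biallelic GT records from a VCF into minor-allele dosages.

    Alt-allele counts are recoded so dosage counts the minor allele in
    the loaded cohort; ``./.`` becomes missing; multi-allelic records are
    skipped with a logged warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    snv_ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic record %s at %s:%s", var.ID, var.CHROM, var.POS)
            continue
        gts = np.asarray(var.gt_types, dtype=float)  # 0,1,2 alt count; 3 unknown
        gts[gts == 3] = np.nan
        snv_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS - 1)  # VCF is 1-based
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(gts)
    vcf.close()
    if not rows:
        raise ValueError(f"{path}: no usable biallelic records")
    dosages = np.vstack(rows)
    # recode to minor-allele counts per cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        alt_freq = np.nanmean(dosages, axis=1) / 2.0
    minor_is_alt = alt_freq <= 0.5
    flip = ~minor_is_alt
    dosages[flip] = 2.0 - dosages[flip]
    return GenotypeMatrix(
        snv_ids=snv_ids,
        chrom=np.array(chroms),
        pos=np.array(poss),
        ref=np.array(refs),
        alt=np.array(alts),
        sample_ids=sample_ids,
        dosages=dosages,
        minor_is_alt=minor_is_alt,
    )


def write_genotypes_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT fields (alt-allele orientation)."""
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(gm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        order = np.lexsort((gm.pos, gm.chrom))
        gt_repr = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for i in order:
            dos = gm.dosages[i]
            if not gm.minor_is_alt[i]:  # restore alt-allele counts
                dos = 2.0 - dos
            gts = ["./." if np.isnan(d) else gt_repr[d] for d in dos]
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i] + 1}\t{gm.snv_ids[i]}\t{gm.ref[i]}\t"
                f"{gm.alt[i]}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# target map & gene sets


def read_target_map(path, high_confidence_only: bool = False) -> TargetMap:
    """Read a miRNA -> target TSV (columns: mirna_id, gene_id[, evidence])."""
    df = pd.read_csv(path, sep="\t")
    needed = {"mirna_id", "gene_id"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}")
    if high_confidence_only and "evidence" in df.columns:
        df = df[df["evidence"] == "high"]
    targets: dict[str, set[str]] = {}
    for mirna, sub in df.groupby("mirna_id"):
        genes = set(sub["gene_id"])
        if genes:
            targets[str(mirna)] = genes
    return TargetMap(targets=targets)


def write_target_map(tm: TargetMap, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("mirna_id\tgene_id\tevidence\n")
        for mirna in sorted(tm.targets):
            for gene in sorted(tm.targets[mirna]):
                fh.write(f"{mirna}\t{gene}\thigh\n")


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from GMT (set id, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            if parts[0] in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {parts[0]!r}")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


# ---------------------------------------------------------------------------
# generic result tables


def write_results(table: pd.DataFrame, path, sort_by: tuple[str, ...] | None = None) -> None:
    """Write a result table as deterministic TSV.

    Reals are rendered at 6 significant digits; rows are ordered by
    ``sort_by`` (defaults to fdr then the first column) so repeated runs
    are byte-identical.
    """
    df = table.copy()
    if sort_by is None:
        keys = [c for c in ("fdr", df.columns[0]) if c in df.columns]
    else:
        keys = [c for c in sort_by if c in df.columns]
    if keys:
        df = df.sort_values(keys, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
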