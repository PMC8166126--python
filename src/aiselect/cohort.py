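"""Cohort count tables: I/O, heterozygote calling, and locus filters.

The on-disk dialect is one TSV row per (SNP, sample) with tumor and normal
ref/alt read counts. In memory a cohort is rectangular: a locus table plus
(SNP x sample) count grids and a heterozygosity mask. The A allele is always
the reference allele and the B allele the alternate, matching the convention
that the mapping-bias parameter phi measures bias toward the reference.

Germline heterozygotes are called from the matched-normal counts alone:
total normal coverage strictly greater than 20 and B-allele frequency within
[0.2, 0.8] (inclusive endpoints; the window is symmetric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "COUNT_COLUMNS",
    "ANNOTATION_COLUMNS",
    "DEPENDENCY_COLUMNS",
    "SnpLocus",
    "CohortCounts",
    "FilterReport",
    "compute_baf",
    "call_heterozygote",
    "set_het_mask",
    "read_count_table",
    "write_count_table",
    "attach_locus_annotations",
    "read_annotation_table",
    "write_annotation_table",
    "read_dependency_table",
    "write_dependency_table",
    "filter_loci",
]

COUNT_COLUMNS = [
    "snp_id", "chrom", "pos", "arm", "ref", "alt", "sample_id",
    "tumor_ref_count", "tumor_alt_count", "normal_ref_count", "normal_alt_count",
]
ANNOTATION_COLUMNS = ["snp_id", "gene", "maf", "cadd", "control_af"]
DEPENDENCY_COLUMNS = ["gene", "dependency_score"]

LOCUS_COLUMNS = ["snp_id", "chrom", "pos", "arm", "ref", "alt"]

HET_MIN_COVERAGE = 20      # strict: coverage must exceed this
HET_BAF_LOW = 0.2          # inclusive window endpoints
HET_BAF_HIGH = 0.8


@dataclass(frozen=True)
class SnpLocus:
    """One biallelic exonic SNP locus (1-based coordinates)."""

    snp_id: str
    chrom: str
    pos: int
    arm: str
    ref_allele: str
    alt_allele: str
    gene: str = ""
    maf: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles must differ at {self.snp_id}")
        if np.isfinite(self.maf) and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"maf must be in [0, 0.5], got {self.maf}")


@dataclass
class CohortCounts:
    """Per-(SNP, sample) tumor/normal allelic depths across a cohort.

    loci: DataFrame with columns snp_id, chrom, pos, arm, ref, alt and
    optionally gene and maf (merged from an annotation table).
    Count grids are (n_snps, n_samples) integer arrays; ``is_het`` marks the
    called germline heterozygotes and ``norm_factor`` carries the per-sample
    coverage scale (global median depth / sample median depth), which is
    inert for the allele-fraction model (the scale cancels) and retained for
    reporting.
    """

    loci: pd.DataFrame
    samples: list[str]
    tumor_a: np.ndarray
    tumor_b: np.ndarray
    normal_a: np.ndarray
    normal_b: np.ndarray
    is_het: np.ndarray = None  # type: ignore[assignment]
    norm_factor: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = (len(self.loci), len(self.samples))
        for name in ("tumor_a", "tumor_b", "normal_a", "normal_b"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.shape != shape:
                raise ValueError(f"{name} grid has shape {arr.shape}, expected {shape}")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative counts")
            setattr(self, name, arr)
        if self.is_het is None:
            self.is_het = np.zeros(shape, dtype=bool)
        self.is_het = np.asarray(self.is_het, dtype=bool)
        if self.is_het.shape != shape:
            raise ValueError("is_het mask shape mismatch")
        if self.norm_factor is None:
            self.norm_factor = np.ones(len(self.samples))
        self.norm_factor = np.asarray(self.norm_factor, dtype=float)
        if np.any(self.norm_factor <= 0):
            raise ValueError("norm_factor must be strictly positive")

    @property
    def n_snps(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, locus_index: np.ndarray) -> "CohortCounts":
        idx = np.asarray(locus_index)
        return CohortCounts(
            loci=self.loci.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            tumor_a=self.tumor_a[idx],
            tumor_b=self.tumor_b[idx],
            normal_a=self.normal_a[idx],
            normal_b=self.normal_b[idx],
            is_het=self.is_het[idx],
            norm_factor=self.norm_factor.copy(),
        )

    def copy(self) -> "CohortCounts":
        return self.subset(np.arange(self.n_snps))


@dataclass(frozen=True)
class FilterReport:
    """Counts of loci surviving each named filter stage, in order."""

    stages: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        counts = [c for _, c in self.stages]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("filter stage counts must be monotone non-increasing")

    @property
    def counts(self) -> list[int]:
        return [c for _, c in self.stages]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_loci"])


def compute_baf(n_a, n_b):
    """B-allele frequency n_b / (n_a + n_b); undefined at zero total depth."""
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    total = n_a + n_b
    if np.any(total <= 0):
        raise ValueError("BAF undefined where total depth is zero")
    out = n_b / total
    return out if out.ndim else float(out)


def call_heterozygote(normal_a, normal_b):
    """Germline het call from normal counts: coverage > 20 (strict) and
    0.2 <= BAF <= 0.8 (inclusive). Vectorized; symmetric in its arguments."""
    normal_a = np.asarray(normal_a, dtype=np.int64)
    normal_b = np.asarray(normal_b, dtype=np.int64)
    if np.any(normal_a < 0) or np.any(normal_b < 0):
        raise ValueError("counts must be non-negative")
    total = normal_a + normal_b
    with np.errstate(invalid="ignore", divide="ignore"):
        baf = np.where(total > 0, normal_b / np.maximum(total, 1), np.nan)
    out = (total > HET_MIN_COVERAGE) & (baf >= HET_BAF_LOW) & (baf <= HET_BAF_HIGH)
    return out if out.ndim else bool(out)


def set_het_mask(cohort: CohortCounts) -> CohortCounts:
    """Set the heterozygosity mask from normal counts and compute the
    per-sample coverage scale (global median tumor depth / sample median)."""
    cohort.is_het = call_heterozygote(cohort.normal_a, cohort.normal_b)
    depth = cohort.tumor_a + cohort.tumor_b
    sample_med = np.median(depth, axis=0).astype(float)
    global_med = float(np.median(depth))
    safe = np.where(sample_med > 0, sample_med, 1.0)
    factor = np.where(sample_med > 0, max(global_med, 1.0) / safe, 1.0)
    cohort.norm_factor = factor
    return cohort


# ---------------------------------------------------------------------------
# TSV I/O


def write_count_table(cohort: CohortCounts, path) -> None:
    """Emit the canonical long TSV (loci in stored order x samples in stored
    order); ``read_count_table`` inverts it and rewriting is byte-identical."""
    n, m = cohort.n_snps, cohort.n_samples
    loci = cohort.loci
    frame = pd.DataFrame({
        "snp_id": np.repeat(loci["snp_id"].to_numpy(), m),
        "chrom": np.repeat(loci["chrom"].astype(str).to_numpy(), m),
        "pos": np.repeat(loci["pos"].to_numpy(), m),
        "arm": np.repeat(loci["arm"].to_numpy(), m),
        "ref": np.repeat(loci["ref"].to_numpy(), m),
        "alt": np.repeat(loci["alt"].to_numpy(), m),
        "sample_id": np.tile(np.asarray(cohort.samples), n),
        "tumor_ref_count": cohort.tumor_a.ravel(),
        "tumor_alt_count": cohort.tumor_b.ravel(),
        "normal_ref_count": cohort.normal_a.ravel(),
        "normal_alt_count": cohort.normal_b.ravel(),
    })
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_count_table(path) -> CohortCounts:
    """Read the long count TSV into a CohortCounts.

    Heterozygote flags are NOT set here; run ``set_het_mask`` afterwards.
    Missing columns and negative or non-integer counts are rejected with the
    offending column or line named.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "arm": str})
    missing = [c for c in COUNT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"count table {path} is missing column(s): {', '.join(missing)}")
    count_cols = ["tumor_ref_count", "tumor_alt_count",
                  "normal_ref_count", "normal_alt_count"]
    for col in count_cols:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(
                f"invalid count {frame[col].iloc[bad.idxmax()]!r} in column "
                f"{col} at line {line} of {path}"
            )
        frame[col] = vals.astype(np.int64)
    if (frame["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")

    frame["ref"] = frame["ref"].str.upper()
    frame["alt"] = frame["alt"].str.upper()
    snp_order = frame["snp_id"].drop_duplicates().to_numpy()
    sample_order = frame["sample_id"].drop_duplicates().to_numpy()
    loci = (frame.drop_duplicates("snp_id")[["snp_id", "chrom", "pos", "arm", "ref", "alt"]]
            .set_index("snp_id").loc[snp_order].reset_index())
    if (loci["ref"] == loci["alt"]).any():
        bad_id = loci.loc[loci["ref"] == loci["alt"], "snp_id"].iloc[0]
        raise ValueError(f"ref and alt alleles must differ at {bad_id}")

    snp_pos = pd.Series(np.arange(len(snp_order)), index=snp_order)
    samp_pos = pd.Series(np.arange(len(sample_order)), index=sample_order)
    i = snp_pos[frame["snp_id"]].to_numpy()
    j = samp_pos[frame["sample_id"]].to_numpy()
    shape = (len(snp_order), len(sample_order))
    grids = {}
    for col in count_cols:
        g = np.zeros(shape, dtype=np.int64)
        g[i, j] = frame[col].to_numpy()
        grids[col] = g
    return CohortCounts(
        loci=loci, samples=[str(s) for s in sample_order],
        tumor_a=grids["tumor_ref_count"], tumor_b=grids["tumor_alt_count"],
        normal_a=grids["normal_ref_count"], normal_b=grids["normal_alt_count"],
    )


def attach_locus_annotations(cohort: CohortCounts, annotations: pd.DataFrame) -> CohortCounts:
    """Merge per-SNP gene and population MAF from an annotation table into
    the cohort's locus frame (left join on snp_id)."""
    cols = [c for c in ("snp_id", "gene", "maf") if c in annotations.columns]
    if "maf" not in cols:
        raise ValueError("annotation table must provide a maf column")
    merged = cohort.loci.drop(columns=[c for c in ("gene", "maf") if c in cohort.loci],
                              errors="ignore").merge(
        annotations[cols], on="snp_id", how="left")
    out = cohort.copy()
    out.loci = merged
    return out


def read_annotation_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"annotation table missing column(s): {', '.join(missing)}")
    return frame


def write_annotation_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_dependency_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str})
    missing = [c for c in DEPENDENCY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"dependency table missing column(s): {', '.join(missing)}")
    return frame


def write_dependency_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# locus filters


def filter_loci(cohort: CohortCounts, maf_min: float = 0.005,
                min_het: int = 10) -> tuple[CohortCounts, FilterReport]:
    """Apply the SNP inclusion filters: drop loci with population MAF below
    ``maf_min``, then loci with fewer than ``min_het`` called heterozygous
    samples. Returns the filtered cohort and a stage-by-stage report.

    Requires het flags already set and a ``maf`` column on the locus table.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError(f"maf_min must be in [0, 0.5], got {maf_min}")
    if "maf" not in cohort.loci.columns:
        raise ValueError("locus table has no maf column; attach annotations first")
    n0 = cohort.n_snps
    maf = cohort.loci["maf"].to_numpy(dtype=float)
    keep_maf = maf >= maf_min
    het_counts = cohort.is_het.sum(axis=1)
    keep_het = keep_maf & (het_counts >= min_het)
    report = FilterReport(stages=(
        ("input", n0),
        (f"maf>={maf_min}", int(keep_maf.sum())),
        (f"het_samples>={min_het}", int(keep_het.sum())),
    ))
    return cohort.subset(np.flatnonzero(keep_het)), report
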