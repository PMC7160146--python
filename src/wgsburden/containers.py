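"""In-memory containers shared across the pipeline.

A cohort is a dense samples x variants genotype matrix (int8; 0/1/2 alt
allele count, -1 missing) with parallel per-genotype DP/GQ matrices, a sample
table (phenotype, sex, covariates) and a variant table (position, alleles,
allele counts, consequence class).  SV callsets carry interval records plus
the same style of genotype matrix.  Annotation tracks bundle named interval
collections, per-bin/per-base constraint tracks, and gene models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CohortGenotypes:
    """Samples x variants genotypes with per-genotype depth and quality.

    ``samples`` is indexed by sample id and must contain a ``phenotype``
    column (1 = case, 0 = control); covariates (sex, mean_coverage, PCs) are
    additional columns. ``variants`` rows align with matrix columns.
    """

    gt: np.ndarray
    samples: pd.DataFrame
    variants: pd.DataFrame
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, m = self.gt.shape
        if len(self.samples) != n:
            raise ValueError("sample table does not match genotype rows")
        if len(self.variants) != m:
            raise ValueError("variant table does not match genotype columns")
        for name in ("dp", "gq"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != self.gt.shape:
                raise ValueError(f"{name} shape does not match genotypes")

    @property
    def n_samples(self) -> int:
        return self.gt.shape[0]

    @property
    def n_variants(self) -> int:
        return self.gt.shape[1]

    def allele_counts(self) -> np.ndarray:
        """Alt allele count per variant, recomputed from the matrix."""
        g = self.gt
        return np.where(g > 0, g, 0).sum(axis=0).astype(np.int64)

    def called_mask(self) -> np.ndarray:
        return self.gt >= 0

    def missing_rate(self) -> np.ndarray:
        return (self.gt < 0).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        called = self.called_mask()
        denom = 2 * called.sum(axis=0)
        ac = np.where(self.gt > 0, self.gt, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, ac / denom, np.nan)

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1 - f)

    def subset_variants(self, mask) -> "CohortGenotypes":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.nonzero(mask)[0]
        else:
            idx = mask
        return CohortGenotypes(
            gt=self.gt[:, idx],
            samples=self.samples,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dp=None if self.dp is None else self.dp[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
        )

    def subset_samples(self, mask) -> "CohortGenotypes":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.nonzero(mask)[0]
        else:
            idx = mask
        return CohortGenotypes(
            gt=self.gt[idx],
            samples=self.samples.iloc[idx],
            variants=self.variants,
            dp=None if self.dp is None else self.dp[idx],
            gq=None if self.gq is None else self.gq[idx],
        )


SV_TYPES = ("DEL", "DUP", "INV", "ALU", "SVA", "LINE1")


@dataclass
class SVCallSet:
    """Interval-valued variant records with per-sample genotypes.

    ``records`` columns: chrom, start, end (0-based half-open), svtype,
    pop_db_max_overlap (largest fraction of the SV covered by any same-type
    population-database SV), plus derived flags (coding, ultra_rare).
    """

    records: pd.DataFrame
    gt: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.records) != self.gt.shape[1]:
            raise ValueError("record table does not match genotype columns")
        if len(self.samples) != self.gt.shape[0]:
            raise ValueError("sample table does not match genotype rows")
        if len(self.records):
            bad = ~self.records["svtype"].isin(SV_TYPES)
            if bad.any():
                raise ValueError(
                    f"unknown svtype(s): {sorted(self.records.loc[bad, 'svtype'].unique())}"
                )
            if (self.records["end"] <= self.records["start"]).any():
                raise ValueError("SV intervals must satisfy end > start")

    @property
    def n_svs(self) -> int:
        return len(self.records)

    def carrier_counts(self) -> np.ndarray:
        """Number of carriers (non-reference genotypes) per SV."""
        return (self.gt > 0).sum(axis=0).astype(np.int64)

    def subset(self, mask) -> "SVCallSet":
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return SVCallSet(
            records=self.records.iloc[idx].reset_index(drop=True),
            gt=self.gt[:, idx],
            samples=self.samples,
        )


@dataclass
class AnnotationTrackSet:
    """Named interval tracks, constraint tracks, and gene models.

    ``intervals`` maps a track name (e.g. ``TAD_boundary``, ``ATAC_peak``,
    ``blacklist``) to a DataFrame with chrom/start/end. ``cdts`` holds one
    percentile value per contiguous 10-bp bin per chromosome; ``gerp`` one
    score per base. ``genes`` has one row per gene (gene_id, chrom, strand,
    tx_start, tx_end, tss, pli, and boolean gene-set columns); ``cds`` one
    row per coding exon (gene_id, start, end).
    """

    chrom_lengths: dict
    intervals: dict = field(default_factory=dict)
    cdts: dict = field(default_factory=dict)
    cdts_bin_size: int = 10
    gerp: dict = field(default_factory=dict)
    genes: pd.DataFrame | None = None
    cds: pd.DataFrame | None = None

    def track(self, name: str) -> pd.DataFrame:
        if name not in self.intervals:
            raise KeyError(
                f"annotation track {name!r} not present; have {sorted(self.intervals)}"
            )
        return self.intervals[name]


@dataclass
class TruthRecord:
    """Ground truth embedded by the generator, for recovery tests."""

    embedded_or_per_annotation: dict = field(default_factory=dict)
    causal_variant_ids: list = field(default_factory=list)
    true_h2: float = 0.0


@dataclass
class QCReport:
    """Audit trail of a QC pass; counts must reconcile exactly."""

    removed_samples: list = field(default_factory=list)  # (sample_id, reason)
    removed_variants: list = field(default_factory=list)  # (variant_id, reason)
    counts: dict = field(default_factory=dict)  # filter -> {"before","removed","after"}

    def log_filter(self, name: str, before: int, removed: int) -> None:
        self.counts[name] = {
            "before": before,
            "removed": removed,
            "after": before - removed,
        }

    def reconciles(self) -> bool:
        return all(
            c["before"] - c["removed"] == c["after"] for c in self.counts.values()
        )
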