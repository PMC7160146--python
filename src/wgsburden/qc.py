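"""Genotype-, variant-, and sample-level quality control.

The filter chain mirrors the QC used for deep case/control WGS callsets:
per-genotype masking at DP < 10 or GQ < 20; removal of monomorphic variants,
variants with call-rate problems overall or differentially between cases and
controls, and variants failing Hardy-Weinberg equilibrium at an FDR
threshold computed within each phenotype stratum; relatedness pruning on a
method-of-moments pi-hat; pruning of samples with outlier total ultra-rare
variant counts; and removal of SV calls mostly contained in blacklist
regions (genome gaps, segmental duplications, V(D)J loci).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .burden import bh_fdr
from .containers import CohortGenotypes, QCReport, SVCallSet

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "apply_genotype_qc",
    "hwe_exact_test",
    "filter_variants",
    "estimate_relatedness",
    "prune_related",
    "prune_urv_outliers",
    "default_urv_outlier_threshold",
    "filter_sv_blacklist",
]


@dataclass(frozen=True)
class QCThresholds:
    """Thresholds for the QC chain (defaults are the study values)."""

    min_dp: int = 10
    min_gq: int = 20
    max_missing_per_variant: float = 0.02
    max_diff_missing: float = 0.02
    diff_missing_p: float = 0.005
    hwe_fdr_controls: float = 1e-6
    hwe_fdr_cases: float = 1e-10
    relatedness_prune_burden: float = 0.2
    relatedness_prune_h2: float = 0.05
    urv_outlier_threshold: float = 6000.0
    blacklist_overlap_max: float = 0.66

    def __post_init__(self) -> None:
        for name in (
            "max_missing_per_variant",
            "max_diff_missing",
            "diff_missing_p",
            "blacklist_overlap_max",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("min_dp", "min_gq", "urv_outlier_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def default_urv_outlier_threshold(mean_urv_count: float) -> float:
    """Scale the 6000-count outlier threshold to a different URV depth.

    The published cutoff of 6000 sits 1.5x the relative excursion above a
    per-sample mean near 4250; for cohorts simulated at other depths the
    default scales the same relative excursion: mean * (1 + 1.5*(6000/4250 - 1)).
    """
    t = mean_urv_count * (1.0 + 1.5 * (6000.0 / 4250.0 - 1.0))
    logger.info("URV outlier threshold scaled to %.1f (mean %.1f)", t, mean_urv_count)
    return t


def apply_genotype_qc(
    cohort: CohortGenotypes, thresholds: QCThresholds = QCThresholds()
) -> CohortGenotypes:
    """Mask genotypes with DP below min_dp or GQ below min_gq as missing.

    Boundary is inclusive: DP == min_dp and GQ == min_gq are retained.
    No other genotype is altered.
    """
    if cohort.dp is None:
        raise ValueError("per-genotype DP is required for genotype QC")
    if cohort.gq is None:
        raise ValueError("per-genotype GQ is required for genotype QC")
    fail = (cohort.dp < thresholds.min_dp) | (cohort.gq < thresholds.min_gq)
    gt = cohort.gt.copy()
    gt[fail & (gt >= 0)] = -1
    return CohortGenotypes(
        gt=gt, samples=cohort.samples, variants=cohort.variants,
        dp=cohort.dp, gq=cohort.gq,
    )


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test (two-sided, not mid-p).

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    the observed one.  Symmetric in allele relabelling; a monomorphic site
    has a single possible table and p = 1.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(int(c) != c or c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotype must be observed")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0:
        return 1.0
    hets, logp = _hwe_log_probs(n, n_rare)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    # tolerance guards against ties lost to floating-point rounding
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _hwe_log_probs(n: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    from scipy.special import gammaln

    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    homr = (n_rare - hets) // 2
    homc = n - hets - homr
    logp = (
        hets * math.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    return hets, logp


def filter_variants(
    cohort: CohortGenotypes, thresholds: QCThresholds = QCThresholds()
) -> tuple[CohortGenotypes, QCReport]:
    """Variant-level filters applied after genotype QC.

    Removal order: monomorphic; overall missing rate > threshold;
    case/control missing-rate difference > threshold or Fisher p below the
    differential-missingness level; BH-adjusted HWE p (within controls, then
    within cases, each across all variants entering that filter) below the
    per-stratum FDR threshold.  The chain is idempotent.
    """
    pheno = cohort.samples["phenotype"].to_numpy()
    is_case = pheno == 1
    is_ctrl = pheno == 0
    if is_case.sum() == 0 or is_ctrl.sum() == 0:
        raise ValueError("both cases and controls are required")

    report = QCReport()
    keep = np.ones(cohort.n_variants, dtype=bool)
    var_ids = (
        cohort.variants["variant_id"]
        if "variant_id" in cohort.variants
        else pd.Series([f"var{i}" for i in range(cohort.n_variants)])
    )

    def drop(mask: np.ndarray, reason: str) -> None:
        mask = mask & keep
        for vid in var_ids[mask]:
            report.removed_variants.append((vid, reason))
        report.log_filter(reason, int(keep.sum()), int(mask.sum()))
        keep[mask] = False

    gt = cohort.gt
    called = gt >= 0

    ac = np.where(gt > 0, gt, 0).sum(axis=0)
    an = 2 * called.sum(axis=0)
    drop((ac == 0) | (ac == an), "monomorphic")

    miss = (~called).mean(axis=0)
    drop(miss > thresholds.max_missing_per_variant, "missing_rate")

    miss_case = (~called[is_case]).mean(axis=0)
    miss_ctrl = (~called[is_ctrl]).mean(axis=0)
    diff_bad = np.abs(miss_case - miss_ctrl) > thresholds.max_diff_missing
    # Fisher exact on called/missing x case/control, only where it can matter
    fisher_bad = np.zeros_like(diff_bad)
    todo = np.nonzero(keep & ~diff_bad & ((miss_case > 0) | (miss_ctrl > 0)))[0]
    n_case, n_ctrl = int(is_case.sum()), int(is_ctrl.sum())
    for j in todo:
        mc = int(round(miss_case[j] * n_case))
        mk = int(round(miss_ctrl[j] * n_ctrl))
        p = stats.fisher_exact(
            [[n_case - mc, mc], [n_ctrl - mk, mk]], alternative="two-sided"
        )[1]
        fisher_bad[j] = p < thresholds.diff_missing_p
    drop(diff_bad | fisher_bad, "differential_missingness")

    for stratum, fdr in (
        (is_ctrl, thresholds.hwe_fdr_controls),
        (is_case, thresholds.hwe_fdr_cases),
    ):
        idx = np.nonzero(keep)[0]
        if idx.size == 0:
            break
        sub = gt[stratum][:, idx]
        p_hwe = np.array(
            [
                hwe_exact_test(
                    int((sub[:, k] == 0).sum()),
                    int((sub[:, k] == 1).sum()),
                    int((sub[:, k] == 2).sum()),
                )
                for k in range(idx.size)
            ]
        )
        adj = bh_fdr(p_hwe)
        bad = np.zeros(cohort.n_variants, dtype=bool)
        bad[idx[adj < fdr]] = True
        name = "hwe_controls" if stratum is is_ctrl else "hwe_cases"
        drop(bad, name)

    return cohort.subset_variants(keep), report


def estimate_relatedness(
    cohort: CohortGenotypes,
    variant_mask: np.ndarray | None = None,
    min_maf: float = 0.05,
) -> pd.DataFrame:
    """Pairwise method-of-moments relatedness (pi-hat).

    Standardized-genotype moment estimator over common (MAF >= min_maf)
    variants: pi_jk = mean_i (x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i (1 - p_i)).
    Residual missingness is mean-imputed.  Self pairs sit near 1, duplicate
    pairs near/above 1, parent-child near 0.5, unrelated pairs near 0; small
    negative excursions are expected from sampling noise.
    """
    gt = cohort.gt.astype(float)
    gt[gt < 0] = np.nan
    if variant_mask is not None:
        gt = gt[:, np.asarray(variant_mask)]
    freq = np.nanmean(gt, axis=0) / 2
    common = (np.minimum(freq, 1 - freq) >= min_maf) & (freq > 0) & (freq < 1)
    gt = gt[:, common]
    freq = freq[common]
    if gt.shape[1] < 50:
        logger.warning(
            "relatedness estimated from %d variants (<50): unstable", gt.shape[1]
        )
    z = (gt - 2 * freq) / np.sqrt(2 * freq * (1 - freq))
    z = np.where(np.isnan(z), 0.0, z)  # mean imputation in standardized space
    pihat = (z @ z.T) / gt.shape[1]
    ids = cohort.samples.index
    return pd.DataFrame(pihat, index=ids, columns=ids)


def prune_related(
    pihat: pd.DataFrame,
    threshold: float = 0.2,
    missingness: pd.Series | None = None,
) -> list:
    """Kept-sample ids with no remaining pair above the pi-hat threshold.

    Greedy: repeatedly remove the sample involved in the most remaining
    above-threshold pairs, breaking ties by higher overall missingness, then
    by lexicographically larger id.
    """
    ids = list(pihat.index)
    mat = pihat.to_numpy().copy()
    np.fill_diagonal(mat, 0.0)
    removed: set = set()
    while True:
        active = [i for i, s in enumerate(ids) if s not in removed]
        sub = mat[np.ix_(active, active)]
        over = sub > threshold
        if not over.any():
            break
        degree = over.sum(axis=1)
        cand = np.nonzero(degree == degree.max())[0]

        def key(k: int):
            sid = ids[active[k]]
            m = 0.0 if missingness is None else float(missingness.get(sid, 0.0))
            return (m, str(sid))

        worst = max(cand, key=key)
        removed.add(ids[active[worst]])
    return [s for s in ids if s not in removed]


def prune_urv_outliers(
    urv_counts: pd.Series, threshold: float = 6000.0,
    phenotype: pd.Series | None = None,
) -> pd.Index:
    """Sample ids whose total URV count does not exceed the threshold.

    Strict inequality: a count exactly at the threshold is kept.  Removal
    counts per phenotype are logged when a phenotype series is supplied.
    """
    keep = urv_counts <= threshold
    if phenotype is not None and (~keep).any():
        for label, grp in phenotype[~keep].groupby(phenotype[~keep]):
            logger.info("URV outlier pruning removed %d samples (phenotype=%s)",
                        len(grp), label)
    return urv_counts.index[keep]


def filter_sv_blacklist(
    svset: SVCallSet,
    blacklist: pd.DataFrame,
    max_fraction: float = 0.66,
) -> tuple[SVCallSet, QCReport]:
    """Remove SVs mostly contained in blacklist regions.

    An SV is removed iff the union of its intersections with blacklist
    intervals covers strictly more than ``max_fraction`` of its length
    (66% exactly is retained).
    """
    report = QCReport()
    n = svset.n_svs
    keep = np.ones(n, dtype=bool)
    bl_by_chrom = {c: g for c, g in blacklist.groupby("chrom")}
    for j, row in svset.records.iterrows():
        bl = bl_by_chrom.get(row["chrom"])
        if bl is None:
            continue
        s, e = int(row["start"]), int(row["end"])
        ov_s = np.maximum(bl["start"].to_numpy(), s)
        ov_e = np.minimum(bl["end"].to_numpy(), e)
        seg = [(a, b) for a, b in zip(ov_s, ov_e) if b > a]
        if not seg:
            continue
        covered = _union_length(seg)
        if covered / (e - s) > max_fraction:
            keep[j] = False
            report.removed_variants.append((j, "blacklist_overlap"))
    report.log_filter("blacklist_overlap", n, int((~keep).sum()))
    return svset.subset(keep), report


def _union_length(segments: list) -> int:
    segments = sorted(segments)
    total, cur_s, cur_e = 0, *segments[0]
    for s, e in segments[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)
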