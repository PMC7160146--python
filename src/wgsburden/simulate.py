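"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a deep-WGS case/control study: a cohort of ~1162
cases and ~936 controls; ultra-rare SNV/indels that are cohort singletons
(heterozygous in exactly one subject) at ~4250 per sample with a heavy
right tail of outlier samples; singleton fractions near 45% (SNVs) and 37%
(indels); structural variants with log-normal sizes matching the published
per-type medians, truncated to 500 bp - 1 Mb; annotation tracks (40-kb TAD
boundaries, 10-bp CDTS bins, per-base GERP, gene models with pLI and
gene-set flags, a blacklist); and liability-threshold phenotypes at 1%
lifetime risk.  Known effects (an odds ratio on URVs or SVs hitting a named
annotation, a true h2) are embedded and recorded in a TruthRecord so the
downstream modules can be tested for recovery.

All randomness flows from one seed through named, logged substreams, so an
identical configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import AnnotationTrackSet, CohortGenotypes, SVCallSet, TruthRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "ConfigurationError",
    "simulate_annotation_genome",
    "simulate_snv_cohort",
    "simulate_sv_cohort",
    "simulate_liability_phenotype",
    "simulate_genotypes",
    "sample_case_control",
]


class ConfigurationError(ValueError):
    pass


_DEFAULT_SV_COUNTS = {"DEL": 17895, "DUP": 4129, "INV": 4458}
_DEFAULT_SV_MEDIANS = {
    "DEL": 2592, "DUP": 7179, "INV": 3265,
    "ALU": 279, "SVA": 1162, "LINE1": 1780,
}
_SV_SIGMA = {"DEL": 1.0, "DUP": 1.0, "INV": 1.2, "ALU": 0.5, "SVA": 0.6, "LINE1": 0.7}
_SV_BOUNDS = {
    "DEL": (500, 1_000_000), "DUP": (500, 1_000_000), "INV": (500, 1_000_000),
    "ALU": (15, 6019), "SVA": (15, 6019), "LINE1": (15, 6019),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults are the conditions of the study being emulated: 1162 cases /
    936 controls, singleton fractions 45.43% / 37.03% (SNV / indel), ~4250
    ultra-rare variants per sample, the published per-type SV counts and
    size medians, lifetime risk 1%.  Scale `n_*`, `mean_urv_per_sample` and
    the track geometry down for desk-size runs; the statistical structure is
    preserved.
    """

    n_cases: int = 1162
    n_controls: int = 936
    n_chromosomes: int = 4
    chrom_length: int = 10_000_000
    snv_singleton_fraction: float = 0.4543
    indel_singleton_fraction: float = 0.3703
    mean_urv_per_sample: float = 4250.0
    outlier_fraction: float = 0.035
    outlier_urv_multiplier: float = 1.6
    sv_counts_per_type: dict = field(default_factory=lambda: dict(_DEFAULT_SV_COUNTS))
    sv_size_median_per_type: dict = field(
        default_factory=lambda: dict(_DEFAULT_SV_MEDIANS)
    )
    annotation_burden_or: float = 1.0
    target_annotation: str = "TAD_boundary"
    h2_liability: float = 0.5
    prevalence_K: float = 0.01
    seed: int = 0
    # generator mechanics (documented defaults; not study-reported numbers)
    indel_fraction: float = 0.12
    external_absent_fraction: float = 0.90
    genotype_qc_fail_fraction: float = 0.002
    n_target_urvs: int = 2000
    n_target_svs: int = 200
    sv_ultra_rare_fraction: float = 0.35
    tad_bin_bp: int = 40_000
    tad_boundary_fraction: float = 0.10
    genes_per_mb: float = 8.0
    blacklist_fraction: float = 0.02
    mean_coverage: float = 36.6

    def __post_init__(self) -> None:
        props = {
            "snv_singleton_fraction": self.snv_singleton_fraction,
            "indel_singleton_fraction": self.indel_singleton_fraction,
            "outlier_fraction": self.outlier_fraction,
            "indel_fraction": self.indel_fraction,
            "external_absent_fraction": self.external_absent_fraction,
            "genotype_qc_fail_fraction": self.genotype_qc_fail_fraction,
            "sv_ultra_rare_fraction": self.sv_ultra_rare_fraction,
            "tad_boundary_fraction": self.tad_boundary_fraction,
            "blacklist_fraction": self.blacklist_fraction,
            "h2_liability": self.h2_liability,
        }
        for name, v in props.items():
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_cases < 2 or self.n_controls < 2:
            raise ConfigurationError("n_cases and n_controls must be >= 2")
        if self.annotation_burden_or < 1:
            raise ConfigurationError("annotation_burden_or must be >= 1")
        if not 0 < self.prevalence_K < 0.5:
            raise ConfigurationError("prevalence_K must be in (0, 0.5)")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def chrom_names(self) -> list:
        return [str(i + 1) for i in range(self.n_chromosomes)]


def _rngs(seed: int, *names: str) -> dict:
    """Named substreams split from one seed (logged for reproducibility)."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    logger.debug("rng substreams from seed %d: %s", seed, ", ".join(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# annotation genome


def simulate_annotation_genome(config: SimulationConfig) -> AnnotationTrackSet:
    """Annotation tracks, constraint tracks and gene models.

    TAD-boundary intervals are whole 40-kb bins (a random subset of the
    contiguous candidate bins); the CDTS track tiles each chromosome in
    10-bp bins with percentile values uniform on (0, 100]; GERP is a
    per-base draw; gene models carry CDS exons, a TSS, pLI and boolean
    gene-set flags; a blacklist track marks artefact-prone regions.
    """
    bin_bp = config.tad_bin_bp
    if config.chrom_length % bin_bp != 0:
        raise ConfigurationError(
            f"chrom_length {config.chrom_length} not divisible by TAD bin {bin_bp}"
        )
    if config.chrom_length % 10 != 0:
        raise ConfigurationError("chrom_length must be divisible by the 10-bp CDTS bin")
    r = _rngs(config.seed, "tads", "cdts", "gerp", "genes", "blacklist", "tracks")

    chroms = config.chrom_names
    L = config.chrom_length

    tad_rows, bl_rows, atac_rows = [], [], []
    cdts, gerp = {}, {}
    gene_rows, cds_rows = [], []
    gid = 0
    for chrom in chroms:
        n_bins = L // bin_bp
        n_bound = int(round(n_bins * config.tad_boundary_fraction))
        picks = np.sort(r["tads"].choice(n_bins, size=n_bound, replace=False))
        for b in picks:
            tad_rows.append((chrom, int(b) * bin_bp, (int(b) + 1) * bin_bp))

        # (0, 100]: flip the half-open side of random()
        cdts[chrom] = (100.0 * (1.0 - r["cdts"].random(L // 10))).astype(np.float32)
        gerp[chrom] = r["gerp"].normal(0.0, 2.0, size=L).astype(np.float32)

        n_genes = max(1, int(round(config.genes_per_mb * L / 1e6)))
        slot = L // n_genes
        for i in range(n_genes):
            span = int(r["genes"].integers(5_000, min(60_000, max(6_000, slot - 1_000))))
            start = i * slot + int(r["genes"].integers(0, max(1, slot - span)))
            end = start + span
            strand = "+" if r["genes"].random() < 0.5 else "-"
            tss = start if strand == "+" else end
            pli = float(r["genes"].beta(0.25, 0.25))
            name = f"G{gid:05d}"
            gene_rows.append(
                (
                    name, chrom, strand, start, end, tss, pli,
                    bool(r["genes"].random() < 0.05),  # neurodev risk set
                    bool(r["genes"].random() < 0.08),  # brain-expressed set
                )
            )
            n_ex = int(r["genes"].integers(2, 9))
            bounds = np.sort(r["genes"].choice(np.arange(start, end), 2 * n_ex, replace=False))
            for e in range(n_ex):
                s, t = int(bounds[2 * e]), int(bounds[2 * e + 1])
                if t > s:
                    cds_rows.append((name, chrom, s, t))
            gid += 1

        n_bl = max(1, int(round(config.blacklist_fraction * L / 50_000)))
        for _ in range(n_bl):
            s = int(r["blacklist"].integers(0, L - 50_000))
            bl_rows.append((chrom, s, s + 50_000))

        for _ in range(int(L // 200_000)):
            s = int(r["tracks"].integers(0, L - 500))
            atac_rows.append((chrom, s, s + int(r["tracks"].integers(200, 501))))

    def df(rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "chrom", "strand", "tx_start", "tx_end", "tss", "pli",
                 "set_neurodev", "set_brain_expressed"],
    )
    cds = pd.DataFrame(cds_rows, columns=["gene_id", "chrom", "start", "end"])
    return AnnotationTrackSet(
        chrom_lengths={c: L for c in chroms},
        intervals={
            "TAD_boundary": df(tad_rows),
            "blacklist": df(bl_rows),
            "ATAC_peak": df(atac_rows),
        },
        cdts=cdts,
        gerp=gerp,
        genes=genes,
        cds=cds,
    )


# ---------------------------------------------------------------------------
# SNV/indel cohort


def _sample_positions(rng, n, tracks, config, inside: pd.DataFrame | None):
    """Uniform positions (chrom, 0-based pos) inside or outside a track."""
    chroms = np.array(config.chrom_names)
    L = config.chrom_length
    if inside is None:
        c = rng.integers(0, chroms.size, size=n)
        return chroms[c], rng.integers(0, L, size=n)
    widths = (inside["end"] - inside["start"]).to_numpy()
    pick = rng.choice(len(inside), size=n, p=widths / widths.sum())
    offs = (rng.random(n) * widths[pick]).astype(np.int64)
    return (
        inside["chrom"].to_numpy()[pick],
        inside["start"].to_numpy()[pick] + offs,
    )


def _in_track(chroms, pos, track: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for chrom, grp in track.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = np.sort(grp["start"].to_numpy())
        ends = grp.sort_values("start")["end"].to_numpy()
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[sel][ok] < ends[idx[ok]]
        mask[np.nonzero(sel)[0]] = ok
    return mask


_BASES = np.array(list("ACGT"))


def simulate_snv_cohort(
    config: SimulationConfig, tracks: AnnotationTrackSet
) -> tuple[CohortGenotypes, TruthRecord]:
    """SNV/indel cohort with singletons, external ACs, DP/GQ and embedded burden.

    Singletons are heterozygous in exactly one subject. Ultra-rare variants
    (singleton + absent externally) arrive at `mean_urv_per_sample` per
    subject, multiplied for a fraction of outlier subjects; URVs inside the
    target annotation are generated at a case:control per-sample rate ratio
    equal to ``annotation_burden_or`` (the remainder land outside it).
    Non-singleton variants fill the variant table up to the configured
    singleton fractions, with HWE genotypes at a skewed MAF distribution.
    """
    if config.target_annotation not in tracks.intervals:
        raise ConfigurationError(
            f"target annotation {config.target_annotation!r} not in tracks"
        )
    r = _rngs(
        config.seed,
        "samples", "counts", "positions", "alleles", "genotypes", "dpgq", "external",
    )
    n = config.n_samples
    pheno = np.zeros(n, dtype=np.int8)
    pheno[: config.n_cases] = 1
    outlier = r["samples"].random(n) < config.outlier_fraction
    pc1 = 1.2 * outlier + r["samples"].normal(0, 1, n)
    pc2 = 0.15 * (pheno - pheno.mean()) + r["samples"].normal(0, 1, n)
    pc3 = r["samples"].normal(0, 1, n)
    samples = pd.DataFrame(
        {
            "phenotype": pheno,
            "sex": r["samples"].integers(0, 2, n).astype(np.int8),
            "mean_coverage": r["samples"].normal(config.mean_coverage, 2.5, n),
            "PC1": pc1,
            "PC2": pc2,
            "PC3": pc3,
            "is_outlier": outlier,
        },
        index=pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id"),
    )

    target_track = tracks.track(config.target_annotation)
    orr = config.annotation_burden_or
    lam0 = config.n_target_urvs / (config.n_controls + orr * config.n_cases)
    target_counts = r["counts"].poisson(lam0 * np.where(pheno == 1, orr, 1.0))
    base_rate = config.mean_urv_per_sample * np.where(
        outlier, config.outlier_urv_multiplier, 1.0
    )
    other_counts = r["counts"].poisson(np.maximum(base_rate - lam0 * orr, 0.0))

    # carriers sample-by-sample -> flat lists of (carrier, is_target)
    carrier_t = np.repeat(np.arange(n), target_counts)
    carrier_o = np.repeat(np.arange(n), other_counts)
    n_urv = carrier_t.size + carrier_o.size

    # non-URV singletons (externally seen) and non-singleton fill
    p_abs = config.external_absent_fraction
    n_sing_ext = int(round(n_urv * (1 - p_abs) / p_abs))
    n_sing = n_urv + n_sing_ext
    is_indel_sing = r["alleles"].random(n_sing) < config.indel_fraction
    s_indel = int(is_indel_sing.sum())
    s_snv = n_sing - s_indel
    m_ns_snv = int(round(s_snv * (1 / config.snv_singleton_fraction - 1)))
    m_ns_indel = int(round(s_indel * (1 / config.indel_singleton_fraction - 1)))
    m_ns = m_ns_snv + m_ns_indel

    # --- positions
    chrom_t, pos_t = _sample_positions(
        r["positions"], carrier_t.size, tracks, config, target_track
    )
    chrom_rest, pos_rest = _sample_positions(
        r["positions"], carrier_o.size + n_sing_ext + m_ns, tracks, config, None
    )
    # push the non-target draws that landed inside the target region out of it
    in_t = _in_track(chrom_rest, pos_rest, target_track)
    while in_t.any():
        c2, p2 = _sample_positions(r["positions"], int(in_t.sum()), tracks, config, None)
        chrom_rest[in_t], pos_rest[in_t] = c2, p2
        in_t = _in_track(chrom_rest, pos_rest, target_track)

    chroms = np.concatenate([chrom_t, chrom_rest])
    pos = np.concatenate([pos_t, pos_rest])
    m = chroms.size
    is_singleton = np.zeros(m, dtype=bool)
    is_singleton[:n_sing] = True
    is_urv_slot = np.zeros(m, dtype=bool)
    is_urv_slot[:n_urv] = True
    is_target_slot = np.zeros(m, dtype=bool)
    is_target_slot[: carrier_t.size] = True

    # --- variant class and alleles
    is_indel = np.zeros(m, dtype=bool)
    is_indel[:n_sing] = is_indel_sing
    ns_order = np.arange(n_sing, m)
    is_indel[ns_order[:m_ns_snv]] = False
    is_indel[ns_order[m_ns_snv:]] = True

    ref = _BASES[r["alleles"].integers(0, 4, m)]
    alt = _BASES[r["alleles"].integers(0, 4, m)]
    same = ref == alt
    alt[same] = _BASES[(np.searchsorted(_BASES, alt[same]) + 1) % 4]
    ref = ref.astype(object)
    alt = alt.astype(object)
    ins = is_indel & (r["alleles"].random(m) < 0.5)
    for i in np.nonzero(is_indel)[0]:
        extra = "".join(r["alleles"].choice(list("ACGT"), size=int(r["alleles"].integers(1, 6))))
        if ins[i]:
            alt[i] = str(ref[i]) + extra
        else:
            ref[i] = str(ref[i]) + extra

    # --- genotypes
    gt = np.zeros((n, m), dtype=np.int8)
    carriers_sing = np.concatenate(
        [carrier_t, carrier_o, r["genotypes"].integers(0, n, size=n_sing_ext)]
    )
    gt[carriers_sing, np.arange(n_sing)] = 1
    maf_min = min(0.05, max(0.005, 3.0 / n))
    mafs_ns = maf_min + (0.5 - maf_min) * r["genotypes"].beta(0.6, 2.5, size=m_ns)
    gt[:, n_sing:] = r["genotypes"].binomial(2, mafs_ns, size=(n, m_ns)).astype(np.int8)

    # --- DP / GQ
    dp = (10 + r["dpgq"].poisson(config.mean_coverage - 10, size=(n, m))).astype(np.int16)
    gq = r["dpgq"].integers(20, 100, size=(n, m), dtype=np.int16).astype(np.int16)
    fail = r["dpgq"].random((n, m)) < config.genotype_qc_fail_fraction
    which = r["dpgq"].integers(0, 3, size=int(fail.sum()))
    fi, fj = np.nonzero(fail)
    low_dp = which != 1
    low_gq = which != 0
    dp[fi[low_dp], fj[low_dp]] = r["dpgq"].integers(0, 10, size=int(low_dp.sum()))
    gq[fi[low_gq], fj[low_gq]] = r["dpgq"].integers(0, 20, size=int(low_gq.sum()))

    # --- external allele counts
    ac_gnomad = np.zeros(m, dtype=np.int32)
    ac_exac = np.zeros(m, dtype=np.int32)
    ext = slice(n_urv, n_sing)
    n_ext = n_sing - n_urv
    ac_gnomad[ext] = 1 + r["external"].poisson(2.0, size=n_ext)
    ac_exac[ext] = r["external"].poisson(1.0, size=n_ext)
    ac_gnomad[n_sing:] = r["external"].poisson(2 * 15000 * mafs_ns)
    ac_exac[n_sing:] = r["external"].poisson(2 * 5000 * mafs_ns)

    # --- consequence classes from gene models
    in_cds = (
        _in_track(chroms, pos, tracks.cds[["chrom", "start", "end"]])
        if tracks.cds is not None and len(tracks.cds)
        else np.zeros(m, dtype=bool)
    )
    consequence = np.array(["noncoding"] * m, dtype=object)
    coding_idx = np.nonzero(in_cds)[0]
    consequence[coding_idx] = r["alleles"].choice(
        ["synonymous", "missense_nondamaging", "missense_damaging", "LOF"],
        size=coding_idx.size,
        p=[0.30, 0.35, 0.15, 0.20],
    )

    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i:08d}" for i in range(m)],
            "chrom": chroms,
            "pos": pos + 1,  # expose 1-based positions, VCF style
            "ref": ref,
            "alt": alt,
            "variant_class": np.where(is_indel, "indel", "SNV"),
            "consequence_class": consequence,
            "ac_gnomad": ac_gnomad,
            "ac_exac": ac_exac,
            "is_target_truth": is_target_slot,
        }
    )
    variants["cohort_ac"] = np.where(gt > 0, gt, 0).sum(axis=0)

    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)
    cohort = CohortGenotypes(
        gt=gt[:, order], samples=samples, variants=variants,
        dp=dp[:, order], gq=gq[:, order],
    )
    truth = TruthRecord(
        embedded_or_per_annotation={config.target_annotation: orr},
        causal_variant_ids=list(variants.loc[variants["is_target_truth"], "variant_id"]),
        true_h2=config.h2_liability,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# SV cohort


def _truncated_lognormal_sizes(rng, n, median, sigma, lo, hi):
    """Sizes whose truncated distribution has the requested median."""
    a = np.log(lo)
    b = np.log(hi)
    if not lo < median < hi:
        raise ConfigurationError(f"median {median} outside bounds [{lo}, {hi}]")

    def med_gap(mu):
        za, zb = (a - mu) / sigma, (b - mu) / sigma
        mid = (stats.norm.cdf(za) + stats.norm.cdf(zb)) / 2
        return mu + sigma * stats.norm.ppf(mid) - np.log(median)

    mu = optimize.brentq(med_gap, np.log(median) - 6 * sigma, np.log(median) + 6 * sigma)
    za, zb = (a - mu) / sigma, (b - mu) / sigma
    u = stats.norm.cdf(za) + rng.random(n) * (stats.norm.cdf(zb) - stats.norm.cdf(za))
    return np.exp(mu + sigma * stats.norm.ppf(u)).astype(np.int64).clip(lo, hi)


def simulate_sv_cohort(
    config: SimulationConfig, tracks: AnnotationTrackSet
) -> tuple[SVCallSet, TruthRecord]:
    """SV callset with per-type truncated log-normal sizes and embedded burden.

    Each type's size distribution is log-normal with mu solved so that the
    *truncated* median equals the configured median (bounds 500 bp - 1 Mb
    for DEL/DUP/INV, 15 bp - 6 kb for mobile elements). A configured
    fraction of calls is designated ultra-rare (single carrier, population
    overlap < 30%); ``n_target_svs`` additional ultra-rare calls are placed
    to cover >= 10% of a target-annotation element, with carriers drawn at a
    case:control ratio implied by ``annotation_burden_or``.
    """
    r = _rngs(config.seed, "sv_sizes", "sv_pos", "sv_gt", "sv_pop", "sv_target")
    n = config.n_samples
    pheno = np.zeros(n, dtype=np.int8)
    pheno[: config.n_cases] = 1
    samples = pd.DataFrame(
        {"phenotype": pheno},
        index=pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id"),
    )
    chroms = np.array(config.chrom_names)
    L = config.chrom_length

    rows = []
    gts = []
    for svtype, count in config.sv_counts_per_type.items():
        if count == 0:
            continue
        median = config.sv_size_median_per_type[svtype]
        lo, hi = _SV_BOUNDS[svtype]
        sizes = _truncated_lognormal_sizes(
            r["sv_sizes"], count, median, _SV_SIGMA[svtype], lo, min(hi, L // 2)
        )
        c_idx = r["sv_pos"].integers(0, chroms.size, size=count)
        starts = (r["sv_pos"].random(count) * (L - sizes)).astype(np.int64)
        is_ur = r["sv_gt"].random(count) < config.sv_ultra_rare_fraction
        pop_ov = np.where(
            is_ur,
            0.30 * r["sv_pop"].random(count),
            0.30 + 0.70 * r["sv_pop"].random(count),
        )
        gt = np.zeros((n, count), dtype=np.int8)
        carriers_ur = r["sv_gt"].integers(0, n, size=int(is_ur.sum()))
        gt[carriers_ur, np.nonzero(is_ur)[0]] = 1
        common_idx = np.nonzero(~is_ur)[0]
        freqs = 0.002 + 0.25 * r["sv_gt"].beta(0.4, 6.0, size=common_idx.size)
        gt[:, common_idx] = r["sv_gt"].binomial(
            2, freqs, size=(n, common_idx.size)
        ).astype(np.int8)
        for k in range(count):
            rows.append(
                (chroms[c_idx[k]], int(starts[k]), int(starts[k] + sizes[k]),
                 svtype, float(pop_ov[k]), False)
            )
        gts.append(gt)

    # embedded target SVs: ultra-rare, >=10% coverage of a target element
    truth_ids = []
    if config.n_target_svs > 0:
        target = tracks.track(config.target_annotation)
        orr = config.annotation_burden_or
        p_case = orr * config.n_cases / (orr * config.n_cases + config.n_controls)
        types = r["sv_target"].choice(["DEL", "DUP", "INV"], size=config.n_target_svs,
                                      p=[0.6, 0.2, 0.2])
        gt = np.zeros((n, config.n_target_svs), dtype=np.int8)
        for k in range(config.n_target_svs):
            el = target.iloc[int(r["sv_target"].integers(0, len(target)))]
            el_len = int(el["end"] - el["start"])
            lo, hi = _SV_BOUNDS[types[k]]
            size = int(
                _truncated_lognormal_sizes(
                    r["sv_target"], 1, config.sv_size_median_per_type[types[k]],
                    _SV_SIGMA[types[k]], lo, min(hi, L // 2),
                )[0]
            )
            size = max(size, int(np.ceil(0.12 * el_len)))
            # start range guaranteeing overlap >= 10% of the element
            need = int(np.ceil(0.10 * el_len))
            s_min = max(0, int(el["start"]) - (size - need))
            s_max = min(L - size, int(el["end"]) - need)
            s = int(r["sv_target"].integers(s_min, max(s_min + 1, s_max + 1)))
            if r["sv_target"].random() < p_case:
                carrier = int(r["sv_target"].integers(0, config.n_cases))
            else:
                carrier = config.n_cases + int(
                    r["sv_target"].integers(0, config.n_controls)
                )
            gt[carrier, k] = 1
            rows.append(
                (str(el["chrom"]), s, s + size, types[k],
                 float(0.30 * r["sv_target"].random()), True)
            )
            truth_ids.append(len(rows) - 1)
        gts.append(gt)

    records = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "svtype", "pop_db_max_overlap",
                       "is_target_truth"],
    )
    gt_all = np.concatenate(gts, axis=1) if gts else np.zeros((n, 0), dtype=np.int8)
    svset = SVCallSet(records=records, gt=gt_all, samples=samples)
    truth = TruthRecord(
        embedded_or_per_annotation={config.target_annotation: config.annotation_burden_or},
        causal_variant_ids=truth_ids,
        true_h2=config.h2_liability,
    )
    return svset, truth


# ---------------------------------------------------------------------------
# phenotypes and raw genotypes


def simulate_genotypes(
    n: int, m: int, rng, maf_low: float = 0.01, maf_high: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """HWE genotypes at uniform MAFs; returns (genotypes, mafs)."""
    mafs = rng.uniform(maf_low, maf_high, size=m)
    g = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)
    return g, mafs


def simulate_liability_phenotype(
    genotypes: np.ndarray,
    h2: float,
    K: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, TruthRecord]:
    """Liability-threshold phenotype from standardized genotypes.

    Per-variant effects are normal with total additive variance h2 (the
    realized genetic values are rescaled to exactly that variance); the
    residual is normal with variance 1 - h2; a subject is a case iff its
    liability exceeds the (1 - K) quantile of the realized liability
    distribution.  Returns (labels, liability, truth).
    """
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must be in [0, 1]")
    rng = np.random.default_rng(seed)
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    p = G.mean(axis=0) / 2
    ok = (p > 0) & (p < 1)
    Z = np.zeros_like(G)
    Z[:, ok] = (G[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
    if h2 > 0:
        beta = rng.normal(0.0, np.sqrt(h2 / m), size=m)
        g = Z @ beta
        sd = g.std()
        if sd > 0:
            g *= np.sqrt(h2) / sd
    else:
        g = np.zeros(n)
    e = rng.normal(0.0, np.sqrt(1.0 - h2), size=n)
    liab = g + e
    thresh = np.quantile(liab, 1.0 - K)
    labels = (liab > thresh).astype(np.int8)
    return labels, liab, TruthRecord(true_h2=h2)


def sample_case_control(
    labels: np.ndarray, n_cases: int, n_controls: int, seed: int
) -> np.ndarray:
    """Indices oversampling cases to the target design (without replacement)."""
    rng = np.random.default_rng(seed)
    cases = np.nonzero(labels == 1)[0]
    ctrls = np.nonzero(labels == 0)[0]
    if cases.size < n_cases or ctrls.size < n_controls:
        raise ValueError("not enough cases/controls to reach the target design")
    idx = np.concatenate(
        [rng.choice(cases, n_cases, replace=False),
         rng.choice(ctrls, n_controls, replace=False)]
    )
    return np.sort(idx)
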