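"""Frequency-class, consequence, constraint and region labels for variants.

An ultra-rare variant (URV) is a cohort singleton (allele count exactly 1)
absent from every external population source (allele count 0 in each).
Consequence classes for SNV/indels are consumed as inputs (synonymous,
missense non-damaging, missense damaging, loss-of-function, noncoding);
coding status for SVs is computed here, including the inversion breakpoint
logic (an inversion that flips a whole gene with intergenic breakpoints is
noncoding). Constraint uses the human-population CDTS percentile (mean over
spanned 10-bp bins, constrained below 1%) and cross-species GERP (maximum
over the span, constrained at >= 4).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AnnotationTrackSet, CohortGenotypes, SVCallSet
from .intervals import overlap_bases

__all__ = [
    "flag_ultra_rare",
    "flag_ultra_rare_sv",
    "classify_sv_coding",
    "constrained_mask",
    "promoter_intervals",
    "gene_region_intervals",
    "count_per_sample",
    "count_per_sample_sv",
]

CONSEQUENCE_CLASSES = (
    "synonymous",
    "missense_nondamaging",
    "missense_damaging",
    "LOF",
    "noncoding",
)


def flag_ultra_rare(
    variants: pd.DataFrame, external_sources: list | None = None
) -> np.ndarray:
    """URV flag per SNV/indel row.

    True iff ``cohort_ac == 1`` and the allele count is 0 in every external
    source column (``ac_<source>``). Raises when a required source column is
    absent, listing what is missing.
    """
    if external_sources is None:
        external_sources = [
            c.removeprefix("ac_") for c in variants.columns if c.startswith("ac_")
        ]
        if not external_sources:
            raise ValueError("no external allele-count columns (ac_*) found")
    missing = [s for s in external_sources if f"ac_{s}" not in variants.columns]
    if missing:
        raise ValueError(f"missing external AC sources: {missing}")
    flag = variants["cohort_ac"].to_numpy() == 1
    for s in external_sources:
        flag &= variants[f"ac_{s}"].to_numpy() == 0
    return flag


def flag_ultra_rare_sv(svset: SVCallSet, absence_threshold: float = 0.30) -> np.ndarray:
    """Ultra-rare flag per SV: single occurrence and population absence.

    Single occurrence means exactly one carrier in the cohort; population
    absence means no same-type database SV covers >= ``absence_threshold``
    of the call (the ``pop_db_max_overlap`` column holds the largest such
    fraction).
    """
    single = svset.carrier_counts() == 1
    absent = svset.records["pop_db_max_overlap"].to_numpy() < absence_threshold
    return single & absent


def _gene_cds(cds: pd.DataFrame, gene_id) -> pd.DataFrame:
    return cds[cds["gene_id"] == gene_id]


def classify_sv_coding(
    sv_row, genes: pd.DataFrame, cds: pd.DataFrame
) -> bool:
    """Coding flag for one SV record.

    DEL/DUP/MEI are coding iff they remove/duplicate/insert into at least
    one CDS base. Inversions rearrange rather than delete, so breakpoints
    decide: an INV is coding iff (a) a breakpoint falls inside a coding
    exon, or (b) both breakpoints fall in different introns of one gene with
    a coding exon between them, or (c) one breakpoint is intronic and the
    other lies outside that gene. Whole-gene inversions with intergenic
    breakpoints are noncoding.
    """
    chrom = sv_row["chrom"]
    start, end = int(sv_row["start"]), int(sv_row["end"])
    svtype = sv_row["svtype"]
    g = genes[genes["chrom"] == chrom]
    if g.empty:
        return False
    c = cds[cds["gene_id"].isin(g["gene_id"])]
    if len(c):
        bad = c.merge(g[["gene_id", "tx_start", "tx_end"]], on="gene_id")
        if ((bad["start"] < bad["tx_start"]) | (bad["end"] > bad["tx_end"])).any():
            raise ValueError("malformed gene model: CDS outside transcript")

    if svtype != "INV":
        if c.empty:
            return False
        ov = overlap_bases(start, end, c["start"].to_numpy(), c["end"].to_numpy())
        return bool((ov > 0).any())

    # inversion: reason about the two breakpoints
    def locate(bp: int):
        """Return (gene_id, where) with where in {exon, intron, outside}."""
        hit = g[(g["tx_start"] <= bp) & (bp < g["tx_end"])]
        if hit.empty:
            return None, "outside"
        gid = hit.iloc[0]["gene_id"]
        gc = _gene_cds(c, gid)
        in_exon = ((gc["start"] <= bp) & (bp < gc["end"])).any()
        return gid, ("exon" if in_exon else "intron")

    (g1, w1), (g2, w2) = locate(start), locate(end - 1)
    if w1 == "exon" or w2 == "exon":
        return True
    if w1 == "outside" and w2 == "outside":
        return False  # may span whole genes; intergenic breakpoints => noncoding
    if w1 == "intron" and w2 == "intron":
        if g1 == g2:
            gc = _gene_cds(c, g1)
            between = (gc["start"] >= start) & (gc["end"] <= end)
            return bool(between.any())
        return True  # introns of two different genes: each gene truncated
    # exactly one breakpoint intronic, the other outside that gene
    return True


def constrained_mask(
    start: int,
    end: int,
    chrom: str,
    tracks: AnnotationTrackSet,
    cdts_percentile_max: float = 1.0,
    gerp_min: float = 4.0,
    gerp_aggregate: str = "max",
) -> bool:
    """Constraint flag for a variant span (0-based half-open).

    True iff the mean CDTS percentile over the spanned 10-bp bins is below
    ``cdts_percentile_max`` OR the aggregated GERP over the span reaches
    ``gerp_min`` (boundary inclusive).  GERP aggregation is the per-base
    maximum by default (conservative toward inclusion); ``"mean"`` is
    available.
    """
    if chrom not in tracks.cdts or chrom not in tracks.gerp:
        raise ValueError(f"no constraint tracks for chromosome {chrom!r}")
    cdts = tracks.cdts[chrom]
    gerp = tracks.gerp[chrom]
    bs = tracks.cdts_bin_size
    if start < 0 or end > len(gerp):
        raise ValueError("variant span outside track coverage")
    b0 = start // bs
    b1 = (end - 1) // bs + 1
    mean_cdts = float(np.mean(cdts[b0:b1]))
    span_gerp = gerp[start:end]
    agg = float(np.max(span_gerp)) if gerp_aggregate == "max" else float(np.mean(span_gerp))
    return mean_cdts < cdts_percentile_max or agg >= gerp_min


def promoter_intervals(
    genes: pd.DataFrame,
    chrom_lengths: dict,
    upstream: int = 2000,
) -> pd.DataFrame:
    """One 2-kb interval upstream of each annotated TSS, strand-aware.

    Plus-strand TSS at t gives [t - upstream, t); minus-strand gives
    [t, t + upstream). Intervals are clipped at chromosome edges.
    """
    rows = []
    for _, g in genes.iterrows():
        L = chrom_lengths[g["chrom"]]
        t = int(g["tss"])
        if g["strand"] == "+":
            s, e = max(0, t - upstream), t
        else:
            s, e = t, min(L, t + upstream)
        if e > s:
            rows.append((g["chrom"], s, e, g["gene_id"]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def gene_region_intervals(
    genes: pd.DataFrame,
    chrom_lengths: dict,
    upstream: int = 35000,
    downstream: int = 10000,
) -> pd.DataFrame:
    """Generalised transcript regions: 35 kb upstream to 10 kb downstream.

    The upstream flank extends from the most distal transcription start
    site; the downstream flank from the most distal transcription end (the
    only geometry that produces an interval containing the gene). Flanks are
    strand-aware and configurable; intervals are clipped at chromosome edges.
    """
    if genes.empty:
        raise ValueError("no transcripts supplied")
    rows = []
    for _, g in genes.iterrows():
        L = chrom_lengths[g["chrom"]]
        if g["strand"] == "+":
            s = g["tx_start"] - upstream
            e = g["tx_end"] + downstream
        else:
            s = g["tx_start"] - downstream
            e = g["tx_end"] + upstream
        rows.append((g["chrom"], max(0, int(s)), min(L, int(e)), g["gene_id"]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def _positions_in_intervals(pos: np.ndarray, chroms: np.ndarray,
                            intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask: 0-based position inside any interval of its chromosome."""
    mask = np.zeros(pos.size, dtype=bool)
    for chrom, grp in intervals.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = np.sort(grp["start"].to_numpy())
        ends = grp["end"].to_numpy()[np.argsort(grp["start"].to_numpy(), kind="stable")]
        # assumes non-overlapping intervals within a track (generator contract)
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[sel][ok] < ends[idx[ok]]
        mask[np.nonzero(sel)[0]] = ok
    return mask


def count_per_sample(
    cohort: CohortGenotypes,
    annotation: pd.DataFrame,
    variant_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sample count of qualifying SNV/indels inside an annotation.

    A variant counts for a sample when the sample carries it (genotype > 0)
    and its position (0-based) lies inside any interval of the annotation.
    ``variant_mask`` restricts to a qualifying subset (e.g. the URV flag, a
    consequence class, the constraint mask).
    """
    pos0 = cohort.variants["pos"].to_numpy() - 1  # VCF 1-based -> 0-based
    chroms = cohort.variants["chrom"].to_numpy()
    inside = _positions_in_intervals(pos0, chroms, annotation)
    if variant_mask is not None:
        inside &= np.asarray(variant_mask, dtype=bool)
    carrier = cohort.gt > 0
    return (carrier[:, inside]).sum(axis=1).astype(np.int64)


def count_per_sample_sv(
    svset: SVCallSet,
    annotation: pd.DataFrame,
    sv_mask: np.ndarray | None = None,
    min_element_fraction: float = 0.10,
    denominator: str = "element",
) -> np.ndarray:
    """Per-sample count of SVs intersecting >= 10% of an annotation element.

    An SV qualifies when its overlap with at least one element of the
    annotation reaches ``min_element_fraction`` of that element's length
    (set ``denominator="sv"`` for the SV-length reading). Counts use carrier
    genotypes.
    """
    qualifies = np.zeros(svset.n_svs, dtype=bool)
    ann_by_chrom = {c: g for c, g in annotation.groupby("chrom")}
    for j, row in svset.records.iterrows():
        grp = ann_by_chrom.get(row["chrom"])
        if grp is None:
            continue
        es = grp["start"].to_numpy()
        ee = grp["end"].to_numpy()
        ov = overlap_bases(int(row["start"]), int(row["end"]), es, ee)
        denom = (ee - es) if denominator == "element" else (row["end"] - row["start"])
        with np.errstate(invalid="ignore"):
            frac = ov / denom
        qualifies[j] = bool((frac >= min_element_fraction).any())
    if sv_mask is not None:
        qualifies &= np.asarray(sv_mask, dtype=bool)
    carrier = svset.gt > 0
    return carrier[:, qualifies].sum(axis=1).astype(np.int64)
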