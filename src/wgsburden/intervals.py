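"""Interval arithmetic for structural-variant analysis.

Everything here works on 0-based half-open intervals. The operations cover
the comparisons a case/control SV analysis needs: reciprocal overlap for
callset matching and concordance, the "population absence" rule used to call
an SV ultra-rare (every database SV of the same type must cover <30% of the
query), and the fraction of a functional element covered by an SV (the >=10%
rule used to count SVs against an annotation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "ConcordanceReport",
    "reciprocal_overlap",
    "match_callsets",
    "population_absence",
    "element_overlap_fraction",
    "genotype_concordance",
    "interval_union_length",
    "overlap_bases",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def overlap_bases(a_start, a_end, b_start, b_end):
    """Number of bases shared by two half-open intervals (vectorizes)."""
    return np.maximum(
        0, np.minimum(a_end, b_end) - np.maximum(a_start, b_start)
    )


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> tuple[float, float]:
    """Overlap of two intervals as a fraction of each.

    Returns ``(|a∩b|/|a|, |a∩b|/|b|)``; ``(0.0, 0.0)`` when the intervals sit
    on different chromosomes.  The reciprocal-overlap-at-t predicate used for
    callset matching is ``frac_a >= t and frac_b >= t``.
    """
    if a.chrom != b.chrom:
        return (0.0, 0.0)
    ov = overlap_bases(a.start, a.end, b.start, b.end)
    return (ov / len(a), ov / len(b))


def element_overlap_fraction(
    sv: GenomicInterval, element: GenomicInterval, denominator: str = "element"
) -> float:
    """Fraction of a functional element covered by an SV.

    The default denominator is the element length: an SV "intersects" an
    annotation element when it covers at least 10% of that element. Set
    ``denominator="sv"`` for the alternative reading (fraction of the SV).
    """
    if sv.chrom != element.chrom:
        return 0.0
    ov = overlap_bases(sv.start, sv.end, element.start, element.end)
    if denominator == "element":
        return ov / len(element)
    if denominator == "sv":
        return ov / len(sv)
    raise ValueError("denominator must be 'element' or 'sv'")


def interval_union_length(starts, ends) -> int:
    """Total bases covered by the union of half-open intervals."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return 0
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    total = 0
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = int(s), int(e)
        else:
            cur_e = max(cur_e, int(e))
    total += cur_e - cur_s
    return total


def population_absence(
    sv_row,
    population_svs: pd.DataFrame,
    threshold: float = 0.30,
) -> bool:
    """Whether an SV is "absent" from population databases.

    True iff every population SV *of the same type and chromosome* covers
    strictly less than ``threshold`` of the query SV (AnnotSV-style: the
    query length is the denominator).  A population SV covering exactly the
    threshold fraction means the query is NOT absent.
    """
    chrom, start, end, svtype = (
        sv_row["chrom"],
        int(sv_row["start"]),
        int(sv_row["end"]),
        sv_row["svtype"],
    )
    length = end - start
    pop = population_svs
    pop = pop[(pop["chrom"] == chrom) & (pop["svtype"] == svtype)]
    if pop.empty:
        return True
    ov = overlap_bases(start, end, pop["start"].to_numpy(), pop["end"].to_numpy())
    return bool(np.all(ov / length < threshold))


def match_callsets(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    threshold: float = 0.5,
) -> dict:
    """One-to-one matching of two SV callsets within (sample, svtype).

    Both frames need columns ``sample, svtype, chrom, start, end``. A pair
    qualifies when the reciprocal overlap is ``>= threshold`` on both sides.
    Matching is greedy by descending minimum overlap fraction; ties break on
    leftmost start of the A-interval, then on shorter A-length, so the result
    is invariant to input row order.

    Returns a dict with ``pairs`` (DataFrame of index_a, index_b, frac_a,
    frac_b), ``unmatched_a`` and ``unmatched_b`` (index arrays).
    """
    required = {"sample", "svtype", "chrom", "start", "end"}
    for name, df in (("set_a", set_a), ("set_b", set_b)):
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{name} lacks columns: {sorted(missing)}")

    candidates = []
    b_groups = {k: g for k, g in set_b.groupby(["sample", "svtype", "chrom"])}
    for key, ga in set_a.groupby(["sample", "svtype", "chrom"]):
        gb = b_groups.get(key)
        if gb is None:
            continue
        a_s = ga["start"].to_numpy()
        a_e = ga["end"].to_numpy()
        b_s = gb["start"].to_numpy()
        b_e = gb["end"].to_numpy()
        ov = overlap_bases(a_s[:, None], a_e[:, None], b_s[None, :], b_e[None, :])
        fa = ov / (a_e - a_s)[:, None]
        fb = ov / (b_e - b_s)[None, :]
        ok = (fa >= threshold) & (fb >= threshold)
        ai, bi = np.nonzero(ok)
        for i, j in zip(ai, bi):
            candidates.append(
                (
                    min(fa[i, j], fb[i, j]),
                    int(a_s[i]),
                    int(a_e[i] - a_s[i]),
                    ga.index[i],
                    gb.index[j],
                    fa[i, j],
                    fb[i, j],
                )
            )
    # greedy: best reciprocal fraction first; ties by leftmost then shorter A
    candidates.sort(key=lambda t: (-t[0], t[1], t[2], str(t[3]), str(t[4])))
    used_a: set = set()
    used_b: set = set()
    pairs = []
    for _, _, _, ia, ib, fa, fb in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((ia, ib, fa, fb))
    pairs_df = pd.DataFrame(pairs, columns=["index_a", "index_b", "frac_a", "frac_b"])
    return {
        "pairs": pairs_df,
        "unmatched_a": set_a.index[~set_a.index.isin(used_a)],
        "unmatched_b": set_b.index[~set_b.index.isin(used_b)],
    }


@dataclass
class ConcordanceReport:
    """Genotype concordance between two technologies.

    Rates are "fraction of comparison-set genotypes reproduced", stratified
    by the comparison set's genotype class. ``n_excluded`` counts genotypes
    dropped by the depth/quality filter before comparison.
    """

    overall: float
    per_class: dict = field(default_factory=dict)
    matched: int = 0
    compared: int = 0
    n_excluded: int = 0
    empty: bool = False


def genotype_concordance(
    gt_a: np.ndarray,
    gt_b: np.ndarray,
    dp_a: np.ndarray | None = None,
    gq_a: np.ndarray | None = None,
    dp_b: np.ndarray | None = None,
    gq_b: np.ndarray | None = None,
    min_dp: int = 10,
    min_gq: int = 20,
) -> ConcordanceReport:
    """Concordance of genotype matrix ``gt_a`` against comparison set ``gt_b``.

    Matrices are samples x variants with genotypes coded 0/1/2 and -1 for
    missing. Genotypes failing ``DP >= min_dp and GQ >= min_gq`` on either
    side (where DP/GQ are supplied) are excluded from the comparison, as are
    genotypes missing on either side. Per-class rates are keyed by the
    comparison genotype: ``hom_ref``, ``het``, ``hom_alt``.
    """
    if gt_a.shape != gt_b.shape:
        raise ValueError("genotype matrices must align on (samples, variants)")
    keep = (gt_a >= 0) & (gt_b >= 0)
    n_candidate = int(keep.sum())
    for dp, gq in ((dp_a, gq_a), (dp_b, gq_b)):
        if dp is not None:
            keep &= dp >= min_dp
        if gq is not None:
            keep &= gq >= min_gq
    n_excluded = n_candidate - int(keep.sum())
    compared = int(keep.sum())
    if compared == 0:
        return ConcordanceReport(
            overall=float("nan"), matched=0, compared=0,
            n_excluded=n_excluded, empty=True,
        )
    agree = (gt_a == gt_b) & keep
    per_class = {}
    for label, code in (("hom_ref", 0), ("het", 1), ("hom_alt", 2)):
        denom = int((keep & (gt_b == code)).sum())
        num = int((agree & (gt_b == code)).sum())
        per_class[label] = {"rate": (num / denom) if denom else float("nan"),
                            "n": denom}
    return ConcordanceReport(
        overall=int(agree.sum()) / compared,
        per_class=per_class,
        matched=int(agree.sum()),
        compared=compared,
        n_excluded=n_excluded,
    )
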