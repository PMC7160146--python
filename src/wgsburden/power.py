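"""Analytic case/control power and 2x2 exact contrasts.

Power here is for a 1-df comparison of the expected risk-allele frequency
between cases and controls under an additive disease model on the penetrance
scale: genotype relative risks ``(1, grr, 2*grr - 1)`` scaled so that the
population risk equals the lifetime prevalence K.  Following the convention
of the population-genetics power calculators used for study design in this
field, each subject contributes one frequency observation, and the test is a
one-sided normal comparison of the two group frequencies with unpooled
variance.  ``min_detectable_grr`` inverts the power function by bisection.

The 2x2 helpers wrap the standard Fisher exact test (probability-mass
two-sided convention) and the Woolf odds-ratio interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PowerSpec",
    "Table2x2",
    "case_control_freqs",
    "cc_power",
    "min_detectable_grr",
    "fisher_exact_2x2",
    "odds_ratio_2x2",
]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to the analytic case/control power computation.

    maf is the population frequency of the risk allele (for burden tests,
    the aggregated frequency of the variant set); grr the per-allele
    genotypic relative risk; prevalence_k the lifetime risk used to scale
    penetrances; alpha the one-sided type-I error level.
    """

    maf: float
    grr: float = 1.0
    prevalence_k: float = 0.01
    alpha: float = 5e-8
    n_cases: int = 1162
    n_controls: int = 936
    model: str = "additive"

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if self.grr < 1:
            raise ValueError("grr must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.prevalence_k < 1:
            raise ValueError("prevalence_k must be in (0, 1)")
        if self.model != "additive":
            raise ValueError("only the additive risk model is supported")


def case_control_freqs(maf: float, grr: float, k: float) -> tuple[float, float]:
    """Expected risk-allele frequency in cases and in controls.

    Genotype frequencies follow HWE at ``maf``; penetrances are proportional
    to ``(1, grr, 2*grr - 1)`` and scaled so the population risk equals
    ``k``.  Raises if the implied homozygote penetrance exceeds 1 (grr too
    large for the given K and maf).
    """
    p = maf
    geno = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
    rr = np.array([1.0, grr, 2.0 * grr - 1.0])
    f0 = k / float(geno @ rr)
    pen = f0 * rr
    if pen[2] > 1.0:
        raise ValueError(
            f"grr={grr} implies homozygote penetrance {pen[2]:.3f} > 1 "
            f"at K={k}, maf={maf}"
        )
    p_case = (geno[1] * pen[1] * 0.5 + geno[2] * pen[2]) / k
    p_ctrl = (geno[1] * (1 - pen[1]) * 0.5 + geno[2] * (1 - pen[2])) / (1 - k)
    return float(p_case), float(p_ctrl)


def cc_power(spec: PowerSpec) -> float:
    """Power of the 1-df case/control frequency comparison.

    One-sided normal test of ``p_case > p_control`` with one observation per
    subject and unpooled variance.  At ``grr = 1`` the power equals alpha.
    """
    p1, p0 = case_control_freqs(spec.maf, spec.grr, spec.prevalence_k)
    se = np.sqrt(
        p1 * (1 - p1) / spec.n_cases + p0 * (1 - p0) / spec.n_controls
    )
    z_alpha = stats.norm.isf(spec.alpha)
    if se == 0:
        return float(spec.alpha)
    ncp = (p1 - p0) / se
    return float(stats.norm.sf(z_alpha - ncp))


def min_detectable_grr(
    spec: PowerSpec, target_power: float = 0.8, grr_max: float = 200.0
) -> float:
    """Smallest genotypic relative risk reaching ``target_power``.

    Bisection on grr over [1, grr_max] to 1e-6; report with one-decimal
    rounding when quoting study-design numbers.  Raises when the target is
    unattainable within the grid (or when the penetrance bound binds first).
    """
    if not spec.alpha < target_power < 1:
        raise ValueError("target_power must be in (alpha, 1)")

    def gap_at(grr: float) -> float:
        return cc_power(replace(spec, grr=grr)) - target_power

    # shrink the upper bracket if the penetrance constraint binds
    hi = grr_max
    while hi > 1.0001:
        try:
            if gap_at(hi) >= 0:
                break
        except ValueError:
            hi *= 0.7
            continue
        raise ValueError(
            f"target power {target_power} unattainable at grr <= {hi}"
        )
    else:
        raise ValueError("penetrance bound excludes all grr > 1")
    g = float(optimize.brentq(gap_at, 1.0 + 1e-9, hi, xtol=1e-6))
    while gap_at(g) < 0:  # land on the attaining side of the root
        g += 1e-6
    return g


@dataclass(frozen=True)
class Table2x2:
    """A 2x2 count table; rows are groups, columns are outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("table must have at least one positive margin")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact_2x2(table: Table2x2) -> float:
    """Two-sided Fisher exact p (probability-mass ordering).

    Sum of hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.
    Degenerate margins give p = 1.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def odds_ratio_2x2(table: Table2x2) -> dict:
    """Odds ratio ad/bc with a Woolf 95% CI.

    A 0.5 continuity correction is applied to every cell when any cell is
    zero, keeping the estimate and interval finite.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return {
        "odds_ratio": float(np.exp(log_or)),
        "ci95": (float(np.exp(log_or - 1.96 * se)), float(np.exp(log_or + 1.96 * se))),
    }
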