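"""Quality control: genotype masking, HWE, variant filters, relatedness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from wgsburden.containers import CohortGenotypes, SVCallSet
from wgsburden.qc import (
    QCThresholds,
    apply_genotype_qc,
    default_urv_outlier_threshold,
    estimate_relatedness,
    filter_sv_blacklist,
    filter_variants,
    hwe_exact_test,
    prune_related,
    prune_urv_outliers,
)


def make_cohort(gt, pheno, dp=None, gq=None):
    n, m = gt.shape
    return CohortGenotypes(
        gt=gt.astype(np.int8),
        samples=pd.DataFrame(
            {"phenotype": pheno},
            index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
        ),
        variants=pd.DataFrame(
            {"variant_id": [f"v{j}" for j in range(m)],
             "chrom": "1", "pos": np.arange(1, m + 1)}
        ),
        dp=dp,
        gq=gq,
    )


class TestGenotypeQC:
    def test_boundaries(self):
        gt = np.array([[1, 1, 1, 1]], dtype=np.int8)
        dp = np.array([[9, 10, 10, 30]], dtype=np.int16)
        gq = np.array([[99, 20, 19, 99]], dtype=np.int16)
        cohort = make_cohort(gt, [1], dp, gq)
        out = apply_genotype_qc(cohort)
        # DP=9 masked; DP=10,GQ=20 retained; GQ=19 masked
        assert list(out.gt[0]) == [-1, 1, -1, 1]

    def test_all_pass_identity(self, rng):
        gt = rng.integers(0, 3, (10, 20)).astype(np.int8)
        dp = np.full(gt.shape, 30, dtype=np.int16)
        gq = np.full(gt.shape, 90, dtype=np.int16)
        out = apply_genotype_qc(make_cohort(gt, [1] * 10, dp, gq))
        assert np.array_equal(out.gt, gt)

    def test_missing_fields_error(self, rng):
        gt = rng.integers(0, 3, (4, 3)).astype(np.int8)
        with pytest.raises(ValueError, match="DP"):
            apply_genotype_qc(make_cohort(gt, [1, 1, 0, 0]))


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Independent brute-force enumeration of the exact conditional test."""
    n = n_aa + n_ab + n_bb
    n_rare = 2 * min(n_aa, n_bb) + n_ab
    if n_rare == 0:
        return 1.0
    probs = {}
    for het in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        hr = (n_rare - het) // 2
        hc = n - het - hr
        logp = (
            het * np.log(2)
            + gammaln(n + 1) - gammaln(het + 1) - gammaln(hr + 1) - gammaln(hc + 1)
            + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1) - gammaln(2 * n + 1)
        )
        probs[het] = np.exp(logp)
    z = sum(probs.values())
    p_obs = probs[n_ab] / z
    return min(1.0, sum(p / z for p in probs.values() if p / z <= p_obs * (1 + 1e-12)))


class TestHWE:
    def test_frozen_example(self):
        # value computed with the enumeration oracle above
        assert hwe_exact_test(57, 14, 50) == pytest.approx(
            hwe_enumeration_oracle(57, 14, 50), abs=1e-12
        )
        assert hwe_exact_test(57, 14, 50) < 1e-15  # extreme het deficit

    def test_monomorphic(self):
        assert hwe_exact_test(25, 0, 0) == 1.0

    def test_het_only(self):
        for n in (2, 5, 12):
            assert hwe_exact_test(0, n, 0) == pytest.approx(
                hwe_enumeration_oracle(0, n, 0), abs=1e-12
            )

    def test_symmetry_allele_relabel(self):
        assert hwe_exact_test(30, 12, 4) == hwe_exact_test(4, 12, 30)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        n_aa=st.integers(0, 70), n_ab=st.integers(0, 70), n_bb=st.integers(0, 70)
    )
    def test_matches_enumeration_oracle(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
            hwe_enumeration_oracle(n_aa, n_ab, n_bb), abs=1e-12
        )


class TestFilterVariants:
    def _clean_cohort(self, rng, n=200, m=10):
        mafs = rng.uniform(0.2, 0.4, m)
        gt = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)
        pheno = np.r_[np.ones(n // 2), np.zeros(n - n // 2)].astype(int)
        return make_cohort(gt, pheno), mafs

    def test_high_missing_removed(self, rng):
        cohort, _ = self._clean_cohort(rng)
        gt = cohort.gt.copy()
        gt[: int(0.03 * 200), 0] = -1  # 3% missing in variant 0, balanced-ish
        cohort = make_cohort(gt, cohort.samples["phenotype"].to_numpy())
        out, report = filter_variants(cohort)
        reasons = {v: r for v, r in report.removed_variants}
        assert reasons.get("v0") == "missing_rate"

    def test_clean_variant_retained(self, rng):
        cohort, _ = self._clean_cohort(rng)
        out, report = filter_variants(cohort)
        assert out.n_variants == cohort.n_variants
        assert report.reconciles()

    def test_hwe_violation_removed_control_fdr(self, rng):
        cohort, _ = self._clean_cohort(rng, n=300, m=10)
        gt = cohort.gt.copy()
        gt[:, 3] = 1  # every subject heterozygous: extreme HWE violation
        cohort = make_cohort(gt, cohort.samples["phenotype"].to_numpy())
        # enumeration oracle confirms the engineered variant is extreme
        assert hwe_enumeration_oracle(0, 150, 0) < 1e-6 / 10
        out, report = filter_variants(cohort)
        reasons = {v: r for v, r in report.removed_variants}
        assert reasons == {"v3": "hwe_controls"}

    def test_differential_missingness(self, rng):
        cohort, _ = self._clean_cohort(rng, n=400)
        gt = cohort.gt.copy()
        gt[:40, 1] = -1  # 20% missing in cases only (cases are first half)
        cohort = make_cohort(gt, cohort.samples["phenotype"].to_numpy())
        out, report = filter_variants(cohort)
        reasons = {v: r for v, r in report.removed_variants}
        assert reasons.get("v1") in ("missing_rate", "differential_missingness")

    def test_monomorphic_removed(self, rng):
        cohort, _ = self._clean_cohort(rng)
        gt = cohort.gt.copy()
        gt[:, 2] = 0
        cohort = make_cohort(gt, cohort.samples["phenotype"].to_numpy())
        _, report = filter_variants(cohort)
        assert ("v2", "monomorphic") in report.removed_variants

    def test_idempotent(self, rng):
        cohort, _ = self._clean_cohort(rng, n=300, m=30)
        gt = cohort.gt.copy()
        gt[:, 5] = 1
        gt[:9, 7] = -1
        cohort = make_cohort(gt, cohort.samples["phenotype"].to_numpy())
        once, _ = filter_variants(cohort)
        twice, rep2 = filter_variants(once)
        assert twice.n_variants == once.n_variants
        assert np.array_equal(twice.gt, once.gt)

    def test_requires_both_phenotypes(self, rng):
        cohort, _ = self._clean_cohort(rng)
        cohort.samples["phenotype"] = 1
        with pytest.raises(ValueError):
            filter_variants(cohort)


class TestRelatedness:
    def _hwe_genotypes(self, rng, n, m, maf_low=0.1):
        mafs = rng.uniform(maf_low, 0.5, m)
        return rng.binomial(2, mafs, size=(n, m)).astype(np.int8), mafs

    def test_duplicate_detected(self, rng):
        gt, _ = self._hwe_genotypes(rng, 100, 5000, maf_low=0.3)
        gt[1] = gt[0]
        cohort = make_cohort(gt, [1] * 50 + [0] * 50)
        pihat = estimate_relatedness(cohort)
        assert pihat.iloc[0, 1] >= 0.95
        assert np.allclose(pihat.values, pihat.values.T)

    def test_unrelated_near_zero(self, rng):
        gt, _ = self._hwe_genotypes(rng, 60, 2000)
        pihat = estimate_relatedness(make_cohort(gt, [1] * 30 + [0] * 30))
        off = pihat.values[~np.eye(60, dtype=bool)]
        assert abs(off.mean()) < 0.02
        diag = np.diag(pihat.values)
        assert abs(diag.mean() - 1) < 0.05

    def test_parent_child(self, rng):
        m = 3000
        mafs = rng.uniform(0.2, 0.5, m)
        # transmit one haplotype from the parent to the child
        p_h1 = (rng.random(m) < mafs).astype(np.int8)
        p_h2 = (rng.random(m) < mafs).astype(np.int8)
        c_h2 = (rng.random(m) < mafs).astype(np.int8)
        others = rng.binomial(2, mafs, size=(98, m)).astype(np.int8)
        gt = np.vstack([p_h1 + p_h2, p_h1 + c_h2, others])
        pihat = estimate_relatedness(make_cohort(gt, [1] * 50 + [0] * 50))
        assert pihat.iloc[0, 1] == pytest.approx(0.5, abs=0.05)

    def test_prune_removes_one_per_pair(self, rng):
        ids = ["A", "B", "C", "D"]
        mat = pd.DataFrame(np.eye(4), index=ids, columns=ids)
        mat.loc["A", "B"] = mat.loc["B", "A"] = 0.6
        kept = prune_related(mat, threshold=0.2)
        assert sorted(kept) == ["A", "C", "D"]  # lexicographically larger removed

    def test_prune_ties_on_missingness(self):
        ids = ["A", "B"]
        mat = pd.DataFrame([[1, 0.5], [0.5, 1]], index=ids, columns=ids)
        kept = prune_related(mat, 0.2, missingness=pd.Series({"A": 0.1, "B": 0.0}))
        assert kept == ["B"]


class TestUrvOutliers:
    def test_strict_threshold(self):
        counts = pd.Series({"a": 5900, "b": 6000, "c": 6001})
        kept = prune_urv_outliers(counts, 6000)
        assert list(kept) == ["a", "b"]

    def test_identity_when_all_below(self):
        counts = pd.Series({"a": 10, "b": 20})
        assert list(prune_urv_outliers(counts, 6000)) == ["a", "b"]

    def test_outlier_fraction_recovered(self, rng):
        # generator truth: fraction of samples at 2x the base rate
        n = 2000
        outlier = rng.random(n) < 0.03
        counts = pd.Series(
            rng.poisson(np.where(outlier, 2.0, 1.0) * 1000),
            index=[f"S{i}" for i in range(n)],
        )
        thresh = default_urv_outlier_threshold(1000)
        removed_frac = 1 - len(prune_urv_outliers(counts, thresh)) / n
        se = np.sqrt(0.03 * 0.97 / n)
        assert removed_frac == pytest.approx(0.03, abs=3 * se)


class TestBlacklist:
    def _svset(self, rows):
        rec = pd.DataFrame(rows, columns=["chrom", "start", "end", "svtype"])
        rec["pop_db_max_overlap"] = 0.0
        return SVCallSet(
            records=rec,
            gt=np.ones((2, len(rec)), dtype=np.int8),
            samples=pd.DataFrame(index=pd.Index(["S1", "S2"], name="sample_id")),
        )

    def test_fully_inside_removed(self):
        sv = self._svset([("1", 100, 200, "DEL")])
        bl = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [1000]})
        out, _ = filter_sv_blacklist(sv, bl)
        assert out.n_svs == 0

    def test_exact_66pct_retained(self):
        sv = self._svset([("1", 0, 100, "DEL")])
        bl = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [66]})
        out, _ = filter_sv_blacklist(sv, bl)
        assert out.n_svs == 1

    def test_union_40_plus_30_removed(self):
        sv = self._svset([("1", 0, 100, "DEL")])
        bl = pd.DataFrame(
            {"chrom": ["1", "1"], "start": [0, 50], "end": [40, 80]}
        )
        out, report = filter_sv_blacklist(sv, bl)
        assert out.n_svs == 0
        assert report.reconciles()


def test_thresholds_validation():
    with pytest.raises(ValueError):
        QCThresholds(max_missing_per_variant=1.5)
    with pytest.raises(ValueError):
        QCThresholds(min_dp=0)
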