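"""Generator contracts: geometry, singleton fractions, SV sizes, phenotypes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wgsburden.simulate import (
    ConfigurationError,
    SimulationConfig,
    simulate_annotation_genome,
    simulate_genotypes,
    simulate_liability_phenotype,
    simulate_snv_cohort,
    simulate_sv_cohort,
)


class TestConfigValidation:
    def test_proportions_checked(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(snv_singleton_fraction=1.2)

    def test_min_samples(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_cases=1)

    def test_or_bound(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(annotation_burden_or=0.8)

    def test_prevalence_domain(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(prevalence_K=0.6)


class TestAnnotationGenome:
    def test_tad_bin_arithmetic(self, small_config, tracks):
        # chrom_length 2 Mb with 40 kb bins -> 50 candidate bins per chromosome
        tad = tracks.track("TAD_boundary")
        assert ((tad["end"] - tad["start"]) == 40_000).all()
        per_chrom = tad.groupby("chrom").size()
        expected = round(50 * small_config.tad_boundary_fraction)
        assert (per_chrom == expected).all()
        # boundaries are non-overlapping, aligned 40-kb bins
        for _, grp in tad.groupby("chrom"):
            s = np.sort(grp["start"].to_numpy())
            assert (np.diff(s) >= 40_000).all()
            assert (s % 40_000 == 0).all()

    def test_cdts_partitions_genome(self, small_config, tracks):
        for chrom in small_config.chrom_names:
            bins = tracks.cdts[chrom]
            assert bins.size * tracks.cdts_bin_size == small_config.chrom_length
            assert (bins > 0).all() and (bins <= 100).all()
            assert tracks.gerp[chrom].size == small_config.chrom_length

    def test_invalid_chrom_length(self, small_config):
        from dataclasses import replace

        with pytest.raises(ConfigurationError):
            simulate_annotation_genome(replace(small_config, chrom_length=4_000_010))

    def test_deterministic(self, small_config, tracks):
        again = simulate_annotation_genome(small_config)
        assert tracks.track("TAD_boundary").equals(again.track("TAD_boundary"))
        for chrom in small_config.chrom_names:
            assert np.array_equal(tracks.cdts[chrom], again.cdts[chrom])
            assert np.array_equal(tracks.gerp[chrom], again.gerp[chrom])
        assert tracks.genes.equals(again.genes)


class TestSNVCohort:
    def test_singleton_fractions_at_scale(self):
        # >= 50k variants: realized singleton fractions within +/-0.02
        cfg = SimulationConfig(
            n_cases=300, n_controls=300, n_chromosomes=2, chrom_length=4_000_000,
            mean_urv_per_sample=40.0, n_target_urvs=800, seed=99,
        )
        tracks = simulate_annotation_genome(cfg)
        cohort, _ = simulate_snv_cohort(cfg, tracks)
        assert cohort.n_variants >= 50_000
        v = cohort.variants
        snv = v["variant_class"] == "SNV"
        f_snv = (v.loc[snv, "cohort_ac"] == 1).mean()
        f_indel = (v.loc[~snv, "cohort_ac"] == 1).mean()
        assert f_snv == pytest.approx(0.4543, abs=0.02)
        assert f_indel == pytest.approx(0.3703, abs=0.02)

    def test_ac_conservation(self, cohort):
        assert np.array_equal(
            cohort.variants["cohort_ac"].to_numpy(), cohort.allele_counts()
        )

    def test_singletons_are_het_in_one_sample(self, cohort):
        sing = cohort.variants["cohort_ac"].to_numpy() == 1
        sub = cohort.gt[:, sing]
        assert ((sub == 1).sum(axis=0) == 1).all()
        assert (sub != 2).all()

    def test_null_or_symmetry(self, small_config, tracks, cohort):
        # annotation_burden_or = 1: case/control target means within 2 pooled SE
        from wgsburden.classify import count_per_sample, flag_ultra_rare

        urv = flag_ultra_rare(cohort.variants)
        counts = count_per_sample(cohort, tracks.track("TAD_boundary"), urv)
        y = cohort.samples["phenotype"].to_numpy()
        m1, m0 = counts[y == 1].mean(), counts[y == 0].mean()
        se = np.sqrt(
            counts[y == 1].var(ddof=1) / (y == 1).sum()
            + counts[y == 0].var(ddof=1) / (y == 0).sum()
        )
        assert abs(m1 - m0) < 2 * se + 1e-9

    def test_unknown_target_annotation(self, small_config, tracks):
        from dataclasses import replace

        bad = replace(small_config, target_annotation="nonexistent")
        with pytest.raises(ConfigurationError):
            simulate_snv_cohort(bad, tracks)

    def test_dp_gq_fail_fraction(self, small_config, cohort):
        fail = (cohort.dp < 10) | (cohort.gq < 20)
        q = small_config.genotype_qc_fail_fraction
        se = np.sqrt(q * (1 - q) / fail.size)
        assert fail.mean() == pytest.approx(q, abs=4 * se)

    def test_outlier_tail(self):
        cfg = SimulationConfig(
            n_cases=400, n_controls=400, n_chromosomes=2, chrom_length=2_000_000,
            mean_urv_per_sample=60.0, outlier_fraction=0.05,
            outlier_urv_multiplier=2.0, n_target_urvs=100, seed=5,
        )
        tracks = simulate_annotation_genome(cfg)
        cohort, _ = simulate_snv_cohort(cfg, tracks)
        from wgsburden.classify import flag_ultra_rare

        urv = flag_ultra_rare(cohort.variants)
        per_sample = (cohort.gt[:, urv] > 0).sum(axis=1)
        out = cohort.samples["is_outlier"].to_numpy()
        assert per_sample[out].mean() > 1.7 * per_sample[~out].mean()

    def test_deterministic(self, small_config, tracks, cohort):
        again, _ = simulate_snv_cohort(small_config, tracks)
        assert np.array_equal(cohort.gt, again.gt)
        assert np.array_equal(cohort.dp, again.dp)
        assert cohort.variants.equals(again.variants)

    def test_truth_ids_exist(self, cohort_truth):
        cohort, truth = cohort_truth
        ids = set(cohort.variants["variant_id"])
        assert set(truth.causal_variant_ids) <= ids


class TestSVCohort:
    def test_median_sizes(self):
        cfg = SimulationConfig(
            n_cases=50, n_controls=50, n_chromosomes=2, chrom_length=4_000_000,
            sv_counts_per_type={"DEL": 1000, "DUP": 1000, "INV": 1000},
            n_target_svs=0, seed=3,
        )
        tracks = simulate_annotation_genome(cfg)
        sv, _ = simulate_sv_cohort(cfg, tracks)
        sizes = sv.records["end"] - sv.records["start"]
        med = sizes.groupby(sv.records["svtype"]).median()
        assert 2333 <= med["DEL"] <= 2851  # 2592 +/- 10%
        assert med["DUP"] == pytest.approx(7179, rel=0.10)
        assert med["INV"] == pytest.approx(3265, rel=0.10)
        assert sizes.min() >= 500 and sizes.max() <= 1_000_000

    def test_empty_type_schema_valid(self, small_config, tracks):
        from dataclasses import replace

        cfg = replace(
            small_config, sv_counts_per_type={"DEL": 0}, n_target_svs=0
        )
        sv, _ = simulate_sv_cohort(cfg, tracks)
        assert sv.n_svs == 0 and sv.gt.shape == (small_config.n_samples, 0)

    def test_population_absence_fraction(self, svset, small_config):
        ov = svset.records.loc[~svset.records["is_target_truth"], "pop_db_max_overlap"]
        frac = (ov < 0.30).mean()
        assert frac == pytest.approx(small_config.sv_ultra_rare_fraction, abs=0.1)

    def test_target_svs_hit_annotation(self, svset_truth, tracks):
        from wgsburden.intervals import overlap_bases

        sv, truth = svset_truth
        tad = tracks.track("TAD_boundary")
        for j in truth.causal_variant_ids:
            row = sv.records.iloc[j]
            grp = tad[tad["chrom"] == row["chrom"]]
            ov = overlap_bases(
                row["start"], row["end"], grp["start"].to_numpy(), grp["end"].to_numpy()
            )
            assert (ov / (grp["end"] - grp["start"]).to_numpy() >= 0.10).any()

    def test_deterministic(self, small_config, tracks, svset):
        again, _ = simulate_sv_cohort(small_config, tracks)
        assert svset.records.equals(again.records)
        assert np.array_equal(svset.gt, again.gt)


class TestLiabilityPhenotype:
    def test_null_h2_uniform_association(self, rng):
        G, _ = simulate_genotypes(300, 1000, rng)
        labels, liab, _ = simulate_liability_phenotype(G, 0.0, 0.3, seed=1)
        # single-variant association of the continuous liability: uniform p
        p = G.mean(axis=0) / 2
        Z = (G - 2 * p) / np.sqrt(2 * p * (1 - p))
        r = Z.T @ (liab - liab.mean()) / (liab.std() * len(liab))
        t = r * np.sqrt((len(liab) - 2) / (1 - r**2))
        pv = 2 * stats.t.sf(np.abs(t), len(liab) - 2)
        assert stats.kstest(pv, "uniform").pvalue > 0.01

    def test_case_fraction_matches_K(self, rng):
        G, _ = simulate_genotypes(10_000, 50, rng)
        labels, _, _ = simulate_liability_phenotype(G, 0.3, 0.01, seed=2)
        lo, hi = stats.binom.interval(0.99, 10_000, 0.01)
        assert lo <= labels.sum() <= hi

    def test_h2_domain(self, rng):
        G, _ = simulate_genotypes(50, 10, rng)
        with pytest.raises(ValueError):
            simulate_liability_phenotype(G, 1.5, 0.01, seed=0)

    def test_genetic_variance_scaled(self, rng):
        G, _ = simulate_genotypes(2000, 500, rng)
        _, liab, truth = simulate_liability_phenotype(G, 0.5, 0.01, seed=3)
        assert truth.true_h2 == 0.5
        assert liab.var() == pytest.approx(1.0, abs=0.1)
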