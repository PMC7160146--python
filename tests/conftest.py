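import numpy as np
import pandas as pd
import pytest

from wgsburden.simulate import (
    SimulationConfig,
    simulate_annotation_genome,
    simulate_snv_cohort,
    simulate_sv_cohort,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_cases=120,
        n_controls=100,
        n_chromosomes=2,
        chrom_length=2_000_000,
        mean_urv_per_sample=12.0,
        n_target_urvs=500,
        annotation_burden_or=1.0,
        sv_counts_per_type={"DEL": 400, "DUP": 150, "INV": 120},
        n_target_svs=60,
        seed=1234,
    )


@pytest.fixture(scope="session")
def tracks(small_config):
    return simulate_annotation_genome(small_config)


@pytest.fixture(scope="session")
def cohort_truth(small_config, tracks):
    return simulate_snv_cohort(small_config, tracks)


@pytest.fixture(scope="session")
def cohort(cohort_truth):
    return cohort_truth[0]


@pytest.fixture(scope="session")
def svset_truth(small_config, tracks):
    return simulate_sv_cohort(small_config, tracks)


@pytest.fixture(scope="session")
def svset(svset_truth):
    return svset_truth[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def whole_genome_track(config) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": config.chrom_names,
            "start": 0,
            "end": config.chrom_length,
        }
    )
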