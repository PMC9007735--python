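"""Shared fixtures: a small hand-checkable cohort and the full benchmark cohort."""

import pytest

import svidx
from svidx.cohort_index import BruteForceSearcher, build_index
from svidx.query_engine import load_ped


@pytest.fixture(scope="session")
def insert_model():
    return svidx.InsertSizeModel(mean_fragment=300.0, sd_fragment=50.0, discordant_distance=500)


@pytest.fixture(scope="session")
def tiny_spec():
    """3 samples, one 200-kb chromosome, one het/hom deletion, no noise."""
    import numpy as np

    sv = svidx.StructuralVariant("del1", "DEL", "1", 100_000, 101_000)
    return svidx.CohortSpec(
        sample_ids=["A", "B", "C"],
        chrom_lengths={"1": 200_000},
        svs=[sv],
        genotypes=np.array([[2, 1, 0]], dtype=np.int8),
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec, tmp_path_factory):
    return svidx.realize_cohort(tiny_spec, tmp_path_factory.mktemp("tiny"))


@pytest.fixture(scope="session")
def bench_noisy(tmp_path_factory):
    """The standard 20-sample benchmark cohort at the default 4% noise rate."""
    spec = svidx.default_test_cohort(11)
    return svidx.realize_cohort(spec, tmp_path_factory.mktemp("bench_noisy"))


@pytest.fixture(scope="session")
def bench_noisy_index(bench_noisy):
    return build_index(bench_noisy.evidence_files, bench_noisy.sample_ids)


@pytest.fixture(scope="session")
def bench_noisy_scan(bench_noisy):
    return BruteForceSearcher.from_files(bench_noisy.evidence_files, bench_noisy.sample_ids)


@pytest.fixture(scope="session")
def bench_noisy_samples(bench_noisy):
    return load_ped(bench_noisy.ped_path, 5)


@pytest.fixture(scope="session")
def bench_clean(tmp_path_factory):
    """The same benchmark cohort with the noise process switched off."""
    spec = svidx.default_test_cohort(11, noise_discordant_rate=0.0)
    return svidx.realize_cohort(spec, tmp_path_factory.mktemp("bench_clean"))


@pytest.fixture(scope="session")
def bench_clean_index(bench_clean):
    return build_index(bench_clean.evidence_files, bench_clean.sample_ids)


@pytest.fixture(scope="session")
def bench_clean_samples(bench_clean):
    return load_ped(bench_clean.ped_path, 5)
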