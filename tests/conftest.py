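"""Shared fixtures: the planted-motif training set and the multi-genome benchmark."""

import warnings

import pytest

from regulonkit.motif import PalindromeSearch, discover_motif
from regulonkit.pipeline import config_for_synthetic, run_pipeline
from regulonkit.synthetic import PlantConfig, generate_genome_set, planted_training_regions


@pytest.fixture(scope="session")
def xylr_regions():
    """40 x 180 bp AT-rich regions, each with one sampled 25-bp inverted-repeat site."""
    return planted_training_regions(n_regions=40, length=180, seed=0)


@pytest.fixture(scope="session")
def xylr_model(xylr_regions):
    """Model discovered over the full arm/spacer grid on the standing training set."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return discover_motif(
            xylr_regions,
            width_range=(17, 31),
            palindrome=PalindromeSearch(arm_range=(7, 13), spacers=(3, 5, 7)),
            seed=0,
        )


@pytest.fixture(scope="session")
def benchmark_dataset(tmp_path_factory):
    """The default 8-genome benchmark with ground truth, written to disk."""
    d = tmp_path_factory.mktemp("bench_data")
    ds = generate_genome_set(PlantConfig(seed=0), outdir=str(d))
    return ds, str(d)


@pytest.fixture(scope="session")
def benchmark_run(benchmark_dataset, tmp_path_factory):
    """Full pipeline executed on the benchmark dataset."""
    ds, ds_dir = benchmark_dataset
    out = tmp_path_factory.mktemp("bench_out")
    cfg = config_for_synthetic(ds_dir, str(out))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(cfg)
    return ds, result
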