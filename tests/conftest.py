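"""Shared fixtures: the standard synthetic benchmark, trained once per session.

The "standard benchmark" is the desk-scale study condition used throughout:
tiny backbones, 60 training images, 40 test images, appearance separation
0.8, fixed global seed.  Training the full model zoo takes a couple of
minutes, so it is session-scoped and shared by the detector, aggregation,
clinical and acceptance tests.
"""

from __future__ import annotations

import pytest

from lesionkit.pipeline import RunConfig, run_benchmark, train_benchmark_models
from lesionkit.simulate import SimConfig, generate_dataset
from lesionkit.taxonomy import DEFAULT_TAXONOMY

BENCH_SEED = 1


@pytest.fixture(scope="session")
def bench_config() -> RunConfig:
    return RunConfig(global_seed=BENCH_SEED)


@pytest.fixture(scope="session")
def bench_models(bench_config):
    return train_benchmark_models(bench_config)


@pytest.fixture(scope="session")
def bench_report(bench_config, bench_models):
    return run_benchmark(bench_config, models=bench_models)


@pytest.fixture(scope="session")
def taxonomy():
    return DEFAULT_TAXONOMY


@pytest.fixture(scope="session")
def small_images():
    """A small, cheap annotated set for I/O and bookkeeping tests."""
    return generate_dataset(SimConfig(seed=5, image_size_range=(64, 96)), 8)


@pytest.fixture(scope="session")
def easy_single_lesion_images():
    """High-contrast wide-field images with exactly one lesion each."""
    config = SimConfig(
        seed=17,
        lesions_per_image_range=(1, 1),
        appearance_separation=1.0,
        dermoscopy_fraction=0.0,
        noise_sd=4.0,
    )
    return generate_dataset(config, 50)
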