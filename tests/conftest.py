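from dataclasses import replace

import numpy as np
import pytest

from ogmsv.genome import GenomeBuild
from ogmsv.simulate import DEFAULT_CONFIG, PlatformParams, generate_cohort


@pytest.fixture
def tiny_genome() -> GenomeBuild:
    """Two short chromosomes for per-base brute-force work."""
    return GenomeBuild(
        "tiny",
        [("chr1", 100_000), ("chr2", 50_000)],
        {"chr1": (40_000, 45_000), "chr2": (20_000, 22_000)},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def exact_platform(name: str) -> PlatformParams:
    return PlatformParams(name, boundary_jitter_sd=0, min_segment_bp=1,
                          detection_floor_log2=0.0)


ZERO_NOISE_CONFIG = replace(
    DEFAULT_CONFIG,
    noise_sd=0.0,
    ogm=exact_platform("ogm"),
    array=exact_platform("array"),
)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Noiseless, jitter-free rendering: observations equal planted truth."""
    return generate_cohort(ZERO_NOISE_CONFIG, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """Study-condition cohort at default noise and platform resolution."""
    return generate_cohort(DEFAULT_CONFIG, seed=13)
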