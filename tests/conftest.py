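"""Shared fixtures: small planted populations reused across test modules."""

import numpy as np
import pytest

from rohbench.synthpop import GeneratorConfig, make_reference, plant_population


@pytest.fixture(scope="session")
def tiny_cfg() -> GeneratorConfig:
    """A 2x2 Mb genome with two individuals; fast enough for per-test reuse."""
    return GeneratorConfig(
        n_contigs=2,
        contig_len=2_000_000,
        target_f_roh_levels=(0.15, 0.35),
        roh_length_mix=((200_000, 400_000, 0.6), (400_000, 900_000, 0.4)),
        min_roh_len=200_000,
        min_separation=150_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_pop(tiny_cfg):
    ref = make_reference(tiny_cfg)
    truths, vs = plant_population(ref, tiny_cfg)
    return ref, truths, vs


@pytest.fixture(scope="session")
def medium_cfg() -> GeneratorConfig:
    """The sweep-scale genome: 2x10 Mb, the full eight-level ladder."""
    return GeneratorConfig(n_contigs=2, contig_len=10_000_000, seed=0)


@pytest.fixture(scope="session")
def medium_pop(medium_cfg):
    ref = make_reference(medium_cfg)
    truths, vs = plant_population(ref, medium_cfg)
    return ref, truths, vs


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)
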