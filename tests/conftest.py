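"""Shared fixtures: seeded pipeline runs reused across test modules."""

from __future__ import annotations

import time

import pytest
from hypothesis import settings

from radmarkers.pipeline import run_rad_pipeline, run_shotgun_pipeline
from radmarkers.simdata import SimConfig

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def mini_config(**overrides) -> SimConfig:
    """A small, fast study configuration for unit-level end-to-end checks."""
    base = dict(genome_length=60_000, n_enzyme_sites=12, n_duplicated_loci=2,
                n_private_per_individual=1, error_rate=0.0, per_base_depth=12.0,
                snp_density=4e-4, seed=1)
    base.update(overrides)
    return SimConfig(**base)


def study_config(seed: int = 7) -> SimConfig:
    """The error-free validation study: 8 individuals, 100 planted cut
    sites (200 RAD loci), 10 duplicated loci, per-base depth 30."""
    return SimConfig(genome_length=250_000, n_enzyme_sites=100,
                     n_duplicated_loci=10, n_private_per_individual=3,
                     error_rate=0.0, per_base_depth=30.0, snp_density=8e-4,
                     seed=seed)


@pytest.fixture(scope="session")
def mini_rad_result():
    return run_rad_pipeline(mini_config())


@pytest.fixture(scope="session")
def study_rad_result():
    """Full-scale error-free RAD run plus its wall-clock duration."""
    t0 = time.perf_counter()
    result = run_rad_pipeline(study_config())
    return result, time.perf_counter() - t0


@pytest.fixture(scope="session")
def shotgun_result():
    cfg = SimConfig(genome_length=40_000, n_enzyme_sites=8, n_duplicated_loci=0,
                    n_private_per_individual=0, error_rate=0.0, snp_density=5e-4,
                    n_indels=6, seed=11)
    return run_shotgun_pipeline(cfg, n_reads=2800)
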