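"""Shared fixtures: small seeded cohorts and their preprocessed blocks."""

from __future__ import annotations

import numpy as np
import pytest

from plsomics import SyntheticConfig, simulate_cohort
from plsomics.pipeline import PipelineConfig, preprocess_cohort
from plsomics.preprocess import autoscale


@pytest.fixture(scope="session")
def small_cohort():
    """60-sample reduced cohort with planted effects (fast unit fixture)."""
    cfg = SyntheticConfig(
        n_samples=60, n_genes=150, n_cpgs=150, n_snps=80,
        n_informative={"expression": 10, "methylation": 10, "genotype": 10},
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_blocks(small_cohort):
    blocks, _ = preprocess_cohort(small_cohort, PipelineConfig())
    return blocks


@pytest.fixture(scope="session")
def small_scaled(small_blocks):
    return [autoscale(b)[0] for b in small_blocks]


@pytest.fixture(scope="session")
def default_cohort():
    """The full-scale study-structure cohort (110 samples, default blocks)."""
    return simulate_cohort(SyntheticConfig())


@pytest.fixture(scope="session")
def default_blocks(default_cohort):
    blocks, _ = preprocess_cohort(default_cohort, PipelineConfig())
    return blocks


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
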