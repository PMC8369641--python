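"""Shared fixtures: populations are simulated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from pearqtl import simpop


@pytest.fixture(scope="session")
def pear_study():
    """Default preset: 106 cultivars + 17 F1 families, 1218 individuals."""
    return simpop.simulate_pear_study(seed=1)


@pytest.fixture(scope="session")
def small_config():
    return simpop.SimConfig(
        n_founders=20, n_cultivars=30, family_sizes=(30, 30, 30, 30),
        family_size_bounds=(3, 200), n_chromosomes=5, chrom_length_bp=5_000_000,
        chrom_length_morgans=0.8, n_markers_per_chrom=60, seed=11)


@pytest.fixture(scope="session")
def small_pop(small_config):
    """150 individuals x 300 markers; fast enough for model fits."""
    panel = simpop.simulate_founders(small_config)
    g, fam = simpop.build_population(small_config, panel)
    return g, fam


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
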