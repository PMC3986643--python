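"""Shared fixtures: small simulated datasets, reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from sweepscan import windows
from sweepscan.core import GenomeMap, HaplotypePanel
from sweepscan.simulate import (
    SimulationConfig,
    TraitSpec,
    simulate_dataset,
    simulate_neutral_panel,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, chrom_length=5_000_000, trait=TraitSpec(n_qtl=100, h2=0.5))


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_grid(small_dataset):
    return windows.build_grid(small_dataset.gmap)


@pytest.fixture(scope="session")
def tiny_panel():
    """Deterministic neutral single-population panel (fast)."""
    cfg = SimulationConfig(
        seed=7, chrom_length=1_000_000, base_ne=50, burn_in_factor=6, breeds=[]
    )
    panel, gmap = simulate_neutral_panel(cfg)
    return panel, gmap, cfg


def make_panel(haps: np.ndarray, positions=None, chrom_length: int = 1_000_000, name="pop"):
    """Hand-built panel from an explicit binary matrix (tests only)."""
    haps = np.asarray(haps, dtype=np.uint8)
    m = haps.shape[1]
    if positions is None:
        positions = np.arange(m) * 1000 + 500
    gmap = GenomeMap(np.zeros(m, dtype=np.int64), np.asarray(positions), {0: chrom_length})
    return HaplotypePanel(name, haps, gmap)
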