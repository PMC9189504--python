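from __future__ import annotations

import numpy as np
import pytest

from parscan.core import HaplotypePanel, Window
from parscan.synthetic_data import CrossDesign, PanelConfig, simulate_sex_panels


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_random_panel(rng) -> HaplotypePanel:
    """30 haplotypes (15 X, 15 Y) over 40 random biallelic sites."""
    alleles = rng.integers(0, 2, size=(30, 40)).astype(np.int8)
    positions = np.sort(rng.choice(np.arange(1, 100_000), size=40, replace=False))
    labels = np.array(["X"] * 15 + ["Y"] * 15)
    return HaplotypePanel("chrT", positions, alleles, labels)


@pytest.fixture
def par_only_config() -> PanelConfig:
    """1 Mb chromosome that is all PAR (no SDR)."""
    return PanelConfig(chrom_length_bp=1_000_000, sdr_boundary_bp=1,
                       snp_per_10kb=10.0)


@pytest.fixture
def default_design() -> CrossDesign:
    return CrossDesign()


@pytest.fixture
def window_100kb() -> Window:
    return Window("chrT", 1, 100_001)


def make_neutral_panel(seed: int, n_windows: int = 200, snp_per_10kb: float = 12.0,
                       window_size: int = 10_000) -> HaplotypePanel:
    """PAR-only panel spanning n_windows windows, labels exchangeable."""
    cfg = PanelConfig(
        chrom_length_bp=n_windows * window_size,
        sdr_boundary_bp=1,
        snp_per_10kb=snp_per_10kb,
        species_divergence_per_10kb=0.0,
        n_sister=1,
    )
    panel, _ = simulate_sex_panels(cfg, seed)
    return panel
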