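import numpy as np
import pandas as pd
import pytest

from ladomics.simulate import SimulationConfig, make_genome, make_methylation


def small_config(**overrides) -> SimulationConfig:
    """Scaled-down study for fast unit tests (same structure, fewer units)."""
    base = dict(
        n_chromosomes=2,
        chrom_length=5_000_000,
        lad_mean_length=100_000,  # keep realized LAD coverage concentrated
        n_probes=2000,
        n_affected_probes=150,
        n_diff_peaks=60,
        n_gained=40,
        n_lost=20,
        n_background_peaks=500,
        peak_lad_enrichment=2.0,  # realized LAD coverage varies more on a tiny genome
        n_genes=300,
        n_de_genes=60,
        n_de_up=30,
        n_de_down=30,
        clock_n_probes=50,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """One small synthetic study shared across read-only tests."""
    cfg = small_config()
    genome = make_genome(cfg, seed=11)
    beta, det, sheet, truth = make_methylation(cfg, genome, seed=11)
    return {
        "config": cfg,
        "genome": genome,
        "beta": beta,
        "detection": det,
        "sheet": sheet,
        "truth": truth,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
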