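import numpy as np
import pandas as pd
import pytest

from mothscape._core import GenotypeMatrix
from mothscape.synthdata import SimulationConfig, simulate_dataset


def make_config(**overrides) -> SimulationConfig:
    """Small-but-realistic simulation settings for fast tests."""
    base = dict(grid_rows=32, grid_cols=32, cell_size=10.0, n_env_layers=4,
                spatial_range=100.0, n_individuals=60, n_hosts=4, n_sites=12,
                n_loci=400, seed=11)
    base.update(overrides)
    return SimulationConfig(**base)


def neutral_config(seed: int, **overrides) -> SimulationConfig:
    """All signal components switched off."""
    return make_config(ibd_sd=0.0, env_effect=0.0, host_effect=0.0,
                       frac_env_loci=0.0, frac_host_loci=0.0, seed=seed,
                       **overrides)


@pytest.fixture(scope="session")
def structured_dataset():
    """One dataset with IBD, IBE, and HAD all present."""
    cfg = make_config(ibd_sd=0.8, env_effect=1.0, host_effect=1.0,
                      frac_env_loci=0.1, frac_host_loci=0.1, seed=21)
    rasters, suit, samples, g, truth = simulate_dataset(cfg)
    return {"config": cfg, "rasters": rasters, "suitability": suit,
            "samples": samples, "genotypes": g, "truth": truth}


@pytest.fixture(scope="session")
def neutral_dataset():
    rasters, suit, samples, g, truth = simulate_dataset(neutral_config(31))
    return {"rasters": rasters, "suitability": suit, "samples": samples,
            "genotypes": g, "truth": truth}


def toy_genotypes(dosage, scaffold="s1", positions=None, ids=None,
                  depth=None) -> GenotypeMatrix:
    dosage = np.asarray(dosage, float)
    n, L = dosage.shape
    if positions is None:
        positions = np.arange(1, L + 1) * 1000
    if np.isscalar(scaffold):
        scaffold = [scaffold] * L
    loci = pd.DataFrame({"scaffold": scaffold, "pos": positions})
    if ids is None:
        ids = [f"i{k}" for k in range(n)]
    return GenotypeMatrix(sample_ids=list(ids), loci=loci, dosage=dosage,
                          depth=None if depth is None
                          else np.asarray(depth, float))
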