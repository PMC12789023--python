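import numpy as np
import pandas as pd
import pytest

from ecoprice.biomass import FunctionVector
from ecoprice.data_model import AllometricTable, SampleKey


@pytest.fixture
def allometry():
    return AllometricTable.from_records(
        {"beetle": (0.05, 2.5), "bug": (0.02, 2.6), "spider": (1.0, 1.0)}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_vector(z_by_species, key=None, mode="total_biomass", abundance=None):
    """FunctionVector from a {species: z} mapping (abundance defaults to 1)."""
    species = list(z_by_species)
    entries = pd.DataFrame(
        {
            "abundance": [1 if abundance is None else abundance[s] for s in species],
            "z": [float(z_by_species[s]) for s in species],
        },
        index=pd.Index(species, name="species_id"),
    )
    return FunctionVector(
        key=key or SampleKey("p1", 2010, "A"), mode=mode, entries=entries
    )


def make_observations(rows):
    """Observation table from (plot, year, season, rep, species, taxon, guild,
    count, length) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "plot_id", "year", "season", "replicate", "species_id",
            "taxon_group", "guild", "count", "body_length_mm",
        ],
    ).assign(region="")


def random_vector(rng, n_species_max=20, pool_size=30, key=None, mode="total_biomass"):
    """Random function vector over a shared species pool (for fuzz tests)."""
    n = rng.integers(0, n_species_max + 1)
    species = rng.choice(pool_size, size=n, replace=False)
    z = rng.gamma(1.5, 2.0, size=n)
    abund = rng.integers(1, 50, size=n)
    return make_vector(
        {f"sp{int(s)}": float(v) for s, v in zip(species, z)},
        key=key,
        mode=mode,
        abundance={f"sp{int(s)}": int(a) for s, a in zip(species, abund)},
    )
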