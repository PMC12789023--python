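"""Per-sample community function vectors.

A function vector holds, for one pooled community sample (plot x year x
replicate, seasons merged), each detected species' contribution z_i to the
community function.  Two modes are supported:

* ``total_biomass`` -- z_i = abundance_i * m_i, the species' total dry biomass
  (mg); the default, combining abundance and individual size.
* ``mean_individual_biomass`` -- z_i = m_i, the per-individual dry mass only,
  which removes abundance effects from the partition.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import AllometricTable, DataValidationError, SampleKey

MODES = ("total_biomass", "mean_individual_biomass")


def individual_dry_mass(length_mm, taxon_group: str, allometry: AllometricTable):
    """Individual dry mass (mg) from body length via ``m = a * L**b``."""
    return allometry.mass(length_mm, taxon_group)


@dataclass(frozen=True)
class FunctionVector:
    """Species-level function contributions of one community sample.

    ``entries`` is indexed by species_id with columns ``abundance`` (int > 0)
    and ``z`` (mg >= 0).  Species with zero abundance are absent by invariant.
    """

    key: SampleKey
    mode: str
    entries: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if len(self.entries):
            if (self.entries["abundance"] <= 0).any():
                raise DataValidationError("zero-abundance species must be absent")
            if (self.entries["z"] < 0).any():
                raise DataValidationError("z must be >= 0")

    @property
    def total(self) -> float:
        """T -- total community function (mg)."""
        return float(self.entries["z"].sum())

    @property
    def richness(self) -> int:
        """s -- number of detected species."""
        return int(len(self.entries))

    @property
    def mean_z(self) -> float:
        """z-bar = T / s; NaN for an empty community."""
        return self.total / self.richness if self.richness else float("nan")

    @property
    def species(self) -> pd.Index:
        return self.entries.index

    def z(self, species_id: str) -> float:
        return float(self.entries.at[species_id, "z"])

    @property
    def is_empty(self) -> bool:
        return self.richness == 0


def build_function_vector(
    observations: pd.DataFrame,
    allometry: AllometricTable,
    mode: str = "total_biomass",
    guild_filter: set[str] | None = None,
) -> FunctionVector:
    """Build the function vector for the observations of one sample.

    All rows must share one (plot, year, replicate); both seasons are allowed
    and are pooled by summing counts per species before z computation.  With a
    guild filter, species outside the filter are removed before pooling.  An
    empty result (all filtered, or all counts zero) is a valid empty vector.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    keys = observations[["plot_id", "year", "replicate"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError(
            "observations span more than one (plot, year, replicate) sample"
        )
    key = SampleKey(keys.iloc[0, 0], int(keys.iloc[0, 1]), keys.iloc[0, 2])
    return _vector_from_rows(observations, key, allometry, mode, guild_filter)


def _vector_from_rows(rows, key, allometry, mode, guild_filter):
    if guild_filter is not None:
        rows = rows[rows["guild"].isin(guild_filter)]
    pooled = (
        rows.groupby("species_id")
        .agg(
            abundance=("count", "sum"),
            body_length_mm=("body_length_mm", "first"),
            taxon_group=("taxon_group", "first"),
        )
        .query("abundance > 0")
    )
    if len(pooled):
        mass = np.array(
            [
                allometry.mass(length, taxon)
                for length, taxon in zip(
                    pooled["body_length_mm"], pooled["taxon_group"]
                )
            ]
        )
        z = pooled["abundance"].to_numpy() * mass if mode == "total_biomass" else mass
    else:
        z = np.empty(0)
    entries = pd.DataFrame(
        {"abundance": pooled["abundance"].to_numpy(dtype=np.int64), "z": z},
        index=pooled.index,
    )
    return FunctionVector(key=key, mode=mode, entries=entries)


def build_function_vectors(
    observations: pd.DataFrame,
    allometry: AllometricTable,
    mode: str = "total_biomass",
    guild_filter: set[str] | None = None,
) -> dict[SampleKey, FunctionVector]:
    """Function vectors for every (plot, year, replicate) sample in a table."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    obs = observations
    sample_cols = ["plot_id", "year", "replicate"]
    all_keys = [
        SampleKey(p, int(y), r)
        for p, y, r in obs[sample_cols].drop_duplicates().itertuples(index=False)
    ]
    if guild_filter is not None:
        obs = obs[obs["guild"].isin(guild_filter)]
    pooled = obs.groupby(sample_cols + ["species_id"], as_index=False).agg(
        abundance=("count", "sum"),
        body_length_mm=("body_length_mm", "first"),
        taxon_group=("taxon_group", "first"),
    )
    pooled = pooled[pooled["abundance"] > 0]
    # vectorized allometric mass over the whole table
    coef = allometry.coefficients
    unknown = set(pooled["taxon_group"].unique()) - allometry.groups
    if unknown:
        from .data_model import AllometryError

        raise AllometryError(f"taxon group(s) {sorted(unknown)} absent from allometric table")
    a = pooled["taxon_group"].map(coef["a"]).to_numpy(dtype=float)
    b = pooled["taxon_group"].map(coef["b"]).to_numpy(dtype=float)
    mass = a * pooled["body_length_mm"].to_numpy(dtype=float) ** b
    z = pooled["abundance"].to_numpy() * mass if mode == "total_biomass" else mass
    pooled = pooled.assign(z=z)

    vectors: dict[SampleKey, FunctionVector] = {}
    for (plot, year, rep), rows in pooled.groupby(sample_cols, sort=True):
        key = SampleKey(plot, int(year), rep)
        entries = pd.DataFrame(
            {
                "abundance": rows["abundance"].to_numpy(dtype=np.int64),
                "z": rows["z"].to_numpy(),
            },
            index=pd.Index(rows["species_id"], name="species_id"),
        )
        vectors[key] = FunctionVector(key=key, mode=mode, entries=entries)
    empty = pd.DataFrame({"abundance": np.empty(0, np.int64), "z": np.empty(0)})
    for key in all_keys:  # samples emptied by filtering stay as empty vectors
        if key not in vectors:
            vectors[key] = FunctionVector(key=key, mode=mode, entries=empty.copy())
    return vectors


def vectors_to_frame(vectors: dict[SampleKey, FunctionVector]) -> pd.DataFrame:
    """Export function vectors as a long table (one row per species entry)."""
    parts = []
    for key, vec in vectors.items():
        if vec.is_empty:
            continue
        part = vec.entries.reset_index().rename(columns={"index": "species_id"})
        part.insert(0, "plot_id", key.plot_id)
        part.insert(1, "year", key.year)
        part.insert(2, "replicate", key.replicate)
        part.insert(3, "mode", vec.mode)
        parts.append(part)
    if not parts:
        return pd.DataFrame(
            columns=["plot_id", "year", "replicate", "mode", "species_id", "abundance", "z"]
        )
    return pd.concat(parts, ignore_index=True)
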