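"""Domain types, validation and CSV I/O for community observation tables.

The pipeline works on long-format species observation tables: one row per
species count at one (plot, year, season, replicate) sampling event, with a
constant per-species body length, taxon group and trophic guild.  Individual
dry mass is obtained from taxon-specific allometric length-mass regressions
``m = a * L**b`` supplied as a separate coefficient table.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: exact column order of an observation CSV
OBSERVATION_COLUMNS = [
    "plot_id",
    "region",
    "year",
    "season",
    "replicate",
    "species_id",
    "taxon_group",
    "guild",
    "count",
    "body_length_mm",
]

#: columns identifying one community sample row (a species within an event)
OBSERVATION_KEY = ["plot_id", "year", "season", "replicate", "species_id"]

GUILDS = frozenset({"herbivore", "predator", "other"})

#: per-species attributes that must be constant across the whole table
SPECIES_ATTRIBUTES = ["body_length_mm", "taxon_group", "guild"]


class SchemaError(ValueError):
    """A CSV is missing required columns or has the wrong layout."""


class DataValidationError(ValueError):
    """A table violates a domain invariant (negative count, bad length...)."""


class AllometryError(LookupError):
    """A taxon group has no allometric coefficients."""


class MissingCovariateError(LookupError):
    """A plot (or plot/year) has no covariate value."""


class SampleKey(NamedTuple):
    """Identifies one pooled community sample (seasons merged)."""

    plot_id: str
    year: int
    replicate: str


@dataclass(frozen=True)
class AllometricTable:
    """Length-mass regression coefficients ``m = a * L**b`` per taxon group.

    ``a`` is the intercept in mg * mm**(-b); ``b`` is dimensionless.  The
    coefficients are a configurable input: published taxon-specific values
    should be supplied for real data.
    """

    coefficients: pd.DataFrame  # index: taxon_group; columns: a, b

    def __post_init__(self) -> None:
        df = self.coefficients
        missing = {"a", "b"} - set(df.columns)
        if missing:
            raise SchemaError(f"allometric table missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            raise DataValidationError("duplicate taxon_group in allometric table")
        if (df["a"] <= 0).any():
            bad = df.index[df["a"] <= 0].tolist()
            raise DataValidationError(f"allometric intercept a must be > 0 for {bad}")

    @classmethod
    def from_records(cls, records: dict[str, tuple[float, float]]) -> "AllometricTable":
        df = pd.DataFrame.from_dict(records, orient="index", columns=["a", "b"])
        df.index.name = "taxon_group"
        return cls(df)

    @classmethod
    def read_csv(cls, path) -> "AllometricTable":
        df = pd.read_csv(path)
        missing = {"taxon_group", "a", "b"} - set(df.columns)
        if missing:
            raise SchemaError(f"allometry CSV missing columns: {sorted(missing)}")
        return cls(df.set_index("taxon_group")[["a", "b"]].astype(float))

    def to_csv(self, path) -> None:
        self.coefficients.reset_index().to_csv(path, index=False)

    @property
    def groups(self) -> frozenset:
        return frozenset(self.coefficients.index)

    def __contains__(self, taxon_group: str) -> bool:
        return taxon_group in self.coefficients.index

    def mass(self, length_mm, taxon_group: str):
        """Individual dry mass in mg for a body length in mm."""
        if taxon_group not in self:
            raise AllometryError(f"no allometric coefficients for {taxon_group!r}")
        a, b = self.coefficients.loc[taxon_group, ["a", "b"]]
        length_mm = np.asarray(length_mm, dtype=float)
        if np.any(length_mm <= 0):
            raise DataValidationError("body length must be > 0")
        out = a * length_mm**b
        return float(out) if out.ndim == 0 else out


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} missing column(s): {missing}")


def validate_observations(
    df: pd.DataFrame, allometry: AllometricTable | None = None
) -> pd.DataFrame:
    """Validate and normalize an observation table.

    Enforces the table invariants: integer counts >= 0, body lengths > 0,
    known guilds, one (length, taxon, guild) triple per species, unique
    (event, species) rows (duplicates are summed with a warning), and -- if an
    allometric table is supplied -- coverage of every taxon group present.
    """
    _require_columns(df, [c for c in OBSERVATION_COLUMNS if c != "region"], "observations")
    df = df.copy()
    if "region" not in df.columns:
        df["region"] = ""
    df["region"] = df["region"].fillna("")
    df["plot_id"] = df["plot_id"].astype(str)
    df["species_id"] = df["species_id"].astype(str)
    df["replicate"] = df["replicate"].astype(str)
    df["season"] = df["season"].astype(str)

    years = pd.to_numeric(df["year"], errors="coerce")
    if years.isna().any():
        rows = df.index[years.isna()].tolist()[:5]
        raise DataValidationError(f"non-numeric year at rows {rows}")
    df["year"] = years.astype(np.int64)

    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != np.floor(counts))
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise DataValidationError(
            f"count must be a non-negative integer; offending rows {rows}"
        )
    df["count"] = counts.astype(np.int64)

    lengths = pd.to_numeric(df["body_length_mm"], errors="coerce")
    bad = lengths.isna() | (lengths <= 0)
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise DataValidationError(f"body_length_mm must be > 0; offending rows {rows}")
    df["body_length_mm"] = lengths.astype(float)

    unknown_guilds = set(df["guild"].unique()) - GUILDS
    if unknown_guilds:
        raise DataValidationError(
            f"unknown guild(s) {sorted(unknown_guilds)}; expected one of {sorted(GUILDS)}"
        )

    # cross-validate species attributes: first-row-wins is forbidden
    attr_counts = df.groupby("species_id")[SPECIES_ATTRIBUTES].nunique()
    inconsistent = attr_counts[(attr_counts > 1).any(axis=1)]
    if len(inconsistent):
        raise DataValidationError(
            "inconsistent species attributes for "
            f"{inconsistent.index.tolist()[:5]} (body length, taxon group and "
            "guild must be constant per species)"
        )

    dup = df.duplicated(OBSERVATION_KEY, keep=False)
    if dup.any():
        n_dup = int(dup.sum())
        logger.warning(
            "summing %d duplicate (event, species) observation rows", n_dup
        )
        keep_attrs = ["region"] + SPECIES_ATTRIBUTES
        df = (
            df.groupby(OBSERVATION_KEY, as_index=False)
            .agg({**{c: "first" for c in keep_attrs}, "count": "sum"})
        )

    if allometry is not None:
        unknown = set(df["taxon_group"].unique()) - allometry.groups
        if unknown:
            raise AllometryError(
                f"taxon group(s) {sorted(unknown)} absent from allometric table"
            )

    return df[OBSERVATION_COLUMNS].reset_index(drop=True)


def read_observations(path, allometry: AllometricTable | None = None) -> pd.DataFrame:
    """Read and validate an observation CSV (see :data:`OBSERVATION_COLUMNS`)."""
    df = pd.read_csv(path, dtype={"plot_id": str, "species_id": str, "region": str})
    return validate_observations(df, allometry=allometry)


def write_observations(df: pd.DataFrame, path) -> None:
    df[OBSERVATION_COLUMNS].to_csv(path, index=False)


def read_psr_covariates(path) -> pd.DataFrame:
    """Plot covariates for the experiment mode: sown plant species richness."""
    df = pd.read_csv(path, dtype={"plot_id": str})
    _require_columns(df, ["plot_id", "psr"], "PSR covariates")
    df["psr"] = pd.to_numeric(df["psr"])
    if df["plot_id"].duplicated().any():
        raise DataValidationError("duplicate plot_id in PSR covariate table")
    if (df["psr"] <= 0).any():
        raise DataValidationError("PSR must be positive")
    return df[["plot_id", "psr"]]


def read_lui_covariates(path) -> pd.DataFrame:
    """Plot x year covariates for the real-world mode: land-use intensity."""
    df = pd.read_csv(path, dtype={"plot_id": str})
    _require_columns(df, ["plot_id", "year", "lui"], "LUI covariates")
    df["year"] = pd.to_numeric(df["year"]).astype(np.int64)
    df["lui"] = pd.to_numeric(df["lui"])
    if df.duplicated(["plot_id", "year"]).any():
        raise DataValidationError("duplicate (plot_id, year) in LUI covariate table")
    if (df["lui"] < 0).any():
        raise DataValidationError("LUI must be >= 0")
    return df[["plot_id", "year", "lui"]]
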