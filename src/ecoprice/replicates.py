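"""Synthesis of within-year replicates from pooled samples.

Study designs without true field replicates still need a within-year control
for detection noise.  Two operations provide it:

* :func:`split_sample` -- split one pooled sample into replicates A and B by
  drawing a Poisson-distributed number of individuals (mean N/2, truncated to
  [0, N]) uniformly without replacement; B receives the complement, so
  per-species counts are conserved exactly.
* :func:`bootstrap_replicate` -- resample a Poisson-distributed number of
  individuals (mean N by default, configurable to N/2) with replacement; used
  to fabricate a replicate for an incomplete sampling.

Both operate at the individual level: each of the N individuals is equally
likely, regardless of species.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def split_counts(
    counts: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split a per-species count vector into (A, B) with A + B == counts.

    n_A ~ Poisson(N/2) truncated to [0, N]; the n_A individuals are drawn
    uniformly without replacement (multivariate hypergeometric over species).
    """
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    n = int(counts.sum())
    if n == 0:
        return np.zeros_like(counts), np.zeros_like(counts)
    n_a = min(int(rng.poisson(n / 2.0)), n)
    a = rng.multivariate_hypergeometric(counts, n_a)
    return a, counts - a


def bootstrap_counts(
    counts: np.ndarray, rng: np.random.Generator, mean: str = "N"
) -> np.ndarray:
    """Resample a per-species count vector with replacement.

    Draw size ~ Poisson(N) (``mean="N"``) or Poisson(N/2) (``mean="N/2"``);
    individuals are drawn with replacement in proportion to species counts.
    """
    if mean not in ("N", "N/2"):
        raise ValueError("mean must be 'N' or 'N/2'")
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    n = int(counts.sum())
    if n == 0:
        logger.warning("bootstrap_counts on an empty sample returns empty")
        return np.zeros_like(counts)
    lam = n if mean == "N" else n / 2.0
    size = int(rng.poisson(lam))
    if size == 0:
        return np.zeros_like(counts)
    return rng.multinomial(size, counts / n)


def _split_event(rows: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    a, b = split_counts(rows["count"].to_numpy(), rng)
    out_a = rows.assign(replicate="A", count=a)
    out_b = rows.assign(replicate="B", count=b)
    out = pd.concat([out_a, out_b], ignore_index=True)
    return out[out["count"] > 0]


def split_sample(
    observations: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the observation rows of one sampling event into replicates A/B.

    Returns two observation tables with replicate labels "A" and "B"; their
    per-species counts sum exactly to the input's.
    """
    out = _split_event(observations, rng)
    return (
        out[out["replicate"] == "A"].reset_index(drop=True),
        out[out["replicate"] == "B"].reset_index(drop=True),
    )


def bootstrap_replicate(
    observations: pd.DataFrame,
    rng: np.random.Generator,
    mean: str = "N",
    replicate_label: str = "B",
) -> pd.DataFrame:
    """Fabricate an artificial replicate for one sampling event's rows."""
    counts = bootstrap_counts(observations["count"].to_numpy(), rng, mean=mean)
    out = observations.assign(replicate=replicate_label, count=counts)
    return out[out["count"] > 0].reset_index(drop=True)


def synthesize_replicates(
    observations: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Split every pooled sampling event of a table into replicates A and B.

    Events are (plot, year, season) groups; existing replicate labels are
    ignored (counts are pooled per event first).  Deterministic for a given
    generator state and table order.
    """
    key = ["plot_id", "year", "season"]
    pooled = (
        observations.groupby(key + ["species_id"], as_index=False)
        .agg(
            region=("region", "first"),
            taxon_group=("taxon_group", "first"),
            guild=("guild", "first"),
            count=("count", "sum"),
            body_length_mm=("body_length_mm", "first"),
        )
    )
    parts = [
        _split_event(rows, rng)
        for _, rows in pooled.groupby(key, sort=True)
    ]
    from .data_model import OBSERVATION_COLUMNS

    if not parts:
        return pd.DataFrame(columns=OBSERVATION_COLUMNS)
    out = pd.concat(parts, ignore_index=True)
    return out[OBSERVATION_COLUMNS].reset_index(drop=True)
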