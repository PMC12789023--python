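"""Comparison design: pair enumeration, covariates, and no-reuse subsets.

Temporal comparisons pair samples of the same plot and replicate label across
years under one of three schemes:

* ``fixed_baseline`` -- every later year against the plot's first sampled year;
* ``moving_average`` -- all ordered within-plot year pairs, pooled by time span;
* ``restricted_moving_average`` -- the moving-average pairs whose baseline lies
  among the first ``baseline_window`` (default 5) sampled years, reducing
  sensitivity to the first sampling year while retaining systematic trends.

Intra-annual controls (replicate A vs B of one plot/year, span 0) quantify the
species turnover and function change expected from detection noise alone.

Because every sample participates in many pairs, modelling all pairs at once
would pseudoreplicate.  :class:`DisjointPairSampler` draws random subsets in
which no (plot, year) sampling event is used twice, with the temporal subset
size fixed at the per-plot maximum matching size.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import MissingCovariateError, SampleKey

logger = logging.getLogger(__name__)

SCHEMES = ("fixed_baseline", "moving_average", "restricted_moving_average")

PAIR_COLUMNS = [
    "plot_id",
    "year_baseline",
    "year_comparison",
    "replicate_baseline",
    "replicate_comparison",
    "span",
    "scheme",
]


def lui_rolling_mean(series: Mapping[int, float], year: int) -> float:
    """Mean land-use intensity over the sampling year and the two before it.

    Missing years inside the window are skipped (the window truncates at the
    start of the series); a window with no value at all is an error.
    """
    window = [series[y] for y in (year - 2, year - 1, year) if y in series]
    if not window:
        raise MissingCovariateError(f"no LUI value in window [{year - 2}, {year}]")
    return float(np.mean(window))


def _sample_frame(sample_keys) -> pd.DataFrame:
    if isinstance(sample_keys, pd.DataFrame):
        df = sample_keys[["plot_id", "year", "replicate"]].drop_duplicates()
    else:
        df = pd.DataFrame(list(sample_keys), columns=["plot_id", "year", "replicate"])
    return df.drop_duplicates().reset_index(drop=True)


def enumerate_pairs(
    sample_keys: Iterable[SampleKey] | pd.DataFrame,
    scheme: str,
    baseline_window: int = 5,
    min_replicates: int = 2,
    include_controls: bool = True,
    control_directions: int = 1,
) -> pd.DataFrame:
    """Enumerate comparison pairs for a set of samples under one scheme.

    Temporal pairs join identical replicate labels within a plot.  For the
    moving-average schemes, spans represented by fewer than ``min_replicates``
    distinct (baseline year, comparison year) combinations across the design
    are dropped; the fixed-baseline scheme keeps all its spans (each occurs
    once by construction).  ``baseline_window`` counts sampled years from the
    start of the whole design.  Controls (one per plot/year with two
    replicates) are appended when requested; ``control_directions=2`` emits
    both orderings so a subset sampler can pick one at random.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    if control_directions not in (1, 2):
        raise ValueError("control_directions must be 1 or 2")
    samples = _sample_frame(sample_keys)
    all_years = np.sort(samples["year"].unique())
    allowed_baselines = set(all_years[:baseline_window]) if np.isfinite(
        baseline_window
    ) else set(all_years)

    records = []
    for (plot, rep), grp in samples.groupby(["plot_id", "replicate"], sort=True):
        years = np.sort(grp["year"].unique())
        first = years.min() if len(years) else None
        for i, yb in enumerate(years):
            if scheme == "fixed_baseline" and yb != first:
                continue
            if scheme == "restricted_moving_average" and yb not in allowed_baselines:
                continue
            for yc in years[i + 1 :]:
                records.append(
                    (plot, int(yb), int(yc), rep, rep, int(yc - yb), scheme)
                )
    pairs = pd.DataFrame(records, columns=PAIR_COLUMNS)

    if scheme != "fixed_baseline" and len(pairs):
        combos = pairs.drop_duplicates(["year_baseline", "year_comparison"])
        span_counts = combos.groupby("span").size()
        kept_spans = set(span_counts[span_counts >= min_replicates].index)
        dropped = sorted(set(span_counts.index) - kept_spans)
        if dropped:
            logger.info("dropping under-replicated spans: %s", dropped)
        pairs = pairs[pairs["span"].isin(kept_spans)]

    if include_controls:
        controls = []
        for (plot, year), grp in samples.groupby(["plot_id", "year"], sort=True):
            reps = sorted(grp["replicate"].unique())
            if len(reps) < 2:
                continue
            a, b = reps[0], reps[1]
            controls.append((plot, int(year), int(year), a, b, 0, "control"))
            if control_directions == 2:
                controls.append((plot, int(year), int(year), b, a, 0, "control"))
        pairs = pd.concat(
            [pairs, pd.DataFrame(controls, columns=PAIR_COLUMNS)], ignore_index=True
        )
    return pairs.reset_index(drop=True)


@dataclass(frozen=True)
class CovariateScaling:
    """z-scoring constants fitted once on the full pair table."""

    mean: float
    sd: float

    def z(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd


def attach_covariates(
    pairs: pd.DataFrame, covariates: pd.DataFrame, mode: str = "experiment"
) -> pd.DataFrame:
    """Attach the comparison-level covariate to each pair.

    Experiment mode: the plot's sown plant species richness (PSR), constant
    over time.  Real-world mode: the mean of the two endpoint years' rolling
    3-year-mean land-use intensities (LUI).
    """
    pairs = pairs.copy()
    if mode == "experiment":
        lut = covariates.set_index("plot_id")["psr"]
        missing = set(pairs["plot_id"].unique()) - set(lut.index)
        if missing:
            raise MissingCovariateError(f"no PSR for plot(s) {sorted(missing)[:5]}")
        pairs["covariate"] = pairs["plot_id"].map(lut).astype(float)
    elif mode == "real_world":
        series = {
            plot: dict(zip(grp["year"], grp["lui"]))
            for plot, grp in covariates.groupby("plot_id")
        }
        values = []
        for row in pairs.itertuples(index=False):
            if row.plot_id not in series:
                raise MissingCovariateError(f"no LUI series for plot {row.plot_id!r}")
            s = series[row.plot_id]
            values.append(
                0.5
                * (
                    lui_rolling_mean(s, int(row.year_baseline))
                    + lui_rolling_mean(s, int(row.year_comparison))
                )
            )
        pairs["covariate"] = values
    else:
        raise ValueError("mode must be 'experiment' or 'real_world'")
    return pairs


def scale_covariate(pairs: pd.DataFrame) -> tuple[pd.DataFrame, CovariateScaling]:
    """Add the z-scored covariate column; scaling constants are returned so
    conditional slopes stay comparable across resampled model fits."""
    x = pairs["covariate"].to_numpy(dtype=float)
    mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("covariate has zero variance; cannot z-score")
    scaling = CovariateScaling(mean=mean, sd=sd)
    pairs = pairs.copy()
    pairs["covariate_z"] = scaling.z(x)
    return pairs, scaling


def _max_matching_size(edges: list[tuple[int, int]]) -> int:
    g = nx.Graph()
    g.add_edges_from(edges)
    return len(nx.max_weight_matching(g, maxcardinality=True))


class DisjointPairSampler:
    """Draw random pair subsets in which no (plot, year) event is reused.

    Within each plot, temporal pairs form a graph on the plot's sampled years;
    a subset is a matching.  Drawing shuffles the plot's pairs and accepts
    greedily, restarting (up to ``max_restarts`` times) until the brute-force
    maximum matching size -- computed once per plot -- is reached, so the
    temporal subset size is a design invariant.  Controls then fill every
    event not consumed by a temporal pair, one random direction per event.
    """

    def __init__(self, pairs: pd.DataFrame, max_restarts: int = 50):
        self.pairs = pairs.reset_index(drop=True)
        self.max_restarts = max_restarts
        temporal = self.pairs[self.pairs["scheme"] != "control"]
        controls = self.pairs[self.pairs["scheme"] == "control"]
        self._plot_edges: dict[str, list[tuple[int, int, int]]] = {}
        for plot, grp in temporal.groupby("plot_id", sort=True):
            self._plot_edges[plot] = [
                (idx, int(yb), int(yc))
                for idx, yb, yc in zip(
                    grp.index, grp["year_baseline"], grp["year_comparison"]
                )
            ]
        self._targets = {
            plot: _max_matching_size([(yb, yc) for _, yb, yc in edges])
            for plot, edges in self._plot_edges.items()
        }
        # control rows grouped per event; 1 or 2 directions per event
        self._controls: dict[tuple[str, int], list[int]] = {}
        for idx, row in controls.iterrows():
            self._controls.setdefault(
                (row["plot_id"], int(row["year_baseline"])), []
            ).append(idx)

    @property
    def temporal_subset_size(self) -> int:
        """Temporal comparisons per subset (the summed maximum matching)."""
        return sum(self._targets.values())

    def draw(self, rng: np.random.Generator) -> pd.DataFrame:
        """One no-reuse subset of the pair table."""
        chosen: list[int] = []
        used_events: set[tuple[str, int]] = set()
        for plot, edges in self._plot_edges.items():
            target = self._targets[plot]
            best: list[int] = []
            best_years: set[int] = set()
            for _ in range(self.max_restarts):
                order = rng.permutation(len(edges))
                taken: list[int] = []
                used_years: set[int] = set()
                for j in order:
                    idx, yb, yc = edges[j]
                    if yb not in used_years and (yb == yc or yc not in used_years):
                        taken.append(idx)
                        used_years.add(yb)
                        used_years.add(yc)
                if len(taken) > len(best):
                    best, best_years = taken, used_years
                if len(best) == target:
                    break
            else:
                logger.warning(
                    "plot %s: greedy matching reached %d of %d after %d restarts",
                    plot, len(best), target, self.max_restarts,
                )
            chosen.extend(best)
            used_events.update((plot, y) for y in best_years)
        for (plot, year), rows in self._controls.items():
            if (plot, year) in used_events:
                continue
            pick = rows[rng.integers(len(rows))] if len(rows) > 1 else rows[0]
            chosen.append(pick)
            used_events.add((plot, year))
        return self.pairs.loc[sorted(chosen)]


def sample_disjoint_subset(
    pairs: pd.DataFrame, rng: np.random.Generator, max_restarts: int = 50
) -> pd.DataFrame:
    """One-shot convenience wrapper around :class:`DisjointPairSampler`."""
    return DisjointPairSampler(pairs, max_restarts=max_restarts).draw(rng)
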