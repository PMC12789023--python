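"""Sample-coverage estimation, occupancy filters and collinearity checks."""
from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ESTIMATORS = ("good_turing", "chao")


def sample_coverage(counts, estimator: str = "chao") -> float:
    """Estimated sample coverage of one community sample in [0, 1].

    Coverage is the estimated fraction of the community's individuals that
    belong to species represented in the sample, from the singleton (f1) and
    doubleton (f2) frequency counts:

    * ``good_turing``: C = 1 - f1/n
    * ``chao``:        C = 1 - (f1/n) * (n-1) f1 / ((n-1) f1 + 2 f2)

    The chao form falls back to Good-Turing when f2 = 0.  n = 0 is undefined.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    n = int(counts.sum())
    if n == 0:
        raise ValueError("sample coverage is undefined for an empty sample")
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    if f1 == 0:
        return 1.0
    if estimator == "good_turing" or f2 == 0:
        c = 1.0 - f1 / n
    else:
        c = 1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2.0 * f2))
    return float(min(max(c, 0.0), 1.0))


def coverage_table(observations: pd.DataFrame, estimator: str = "chao") -> pd.DataFrame:
    """Per-sample (plot, year, replicate) coverage with its ingredients."""
    records = []
    for (plot, year, rep), grp in observations.groupby(
        ["plot_id", "year", "replicate"], sort=True
    ):
        counts = grp.groupby("species_id")["count"].sum().to_numpy()
        counts = counts[counts > 0]
        n = int(counts.sum())
        f1 = int(np.sum(counts == 1))
        f2 = int(np.sum(counts == 2))
        used = estimator if (f2 > 0 or estimator == "good_turing") else "good_turing"
        cov = sample_coverage(counts, estimator) if n else float("nan")
        records.append((plot, int(year), rep, n, f1, f2, used, cov))
    return pd.DataFrame(
        records,
        columns=["plot_id", "year", "replicate", "n", "f1", "f2", "estimator", "coverage"],
    )


def occupancy_filter(observations: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Keep only species occurring in at least ``threshold`` of plots per year.

    Occupancy is assessed per year with replicates and seasons pooled
    (count > 0 in a plot counts as occupied); the plot universe is the set of
    plots sampled in that year.  The plot-count cutoff uses the ceiling, so a
    10% threshold over 80 plots demands at least 8 plots.  A species may pass
    in some years only.
    """
    if threshold <= 0:
        return observations.reset_index(drop=True)
    keep_masks = []
    for year, grp in observations.groupby("year", sort=True):
        n_plots = grp["plot_id"].nunique()
        cutoff = math.ceil(threshold * n_plots)
        occ = (
            grp[grp["count"] > 0]
            .groupby("species_id")["plot_id"]
            .nunique()
        )
        retained = set(occ[occ >= cutoff].index)
        removed = occ.index.difference(retained)
        logger.info(
            "year %s: occupancy filter %.0f%% keeps %d species, removes %d",
            year, 100 * threshold, len(retained), len(removed),
        )
        keep_masks.append(grp[grp["species_id"].isin(retained)])
    if not keep_masks:
        return observations.iloc[:0]
    return pd.concat(keep_masks).sort_index().reset_index(drop=True)


def variance_inflation(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1 / (1 - R^2_j) per design column.

    Each non-intercept column is regressed on the others (with an intercept).
    Perfectly collinear columns report ``inf``.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two columns")
    if n <= p:
        raise ValueError("VIF needs more rows than columns")
    out = {}
    ones = np.ones((n, 1))
    for j, name in enumerate(design.columns):
        yj = X[:, j]
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        tss = float(np.sum((yj - yj.mean()) ** 2))
        rss = float(resid @ resid)
        if tss == 0 or rss / tss < 1e-12:
            logger.warning("column %s is (near-)perfectly collinear", name)
            out[name] = float("inf")
        else:
            out[name] = 1.0 / (rss / tss)
    return pd.Series(out, name="vif")
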