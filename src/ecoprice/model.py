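"""Model/Results interface for resampling trend inference on Price partitions.

:class:`CommunityTrendModel` is built from data (an observation table plus
covariates, or a ready partition table) and describes the comparison design;
:meth:`CommunityTrendModel.fit` runs the resampling ensemble -- for each of
``n_models`` no-reuse subsets, one (mixed) linear model per response -- and
returns a :class:`CommunityTrendResults` carrying median estimates,
percentile confidence intervals, empirical P-values, conditional time slopes
at chosen covariate levels, back-transformed prediction grids, component
contributions to total change, and percentage decline rates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design as design_mod
from .biomass import build_function_vectors
from .data_model import AllometricTable, validate_observations
from .design import CovariateScaling, DisjointPairSampler
from .diagnostics import occupancy_filter, variance_inflation
from .inference import (
    CrossedREML,
    FitError,
    _design,
    empirical_p,
    empirical_p_floor,
    fit_ols,
    sqrt_signed,
    sqrt_signed_inverse,
    summarize_ensemble,
)
from .price import RESPONSES, partition_batch

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = {"experiment": (1.0, 60.0), "real_world": (0.5, 3.5)}

#: component groupings reported by contributions()
GROUPINGS = {
    "richness": ("sre_loss", "sre_gain"),
    "identity": ("sie_loss", "sie_gain"),
    "turnover": ("sre_loss", "sie_loss", "sre_gain", "sie_gain"),
    "cde": ("cde",),
}


class CommunityTrendModel:
    """Trend model for the nine partition responses of one comparison design.

    Parameters
    ----------
    partitions
        Partition table (one row per comparison pair) carrying the response
        columns, ``span``, ``scheme``, ``covariate`` and ``covariate_z``.
    scheme
        Comparison scheme the temporal pairs were enumerated under.
    scaling
        z-scoring constants of the covariate (fitted on the full pair table).
    design_mode
        'experiment' (PSR covariate) or 'real_world' (LUI covariate);
        selects the default conditional-slope levels.
    baseline_mean
        Mean community function over the baseline-window samples, used as the
        denominator of percentage-decline estimates.
    """

    def __init__(
        self,
        partitions: pd.DataFrame,
        scheme: str,
        scaling: CovariateScaling,
        design_mode: str = "experiment",
        baseline_mean: float | None = None,
        responses: list[str] | None = None,
    ):
        if not len(partitions):
            raise ValueError("empty partition table")
        self.partitions = partitions.reset_index(drop=True)
        self.scheme = scheme
        self.scaling = scaling
        self.design_mode = design_mode
        self.baseline_mean = baseline_mean
        self.responses = list(responses) if responses is not None else list(RESPONSES)
        self.max_span = int(self.partitions["span"].max())

    @classmethod
    def from_observations(
        cls,
        observations: pd.DataFrame,
        covariates: pd.DataFrame,
        allometry: AllometricTable,
        *,
        design_mode: str = "experiment",
        scheme: str = "restricted_moving_average",
        biomass_mode: str = "total_biomass",
        guild_filter: set[str] | None = None,
        baseline_window: int = 5,
        min_replicates: int = 2,
        include_controls: bool = True,
        control_directions: int = 2,
        occupancy_threshold: float | None = None,
    ) -> "CommunityTrendModel":
        """Build the model from a validated observation table.

        Runs the full preparation pipeline: optional occupancy filtering,
        function vectors (seasons pooled), pair enumeration under the scheme,
        covariate attachment and scaling, and the Price partition of every
        pair.
        """
        observations = validate_observations(observations, allometry=allometry)
        if occupancy_threshold:
            observations = occupancy_filter(observations, occupancy_threshold)
        vectors = build_function_vectors(
            observations, allometry, mode=biomass_mode, guild_filter=guild_filter
        )
        keys = pd.DataFrame(
            [(k.plot_id, k.year, k.replicate) for k in vectors],
            columns=["plot_id", "year", "replicate"],
        )
        pairs = design_mod.enumerate_pairs(
            keys,
            scheme,
            baseline_window=baseline_window,
            min_replicates=min_replicates,
            include_controls=include_controls,
            control_directions=control_directions,
        )
        pairs = design_mod.attach_covariates(pairs, covariates, mode=design_mode)
        pairs, scaling = design_mod.scale_covariate(pairs)
        partitions = partition_batch(pairs, vectors, mode=biomass_mode)

        first_years = set(np.sort(keys["year"].unique())[:baseline_window])
        baseline_totals = [
            v.total for k, v in vectors.items() if k.year in first_years
        ]
        baseline_mean = float(np.mean(baseline_totals)) if baseline_totals else None
        return cls(
            partitions,
            scheme=scheme,
            scaling=scaling,
            design_mode=design_mode,
            baseline_mean=baseline_mean,
        )

    def design_vif(self) -> pd.Series:
        """VIF of the fixed-effect design on the full pair table (flag if >= 2)."""
        df = self.partitions
        X = pd.DataFrame(
            {
                "span": df["span"].astype(float),
                "covariate_z": df["covariate_z"].astype(float),
                "span:covariate_z": df["span"].astype(float) * df["covariate_z"],
            }
        )
        vif = variance_inflation(X)
        if (vif >= 2).any():
            logger.warning("fixed-effect design has VIF >= 2:\n%s", vif)
        return vif

    def fit(
        self,
        n_models: int = 1000,
        seed: int | np.random.Generator | None = None,
        covariate_levels: tuple[float, ...] | None = None,
        spans: list[int] | None = None,
        max_failure_rate: float = 0.05,
    ) -> "CommunityTrendResults":
        """Run the resampling ensemble.

        For each of ``n_models`` subsets every response is fitted under the
        scheme's model contract; subsets whose fit fails are redrawn (aborting
        if failures exceed ``max_failure_rate`` of ``n_models``).  Prediction
        grids cover spans 0..max retained span at the requested covariate
        levels plus the design mean.
        """
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        if covariate_levels is None:
            covariate_levels = DEFAULT_LEVELS[self.design_mode]
        levels = [float(x) for x in covariate_levels]
        levels_z = list(self.scaling.z(levels)) + [0.0]  # trailing: design mean
        if spans is None:
            spans = list(range(0, self.max_span + 1))
        spans_arr = np.asarray(spans, dtype=float)
        levels_z_arr = np.asarray(levels_z, dtype=float)

        sampler = DisjointPairSampler(self.partitions)
        n_resp = len(self.responses)
        coefs = np.empty((n_models, n_resp, 4))
        slopes = np.empty((n_models, n_resp, len(levels_z)))
        preds = np.empty((n_models, n_resp, len(spans), len(levels_z)))
        span_grid = spans_arr[:, None] * np.ones_like(levels_z_arr)[None, :]
        level_grid = np.ones_like(spans_arr)[:, None] * levels_z_arr[None, :]

        n_failures = 0
        m = 0
        while m < n_models:
            subset = sampler.draw(rng)
            try:
                fits = self._fit_subset(subset)
            except FitError as err:
                n_failures += 1
                logger.warning("subset fit failed (%s); redrawing", err)
                if n_failures > max_failure_rate * n_models:
                    raise RuntimeError(
                        f"{n_failures} failed subset fits exceed "
                        f"{max_failure_rate:.0%} of {n_models}"
                    ) from err
                continue
            for r, fit in enumerate(fits):
                coefs[m, r] = fit.params
                slopes[m, r] = fit.conditional_slope(levels_z_arr)
                preds[m, r] = sqrt_signed_inverse(fit.predict(span_grid, level_grid))
            m += 1

        return CommunityTrendResults(
            model=self,
            coefs=coefs,
            slopes=slopes,
            predictions_raw=preds,
            spans=list(int(s) for s in spans),
            covariate_levels=levels,
            n_fits=n_models,
            n_failures=n_failures,
        )

    def _fit_subset(self, subset: pd.DataFrame):
        span = subset["span"].to_numpy(dtype=float)
        cov_z = subset["covariate_z"].to_numpy(dtype=float)
        X = _design(span, cov_z)
        fits = []
        if self.scheme == "fixed_baseline":
            for resp in self.responses:
                y = sqrt_signed(subset[resp].to_numpy(dtype=float))
                fits.append(fit_ols(y, X))
            return fits
        solver = CrossedREML(
            X,
            {
                "plot": subset["plot_id"].to_numpy(),
                "year_baseline": subset["year_baseline"].to_numpy(),
                "year_comparison": subset["year_comparison"].to_numpy(),
            },
        )
        for resp in self.responses:
            y = sqrt_signed(subset[resp].to_numpy(dtype=float))
            fits.append(solver.fit(y))
        return fits


@dataclass
class CommunityTrendResults:
    """Ensemble summaries of a fitted :class:`CommunityTrendModel`.

    Raw per-model arrays are retained so every summary (estimates, grids,
    contributions, decline) is recomputed from the same 'n_fits' fits.
    """

    model: CommunityTrendModel
    coefs: np.ndarray            # (n_fits, n_responses, 4), transformed scale
    slopes: np.ndarray           # (n_fits, n_responses, n_levels + 1)
    predictions_raw: np.ndarray  # (n_fits, n_responses, n_spans, n_levels + 1), original scale
    spans: list[int]
    covariate_levels: list[float]
    n_fits: int
    n_failures: int = 0
    _level_labels: list[str] = field(init=False)

    def __post_init__(self):
        self._level_labels = [self._fmt(x) for x in self.covariate_levels] + ["mean"]

    @staticmethod
    def _fmt(x: float) -> str:
        return f"{x:g}"

    @property
    def responses(self) -> list[str]:
        return self.model.responses

    def trend_estimates(self) -> pd.DataFrame:
        """Median, 95% percentile CI and empirical P per response and term."""
        terms = ["intercept", "time", "covariate", "time:covariate"]
        records = []
        for r, resp in enumerate(self.responses):
            for t, term in enumerate(terms):
                records.append(self._summary_row(resp, term, self.coefs[:, r, t]))
            for l, label in enumerate(self._level_labels):
                records.append(
                    self._summary_row(
                        resp, f"time slope @ covariate {label}", self.slopes[:, r, l]
                    )
                )
        return pd.DataFrame.from_records(records)

    def _summary_row(self, resp, term, values):
        med, lo, hi = summarize_ensemble(values)
        return {
            "response": resp,
            "term": term,
            "median": float(med),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "p": empirical_p(values),
            "p_floor": empirical_p_floor(len(values)),
            "n_fits": len(values),
        }

    def predictions(self) -> pd.DataFrame:
        """Median and 95% CI of back-transformed predictions on the grid."""
        med, lo, hi = summarize_ensemble(self.predictions_raw)
        records = []
        for r, resp in enumerate(self.responses):
            for s, span in enumerate(self.spans):
                for l, label in enumerate(self._level_labels):
                    records.append(
                        {
                            "response": resp,
                            "span": span,
                            "covariate_level": label,
                            "median": float(med[r, s, l]),
                            "ci_low": float(lo[r, s, l]),
                            "ci_high": float(hi[r, s, l]),
                        }
                    )
        return pd.DataFrame.from_records(records)

    def _pred_at(self, response: str, span: int, level: str) -> np.ndarray:
        r = self.responses.index(response)
        s = self.spans.index(span)
        l = self._level_labels.index(level)
        return self.predictions_raw[:, r, s, l]

    def contributions(self, horizon: int, level: str = "mean") -> pd.DataFrame:
        """Component-group contributions (%) to total change at a horizon.

        Per model, each grouping's combined prediction at the horizon is
        divided by the predicted total change; groups are summarised by the
        median and 95% percentile CI across models.  Shares can exceed 100%
        or be negative when components oppose the total.  Models predicting
        exactly zero total change are excluded (and counted).
        """
        delta = self._pred_at("delta_function", horizon, level)
        ok = delta != 0
        n_excluded = int((~ok).sum())
        if n_excluded:
            logger.warning(
                "%d model(s) predict zero total change at span %d; excluded",
                n_excluded, horizon,
            )
        records = []
        for name, members in GROUPINGS.items():
            combined = sum(self._pred_at(m, horizon, level) for m in members)
            shares = 100.0 * combined[ok] / delta[ok]
            med, lo, hi = summarize_ensemble(shares)
            records.append(
                {
                    "grouping": name,
                    "horizon": horizon,
                    "covariate_level": level,
                    "share_median": float(med),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "n_models": int(ok.sum()),
                    "n_excluded": n_excluded,
                }
            )
        return pd.DataFrame.from_records(records)

    def percent_decline(
        self,
        horizon: int | None = None,
        level: str = "mean",
        baseline_mean: float | None = None,
        annualization: str = "linear",
    ) -> pd.DataFrame:
        """Percentage function loss at the last span and its yearly rate.

        Per model: total % = 100 * (-predicted delta at the horizon) /
        baseline mean function; yearly % = total / horizon (linear) or the
        geometric equivalent.  The baseline mean defaults to the model's
        stored mean over the baseline-window samples.
        """
        if horizon is None:
            horizon = max(self.spans)
        baseline_mean = (
            baseline_mean if baseline_mean is not None else self.model.baseline_mean
        )
        if baseline_mean is None or baseline_mean <= 0:
            raise ValueError("percent_decline requires a positive baseline mean")
        if annualization not in ("linear", "geometric"):
            raise ValueError("annualization must be 'linear' or 'geometric'")
        delta = self._pred_at("delta_function", horizon, level)
        total = 100.0 * (-delta) / baseline_mean
        if annualization == "linear":
            yearly = total / horizon
        else:
            yearly = 100.0 * (1.0 - (1.0 - total / 100.0) ** (1.0 / horizon))
        records = []
        for name, values in (("total_pct", total), ("yearly_pct", yearly)):
            med, lo, hi = summarize_ensemble(values)
            records.append(
                {
                    "quantity": name,
                    "horizon": horizon,
                    "covariate_level": level,
                    "median": float(med),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
        return pd.DataFrame.from_records(records)

    def summary(self) -> str:
        """Plain-text summary of the time terms and headline quantities."""
        est = self.trend_estimates()
        lines = [
            "Community function-change trend ensemble",
            f"  scheme: {self.model.scheme}   design: {self.model.design_mode}",
            f"  fits: {self.n_fits} (failures redrawn: {self.n_failures})",
            f"  enumerated comparison pairs: {len(self.model.partitions)}",
            "",
            f"{'response':<16}{'time median':>12}{'2.5%':>10}{'97.5%':>10}{'P':>8}",
        ]
        time_rows = est[est["term"] == "time"]
        for row in time_rows.itertuples(index=False):
            p = f"<{row.p_floor:.3g}" if row.p == 0 else f"{row.p:.3f}"
            lines.append(
                f"{row.response:<16}{row.median:>12.4f}{row.ci_low:>10.4f}"
                f"{row.ci_high:>10.4f}{p:>8}"
            )
        lines.append("")
        lines.append("(estimates on the signed-sqrt scale; predictions back-transformed)")
        return "\n".join(lines)
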