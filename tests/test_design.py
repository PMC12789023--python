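import itertools

import numpy as np
import pandas as pd
import pytest

from ecoprice.data_model import MissingCovariateError
from ecoprice.design import (
    DisjointPairSampler,
    attach_covariates,
    enumerate_pairs,
    lui_rolling_mean,
    sample_disjoint_subset,
    scale_covariate,
)

GAPPY_YEARS = [2010, 2012, 2014, 2016, 2017, 2019, 2020]


def keys_for(plots, years, reps=("A", "B")):
    return pd.DataFrame(
        [(p, y, r) for p in plots for y in years for r in reps],
        columns=["plot_id", "year", "replicate"],
    )


class TestLuiRollingMean:
    def test_three_year_mean(self):
        assert lui_rolling_mean({2008: 1.0, 2009: 2.0, 2010: 3.0}, 2010) == pytest.approx(2.0)

    def test_constant_series(self):
        assert lui_rolling_mean({y: 1.7 for y in range(2008, 2012)}, 2011) == pytest.approx(1.7)

    def test_window_truncates_at_series_start(self):
        assert lui_rolling_mean({2008: 1.5}, 2008) == pytest.approx(1.5)

    def test_empty_window_is_an_error(self):
        with pytest.raises(MissingCovariateError):
            lui_rolling_mean({2008: 1.5}, 2015)


class TestEnumeratePairs:
    def test_restricted_scheme_max_retained_span_is_seven_for_gappy_years(self):
        pairs = enumerate_pairs(
            keys_for(["p1"], GAPPY_YEARS), "restricted_moving_average"
        )
        temporal = pairs[pairs["scheme"] != "control"]
        assert temporal["span"].max() == 7
        # spans represented by a single year combination are dropped
        assert 1 not in set(temporal["span"])
        assert {2, 3, 4, 5, 6, 7} == set(temporal["span"])

    def test_moving_average_max_retained_span_is_nine_for_annual_years(self):
        pairs = enumerate_pairs(
            keys_for(["p1"], list(range(2008, 2019))), "moving_average"
        )
        temporal = pairs[pairs["scheme"] != "control"]
        assert temporal["span"].max() == 9

    def test_fixed_baseline_keeps_all_spans(self):
        pairs = enumerate_pairs(keys_for(["p1"], GAPPY_YEARS), "fixed_baseline")
        temporal = pairs[pairs["scheme"] != "control"]
        assert set(temporal["year_baseline"]) == {2010}
        assert temporal["span"].max() == 10

    def test_single_year_yields_exactly_one_control_pair(self):
        pairs = enumerate_pairs(keys_for(["p1"], [2015]), "moving_average")
        assert len(pairs) == 1
        assert pairs.loc[0, "scheme"] == "control"
        assert pairs.loc[0, "span"] == 0

    def test_restricted_with_infinite_window_equals_moving_average(self):
        a = enumerate_pairs(
            keys_for(["p1", "p2"], GAPPY_YEARS), "restricted_moving_average",
            baseline_window=10_000,
        )
        b = enumerate_pairs(keys_for(["p1", "p2"], GAPPY_YEARS), "moving_average")
        pd.testing.assert_frame_equal(
            a[a.scheme != "control"].reset_index(drop=True),
            b[b.scheme != "control"].assign(scheme="restricted_moving_average").reset_index(drop=True),
        )

    def test_every_retained_span_has_min_replicates_year_combos(self):
        pairs = enumerate_pairs(
            keys_for(["p1"], GAPPY_YEARS), "restricted_moving_average", min_replicates=2
        )
        temporal = pairs[pairs["scheme"] != "control"]
        combos = temporal.drop_duplicates(["year_baseline", "year_comparison"])
        assert (combos.groupby("span").size() >= 2).all()

    def test_temporal_pairs_share_the_replicate_label(self):
        pairs = enumerate_pairs(keys_for(["p1"], [2010, 2011]), "moving_average")
        temporal = pairs[pairs["scheme"] != "control"]
        assert (temporal["replicate_baseline"] == temporal["replicate_comparison"]).all()

    def test_both_control_directions_when_requested(self):
        pairs = enumerate_pairs(
            keys_for(["p1"], [2015]), "moving_average", control_directions=2
        )
        assert len(pairs) == 2
        assert set(zip(pairs.replicate_baseline, pairs.replicate_comparison)) == {
            ("A", "B"), ("B", "A"),
        }


class TestAttachCovariates:
    def test_psr_constant_per_plot(self):
        pairs = enumerate_pairs(keys_for(["p1", "p2"], [2010, 2012]), "moving_average")
        cov = pd.DataFrame({"plot_id": ["p1", "p2"], "psr": [16, 1]})
        out = attach_covariates(pairs, cov, mode="experiment")
        assert (out.loc[out.plot_id == "p1", "covariate"] == 16).all()
        assert (out.loc[out.plot_id == "p2", "covariate"] == 1).all()

    def test_lui_pair_covariate_is_mean_of_endpoint_rolling_means(self):
        pairs = pd.DataFrame(
            {
                "plot_id": ["p1"], "year_baseline": [2010], "year_comparison": [2012],
                "replicate_baseline": ["A"], "replicate_comparison": ["A"],
                "span": [2], "scheme": ["moving_average"],
            }
        )
        cov = pd.DataFrame(
            {"plot_id": "p1", "year": [2008, 2009, 2010, 2011, 2012],
             "lui": [1.0, 1.0, 1.6, 1.8, 2.0]}
        )
        out = attach_covariates(pairs, cov, mode="real_world")
        # endpoint rolling means: (1.0+1.0+1.6)/3 = 1.2 and (1.6+1.8+2.0)/3 = 1.8
        assert out.loc[0, "covariate"] == pytest.approx(1.5)

    def test_missing_covariate_is_an_error(self):
        pairs = enumerate_pairs(keys_for(["p9"], [2010]), "moving_average")
        with pytest.raises(MissingCovariateError, match="p9"):
            attach_covariates(pairs, pd.DataFrame({"plot_id": ["p1"], "psr": [1]}), "experiment")

    def test_zero_variance_covariate_cannot_be_scaled(self):
        pairs = enumerate_pairs(keys_for(["p1", "p2"], [2010, 2012]), "moving_average")
        cov = pd.DataFrame({"plot_id": ["p1", "p2"], "psr": [8, 8]})
        out = attach_covariates(pairs, cov, mode="experiment")
        with pytest.raises(ValueError, match="zero variance"):
            scale_covariate(out)

    def test_scaling_constants_are_full_table_statistics(self):
        pairs = enumerate_pairs(keys_for(["p1", "p2"], [2010, 2012]), "moving_average")
        cov = pd.DataFrame({"plot_id": ["p1", "p2"], "psr": [1, 60]})
        out, scaling = scale_covariate(attach_covariates(pairs, cov, "experiment"))
        x = out["covariate"]
        assert scaling.mean == pytest.approx(x.mean())
        assert scaling.sd == pytest.approx(x.std(ddof=1))
        assert out["covariate_z"].mean() == pytest.approx(0.0, abs=1e-12)


def brute_force_max_matching(edges):
    """Maximum number of vertex-disjoint edges, by exhaustive search."""
    best = 0
    for k in range(len(edges), 0, -1):
        for combo in itertools.combinations(edges, k):
            used = [v for e in combo for v in e]
            if len(used) == len(set(used)):
                return k
    return best


class TestDisjointSubsets:
    def test_no_event_reuse_across_many_draws(self, rng):
        pairs = enumerate_pairs(
            keys_for(["p1", "p2", "p3"], GAPPY_YEARS),
            "restricted_moving_average",
            control_directions=2,
        )
        sampler = DisjointPairSampler(pairs)
        sizes = set()
        for _ in range(200):
            subset = sampler.draw(rng)
            events = list(
                zip(subset["plot_id"], subset["year_baseline"])
            ) + [
                (p, y)
                for p, y, s in zip(
                    subset["plot_id"], subset["year_comparison"], subset["span"]
                )
                if s > 0
            ]
            assert len(events) == len(set(events))
            sizes.add(len(subset))
        assert len(sizes) == 1  # subset size is a design invariant

    def test_subset_size_equals_brute_force_matching_on_random_designs(self, rng):
        for trial in range(20):
            n_years = int(rng.integers(2, 7))
            years = sorted(rng.choice(range(2008, 2020), size=n_years, replace=False))
            keys = keys_for(["p1"], [int(y) for y in years], reps=("A",))
            pairs = enumerate_pairs(
                keys, "moving_average", min_replicates=1, include_controls=False
            )
            if not len(pairs):
                continue
            subset = sample_disjoint_subset(pairs, rng)
            edges = list(zip(pairs["year_baseline"], pairs["year_comparison"]))
            assert len(subset) == brute_force_max_matching(edges)

    def test_three_and_four_year_designs(self, rng):
        for years, expected in [([2010, 2011, 2012], 1), ([2010, 2011, 2012, 2013], 2)]:
            pairs = enumerate_pairs(
                keys_for(["p1"], years, reps=("A",)),
                "moving_average", min_replicates=1, include_controls=False,
            )
            subset = sample_disjoint_subset(pairs, rng)
            assert len(subset) == expected

    def test_controls_only_design_keeps_every_event_once(self, rng):
        pairs = enumerate_pairs(
            keys_for(["p1", "p2"], [2010, 2011]), "moving_average",
            control_directions=2,
        ).query("scheme == 'control'")
        subset = DisjointPairSampler(pairs).draw(rng)
        assert len(subset) == 4  # 2 plots x 2 years, one direction each
        events = set(zip(subset["plot_id"], subset["year_baseline"]))
        assert len(events) == 4

    def test_control_direction_is_randomized(self, rng):
        pairs = enumerate_pairs(
            keys_for(["p1"], [2010]), "moving_average", control_directions=2
        )
        sampler = DisjointPairSampler(pairs)
        seen = {
            sampler.draw(rng).iloc[0]["replicate_baseline"] for _ in range(50)
        }
        assert seen == {"A", "B"}
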