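import numpy as np
import pandas as pd
import pytest

from ecoprice.data_model import SampleKey
from ecoprice.price import RESPONSES, partition_batch, price_partition

from .conftest import make_vector, random_vector
from .oracle import brute_force_partition

COMPONENTS = ["sre_loss", "sie_loss", "sre_gain", "sie_gain", "cde"]


def as_zdict(vec):
    return dict(zip(vec.entries.index, vec.entries["z"]))


class TestWorkedExample:
    baseline = {"A": 4.0, "B": 2.0, "C": 6.0}
    comparison = {"A": 3.0, "B": 2.0, "D": 1.0}
    # hand derivation, confirmed against the brute-force oracle below:
    # z-bar = 4, z-bar' = 2, shared = {A, B}
    expected = {
        "sre_loss": -4.0,
        "sie_loss": -2.0,
        "sre_gain": 2.0,
        "sie_gain": -1.0,
        "cde": -1.0,
        "delta_function": -6.0,
    }

    def test_oracle_confirms_hand_derivation(self):
        oracle = brute_force_partition(self.baseline, self.comparison)
        for name, value in self.expected.items():
            assert oracle[name] == pytest.approx(value, abs=1e-12)

    def test_partition_matches_hand_derivation(self):
        part = price_partition(
            make_vector(self.baseline), make_vector(self.comparison)
        )
        for name, value in self.expected.items():
            assert getattr(part, name) == pytest.approx(value, abs=1e-12)
        assert part.richness_shared == 2
        assert part.species_lost == -1 and part.species_gained == 1


class TestStructuralCases:
    def test_identical_vectors_give_all_zero_components(self):
        vec = make_vector({"A": 4.0, "B": 2.0})
        part = price_partition(vec, make_vector({"A": 4.0, "B": 2.0}))
        for name in COMPONENTS:
            assert getattr(part, name) == 0.0

    def test_losing_an_average_species_is_pure_richness_loss(self):
        # the lost species has z exactly equal to the baseline mean
        part = price_partition(
            make_vector({"A": 2.0, "B": 2.0}), make_vector({"A": 2.0})
        )
        assert part.sre_loss == pytest.approx(-2.0)
        assert part.sie_loss == 0.0
        assert part.sre_gain == 0.0 and part.sie_gain == 0.0 and part.cde == 0.0

    def test_empty_baseline_loads_all_change_on_gain_terms(self):
        part = price_partition(make_vector({}), make_vector({"A": 3.0, "B": 1.0}))
        assert part.sre_loss == 0.0 and part.sie_loss == 0.0 and part.cde == 0.0
        assert part.sre_gain == pytest.approx(4.0)
        assert part.sie_gain == 0.0
        assert part.component_sum == pytest.approx(part.delta_function)

    def test_empty_vs_empty_is_all_zero(self):
        part = price_partition(make_vector({}), make_vector({}))
        assert part.component_sum == 0.0 and part.delta_function == 0.0

    def test_mode_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            price_partition(
                make_vector({"A": 1.0}),
                make_vector({"A": 1.0}, mode="mean_individual_biomass"),
            )

    def test_equal_z_everywhere_kills_identity_terms(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(1, 8, size=2)
            b = {f"sp{i}": 3.0 for i in range(n1)}
            c = {f"sp{i}": 3.0 for i in rng.choice(12, size=n2, replace=False)}
            part = price_partition(make_vector(b), make_vector(c))
            assert part.sie_loss == pytest.approx(0.0, abs=1e-12)
            assert part.sie_gain == pytest.approx(0.0, abs=1e-12)


class TestFuzzedProperties:
    def test_sum_identity_on_1000_random_pairs(self, rng):
        worst = 0.0
        for _ in range(1000):
            part = price_partition(random_vector(rng), random_vector(rng))
            err = abs(part.component_sum - part.delta_function) / max(
                1.0, abs(part.delta_function)
            )
            worst = max(worst, err)
        assert worst < 1e-9

    def test_oracle_equivalence_on_100_random_instances(self, rng):
        for _ in range(100):
            b, c = random_vector(rng), random_vector(rng)
            part = price_partition(b, c)
            oracle = brute_force_partition(as_zdict(b), as_zdict(c))
            for name in COMPONENTS + ["delta_function"]:
                assert getattr(part, name) == pytest.approx(
                    oracle[name], abs=1e-12
                ), name

    def test_role_swap_antisymmetry(self, rng):
        for _ in range(100):
            b, c = random_vector(rng), random_vector(rng)
            fwd = price_partition(b, c)
            rev = price_partition(c, b)
            assert rev.delta_function == pytest.approx(-fwd.delta_function, abs=1e-9)
            assert rev.cde == pytest.approx(-fwd.cde, abs=1e-9)
            # the loss terms of the reversed pair mirror the gain terms
            assert rev.sre_loss == pytest.approx(-fwd.sre_gain, abs=1e-9)
            assert rev.sie_loss == pytest.approx(-fwd.sie_gain, abs=1e-9)
            assert rev.sre_gain == pytest.approx(-fwd.sre_loss, abs=1e-9)

    def test_sign_constraints(self, rng):
        for _ in range(200):
            part = price_partition(random_vector(rng), random_vector(rng))
            assert part.sre_loss <= 0.0 <= part.sre_gain
            assert part.richness_shared <= min(
                part.richness_baseline, part.richness_comparison
            )

    def test_mean_individual_mode_kills_cde(self, rng):
        # constant per-species z on both sides: persisting species change nothing
        for _ in range(1000):
            pool = {f"sp{i}": float(m) for i, m in enumerate(rng.gamma(2, 1, 15))}
            pick = lambda: {
                s: pool[s]
                for s in rng.choice(list(pool), size=rng.integers(0, 10), replace=False)
            }
            part = price_partition(
                make_vector(pick(), mode="mean_individual_biomass"),
                make_vector(pick(), mode="mean_individual_biomass"),
            )
            assert part.cde == 0.0


class TestPartitionBatch:
    def make_pairs(self):
        return pd.DataFrame(
            {
                "plot_id": ["p1"],
                "year_baseline": [2010],
                "year_comparison": [2012],
                "replicate_baseline": ["A"],
                "replicate_comparison": ["A"],
                "span": [2],
                "scheme": ["moving_average"],
            }
        )

    def test_single_pair_row_has_nine_responses(self):
        vectors = {
            SampleKey("p1", 2010, "A"): make_vector(
                TestWorkedExample.baseline, key=SampleKey("p1", 2010, "A")
            ),
            SampleKey("p1", 2012, "A"): make_vector(
                TestWorkedExample.comparison, key=SampleKey("p1", 2012, "A")
            ),
        }
        table = partition_batch(self.make_pairs(), vectors)
        assert len(table) == 1
        for name, value in TestWorkedExample.expected.items():
            assert table.loc[0, name] == pytest.approx(value)
        assert set(RESPONSES) <= set(table.columns)

    def test_empty_pair_table_keeps_schema(self):
        table = partition_batch(self.make_pairs().iloc[:0], {})
        assert len(table) == 0
        assert set(RESPONSES) <= set(table.columns)

    def test_unresolved_key_is_reported(self):
        with pytest.raises(KeyError, match="p1"):
            partition_batch(self.make_pairs(), {})

    def test_control_pair_of_identical_replicates_is_all_zero(self):
        pairs = self.make_pairs().assign(
            year_comparison=2010, replicate_comparison="B", span=0, scheme="control"
        )
        z = {"A": 1.5, "B": 2.5}
        vectors = {
            SampleKey("p1", 2010, "A"): make_vector(z, key=SampleKey("p1", 2010, "A")),
            SampleKey("p1", 2010, "B"): make_vector(z, key=SampleKey("p1", 2010, "B")),
        }
        table = partition_batch(pairs, vectors)
        assert np.allclose(table[COMPONENTS + ["delta_function"]].to_numpy(), 0.0)
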