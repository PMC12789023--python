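"""Five-part ecological Price partition of community function change.

The partition decomposes the change in total community function
Delta-T = T' - T between a baseline and a comparison community into five
additive components.  With s, s' the two richnesses, s_c the shared-species
richness, z-bar = T/s and z-bar' = T'/s' the mean per-species functions, and
C the shared species set:

* ``sre_loss``  = -(s - s_c) * z-bar          (species richness loss, <= 0)
* ``sie_loss``  = sum_{i in C} z_i - s_c * z-bar   (species identity loss)
* ``sre_gain``  = (s' - s_c) * z-bar'          (species richness gain, >= 0)
* ``sie_gain``  = s_c * z-bar' - sum_{i in C} z'_i (species identity gain)
* ``cde``       = sum_{i in C} (z'_i - z_i)    (function change of persisters)

The richness terms give the change expected if every lost (gained) species
had the average function of its community; the identity terms absorb the
deviation of the actually lost/gained species from that average; the cde term
collects the change among persisting species, which with constant per-species
body mass is attributable purely to abundance change.  The five terms sum to
Delta-T exactly.

Empty-community convention: an empty side has z-bar taken as 0, so all change
loads on the other side's terms and the sum identity is preserved; an
empty-vs-empty pair yields an all-zero partition.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .biomass import FunctionVector
from .data_model import SampleKey

#: the nine response columns modelled downstream
RESPONSES = [
    "sre_loss",
    "sie_loss",
    "sre_gain",
    "sie_gain",
    "cde",
    "delta_function",
    "species_lost",
    "species_gained",
    "delta_richness",
]

COMPONENTS = RESPONSES[:5]


@dataclass(frozen=True)
class PricePartition:
    """Price partition of one ordered (baseline, comparison) sample pair."""

    baseline_key: SampleKey
    comparison_key: SampleKey
    span: int
    richness_baseline: int       # s
    richness_comparison: int     # s'
    richness_shared: int         # s_c
    total_baseline: float        # T (mg)
    total_comparison: float      # T' (mg)
    sre_loss: float
    sie_loss: float
    sre_gain: float
    sie_gain: float
    cde: float

    @property
    def delta_function(self) -> float:
        """Delta-T = T' - T (mg)."""
        return self.total_comparison - self.total_baseline

    @property
    def component_sum(self) -> float:
        return self.sre_loss + self.sie_loss + self.sre_gain + self.sie_gain + self.cde

    @property
    def species_lost(self) -> int:
        """Signed count of lost species, -(s - s_c) <= 0."""
        return -(self.richness_baseline - self.richness_shared)

    @property
    def species_gained(self) -> int:
        return self.richness_comparison - self.richness_shared

    @property
    def delta_richness(self) -> int:
        return self.richness_comparison - self.richness_baseline

    def responses(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RESPONSES}


def price_partition(
    baseline: FunctionVector, comparison: FunctionVector, span: int = 0
) -> PricePartition:
    """Partition the function change from ``baseline`` to ``comparison``."""
    if baseline.mode != comparison.mode:
        raise ValueError(
            f"mode mismatch: {baseline.mode!r} (baseline) vs {comparison.mode!r}"
        )
    s, s_p = baseline.richness, comparison.richness
    total_b, total_c = baseline.total, comparison.total
    shared = baseline.species.intersection(comparison.species)
    s_c = len(shared)
    zbar_b = total_b / s if s else 0.0
    zbar_c = total_c / s_p if s_p else 0.0
    z_shared_b = float(baseline.entries.loc[shared, "z"].sum())
    z_shared_c = float(comparison.entries.loc[shared, "z"].sum())
    return PricePartition(
        baseline_key=baseline.key,
        comparison_key=comparison.key,
        span=span,
        richness_baseline=s,
        richness_comparison=s_p,
        richness_shared=s_c,
        total_baseline=total_b,
        total_comparison=total_c,
        sre_loss=-(s - s_c) * zbar_b,
        sie_loss=z_shared_b - s_c * zbar_b,
        sre_gain=(s_p - s_c) * zbar_c,
        sie_gain=s_c * zbar_c - z_shared_c,
        cde=z_shared_c - z_shared_b,
    )


#: columns of a partition table, in deterministic output order
PARTITION_COLUMNS = [
    "plot_id",
    "year_baseline",
    "year_comparison",
    "replicate_baseline",
    "replicate_comparison",
    "span",
    "scheme",
    "mode",
    "richness_baseline",
    "richness_comparison",
    "richness_shared",
    "total_baseline",
    "total_comparison",
] + RESPONSES


def partition_batch(
    pairs: pd.DataFrame,
    vectors: dict[SampleKey, FunctionVector],
    mode: str = "total_biomass",
) -> pd.DataFrame:
    """Partition every comparison pair of a pair table.

    ``pairs`` must carry the enumeration columns (see :mod:`ecoprice.design`);
    every (plot, year, replicate) endpoint must resolve to a function vector.
    Extra columns (covariates, direction flags) are carried through.  Returns
    one row per pair with the nine response columns.
    """
    carried = [c for c in pairs.columns if c not in PARTITION_COLUMNS]
    # pre-extract plain-dict views of the vectors for speed
    zmaps: dict[SampleKey, dict[str, float]] = {}
    totals: dict[SampleKey, float] = {}
    for key, vec in vectors.items():
        if vec.mode != mode:
            raise ValueError(f"vector for {key} has mode {vec.mode!r}, expected {mode!r}")
        zmaps[key] = dict(zip(vec.entries.index, vec.entries["z"]))
        totals[key] = vec.total
    records = []
    for row in pairs.itertuples(index=False):
        key_b = SampleKey(row.plot_id, int(row.year_baseline), row.replicate_baseline)
        key_c = SampleKey(row.plot_id, int(row.year_comparison), row.replicate_comparison)
        for key in (key_b, key_c):
            if key not in zmaps:
                raise KeyError(f"no function vector for sample {key}")
        zb, zc = zmaps[key_b], zmaps[key_c]
        s, s_p = len(zb), len(zc)
        total_b, total_c = totals[key_b], totals[key_c]
        if s_p < s:
            shared = [sp for sp in zc if sp in zb]
        else:
            shared = [sp for sp in zb if sp in zc]
        s_c = len(shared)
        zbar_b = total_b / s if s else 0.0
        zbar_c = total_c / s_p if s_p else 0.0
        z_shared_b = sum(zb[sp] for sp in shared)
        z_shared_c = sum(zc[sp] for sp in shared)
        rec = {
            "plot_id": row.plot_id,
            "year_baseline": int(row.year_baseline),
            "year_comparison": int(row.year_comparison),
            "replicate_baseline": row.replicate_baseline,
            "replicate_comparison": row.replicate_comparison,
            "span": int(row.span),
            "scheme": row.scheme,
            "mode": mode,
            "richness_baseline": s,
            "richness_comparison": s_p,
            "richness_shared": s_c,
            "total_baseline": total_b,
            "total_comparison": total_c,
            "sre_loss": -(s - s_c) * zbar_b,
            "sie_loss": z_shared_b - s_c * zbar_b,
            "sre_gain": (s_p - s_c) * zbar_c,
            "sie_gain": s_c * zbar_c - z_shared_c,
            "cde": z_shared_c - z_shared_b,
            "delta_function": total_c - total_b,
            "species_lost": -(s - s_c),
            "species_gained": s_p - s_c,
            "delta_richness": s_p - s,
        }
        for col in carried:
            rec[col] = getattr(row, col)
        records.append(rec)
    columns = PARTITION_COLUMNS + carried
    if not records:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame.from_records(records)[columns]
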