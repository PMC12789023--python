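"""Synthetic arthropod community time series with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a regional species pool with log-normal relative abundances and log-normal
  body lengths, negatively correlated (rare species tend to be large-bodied);
* plots with a local pool whose size increases with sown plant species
  richness (experiment mode) or decreases with land-use intensity
  (real-world mode);
* yearly community dynamics: species go locally extinct with a hazard that is
  modulated by the plot covariate and weighted towards rare (and optionally
  large-bodied) species, while persisting species' detection intensities
  decay at a constant yearly rate;
* imperfect detection: counts per plot, season and replicate are Poisson in
  effort x intensity, so detected losses and gains mix real extinctions with
  detection noise -- the latent truth is written to a side table so tests can
  separate the two, which field data cannot.

With all decline rates zero the process is stationary.
:func:`expected_components` is a Monte-Carlo oracle returning the expected
Price components (and component shares) of a (baseline, baseline + h)
comparison under a configuration, for parameter-recovery tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import AllometricTable, OBSERVATION_COLUMNS, SampleKey
from .biomass import FunctionVector
from .price import price_partition, COMPONENTS

#: allocation of 80 experimental plots over sown plant species richness levels
PSR_ALLOCATION = {1: 14, 2: 16, 4: 16, 8: 16, 16: 14, 60: 4}

EXPERIMENT_YEARS = (2010, 2012, 2014, 2016, 2017, 2019, 2020)
ANNUAL_SURVEY_YEARS = tuple(range(2008, 2019))

_TAXA_BY_GUILD = {
    "herbivore": (("Hemiptera", 0.5), ("Orthoptera", 0.2), ("Coleoptera", 0.3)),
    "predator": (("Araneae-hunting", 0.35), ("Araneae-web", 0.35), ("Coleoptera", 0.3)),
    "other": (("Hymenoptera", 0.6), ("Coleoptera", 0.4)),
}
_GUILD_PROBS = {"herbivore": 0.45, "predator": 0.35, "other": 0.20}


def default_allometry() -> AllometricTable:
    """Placeholder taxon-specific length-mass coefficients for synthetic data.

    These are synthetic stand-in values of realistic magnitude for grassland
    arthropods; analyses of real data must supply published taxon-specific
    coefficients instead.
    """
    return AllometricTable.from_records(
        {
            "Coleoptera": (0.040, 2.64),
            "Hemiptera": (0.021, 2.52),
            "Araneae-hunting": (0.050, 2.40),
            "Araneae-web": (0.045, 2.35),
            "Hymenoptera": (0.025, 2.59),
            "Orthoptera": (0.030, 2.55),
        }
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults mirror the emulated study designs."""

    mode: str = "experiment"                 # experiment | real_world
    n_plots: int = 80
    psr_allocation: dict = field(default_factory=lambda: dict(PSR_ALLOCATION))
    lui_range: tuple[float, float] = (0.5, 3.5)
    years: tuple[int, ...] = EXPERIMENT_YEARS
    seasons: tuple[str, ...] = ("spring", "summer")
    n_replicates: int = 2
    n_species: int = 300
    sigma_abundance: float = 1.3             # sd of log relative intensity
    mean_log_length: float = 1.4             # log mm (~4 mm typical)
    sigma_log_length: float = 0.6
    length_abundance_corr: float = -0.4      # rho, in [-1, 0]
    plot_sigma: float = 0.3                  # per-plot lognormal intensity jitter
    pool_inclusion: tuple[float, float] = (0.30, 0.65)
    richness_decline: float = 0.06           # yearly local extinction hazard
    abundance_decline: float = 0.02          # yearly intensity decay of persisters
    rarity_exponent: float = 1.0             # gamma: extinction weight ~ rarity rank
    size_bias: float = 0.25                  # beta: extra weight on large species
    covariate_effect: float = 0.5            # PSR protection / LUI acceleration
    effort: float = 1.0                      # Poisson detection effort scale
    overdispersion: float = 0.0              # gamma-mixing CV^2; 0 = pure Poisson
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("experiment", "real_world"):
            raise ValueError("mode must be 'experiment' or 'real_world'")
        if not (-1.0 <= self.length_abundance_corr <= 0.0):
            raise ValueError("length_abundance_corr must lie in [-1, 0]")
        for name in ("richness_decline", "abundance_decline", "rarity_exponent",
                     "effort", "overdispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mode == "experiment" and sum(self.psr_allocation.values()) != self.n_plots:
            raise ValueError("psr_allocation must sum to n_plots")

    @classmethod
    def experiment(cls, **overrides) -> "SyntheticConfig":
        """Small experimental plots along a sown plant-richness gradient.

        ``n_plots`` may be passed without a matching ``psr_allocation``; the
        default allocation is rescaled proportionally.
        """
        n_plots = overrides.pop("n_plots", None)
        if n_plots is not None and "psr_allocation" in overrides:
            return cls(n_plots=n_plots, **overrides)
        cfg = cls(**overrides)
        if n_plots is not None:
            cfg = cfg.with_plots(n_plots)
        return cfg

    @classmethod
    def real_world(cls, **overrides) -> "SyntheticConfig":
        """Farmed grassland plots along a land-use intensity gradient."""
        defaults = dict(
            mode="real_world", n_plots=150, years=ANNUAL_SURVEY_YEARS
        )
        defaults.update(overrides)
        return cls(**defaults)

    def with_plots(self, n_plots: int) -> "SyntheticConfig":
        """Scale the design down (or up) keeping PSR level proportions."""
        if self.mode == "real_world":
            return replace(self, n_plots=n_plots)
        if n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        total = sum(self.psr_allocation.values())
        # largest-remainder apportionment; levels may drop out at small sizes
        quotas = {lv: k * n_plots / total for lv, k in self.psr_allocation.items()}
        alloc = {lv: int(q) for lv, q in quotas.items()}
        short = n_plots - sum(alloc.values())
        for lv in sorted(quotas, key=lambda lv: quotas[lv] - alloc[lv], reverse=True)[:short]:
            alloc[lv] += 1
        alloc = {lv: k for lv, k in alloc.items() if k > 0}
        return replace(self, n_plots=n_plots, psr_allocation=alloc)


def build_species_pool(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Regional species pool: intensities, body lengths, taxa and guilds.

    Log intensity and log length are bivariate normal with the configured
    negative correlation.
    """
    s = config.n_species
    if s < 1:
        raise ValueError("n_species must be >= 1")
    rho = config.length_abundance_corr
    cov = np.array(
        [
            [config.sigma_abundance**2, rho * config.sigma_abundance * config.sigma_log_length],
            [rho * config.sigma_abundance * config.sigma_log_length, config.sigma_log_length**2],
        ]
    )
    mean = np.array([0.0, config.mean_log_length])
    draws = rng.multivariate_normal(mean, cov, size=s)
    intensity = np.exp(draws[:, 0])
    length = np.exp(draws[:, 1])
    guilds = rng.choice(
        list(_GUILD_PROBS), size=s, p=list(_GUILD_PROBS.values())
    )
    taxa = np.empty(s, dtype=object)
    for guild, options in _TAXA_BY_GUILD.items():
        mask = guilds == guild
        names = [t for t, _ in options]
        probs = [p for _, p in options]
        taxa[mask] = rng.choice(names, size=int(mask.sum()), p=probs)
    return pd.DataFrame(
        {
            "species_id": [f"sp{i:04d}" for i in range(s)],
            "intensity": intensity,
            "body_length_mm": length,
            "taxon_group": taxa,
            "guild": guilds,
        }
    )


class _PlotSimulator:
    """Latent dynamics and detection for one plot."""

    def __init__(self, config, pool, u_cov, lui_by_year, rng):
        self.config = config
        self.rng = rng
        incl_lo, incl_hi = config.pool_inclusion
        p_incl = incl_lo + (incl_hi - incl_lo) * u_cov
        member = rng.random(len(pool)) < p_incl
        local = pool[member].reset_index(drop=True)
        jitter = np.exp(rng.normal(0.0, config.plot_sigma, size=len(local)))
        self.species = local["species_id"].to_numpy()
        self.length = local["body_length_mm"].to_numpy()
        self.taxon = local["taxon_group"].to_numpy()
        self.guild = local["guild"].to_numpy()
        self.intensity = local["intensity"].to_numpy() * jitter
        self.present = np.ones(len(local), dtype=bool)
        self.u_cov = u_cov
        self.lui_by_year = lui_by_year
        # extinction weights from initial rarity rank (1 = rarest) and size
        n = len(local)
        if n:
            order = np.argsort(np.argsort(-self.intensity))  # 0 = most abundant
            rank_q = (order + 1) / n                          # -> 1 for rarest
            size_dev = (np.log(self.length) - config.mean_log_length) / max(
                config.sigma_log_length, 1e-12
            )
            self.weight = rank_q**config.rarity_exponent * np.exp(
                config.size_bias * size_dev
            )
        else:
            self.weight = np.zeros(0)

    def _hazard(self, year: int) -> float:
        c = self.config
        if c.mode == "experiment":
            return c.richness_decline * (1.0 - c.covariate_effect * self.u_cov)
        lui = self.lui_by_year.get(year, 2.0)
        return c.richness_decline * max(
            0.0, 1.0 + c.covariate_effect * (lui - 2.0) / 1.5
        )

    def step(self, year: int) -> None:
        """Advance the latent state by one calendar year ending at ``year``."""
        c = self.config
        alive = np.flatnonzero(self.present)
        if len(alive):
            w = self.weight[alive]
            p = np.clip(self._hazard(year) * w / w.mean(), 0.0, 1.0)
            dead = alive[self.rng.random(len(alive)) < p]
            self.present[dead] = False
        self.intensity = self.intensity * (1.0 - c.abundance_decline)

    def detect(self, year: int) -> list[tuple]:
        """Observation rows (plot-agnostic) for all seasons x replicates."""
        c = self.config
        rows = []
        lam_base = c.effort * self.intensity * self.present
        reps = [chr(ord("A") + r) for r in range(c.n_replicates)]
        for season in c.seasons:
            for rep in reps:
                lam = lam_base
                if c.overdispersion > 0:
                    shape = 1.0 / c.overdispersion
                    lam = lam * self.rng.gamma(shape, 1.0 / shape, size=lam.shape)
                counts = self.rng.poisson(lam)
                for i in np.flatnonzero(counts):
                    rows.append(
                        (
                            year,
                            season,
                            rep,
                            self.species[i],
                            self.taxon[i],
                            self.guild[i],
                            int(counts[i]),
                            float(self.length[i]),
                        )
                    )
        return rows

    def truth_rows(self, year: int) -> list[tuple]:
        return [
            (year, self.species[i], float(self.intensity[i]), bool(self.present[i]))
            for i in range(len(self.species))
        ]


def _plot_covariates(config: SyntheticConfig, rng: np.random.Generator):
    """Per-plot covariate values and normalized 'benign-ness' u in [0, 1]."""
    if config.mode == "experiment":
        levels = []
        for level, k in sorted(config.psr_allocation.items()):
            levels.extend([level] * k)
        levels = np.array(levels)
        rng.shuffle(levels)
        u = np.log(levels) / np.log(max(levels.max(), 2))
        return levels, u, None
    lo, hi = config.lui_range
    base = rng.uniform(lo, hi, size=config.n_plots)
    years_all = range(config.years[0] - 2, config.years[-1] + 1)
    lui = {
        y: np.clip(base + rng.normal(0.0, 0.25, size=config.n_plots), lo, hi)
        for y in years_all
    }
    u = (hi - base) / (hi - lo)
    return base, u, lui


@dataclass
class SimulationResult:
    observations: pd.DataFrame
    covariates: pd.DataFrame
    truth: pd.DataFrame
    pool: pd.DataFrame


def simulate(config: SyntheticConfig, rng: np.random.Generator | None = None) -> SimulationResult:
    """Generate a full observation table plus covariates and latent truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pool = build_species_pool(config, rng)
    cov_values, u, lui = _plot_covariates(config, rng)

    obs_rows, truth_rows, cov_rows = [], [], []
    years = sorted(config.years)
    for p in range(config.n_plots):
        plot_id = f"plot{p:03d}"
        lui_by_year = (
            {y: float(lui[y][p]) for y in lui} if lui is not None else None
        )
        sim = _PlotSimulator(config, pool, float(u[p]), lui_by_year, rng)
        for year in range(years[0], years[-1] + 1):
            if year > years[0]:
                sim.step(year)
            if year in config.years:
                for row in sim.detect(year):
                    obs_rows.append((plot_id, "") + row)
                for row in sim.truth_rows(year):
                    truth_rows.append((plot_id,) + row)
        if config.mode == "experiment":
            cov_rows.append((plot_id, int(cov_values[p])))
        else:
            for y, vals in lui.items():
                cov_rows.append((plot_id, int(y), float(vals[p])))

    observations = pd.DataFrame(
        obs_rows,
        columns=["plot_id", "region", "year", "season", "replicate", "species_id",
                 "taxon_group", "guild", "count", "body_length_mm"],
    )[OBSERVATION_COLUMNS]
    truth = pd.DataFrame(
        truth_rows, columns=["plot_id", "year", "species_id", "intensity", "present"]
    )
    if config.mode == "experiment":
        covariates = pd.DataFrame(cov_rows, columns=["plot_id", "psr"])
    else:
        covariates = pd.DataFrame(cov_rows, columns=["plot_id", "year", "lui"])
    return SimulationResult(observations, covariates, truth, pool)


def _single_pair_partition(config, pool, u_cov, lui_by_year, horizon, mode, rng):
    """Simulate one plot to horizon h and partition (year0, year0 + h)."""
    sim = _PlotSimulator(config, pool, u_cov, lui_by_year, rng)
    year0 = sorted(config.years)[0]
    allo = default_allometry()

    def vector_at(year):
        rows = sim.detect(year)
        counts: dict[str, int] = {}
        meta: dict[str, tuple] = {}
        for (_, _, rep, sp, taxon, guild, count, length) in rows:
            if rep != "A":
                continue
            counts[sp] = counts.get(sp, 0) + count
            meta[sp] = (taxon, length)
        species = sorted(counts)
        abund = np.array([counts[s] for s in species], dtype=np.int64)
        mass = np.array(
            [allo.mass(meta[s][1], meta[s][0]) for s in species]
        )
        z = abund * mass if mode == "total_biomass" else mass
        entries = pd.DataFrame({"abundance": abund, "z": z}, index=pd.Index(species))
        return FunctionVector(
            key=SampleKey("oracle", int(year), "A"), mode=mode, entries=entries
        )

    base = vector_at(year0)
    for year in range(year0 + 1, year0 + horizon + 1):
        sim.step(year)
    comp = vector_at(year0 + horizon)
    return price_partition(base, comp, span=horizon)


def expected_components(
    config: SyntheticConfig,
    horizon: int,
    n_oracle: int = 200,
    rng: np.random.Generator | None = None,
    mode: str = "total_biomass",
    n_boot: int = 500,
) -> pd.DataFrame:
    """Monte-Carlo expectation of the Price components at a time span.

    Simulates ``n_oracle`` independent (baseline, baseline + horizon) plot
    pairs (cycling over the design's plots), partitions each, and returns the
    mean, standard error and -- for the component groupings richness
    (sre_loss + sre_gain), identity (sie_loss + sie_gain), turnover
    (richness + identity) and cde -- the percentage share of the mean total
    change, with bootstrap standard errors.
    """
    if n_oracle < 1:
        raise ValueError("n_oracle must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pool = build_species_pool(config, rng)
    cov_values, u, lui = _plot_covariates(config, rng)
    samples = np.empty((n_oracle, 6))
    for r in range(n_oracle):
        p = r % config.n_plots
        lui_by_year = {y: float(lui[y][p]) for y in lui} if lui is not None else None
        part = _single_pair_partition(
            config, pool, float(u[p]), lui_by_year, horizon, mode, rng
        )
        samples[r] = [
            part.sre_loss, part.sie_loss, part.sre_gain, part.sie_gain, part.cde,
            part.delta_function,
        ]
    names = COMPONENTS + ["delta_function"]
    mean = samples.mean(axis=0)
    se = samples.std(axis=0, ddof=1) / np.sqrt(n_oracle)
    out = pd.DataFrame({"quantity": names, "mean": mean, "se": se})

    groupings = {
        "share_richness": samples[:, 0] + samples[:, 2],
        "share_identity": samples[:, 1] + samples[:, 3],
        "share_turnover": samples[:, 0] + samples[:, 1] + samples[:, 2] + samples[:, 3],
        "share_cde": samples[:, 4],
    }
    delta = samples[:, 5]
    share_rows = []
    for name, vals in groupings.items():
        share = 100.0 * vals.mean() / delta.mean() if delta.mean() != 0 else np.nan
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n_oracle, size=n_oracle)
            d = delta[idx].mean()
            boots[b] = 100.0 * vals[idx].mean() / d if d != 0 else np.nan
        share_rows.append((name, share, float(np.nanstd(boots, ddof=1))))
    shares = pd.DataFrame(share_rows, columns=["quantity", "mean", "se"])
    return pd.concat([out, shares], ignore_index=True)
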