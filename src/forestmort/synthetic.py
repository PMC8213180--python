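"""Synthetic permanent-sample-plot inventories with a planted mortality law.

Emulates the structure of a provincial PSP network — 400 m² plots
remeasured every 3 or 5 years, trees tallied at DBH > 5.1 cm, nominal age
classes, a species pool dominated by balsam fir and the spruces — while
planting a *known* covariate-dependent five-year mortality probability, so
that every downstream stage (covariate construction, tree fitting,
cross-validation) can be checked against ground truth.

The planted law is a :class:`HazardSpec`: an ordered rule list over the
covariate vector (first match wins) on top of a baseline five-year
probability, scaled by per-species multipliers.  Deaths are drawn per
remeasurement interval with the five-year probability converted to the
interval length by compound survival, the inverse of the estimator's
period conversion, so generator and estimator agree by construction.

Randomness is reproducible per plot: each plot draws from a generator
seeded with ``(seed, plot index)``, so a plot's data do not depend on how
many other plots are generated.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from . import climate as _climate
from . import covariates as _cov
from .response import convert_rate

#: Default pool: the eight most frequent species of the emulated inventory,
#: weighted by their observation counts (FB balsam fir, SB black spruce,
#: SR red spruce, MR red maple, BW white birch, MS sugar maple,
#: SW white spruce, RT trembling aspen).
DEFAULT_SPECIES_POOL = [
    ("FB", 163119), ("SB", 108378), ("SR", 62614), ("MR", 56676),
    ("BW", 33489), ("MS", 24358), ("SW", 21158), ("RT", 21137),
]

#: Monthly mean daily temperature profile (°C) of a cool maritime climate;
#: yields ~1500 growing degree-days at base 4.4 °C before plot offsets.
BASE_TEMP_PROFILE = np.array(
    [-10.0, -9.0, -4.0, 3.0, 10.0, 15.0, 18.0, 17.0, 12.0, 6.0, 0.0, -7.0])

MIN_TALLY_DBH = 5.1


@dataclass(frozen=True)
class GrowthModel:
    """Annual basal-area increment model.

    Mean increment is suppressed exponentially by stand crowding:
    ``E[dBA/yr] = mean_ba_increment * exp(-suppression * ERD)``; Gaussian
    noise (sd ``noise_sd``) is added per interval-year and increments are
    floored at zero (a stem cannot shrink in the generator).
    """

    mean_ba_increment: float = 8.0      # cm^2 yr^-1 at zero competition
    noise_sd: float = 3.0               # cm^2 yr^-1
    suppression: float = 1.2            # per unit relative density


@dataclass(frozen=True)
class ClimateModel:
    """Cross-plot climate variation targets.

    Each plot is assigned a target annual GDD drawn from
    ``Normal(gdd_mean, gdd_sd)``; the monthly temperature profile is
    shifted to hit that target, with small year-to-year noise
    (``annual_temp_sd`` °C) so interval averaging is exercised.  Annual
    precipitation targets are drawn from ``Normal(pcp_mean, pcp_sd)``.
    """

    gdd_mean: float = 1500.0
    gdd_sd: float = 150.0
    annual_temp_sd: float = 0.25
    pcp_mean: float = 1100.0
    pcp_sd: float = 130.0
    pcp_month_noise: float = 12.0


@dataclass(frozen=True)
class TerrainModel:
    slope_mean: float = 10.0            # percent
    slope_sd: float = 8.0
    ins_mean: float = 10000.0           # Wh m^-2
    ins_sd: float = 1500.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Full configuration of the synthetic inventory generator."""

    n_plots: int = 50
    trees_per_plot_mean: float = 25.0
    n_measurements: int = 4
    interval_choices: tuple = (3, 5)
    interval_weights: tuple = (0.5, 0.5)
    plot_area_m2: float = 400.0
    start_year: int = 1990
    species_pool: tuple = tuple(DEFAULT_SPECIES_POOL)
    dbh_init_median: float = 12.0       # cm
    dbh_init_log_sd: float = 0.35
    growth: GrowthModel = field(default_factory=GrowthModel)
    climate: ClimateModel = field(default_factory=ClimateModel)
    terrain: TerrainModel = field(default_factory=TerrainModel)
    age_class_weights: tuple = (0.15, 0.35, 0.35, 0.15)
    self_thinning: _cov.SelfThinningParams = field(
        default_factory=_cov.SelfThinningParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        if self.n_measurements < 2:
            raise ValueError("n_measurements must be >= 2")
        if any(iv not in (3, 5) for iv in self.interval_choices):
            raise ValueError("interval_choices must be a subset of {3, 5}")
        w = np.asarray(self.interval_weights, dtype=float)
        if len(w) != len(self.interval_choices) or w.sum() <= 0:
            raise ValueError("interval_weights must match interval_choices")
        sw = np.array([float(w) for _, w in self.species_pool])
        if np.any(sw < 0) or sw.sum() <= 0:
            raise ValueError("species_pool weights must be non-negative "
                             "with a positive sum")
        for fname in ("trees_per_plot_mean", "plot_area_m2",
                      "dbh_init_median", "dbh_init_log_sd"):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{fname} must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("growth", GrowthModel), ("climate", ClimateModel),
                         ("terrain", TerrainModel),
                         ("self_thinning", _cov.SelfThinningParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        for key in ("interval_choices", "interval_weights",
                    "age_class_weights"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "species_pool" in raw:
            raw["species_pool"] = tuple(
                (str(c), float(w)) for c, w in raw["species_pool"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj
        with open(path, "w") as fh:
            yaml.safe_dump(plain(asdict(self)), fh)


# ---------------------------------------------------------------------------
# Hazard specification
# ---------------------------------------------------------------------------

_OPS = {">": operator.gt, ">=": operator.ge, "<": operator.lt,
        "<=": operator.le, "==": operator.eq, "in": lambda v, s: v in s}


@dataclass(frozen=True)
class HazardRule:
    """One rule: if every condition holds, the rate applies (first match wins).

    Conditions are ``(covariate name, op, value)`` triples with op one of
    ``> >= < <= == in``.
    """

    conditions: tuple
    rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rule rate must be in [0, 1]")
        for cond in self.conditions:
            if len(cond) != 3 or cond[1] not in _OPS:
                raise ValueError(f"malformed condition {cond!r}")

    def matches(self, covariates) -> bool:
        return all(_OPS[op](covariates[name], value)
                   for name, op, value in self.conditions)


@dataclass(frozen=True)
class HazardSpec:
    """Planted five-year mortality law: baseline + ordered rules + species
    multipliers.  An empty multiplier map means factor 1 for every species;
    a non-empty map must cover every species encountered."""

    baseline: float = 0.08
    rules: tuple = ()
    species_multipliers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline <= 1.0:
            raise ValueError("baseline must be in [0, 1]")
        for mult in self.species_multipliers.values():
            if mult < 0:
                raise ValueError("species multipliers must be positive")


def planted_rate(covariates, hazard: HazardSpec, species: str) -> float:
    """Five-year mortality probability the generator uses for one record.

    First matching rule wins, otherwise the baseline applies; the result is
    scaled by the species multiplier and clipped to [0, 1].
    """
    rate = hazard.baseline
    for rule in hazard.rules:
        if rule.matches(covariates):
            rate = rule.rate
            break
    if hazard.species_multipliers:
        if species not in hazard.species_multipliers:
            raise KeyError(f"unknown species code {species!r} "
                           "(not in species_multipliers)")
        rate *= hazard.species_multipliers[species]
    return float(min(1.0, max(0.0, rate)))


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------

def simulate_growth(dbh: float, erd_proxy: float, growth: GrowthModel,
                    interval_years: int, rng: np.random.Generator) -> float:
    """Next-measurement DBH (cm) after ``interval_years`` of growth.

    Mean annual BA increment decays exponentially in stand relative
    density; each year's realised increment is floored at zero.
    """
    if dbh <= 0:
        raise ValueError("DBH must be positive")
    mean_inc = growth.mean_ba_increment * np.exp(
        -growth.suppression * max(0.0, erd_proxy))
    if growth.noise_sd > 0:
        incs = rng.normal(mean_inc, growth.noise_sd, size=int(interval_years))
    else:
        incs = np.full(int(interval_years), mean_inc)
    ba_next = _cov.basal_area(dbh) + float(np.clip(incs, 0.0, None).sum())
    return float(2.0 * np.sqrt(ba_next / np.pi))


def _growth_increments(dbhs: np.ndarray, erd_proxy: float, growth: GrowthModel,
                       interval_years: int, rng: np.random.Generator
                       ) -> np.ndarray:
    """Vectorised interval BA increments for all live stems (cm²)."""
    mean_inc = growth.mean_ba_increment * np.exp(
        -growth.suppression * max(0.0, erd_proxy))
    if growth.noise_sd > 0:
        incs = rng.normal(mean_inc, growth.noise_sd,
                          size=(dbhs.size, int(interval_years)))
    else:
        incs = np.full((dbhs.size, int(interval_years)), mean_inc)
    return np.clip(incs, 0.0, None).sum(axis=1)


# ---------------------------------------------------------------------------
# Climate generation
# ---------------------------------------------------------------------------

def _offset_for_gdd(target_gdd: float) -> float:
    """Uniform temperature offset making the base profile hit a GDD target."""
    def f(delta: float) -> float:
        tm = {m + 1: BASE_TEMP_PROFILE[m] + delta for m in range(12)}
        return _climate.gdd_annual(tm, 2001) - target_gdd  # non-leap year
    return float(brentq(f, -20.0, 25.0))


def _plot_climate(plot_id: str, years, cfg: ClimateModel,
                  rng: np.random.Generator) -> list[dict]:
    target_gdd = rng.normal(cfg.gdd_mean, cfg.gdd_sd)
    delta = _offset_for_gdd(max(200.0, target_gdd))
    target_pcp = max(100.0, rng.normal(cfg.pcp_mean, cfg.pcp_sd))
    rows = []
    for year in years:
        year_shift = rng.normal(0.0, cfg.annual_temp_sd)
        tmeans = BASE_TEMP_PROFILE + delta + year_shift
        pcps = np.clip(rng.normal(target_pcp / 12.0, cfg.pcp_month_noise,
                                  size=12), 0.0, None)
        for m in range(12):
            rows.append({"plot_id": plot_id, "year": int(year),
                         "month": m + 1, "tmean_c": float(tmeans[m]),
                         "pcp_mm": float(pcps[m])})
    return rows


# ---------------------------------------------------------------------------
# Inventory generation
# ---------------------------------------------------------------------------

AGE_CLASSES = _cov.AGE_CLASSES


def generate_inventory(config: SyntheticConfig, hazard: HazardSpec
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (trees, plots, climate) tables for one synthetic inventory.

    Returns
    -------
    trees : columns ``plot_id, tree_id, species, year, dbh_cm, status,
        age_class`` — one row per tree per measurement; a tree's history is
        a run of live records optionally ended by a single dead record.
    plots : columns ``plot_id, area_m2, slope_pct, ins_wh_m2, ecoregion,
        interval_years``.
    climate : monthly rows ``plot_id, year, month, tmean_c, pcp_mm``.
    """
    sp_codes = [c for c, _ in config.species_pool]
    sp_w = np.array([float(w) for _, w in config.species_pool])
    sp_w = sp_w / sp_w.sum()
    iv_w = np.asarray(config.interval_weights, dtype=float)
    iv_w = iv_w / iv_w.sum()
    age_w = np.asarray(config.age_class_weights, dtype=float)
    age_w = age_w / age_w.sum()

    tree_rows: list[dict] = []
    plot_rows: list[dict] = []
    climate_rows: list[dict] = []

    for p in range(config.n_plots):
        rng = np.random.default_rng([config.seed, p])
        plot_id = f"P{p:04d}"
        interval = int(rng.choice(config.interval_choices, p=iv_w))
        years = [config.start_year + k * interval
                 for k in range(config.n_measurements)]
        slope = float(np.clip(abs(rng.normal(config.terrain.slope_mean,
                                             config.terrain.slope_sd)),
                              0.0, 80.0))
        ins = float(max(0.0, rng.normal(config.terrain.ins_mean,
                                        config.terrain.ins_sd)))
        ecoregion = int(rng.integers(1, 8))
        plot_rows.append({"plot_id": plot_id, "area_m2": config.plot_area_m2,
                          "slope_pct": slope, "ins_wh_m2": ins,
                          "ecoregion": ecoregion,
                          "interval_years": interval})

        plot_clim = _plot_climate(plot_id, range(years[0], years[-1] + 1),
                                  config.climate, rng)
        climate_rows.extend(plot_clim)
        ann = _annual_from_rows(plot_clim, plot_id)

        n_trees = max(1, int(rng.poisson(config.trees_per_plot_mean)))
        dbhs = np.exp(rng.normal(np.log(config.dbh_init_median),
                                 config.dbh_init_log_sd, size=n_trees))
        dbhs = np.maximum(dbhs, MIN_TALLY_DBH + 0.1)
        species = rng.choice(sp_codes, p=sp_w, size=n_trees)
        ages = rng.choice(AGE_CLASSES, p=age_w, size=n_trees)
        alive = np.ones(n_trees, dtype=bool)

        for i in range(n_trees):
            tree_rows.append({"plot_id": plot_id, "tree_id": f"T{i:04d}",
                              "species": species[i], "year": years[0],
                              "dbh_cm": float(dbhs[i]), "status": 1,
                              "age_class": ages[i]})

        for k in range(config.n_measurements - 1):
            t0, t1 = years[k], years[k + 1]
            live_idx = np.flatnonzero(alive)
            if live_idx.size == 0:
                break
            live_dbh = dbhs[live_idx]
            qmd = _cov.quadratic_mean_dbh(live_dbh)
            stems_ha = live_idx.size * (10000.0 / config.plot_area_m2)
            erd_now = _cov.erd(stems_ha, qmd, config.self_thinning)
            gdd_iv = _climate.interval_average(ann["gdd"], t0, t1)
            pcp_iv = _climate.interval_average(ann["pcp"], t0, t1)

            incs = _growth_increments(live_dbh, erd_now, config.growth,
                                      interval, rng)
            new_ba = _cov.basal_area(live_dbh) + incs
            new_dbh = 2.0 * np.sqrt(new_ba / np.pi)
            draws = rng.random(live_idx.size)

            for j, i in enumerate(live_idx):
                cov_vec = {"gdd": gdd_iv, "pcp": pcp_iv, "slp": slope,
                           "ins": ins, "erd": erd_now,
                           "dbh": float(live_dbh[j]),
                           "species": str(species[i]),
                           "delta_ba": float(incs[j]) / interval}
                p5 = planted_rate(cov_vec, hazard, str(species[i]))
                p_int = convert_rate(p5, 5.0, float(interval))
                died = draws[j] < p_int
                tree_rows.append({
                    "plot_id": plot_id, "tree_id": f"T{i:04d}",
                    "species": species[i], "year": t1,
                    "dbh_cm": float(new_dbh[j]),
                    "status": 0 if died else 1, "age_class": ages[i]})
                dbhs[i] = new_dbh[j]
                if died:
                    alive[i] = False

    trees = pd.DataFrame(tree_rows, columns=[
        "plot_id", "tree_id", "species", "year", "dbh_cm", "status",
        "age_class"])
    plots = pd.DataFrame(plot_rows, columns=[
        "plot_id", "area_m2", "slope_pct", "ins_wh_m2", "ecoregion",
        "interval_years"])
    climate = pd.DataFrame(climate_rows, columns=_climate.CLIMATE_COLUMNS)
    return trees, plots, climate


def _annual_from_rows(climate_rows: list[dict], plot_id: str) -> dict:
    """Annual GDD/PCP maps for one plot from freshly generated monthly rows."""
    sub = [r for r in climate_rows if r["plot_id"] == plot_id]
    by_year: dict[int, dict] = {}
    for r in sub:
        by_year.setdefault(r["year"], {"t": {}, "p": {}})
        by_year[r["year"]]["t"][r["month"]] = r["tmean_c"]
        by_year[r["year"]]["p"][r["month"]] = r["pcp_mm"]
    gdd = {y: _climate.gdd_annual(d["t"], y) for y, d in by_year.items()}
    pcp = {y: _climate.pcp_annual(d["p"]) for y, d in by_year.items()}
    return {"gdd": gdd, "pcp": pcp}


def write_inventory(out_dir, trees: pd.DataFrame, plots: pd.DataFrame,
                    climate: pd.DataFrame) -> dict:
    """Write the three inventory CSVs; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"trees": out / "trees.csv", "plots": out / "plots.csv",
             "climate": out / "climate.csv"}
    trees.to_csv(paths["trees"], index=False)
    plots.to_csv(paths["plots"], index=False)
    climate.to_csv(paths["climate"], index=False)
    return paths
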