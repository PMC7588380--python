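"""Attributable-mortality engine with Monte-Carlo uncertainty.

Combines gridded exposures, exposure–response curve draws and baseline
cause-specific mortality into PM2.5-attributable deaths per stratum
(country × cause × sex × age group), propagates uncertainty by matched
Monte-Carlo sampling, and aggregates draws to country / WHO-region /
world totals.

The attribution model: baseline deaths in a stratum are apportioned to
grid cells proportionally to cell population (mortality data are
national), and each cell contributes its population attributable
fraction at the cell's concentration,

    attributable = Σ_i deaths · (pop_i / Σpop) · PAF(RR(pm25_i)).

Uncertainty: each Monte-Carlo draw pairs one sampled counterfactual
concentration z_cf ~ U(low, high) — shared by all causes within the
draw — with one curve-parameter draw per cause/age stratum (cycled when
fewer curve draws than Monte-Carlo draws are available).  Draws are
index-matched across scenarios run with the same seed, which is what
makes scenario differences (percent reductions) well defined per draw.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exposure import ExposureGrid, ScenarioSpec, cap_exposures
from .risk import (
    ADULT_CAUSES,
    CAUSES,
    GemmCurveDraw,
    RiskCurveDraw,
    gemm_hazard_ratio,
    ier_relative_risk,
)

__all__ = [
    "CounterfactualSpec",
    "MortalityTable",
    "StratumKey",
    "BurdenEstimate",
    "AggregateSet",
    "attributable_deaths_one_draw",
    "run_monte_carlo",
    "aggregate",
    "percent_reduction",
    "deaths_per_100k",
    "run_scenario_analysis",
    "ScenarioAnalysis",
    "age_band_lower",
]

SEXES = ("male", "female")

_AGE_RANGE = re.compile(r"^\s*(\d+)\s*[-–]\s*(\d+)\s*$")
_AGE_OPEN = re.compile(r"^\s*(\d+)\s*\+\s*$")


def age_band_lower(label: str) -> float:
    """Lower bound in years of an age-band label ("all", "a-b", "a+")."""
    if str(label).strip().lower() == "all":
        return 0.0
    m = _AGE_RANGE.match(str(label)) or _AGE_OPEN.match(str(label))
    if m:
        return float(m.group(1))
    raise ValueError(f"unrecognised age_group label {label!r}")


@dataclass(frozen=True)
class CounterfactualSpec:
    """Uniform TMREL distribution for the counterfactual concentration.

    Defaults to U(2.4, 5.9) μg/m³, the range adopted by recent global
    assessments (minimum and fifth percentile of exposure in outdoor
    cohort studies).
    """

    low: float = 2.4
    high: float = 5.9

    def __post_init__(self) -> None:
        if not (0 <= self.low <= self.high) or not np.isfinite(self.high):
            raise ValueError(
                f"counterfactual bounds must satisfy 0 <= low <= high, "
                f"got ({self.low}, {self.high})"
            )


@dataclass(frozen=True)
class MortalityTable:
    """Baseline deaths by country × cause × sex × age group.

    ``deaths`` holds columns country_code, cause, sex, age_group,
    deaths; ``population`` maps country code to total persons (used for
    per-100,000 rates).  Age restrictions are enforced at construction:
    IHD, stroke, COPD and lung cancer only in bands starting at 25
    years or later; LRI in any band.
    """

    deaths: pd.DataFrame
    population: Mapping[str, float]

    def __post_init__(self) -> None:
        df = self.deaths.reset_index(drop=True)
        required = ["country_code", "cause", "sex", "age_group", "deaths"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"mortality table missing columns {missing}")
        bad_cause = set(df["cause"]) - set(CAUSES)
        if bad_cause:
            raise ValueError(f"unknown cause labels {sorted(bad_cause)}; expected {CAUSES}")
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex labels {sorted(bad_sex)}")
        d = df["deaths"].to_numpy(dtype=float)
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("deaths must be finite and >= 0")
        for cause, age in df[["cause", "age_group"]].drop_duplicates().itertuples(index=False):
            if cause in ADULT_CAUSES and age_band_lower(age) < 25:
                raise ValueError(
                    f"cause {cause!r} is restricted to ages > 25 years; "
                    f"age band {age!r} is not allowed"
                )
        object.__setattr__(self, "deaths", df)
        object.__setattr__(self, "population", dict(self.population))

    @property
    def countries(self) -> list[str]:
        return sorted(self.deaths["country_code"].unique())

    def scaled(self, deaths_factor: float = 1.0) -> "MortalityTable":
        df = self.deaths.copy()
        df["deaths"] = df["deaths"] * deaths_factor
        return MortalityTable(df, self.population)


class StratumKey(NamedTuple):
    country: str
    cause: str
    sex: str
    age_group: str


@dataclass(frozen=True)
class BurdenEstimate:
    """Attributable deaths (or a derived rate) with its Monte-Carlo draws.

    ``point`` is the mean of the per-draw values (median if constructed
    with ``point_statistic="median"``); the 95% uncertainty interval is
    the 2.5th–97.5th percentile of draws.
    """

    scope: str  # "stratum" | "country" | "region" | "world"
    key: str
    draws: np.ndarray
    point_statistic: str = "mean"
    units: str = "deaths"
    cause: str | None = None
    sex: str | None = None
    age_group: str | None = None

    def __post_init__(self) -> None:
        draws = np.asarray(self.draws, dtype=float)
        object.__setattr__(self, "draws", draws)
        if self.point_statistic not in ("mean", "median"):
            raise ValueError(f"unknown point statistic {self.point_statistic!r}")

    @property
    def point(self) -> float:
        fn = np.mean if self.point_statistic == "mean" else np.median
        return float(fn(self.draws))

    @property
    def ui_low(self) -> float:
        return float(np.percentile(self.draws, 2.5))

    @property
    def ui_high(self) -> float:
        return float(np.percentile(self.draws, 97.5))

    @property
    def defined(self) -> bool:
        return bool(np.all(np.isfinite(self.draws)))


def _population_weights(grid: ExposureGrid) -> np.ndarray:
    total = grid.population.sum()
    if total <= 0:
        raise ValueError(f"{grid.country_code}: total population must be > 0")
    return grid.population / total


def attributable_deaths_one_draw(
    grid: ExposureGrid,
    curve: RiskCurveDraw | GemmCurveDraw,
    stratum_deaths: float,
    *,
    cause: str | None = None,
    age_group: str | None = None,
) -> float:
    """Attributable deaths for one stratum under one fixed curve draw.

    ``cause``/``age_group``, when given, are checked against the curve
    to catch mispaired inputs.  Returns a value in
    ``[0, stratum_deaths)``.
    """
    if stratum_deaths < 0 or not np.isfinite(stratum_deaths):
        raise ValueError("stratum_deaths must be finite and >= 0")
    if isinstance(curve, RiskCurveDraw):
        if cause is not None and cause != curve.cause:
            raise ValueError(
                f"curve is for cause {curve.cause!r} but stratum is {cause!r}"
            )
        if age_group is not None and age_group != curve.age_group:
            raise ValueError(
                f"curve is for age band {curve.age_group!r} but stratum is {age_group!r}"
            )
        rr = ier_relative_risk(grid.pm25, curve.alpha, curve.gamma, curve.delta, curve.z_cf)
    else:
        rr = gemm_hazard_ratio(
            grid.pm25, curve.theta, curve.knot_alpha, curve.mu, curve.nu, curve.z_cf
        )
    weights = _population_weights(grid)
    cell_paf = (rr - 1.0) / rr
    return float(stratum_deaths * np.dot(weights, cell_paf))


def _curve_key_for(
    curves: Mapping[tuple[str, str], Sequence], cause: str, age_group: str
) -> tuple[str, str]:
    """Resolve a stratum to its curve set; single-band sets serve all bands."""
    if (cause, age_group) in curves:
        return (cause, age_group)
    cause_keys = [k for k in curves if k[0] == cause]
    if len(cause_keys) == 1:
        return cause_keys[0]
    if not cause_keys:
        raise ValueError(f"no risk-curve draws supplied for cause {cause!r}")
    raise ValueError(
        f"no curve draws for ({cause!r}, {age_group!r}) and {len(cause_keys)} "
        "age-specific sets exist; cannot disambiguate"
    )


def _stacked_ier_params(draws: Sequence[RiskCurveDraw], idx: np.ndarray):
    alpha = np.array([d.alpha for d in draws])[idx]
    gamma = np.array([d.gamma for d in draws])[idx]
    delta = np.array([d.delta for d in draws])[idx]
    z_cf = np.array([d.z_cf for d in draws])[idx]
    return alpha, gamma, delta, z_cf


def run_monte_carlo(
    grids: Mapping[str, ExposureGrid],
    mortality: MortalityTable,
    curves: Mapping[tuple[str, str], Sequence[RiskCurveDraw | GemmCurveDraw]],
    cf: CounterfactualSpec = CounterfactualSpec(),
    n_draws: int = 1000,
    seed: int = 0,
    point_statistic: str = "mean",
    sample_z_cf: bool = True,
) -> dict[StratumKey, BurdenEstimate]:
    """Per-stratum attributable deaths with matched Monte-Carlo draws.

    For draw ``d``: one z_cf is sampled from the TMREL distribution and
    applied to every IER curve in that draw; curve-parameter draws are
    taken in ``draw_id`` order and cycled modulo their count.  GEMM
    curves keep their fixed counterfactual and instead perturb the
    log-hazard coefficient with N(0, se_theta) noise, truncated at
    zero.  Identical seeds give bitwise-identical output, and runs on
    capped grids with the same seed are draw-index-matched with the
    uncapped run.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if len(mortality.deaths) == 0:
        raise ValueError("mortality table is empty")
    missing = set(mortality.deaths["country_code"]) - set(grids)
    if missing:
        raise ValueError(f"countries in mortality but not in exposures: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    z_cf_draws = rng.uniform(cf.low, cf.high, size=n_draws)

    # Per curve set: parameter vectors of length n_draws (cycled), plus
    # GEMM theta noise drawn in sorted-key order for determinism.
    param_cache: dict[tuple[str, str], tuple] = {}
    for key in sorted(curves):
        draws = sorted(curves[key], key=lambda c: c.draw_id)
        if not draws:
            raise ValueError(f"empty curve-draw list for {key}")
        idx = np.arange(n_draws) % len(draws)
        if isinstance(draws[0], GemmCurveDraw):
            theta = np.array([d.theta for d in draws])[idx]
            se = np.array([d.se_theta for d in draws])[idx]
            eps = rng.standard_normal(n_draws)
            theta = np.maximum(theta + se * eps, 0.0)
            knot = np.array([d.knot_alpha for d in draws])[idx]
            mu = np.array([d.mu for d in draws])[idx]
            nu = np.array([d.nu for d in draws])[idx]
            z0 = np.array([d.z_cf for d in draws])[idx]
            param_cache[key] = ("gemm", theta, knot, mu, nu, z0)
        else:
            alpha, gamma, delta, z0 = _stacked_ier_params(draws, idx)
            z_cf = z_cf_draws if sample_z_cf else z0
            param_cache[key] = ("ier", alpha, gamma, delta, z_cf)

    # Population-weighted PAF per (country, curve set), shape (n_draws,)
    pw_paf: dict[tuple[str, tuple[str, str]], np.ndarray] = {}

    def _pw_paf(country: str, key: tuple[str, str]) -> np.ndarray:
        cached = pw_paf.get((country, key))
        if cached is not None:
            return cached
        grid = grids[country]
        weights = _population_weights(grid)
        z = grid.pm25[:, None]  # (cells, 1) against (n_draws,) params
        kind, *params = param_cache[key]
        if kind == "ier":
            rr = ier_relative_risk(z, *params)
        else:
            rr = gemm_hazard_ratio(z, *params)
        result = weights @ ((rr - 1.0) / rr)
        pw_paf[(country, key)] = result
        return result

    estimates: dict[StratumKey, BurdenEstimate] = {}
    for row in mortality.deaths.itertuples(index=False):
        key = _curve_key_for(curves, row.cause, row.age_group)
        draws_vec = float(row.deaths) * _pw_paf(row.country_code, key)
        skey = StratumKey(row.country_code, row.cause, row.sex, row.age_group)
        estimates[skey] = BurdenEstimate(
            scope="stratum",
            key=row.country_code,
            draws=draws_vec,
            point_statistic=point_statistic,
            cause=row.cause,
            sex=row.sex,
            age_group=row.age_group,
        )
    return estimates


@dataclass(frozen=True)
class AggregateSet:
    """All-cause aggregates at country, WHO-region and world level."""

    country: dict[str, BurdenEstimate]
    region: dict[str, BurdenEstimate]
    world: BurdenEstimate


def aggregate(
    estimates: Mapping[StratumKey, BurdenEstimate],
    region_map: Mapping[str, str],
) -> AggregateSet:
    """Sum per-draw vectors to country, region and world totals.

    Aggregation is on draw vectors (sum within a draw, then summarise),
    never on summarised intervals.  Summation is hierarchical in sorted
    key order, so world = Σ regions = Σ countries holds bitwise per
    draw.  A country absent from ``region_map`` is rejected.
    """
    if not estimates:
        raise ValueError("no estimates to aggregate")
    point_statistic = next(iter(estimates.values())).point_statistic

    by_country: dict[str, np.ndarray] = {}
    for skey in sorted(estimates):
        est = estimates[skey]
        if skey.country in by_country:
            by_country[skey.country] = by_country[skey.country] + est.draws
        else:
            by_country[skey.country] = est.draws.copy()

    unmapped = [c for c in by_country if c not in region_map]
    if unmapped:
        raise ValueError(f"countries missing from region map: {unmapped}")

    by_region: dict[str, np.ndarray] = {}
    for country in sorted(by_country):
        region = region_map[country]
        if region in by_region:
            by_region[region] = by_region[region] + by_country[country]
        else:
            by_region[region] = by_country[country].copy()

    world = np.zeros_like(next(iter(by_region.values())))
    for region in sorted(by_region):
        world = world + by_region[region]

    def _est(scope: str, key: str, draws: np.ndarray) -> BurdenEstimate:
        return BurdenEstimate(scope=scope, key=key, draws=draws,
                              point_statistic=point_statistic, cause="all")

    return AggregateSet(
        country={c: _est("country", c, v) for c, v in by_country.items()},
        region={r: _est("region", r, v) for r, v in by_region.items()},
        world=_est("world", "World", world),
    )


def percent_reduction(current: BurdenEstimate, scenario: BurdenEstimate) -> BurdenEstimate:
    """Per-draw percent reduction of scenario vs current attributable deaths.

    ``r_d = 100·(D_current,d − D_scenario,d)/D_current,d``; the point is
    the summary of the r_d, not the ratio of summarised points.  If any
    current draw is zero the reduction is undefined for that stratum
    and every value is reported as NaN (``defined`` is False), never 0.
    """
    if current.draws.shape != scenario.draws.shape:
        raise ValueError("current and scenario draws must be index-matched")
    if np.any(current.draws == 0):
        draws = np.full_like(current.draws, np.nan)
    else:
        draws = 100.0 * (current.draws - scenario.draws) / current.draws
    return replace(current, draws=draws, units="percent")


def deaths_per_100k(estimate: BurdenEstimate, population: float) -> BurdenEstimate:
    """Rescale an estimate to deaths per 100,000 population."""
    if not population > 0:
        raise ValueError("population must be > 0")
    return replace(
        estimate, draws=estimate.draws * (100000.0 / population), units="per_100k"
    )


@dataclass(frozen=True)
class ScenarioAnalysis:
    """Results of a full multi-scenario burden run.

    Holds per-stratum estimates and all-cause aggregates for every
    scenario, with draw vectors retained so that every derived number
    (reductions, rates, intervals) is traceable to stored draws.
    """

    scenarios: tuple[ScenarioSpec, ...]
    strata: Mapping[str, Mapping[StratumKey, BurdenEstimate]]
    aggregates: Mapping[str, AggregateSet]
    populations: Mapping[str, float]
    region_map: Mapping[str, str]
    cf: CounterfactualSpec
    n_draws: int
    seed: int
    point_statistic: str = "mean"

    @property
    def scenario_names(self) -> list[str]:
        return [s.name for s in self.scenarios]

    @property
    def current_name(self) -> str:
        for s in self.scenarios:
            if s.cap is None:
                return s.name
        raise ValueError("analysis has no uncapped (current) scenario")

    def region_population(self, region: str) -> float:
        return sum(
            p for c, p in self.populations.items() if self.region_map.get(c) == region
        )

    def world_population(self) -> float:
        return float(sum(self.populations.values()))

    def reduction(self, scope: str, key: str, scenario: str) -> BurdenEstimate:
        """Percent reduction vs the current scenario for an aggregate."""
        current = self._aggregate(scope, key, self.current_name)
        return percent_reduction(current, self._aggregate(scope, key, scenario))

    def _aggregate(self, scope: str, key: str, scenario: str) -> BurdenEstimate:
        agg = self.aggregates[scenario]
        if scope == "world":
            return agg.world
        if scope == "region":
            return agg.region[key]
        if scope == "country":
            return agg.country[key]
        raise ValueError(f"unknown scope {scope!r}")

    def region_table(self) -> pd.DataFrame:
        """Tidy region×scenario table of deaths and percent reductions."""
        rows = []
        current = self.current_name
        regions = sorted(self.aggregates[current].region)
        for scope, keys in (("region", regions), ("world", ["World"])):
            for key in keys:
                for scen in self.scenario_names:
                    est = self._aggregate(scope, key, scen)
                    row = {
                        "region": key,
                        "scenario": scen,
                        "deaths_point": est.point,
                        "deaths_ui_low": est.ui_low,
                        "deaths_ui_high": est.ui_high,
                    }
                    if scen != current:
                        red = self.reduction(scope, key, scen)
                        row.update(
                            pct_reduction_point=red.point,
                            pct_reduction_ui_low=red.ui_low,
                            pct_reduction_ui_high=red.ui_high,
                        )
                    else:
                        row.update(
                            pct_reduction_point=np.nan,
                            pct_reduction_ui_low=np.nan,
                            pct_reduction_ui_high=np.nan,
                        )
                    rows.append(row)
        return pd.DataFrame(rows)

    def country_rate_table(self) -> pd.DataFrame:
        """Per-country deaths per 100,000 and avoided rate vs current."""
        rows = []
        current = self.current_name
        for country in sorted(self.aggregates[current].country):
            pop = self.populations[country]
            cur_rate = deaths_per_100k(
                self.aggregates[current].country[country], pop
            )
            for scen in self.scenario_names:
                est = deaths_per_100k(self.aggregates[scen].country[country], pop)
                avoided = replace(est, draws=cur_rate.draws - est.draws)
                rows.append(
                    {
                        "country_code": country,
                        "scenario": scen,
                        "rate_per_100k_point": est.point,
                        "rate_per_100k_ui_low": est.ui_low,
                        "rate_per_100k_ui_high": est.ui_high,
                        "avoided_per_100k_point": avoided.point,
                        "avoided_per_100k_ui_low": avoided.ui_low,
                        "avoided_per_100k_ui_high": avoided.ui_high,
                    }
                )
        return pd.DataFrame(rows)

    def stratum_draws_frame(self) -> pd.DataFrame:
        """Long-format per-stratum per-draw deaths (the draws store)."""
        frames = []
        for scen in self.scenario_names:
            for skey, est in self.strata[scen].items():
                frames.append(
                    pd.DataFrame(
                        {
                            "scenario": scen,
                            "country_code": skey.country,
                            "cause": skey.cause,
                            "sex": skey.sex,
                            "age_group": skey.age_group,
                            "draw": np.arange(est.draws.size),
                            "deaths": est.draws,
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_strata(
        cls,
        scenarios: Sequence[ScenarioSpec],
        strata: Mapping[str, Mapping[StratumKey, BurdenEstimate]],
        populations: Mapping[str, float],
        region_map: Mapping[str, str],
        cf: CounterfactualSpec,
        n_draws: int,
        seed: int,
        point_statistic: str = "mean",
    ) -> "ScenarioAnalysis":
        aggregates = {
            name: aggregate(per_stratum, region_map)
            for name, per_stratum in strata.items()
        }
        return cls(
            scenarios=tuple(scenarios),
            strata={k: dict(v) for k, v in strata.items()},
            aggregates=aggregates,
            populations=dict(populations),
            region_map=dict(region_map),
            cf=cf,
            n_draws=n_draws,
            seed=seed,
            point_statistic=point_statistic,
        )


def run_scenario_analysis(
    grids: Mapping[str, ExposureGrid],
    mortality: MortalityTable,
    curves: Mapping[tuple[str, str], Sequence[RiskCurveDraw | GemmCurveDraw]],
    region_map: Mapping[str, str],
    scenarios: Sequence[ScenarioSpec] | None = None,
    cf: CounterfactualSpec = CounterfactualSpec(),
    n_draws: int = 1000,
    seed: int = 0,
    point_statistic: str = "mean",
    sample_z_cf: bool = True,
) -> ScenarioAnalysis:
    """Run the burden pipeline for every scenario with matched draws.

    Each scenario caps the grids cell-wise and re-runs the Monte-Carlo
    engine with the *same* seed, so draw ``d`` of every scenario shares
    its z_cf and curve parameters with draw ``d`` of the current run.
    """
    from .exposure import default_scenario_ladder

    if scenarios is None:
        scenarios = default_scenario_ladder()
    strata = {}
    for scenario in scenarios:
        capped = {c: cap_exposures(g, scenario) for c, g in grids.items()}
        strata[scenario.name] = run_monte_carlo(
            capped,
            mortality,
            curves,
            cf=cf,
            n_draws=n_draws,
            seed=seed,
            point_statistic=point_statistic,
            sample_z_cf=sample_z_cf,
        )
    return ScenarioAnalysis.from_strata(
        scenarios, strata, mortality.population, region_map, cf, n_draws, seed,
        point_statistic,
    )
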