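"""File formats and run configuration.

CSV is the canonical dialect for every input: exposure grids, baseline
mortality, national populations, WHO-region membership and risk-curve
parameter draws.  A thin shim also reads the WHO per-country XLSX
summary layout (country, population-weighted mean) for summary-level
comparisons only.  All schema and domain validation happens at load,
with file and line context in every rejection.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .burden import CounterfactualSpec, MortalityTable
from .exposure import ExposureGrid, ScenarioSpec, default_scenario_ladder
from .risk import CAUSES, GemmCurveDraw, RiskCurveDraw

__all__ = [
    "read_exposure_csv",
    "write_exposure_csv",
    "read_mortality_csv",
    "write_mortality_csv",
    "read_population_csv",
    "write_population_csv",
    "read_region_map_csv",
    "write_region_map_csv",
    "read_ier_curves_csv",
    "write_ier_curves_csv",
    "read_gemm_curves_csv",
    "read_country_summary_xlsx",
    "RunConfig",
    "Inputs",
    "read_inputs",
    "write_world",
]

WHO_REGIONS = ("AFR", "AMR", "EMR", "EUR", "SEAR", "WPR")

EXPOSURE_COLUMNS = ["country_code", "cell_id", "pm25", "population"]
MORTALITY_COLUMNS = ["country_code", "cause", "sex", "age_group", "deaths"]
IER_COLUMNS = ["cause", "age_group", "draw_id", "alpha", "gamma", "delta", "z_cf"]
GEMM_COLUMNS = ["cause_group", "draw_id", "theta", "se_theta", "knot_alpha", "mu", "nu", "z_cf"]


def _load_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _line(df_index: int) -> int:
    # +2: one for the header row, one for 1-based numbering
    return int(df_index) + 2


def read_exposure_csv(path) -> dict[str, ExposureGrid]:
    """Read per-country exposure grids (columns country_code, cell_id,
    pm25, population; optional lon, lat)."""
    df = _load_csv(path, EXPOSURE_COLUMNS)
    pm25 = pd.to_numeric(df["pm25"], errors="coerce")
    bad = df.index[~np.isfinite(pm25) | (pm25 < 0)]
    if len(bad):
        raise ValueError(
            f"{path}, line {_line(bad[0])}: pm25 must be finite and >= 0 "
            f"(got {df['pm25'].iloc[bad[0]]!r})"
        )
    pop = pd.to_numeric(df["population"], errors="coerce")
    bad = df.index[~np.isfinite(pop) | (pop < 0)]
    if len(bad):
        raise ValueError(
            f"{path}, line {_line(bad[0])}: population must be finite and >= 0"
        )
    has_coords = {"lon", "lat"}.issubset(df.columns)
    grids = {}
    for code, sub in df.groupby("country_code", sort=True):
        grids[str(code)] = ExposureGrid(
            country_code=str(code),
            cell_id=tuple(sub["cell_id"].astype(str)),
            pm25=sub["pm25"].to_numpy(dtype=float),
            population=sub["population"].to_numpy(dtype=float),
            lon=sub["lon"].to_numpy(dtype=float) if has_coords else None,
            lat=sub["lat"].to_numpy(dtype=float) if has_coords else None,
        )
    return grids


def write_exposure_csv(grids: Mapping[str, ExposureGrid], path) -> None:
    frames = []
    for code in sorted(grids):
        g = grids[code]
        frame = pd.DataFrame(
            {
                "country_code": g.country_code,
                "cell_id": list(g.cell_id),
                "pm25": g.pm25,
                "population": g.population,
            }
        )
        if g.lon is not None and g.lat is not None:
            frame["lon"], frame["lat"] = g.lon, g.lat
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_mortality_csv(deaths_path, population_path) -> MortalityTable:
    """Read baseline deaths and national populations; domain rules
    (valid causes/sexes, non-negative deaths, >25y restriction) are
    enforced by :class:`MortalityTable`, re-raised with file context."""
    df = _load_csv(deaths_path, MORTALITY_COLUMNS)
    bad = df.index[~df["cause"].isin(CAUSES)]
    if len(bad):
        raise ValueError(
            f"{deaths_path}, line {_line(bad[0])}: unknown cause "
            f"{df['cause'].iloc[bad[0]]!r} (expected one of {CAUSES})"
        )
    population = read_population_csv(population_path)
    try:
        return MortalityTable(df, population)
    except ValueError as exc:
        raise ValueError(f"{deaths_path}: {exc}") from exc


def write_mortality_csv(mortality: MortalityTable, deaths_path, population_path) -> None:
    mortality.deaths.to_csv(deaths_path, index=False)
    write_population_csv(mortality.population, population_path)


def read_population_csv(path) -> dict[str, float]:
    df = _load_csv(path, ["country_code", "population"])
    pop = pd.to_numeric(df["population"], errors="coerce")
    bad = df.index[~np.isfinite(pop) | (pop <= 0)]
    if len(bad):
        raise ValueError(f"{path}, line {_line(bad[0])}: population must be > 0")
    return dict(zip(df["country_code"].astype(str), pop.astype(float)))


def write_population_csv(population: Mapping[str, float], path) -> None:
    pd.DataFrame(
        sorted(population.items()), columns=["country_code", "population"]
    ).to_csv(path, index=False)


def read_region_map_csv(path) -> dict[str, str]:
    df = _load_csv(path, ["country_code", "who_region"])
    bad = df.index[~df["who_region"].isin(WHO_REGIONS)]
    if len(bad):
        raise ValueError(
            f"{path}, line {_line(bad[0])}: unknown WHO region "
            f"{df['who_region'].iloc[bad[0]]!r} (expected one of {WHO_REGIONS})"
        )
    return dict(zip(df["country_code"].astype(str), df["who_region"].astype(str)))


def write_region_map_csv(region_map: Mapping[str, str], path) -> None:
    pd.DataFrame(
        sorted(region_map.items()), columns=["country_code", "who_region"]
    ).to_csv(path, index=False)


def read_ier_curves_csv(path) -> dict[tuple[str, str], list[RiskCurveDraw]]:
    """Read IER parameter draws, grouped by (cause, age_group)."""
    df = _load_csv(path, IER_COLUMNS)
    curves: dict[tuple[str, str], list[RiskCurveDraw]] = {}
    for idx, row in df.iterrows():
        try:
            draw = RiskCurveDraw(
                cause=str(row["cause"]),
                age_group=str(row["age_group"]),
                alpha=float(row["alpha"]),
                gamma=float(row["gamma"]),
                delta=float(row["delta"]),
                z_cf=float(row["z_cf"]),
                draw_id=int(row["draw_id"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {_line(idx)}: {exc}") from exc
        curves.setdefault((draw.cause, draw.age_group), []).append(draw)
    for key in curves:
        curves[key].sort(key=lambda d: d.draw_id)
    return curves


def write_ier_curves_csv(curves: Mapping[tuple[str, str], Sequence[RiskCurveDraw]], path) -> None:
    rows = [
        {
            "cause": d.cause,
            "age_group": d.age_group,
            "draw_id": d.draw_id,
            "alpha": d.alpha,
            "gamma": d.gamma,
            "delta": d.delta,
            "z_cf": d.z_cf,
        }
        for key in sorted(curves)
        for d in curves[key]
    ]
    pd.DataFrame(rows, columns=IER_COLUMNS).to_csv(path, index=False)


def read_gemm_curves_csv(path) -> dict[tuple[str, str], list[GemmCurveDraw]]:
    """Read GEMM parameter draws.

    GEMM publishes one hazard-ratio curve for NCD + LRI mortality, so
    the same draw set is mapped to every modelled cause under the key
    ``(cause, "all")`` — baseline deaths still enter per cause.
    """
    df = _load_csv(path, GEMM_COLUMNS)
    draws = []
    for idx, row in df.iterrows():
        try:
            draws.append(
                GemmCurveDraw(
                    theta=float(row["theta"]),
                    se_theta=float(row["se_theta"]),
                    knot_alpha=float(row["knot_alpha"]),
                    mu=float(row["mu"]),
                    nu=float(row["nu"]),
                    z_cf=float(row["z_cf"]),
                    cause_group=str(row["cause_group"]),
                    draw_id=int(row["draw_id"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {_line(idx)}: {exc}") from exc
    draws.sort(key=lambda d: d.draw_id)
    return {(cause, "all"): list(draws) for cause in CAUSES}


def read_country_summary_xlsx(path, sheet: int | str = 0) -> pd.DataFrame:
    """Read a WHO-style per-country XLSX summary.

    Expects a sheet whose first two recognisable columns are the
    country identifier and the population-weighted mean PM2.5.  This is
    a comparison aid only — the burden pipeline needs cell-level grids.
    """
    df = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    cols = {str(c).strip().lower(): c for c in df.columns}
    country_col = next(
        (cols[k] for k in cols if "country" in k or k in ("iso3", "code")), None
    )
    mean_col = next(
        (cols[k] for k in cols if "pm" in k or "mean" in k or "exposure" in k), None
    )
    if country_col is None or mean_col is None:
        raise ValueError(
            f"{path}: could not locate country and population-weighted-mean columns"
        )
    out = df[[country_col, mean_col]].copy()
    out.columns = ["country", "pw_mean_pm25"]
    return out


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a burden run."""

    exposure_path: str
    mortality_path: str
    population_path: str
    region_path: str
    curves_path: str
    output_dir: str = "pmburden_out"
    risk_model: str = "ier"  # "ier" | "gemm"
    scenario_caps: tuple[float, ...] = (35.0, 25.0, 15.0, 10.0)
    cf_low: float = 2.4
    cf_high: float = 5.9
    n_draws: int = 1000
    seed: int = 0
    point_statistic: str = "mean"

    def __post_init__(self) -> None:
        if self.risk_model not in ("ier", "gemm"):
            raise ValueError(f"risk_model must be 'ier' or 'gemm', got {self.risk_model!r}")
        caps = tuple(float(c) for c in self.scenario_caps)
        if list(caps) == [35.0, 25.0, 15.0, 10.0]:
            pass  # the default WHO ladder
        elif any(b >= a for a, b in zip(caps, caps[1:])):
            raise ValueError("scenario caps must be strictly decreasing")
        object.__setattr__(self, "scenario_caps", caps)

    def scenarios(self) -> list[ScenarioSpec]:
        if self.scenario_caps == (35.0, 25.0, 15.0, 10.0):
            return default_scenario_ladder()
        from .exposure import CURRENT

        return [CURRENT] + [
            ScenarioSpec(f"cap{cap:g}", cap) for cap in self.scenario_caps
        ]

    def counterfactual(self) -> CounterfactualSpec:
        return CounterfactualSpec(self.cf_low, self.cf_high)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "scenario_caps" in raw:
            raw["scenario_caps"] = tuple(raw["scenario_caps"])
        return cls(**raw)


@dataclass(frozen=True)
class Inputs:
    """Validated, cross-checked model inputs ready for the engine."""

    grids: dict[str, ExposureGrid]
    mortality: MortalityTable
    curves: dict
    region_map: dict[str, str]


def read_inputs(config: RunConfig) -> Inputs:
    """Load and cross-validate all input files for a run.

    Beyond per-file schema checks, enforces that every mortality
    country has an exposure grid and a region assignment.
    """
    grids = read_exposure_csv(config.exposure_path)
    mortality = read_mortality_csv(config.mortality_path, config.population_path)
    region_map = read_region_map_csv(config.region_path)
    if config.risk_model == "gemm":
        curves = read_gemm_curves_csv(config.curves_path)
    else:
        curves = read_ier_curves_csv(config.curves_path)

    missing_grid = sorted(set(mortality.countries) - set(grids))
    if missing_grid:
        raise ValueError(
            f"{config.mortality_path}: countries with deaths but no exposure "
            f"grid in {config.exposure_path}: {missing_grid}"
        )
    missing_region = sorted(set(mortality.countries) - set(region_map))
    if missing_region:
        raise ValueError(
            f"{config.region_path}: countries missing a WHO region: {missing_region}"
        )
    missing_pop = sorted(set(mortality.countries) - set(mortality.population))
    if missing_pop:
        raise ValueError(
            f"{config.population_path}: countries missing a population: {missing_pop}"
        )
    return Inputs(grids=grids, mortality=mortality, curves=curves, region_map=region_map)


def write_world(world, directory) -> dict[str, Path]:
    """Write a synthetic world to the canonical CSV set; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": directory / "exposure.csv",
        "mortality": directory / "mortality.csv",
        "population": directory / "population.csv",
        "regions": directory / "regions.csv",
        "curves": directory / "ier_curves.csv",
    }
    write_exposure_csv(world.grids, paths["exposure"])
    write_mortality_csv(world.mortality, paths["mortality"], paths["population"])
    write_region_map_csv(world.region_map, paths["regions"])
    write_ier_curves_csv(world.curves, paths["curves"])
    return paths
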