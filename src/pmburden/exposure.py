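"""Gridded exposure data and counterfactual exposure-cap scenarios.

An :class:`ExposureGrid` holds one country's grid cells with annual-mean
PM2.5 concentration and resident population.  Scenario analysis replaces
each cell's concentration with the scenario cap wherever the current
level is higher — the caps are the 2005 WHO interim targets
(IT1 = 35, IT2 = 25, IT3 = 15 μg/m³) and the air quality guideline
level (AQG = 10 μg/m³).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ExposureGrid",
    "ScenarioSpec",
    "CURRENT",
    "default_scenario_ladder",
    "cap_exposures",
    "population_weighted_mean",
    "fraction_above",
]


@dataclass(frozen=True)
class ExposureGrid:
    """Per-country grid of (PM2.5 concentration, population) cells.

    Concentrations are annual means in μg/m³; populations are persons.
    Cells with zero population are retained — they contribute nothing
    to burden but round-trip through files unchanged.  Optional lon/lat
    (degrees) are carried for provenance only.
    """

    country_code: str
    cell_id: tuple[str, ...]
    pm25: np.ndarray
    population: np.ndarray
    lon: np.ndarray | None = None
    lat: np.ndarray | None = None

    def __post_init__(self) -> None:
        pm25 = np.asarray(self.pm25, dtype=float)
        pop = np.asarray(self.population, dtype=float)
        object.__setattr__(self, "cell_id", tuple(str(c) for c in self.cell_id))
        object.__setattr__(self, "pm25", pm25)
        object.__setattr__(self, "population", pop)
        if pm25.ndim != 1 or pop.shape != pm25.shape or len(self.cell_id) != pm25.size:
            raise ValueError(
                f"{self.country_code}: cell_id, pm25 and population must be "
                "equal-length 1-d sequences"
            )
        if pm25.size == 0:
            raise ValueError(f"{self.country_code}: grid has no cells")
        if not np.all(np.isfinite(pm25)) or np.any(pm25 < 0):
            raise ValueError(f"{self.country_code}: pm25 must be finite and >= 0")
        if not np.all(np.isfinite(pop)) or np.any(pop < 0):
            raise ValueError(f"{self.country_code}: population must be finite and >= 0")
        if not np.any(pop > 0):
            raise ValueError(
                f"{self.country_code}: at least one cell must have population > 0"
            )
        for name in ("lon", "lat"):
            coord = getattr(self, name)
            if coord is not None:
                coord = np.asarray(coord, dtype=float)
                if coord.shape != pm25.shape:
                    raise ValueError(f"{self.country_code}: {name} length mismatch")
                object.__setattr__(self, name, coord)

    @property
    def n_cells(self) -> int:
        return self.pm25.size

    @property
    def total_population(self) -> float:
        return float(self.population.sum())


@dataclass(frozen=True)
class ScenarioSpec:
    """A named exposure cap applied grid-cell-wise.

    ``cap=None`` denotes the "current" (no-cap) scenario.  The built-in
    ladder uses the WHO caps 35/25/15/10 μg/m³.
    """

    name: str
    cap: float | None = None

    def __post_init__(self) -> None:
        if self.cap is not None:
            cap = float(self.cap)
            if not np.isfinite(cap) or cap < 0:
                raise ValueError(f"scenario {self.name!r}: cap must be finite and >= 0")
            object.__setattr__(self, "cap", cap)


CURRENT = ScenarioSpec("current", None)

_BUILTIN_CAPS = {"IT1": 35.0, "IT2": 25.0, "IT3": 15.0, "AQG": 10.0}


def default_scenario_ladder() -> list[ScenarioSpec]:
    """The current → IT1 → IT2 → IT3 → AQG scenario sequence."""
    return [CURRENT] + [ScenarioSpec(n, c) for n, c in _BUILTIN_CAPS.items()]


def cap_exposures(grid: ExposureGrid, scenario: ScenarioSpec) -> ExposureGrid:
    """Replace each cell's PM2.5 with the cap where current levels are higher.

    Populations and cell order are preserved; the "current" scenario
    returns the grid unchanged.
    """
    if scenario.cap is None:
        return grid
    return replace(grid, pm25=np.minimum(grid.pm25, scenario.cap))


def population_weighted_mean(grid: ExposureGrid) -> float:
    """Population-weighted mean concentration Σ(pm25·pop)/Σpop in μg/m³."""
    total = grid.population.sum()
    if total <= 0:
        raise ValueError(f"{grid.country_code}: total population must be > 0")
    return float(np.dot(grid.pm25, grid.population) / total)


def fraction_above(grid: ExposureGrid, threshold: float) -> float:
    """Population share living in cells with PM2.5 strictly above ``threshold``."""
    total = grid.population.sum()
    if total <= 0:
        raise ValueError(f"{grid.country_code}: total population must be > 0")
    return float(grid.population[grid.pm25 > threshold].sum() / total)
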