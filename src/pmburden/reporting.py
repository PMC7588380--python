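"""Rendering of burden results: tables, manifest, bar charts.

Outputs mirror the shape global assessments publish: a region × scenario
table of attributable deaths and percent reductions with 95% uncertainty
intervals formatted "point (low, high)", and a per-country deaths-per-
100,000 table.  Machine-readable columns are always emitted alongside
formatted strings, and every number is computed from the stored draw
vectors — nothing is re-derived at render time.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .burden import BurdenEstimate, CounterfactualSpec, ScenarioAnalysis, StratumKey
from .exposure import ScenarioSpec
from .io import read_population_csv, read_region_map_csv

__all__ = [
    "format_ui",
    "render_tables",
    "analysis_from_draws",
    "load_analysis",
    "plot_reduction_bars",
]


def format_ui(point: float, low: float, high: float, unit: str = "") -> str:
    """Format a point estimate with its 95% UI, e.g. "47.8% (40.8%, 55.2%)".

    Deaths (``unit=""``) are rounded to whole counts with thousands
    separators; percentages and rates keep one decimal.
    """
    if not np.isfinite(point):
        return ""
    if unit == "":
        return f"{point:,.0f} ({low:,.0f}, {high:,.0f})"
    return f"{point:.1f}{unit} ({low:.1f}{unit}, {high:.1f}{unit})"


def _config_hash(config: Mapping) -> str:
    # output location is not part of the run's scientific identity
    stripped = {k: v for k, v in config.items() if k != "output_dir"}
    canonical = json.dumps(stripped, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def render_tables(
    analysis: ScenarioAnalysis, outdir, config: Mapping | None = None
) -> dict[str, Path]:
    """Write the region table, country rate table, draws store and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    region = analysis.region_table()
    region["deaths_formatted"] = [
        format_ui(p, lo, hi)
        for p, lo, hi in zip(
            region["deaths_point"], region["deaths_ui_low"], region["deaths_ui_high"]
        )
    ]
    region["pct_reduction_formatted"] = [
        format_ui(p, lo, hi, unit="%")
        for p, lo, hi in zip(
            region["pct_reduction_point"],
            region["pct_reduction_ui_low"],
            region["pct_reduction_ui_high"],
        )
    ]

    rates = analysis.country_rate_table()
    draws = analysis.stratum_draws_frame()

    manifest = {
        "seed": analysis.seed,
        "n_draws": analysis.n_draws,
        "point_statistic": analysis.point_statistic,
        "cf_low": analysis.cf.low,
        "cf_high": analysis.cf.high,
        "scenarios": [
            {"name": s.name, "cap": s.cap} for s in analysis.scenarios
        ],
        "config_hash": _config_hash(dict(config) if config else {}),
    }

    paths = {
        "region_table": outdir / "region_table.csv",
        "country_rates": outdir / "country_rates.csv",
        "stratum_draws": outdir / "stratum_draws.csv",
        "manifest": outdir / "manifest.json",
    }
    region.to_csv(paths["region_table"], index=False)
    rates.to_csv(paths["country_rates"], index=False)
    draws.to_csv(paths["stratum_draws"], index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def analysis_from_draws(
    draws: pd.DataFrame,
    populations: Mapping[str, float],
    region_map: Mapping[str, str],
    scenarios: list[ScenarioSpec],
    cf: CounterfactualSpec,
    seed: int,
    point_statistic: str = "mean",
) -> ScenarioAnalysis:
    """Rebuild a :class:`ScenarioAnalysis` from a long-format draws store."""
    strata: dict[str, dict[StratumKey, BurdenEstimate]] = {}
    n_draws = int(draws["draw"].max()) + 1
    group_cols = ["scenario", "country_code", "cause", "sex", "age_group"]
    for (scen, country, cause, sex, age), sub in draws.groupby(group_cols, sort=True):
        vec = sub.sort_values("draw")["deaths"].to_numpy(dtype=float)
        strata.setdefault(scen, {})[StratumKey(country, cause, sex, age)] = (
            BurdenEstimate(
                scope="stratum",
                key=country,
                draws=vec,
                point_statistic=point_statistic,
                cause=cause,
                sex=sex,
                age_group=age,
            )
        )
    return ScenarioAnalysis.from_strata(
        scenarios, strata, populations, region_map, cf, n_draws, seed, point_statistic
    )


def load_analysis(run_dir, population_path, region_path) -> ScenarioAnalysis:
    """Reload a completed run (draws store + manifest) for re-rendering."""
    run_dir = Path(run_dir)
    with open(run_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    draws = pd.read_csv(run_dir / "stratum_draws.csv", float_precision="round_trip")
    scenarios = [ScenarioSpec(s["name"], s["cap"]) for s in manifest["scenarios"]]
    return analysis_from_draws(
        draws,
        read_population_csv(population_path),
        read_region_map_csv(region_path),
        scenarios,
        CounterfactualSpec(manifest["cf_low"], manifest["cf_high"]),
        manifest["seed"],
        manifest["point_statistic"],
    )


def plot_reduction_bars(analysis: ScenarioAnalysis, path) -> Path:
    """Grouped bar chart of percent reductions by region and scenario."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    current = analysis.current_name
    capped = [s for s in analysis.scenario_names if s != current]
    regions = sorted(analysis.aggregates[current].region) + ["World"]
    width = 0.8 / max(len(capped), 1)
    fig, ax = plt.subplots(figsize=(9, 4.5))
    x = np.arange(len(regions))
    for i, scen in enumerate(capped):
        points = []
        for region in regions:
            scope = "world" if region == "World" else "region"
            points.append(analysis.reduction(scope, region, scen).point)
        ax.bar(x + i * width, points, width, label=scen)
    ax.set_xticks(x + width * (len(capped) - 1) / 2)
    ax.set_xticklabels(regions)
    ax.set_ylabel("Reduction in attributable deaths (%)")
    ax.set_xlabel("WHO region")
    ax.legend(title="Scenario")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
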