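"""End-to-end analysis orchestration.

One configuration drives the whole pipeline: preprocess the three
proxies onto a common 25-year grid, fit the candidate dynamic models
for both responses (population rates, in normalized and unnormalized
SPD variants in parallel, and warfare rates), rank them by BIC,
validate each by total-trajectory simulation, and write tables plus a
machine-readable run manifest.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import (
    FTOL,
    MAX_NFEV,
    FitResult,
    compare_models,
    fit_model,
    validate_trajectory,
)
from .models import ModelVariant, simulate_trajectory
from .series import (
    DEFAULT_WARFARE_FLOOR,
    ProxyTimeSeries,
    aligned_table,
    apply_floor,
    clip_range,
    growth_rates,
    read_proxy_csv,
    resample,
    smooth_spline,
)
from .synthetic import CoupledData, SyntheticScenario, generate_coupled

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "StageError",
    "run_analysis",
    "load_supplementary_table",
    "southern_structure",
]

POPULATION_MENU = (
    ModelVariant.POP_CLIMATE,
    ModelVariant.POP_WARFARE,
    ModelVariant.POP_CLIMATE_WARFARE,
)
WARFARE_MENU = (
    ModelVariant.WAR_BASIC,
    ModelVariant.WAR_ADDITIVE_CLIMATE,
    ModelVariant.WAR_PRESSURE,
)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Everything one run needs; defaults follow the study settings
    (25-year step, spar 0.90 for warfare, 0.65 for climate).

    Inputs are either file paths (two-column CSVs for each proxy) or a
    synthetic scenario; exactly one of the two must be given.
    """

    area: str = "synthetic"
    spd_normalized: str | None = None
    spd_unnormalized: str | None = None
    warfare: str | None = None
    climate: str | None = None
    scenario: SyntheticScenario | None = None
    window: tuple[int, int] | None = None
    step: int = 25
    spar_warfare: float = 0.90
    spar_climate: float = 0.65
    warfare_floor: float = DEFAULT_WARFARE_FLOOR
    population_menu: tuple[ModelVariant, ...] = POPULATION_MENU
    warfare_menu: tuple[ModelVariant, ...] = WARFARE_MENU
    outdir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "scenario" in d and d["scenario"] is not None:
            s = d["scenario"]
            s["pop_variant"] = ModelVariant(s["pop_variant"])
            s["war_variant"] = ModelVariant(s["war_variant"])
            d["scenario"] = SyntheticScenario(**s)
        for key in ("population_menu", "warfare_menu"):
            if key in d:
                d[key] = tuple(ModelVariant(v) for v in d[key])
        if "window" in d and d["window"] is not None:
            d["window"] = tuple(d["window"])
        return cls(**d)

    def manifest(self) -> dict:
        """Machine-readable record of the run settings."""
        d = {
            "area": self.area,
            "window": list(self.window) if self.window else None,
            "step": self.step,
            "spar_warfare": self.spar_warfare,
            "spar_climate": self.spar_climate,
            "warfare_floor": self.warfare_floor,
            "population_menu": [v.value for v in self.population_menu],
            "warfare_menu": [v.value for v in self.warfare_menu],
            "seed": self.seed,
            "versions": {
                "andesdyn": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "tolerances": {"ftol": FTOL, "max_nfev": MAX_NFEV},
        }
        if self.scenario is not None:
            d["scenario"] = {
                "pop_variant": self.scenario.pop_variant.value,
                "war_variant": self.scenario.war_variant.value,
                "true_params": dict(self.scenario.true_params),
                "n_steps": self.scenario.n_steps,
                "obs_noise_sd": self.scenario.obs_noise_sd,
                "seed": self.scenario.seed,
            }
        else:
            d["inputs"] = {
                "spd_normalized": self.spd_normalized,
                "spd_unnormalized": self.spd_unnormalized,
                "warfare": self.warfare,
                "climate": self.climate,
            }
        return d


@dataclass
class AnalysisReport:
    """All run outputs in memory; ``write`` persists them as CSV/JSON."""

    config: AnalysisConfig
    table: pd.DataFrame
    series: dict[str, ProxyTimeSeries]
    population_fits: dict[str, list[FitResult]]  # per SPD variant ("SPDn"/"SPDnn")
    warfare_fits: list[FitResult]
    comparisons: dict[str, pd.DataFrame]
    trajectories: dict[str, ProxyTimeSeries]

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        p = outdir / "aligned_series.csv"
        self.table.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
        for name, comp in self.comparisons.items():
            p = outdir / f"model_comparison_{name}.csv"
            comp.to_csv(p, index=False, float_format="%.10g")
            written.append(p)
            p = outdir / f"model_comparison_{name}.json"
            p.write_text(json.dumps(comp.to_dict("records"), indent=2, default=float))
            written.append(p)
        traj = pd.DataFrame({"yearAD": self.table["yearAD"]})
        for name, s in self.trajectories.items():
            traj[name] = s.values
        p = outdir / "trajectories.csv"
        traj.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
        p = outdir / "manifest.json"
        p.write_text(json.dumps(self.config.manifest(), indent=2, default=str))
        written.append(p)
        return written


def _prepare_from_files(cfg: AnalysisConfig) -> tuple[ProxyTimeSeries, ...]:
    """Load, smooth and resample raw proxy files onto the study grid."""
    if not all((cfg.spd_normalized, cfg.spd_unnormalized, cfg.warfare, cfg.climate)):
        raise StageError("prep", "file-based runs need all four proxy paths")
    spd_n = read_proxy_csv(cfg.spd_normalized, "SPD (normalized)")
    spd_nn = read_proxy_csv(cfg.spd_unnormalized, "SPD (unnormalized)")
    war_raw = read_proxy_csv(cfg.warfare, "warfare index")
    clim_raw = read_proxy_csv(cfg.climate, "lithic %")
    window = cfg.window
    if window is None:
        lo = max(s.times[0] for s in (spd_n, spd_nn, war_raw, clim_raw))
        hi = min(s.times[-1] for s in (spd_n, spd_nn, war_raw, clim_raw))
        hi = lo + ((hi - lo) // cfg.step) * cfg.step
        window = (int(lo), int(hi))
    start, end = window
    # warfare and climate: smooth annual series, then resample; the
    # smoothed ordinal index is clipped back into [0, 6]
    war = clip_range(resample(
        smooth_spline(war_raw, cfg.spar_warfare), cfg.step, start, end))
    clim = resample(smooth_spline(clim_raw, cfg.spar_climate), cfg.step, start, end)
    spd_n = resample(spd_n, cfg.step, start, end)
    spd_nn = resample(spd_nn, cfg.step, start, end)
    return spd_n, spd_nn, clim, war


def _prepare_from_scenario(cfg: AnalysisConfig) -> tuple[ProxyTimeSeries, ...]:
    data: CoupledData = generate_coupled(cfg.scenario)
    rng = np.random.default_rng((cfg.scenario.seed, 2))
    spd_nn = data.latent_N.with_values(
        120.0 * data.latent_N.values
        * np.exp(cfg.scenario.obs_noise_sd * rng.standard_normal(len(data.latent_N))),
        label="SPD (unnormalized)",
    )
    return data.N, spd_nn, data.C, data.W


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run every stage: prep → fit → compare → validate → (write).

    Returns the report; if ``config.outdir`` is set the tables are also
    written there.  Any stage failure raises :class:`StageError` naming
    the stage.
    """
    try:
        if config.scenario is not None:
            spd_n, spd_nn, clim, war = _prepare_from_scenario(config)
        else:
            spd_n, spd_nn, clim, war = _prepare_from_files(config)
        war_pos = apply_floor(war, config.warfare_floor) if np.any(war.values <= 0) else war
        table = aligned_table(spd_n, spd_nn, clim, war)
    except StageError:
        raise
    except Exception as err:
        raise StageError("prep", str(err)) from err

    series = {"SPDn": spd_n, "SPDnn": spd_nn, "LithPct": clim, "War": war_pos}
    population_fits: dict[str, list[FitResult]] = {}
    warfare_fits: list[FitResult] = []
    comparisons: dict[str, pd.DataFrame] = {}
    trajectories: dict[str, ProxyTimeSeries] = {}

    try:
        for spd_name, spd in (("SPDn", spd_n), ("SPDnn", spd_nn)):
            cov = {"N": spd, "W": war_pos, "C": clim}
            fits = [
                fit_model(v, growth_rates(spd), cov)
                for v in config.population_menu
            ]
            population_fits[spd_name] = fits
        cov_w = {"N": spd_n, "W": war_pos, "C": clim}
        warfare_fits = [
            fit_model(v, growth_rates(war_pos), cov_w)
            for v in config.warfare_menu
        ]
    except Exception as err:
        raise StageError("fit", str(err)) from err

    try:
        for spd_name, spd in (("SPDn", spd_n), ("SPDnn", spd_nn)):
            forc = {"W": war_pos, "C": clim}
            for f in population_fits[spd_name]:
                validate_trajectory(f, spd, forc)
                sim = simulate_trajectory(
                    f.variant, f.params, float(spd.values[0]), dict(forc)
                ) if f.sigma2 != float("-inf") else None
                if sim is not None:
                    trajectories[f"{spd_name}_{f.variant.value}"] = sim
        for f in warfare_fits:
            forc = {"N": spd_n, "C": clim}
            validate_trajectory(f, war_pos, forc)
            if f.sigma2 != float("-inf"):
                trajectories[f"War_{f.variant.value}"] = simulate_trajectory(
                    f.variant, f.params, float(war_pos.values[0]), dict(forc)
                )
    except Exception as err:
        raise StageError("validate", str(err)) from err

    try:
        if config.population_menu:
            for spd_name in ("SPDn", "SPDnn"):
                comparisons[f"population_{spd_name}"] = compare_models(
                    population_fits[spd_name]
                )
        if config.warfare_menu:
            comparisons["warfare"] = compare_models(warfare_fits)
    except Exception as err:
        raise StageError("compare", str(err)) from err

    report = AnalysisReport(
        config=config,
        table=table,
        series=series,
        population_fits=population_fits,
        warfare_fits=warfare_fits,
        comparisons=comparisons,
        trajectories=trajectories,
    )
    if config.outdir:
        try:
            report.write(config.outdir)
        except Exception as err:
            raise StageError("write", str(err)) from err
    return report


# ---------------------------------------------------------------------------
# structural checks on an exchange-format table


def load_supplementary_table(path: str | Path) -> dict[str, ProxyTimeSeries]:
    """Load an exchange-format CSV (calBP, yearAD, SPDn, SPDnn, Rn,
    Rnn, LithPct, War, Rwar) into proxy series keyed by column name."""
    df = pd.read_csv(path)
    required = {"yearAD", "SPDn", "SPDnn", "LithPct", "War"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    years = df["yearAD"].to_numpy(int)
    return {
        col: ProxyTimeSeries(years, df[col].to_numpy(float), label=col)
        for col in ("SPDn", "SPDnn", "LithPct", "War")
    }


def southern_structure(
    series: Mapping[str, ProxyTimeSeries],
    spd_key: str = "SPDn",
    warfare_floor: float = DEFAULT_WARFARE_FLOOR,
) -> dict[str, float | bool]:
    """Check the warfare-driven result structure on one aligned table.

    Fits the population models with and without warfare and the basic
    (population-only) warfare model, then reports:

    * ``variance_ratio`` — best warfare-inclusive population model R²
      over the climate-only model R² (a warfare-driven area exceeds 3);
    * ``war_r_squared`` — R² of the population-only warfare model
      (above 0.80 in a warfare-driven area);
    * the corresponding boolean flags.
    """
    spd = series[spd_key]
    war = series["War"]
    if np.any(war.values <= 0):
        war = apply_floor(war, warfare_floor)
    clim = series["LithPct"]
    cov = {"N": spd, "W": war, "C": clim}
    r_pop = growth_rates(spd)
    climate_only = fit_model(ModelVariant.POP_CLIMATE, r_pop, cov)
    with_war = [
        fit_model(ModelVariant.POP_WARFARE, r_pop, cov),
        fit_model(ModelVariant.POP_CLIMATE_WARFARE, r_pop, cov),
    ]
    best_war_r2 = max(f.r_squared for f in with_war)
    ratio = best_war_r2 / climate_only.r_squared if climate_only.r_squared > 0 \
        else float("inf")
    war_basic = fit_model(ModelVariant.WAR_BASIC, growth_rates(war), cov)
    return {
        "climate_only_r2": climate_only.r_squared,
        "best_warfare_r2": best_war_r2,
        "variance_ratio": ratio,
        "war_r_squared": war_basic.r_squared,
        "warfare_dominates": bool(ratio > 3.0),
        "war_model_strong": bool(war_basic.r_squared > 0.80),
    }
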