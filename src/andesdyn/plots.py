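"""Figure generation for an analysis report.

Produces the standard panels: the four aligned proxy series with their
log rates, and one observed-versus-predicted trajectory figure per
fitted model, optionally with a parametric-bootstrap confidence band.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .fitting import FitResult
from .models import DivergenceError, simulate_trajectory
from .pipeline import AnalysisReport
from .series import ProxyTimeSeries

__all__ = ["plot_report", "bootstrap_band"]


def bootstrap_band(
    fit: FitResult,
    initial: float,
    forcings: Mapping[str, ProxyTimeSeries],
    n_boot: int = 200,
    rel_sd: float = 0.05,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Parametric bootstrap band for a trajectory prediction.

    Parameters are perturbed multiplicatively (lognormal, relative sd
    ``rel_sd``) around the fitted values and the trajectory re-simulated;
    the band is the pointwise (1−level)/2 … (1+level)/2 percentile
    envelope.  This is a pragmatic uncertainty display, not a formal
    interval.  Returns ``None`` if fewer than half the draws simulate
    without diverging.
    """
    rng = np.random.default_rng(seed)
    sims = []
    for _ in range(n_boot):
        params = {
            k: v * float(np.exp(rel_sd * rng.standard_normal()))
            if v != 0 else 0.0
            for k, v in fit.params.items()
        }
        try:
            s = simulate_trajectory(fit.variant, params, initial, dict(forcings))
        except (DivergenceError, ValueError):
            continue
        sims.append(s.values)
    if len(sims) < n_boot / 2:
        return None
    arr = np.vstack(sims)
    lo = np.percentile(arr, 100 * (1 - level) / 2, axis=0)
    hi = np.percentile(arr, 100 * (1 + level) / 2, axis=0)
    return lo, hi


def plot_report(
    report: AnalysisReport,
    outdir: str | Path,
    with_bands: bool = True,
) -> list[Path]:
    """Write the proxy-panel figure and per-model trajectory figures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    t = report.table
    fig, axes = plt.subplots(4, 1, figsize=(8, 10), sharex=True)
    axes[0].plot(t["yearAD"], t["SPDn"], label="SPD (normalized)")
    axes[0].plot(t["yearAD"], t["SPDnn"] / t["SPDnn"].max() * t["SPDn"].max(),
                 "--", label="SPD (unnorm., rescaled)")
    axes[0].set_ylabel("SPD")
    axes[0].legend(fontsize=8)
    axes[1].plot(t["yearAD"], t["Rn"], label="population rate")
    axes[1].plot(t["yearAD"], t["Rwar"], "--", label="warfare rate")
    axes[1].axhline(0, color="k", lw=0.5)
    axes[1].set_ylabel("log rate / step")
    axes[1].legend(fontsize=8)
    axes[2].plot(t["yearAD"], t["War"], color="firebrick")
    axes[2].set_ylabel("warfare index")
    axes[3].plot(t["yearAD"], t["LithPct"], color="seagreen")
    axes[3].set_ylabel("lithic %")
    axes[3].set_xlabel("year AD")
    fig.suptitle(f"Aligned proxy series — {report.config.area}")
    fig.tight_layout()
    p = outdir / "proxy_panels.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    def _traj_figure(name: str, observed: ProxyTimeSeries, fit: FitResult,
                     forcings: Mapping[str, ProxyTimeSeries]) -> None:
        sim = report.trajectories.get(name)
        if sim is None:
            return
        fig, ax = plt.subplots(figsize=(7, 4))
        if with_bands:
            band = bootstrap_band(fit, float(observed.values[0]), forcings,
                                  seed=report.config.seed)
            if band is not None:
                ax.fill_between(observed.times, band[0], band[1],
                                alpha=0.25, color="gray", label="95% band")
            else:
                ax.annotate("band skipped (divergent draws)", xy=(0.02, 0.95),
                            xycoords="axes fraction", fontsize=7)
        ax.plot(observed.times, observed.values, "o-", ms=3, label="observed")
        ax.plot(sim.times, sim.values, "r-", label="predicted")
        s2 = "—" if fit.sigma2 is None else f"{fit.sigma2:.3f}"
        ax.set_title(f"{name}  (σ² = {s2})", fontsize=10)
        ax.set_xlabel("year AD")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = outdir / f"trajectory_{name}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)

    war_pos = report.series["War"]
    clim = report.series["LithPct"]
    for spd_name in ("SPDn", "SPDnn"):
        observed = report.series[spd_name]
        for fit in report.population_fits.get(spd_name, []):
            _traj_figure(f"{spd_name}_{fit.variant.value}", observed, fit,
                         {"W": war_pos, "C": clim})
    for fit in report.warfare_fits:
        _traj_figure(f"War_{fit.variant.value}", war_pos, fit,
                     {"N": report.series["SPDn"], "C": clim})
    return written
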