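"""Discrete-time population and warfare dynamics.

Six one-step multiplicative (Ricker-type) maps describe the coupled
system of population level N, warfare intensity W and an exogenous
hydroclimate proxy C.  Each map has the form  X_t = X_{t-1} · exp(rate),
where the rate is the per-step log growth:

population response
    pop_climate            r = rN·(1 − N/k + α·C)          climate as a
                           lateral perturbation of carrying capacity k
    pop_warfare            r = rN·(1 − N/k) − β·W          β is direct
                           warfare mortality
    pop_climate_warfare    r = rN·(1 − N/k + α·C + γ·W)    climate and
                           warfare both act on land productivity

warfare response
    war_basic              w = λ·N − μ                     conflict rises
                           with population, decays at rate μ
    war_additive_climate   w = λ·N + ψ·C − μ
    war_pressure           w = λ·N/C − μ                   population
                           pressure = population over resource proxy

All forcings enter lagged one step (values at t−1 drive the step into
t).  The log-rate forms are the regression equations of the fits; the
maps themselves are used for full-trajectory simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

from .series import ProxyTimeSeries

__all__ = [
    "ModelVariant",
    "ModelSpec",
    "PARAM_NAMES",
    "POSITIVE_PARAMS",
    "DivergenceError",
    "pop_rate",
    "war_rate",
    "rate",
    "step",
    "simulate_trajectory",
    "simulate_coupled",
]

#: Exponent clip guard: |rate| beyond this triggers a divergence warning
#: and clipping (protects exp under extreme trial parameters during
#: optimization).
EXP_CAP = 50.0

#: State magnitude beyond which a simulated trajectory is declared divergent.
STATE_CAP = 1e12

#: Division guard for the population-pressure ratio N/C.
PRESSURE_EPS = 1e-9


class ModelVariant(str, Enum):
    """Stable string identifiers for the six model variants."""

    POP_CLIMATE = "pop_climate"
    POP_WARFARE = "pop_warfare"
    POP_CLIMATE_WARFARE = "pop_climate_warfare"
    WAR_BASIC = "war_basic"
    WAR_ADDITIVE_CLIMATE = "war_additive_climate"
    WAR_PRESSURE = "war_pressure"

    @property
    def target(self) -> str:
        return "population" if self.value.startswith("pop") else "warfare"


#: Free parameters of each variant, in canonical order.
PARAM_NAMES: dict[ModelVariant, tuple[str, ...]] = {
    ModelVariant.POP_CLIMATE: ("rN", "k", "alpha"),
    ModelVariant.POP_WARFARE: ("rN", "k", "beta"),
    ModelVariant.POP_CLIMATE_WARFARE: ("rN", "k", "alpha", "gamma"),
    ModelVariant.WAR_BASIC: ("lam", "mu"),
    ModelVariant.WAR_ADDITIVE_CLIMATE: ("lam", "mu", "psi"),
    ModelVariant.WAR_PRESSURE: ("lam", "mu"),
}

#: Parameters constrained positive (rates and the carrying capacity);
#: the climate/warfare coefficients alpha, beta, gamma, psi are signed.
POSITIVE_PARAMS = frozenset({"rN", "k", "lam", "mu"})

#: Covariates each variant needs besides its own lagged state.
REQUIRED_FORCINGS: dict[ModelVariant, tuple[str, ...]] = {
    ModelVariant.POP_CLIMATE: ("C",),
    ModelVariant.POP_WARFARE: ("W",),
    ModelVariant.POP_CLIMATE_WARFARE: ("C", "W"),
    ModelVariant.WAR_BASIC: ("N",),
    ModelVariant.WAR_ADDITIVE_CLIMATE: ("N", "C"),
    ModelVariant.WAR_PRESSURE: ("N", "C"),
}


class DivergenceError(RuntimeError):
    """A simulated trajectory left the admissible range."""

    def __init__(self, message: str, step_index: int | None = None):
        super().__init__(message)
        self.step_index = step_index


@dataclass(frozen=True)
class ModelSpec:
    """A model variant plus which of its parameters are free.

    By default every parameter of the variant is free; fixing a subset
    (e.g. ``alpha=0``) yields the nested reduced model.
    """

    variant: ModelVariant
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        foreign = set(self.fixed) - set(PARAM_NAMES[self.variant])
        if foreign:
            raise ValueError(
                f"parameters {sorted(foreign)} are foreign to variant "
                f"{self.variant.value}"
            )
        object.__setattr__(self, "fixed", dict(self.fixed))

    @property
    def target(self) -> str:
        return self.variant.target

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return tuple(p for p in PARAM_NAMES[self.variant] if p not in self.fixed)

    def full_params(self, free: Mapping[str, float]) -> dict[str, float]:
        """Merge free-parameter values with the fixed ones."""
        out = dict(self.fixed)
        out.update(free)
        missing = set(PARAM_NAMES[self.variant]) - set(out)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        return out


def _check_params(variant: ModelVariant, params: Mapping[str, float]) -> None:
    names = set(PARAM_NAMES[variant])
    missing = names - set(params)
    if missing:
        raise ValueError(
            f"{variant.value}: missing parameters {sorted(missing)}"
        )


def pop_rate(
    variant: ModelVariant,
    params: Mapping[str, float],
    N_prev,
    C_prev=None,
    W_prev=None,
):
    """Log growth rate of the population for one step (vectorized).

    ``N_prev`` must be positive; ``C_prev``/``W_prev`` are required by
    the variants that use them.
    """
    if variant.target != "population":
        raise ValueError(f"{variant.value} is not a population model")
    _check_params(variant, params)
    N = np.asarray(N_prev, dtype=float)
    if np.any(N <= 0):
        raise ValueError("N_prev must be strictly positive")
    rN, k = params["rN"], params["k"]
    if variant is ModelVariant.POP_CLIMATE:
        if C_prev is None:
            raise ValueError("pop_climate requires the climate forcing C_prev")
        return rN * (1.0 - N / k + params["alpha"] * np.asarray(C_prev, float))
    if variant is ModelVariant.POP_WARFARE:
        if W_prev is None:
            raise ValueError("pop_warfare requires the warfare forcing W_prev")
        return rN * (1.0 - N / k) - params["beta"] * np.asarray(W_prev, float)
    # pop_climate_warfare
    if C_prev is None or W_prev is None:
        raise ValueError("pop_climate_warfare requires both C_prev and W_prev")
    return rN * (
        1.0 - N / k
        + params["alpha"] * np.asarray(C_prev, float)
        + params["gamma"] * np.asarray(W_prev, float)
    )


def war_rate(
    variant: ModelVariant,
    params: Mapping[str, float],
    W_prev,
    N_prev=None,
    C_prev=None,
):
    """Log growth rate of warfare intensity for one step (vectorized)."""
    if variant.target != "warfare":
        raise ValueError(f"{variant.value} is not a warfare model")
    _check_params(variant, params)
    W = np.asarray(W_prev, dtype=float)
    if np.any(W <= 0):
        raise ValueError("W_prev must be strictly positive")
    if N_prev is None:
        raise ValueError(f"{variant.value} requires the population level N_prev")
    N = np.asarray(N_prev, dtype=float)
    lam, mu = params["lam"], params["mu"]
    if variant is ModelVariant.WAR_BASIC:
        return lam * N - mu
    if variant is ModelVariant.WAR_ADDITIVE_CLIMATE:
        if C_prev is None:
            raise ValueError("war_additive_climate requires C_prev")
        return lam * N + params["psi"] * np.asarray(C_prev, float) - mu
    # war_pressure: population over resource availability
    if C_prev is None:
        raise ValueError("war_pressure requires C_prev")
    C = np.asarray(C_prev, dtype=float)
    if np.any(C <= PRESSURE_EPS):
        raise ZeroDivisionError(
            "war_pressure: climate proxy at or below the division guard"
        )
    return lam * N / C - mu


def rate(
    variant: ModelVariant,
    params: Mapping[str, float],
    *,
    N=None,
    W=None,
    C=None,
):
    """Unified lagged-covariate rate used by the fitting layer."""
    if variant.target == "population":
        return pop_rate(variant, params, N, C_prev=C, W_prev=W)
    return war_rate(variant, params, W, N_prev=N, C_prev=C)


def _clipped_exp(r):
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > EXP_CAP):
        warnings.warn(
            f"rate exceeded ±{EXP_CAP:g}; exponent clipped", RuntimeWarning,
            stacklevel=3,
        )
        r = np.clip(r, -EXP_CAP, EXP_CAP)
    return np.exp(r)


def step(
    variant: ModelVariant,
    params: Mapping[str, float],
    state_prev: Mapping[str, float],
    forcing_prev: Mapping[str, float] | None = None,
    *,
    beta_outside: bool = False,
) -> float:
    """Advance the variant's state one step.

    ``state_prev`` holds the endogenous values at t−1 (keys "N" and/or
    "W"); ``forcing_prev`` holds exogenous values at t−1 (key "C").
    The next value is  previous · exp(rate), hence strictly positive.

    ``beta_outside`` selects an alternative reading of the warfare-
    mortality model in which β·W is subtracted from the whole map
    rather than from the exponent; the exponent (rate-scale) placement
    is the default because the models are fitted on log rates.
    """
    f = dict(forcing_prev or {})
    if variant.target == "population":
        N = state_prev["N"]
        if beta_outside and variant is ModelVariant.POP_WARFARE:
            nxt = N * _clipped_exp(
                params["rN"] * (1.0 - N / params["k"])
            ) - params["beta"] * state_prev.get("W", f.get("W", 0.0))
            if nxt <= 0:
                raise DivergenceError(
                    "beta_outside map drove the population non-positive"
                )
            return float(nxt)
        r = pop_rate(
            variant, params, N,
            C_prev=f.get("C"), W_prev=state_prev.get("W", f.get("W")),
        )
        return float(N * _clipped_exp(r))
    W = state_prev["W"]
    w = war_rate(
        variant, params, W,
        N_prev=state_prev.get("N", f.get("N")), C_prev=f.get("C"),
    )
    return float(W * _clipped_exp(w))


def _forcing_values(
    forcings: Mapping[str, ProxyTimeSeries] | None, name: str, grid: np.ndarray
) -> np.ndarray | None:
    if not forcings or name not in forcings:
        return None
    s = forcings[name]
    if len(s) != len(grid) or not np.array_equal(s.times, grid):
        raise ValueError(f"forcing {name!r} is not on the trajectory grid")
    return s.values


def simulate_trajectory(
    variant: ModelVariant,
    params: Mapping[str, float],
    initial: float,
    forcings: Mapping[str, ProxyTimeSeries],
    *,
    beta_outside: bool = False,
) -> ProxyTimeSeries:
    """Iterate one variant over the grid of its forcing series.

    Element 0 of the output is ``initial`` (the first observed value in
    a validation run); element t applies :func:`step` to element t−1
    with the observed exogenous covariates at t−1.  The simulated
    endogenous variable is never re-anchored to observations after
    t = 0.  Exceeding the state cap raises :class:`DivergenceError`
    naming the step.
    """
    if initial <= 0:
        raise ValueError("initial state must be positive")
    series = list(forcings.values())
    if not series:
        raise ValueError("at least one forcing series is required")
    grid = series[0].times
    cov = {name: _forcing_values(forcings, name, grid) for name in forcings}
    endo = "N" if variant.target == "population" else "W"
    out = np.empty(len(grid))
    out[0] = initial
    for t in range(1, len(grid)):
        state = {endo: out[t - 1]}
        forc = {
            name: vals[t - 1] for name, vals in cov.items()
            if vals is not None and name != endo
        }
        out[t] = step(variant, params, state, forc, beta_outside=beta_outside)
        if not np.isfinite(out[t]) or out[t] > STATE_CAP:
            raise DivergenceError(
                f"trajectory diverged at step {t} (year {grid[t]})", step_index=t
            )
    return ProxyTimeSeries(grid, out, label=f"simulated {variant.value}")


def simulate_coupled(
    pop_variant: ModelVariant,
    war_variant: ModelVariant,
    params: Mapping[str, float],
    N0: float,
    W0: float,
    climate: ProxyTimeSeries,
) -> tuple[ProxyTimeSeries, ProxyTimeSeries]:
    """Simulate N and W jointly, both endogenous, under exogenous climate.

    ``params`` holds the union of both variants' parameters.  Each
    variable at t is driven by both variables at t−1, reproducing the
    mutual population–warfare feedback.
    """
    if N0 <= 0 or W0 <= 0:
        raise ValueError("initial states must be positive")
    grid = climate.times
    C = climate.values
    N = np.empty(len(grid))
    W = np.empty(len(grid))
    N[0], W[0] = N0, W0
    pop_params = {p: params[p] for p in PARAM_NAMES[pop_variant]}
    war_params = {p: params[p] for p in PARAM_NAMES[war_variant]}
    for t in range(1, len(grid)):
        r = pop_rate(pop_variant, pop_params, N[t - 1], C_prev=C[t - 1], W_prev=W[t - 1])
        w = war_rate(war_variant, war_params, W[t - 1], N_prev=N[t - 1], C_prev=C[t - 1])
        N[t] = N[t - 1] * _clipped_exp(r)
        W[t] = W[t - 1] * _clipped_exp(w)
        if not (np.isfinite(N[t]) and np.isfinite(W[t])) or max(N[t], W[t]) > STATE_CAP:
            raise DivergenceError(f"coupled simulation diverged at step {t}", step_index=t)
    return (
        ProxyTimeSeries(grid, N, label="population (latent)"),
        ProxyTimeSeries(grid, W, label="warfare (latent)"),
    )
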