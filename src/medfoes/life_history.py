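"""Biological submodels: development, reproduction, and mortality.

All functions are pure and vectorization-friendly; stochastic ones take an
explicit numpy Generator so every run is seed-reproducible.

Development follows thermal-unit accumulation: each hour contributes
max(0, T - T_min) degree-hours while T <= T_max (development halts above
the ceiling), and a stage completes when the accumulated total reaches the
individual's threshold, drawn once per stage entry as 24*K*(1 + gamma*z).
An alternative memoryless mode converts the same increment into a per-hour
transition probability with the same expected stage duration.

Natural mortality composes a stage-specific daily baseline at the thermal
optimum (M*) with upward-opening quadratics mu_x(T) fitted to Medfly
survival data (eggs and larvae share one curve); the daily rate is tested
hourly via survival compounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Stage

__all__ = [
    "MortalityQuadratic",
    "FixedMortality",
    "DEFAULT_QUADRATICS",
    "thermal_increment",
    "draw_threshold",
    "draw_thresholds",
    "transition_due",
    "hourly_transition_probability",
    "mu_temperature",
    "daily_natural_mortality",
    "hourly_death_probability",
    "daily_eggs",
    "sterilization_event",
]


@dataclass(frozen=True)
class MortalityQuadratic:
    """mu(T) = a2*T^2 + a1*T + a0, daily mortality proportion (clamped to [0,1])."""

    a2: float
    a1: float
    a0: float

    def __call__(self, T):
        T = np.asarray(T, dtype=float)
        out = np.clip(self.a2 * T * T + self.a1 * T + self.a0, 0.0, 1.0)
        return out if out.shape else float(out)

    @property
    def vertex(self) -> float:
        """Temperature of minimum mortality (the thermal optimum)."""
        return -self.a1 / (2.0 * self.a2)


#: Fitted daily-mortality quadratics: eggs & larvae share one curve.
DEFAULT_QUADRATICS: dict[Stage, MortalityQuadratic] = {
    Stage.EGG: MortalityQuadratic(0.00040, -0.0145, 0.1314),
    Stage.LARVA: MortalityQuadratic(0.00040, -0.0145, 0.1314),
    Stage.PUPA: MortalityQuadratic(0.00050, -0.0207, 0.2142),
    Stage.ADULT_IMMATURE: MortalityQuadratic(0.00049, -0.0187, 0.1846),
    Stage.ADULT_MATURE: MortalityQuadratic(0.00049, -0.0187, 0.1846),
}


@dataclass(frozen=True)
class FixedMortality:
    """Mode-(i) mortality: one fixed daily rate per stage (adults share M_a)."""

    M_e: float
    M_l: float
    M_p: float
    M_a: float

    def as_array(self) -> np.ndarray:
        return np.array([self.M_e, self.M_l, self.M_p, self.M_a, self.M_a])


def thermal_increment(T, T_min, T_max):
    """Degree-hours contributed by one hour at temperature T.

    Zero below the base temperature and zero above the developmental
    ceiling T_max (development halts, no accumulation).
    """
    T = np.asarray(T, dtype=float)
    out = np.where(T <= T_max, np.maximum(0.0, T - T_min), 0.0)
    return out if out.shape else float(out)


def draw_threshold(K: float, gamma: float, rng: np.random.Generator) -> float:
    """Individual degree-hour threshold: 24*K*(1 + gamma*z), z ~ N(0,1).

    Redraws until positive (relevant only for implausibly large gamma).
    """
    return float(draw_thresholds(np.array([K]), gamma, rng)[0])


def draw_thresholds(K, gamma: float, rng: np.random.Generator) -> np.ndarray:
    """Vector version of :func:`draw_threshold` (one draw per element of K)."""
    K = np.asarray(K, dtype=float)
    mean = 24.0 * K
    if gamma == 0.0:
        return mean.copy()
    out = mean * (1.0 + gamma * rng.standard_normal(K.size))
    bad = out <= 0.0
    while bad.any():  # truncate at zero by redrawing
        out[bad] = mean[bad] * (1.0 + gamma * rng.standard_normal(int(bad.sum())))
        bad = out <= 0.0
    return out


def transition_due(accumulated, threshold):
    """True once accumulated degree-hours reach the threshold (inclusive).

    Accumulation in excess of the threshold carries into the next stage.
    """
    return np.asarray(accumulated) >= np.asarray(threshold)


def hourly_transition_probability(T, T_min, T_max, K):
    """Per-hour transition probability for the memoryless development mode.

    The expected fraction of the stage completed this hour,
    min(1, increment / (24*K)), so the mean stage duration matches the
    thermal-unit mode at constant temperature.
    """
    inc = thermal_increment(T, T_min, T_max)
    out = np.minimum(1.0, inc / (24.0 * np.asarray(K, dtype=float)))
    return out if np.asarray(out).shape else float(out)


def mu_temperature(stage: Stage, T, quadratics=None):
    """Temperature-dependent daily mortality mu_x(T) for a stage, in [0, 1]."""
    quadratics = DEFAULT_QUADRATICS if quadratics is None else quadratics
    return quadratics[Stage(stage)](T)


def daily_natural_mortality(stage: Stage, T, M_star: float, quadratics=None):
    """Daily mortality = clamp(M* + mu_x(T), 0, 1).

    The composition is additive: the fitted quadratics are ~0 at their
    vertices, so M* is exactly the mortality at the thermal optimum.
    """
    out = np.clip(M_star + mu_temperature(stage, T, quadratics), 0.0, 1.0)
    return out if np.asarray(out).shape else float(out)


def hourly_death_probability(daily, literal: bool = False):
    """Per-hour death probability equivalent to a daily rate.

    Survival compounding, 1 - (1 - daily)^(1/24): twenty-four independent
    hourly trials reproduce the daily probability exactly.  ``literal=True``
    instead returns daily^(1/24) — the rule as historically printed, kept
    for archaeology; it grossly inflates mortality and is never the default.
    """
    daily = np.asarray(daily, dtype=float)
    if np.any((daily < 0) | (daily > 1)):
        raise ValueError("daily mortality must lie in [0, 1]")
    out = daily ** (1.0 / 24.0) if literal else 1.0 - (1.0 - daily) ** (1.0 / 24.0)
    return out if out.shape else float(out)


def daily_eggs(r: float, r_var: float, rng: np.random.Generator, size=None):
    """Eggs laid by one female today: round(N(r, r_var)) clamped at zero."""
    draw = rng.normal(r, np.sqrt(r_var), size=size)
    out = np.maximum(np.rint(draw), 0.0).astype(np.int64)
    return out if size is not None else int(out)


def sterilization_event(r_red: float, rng: np.random.Generator, size=None):
    """Daily test of permanent fertility loss (probability r_red)."""
    out = rng.random(size) < r_red
    return out if size is not None else bool(out)
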