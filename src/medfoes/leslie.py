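"""Leslie-matrix projection: the deterministic oracle for the agent model.

Under constant temperature, fixed daily stage mortalities and constant
fecundity, the agent-based simulator should reproduce the demography of a
classic Leslie matrix: fecundities on the first row, daily survival
probabilities on the subdiagonal, one age class per day.  This module
builds such matrices from stage durations, projects them, aggregates age
classes back into the five life stages, and measures the worst per-stage
proportion discrepancy against averaged agent-model output — the published
validation design for this simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Stage

__all__ = [
    "LeslieModel",
    "build_stage_structured_model",
    "leslie_project",
    "stage_proportions",
    "compare_abs_leslie",
]


@dataclass
class LeslieModel:
    """Age-classified projection model.

    ``survival[i]`` is the daily probability of advancing from class i to
    i+1 (the subdiagonal); the final class has no successor.  ``fecundity``
    is daily female eggs per female by class (first matrix row).
    ``stage_of_class`` maps each age class to one of the five life stages
    for aggregation.
    """

    survival: np.ndarray
    fecundity: np.ndarray
    initial: np.ndarray
    stage_of_class: np.ndarray

    def __post_init__(self):
        self.survival = np.asarray(self.survival, float)
        self.fecundity = np.asarray(self.fecundity, float)
        self.initial = np.asarray(self.initial, float)
        self.stage_of_class = np.asarray(self.stage_of_class, np.int64)
        n = self.survival.size
        if not (self.fecundity.size == n == self.initial.size
                == self.stage_of_class.size):
            raise ValueError("survival/fecundity/initial/stage map lengths differ")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("survivals must lie in [0, 1]")
        if np.any(self.fecundity < 0):
            raise ValueError("fecundities must be >= 0")

    @property
    def n_classes(self) -> int:
        return self.survival.size

    def matrix(self) -> np.ndarray:
        n = self.n_classes
        L = np.zeros((n, n))
        L[0, :] = self.fecundity
        L[np.arange(1, n), np.arange(n - 1)] = self.survival[:-1]
        return L


def build_stage_structured_model(
    durations_days: dict[Stage, int],
    daily_mortality: dict[Stage, float],
    mature_fecundity: float,
    n_classes: int = 40,
    initial_mature: float = 100.0,
) -> LeslieModel:
    """Assemble a Leslie model from per-stage durations and mortalities.

    Classes are assigned stage by stage in life-cycle order (one class per
    day); all classes beyond the immature-adult block are mature adults,
    each with ``mature_fecundity`` daily female eggs.  The population
    starts with ``initial_mature`` females in the first mature class.
    """
    order = [Stage.EGG, Stage.LARVA, Stage.PUPA, Stage.ADULT_IMMATURE]
    stage_of_class = np.full(n_classes, int(Stage.ADULT_MATURE), np.int64)
    pos = 0
    for s in order:
        d = int(durations_days[s])
        if pos + d > n_classes:
            raise ValueError("stage durations exceed the number of age classes")
        stage_of_class[pos:pos + d] = int(s)
        pos += d
    survival = np.empty(n_classes)
    for s in Stage:
        survival[stage_of_class == int(s)] = 1.0 - daily_mortality[s]
    fecundity = np.where(stage_of_class == int(Stage.ADULT_MATURE),
                         mature_fecundity, 0.0)
    initial = np.zeros(n_classes)
    initial[pos] = initial_mature  # first mature class
    return LeslieModel(survival, fecundity, initial, stage_of_class)


def leslie_project(model: LeslieModel, days: int) -> np.ndarray:
    """Iterate n(t+1) = L n(t); rows are days 0..days, columns age classes."""
    if days < 0:
        raise ValueError("days must be >= 0")
    L = model.matrix()
    out = np.empty((days + 1, model.n_classes))
    out[0] = model.initial
    for t in range(days):
        out[t + 1] = L @ out[t]
    return out


def stage_proportions(abundance: np.ndarray,
                      stage_of_class: np.ndarray) -> np.ndarray:
    """Aggregate per-class abundances into per-stage proportions by day.

    Rows with zero total are returned as all-zero rather than NaN.
    """
    abundance = np.atleast_2d(abundance)
    by_stage = np.zeros((abundance.shape[0], 5))
    for s in range(5):
        cols = stage_of_class == s
        if cols.any():
            by_stage[:, s] = abundance[:, cols].sum(axis=1)
    totals = by_stage.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(totals > 0, by_stage / totals, 0.0)
    return props


def compare_abs_leslie(abs_props: np.ndarray, leslie_props: np.ndarray,
                       days: slice | None = None) -> float:
    """Max absolute per-stage proportion discrepancy over days and stages."""
    a = np.asarray(abs_props, float)
    b = np.asarray(leslie_props, float)
    if a.shape != b.shape:
        raise ValueError("proportion arrays must have equal shapes")
    if days is not None:
        a, b = a[days], b[days]
    return float(np.max(np.abs(a - b)))
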