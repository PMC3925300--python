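"""Batch experiments: LHS parameter sweeps, extirpation statistics, PRCC
sensitivity analysis, and the degree-day quarantine-length comparator.

A batch draws one parameter vector per run by Latin hypercube sampling over
literature-derived ranges, executes the agent model once per vector with a
deterministic per-run seed, and summarizes the distribution of extirpation
times t_e: the mean t_m over extirpated runs and the time t_q by which a
given fraction q of *all* runs (censored runs counted as not yet
extirpated) have gone extinct.  Parameter importance is ranked by partial
rank correlation coefficients between each input and t_e, controlling for
all other inputs.  The quarantine-length comparator reproduces the
regulatory yardstick: days until three full degree-day generations have
accumulated at local temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .params import Termination
from .temperature import TemperatureSeries

__all__ = [
    "ParameterRanges",
    "BatchResult",
    "TABLE_RANGES",
    "lhs_sample",
    "run_batch",
    "extirpation_stats",
    "prcc",
    "degree_day_quarantine_length",
    "NOT_REACHED",
]

#: Sentinel returned when the series ends before the degree-day target.
NOT_REACHED = -1

#: Literature-review ranges for the varied inputs.  trap_sensitivity feeds
#: the initial-population size N_0; r_var is fixed at 3.57 and gamma at
#: 0.05 across sweeps.
TABLE_RANGES: dict[str, tuple[float, float]] = {
    "M_star_e": (0.0198, 0.1200),
    "M_star_l": (0.0068, 0.0946),
    "M_star_p": (0.0016, 0.0465),
    "M_star_a": (0.0245, 0.1340),
    "S": (0.005, 0.050),
    "T_min_e": (9.6, 12.5),
    "K_e": (27.27, 33.80),
    "T_min_l": (5.0, 10.8),
    "K_l": (94.50, 186.78),
    "T_min_p": (9.1, 13.8),
    "K_p": (123.96, 169.49),
    "T_min_a": (7.9, 9.9),
    "K_a": (58.20, 105.71),
    "r": (5.0, 35.0),
    "r_red": (0.5, 1.0),
    "trap_sensitivity": (0.02, 0.03),
}


@dataclass
class ParameterRanges:
    """Named [min, max] intervals for every varied input."""

    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE_RANGES))

    def __post_init__(self):
        for name, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"{name}: min > max")

    @property
    def names(self) -> list[str]:
        return list(self.ranges)


@dataclass
class BatchResult:
    """Per-run parameter vectors, seeds, extirpation times and outcomes.

    ``t_e`` is NaN for runs that did not extirpate; ``terminated`` records
    why each run ended.
    """

    design: pd.DataFrame
    t_e: np.ndarray
    terminated: list[Termination]
    seeds: np.ndarray

    def extirpated_mask(self) -> np.ndarray:
        return np.array([t is Termination.EXTIRPATED for t in self.terminated])


def lhs_sample(ranges: ParameterRanges | dict, n: int,
               rng: np.random.Generator) -> pd.DataFrame:
    """Latin hypercube design: one uniform draw per equal stratum per column.

    Each parameter's interval is split into n equal strata; one value is
    drawn uniformly inside each stratum and the n values are randomly
    permuted, independently per column.  A degenerate range (min == max)
    yields a constant column.
    """
    if n < 1:
        raise ValueError("need at least one run")
    if isinstance(ranges, dict):
        ranges = ParameterRanges(dict(ranges))
    cols = {}
    for name, (lo, hi) in ranges.ranges.items():
        u = (np.arange(n) + rng.random(n)) / n     # one point per stratum
        cols[name] = lo + (hi - lo) * rng.permutation(u)
    return pd.DataFrame(cols)


def run_batch(design: pd.DataFrame, temps: TemperatureSeries,
              make_run: Callable, base_seed: int,
              progress: Callable[[int], None] | None = None) -> BatchResult:
    """Execute one simulation per design row with seed = base_seed + row.

    ``make_run(row: dict, rng) -> SimulationResult`` builds and runs the
    scenario for one parameter vector (see scenario.analyze_outbreak for
    the standard builder).  Per-row failures are recorded, not fatal.
    """
    n = len(design)
    t_e = np.full(n, np.nan)
    terminated: list[Termination] = []
    seeds = base_seed + np.arange(n)
    for i, row in enumerate(design.itertuples(index=False)):
        rng = np.random.default_rng(int(seeds[i]))
        try:
            res = make_run(row._asdict(), rng)
            terminated.append(res.terminated_by)
            if res.terminated_by is Termination.EXTIRPATED:
                t_e[i] = res.t_e
        except Exception:
            terminated.append(Termination.TEMPS_EXHAUSTED)
        if progress is not None:
            progress(i)
    return BatchResult(design=design.copy(), t_e=t_e, terminated=terminated,
                       seeds=seeds)


def extirpation_stats(batch: BatchResult, q: float = 0.95
                      ) -> tuple[float, float]:
    """(t_m, t_q): mean extirpation time and the q-quantile day.

    t_m averages t_e over extirpated runs only.  t_q is the smallest t such
    that at least a fraction q of *all* runs have extirpated by day t; runs
    the temperature series outlived count as censored above every observed
    t_e, so t_q is NaN when fewer than q of the runs extirpated at all.
    """
    ext = batch.t_e[np.isfinite(batch.t_e)]
    if ext.size == 0:
        raise ValueError("no extirpated runs")
    t_m = float(ext.mean())
    n_total = batch.t_e.size
    k = int(np.ceil(q * n_total))
    if k <= 0:
        return t_m, float(ext.min())
    if k > ext.size:
        return t_m, float("nan")
    t_q = float(np.sort(ext)[k - 1])
    return t_m, t_q


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=0)


def prcc(design: pd.DataFrame, response: np.ndarray) -> pd.DataFrame:
    """Partial rank correlation of each input with the response.

    All columns and the response are rank-transformed; PRCC_j is the
    correlation between the residuals of ranked x_j and ranked y after
    regressing each on all the other ranked inputs.  The significance test
    uses t = PRCC * sqrt((N - 2 - k) / (1 - PRCC^2)) with k the number of
    controlled inputs, against a two-sided t distribution.

    Returns one row per parameter (coefficient, statistic, p), ordered by
    |coefficient| descending.  Constant columns get NaN and a flag.
    """
    y = np.asarray(response, float)
    if np.isnan(y).any():
        raise ValueError("response has missing entries; drop censored runs first")
    X = design.to_numpy(float)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError("need more runs than parameters + 2")
    ry = _rank(y[:, None])[:, 0]
    rX = _rank(X)
    ry = ry - ry.mean()
    rX = rX - rX.mean(axis=0)
    k_controlled = p - 1
    dof = n - 2 - k_controlled

    rows = []
    for j in range(p):
        xj = rX[:, j]
        if np.ptp(xj) == 0:
            rows.append((design.columns[j], np.nan, np.nan, np.nan, True))
            continue
        others = np.delete(rX, j, axis=1)
        others = np.column_stack([np.ones(n), others])
        beta_x, *_ = np.linalg.lstsq(others, xj, rcond=None)
        beta_y, *_ = np.linalg.lstsq(others, ry, rcond=None)
        ex = xj - others @ beta_x
        ey = ry - others @ beta_y
        denom = np.sqrt((ex ** 2).sum() * (ey ** 2).sum())
        coef = float((ex * ey).sum() / denom) if denom > 0 else np.nan
        tstat = prcc_test_statistic(coef, n, k_controlled)
        pval = float(2.0 * stats.t.sf(abs(tstat), dof))
        rows.append((design.columns[j], coef, tstat, pval, False))
    out = pd.DataFrame(rows, columns=["parameter", "coefficient",
                                      "statistic", "p", "constant"])
    return out.reindex(
        out["coefficient"].abs().sort_values(ascending=False, na_position="last").index
    ).reset_index(drop=True)


def prcc_test_statistic(coef: float, n: int, k_controlled: int) -> float:
    """t statistic for a partial correlation: coef*sqrt((N-2-k)/(1-coef^2))."""
    if not np.isfinite(coef) or abs(coef) >= 1.0:
        return float(np.sign(coef) * np.inf) if np.isfinite(coef) else np.nan
    return float(coef * np.sqrt((n - 2 - k_controlled) / (1.0 - coef ** 2)))


def degree_day_quarantine_length(temps: TemperatureSeries, T_min: float,
                                 K_generation: float,
                                 generations: int = 3) -> int:
    """Days for `generations` full degree-day generations to accumulate.

    Walks the hourly series accumulating max(0, T - T_min)/24 day-degrees
    and returns the 1-based day index on which the cumulative total first
    reaches generations * K_generation, or NOT_REACHED if the series ends
    first.  This mirrors the regulatory three-generation quarantine rule.
    """
    if K_generation <= 0:
        raise ValueError("K_generation must be positive")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if temps.missing.any():
        raise ValueError("temperature series has missing hours")
    inc = np.maximum(0.0, temps.values - T_min) / 24.0
    cum = np.cumsum(inc)
    target = generations * K_generation
    hit = np.searchsorted(cum, target)
    if hit >= cum.size:
        return NOT_REACHED
    return int(hit // 24) + 1
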