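"""Stakeholder objectives, scalarization and the penalized comprehensive score.

Four objectives are scored per candidate configuration:

* **equity** (government, minimize): sum of squared deviations of per-center
  accessibility from its demand-weighted mean;
* **efficiency** (government, maximize): mean relative accessibility change
  versus a baseline field;
* **travel cost** (elderly, minimize): demand-weighted travel distance;
* **profit** (investor, maximize): mean monthly margin per open facility.

Objectives are standardized to [0, 1] over a reference population of
solutions (smaller is better for every objective after standardization),
combined by nonnegative weights summing to one, and multiplied by an
adaptive penalty ``r >= 1`` that grows with constraint violation, so every
infeasible solution scores strictly worse than a feasible one with the same
weighted sum.  Affinity, the quantity the immune algorithm maximizes, is the
reciprocal of the penalized score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .accessibility import AccessibilityField
from .core import FacilityConfiguration, ProblemInstance, ViolationReport

__all__ = [
    "ObjectiveVector",
    "ComprehensiveScore",
    "OBJECTIVE_NAMES",
    "MAXIMIZED",
    "equity_objective",
    "efficiency_objective",
    "travel_cost_objective",
    "profit_objective",
    "mean_profit",
    "standardize",
    "comprehensive_objective",
    "equal_weights",
    "adaptive_weights",
]

OBJECTIVE_NAMES = ("equity", "efficiency", "travel_cost", "profit")
#: Mask of objectives that are maximized (flipped during standardization).
MAXIMIZED = np.array([False, True, False, True])

#: Floor on the weighted sum so the affinity 1/F stays finite.
EPS_F = 1e-6


@dataclass(frozen=True)
class ObjectiveVector:
    """Raw values of the four objectives for one configuration."""

    equity: float
    efficiency: float  # nan when no baseline exists
    travel_cost: float
    profit: float
    per_facility_profit: np.ndarray | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.equity, self.efficiency, self.travel_cost, self.profit])


@dataclass(frozen=True)
class ComprehensiveScore:
    """Weighted standardized sum ``f``, penalty ``r``, ``F = f*r``, affinity ``1/F``."""

    f: float
    r: float

    @property
    def F(self) -> float:
        return self.f * self.r

    @property
    def affinity(self) -> float:
        return 1.0 / self.F


def equity_objective(field: AccessibilityField) -> float:
    """Sum of squared deviations from the demand-weighted mean accessibility."""
    if field.values.size == 0:
        raise ValueError("empty accessibility field")
    return float(((field.values - field.weighted_mean) ** 2).sum())


def efficiency_objective(field_after: AccessibilityField, baseline: np.ndarray) -> float:
    """Mean relative accessibility change versus the pre-optimization field."""
    a0 = np.asarray(baseline, dtype=float)
    if a0.shape != field_after.values.shape:
        raise ValueError("baseline length must match the field")
    if np.any(a0 <= 0):
        raise ValueError("baseline accessibility must be strictly positive")
    return float(np.mean((field_after.values - a0) / a0))


def travel_cost_objective(
    instance: ProblemInstance, allocation: np.ndarray, per_capita: bool = False
) -> float:
    """Demand-weighted travel distance sum_ij w_i d_ij Z_ij (meter-persons).

    With ``per_capita=True`` the total is divided by the served demand,
    giving meters per person as reported in evaluation tables.
    """
    z = np.asarray(allocation, dtype=float)
    w = instance.demand
    total = float((w[:, np.newaxis] * instance.distances * z).sum())
    if not per_capita:
        return total
    served = float((w * z.sum(axis=1)).sum())
    return total / served if served > 0 else 0.0


def profit_objective(
    instance: ProblemInstance, config: FacilityConfiguration
) -> tuple[float, np.ndarray]:
    """Mean monthly profit per open facility and the per-facility vector R_j.

    ``R_j = (c0 - c1) * sum_i w_i Z_ij``.  The mean divides by the number of
    open facilities ``p`` (units: currency/month/facility).
    """
    if config.p <= 0:
        raise ValueError("configuration has no open facility")
    w = instance.demand
    served = w @ np.asarray(config.allocation, dtype=float)  # (J,)
    r_j = instance.costs.margin * served
    value = float((r_j * config.open).sum() / config.p)
    return value, r_j


def mean_profit(margin: float, served_demand: float, n_facilities: int) -> float:
    """Mean monthly profit per facility for a given served demand."""
    if n_facilities <= 0:
        raise ValueError("n_facilities must be > 0")
    return margin * served_demand / n_facilities


def standardize(raw: np.ndarray, maximized: np.ndarray = MAXIMIZED) -> np.ndarray:
    """Min-max standardize objective values over a solution population.

    ``raw`` is (K, L): K solutions, L objectives.  Minimization objectives
    map best->0, worst->1; maximization objectives are flipped so smaller is
    uniformly better.  Degenerate objectives (max == min, including K == 1)
    map to 0.5.  Columns that are entirely NaN (objective unavailable, e.g.
    efficiency without a baseline) also map to 0.5 and should receive zero
    weight.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    lo = np.nanmin(raw, axis=0, initial=np.inf)
    hi = np.nanmax(raw, axis=0, initial=-np.inf)
    rng = hi - lo
    out = np.full_like(raw, 0.5)
    ok = np.isfinite(rng) & (rng > 0)
    for col in np.flatnonzero(ok):
        x = (raw[:, col] - lo[col]) / rng[col]
        if maximized[col]:
            x = 1.0 - x
        out[:, col] = np.where(np.isnan(raw[:, col]), 0.5, x)
    return out


def equal_weights(have_baseline: bool = True) -> np.ndarray:
    """Equal objective weights; efficiency drops out without a baseline."""
    w = np.ones(4)
    if not have_baseline:
        w[1] = 0.0
    return w / w.sum()


def adaptive_weights(raw: np.ndarray, have_baseline: bool = True, delta: float = 1e-9) -> np.ndarray:
    """Weights inversely proportional to each objective's observed range.

    Objectives whose population spread is already small get more weight, a
    simple adaptivity rule renormalized each generation.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    rng = np.nanmax(raw, axis=0) - np.nanmin(raw, axis=0)
    rng = np.where(np.isfinite(rng), rng, 0.0)
    scale = np.nanmax(np.abs(raw), axis=0)
    scale = np.where(np.isfinite(scale) & (scale > 0), scale, 1.0)
    w = 1.0 / (rng / scale + delta + 1.0)
    if not have_baseline:
        w[1] = 0.0
    return w / w.sum()


def penalty_multiplier(
    violation: ViolationReport | np.ndarray,
    violation_max: np.ndarray,
    eta: float = 2.0,
) -> float:
    """Adaptive penalty ``r = 1 + mean_g (viol_g / max_g)**eta`` over G=4 families.

    ``violation_max`` holds the largest violation of each family over the
    current population, floored at 1 so feasible populations divide safely.
    """
    mags = violation.magnitudes if isinstance(violation, ViolationReport) else np.asarray(violation, float)
    vmax = np.maximum(np.asarray(violation_max, dtype=float), 1.0)
    return float(1.0 + np.mean((mags / vmax) ** eta))


def comprehensive_objective(
    standardized: np.ndarray,
    weights: np.ndarray,
    violation: ViolationReport | np.ndarray,
    violation_max: np.ndarray | None = None,
    eta: float = 2.0,
) -> ComprehensiveScore:
    """Combine standardized objectives with the adaptive penalty.

    ``f`` is floored at a small positive value so ``F > 0`` and the affinity
    ``1/F`` is always finite.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (4,) or np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be 4 nonnegative values summing to 1")
    std = np.asarray(standardized, dtype=float)
    if std.shape != (4,):
        raise ValueError("standardized vector must have length 4")
    f = max(float(weights @ std), EPS_F)
    if violation_max is None:
        violation_max = np.ones(4)
    r = penalty_multiplier(violation, violation_max, eta=eta)
    return ComprehensiveScore(f=f, r=r)
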