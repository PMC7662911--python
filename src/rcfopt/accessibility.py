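"""Gravity-based spatial accessibility to residential care facilities.

Accessibility of center *i* is a supply-to-demand ratio in which both the
reach of supply and the competition between demands decay with travel
distance raised to ``-beta``::

    A_i = sum_j  v_j * d_ij**(-beta) / sum_i' w_i' * d_i'j**(-beta)   (open j)

Units are beds per person.  The demand-weighted mean of the field equals
``V / W`` (total beds over total demand) exactly — an algebraic identity the
test suite checks to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import FacilityConfiguration, ProblemInstance

__all__ = [
    "AccessibilityField",
    "BetaSensitivityRow",
    "DEFAULT_BETA_GRID",
    "gravity_accessibility",
    "beds_per_100_within_radius",
    "beta_sensitivity",
    "select_beta",
    "sensitivity_table",
]

#: Grid of distance-decay exponents scanned in the sensitivity analysis
#: (literature range, nine scenarios).
DEFAULT_BETA_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.8, 2.401, 0.2), 1))


@dataclass(frozen=True)
class AccessibilityField:
    """Per-center accessibility values and their demand-weighted mean."""

    values: np.ndarray  # (I,), beds per person
    weighted_mean: float
    beta: float


@dataclass(frozen=True)
class BetaSensitivityRow:
    """Descriptive statistics of an accessibility field for one beta."""

    beta: float
    max: float
    min: float
    std: float  # population std, unweighted across centers


def gravity_accessibility(
    instance: ProblemInstance,
    config: FacilityConfiguration,
    beta: float | None = None,
) -> AccessibilityField:
    """Compute the gravity accessibility field of a configuration.

    ``beta`` overrides the instance's distance-decay exponent when given.
    """
    b = instance.beta if beta is None else float(beta)
    open_idx = np.flatnonzero((np.asarray(config.open) > 0) & (np.asarray(config.beds) > 0))
    if open_idx.size == 0:
        raise ValueError("configuration has no open site with beds")
    w = instance.demand
    total = w.sum()
    if total <= 0:
        raise ValueError("total demand is zero")
    dn = instance.distances[:, open_idx] ** (-b)  # (I, n_open)
    demand_pressure = w @ dn  # (n_open,) competition denominators
    v = np.asarray(config.beds, dtype=float)[open_idx]
    values = dn @ (v / demand_pressure)
    wmean = float(w @ values / total)
    return AccessibilityField(values=values, weighted_mean=wmean, beta=b)


def beds_per_100_within_radius(
    instance: ProblemInstance,
    config: FacilityConfiguration,
    radius: float,
    beta: float | None = None,
) -> np.ndarray:
    """Beds available per 100 elderly within an effective service radius.

    The gravity sum is restricted to center/site pairs with ``d_ij <=
    radius``; the competition denominator of each facility is likewise
    restricted to centers within its radius, so catchment semantics are
    symmetric.  Centers with no facility in reach score 0.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    b = instance.beta if beta is None else float(beta)
    open_idx = np.flatnonzero((np.asarray(config.open) > 0) & (np.asarray(config.beds) > 0))
    if open_idx.size == 0:
        raise ValueError("configuration has no open site with beds")
    w = instance.demand
    d = instance.distances[:, open_idx]
    within = d <= radius
    dn = np.where(within, d, np.inf) ** (-b)  # zero outside the radius
    demand_pressure = w @ dn
    v = np.asarray(config.beds, dtype=float)[open_idx]
    # facilities that see no demand within their radius contribute nothing
    ratio = np.divide(v, demand_pressure, out=np.zeros_like(v), where=demand_pressure > 0)
    return 100.0 * (dn @ ratio)


def beta_sensitivity(
    instance: ProblemInstance,
    config: FacilityConfiguration,
    betas: Sequence[float] = DEFAULT_BETA_GRID,
) -> list[BetaSensitivityRow]:
    """Scan the distance-decay exponent and summarize each field."""
    betas = list(betas)
    if not betas:
        raise ValueError("beta grid must be nonempty")
    if any(b <= 0 for b in betas):
        raise ValueError("all betas must be > 0")
    rows = []
    for b in betas:
        field = gravity_accessibility(instance, config, beta=b)
        rows.append(
            BetaSensitivityRow(
                beta=float(b),
                max=float(field.values.max()),
                min=float(field.values.min()),
                std=float(field.values.std()),  # population std
            )
        )
    return rows


def select_beta(rows: Sequence[BetaSensitivityRow]) -> float:
    """Pick the beta whose accessibility field has minimal dispersion.

    Ties resolve to the smaller beta.
    """
    if not rows:
        raise ValueError("no sensitivity rows")
    best = min(rows, key=lambda r: (r.std, r.beta))
    return best.beta


def sensitivity_table(rows: Sequence[BetaSensitivityRow]) -> pd.DataFrame:
    """Sensitivity rows as a DataFrame (columns beta, max, min, std)."""
    return pd.DataFrame(
        [{"beta": r.beta, "max": r.max, "min": r.min, "std": r.std} for r in rows]
    )
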