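"""Domain types and elementary operations for the RCF configuration problem.

The problem is a p-median-style location--allocation model: choose ``p`` open
sites from ``J`` candidates, assign beds to them, and allocate each of ``I``
population centers to its nearest open facility.  The types here are the
immutable problem description (:class:`ProblemInstance`), the decision
variable (:class:`FacilityConfiguration`) and the constraint report
(:class:`ViolationReport`).

All coordinates are planar, in meters; travel distances are strictly
positive because the gravity accessibility kernel ``d**(-beta)`` diverges at
zero distance.  Co-located pairs must be clamped upstream (see
:func:`clamp_distances`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PopulationCenter",
    "CandidateSite",
    "CostParameters",
    "ProblemInstance",
    "FacilityConfiguration",
    "ViolationReport",
    "DEFAULT_BED_CAP",
    "clamp_distances",
    "build_instance",
    "effective_distance",
    "allocate_nearest",
    "check_constraints",
    "size_beds_to_demand",
]

#: Bed-capacity bound for downtown (small/medium) facility classes.
DEFAULT_BED_CAP = 300


@dataclass(frozen=True)
class PopulationCenter:
    """An aggregation point of elderly residents with care demand ``w_i``."""

    id: str
    location: tuple[float, float]
    elderly: int
    demand: int

    def __post_init__(self) -> None:
        if self.elderly < 0:
            raise ValueError(f"center {self.id}: elderly must be >= 0")
        if not (0 <= self.demand <= self.elderly):
            raise ValueError(
                f"center {self.id}: demand must satisfy 0 <= demand <= elderly"
            )


@dataclass(frozen=True)
class CandidateSite:
    """A pre-screened location where a facility may be opened."""

    id: str
    location: tuple[float, float]
    max_beds: int = DEFAULT_BED_CAP

    def __post_init__(self) -> None:
        if self.max_beds <= 0:
            raise ValueError(f"site {self.id}: max_beds must be > 0")


@dataclass(frozen=True)
class CostParameters:
    """Monthly per-bed charge ``c0`` and running cost ``c1`` (currency/bed/month)."""

    charge: float = 2050.0
    cost: float = 1250.0

    def __post_init__(self) -> None:
        if not (self.charge > self.cost > 0):
            raise ValueError("cost parameters must satisfy charge > cost > 0")

    @property
    def margin(self) -> float:
        return self.charge - self.cost


@dataclass(frozen=True)
class ProblemInstance:
    """The complete immutable input of the configuration problem."""

    centers: tuple[PopulationCenter, ...]
    sites: tuple[CandidateSite, ...]
    distances: np.ndarray  # (I, J), meters, strictly positive
    beta: float = 1.0
    costs: CostParameters = field(default_factory=CostParameters)
    baseline_accessibility: np.ndarray | None = None  # A_oi, length I

    @property
    def n_centers(self) -> int:
        return len(self.centers)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def demand(self) -> np.ndarray:
        """Care demand vector ``w_i``."""
        return np.array([c.demand for c in self.centers], dtype=float)

    @property
    def total_demand(self) -> float:
        """Total demand ``W``."""
        return float(self.demand.sum())

    @property
    def max_beds(self) -> np.ndarray:
        return np.array([s.max_beds for s in self.sites], dtype=float)

    @property
    def center_xy(self) -> np.ndarray:
        return np.array([c.location for c in self.centers], dtype=float)

    @property
    def site_xy(self) -> np.ndarray:
        return np.array([s.location for s in self.sites], dtype=float)


@dataclass
class FacilityConfiguration:
    """A candidate decision: open sites ``Y``, beds ``v`` and allocation ``Z``."""

    open: np.ndarray  # (J,) 0/1
    beds: np.ndarray  # (J,) nonnegative, 0 where closed
    allocation: np.ndarray  # (I, J) 0/1
    p: int  # intended facility count, checked against sum(Y)

    @property
    def total_beds(self) -> float:
        """Total beds ``V`` over open sites."""
        return float((self.beds * self.open).sum())

    @property
    def open_sites(self) -> np.ndarray:
        return np.flatnonzero(self.open)


@dataclass(frozen=True)
class ViolationReport:
    """Per-constraint violation magnitudes for the four constraint families.

    ``count``    |sum(Y) - p|                     (facility count)
    ``coverage`` sum_i |sum_j Z_ij - 1|           (every center served once)
    ``linkage``  #{(i,j): Z_ij > Y_j}             (only open sites serve)
    ``capacity`` overflow above max_beds plus the number of open sites
                 with no beds (0 < v_j <= cap must hold for open sites)
    """

    count: float
    coverage: float
    linkage: float
    capacity: float

    @property
    def magnitudes(self) -> np.ndarray:
        return np.array([self.count, self.coverage, self.linkage, self.capacity])

    @property
    def feasible(self) -> bool:
        return bool(np.all(self.magnitudes == 0))


def clamp_distances(distances: np.ndarray, floor: float = 1.0) -> np.ndarray:
    """Clamp distances below ``floor`` (meters) up to it.

    The accessibility kernel is undefined at zero distance, so co-located
    center/site pairs get a small positive separation instead.
    """
    return np.maximum(np.asarray(distances, dtype=float), floor)


def build_instance(
    centers: Sequence[PopulationCenter],
    sites: Sequence[CandidateSite],
    distances: np.ndarray,
    beta: float = 1.0,
    costs: CostParameters | None = None,
    baseline_accessibility: np.ndarray | None = None,
) -> ProblemInstance:
    """Validate inputs and assemble an immutable :class:`ProblemInstance`."""
    if len(centers) < 1 or len(sites) < 1:
        raise ValueError("need at least one center and one site")
    d = np.asarray(distances, dtype=float)
    if d.shape != (len(centers), len(sites)):
        raise ValueError(
            f"distance matrix shape {d.shape} does not match "
            f"({len(centers)}, {len(sites)})"
        )
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite and strictly positive")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    w = sum(c.demand for c in centers)
    if w <= 0:
        raise ValueError("total demand W must be > 0")
    if baseline_accessibility is not None:
        a0 = np.asarray(baseline_accessibility, dtype=float)
        if a0.shape != (len(centers),):
            raise ValueError("baseline accessibility length must equal I")
        if np.any(a0 <= 0):
            raise ValueError("baseline accessibility entries must be > 0")
        baseline_accessibility = a0
    d = d.copy()
    d.setflags(write=False)
    return ProblemInstance(
        centers=tuple(centers),
        sites=tuple(sites),
        distances=d,
        beta=float(beta),
        costs=costs or CostParameters(),
        baseline_accessibility=baseline_accessibility,
    )


def effective_distance(
    shortest_path_distance: float,
    dwell_times: Sequence[float],
    travel_speed: float,
) -> float:
    """Road distance corrected for intersection dwell time.

    In congested networks, waiting time at intersections is a large share of
    door-to-door travel time.  Each dwell (seconds) is converted to an
    equivalent distance at the prevailing travel speed (m/s) and added to the
    shortest-path distance (meters).
    """
    if shortest_path_distance < 0:
        raise ValueError("shortest_path_distance must be >= 0")
    if travel_speed <= 0:
        raise ValueError("travel_speed must be > 0")
    dwell = np.asarray(list(dwell_times), dtype=float)
    if dwell.size and np.any(dwell < 0):
        raise ValueError("dwell times must be >= 0")
    return float(shortest_path_distance + travel_speed * dwell.sum())


def allocate_nearest(
    instance: ProblemInstance, open_sites: Sequence[int] | np.ndarray
) -> np.ndarray:
    """Allocate each center to its nearest open site (ties: lowest site index).

    Returns the binary (I, J) allocation matrix Z.
    """
    open_idx = np.asarray(open_sites, dtype=int)
    if open_idx.size == 0:
        raise ValueError("at least one site must be open")
    open_idx = np.sort(open_idx)
    sub = instance.distances[:, open_idx]  # (I, n_open)
    nearest = open_idx[np.argmin(sub, axis=1)]  # argmin keeps lowest index on ties
    z = np.zeros((instance.n_centers, instance.n_sites), dtype=int)
    z[np.arange(instance.n_centers), nearest] = 1
    return z


def check_constraints(
    instance: ProblemInstance, config: FacilityConfiguration
) -> ViolationReport:
    """Measure violation magnitudes of the four constraint families.

    Never raises on well-shaped input; infeasibility is reported, not
    rejected, because the optimizer scores infeasible antibodies through an
    adaptive penalty.
    """
    y = np.asarray(config.open, dtype=float)
    v = np.asarray(config.beds, dtype=float)
    z = np.asarray(config.allocation, dtype=float)
    count = abs(float(y.sum()) - config.p)
    coverage = float(np.abs(z.sum(axis=1) - 1.0).sum())
    linkage = float(np.count_nonzero(z > y[np.newaxis, :]))
    overflow = float(np.maximum(0.0, v - instance.max_beds).sum())
    empty_open = float(np.count_nonzero((y > 0) & (v <= 0)))
    return ViolationReport(
        count=count, coverage=coverage, linkage=linkage,
        capacity=overflow + empty_open,
    )


def size_beds_to_demand(
    instance: ProblemInstance, open_sites: Sequence[int] | np.ndarray
) -> FacilityConfiguration:
    """Open the given sites, allocate nearest, and size beds to served demand.

    Each facility receives exactly the demand of the centers it serves, so
    total beds always equal total demand W (conservation).
    """
    open_idx = np.unique(np.asarray(open_sites, dtype=int))
    z = allocate_nearest(instance, open_idx)
    w = instance.demand
    beds = (w[:, np.newaxis] * z).sum(axis=0)
    y = np.zeros(instance.n_sites, dtype=int)
    y[open_idx] = 1
    return FacilityConfiguration(open=y, beds=beds, allocation=z, p=open_idx.size)
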