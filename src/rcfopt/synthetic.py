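"""Seeded generator of synthetic district scenarios.

Emulates the inputs of a dense urban elderly-care planning study: clustered
population centers with lognormal elderly counts, a fixed care-demand rate
(2.5 beds per 100 elderly by default), candidate sites several times more
numerous than facilities, and a deliberately imbalanced "current"
configuration — some facilities mislocated to empty corners, total supply
below target, per-facility beds noisily decoupled from assigned demand.
Distances are either Euclidean or shortest paths on a random planar road
graph with intersection-dwell conversion.

Everything is reproducible from the spec seed; no external data is read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, distance_matrix

from .accessibility import gravity_accessibility
from .core import (
    DEFAULT_BED_CAP,
    CandidateSite,
    CostParameters,
    FacilityConfiguration,
    PopulationCenter,
    ProblemInstance,
    allocate_nearest,
    build_instance,
    clamp_distances,
    effective_distance,
)
from .oracle import ExhaustiveResult, exhaustive_optimum
from ._rng import substream

__all__ = ["ScenarioSpec", "generate_scenario", "micro_instance", "oracle_instance"]


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic district."""

    seed: int = 0
    n_centers: int = 60
    n_sites: int = 120
    n_existing: int = 12
    extent: float = 6000.0  # square district side, meters
    n_clusters: int = 5
    cluster_spread: float = 400.0  # std of center scatter around a cluster
    elderly_mu: float = 7.2  # lognormal log-mean of per-center elderly
    elderly_sigma: float = 0.5
    demand_rate: float = 0.025  # beds target share of the elderly
    distance_mode: str = "euclidean"  # or "road-graph"
    speed_range: tuple[float, float] = (3.0, 8.0)  # m/s, rush-hour road speeds
    dwell_range: tuple[float, float] = (0.0, 60.0)  # s per intersection
    frac_mislocated: float = 0.25  # share of existing facilities in bad spots
    supply_ratio: float = 0.8  # existing beds total vs demand W
    supply_noise: float = 0.5  # lognormal sigma of per-facility bed noise
    bed_cap: int = DEFAULT_BED_CAP
    beta: float = 1.0
    # intra-zonal distance convention: door-to-door travel between a zone
    # centroid and a facility is never shorter than about half the typical
    # center spacing, and the gravity kernel diverges as d -> 0
    distance_floor: float = 150.0

    def __post_init__(self) -> None:
        if self.n_centers < 1 or self.n_sites < 1:
            raise ValueError("need at least one center and one site")
        if not (0 < self.demand_rate <= 1):
            raise ValueError("demand_rate must lie in (0, 1]")
        if self.extent <= 0:
            raise ValueError("extent must be > 0")
        if self.n_existing > self.n_sites:
            raise ValueError("more existing facilities than candidate sites")
        if self.distance_mode not in ("euclidean", "road-graph"):
            raise ValueError(f"unknown distance mode {self.distance_mode!r}")


def _road_graph_distances(
    center_xy: np.ndarray, site_xy: np.ndarray, spec: ScenarioSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shortest-path distances on a thinned Delaunay road graph.

    Each edge carries a rush-hour speed and an intersection dwell time; the
    edge weight is the dwell-corrected effective distance.
    """
    import networkx as nx

    points = np.vstack([center_xy, site_xy])
    tri = Delaunay(points)
    g = nx.Graph()
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            u, v = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(u, v), max(u, v)))
    for u, v in sorted(edges):
        if rng.uniform() < 0.15:  # thin the mesh so routes detour
            continue
        length = float(np.linalg.norm(points[u] - points[v]))
        speed = rng.uniform(*spec.speed_range)
        dwell = rng.uniform(*spec.dwell_range)
        g.add_edge(u, v, weight=effective_distance(length, [dwell], speed))
    # thinning may disconnect: re-add the skipped edges touching small parts
    if not nx.is_connected(g) or g.number_of_nodes() < len(points):
        for u, v in sorted(edges):
            if not g.has_edge(u, v):
                length = float(np.linalg.norm(points[u] - points[v]))
                g.add_edge(u, v, weight=effective_distance(length, [30.0], 5.0))
    n_centers = center_xy.shape[0]
    d = np.empty((n_centers, site_xy.shape[0]))
    for i in range(n_centers):
        lengths = nx.single_source_dijkstra_path_length(g, i, weight="weight")
        for j in range(site_xy.shape[0]):
            d[i, j] = lengths[n_centers + j]
    return d


def generate_scenario(
    spec: ScenarioSpec,
) -> tuple[ProblemInstance, FacilityConfiguration]:
    """Generate a district instance plus its imbalanced current configuration."""
    rng_geo = np.random.default_rng(substream(spec.seed, "generator-geometry"))
    rng_pop = np.random.default_rng(substream(spec.seed, "generator-population"))
    rng_fac = np.random.default_rng(substream(spec.seed, "generator-facilities"))

    lo, hi = 0.15 * spec.extent, 0.85 * spec.extent
    clusters = rng_geo.uniform(lo, hi, size=(spec.n_clusters, 2))
    cluster_of = rng_geo.integers(spec.n_clusters, size=spec.n_centers)
    center_xy = np.clip(
        clusters[cluster_of] + rng_geo.normal(0, spec.cluster_spread, size=(spec.n_centers, 2)),
        0.0, spec.extent,
    )

    elderly = np.maximum(
        rng_pop.lognormal(spec.elderly_mu, spec.elderly_sigma, size=spec.n_centers), 40
    ).round().astype(int)
    demand = np.maximum(np.round(spec.demand_rate * elderly), 1).astype(int)

    # candidate sites: most track the population clusters, the rest scatter
    n_near = int(0.7 * spec.n_sites)
    near_cluster = rng_geo.integers(spec.n_clusters, size=n_near)
    near = clusters[near_cluster] + rng_geo.normal(
        0, 1.5 * spec.cluster_spread, size=(n_near, 2)
    )
    far = rng_geo.uniform(0, spec.extent, size=(spec.n_sites - n_near, 2))
    site_xy = np.clip(np.vstack([near, far]), 0.0, spec.extent)

    centers = [
        PopulationCenter(f"c{i:03d}", tuple(center_xy[i]), int(elderly[i]), int(demand[i]))
        for i in range(spec.n_centers)
    ]
    sites = [
        CandidateSite(f"s{j:03d}", tuple(site_xy[j]), spec.bed_cap)
        for j in range(spec.n_sites)
    ]

    if spec.distance_mode == "road-graph":
        d = _road_graph_distances(center_xy, site_xy, spec, rng_geo)
    else:
        d = distance_matrix(center_xy, site_xy)
    d = clamp_distances(d, spec.distance_floor)

    instance = build_instance(centers, sites, d, beta=spec.beta, costs=CostParameters())

    # existing facilities: planted defects.  A few sit in demand-empty
    # corners (mislocated); the rest crowd the densest clusters, the way
    # facilities accrete historically in an old urban core, leaving the
    # remaining clusters undersupplied.
    n_mis = int(round(spec.frac_mislocated * spec.n_existing))
    demand_pull = demand @ (1.0 / d)  # how much demand each site attracts
    order_attractive = np.argsort(-demand_pull, kind="stable")
    order_remote = np.argsort(demand_pull, kind="stable")
    existing = list(order_remote[:n_mis])  # mislocated: demand-empty spots
    cluster_demand = np.bincount(cluster_of, weights=demand, minlength=spec.n_clusters)
    core = set(np.argsort(-cluster_demand)[: max(1, spec.n_clusters // 2)].tolist())
    site_cluster = np.argmin(
        ((site_xy[:, np.newaxis, :] - clusters[np.newaxis, :, :]) ** 2).sum(axis=2),
        axis=1,
    )
    for j in order_attractive:  # core clusters first, then anywhere
        if len(existing) >= spec.n_existing:
            break
        if int(site_cluster[j]) in core and j not in existing:
            existing.append(int(j))
    for j in order_attractive:
        if len(existing) >= spec.n_existing:
            break
        if j not in existing:
            existing.append(int(j))
    existing_idx = np.sort(np.array(existing[: spec.n_existing], dtype=int))

    z = allocate_nearest(instance, existing_idx)
    # facility sizes are drawn independently of the demand they face, so
    # some facilities are oversupplied and others undersupplied
    raw_beds = rng_fac.lognormal(0.0, spec.supply_noise, size=existing_idx.size)
    scale = spec.supply_ratio * instance.total_demand / raw_beds.sum()
    beds_open = np.clip(np.round(raw_beds * scale), 5, spec.bed_cap)

    beds = np.zeros(spec.n_sites)
    beds[existing_idx] = beds_open
    y = np.zeros(spec.n_sites, dtype=int)
    y[existing_idx] = 1
    config = FacilityConfiguration(
        open=y, beds=beds, allocation=z, p=int(existing_idx.size)
    )
    baseline = gravity_accessibility(instance, config).values
    instance = ProblemInstance(
        centers=instance.centers,
        sites=instance.sites,
        distances=instance.distances,
        beta=instance.beta,
        costs=instance.costs,
        baseline_accessibility=baseline,
    )
    return instance, config


def micro_instance() -> ProblemInstance:
    """The fixed 2x2 worked-example instance used throughout the docs.

    Two centers (demand 10 and 20), two sites, distances
    ``[[1000, 2000], [2000, 1000]]`` meters, beta 1, bed margin 800.
    """
    centers = [
        PopulationCenter("c1", (0.0, 0.0), elderly=400, demand=10),
        PopulationCenter("c2", (3000.0, 0.0), elderly=800, demand=20),
    ]
    sites = [
        CandidateSite("s1", (1000.0, 0.0)),
        CandidateSite("s2", (2000.0, 0.0)),
    ]
    d = np.array([[1000.0, 2000.0], [2000.0, 1000.0]])
    return build_instance(centers, sites, d, beta=1.0)


def oracle_instance(
    seed: int = 0,
    n_centers: int = 15,
    n_sites: int = 12,
    p: int = 3,
) -> tuple[ProblemInstance, int, ExhaustiveResult]:
    """A small random instance plus its exhaustively enumerated optimum.

    Used as ground truth when checking that the metaheuristics find the
    true best subset.  Keeps C(J, p) small enough to enumerate.
    """
    spec = ScenarioSpec(
        seed=seed,
        n_centers=n_centers,
        n_sites=n_sites,
        n_existing=min(3, n_sites),
        extent=3000.0,
        n_clusters=3,
        elderly_mu=6.6,
    )
    instance, _config = generate_scenario(spec)
    optimum = exhaustive_optimum(instance, p)
    return instance, p, optimum
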