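"""Applied planning pipeline: assess, optimize in three steps, evaluate.

The pipeline mirrors how a planner uses the optimizer on a district:

* **assessment** — measure how far the existing configuration falls short of
  a per-100-elderly bed target, which facilities are over- or undersupplied
  and which sit far from any optimal location;
* **three-step optimization** — (1) drop the few facilities whose location
  is unreasonable and resize the rest up to the bed cap, (2) choose how
  many new facilities to add for the demand left unmet, by sweeping the
  count and picking the lowest comprehensive objective, (3) size each new
  facility to the demand of the centers it serves;
* **evaluation** — before/after comparison of equity, Gini coefficient,
  travel cost, profit, nearest-facility distances and radius-restricted bed
  supply.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .accessibility import beds_per_100_within_radius, gravity_accessibility
from .core import (
    DEFAULT_BED_CAP,
    FacilityConfiguration,
    ProblemInstance,
    allocate_nearest,
    build_instance,
)
from .mia import MIAParams, run_mia
from .objectives import equity_objective, profit_objective, travel_cost_objective
from .scoring import ScalarizationContext, Scorer

__all__ = [
    "AssessmentReport",
    "PlanResult",
    "EvaluationReport",
    "assess_current",
    "identify_unreasonable",
    "adjust_scales",
    "min_new_facilities",
    "residual_instance",
    "sweep_new_count",
    "select_best_count",
    "finalize_new_beds",
    "three_step_plan",
    "gini_coefficient",
    "evaluation_report",
]

#: Default effective service radius (meters): one hour of travel converted
#: to distance for the synthetic district scale.
DEFAULT_RADIUS = 3000.0


@dataclass(frozen=True)
class AssessmentReport:
    """Rationality assessment of an existing configuration."""

    beds_per_100: np.ndarray  # per center, within the service radius
    share_below_target: float  # fraction of centers under the per-100 goal
    facility_assigned_demand: np.ndarray  # per open facility (nearest rule)
    facility_gap: np.ndarray  # assigned demand minus beds (+ under, - over)
    facility_distance_to_optimal: np.ndarray | None  # meters, per open facility
    target_beds: float  # target_rate * total elderly
    total_bed_deficit: float  # max(0, target_beds - existing beds)


@dataclass
class PlanResult:
    """Outcome of the three-step optimization."""

    flagged: np.ndarray  # site indices of facilities judged mislocated
    retained: np.ndarray  # site indices kept open
    adjusted_beds: np.ndarray  # beds per retained facility (same order)
    unmet_per_center: np.ndarray  # demand left unmet after step 1
    unmet_total: float
    p_star: int  # chosen number of new facilities
    sweep_table: pd.DataFrame | None  # per-count comprehensive values
    new_sites: np.ndarray  # site indices of the added facilities
    new_beds: np.ndarray  # beds per added facility
    final_config: FacilityConfiguration


@dataclass(frozen=True)
class EvaluationReport:
    """Before/after metric table plus the accessibility-ratio share."""

    table: pd.DataFrame  # metric, before, after, change_pct
    ratio_share_after: float  # centers with A_i / mean(A) in [0.9, 1.1]
    efficiency_pct: float  # mean relative accessibility change x 100

    def __getitem__(self, metric: str) -> pd.Series:
        return self.table.set_index("metric").loc[metric]


def assess_current(
    instance: ProblemInstance,
    existing: FacilityConfiguration,
    target_rate: float = 0.025,
    radius: float = DEFAULT_RADIUS,
    per100_target: float = 2.5,
    beta: float | None = 1.8,
    optimal_sites: np.ndarray | None = None,
) -> AssessmentReport:
    """Assess quantity, scale and location rationality of an existing setup.

    ``beta`` defaults to 1.8, the decay found to match observed travel
    behaviour for existing facilities; pass ``None`` to use the instance's
    exponent.  ``optimal_sites`` (site indices of an optimized
    configuration) enables the per-facility distance-to-optimal field.
    """
    per100 = beds_per_100_within_radius(instance, existing, radius, beta=beta)
    elderly = np.array([c.elderly for c in instance.centers], dtype=float)
    target_beds = target_rate * elderly.sum()
    open_idx = existing.open_sites
    z = allocate_nearest(instance, open_idx)
    assigned = (instance.demand[:, np.newaxis] * z).sum(axis=0)[open_idx]
    beds_open = np.asarray(existing.beds, dtype=float)[open_idx]
    dist_opt = None
    if optimal_sites is not None:
        xy = instance.site_xy
        diffs = xy[open_idx][:, np.newaxis, :] - xy[np.asarray(optimal_sites, int)][np.newaxis, :, :]
        dist_opt = np.sqrt((diffs**2).sum(axis=2)).min(axis=1)
    return AssessmentReport(
        beds_per_100=per100,
        share_below_target=float(np.mean(per100 < per100_target)),
        facility_assigned_demand=assigned,
        facility_gap=assigned - beds_open,
        facility_distance_to_optimal=dist_opt,
        target_beds=float(target_beds),
        total_bed_deficit=float(max(0.0, target_beds - existing.total_beds)),
    )


def identify_unreasonable(
    instance: ProblemInstance,
    existing: FacilityConfiguration,
    mia_params: MIAParams | None = None,
    distance_tolerance: float = 500.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Flag existing facilities whose location is unreasonable.

    A facility is flagged when (a) it lies farther than the tolerance from
    every site of an optimized configuration with the same facility count,
    and (b) it is redundant: every center it serves has another existing
    facility at most ``distance_tolerance`` farther away, so closing it
    leaves no center stranded.  Returns (flagged site indices, optimal site
    indices from the reference run).
    """
    open_idx = existing.open_sites
    if mia_params is None:
        mia_params = MIAParams(p=open_idx.size, seed=0)
    result = run_mia(instance, mia_params)
    optimal = result.best_encoding
    xy = instance.site_xy
    d_opt = np.sqrt(
        ((xy[open_idx][:, np.newaxis, :] - xy[optimal][np.newaxis, :, :]) ** 2).sum(axis=2)
    ).min(axis=1)
    z = allocate_nearest(instance, open_idx)
    flagged = []
    for pos, j in enumerate(open_idx):
        if d_opt[pos] <= distance_tolerance:
            continue
        served = np.flatnonzero(z[:, j] > 0)
        if served.size == 0:
            flagged.append(j)  # serves nobody: trivially redundant
            continue
        others = open_idx[open_idx != j]
        if others.size == 0:
            continue
        d_here = instance.distances[served, j]
        d_other = instance.distances[np.ix_(served, others)].min(axis=1)
        if np.all(d_other <= d_here + distance_tolerance):
            flagged.append(j)
    return np.array(flagged, dtype=int), optimal


def adjust_scales(
    instance: ProblemInstance,
    retained: np.ndarray,
    cap: float = DEFAULT_BED_CAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Resize retained facilities to their assigned demand, capped.

    Centers are allocated to their nearest retained facility; each facility
    gets ``min(assigned demand, cap)`` beds, filling its nearest centers
    first, so the overflow of a crowded facility is attributed to its most
    distant centers.  Returns (beds per retained facility, unmet demand per
    center).
    """
    retained = np.asarray(retained, dtype=int)
    if retained.size == 0:
        raise ValueError("no retained facilities")
    z = allocate_nearest(instance, retained)
    w = instance.demand
    beds = np.zeros(retained.size)
    unmet = np.zeros(instance.n_centers)
    for pos, j in enumerate(retained):
        served = np.flatnonzero(z[:, j] > 0)
        order = served[np.argsort(instance.distances[served, j], kind="stable")]
        remaining = float(cap)
        for i in order:
            take = min(w[i], remaining)
            remaining -= take
            unmet[i] = w[i] - take
        beds[pos] = min(w[order].sum(), cap)
    return beds, unmet


def min_new_facilities(unmet_demand: float, cap: float = DEFAULT_BED_CAP) -> int:
    """Minimum facility count able to host the unmet demand: ceil(unmet/cap)."""
    if cap <= 0:
        raise ValueError("cap must be > 0")
    return int(np.ceil(unmet_demand / cap))


def residual_instance(
    instance: ProblemInstance,
    unmet: np.ndarray,
    exclude_sites: np.ndarray | None = None,
) -> tuple[ProblemInstance, np.ndarray, np.ndarray]:
    """Sub-instance of the centers with unmet demand over the free sites.

    Returns (residual instance, original center indices, original site
    indices) so solutions map back to the full district.
    """
    unmet = np.asarray(unmet, dtype=float)
    center_idx = np.flatnonzero(unmet > 0)
    if center_idx.size == 0:
        raise ValueError("no unmet demand")
    site_mask = np.ones(instance.n_sites, dtype=bool)
    if exclude_sites is not None:
        site_mask[np.asarray(exclude_sites, dtype=int)] = False
    site_idx = np.flatnonzero(site_mask)
    centers = [
        replace(instance.centers[i], demand=int(round(unmet[i])))
        for i in center_idx
    ]
    sites = [instance.sites[j] for j in site_idx]
    sub = build_instance(
        centers,
        sites,
        instance.distances[np.ix_(center_idx, site_idx)],
        beta=instance.beta,
        costs=instance.costs,
    )
    return sub, center_idx, site_idx


def select_best_count(counts, values) -> int:
    """The facility count with the lowest comprehensive objective value."""
    counts = list(counts)
    values = np.asarray(values, dtype=float)
    if len(counts) == 0 or values.size != len(counts):
        raise ValueError("counts and values must be nonempty and matched")
    return int(counts[int(np.argmin(values))])


def sweep_new_count(
    residual: ProblemInstance,
    p_range,
    mia_params: MIAParams | None = None,
) -> tuple[pd.DataFrame, int, dict[int, np.ndarray]]:
    """Run the optimizer per candidate facility count and pick the best.

    Comprehensive values across counts are made comparable by standardizing
    the best raw objective vectors over the whole sweep in one frame.
    Returns (table with columns p/F, chosen count, best encoding per count).
    """
    p_values = list(p_range)
    if not p_values:
        raise ValueError("empty facility-count range")
    scorer = Scorer(residual)
    best_enc: dict[int, np.ndarray] = {}
    raws, viols = [], []
    for p in p_values:
        params = (
            replace(mia_params, p=p) if mia_params is not None else MIAParams(p=p, seed=0)
        )
        result = run_mia(residual, params, scorer=scorer)
        best_enc[p] = result.best_encoding
        raw, viol = scorer.evaluate(result.best_encoding[np.newaxis, :])
        raws.append(raw[0])
        viols.append(viol[0])
    raw_all = np.vstack(raws)
    viol_all = np.vstack(viols)
    ctx = ScalarizationContext.from_population(
        raw_all, have_baseline=scorer.have_baseline
    )
    scores = ctx.score(raw_all, viol_all)
    feasible = viol_all.sum(axis=1) == 0
    table = pd.DataFrame({"p": p_values, "F": scores, "feasible": feasible})
    # the chosen count must admit a feasible configuration (cap respected)
    if feasible.any():
        pool = [(p, s) for p, s, ok in zip(p_values, scores, feasible) if ok]
        p_star = select_best_count([p for p, _ in pool], [s for _, s in pool])
    else:
        p_star = select_best_count(p_values, scores)
    return table, p_star, best_enc


def finalize_new_beds(
    residual: ProblemInstance,
    chosen_sites: np.ndarray,
    cap: float = DEFAULT_BED_CAP,
) -> FacilityConfiguration:
    """Size each new facility to the unmet demand of its catchment.

    Beds follow the nearest-allocation demand sums; a configuration whose
    facility would exceed the cap is rejected as infeasible.
    """
    scorer = Scorer(residual)
    config = scorer.config(np.asarray(chosen_sites, dtype=int))
    open_beds = config.beds[config.open_sites]
    if np.any(open_beds > cap):
        raise ValueError(
            f"bed cap {cap} exceeded by demand-sized facility "
            f"(max {open_beds.max():.0f}); add more facilities"
        )
    return config


def rebalance_beds(
    instance: ProblemInstance,
    open_sites: np.ndarray,
    cap: float = DEFAULT_BED_CAP,
) -> np.ndarray:
    """Size every open facility to its capacitated nearest catchment.

    Centers are assigned to their nearest open facility with free capacity
    (closest-served-first), so bed counts match the demand each facility
    actually faces in the final site layout.  Requires total capacity
    >= total demand; returns the load per open site.
    """
    open_sites = np.asarray(open_sites, dtype=int)
    caps = np.minimum(float(cap), instance.max_beds[open_sites])
    if caps.sum() < instance.total_demand:
        raise ValueError("total capacity below total demand; add facilities")
    d = instance.distances[:, open_sites]
    w = instance.demand
    remaining = caps.copy()
    load = np.zeros(open_sites.size)
    for i in np.argsort(d.min(axis=1), kind="stable"):
        need = w[i]
        for j in np.argsort(d[i], kind="stable"):
            take = min(need, remaining[j])
            load[j] += take
            remaining[j] -= take
            need -= take
            if need <= 0:
                break
    return load


def three_step_plan(
    instance: ProblemInstance,
    existing: FacilityConfiguration,
    cap: float = DEFAULT_BED_CAP,
    mia_params: MIAParams | None = None,
    distance_tolerance: float = 500.0,
    extra_counts: int = 3,
) -> PlanResult:
    """Run the full three-step optimization of an existing configuration."""
    flagged, _optimal = identify_unreasonable(
        instance, existing, mia_params=mia_params, distance_tolerance=distance_tolerance
    )
    open_idx = existing.open_sites
    retained = np.setdiff1d(open_idx, flagged)
    if retained.size == 0:
        retained = open_idx  # never drop everything
        flagged = np.array([], dtype=int)
    beds_adj, unmet = adjust_scales(instance, retained, cap)
    unmet_total = float(unmet.sum())

    sweep_table = None
    p_star = 0
    new_sites = np.array([], dtype=int)
    new_beds = np.array([])
    if unmet_total > 0:
        sub, center_idx, site_idx = residual_instance(instance, unmet, exclude_sites=open_idx)
        n_min = max(1, min_new_facilities(unmet_total, cap))
        sweep_params = (
            replace(mia_params, p=n_min) if mia_params is not None else None
        )
        # extend the count range until a feasible (cap-respecting) count exists
        n_max = min(n_min + extra_counts, sub.n_sites)
        while True:
            sweep_table, p_star, best_enc = sweep_new_count(
                sub, range(n_min, n_max + 1), sweep_params
            )
            if bool(sweep_table["feasible"].any()) or n_max >= sub.n_sites:
                break
            n_max = min(n_max + extra_counts + 1, sub.n_sites)
        chosen_local = best_enc[p_star]
        new_config = finalize_new_beds(sub, chosen_local, cap)
        new_sites = site_idx[chosen_local]
        new_beds = new_config.beds[new_config.open_sites]

    # assemble the final district-level configuration: with the new sites
    # open, each retained facility's catchment changes, so all open
    # facilities are re-sized to their capacitated nearest catchments
    # (the demand-oriented sizing rule applied to the final layout)
    all_open = np.concatenate([retained, new_sites])
    load = rebalance_beds(instance, all_open, cap)
    keep = all_open[load > 0]
    beds = np.zeros(instance.n_sites)
    beds[all_open] = load
    y = np.zeros(instance.n_sites, dtype=int)
    y[keep] = 1
    z = allocate_nearest(instance, keep)
    final = FacilityConfiguration(
        open=y, beds=beds * y, allocation=z, p=int(keep.size)
    )
    return PlanResult(
        flagged=flagged,
        retained=retained,
        adjusted_beds=beds_adj,
        unmet_per_center=unmet,
        unmet_total=unmet_total,
        p_star=p_star,
        sweep_table=sweep_table,
        new_sites=new_sites,
        new_beds=np.asarray(new_beds, dtype=float),
        final_config=final,
    )


def gini_coefficient(values: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted Gini coefficient via the Lorenz-curve trapezoid rule.

    ``values`` are per-capita resources (here: accessibility) and
    ``weights`` the population shares; 0 means perfectly equal access.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("values must be nonnegative")
    if not np.any(x > 0):
        raise ValueError("values must not all be zero")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    order = np.argsort(x, kind="stable")
    x, w = x[order], w[order]
    cw = np.concatenate([[0.0], np.cumsum(w)]) / w.sum()
    cv = np.concatenate([[0.0], np.cumsum(x * w)]) / (x * w).sum()
    return float(1.0 - np.sum(np.diff(cw) * (cv[1:] + cv[:-1])))


def _nearest_open_distance(instance: ProblemInstance, config: FacilityConfiguration) -> np.ndarray:
    return instance.distances[:, config.open_sites].min(axis=1)


def evaluation_report(
    instance: ProblemInstance,
    before: FacilityConfiguration,
    after: FacilityConfiguration,
    radius: float = DEFAULT_RADIUS,
    beta: float | None = None,
) -> EvaluationReport:
    """Before/after comparison of the configuration quality metrics.

    Relative changes are plain relative differences on the printed scale:
    ``(before - after)/before * 100`` for minimized metrics and
    ``(after - before)/before * 100`` for maximized ones.
    """
    w = instance.demand
    rows = []

    def metric(name, val_before, val_after, maximized):
        if maximized:
            change = (val_after - val_before) / val_before * 100 if val_before else np.nan
        else:
            change = (val_before - val_after) / val_before * 100 if val_before else np.nan
        rows.append(
            {"metric": name, "before": val_before, "after": val_after, "change_pct": change}
        )

    f_before = gravity_accessibility(instance, before, beta=beta)
    f_after = gravity_accessibility(instance, after, beta=beta)
    metric("equity", equity_objective(f_before), equity_objective(f_after), False)
    metric(
        "gini",
        gini_coefficient(f_before.values, w),
        gini_coefficient(f_after.values, w),
        False,
    )
    metric(
        "travel_cost_per_capita",
        travel_cost_objective(instance, before.allocation, per_capita=True),
        travel_cost_objective(instance, after.allocation, per_capita=True),
        False,
    )
    metric(
        "mean_profit",
        profit_objective(instance, before)[0],
        profit_objective(instance, after)[0],
        True,
    )
    d_before = _nearest_open_distance(instance, before)
    d_after = _nearest_open_distance(instance, after)
    metric("max_nearest_distance", float(d_before.max()), float(d_after.max()), False)
    metric("mean_nearest_distance", float(d_before.mean()), float(d_after.mean()), False)
    metric(
        "mean_beds_per_100_within_radius",
        float(beds_per_100_within_radius(instance, before, radius, beta=beta).mean()),
        float(beds_per_100_within_radius(instance, after, radius, beta=beta).mean()),
        True,
    )
    ratio = f_after.values / f_after.values.mean()
    share = float(np.mean((ratio >= 0.9) & (ratio <= 1.1)))
    efficiency_pct = float(np.mean((f_after.values - f_before.values) / f_before.values) * 100)
    return EvaluationReport(
        table=pd.DataFrame(rows),
        ratio_share_after=share,
        efficiency_pct=efficiency_pct,
    )
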