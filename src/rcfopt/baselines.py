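"""Textbook baseline metaheuristics over the same encoding and scoring.

A genetic algorithm (tournament selection, one-point crossover with
duplicate repair, swap mutation), global-best particle swarm optimization
on the relaxed real index vector with rounding repair, and a standard
immune algorithm (fixed selection threshold, exchange mutation only — none
of the MIA modifications).  All consume the identical scoring callbacks as
the MIA, so a comparison isolates the search strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ProblemInstance
from .mia import (
    MIAParams,
    MIAResult,
    clonal_select,
    concentration,
    initialize_population,
    repair_encoding,
    run_mia,
)
from .objectives import equal_weights
from .scoring import EvaluationArchive, ScalarizationContext, Scorer, reference_context
from ._rng import substream

__all__ = ["BaselineParams", "run_baseline", "compare_algorithms", "relative_difference"]


@dataclass
class BaselineParams:
    """Settings for one baseline algorithm run."""

    algorithm: str  # "ga" | "pso" | "ia"
    p: int
    pop_size: int = 40
    iterations: int = 200
    crossover_rate: float = 0.8  # GA
    mutation_rate: float = 0.1  # GA / IA exchange mutation
    inertia: float = 0.7  # PSO
    cognitive: float = 1.5  # PSO
    social: float = 1.5  # PSO
    a_sel: float = 0.3  # IA fixed threshold
    eta: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("ga", "pso", "ia"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.pop_size < 2:
            raise ValueError("population size must be >= 2")
        for rate in (self.crossover_rate, self.mutation_rate):
            if not (0 <= rate <= 1):
                raise ValueError("rates must lie in [0, 1]")


def _mia_shim(params: BaselineParams) -> MIAParams:
    return MIAParams(
        p=params.p, pop_size=params.pop_size, t_max=params.iterations,
        a_sel=params.a_sel, eta=params.eta, seed=params.seed,
    )


def _trace_row(t, best_F, f_pop, viol):
    return {
        "t": t,
        "best_F": best_F,
        "mean_F": float(np.mean(f_pop)),
        "feasible_fraction": float(np.mean(viol.sum(axis=1) == 0)),
    }


def _finalize(scorer, archive, rows, ref) -> MIAResult:
    # incumbent = archive re-ranked in the canonical frame
    best_enc, best_F, best_raw = archive.best_in(ref)
    return MIAResult(
        best_encoding=best_enc,
        best_F=float(best_F),
        best_config=scorer.config(best_enc),
        trace=pd.DataFrame(rows),
        context=ref,
        best_raw=best_raw,
    )


def _run_ga(instance: ProblemInstance, params: BaselineParams, scorer: Scorer) -> MIAResult:
    rng = np.random.default_rng(substream(params.seed, "ga"))
    shim = _mia_shim(params)
    enc = initialize_population(instance, shim, rng)
    raw, viol = scorer.evaluate(enc)
    archive = EvaluationArchive()
    archive.update(enc, raw, viol)
    ref = reference_context(scorer, params.p, eta=params.eta)
    f = ref.score(raw, viol)
    best = int(np.argmin(f))
    best_enc, best_F, best_raw = enc[best].copy(), float(f[best]), raw[best].copy()
    rows = []
    n, p = enc.shape
    for t in range(1, params.iterations + 1):
        children = np.empty_like(enc)
        for k in range(n):
            # tournament selection, k=2
            i1, i2 = rng.integers(n, size=2)
            a = i1 if f[i1] <= f[i2] else i2
            i1, i2 = rng.integers(n, size=2)
            b = i1 if f[i1] <= f[i2] else i2
            child = enc[a].copy()
            if rng.uniform() < params.crossover_rate and p > 1:
                cut = rng.integers(1, p)
                child = repair_encoding(
                    np.concatenate([enc[a][:cut], enc[b][cut:]]), instance.n_sites
                )
            if rng.uniform() < params.mutation_rate:
                pos = rng.integers(p)
                unused = np.setdiff1d(np.arange(instance.n_sites), child)
                if unused.size:
                    child = child.copy()
                    child[pos] = rng.choice(unused)
                    child = np.sort(child)
            children[k] = child
        children[0] = best_enc  # elitism
        enc = children
        raw, viol = scorer.evaluate(enc)
        archive.update(enc, raw, viol)
        f = ref.score(raw, viol)
        gbest = int(np.argmin(f))
        if f[gbest] < best_F:
            best_enc, best_F, best_raw = enc[gbest].copy(), float(f[gbest]), raw[gbest].copy()
        rows.append(_trace_row(t, best_F, f, viol))
    return _finalize(scorer, archive, rows, ref)


def _run_pso(instance: ProblemInstance, params: BaselineParams, scorer: Scorer) -> MIAResult:
    rng = np.random.default_rng(substream(params.seed, "pso"))
    shim = _mia_shim(params)
    enc = initialize_population(instance, shim, rng)
    n, p = enc.shape
    pos = enc.astype(float) + rng.uniform(-0.4, 0.4, size=enc.shape)
    vel = rng.uniform(-1.0, 1.0, size=enc.shape)
    raw, viol = scorer.evaluate(enc)
    archive = EvaluationArchive()
    archive.update(enc, raw, viol)
    ref = reference_context(scorer, params.p, eta=params.eta)
    f = ref.score(raw, viol)
    pbest_pos, pbest_f = pos.copy(), f.copy()
    g = int(np.argmin(f))
    best_enc, best_F, best_raw = enc[g].copy(), float(f[g]), raw[g].copy()
    gbest_pos = pos[g].copy()
    rows = []
    vmax = instance.n_sites / 4.0
    for t in range(1, params.iterations + 1):
        r1 = rng.uniform(size=pos.shape)
        r2 = rng.uniform(size=pos.shape)
        vel = (
            params.inertia * vel
            + params.cognitive * r1 * (pbest_pos - pos)
            + params.social * r2 * (gbest_pos - pos)
        )
        vel = np.clip(vel, -vmax, vmax)
        pos = np.clip(pos + vel, 0, instance.n_sites - 1)
        enc = np.array([repair_encoding(row, instance.n_sites) for row in pos])
        raw, viol = scorer.evaluate(enc)
        archive.update(enc, raw, viol)
        f = ref.score(raw, viol)
        improved = f < pbest_f
        pbest_pos[improved] = pos[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < best_F:
            best_F = float(pbest_f[g])
            gbest_pos = pbest_pos[g].copy()
            best_enc = repair_encoding(gbest_pos, instance.n_sites)
            braw, bviol = scorer.evaluate(best_enc[np.newaxis, :])
            archive.update(best_enc[np.newaxis, :], braw, bviol)
            best_raw = braw[0]
        rows.append(_trace_row(t, best_F, f, viol))
    return _finalize(scorer, archive, rows, ref)


def _run_ia(instance: ProblemInstance, params: BaselineParams, scorer: Scorer) -> MIAResult:
    """Standard immune algorithm: fixed threshold, exchange mutation only."""
    rng = np.random.default_rng(substream(params.seed, "ia"))
    shim = _mia_shim(params)
    enc = initialize_population(instance, shim, rng)
    raw, viol = scorer.evaluate(enc)
    archive = EvaluationArchive()
    archive.update(enc, raw, viol)
    ref = reference_context(scorer, params.p, eta=params.eta)
    f = ref.score(raw, viol)
    best = int(np.argmin(f))
    best_enc, best_F, best_raw = enc[best].copy(), float(f[best]), raw[best].copy()
    rows = []
    n, p = enc.shape
    # a fixed-threshold params shim: t pinned below t_ave so sigma stays a_sel
    fixed = MIAParams(
        p=params.p, pop_size=params.pop_size, t_max=2, t_ave=1,
        a_sel=params.a_sel, seed=params.seed,
    )
    for t in range(1, params.iterations + 1):
        affinity = 1.0 / f
        conc = concentration(enc, instance.n_sites, fixed.similarity_threshold)
        selected, counts = clonal_select(affinity, conc, 1, fixed)
        clones = np.repeat(enc[selected], counts, axis=0)
        for c in range(clones.shape[0]):
            if rng.uniform() < params.mutation_rate:
                pos = rng.integers(p)
                unused = np.setdiff1d(np.arange(instance.n_sites), clones[c])
                if unused.size:
                    clones[c, pos] = rng.choice(unused)
                    clones[c] = np.sort(clones[c])
        raw_c, viol_c = scorer.evaluate(clones)
        archive.update(clones, raw_c, viol_c)
        all_enc = np.vstack([enc, clones])
        all_raw = np.vstack([raw, raw_c])
        all_viol = np.vstack([viol, viol_c])
        f_all = ref.score(all_raw, all_viol)
        keep = np.argsort(f_all, kind="stable")[:n]
        enc, raw, viol, f = all_enc[keep], all_raw[keep], all_viol[keep], f_all[keep]
        if f[0] < best_F:
            best_enc, best_F, best_raw = enc[0].copy(), float(f[0]), raw[0].copy()
        rows.append(_trace_row(t, best_F, f, viol))
    return _finalize(scorer, archive, rows, ref)


_RUNNERS = {"ga": _run_ga, "pso": _run_pso, "ia": _run_ia}


def run_baseline(
    instance: ProblemInstance, params: BaselineParams, scorer: Scorer | None = None
) -> MIAResult:
    """Run one baseline algorithm; same result contract as :func:`run_mia`."""
    scorer = scorer or Scorer(instance)
    return _RUNNERS[params.algorithm](instance, params, scorer)


def relative_difference(other: float, reference: float) -> float:
    """Percentage by which ``reference`` improves on ``other``: (other - ref)/other * 100."""
    if other == 0:
        raise ValueError("cannot take a relative difference against zero")
    return (other - reference) / other * 100.0


def compare_algorithms(
    instance: ProblemInstance,
    param_sets: dict[str, MIAParams | BaselineParams],
    convergence_tol: float = 1e-6,
) -> pd.DataFrame:
    """Run several algorithms on one instance and tabulate the comparison.

    Raw objective values of each algorithm's best configuration are
    standardized across the set of algorithms and scalarized into one
    comprehensive value per algorithm, plus iterations-to-convergence and
    relative-difference percentages versus the ``mia`` entry (when present).
    """
    if len(param_sets) < 2:
        raise ValueError("need at least two algorithms to compare")
    scorer = Scorer(instance)
    results: dict[str, MIAResult] = {}
    for name, params in param_sets.items():
        if isinstance(params, MIAParams):
            results[name] = run_mia(instance, params, scorer=scorer)
        else:
            results[name] = run_baseline(instance, params, scorer=scorer)

    raw = np.vstack([results[n].best_raw for n in results])
    ctx = ScalarizationContext.from_population(
        raw, weights=equal_weights(scorer.have_baseline),
        have_baseline=scorer.have_baseline,
    )
    comp = ctx.score(raw, np.zeros((raw.shape[0], 4)))
    rows = []
    names = list(results)
    mia_idx = names.index("mia") if "mia" in names else None
    for i, name in enumerate(names):
        res = results[name]
        best = res.trace["best_F"].to_numpy()
        hit = np.flatnonzero(best <= best[-1] + convergence_tol)
        iters = int(res.trace["t"].iloc[hit[0]])
        row = {
            "algorithm": name,
            "equity": res.best_raw[0],
            "efficiency": res.best_raw[1],
            "travel_cost": res.best_raw[2],
            "profit": res.best_raw[3],
            "comprehensive": float(comp[i]),
            "iterations": iters,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    if mia_idx is not None:
        mia_comp = df.loc[mia_idx, "comprehensive"]
        mia_iters = df.loc[mia_idx, "iterations"]
        df["comprehensive_vs_mia_pct"] = [
            relative_difference(c, mia_comp) if c != 0 else 0.0
            for c in df["comprehensive"]
        ]
        df["iterations_vs_mia_pct"] = [
            relative_difference(it, mia_iters) for it in df["iterations"]
        ]
    return df
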