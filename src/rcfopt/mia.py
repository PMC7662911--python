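"""Modified immune algorithm (MIA) for the facility-configuration problem.

Candidate solutions ("antibodies") are ordered sets of ``p`` distinct
candidate-site indices.  Each generation:

1. antibodies are scored (affinity = reciprocal of the penalized
   comprehensive objective) and their concentration — the fraction of the
   population similar to them — is measured;
2. a memory bank archives the best unique antibodies and damps the
   selection score of population members too similar to a memory cell;
3. antibodies with high affinity and low concentration are cloned in
   proportion to a combined score, gated by a selection threshold that
   rises along a sine ramp late in the search;
4. clones mutate through the Guo elite operator (affine recombination of
   several elite parents with weights summing to one, each in [-0.5, 1.5],
   repaired back to a valid subset) at a periodically varying mutation
   probability, with a light exchange mutation retained for ergodicity;
5. the working copy of the global best is perturbed at fixed intervals with
   an exponentially decaying amplitude, to discourage premature
   convergence; the true incumbent archive is never touched.

All scoring happens in the instance's canonical scalarization frame (see
:func:`rcfopt.scoring.reference_context`), which gives a fixed total order
over solutions: affinities, the elite pool, survivor truncation, the memory
bank and the incumbent archive are all consistent with each other and with
the exhaustive-enumeration oracle, and the reported best-F trace is
non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FacilityConfiguration, ProblemInstance
from .objectives import adaptive_weights, equal_weights
from .scoring import EvaluationArchive, ScalarizationContext, Scorer, reference_context
from ._rng import substream

__all__ = [
    "MIAParams",
    "MIAResult",
    "initialize_population",
    "concentration",
    "selection_threshold",
    "clonal_select",
    "mutation_probability",
    "guo_elite_mutation",
    "repair_encoding",
    "perturb_global_best",
    "update_memory",
    "run_mia",
]


@dataclass
class MIAParams:
    """Tunable settings of the modified immune algorithm."""

    p: int  # number of facilities to open
    pop_size: int = 40  # N
    t_max: int = 200
    memory_size: int | None = None  # default N // 2
    a_sel: float = 0.3  # threshold coefficient (early-stage value)
    t_ave: int | None = None  # ramp onset, default t_max // 2
    eps_mut: float = 0.1  # mutation amplitude epsilon
    period: int = 40  # mutation period T
    gamma: float = 0.1  # mutation floor; equal to eps_mut so the mutation stage never idles
    elite_fraction: float = 0.1  # elite-pool fraction for the Guo operator
    theta: int = 10  # perturbation interval
    swap_prob: float = 0.05  # residual exchange-mutation probability
    similarity_threshold: float = 0.8  # Jaccard cut for concentration
    memory_damping: float = 0.5  # selection-score damping near memory cells
    eta: float = 2.0  # penalty exponent
    adaptive: bool = False  # range-adaptive objective weights
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("population size must be >= 2")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if not (0 < self.a_sel < 1):
            raise ValueError("a_sel must be in (0, 1)")
        if not (0 < self.gamma <= self.eps_mut):
            raise ValueError("gamma must satisfy 0 < gamma <= eps_mut")
        if self.theta < 1:
            raise ValueError("theta must be >= 1")
        if self.memory_size is None:
            self.memory_size = max(1, self.pop_size // 2)
        if self.t_ave is None:
            self.t_ave = self.t_max // 2

    @property
    def elite_size(self) -> int:
        return max(2, int(np.ceil(self.elite_fraction * self.pop_size)))


@dataclass
class MIAResult:
    """Best configuration found plus the per-iteration trace."""

    best_encoding: np.ndarray
    best_F: float
    best_config: FacilityConfiguration
    trace: pd.DataFrame
    context: ScalarizationContext
    best_raw: np.ndarray = field(default=None)  # raw objective vector of the best

    @property
    def iterations_to_convergence(self) -> int:
        """First iteration whose incumbent F is within 1e-6 of the final best."""
        best = self.trace["best_F"].to_numpy()
        hit = np.flatnonzero(best <= best[-1] + 1e-6)
        return int(self.trace["t"].iloc[hit[0]])


def initialize_population(
    instance: ProblemInstance, params: MIAParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Random initial population: N ordered p-subsets of the candidate sites."""
    if instance.n_sites < params.p:
        raise ValueError(f"cannot open p={params.p} of J={instance.n_sites} sites")
    if rng is None:
        rng = np.random.default_rng(substream(params.seed, "init"))
    enc = np.empty((params.pop_size, params.p), dtype=int)
    for k in range(params.pop_size):
        enc[k] = np.sort(rng.choice(instance.n_sites, size=params.p, replace=False))
    return enc


def _jaccard_matrix(encodings: np.ndarray, n_sites: int) -> np.ndarray:
    """Pairwise Jaccard similarity of the site sets encoded by each row."""
    k, p = encodings.shape
    onehot = np.zeros((k, n_sites), dtype=float)
    onehot[np.repeat(np.arange(k), p), encodings.ravel()] = 1.0
    inter = onehot @ onehot.T
    union = 2 * p - inter
    return inter / union


def concentration(
    encodings: np.ndarray, n_sites: int, similarity_threshold: float = 0.8
) -> np.ndarray:
    """Fraction of the population similar (Jaccard >= threshold) to each antibody.

    Includes the antibody itself, so values lie in (0, 1].
    """
    sim = _jaccard_matrix(np.atleast_2d(encodings), n_sites)
    return (sim >= similarity_threshold).mean(axis=1)


def selection_threshold(t: int, params: MIAParams) -> float:
    """Variable clonal-selection threshold sigma(t).

    Constant ``a_sel`` up to ``t_ave``, then a quarter-sine ramp to 1 at
    ``t_max`` — small early (broad cloning), large late (selective cloning).
    """
    if not (0 <= t <= params.t_max):
        raise ValueError(f"t={t} outside [0, {params.t_max}]")
    if t <= params.t_ave:
        return params.a_sel
    frac = (t - params.t_ave) / (params.t_max - params.t_ave)
    return params.a_sel + (1.0 - params.a_sel) * np.sin(0.5 * np.pi * frac)


def mutation_probability(t: int, params: MIAParams) -> float:
    """Periodic mutation probability ``eps * |cos(2 pi t / T)| + gamma``."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return params.eps_mut * abs(np.cos(2.0 * np.pi * t / params.period)) + params.gamma


def clonal_select(
    affinities: np.ndarray,
    concentrations: np.ndarray,
    t: int,
    params: MIAParams,
    damping: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Select antibodies for cloning and apportion N clones among them.

    Selection score is normalized affinity times (1 - concentration),
    optionally damped (memory similarity).  Antibodies scoring at or above
    the sigma(t) quantile of the population are selected; clone counts are
    proportional to score with largest-remainder rounding, summing to N.
    """
    aff = np.asarray(affinities, dtype=float)
    score = (aff / aff.max()) * (1.0 - np.asarray(concentrations, dtype=float))
    if damping is not None:
        score = score * damping
    sigma = selection_threshold(t, params)
    cut = np.quantile(score, sigma)
    selected = np.flatnonzero(score >= cut)
    if selected.size == 0:  # all-equal scores at sigma -> keep the best
        selected = np.array([int(np.argmax(score))])
    sel_scores = score[selected]
    if sel_scores.sum() <= 0:
        sel_scores = np.ones_like(sel_scores)
    quota = params.pop_size * sel_scores / sel_scores.sum()
    counts = np.floor(quota).astype(int)
    remainder = params.pop_size - counts.sum()
    if remainder > 0:
        order = np.argsort(-(quota - counts))
        counts[order[:remainder]] += 1
    return selected, counts


def repair_encoding(values: np.ndarray, n_sites: int) -> np.ndarray:
    """Repair a real-valued index vector into a valid ordered p-subset.

    Coordinates are rounded to the nearest integer in [0, J); duplicates are
    replaced by the nearest unused index.  Total: always succeeds for
    p <= J.
    """
    vals = np.clip(np.rint(np.asarray(values, dtype=float)), 0, n_sites - 1).astype(int)
    used: set[int] = set()
    out = []
    for v in vals:
        if v not in used:
            used.add(v)
            out.append(v)
            continue
        for off in range(1, n_sites):
            lo, hi = v - off, v + off
            if lo >= 0 and lo not in used:
                used.add(lo)
                out.append(lo)
                break
            if hi < n_sites and hi not in used:
                used.add(hi)
                out.append(hi)
                break
        else:  # pragma: no cover - unreachable for p <= J
            raise RuntimeError("repair failed")
    return np.sort(np.array(out, dtype=int))


def guo_elite_mutation(
    elite_pool: np.ndarray,
    n_sites: int,
    rng: np.random.Generator,
    phi: np.ndarray | None = None,
) -> np.ndarray:
    """Guo elite recombination: affine combination of elite parents, repaired.

    Weights phi are drawn uniformly in [-0.5, 1.5] and renormalized to sum
    to one (redrawn on near-zero sums); with explicit ``phi`` the operator
    is deterministic.
    """
    pool = np.atleast_2d(np.asarray(elite_pool, dtype=float))
    if pool.shape[0] < 2:
        raise ValueError("elite pool must hold at least 2 antibodies")
    if phi is None:
        for _ in range(100):
            phi = rng.uniform(-0.5, 1.5, size=pool.shape[0])
            if abs(phi.sum()) > 0.1:
                break
        phi = phi / phi.sum()
    else:
        phi = np.asarray(phi, dtype=float)
        if not np.isclose(phi.sum(), 1.0):
            raise ValueError("phi must sum to 1")
    raw = phi @ pool
    return repair_encoding(raw, n_sites)


def perturb_global_best(
    fit_best: float, t: int, params: MIAParams, rng: np.random.Generator
) -> float:
    """Perturbed working copy of the global best comprehensive value.

    Applied only when ``t`` is a multiple of the interval theta; amplitude
    ``exp(-t/theta) * u**2`` with u ~ U(0,1) decays over iterations.  The
    true incumbent archive is never perturbed.
    """
    if t % params.theta != 0:
        return fit_best
    u = rng.uniform()
    return fit_best + np.exp(-t / params.theta) * u * u


def update_memory(
    memory: list[tuple[tuple[int, ...], float]],
    encodings: np.ndarray,
    scores: np.ndarray,
    capacity: int,
) -> list[tuple[tuple[int, ...], float]]:
    """Merge a scored population into the memory bank.

    The bank keeps the ``capacity`` best-scoring unique antibodies seen so
    far (smaller score = better); worse cells are evicted.
    """
    pool = dict(memory)
    for enc, s in zip(np.atleast_2d(encodings), np.asarray(scores, dtype=float)):
        key = tuple(int(x) for x in enc)
        if key not in pool or s < pool[key]:
            pool[key] = float(s)
    ranked = sorted(pool.items(), key=lambda kv: kv[1])
    return ranked[:capacity]


def _memory_damping(
    encodings: np.ndarray,
    memory: list[tuple[tuple[int, ...], float]],
    n_sites: int,
    threshold: float,
    factor: float,
) -> np.ndarray | None:
    """Damping multipliers for antibodies similar to a memory cell.

    The incumbent memory region is already preserved, so crowding it is
    discouraged to keep the search diverse.
    """
    if not memory:
        return None
    mem_enc = np.array([m[0] for m in memory], dtype=int)
    both = np.vstack([np.atleast_2d(encodings), mem_enc])
    sim = _jaccard_matrix(both, n_sites)
    k = np.atleast_2d(encodings).shape[0]
    near = (sim[:k, k:] >= threshold).any(axis=1)
    return np.where(near, factor, 1.0)


def _best_unique(encodings: np.ndarray, scores: np.ndarray, k: int) -> np.ndarray:
    """The k best-scoring distinct encodings (fewer if the population repeats)."""
    order = np.argsort(scores, kind="stable")
    seen: set[tuple[int, ...]] = set()
    picked = []
    for idx in order:
        key = tuple(int(x) for x in encodings[idx])
        if key in seen:
            continue
        seen.add(key)
        picked.append(idx)
        if len(picked) == k:
            break
    return encodings[picked]


def _truncate_unique(encodings: np.ndarray, scores: np.ndarray, n: int) -> np.ndarray:
    """Indices of the n survivors: best unique encodings first, then best repeats."""
    order = np.argsort(scores, kind="stable")
    seen: set[tuple[int, ...]] = set()
    unique, repeats = [], []
    for idx in order:
        key = tuple(int(x) for x in encodings[idx])
        if key in seen:
            repeats.append(idx)
        else:
            seen.add(key)
            unique.append(idx)
    return np.array((unique + repeats)[:n], dtype=int)


def run_mia(
    instance: ProblemInstance,
    params: MIAParams,
    scorer: Scorer | None = None,
    context: ScalarizationContext | None = None,
) -> MIAResult:
    """Run the modified immune algorithm; fully reproducible from the seed.

    ``context`` optionally fixes the incumbent scalarization frame (used by
    the count sweep to compare runs at different p); by default the frame is
    frozen from the initial population.
    """
    scorer = scorer or Scorer(instance)
    rng_init = np.random.default_rng(substream(params.seed, "init"))
    rng_mut = np.random.default_rng(substream(params.seed, "mutation"))
    rng_pert = np.random.default_rng(substream(params.seed, "perturbation"))

    enc = initialize_population(instance, params, rng_init)
    raw, viol = scorer.evaluate(enc)
    archive = EvaluationArchive()
    archive.update(enc, raw, viol)
    weights = (
        adaptive_weights(raw, scorer.have_baseline)
        if params.adaptive
        else equal_weights(scorer.have_baseline)
    )
    ref = context or reference_context(
        scorer, params.p, weights=weights, eta=params.eta
    )

    best_F = np.inf
    best_enc = enc[0]
    best_raw_vec = raw[0]
    memory: list[tuple[tuple[int, ...], float]] = []
    rows = []

    for t in range(1, params.t_max + 1):
        # fixed-frame scores: incumbent archive and trace
        f_ref = ref.score(raw, viol)
        gen_best = int(np.argmin(f_ref))
        if f_ref[gen_best] < best_F:
            best_F = float(f_ref[gen_best])
            best_enc = enc[gen_best].copy()
            best_raw_vec = raw[gen_best].copy()

        # affinity in the same fixed frame: a stable notion of "best"
        affinity = 1.0 / f_ref

        memory = update_memory(memory, enc, f_ref, params.memory_size)
        conc = concentration(enc, instance.n_sites, params.similarity_threshold)
        damp = _memory_damping(
            enc, memory[1:], instance.n_sites,
            params.similarity_threshold, params.memory_damping,
        )
        selected, counts = clonal_select(affinity, conc, t, params, damping=damp)

        # elite pool for the Guo operator: best distinct antibodies, so the
        # affine recombination spans a real subspace instead of a point
        elite = _best_unique(enc, f_ref, params.elite_size)
        p_m = mutation_probability(t, params)

        clones = np.repeat(enc[selected], counts, axis=0)
        for c in range(clones.shape[0]):
            u = rng_mut.uniform()
            if u < p_m and elite.shape[0] >= 2:
                clones[c] = guo_elite_mutation(elite, instance.n_sites, rng_mut)
            elif u < p_m + params.swap_prob:
                # exchange mutation: swap one index for an unused site
                pos = rng_mut.integers(params.p)
                unused = np.setdiff1d(
                    np.arange(instance.n_sites), clones[c], assume_unique=False
                )
                if unused.size:
                    clones[c, pos] = rng_mut.choice(unused)
                    clones[c] = np.sort(clones[c])

        raw_c, viol_c = scorer.evaluate(clones)
        archive.update(clones, raw_c, viol_c)
        all_enc = np.vstack([enc, clones])
        all_raw = np.vstack([raw, raw_c])
        all_viol = np.vstack([viol, viol_c])
        # survivor selection in the fixed frame, so the incumbent region is
        # never evicted by frame drift (the memory role of the best cells);
        # duplicates of a survivor have reduced ability to survive
        f_all = ref.score(all_raw, all_viol)
        keep = _truncate_unique(all_enc, f_all, params.pop_size)
        enc, raw, viol = all_enc[keep], all_raw[keep], all_viol[keep]

        working_best = perturb_global_best(best_F, t, params, rng_pert)
        rows.append(
            {
                "t": t,
                "best_F": best_F,
                "working_best_F": working_best,
                "mean_F": float(np.mean(ref.score(raw, viol))),
                "feasible_fraction": float(np.mean(viol.sum(axis=1) == 0)),
                "sigma": selection_threshold(t, params),
                "p_m": p_m,
            }
        )

    # the run's incumbent: every evaluated solution re-ranked in the fixed
    # frame, so the result is exactly the best solution the search ever saw
    best_enc, best_F, best_raw_vec = archive.best_in(ref)

    return MIAResult(
        best_encoding=best_enc,
        best_F=best_F,
        best_config=scorer.config(best_enc),
        trace=pd.DataFrame(rows),
        context=ref,
        best_raw=best_raw_vec,
    )
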