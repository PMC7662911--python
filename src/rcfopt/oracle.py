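"""Exhaustive enumeration of p-subset configurations.

Tractable only for small instances (C(J, p) up to a few thousand); used as
the independent ground truth against which the metaheuristics are checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core import ProblemInstance
from .scoring import ScalarizationContext, Scorer, reference_context

__all__ = ["ExhaustiveResult", "exhaustive_optimum"]

#: Refuse enumerations beyond this many subsets.
MAX_SUBSETS = 200_000


@dataclass(frozen=True)
class ExhaustiveResult:
    encoding: np.ndarray  # optimal p-subset (sorted indices)
    F: float  # its comprehensive value in the enumeration frame
    context: ScalarizationContext  # frame spanning all enumerated subsets
    n_enumerated: int


def exhaustive_optimum(
    instance: ProblemInstance,
    p: int,
    weights: np.ndarray | None = None,
    eta: float = 2.0,
    chunk: int = 4096,
) -> ExhaustiveResult:
    """Enumerate every p-subset of sites and return the F-minimizer.

    F is scored in the instance's canonical frame (see
    :func:`rcfopt.scoring.reference_context`), the same frame every search
    algorithm reports in, so "the optimum" is search-independent.  Ties
    resolve to the lexicographically smallest subset (enumeration order).
    """
    j = instance.n_sites
    n_total = math.comb(j, p)
    if n_total > MAX_SUBSETS:
        raise ValueError(f"C({j},{p}) = {n_total} subsets is too many to enumerate")
    scorer = Scorer(instance)
    all_enc = np.fromiter(
        (idx for combo in combinations(range(j), p) for idx in combo),
        dtype=int,
        count=n_total * p,
    ).reshape(n_total, p)
    raws, viols = [], []
    for start in range(0, n_total, chunk):
        r, v = scorer.evaluate(all_enc[start : start + chunk])
        raws.append(r)
        viols.append(v)
    raw = np.vstack(raws)
    viol = np.vstack(viols)
    ctx = reference_context(scorer, p, weights=weights, eta=eta)
    scores = ctx.score(raw, viol)
    best = int(np.argmin(scores))
    return ExhaustiveResult(
        encoding=all_enc[best].copy(),
        F=float(scores[best]),
        context=ctx,
        n_enumerated=n_total,
    )
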