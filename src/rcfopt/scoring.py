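"""Batch scoring of site-subset solutions, shared by every search algorithm.

An encoded solution is a set of ``p`` distinct candidate-site indices.  It is
completed deterministically into a full configuration (nearest allocation,
beds sized to served demand) and scored on the four raw objectives plus the
constraint-violation magnitudes.  The completion makes count, coverage and
linkage constraints hold by construction; capacity can still be violated
when a site attracts more demand than its bed cap, which is exactly what the
adaptive penalty must steer away from.

Scoring is vectorized over whole populations — the optimizers evaluate tens
of thousands of solutions per run and would be unusable antibody-by-antibody.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FacilityConfiguration, ProblemInstance, size_beds_to_demand
from .objectives import EPS_F, MAXIMIZED, equal_weights

__all__ = ["Scorer", "ScalarizationContext", "EvaluationArchive", "reference_context"]


@dataclass(frozen=True)
class ScalarizationContext:
    """A frozen min-max standardization frame plus weights and penalty exponent.

    Scoring different solutions in one fixed frame gives a consistent total
    order, which the optimizers use for their incumbent archive and which
    the exhaustive oracle uses to define "the" optimum.  Values outside the
    reference population may map outside [0, 1]; the map stays monotone.
    """

    lo: np.ndarray  # (4,) per-objective reference minima
    hi: np.ndarray  # (4,) per-objective reference maxima
    weights: np.ndarray  # (4,) nonnegative, sum 1
    eta: float = 2.0

    def standardized(self, raw: np.ndarray) -> np.ndarray:
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        rng = self.hi - self.lo
        scale = np.where(rng > 0, rng, np.maximum(np.abs(self.hi), 1.0))
        std = (raw - self.lo) / scale
        std = np.where(MAXIMIZED, (self.hi - raw) / scale, std)
        return np.where(np.isnan(raw), 0.5, std)

    def score(self, raw: np.ndarray, violations: np.ndarray) -> np.ndarray:
        """Penalized comprehensive value F for each (raw, violation) row."""
        std = self.standardized(raw)
        viol = np.atleast_2d(np.asarray(violations, dtype=float))
        f = np.maximum(std @ self.weights, EPS_F)
        r = 1.0 + np.mean(viol ** self.eta, axis=1)
        return f * r

    @classmethod
    def from_population(
        cls,
        raw: np.ndarray,
        weights: np.ndarray | None = None,
        eta: float = 2.0,
        have_baseline: bool = True,
    ) -> "ScalarizationContext":
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        if weights is None:
            weights = equal_weights(have_baseline)
        finite = np.isfinite(raw)
        any_finite = finite.any(axis=0)
        lo = np.where(any_finite, np.min(np.where(finite, raw, np.inf), axis=0), 0.0)
        hi = np.where(any_finite, np.max(np.where(finite, raw, -np.inf), axis=0), 1.0)
        return cls(lo=lo, hi=hi, weights=np.asarray(weights, float), eta=eta)


def reference_context(
    scorer: "Scorer",
    p: int,
    weights: np.ndarray | None = None,
    eta: float = 2.0,
    enum_limit: int = 4096,
    n_samples: int = 512,
) -> ScalarizationContext:
    """Canonical scalarization frame for p-facility solutions of an instance.

    Min-max standardization is only meaningful relative to a population of
    solutions.  To make comprehensive values comparable across algorithms,
    runs and the enumeration oracle, the frame is computed once from a
    deterministic reference population: every p-subset when C(J, p) is small
    enough to enumerate, otherwise a fixed seeded sample of subsets (the
    sample depends only on J and p, never on the run seed).
    """
    import math
    from itertools import combinations

    from ._rng import substream

    j = scorer.instance.n_sites
    total = math.comb(j, p)
    if total <= enum_limit:
        enc = np.fromiter(
            (i for c in combinations(range(j), p) for i in c),
            dtype=int, count=total * p,
        ).reshape(total, p)
    else:
        rng = np.random.default_rng(substream(9157, f"reference-frame-{j}-{p}"))
        enc = np.empty((n_samples, p), dtype=int)
        for k in range(n_samples):
            enc[k] = np.sort(rng.choice(j, size=p, replace=False))
    raw, _viol = scorer.evaluate(enc)
    return ScalarizationContext.from_population(
        raw, weights=weights, eta=eta, have_baseline=scorer.have_baseline
    )


class EvaluationArchive:
    """All distinct solutions evaluated during a run, with raw scores.

    The incumbent of a run is the archive minimizer in the instance's
    canonical frame, so a good solution evaluated but dropped by survivor
    selection is never lost, and results are comparable across algorithms
    and with the brute-force oracle.
    """

    def __init__(self) -> None:
        self._index: dict[tuple[int, ...], int] = {}
        self._enc: list[tuple[int, ...]] = []
        self._raw: list[np.ndarray] = []
        self._viol: list[np.ndarray] = []

    def __len__(self) -> int:
        return len(self._enc)

    def update(self, encodings: np.ndarray, raw: np.ndarray, violations: np.ndarray) -> None:
        for enc, r, v in zip(np.atleast_2d(encodings), raw, violations):
            key = tuple(int(x) for x in enc)
            if key not in self._index:
                self._index[key] = len(self._enc)
                self._enc.append(key)
                self._raw.append(np.asarray(r, dtype=float))
                self._viol.append(np.asarray(v, dtype=float))

    def best_in(
        self, context: "ScalarizationContext"
    ) -> tuple[np.ndarray, float, np.ndarray]:
        """Re-rank the archive in the given frame; return the F-minimizer."""
        raw = np.vstack(self._raw)
        viol = np.vstack(self._viol)
        scores = context.score(raw, viol)
        idx = int(np.argmin(scores))
        return np.array(self._enc[idx], dtype=int), float(scores[idx]), raw[idx].copy()


class Scorer:
    """Evaluates populations of p-subset encodings on one problem instance."""

    def __init__(self, instance: ProblemInstance):
        self.instance = instance
        self.w = instance.demand
        self.total_demand = float(self.w.sum())
        self.margin = instance.costs.margin
        self.cap = instance.max_beds
        self.d = instance.distances
        self.dn = self.d ** (-instance.beta)
        self.demand_pressure = self.w @ self.dn  # (J,)
        self.baseline = instance.baseline_accessibility

    @property
    def have_baseline(self) -> bool:
        return self.baseline is not None

    def evaluate(self, encodings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Score a (K, p) array of encodings.

        Returns ``raw`` (K, 4) objective values (efficiency is NaN without a
        baseline) and ``violations`` (K, 4) constraint magnitudes.
        """
        enc = np.atleast_2d(np.asarray(encodings, dtype=int))
        k_count, p = enc.shape
        i_count = self.d.shape[0]

        dsub = self.d[:, enc]  # (I, K, p)
        local = np.argmin(dsub, axis=2)  # (I, K) nearest open site, local index
        assigned_d = np.take_along_axis(dsub, local[:, :, np.newaxis], axis=2)[:, :, 0]
        travel = self.w @ assigned_d  # (K,)

        beds = np.zeros((k_count, p))
        rows = np.repeat(np.arange(k_count), i_count)
        np.add.at(beds, (rows, local.T.ravel()), np.tile(self.w, k_count))

        dn_sub = self.dn[:, enc]  # (I, K, p)
        supply = beds / self.demand_pressure[enc]  # (K, p)
        acc = np.einsum("ikp,kp->ik", dn_sub, supply)  # (I, K)
        wmean = (self.w @ acc) / self.total_demand  # (K,) == V/W == 1 here
        equity = ((acc - wmean) ** 2).sum(axis=0)

        if self.have_baseline:
            a0 = self.baseline[:, np.newaxis]
            efficiency = np.mean((acc - a0) / a0, axis=0)
        else:
            efficiency = np.full(k_count, np.nan)

        profit = np.full(k_count, self.margin * self.total_demand / p)

        overflow = np.maximum(0.0, beds - self.cap[enc]).sum(axis=1)
        empty_open = np.count_nonzero(beds <= 0, axis=1)
        violations = np.zeros((k_count, 4))
        violations[:, 3] = overflow + empty_open

        raw = np.column_stack([equity, efficiency, travel, profit])
        return raw, violations

    def accessibility(self, encoding: np.ndarray) -> np.ndarray:
        """Per-center accessibility field of one encoding (convenience)."""
        raw_enc = np.asarray(encoding, dtype=int)[np.newaxis, :]
        dsub = self.d[:, raw_enc[0]]
        local = np.argmin(dsub, axis=1)
        beds = np.bincount(local, weights=self.w, minlength=raw_enc.shape[1])
        dn_sub = self.dn[:, raw_enc[0]]
        return dn_sub @ (beds / self.demand_pressure[raw_enc[0]])

    def config(self, encoding: np.ndarray) -> FacilityConfiguration:
        """Complete one encoding into a full configuration."""
        return size_beds_to_demand(self.instance, np.asarray(encoding, dtype=int))
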