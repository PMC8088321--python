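"""Greedy maximization of facility location objectives over experiments.

The ground set Y is every experiment (performed or potential).  The plain
objective

    f(X) = sum_y max_{x in X} phi(x, y)

rewards subsets whose members jointly resemble every element of Y; it is
monotone submodular, so greedy selection is within (1 - 1/e) of the
optimal subset of the same size.  Two extensions are supported:

* per-experiment non-negative weights w(x), giving
  f(X) = sum_y max_x w(x) phi(x, y), still submodular;
* concentration terms lambda_a * ||a(X)||^2 + lambda_b * ||b(X)||^2,
  where a(X) / b(X) count selected experiments per assay / biosample.
  These squared-count terms are supermodular (their marginal gains grow
  with the set), so the mixture is no longer submodular and the lazy
  engine refuses to run on it.

Selection can be seeded with already-performed experiments: the coverage
state starts from the seeds, so each new pick targets activity the
existing experiments miss.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np

from ._types import Experiment, ExperimentSet, SimilarityContainer

__all__ = [
    "SelectionConfig",
    "CoverageState",
    "SelectionResult",
    "facility_location_value",
    "mixture_objective_value",
    "marginal_gain",
    "greedy_select",
    "brute_force_optimum",
]

_CONSISTENCY_TOL = 1e-9


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of one selection run.

    k: number of *new* experiments to pick (cardinality constraint).
    lambda_a / lambda_b: non-negative concentration weights on the squared
        per-assay / per-biosample selection counts; zero recovers the
        plain (weighted) facility location objective.
    engine: 'naive' re-evaluates every candidate each step; 'lazy' is
        Minoux's accelerated greedy, valid only when both lambdas are zero.
    penalize_seeds: whether seeds enter the count vectors a and b.
    """

    k: int = 0
    lambda_a: float = 0.0
    lambda_b: float = 0.0
    engine: str = "naive"
    penalize_seeds: bool = True

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.lambda_a < 0 or self.lambda_b < 0:
            raise ValueError("lambda_a and lambda_b must be non-negative")
        if self.engine not in ("naive", "lazy"):
            raise ValueError(f"unknown engine {self.engine!r}")

    @property
    def has_concentration(self) -> bool:
        return self.lambda_a > 0 or self.lambda_b > 0


@dataclass
class SelectionResult:
    """Ordered ranking produced by one greedy run (seeds excluded)."""

    selected: list[Experiment]
    indices: np.ndarray
    gains: np.ndarray
    objectives: np.ndarray
    seeds: np.ndarray


def _weights(w, n: int) -> np.ndarray:
    if w is None:
        return np.ones(n)
    w = np.asarray(w, dtype=np.float64)
    if w.shape != (n,):
        raise ValueError(f"weight vector shape {w.shape} != ({n},)")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    return w


def _check_members(indices, n: int) -> np.ndarray:
    idx = np.asarray(list(indices), dtype=np.intp)
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise ValueError(f"experiment index out of range for ground set of {n}")
    return idx


def facility_location_value(
    X: Sequence[int],
    sim: SimilarityContainer,
    w: np.ndarray | None = None,
) -> float:
    """f(X) = sum_y max_{x in X} w(x) phi(x, y); 0 for empty X."""
    idx = _check_members(X, sim.n)
    if idx.size == 0:
        return 0.0
    weights = _weights(w, sim.n)
    covered = (weights[idx, None] * sim.values[idx, :]).max(axis=0)
    return float(covered.sum())


def _count_term(X: Sequence[int], labels: ExperimentSet, config: SelectionConfig) -> float:
    if not config.has_concentration:
        return 0.0
    idx = np.asarray(list(X), dtype=np.intp)
    term = 0.0
    if config.lambda_a > 0:
        counts = np.bincount(labels.assay_codes()[idx], minlength=len(labels.assays))
        term += config.lambda_a * float((counts.astype(np.float64) ** 2).sum())
    if config.lambda_b > 0:
        counts = np.bincount(
            labels.biosample_codes()[idx], minlength=len(labels.biosamples)
        )
        term += config.lambda_b * float((counts.astype(np.float64) ** 2).sum())
    return term


def mixture_objective_value(
    X: Sequence[int],
    sim: SimilarityContainer,
    w: np.ndarray | None = None,
    config: SelectionConfig | None = None,
) -> float:
    """Facility location value plus squared-count concentration terms.

    The count vectors are taken over the selected set X (a ground-set
    count would be constant and could not steer the selection).
    """
    config = config or SelectionConfig()
    return facility_location_value(X, sim, w) + _count_term(
        X, sim.experiments, config
    )


class CoverageState:
    """Incremental bookkeeping for greedy selection.

    Maintains the per-target best weighted coverage
    c_y = max_{x in X} w(x) phi(x, y), the per-assay and per-biosample
    selection counts, and the running objective, so each marginal gain is
    an O(n) vector operation instead of a from-scratch recomputation.
    """

    def __init__(
        self,
        sim: SimilarityContainer,
        w: np.ndarray | None = None,
        config: SelectionConfig | None = None,
    ):
        self.sim = sim
        self.config = config or SelectionConfig()
        self.w = _weights(w, sim.n)
        self.coverage = np.zeros(sim.n)
        self.assay_codes = sim.experiments.assay_codes()
        self.biosample_codes = sim.experiments.biosample_codes()
        self.assay_counts = np.zeros(len(sim.experiments.assays), dtype=np.intp)
        self.biosample_counts = np.zeros(
            len(sim.experiments.biosamples), dtype=np.intp
        )
        self.members: list[int] = []
        self.objective = 0.0

    def gain(self, x: int) -> float:
        g = float(
            np.maximum(self.w[x] * self.sim.values[x] - self.coverage, 0.0).sum()
        )
        cfg = self.config
        if cfg.lambda_a > 0:
            g += cfg.lambda_a * (2.0 * self.assay_counts[self.assay_codes[x]] + 1.0)
        if cfg.lambda_b > 0:
            g += cfg.lambda_b * (
                2.0 * self.biosample_counts[self.biosample_codes[x]] + 1.0
            )
        return g

    def add(self, x: int, count_in_penalty: bool = True) -> float:
        """Add x, returning its realized marginal gain."""
        g = self.gain(x) if count_in_penalty else float(
            np.maximum(self.w[x] * self.sim.values[x] - self.coverage, 0.0).sum()
        )
        np.maximum(
            self.coverage, self.w[x] * self.sim.values[x], out=self.coverage
        )
        if count_in_penalty:
            self.assay_counts[self.assay_codes[x]] += 1
            self.biosample_counts[self.biosample_codes[x]] += 1
        self.members.append(x)
        self.objective += g
        return g

    def recomputed_objective(self) -> float:
        """From-scratch objective of the current members (debug check).

        Seeds added with ``count_in_penalty=False`` are excluded from the
        count terms here as well, via the stored count vectors.
        """
        fl = facility_location_value(self.members, self.sim, self.w)
        cfg = self.config
        term = cfg.lambda_a * float(
            (self.assay_counts.astype(np.float64) ** 2).sum()
        ) + cfg.lambda_b * float((self.biosample_counts.astype(np.float64) ** 2).sum())
        return fl + term


def marginal_gain(
    x: int,
    state: CoverageState,
    sim: SimilarityContainer | None = None,
    w: np.ndarray | None = None,
    config: SelectionConfig | None = None,
) -> float:
    """Gain of adding candidate x to the current state.

    Equals sum_y max(0, w(x) phi(x,y) - c_y) plus, per concentration term,
    lambda * (2 * count + 1) — the difference of squared counts.
    """
    if x in state.members:
        raise ValueError(f"candidate {x} already selected")
    return state.gain(x)


def _greedy_naive(state: CoverageState, candidates: np.ndarray, k: int):
    order, gains, objectives = [], [], []
    available = candidates.tolist()
    for _ in range(k):
        best_gain = -np.inf
        best_pos = -1
        for pos, x in enumerate(available):
            g = state.gain(x)
            if g > best_gain:  # strict: first (lowest-index) wins ties
                best_gain = g
                best_pos = pos
        x = available.pop(best_pos)
        state.add(x)
        order.append(x)
        gains.append(best_gain)
        objectives.append(state.objective)
    return order, gains, objectives


def _greedy_lazy(state: CoverageState, candidates: np.ndarray, k: int):
    """Minoux's accelerated greedy: stale upper bounds in a max-heap.

    Valid because with lambda = 0 the objective is submodular, so a gain
    computed at an earlier (smaller) selection upper-bounds the current
    gain.  Ties resolve to the lowest index via the heap key.
    """
    heap = [(-state.gain(x), int(x)) for x in candidates]
    heapq.heapify(heap)
    order, gains, objectives = [], [], []
    for _ in range(k):
        while True:
            neg_stale, x = heapq.heappop(heap)
            fresh = state.gain(x)
            # (-gain, index) comparison keeps exact ties on the lowest
            # index, matching the naive engine's first-maximum rule
            if not heap or (-fresh, x) <= heap[0]:
                break
            heapq.heappush(heap, (-fresh, x))
        state.add(x)
        order.append(x)
        gains.append(fresh)
        objectives.append(state.objective)
    return order, gains, objectives


def greedy_select(
    sim: SimilarityContainer,
    config: SelectionConfig,
    seeds: Sequence[int] | None = None,
    w: np.ndarray | None = None,
) -> SelectionResult:
    """Rank k new experiments by greedy maximization.

    The coverage state is initialized from the seed set (seed weights
    default to 1 via the shared weight vector); when concentration terms
    are active, seeds enter the count vectors unless
    ``config.penalize_seeds`` is False.  Ties break to the lowest label
    index in both engines.
    """
    seed_idx = _check_members(seeds if seeds is not None else [], sim.n)
    if len(set(seed_idx.tolist())) != seed_idx.size:
        raise ValueError("duplicate seed experiments")
    if config.k > sim.n - seed_idx.size:
        raise ValueError(
            f"k={config.k} exceeds {sim.n - seed_idx.size} available candidates"
        )
    if config.engine == "lazy" and config.has_concentration:
        raise ValueError(
            "lazy engine unavailable with concentration terms: stale gain "
            "bounds are unsound for supermodular terms"
        )
    state = CoverageState(sim, w, config)
    for s in seed_idx:
        state.add(int(s), count_in_penalty=config.penalize_seeds)
    baseline = state.objective
    in_seeds = np.zeros(sim.n, dtype=bool)
    in_seeds[seed_idx] = True
    candidates = np.flatnonzero(~in_seeds)
    engine = _greedy_lazy if config.engine == "lazy" else _greedy_naive
    order, gains, objectives = engine(state, candidates, config.k)
    drift = abs(state.recomputed_objective() - state.objective)
    if drift > _CONSISTENCY_TOL * max(1.0, abs(state.objective)):
        raise AssertionError(
            f"incremental objective drifted {drift:.3g} from recomputation"
        )
    return SelectionResult(
        selected=[sim.experiments[i] for i in order],
        indices=np.asarray(order, dtype=np.intp),
        gains=np.asarray(gains, dtype=np.float64),
        objectives=np.asarray(objectives, dtype=np.float64),
        seeds=seed_idx,
    )


def brute_force_optimum(
    sim: SimilarityContainer,
    k: int,
    w: np.ndarray | None = None,
    config: SelectionConfig | None = None,
    seeds: Sequence[int] | None = None,
    budget: int = 10**6,
) -> tuple[tuple[int, ...], float]:
    """Exhaustive search over all size-k candidate subsets.

    Test oracle for the greedy engines; refuses to enumerate more than
    ``budget`` subsets.  Ties break to the lexicographically first subset
    (itertools.combinations order).
    """
    config = config or SelectionConfig()
    seed_idx = _check_members(seeds if seeds is not None else [], sim.n)
    candidates = [i for i in range(sim.n) if i not in set(seed_idx.tolist())]
    if comb(len(candidates), k) > budget:
        raise ValueError(
            f"C({len(candidates)}, {k}) exceeds enumeration budget {budget}"
        )
    best_subset: tuple[int, ...] | None = None
    best_value = -np.inf
    seed_list = seed_idx.tolist()
    for subset in itertools.combinations(candidates, k):
        value = mixture_objective_value(
            seed_list + list(subset), sim, w, config
        )
        if value > best_value + 1e-12:
            best_value = value
            best_subset = subset
    assert best_subset is not None or k == 0
    if k == 0:
        return (), mixture_objective_value(seed_list, sim, w, config)
    return best_subset, float(best_value)
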