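"""Coverage scoring of biosamples and assays.

The facility location value doubles as a diversity score: restricted to
one biosample (or one assay), the performed experiments X of that element
are scored against the element's full ground set Y of experiments,

    score(X) = sum_{y in Y} max_{x in X} phi(x, y),

which ranges from 0 (nothing performed) up to |Y| (every element of the
ground set perfectly covered).  The score is compared against random
panels of the same size and against a greedy-optimized panel, exposing
elements whose many experiments are nonetheless redundant — e.g. a tissue
assayed a dozen times but only ever for transcription.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._types import ExperimentSet, SimilarityContainer
from .selection import SelectionConfig, greedy_select

__all__ = [
    "coverage_score",
    "score_axis",
    "random_baseline_scores",
    "rank_correlation",
    "coverage_table",
]


def _restrict(sim: SimilarityContainer, ground: np.ndarray) -> np.ndarray:
    return sim.values[np.ix_(ground, ground)]


def coverage_score(
    X: Sequence[int], Y: Sequence[int], sim: SimilarityContainer
) -> float:
    """Facility location value of X against ground subset Y.

    X and Y are indices into the similarity container; X must be a subset
    of Y.  Returns 0 for empty X.
    """
    Xs, Ys = set(map(int, X)), set(map(int, Y))
    if not Xs <= Ys:
        raise ValueError(f"X is not a subset of Y: extra elements {sorted(Xs - Ys)}")
    if not Xs:
        return 0.0
    x_idx = np.asarray(sorted(Xs), dtype=np.intp)
    y_idx = np.asarray(sorted(Ys), dtype=np.intp)
    return float(sim.values[np.ix_(x_idx, y_idx)].max(axis=0).sum())


def _axis_groups(labels: ExperimentSet, axis: str):
    if axis == "biosample":
        return labels.by_biosample()
    if axis == "assay":
        return labels.by_assay()
    raise ValueError(f"axis must be 'biosample' or 'assay', got {axis!r}")


def score_axis(
    labels: ExperimentSet,
    sim: SimilarityContainer,
    axis: str = "biosample",
    performed: np.ndarray | None = None,
) -> pd.DataFrame:
    """Performed-set coverage score for every element on one axis.

    Returns a DataFrame with one row per element: the element label, its
    performed count, its ground-set size and the coverage score of its
    performed experiments against its full ground set.
    """
    if performed is None:
        performed = labels.performed_mask()
    performed = np.asarray(performed, dtype=bool)
    rows = []
    for element, members in _axis_groups(labels, axis).items():
        ground = np.asarray(members, dtype=np.intp)
        done = ground[performed[ground]]
        rows.append(
            {
                "element": element,
                "n_performed": int(done.size),
                "n_ground": int(ground.size),
                "performed_score": coverage_score(done, ground, sim),
            }
        )
    return pd.DataFrame(rows)


def random_baseline_scores(
    ground: Sequence[int],
    panel_size: int,
    n_reps: int,
    sim: SimilarityContainer,
    rng: np.random.Generator,
) -> np.ndarray:
    """Coverage scores of ``n_reps`` uniform without-replacement panels."""
    ground = np.asarray(list(ground), dtype=np.intp)
    if panel_size > ground.size:
        raise ValueError(
            f"panel_size {panel_size} exceeds ground set of {ground.size}"
        )
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    scores = np.empty(n_reps)
    for r in range(n_reps):
        panel = rng.choice(ground, size=panel_size, replace=False)
        scores[r] = coverage_score(panel, ground, sim)
    return scores


def _optimized_score(
    ground: np.ndarray, panel_size: int, sim: SimilarityContainer
) -> float:
    """Greedy panel of the same size within the element's ground set."""
    sub = SimilarityContainer(
        _restrict(sim, ground),
        ExperimentSet([sim.experiments[i] for i in ground]),
    )
    result = greedy_select(sub, SelectionConfig(k=panel_size))
    local = result.indices
    return coverage_score(ground[local], ground, sim)


def coverage_table(
    labels: ExperimentSet,
    sim: SimilarityContainer,
    axis: str = "biosample",
    n_random: int = 10,
    seed: int = 0,
    performed: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full per-element score table with random and optimized baselines.

    For each element with at least one performed experiment: the performed
    score, the score of a greedy-optimized panel of the same size, and
    ``n_random`` random same-size panels.  Each element gets its own RNG
    stream derived from the master seed and the element's position, so
    adding elements does not shift other elements' draws.
    """
    if performed is None:
        performed = labels.performed_mask()
    performed = np.asarray(performed, dtype=bool)
    rows = []
    for pos, (element, members) in enumerate(_axis_groups(labels, axis).items()):
        ground = np.asarray(members, dtype=np.intp)
        if ground.size == 0:  # pragma: no cover - groups are never empty
            continue
        done = ground[performed[ground]]
        size = int(done.size)
        rng = np.random.default_rng(np.random.SeedSequence([seed, pos]))
        randoms = (
            random_baseline_scores(ground, size, n_random, sim, rng)
            if size > 0
            else np.zeros(n_random)
        )
        rows.append(
            {
                "element": element,
                "n_performed": size,
                "n_ground": int(ground.size),
                "performed_score": coverage_score(done, ground, sim),
                "optimized_score": _optimized_score(ground, size, sim),
                "random_mean": float(randoms.mean()),
                "random_scores": ";".join(f"{s:.6g}" for s in randoms),
            }
        )
    return pd.DataFrame(rows)


def rank_correlation(counts: Sequence[float], scores: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties).

    Returns NaN when either vector is constant, where the correlation is
    undefined.
    """
    counts = np.asarray(counts, dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)
    if counts.shape != scores.shape or counts.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.unique(counts).size < 2 or np.unique(scores).size < 2:
        return float("nan")
    rho = stats.spearmanr(counts, scores).statistic
    return float(rho)
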