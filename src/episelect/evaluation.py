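"""Panel-quality evaluation by multi-task linear reconstruction.

A representative panel should suffice to reconstruct the signal of every
track.  Quality is therefore quantified by fitting a multi-output linear
model from the panel tracks to all tracks and reporting held-out
mean-squared error.  To avoid information leaking between stages, bins
are split into three disjoint contiguous blocks: *selection* bins feed
the similarity matrix used to choose panels, *training* bins fit the
regression, *evaluation* bins score it.

The fit is closed-form multi-output ridge regression (the model class is
linear with an MSE loss, so the ridge solution at a tiny stabilizer is
the optimum a gradient optimizer would converge to, without optimizer
stochasticity); a gradient-descent cross-check bounds the substitution
error in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from ._types import BinnedTrack, SimilarityContainer
from .selection import SelectionConfig, greedy_select
from .similarity import assay_average_similarity, pairwise_squared_pearson

__all__ = [
    "BinPartition",
    "LinearReconstruction",
    "partition_bins",
    "fit_linear_reconstruction",
    "evaluate_panel_curve",
    "random_panel_curves",
    "per_biosample_comparison",
]

DEFAULT_RIDGE = 1e-6


@dataclass(frozen=True)
class BinPartition:
    """Three disjoint contiguous bin blocks: selection, training, evaluation."""

    selection: np.ndarray
    training: np.ndarray
    evaluation: np.ndarray

    def __post_init__(self) -> None:
        blocks = [self.selection, self.training, self.evaluation]
        union = np.concatenate(blocks)
        if np.unique(union).size != union.size:
            raise ValueError("partition blocks overlap")


def partition_bins(
    n_bins: int, selection_size: int, training_size: int
) -> BinPartition:
    """Split ``n_bins`` genomic-order bins into selection / training /
    evaluation blocks; the evaluation block is whatever remains."""
    if selection_size < 0 or training_size < 0:
        raise ValueError("block sizes must be non-negative")
    if selection_size + training_size > n_bins:
        raise ValueError(
            f"selection {selection_size} + training {training_size} "
            f"exceed {n_bins} bins"
        )
    a = np.arange(selection_size)
    b = np.arange(selection_size, selection_size + training_size)
    c = np.arange(selection_size + training_size, n_bins)
    return BinPartition(a, b, c)


@dataclass
class LinearReconstruction:
    """Fitted panel -> all-tracks linear map with intercepts."""

    weights: np.ndarray  # (n_panel, n_targets)
    intercept: np.ndarray  # (n_targets,)
    training_mse: float
    ridge: float

    def predict(self, panel: np.ndarray) -> np.ndarray:
        return panel @ self.weights + self.intercept

    def evaluation_mse(self, panel: np.ndarray, targets: np.ndarray) -> float:
        resid = self.predict(panel) - targets
        return float(np.mean(resid**2))


def fit_linear_reconstruction(
    panel: np.ndarray,
    targets: np.ndarray,
    ridge: float = DEFAULT_RIDGE,
) -> LinearReconstruction:
    """Closed-form multi-output ridge fit of targets from panel signal.

    ``panel`` is (n_bins, n_panel), ``targets`` is (n_bins, n_targets).
    Minimizes mean squared error plus ``ridge * ||W||^2``; with ridge = 0
    a rank-deficient design raises and instructs a positive ridge.
    """
    panel = np.asarray(panel, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if panel.ndim != 2 or targets.ndim != 2:
        raise ValueError("panel and targets must be 2-D (bins x tracks)")
    if panel.shape[0] != targets.shape[0]:
        raise ValueError("panel and targets disagree on bin count")
    if panel.shape[1] < 1:
        raise ValueError("panel must contain at least one track")
    if panel.shape[0] < panel.shape[1] + 1:
        raise ValueError("need at least panel size + 1 training bins")
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    x_mean = panel.mean(axis=0)
    y_mean = targets.mean(axis=0)
    xc = panel - x_mean
    yc = targets - y_mean
    gram = xc.T @ xc
    if ridge == 0:
        if np.linalg.matrix_rank(gram) < gram.shape[0]:
            raise np.linalg.LinAlgError(
                "design matrix is rank deficient; pass a positive ridge "
                "stabilizer to fit_linear_reconstruction"
            )
        weights = np.linalg.solve(gram, xc.T @ yc)
    else:
        n = panel.shape[0]
        # loss = MSE + ridge * ||W||^2  =>  (X'X + n * ridge * I) W = X'Y
        weights = np.linalg.solve(
            gram + n * ridge * np.eye(gram.shape[0]), xc.T @ yc
        )
    intercept = y_mean - x_mean @ weights
    fitted = panel @ weights + intercept
    training_mse = float(np.mean((fitted - targets) ** 2))
    return LinearReconstruction(weights, intercept, training_mse, ridge)


def _track_matrix(tracks: Sequence[BinnedTrack]) -> np.ndarray:
    return np.stack([t.values for t in tracks]).astype(np.float64)


def evaluate_panel_curve(
    tracks: Sequence[BinnedTrack],
    ranking: Sequence[int],
    sizes: Sequence[int],
    partition: BinPartition,
    ridge: float = DEFAULT_RIDGE,
) -> np.ndarray:
    """Evaluation-bin MSE of reconstructing all tracks from ranking
    prefixes of the given sizes.

    For each size, the panel is the first ``size`` experiments of the
    ranking; the model is fit on training bins and the reported MSE is
    averaged over evaluation bins, then over target tracks (uniform, so
    the two averages commute into one mean over the residual matrix).
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("sizes list must be non-empty")
    if max(sizes) > len(tracks):
        raise ValueError("panel size exceeds number of available tracks")
    ranking = np.asarray(list(ranking), dtype=np.intp)
    data = _track_matrix(tracks)
    train = data[:, partition.training].T
    evaluate = data[:, partition.evaluation].T
    out = np.empty(len(sizes))
    for i, size in enumerate(sizes):
        panel = ranking[:size]
        model = fit_linear_reconstruction(train[:, panel], train, ridge)
        out[i] = model.evaluation_mse(evaluate[:, panel], evaluate)
    return out


def random_panel_curves(
    tracks: Sequence[BinnedTrack],
    sizes: Sequence[int],
    partition: BinPartition,
    n_draws: int = 20,
    seed: int = 0,
    ridge: float = DEFAULT_RIDGE,
) -> np.ndarray:
    """MSE curves of ``n_draws`` uniformly drawn panels, shape
    (n_draws, n_sizes)."""
    rng = np.random.default_rng(seed)
    n = len(tracks)
    out = np.empty((n_draws, len(list(sizes))))
    for d in range(n_draws):
        ranking = rng.permutation(n)
        out[d] = evaluate_panel_curve(tracks, ranking, sizes, partition, ridge)
    return out


def submodular_ranking_on_bins(
    tracks: Sequence[BinnedTrack], bins: np.ndarray, k: int | None = None
) -> np.ndarray:
    """Greedy facility-location ranking using only the given bins."""
    restricted = [
        BinnedTrack(t.experiment, t.values[bins], t.bin_size) for t in tracks
    ]
    sim = pairwise_squared_pearson(restricted)
    k = len(tracks) if k is None else k
    return greedy_select(sim, SelectionConfig(k=k, engine="lazy")).indices


def per_biosample_comparison(
    tracks: Sequence[BinnedTrack],
    sizes: Sequence[int],
    partition: BinPartition,
    ridge: float = DEFAULT_RIDGE,
) -> dict[str, np.ndarray]:
    """Biosample-specific selection versus the assay-averaged baseline.

    For each biosample, assays are ranked two ways: by greedy selection on
    that biosample's own similarity matrix (selection bins only), and by
    greedy selection on the assay-averaged similarity computed from every
    *other* biosample's tracks.  Each prefix panel reconstructs the
    biosample's full assay set; MSE is averaged over bins, then targets,
    then biosamples.

    Returns ``{"own": per-size mean MSE, "assay_averaged": ...}``.
    """
    sizes = list(sizes)
    by_biosample: dict[str, list[BinnedTrack]] = {}
    for t in tracks:
        by_biosample.setdefault(t.experiment.biosample, []).append(t)
    sel_tracks = [
        BinnedTrack(t.experiment, t.values[partition.selection], t.bin_size)
        for t in tracks
    ]
    global_sim = pairwise_squared_pearson(sel_tracks)
    own_curves, base_curves = [], []
    for biosample, members in by_biosample.items():
        if len(members) < max(sizes):
            continue
        local = [t for t in sel_tracks if t.experiment.biosample == biosample]
        own_sim = pairwise_squared_pearson(local)
        own_rank = greedy_select(
            own_sim, SelectionConfig(k=len(local), engine="lazy")
        ).indices
        assay_sim = assay_average_similarity(
            global_sim,
            performed=np.ones(global_sim.n, dtype=bool),
            exclude_biosample=biosample,
        )
        base_container = assay_sim.as_experiment_similarity(own_sim.experiments)
        base_rank = greedy_select(
            base_container, SelectionConfig(k=len(local))
        ).indices
        own_curves.append(
            evaluate_panel_curve(members, own_rank, sizes, partition, ridge)
        )
        base_curves.append(
            evaluate_panel_curve(members, base_rank, sizes, partition, ridge)
        )
    if not own_curves:
        raise ValueError("no biosample has enough assays for the given sizes")
    return {
        "own": np.mean(own_curves, axis=0),
        "assay_averaged": np.mean(base_curves, axis=0),
    }
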