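"""Reading and writing experiment labels, similarity matrices, weights,
seed lists and rankings.

Label identity is the exact (biosample, assay) string pair; no synonym
normalization is attempted.  Similarity matrices travel either as an HDF5
container (datasets ``similarity``, float64 n x n, and ``labels``, n UTF-8
strings ``"biosample\\tassay"``) or, for small fixtures, as
whitespace-delimited text.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING

import h5py
import numpy as np
import pandas as pd

from ._types import Experiment, ExperimentSet, SimilarityContainer

if TYPE_CHECKING:  # pragma: no cover
    from .selection import SelectionResult

__all__ = [
    "load_experiment_labels",
    "save_experiment_labels",
    "load_similarity",
    "save_similarity",
    "load_weights",
    "load_seeds",
    "save_ranking",
    "load_ranking",
]

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _parse_bool(value, path) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"{path}: cannot parse performed flag {value!r}")


def load_experiment_labels(path: str | os.PathLike) -> ExperimentSet:
    """Read a label TSV with columns biosample, assay, performed.

    Row order is preserved and defines matrix row/column order downstream.
    Duplicate (biosample, assay) pairs are a format error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("biosample", "assay", "performed"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dup = df.duplicated(subset=["biosample", "assay"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate experiment "
            f"({row['biosample']!r}, {row['assay']!r})"
        )
    experiments = [
        Experiment(r.biosample, r.assay, _parse_bool(r.performed, path))
        for r in df.itertuples(index=False)
    ]
    return ExperimentSet(experiments)


def save_experiment_labels(labels: ExperimentSet, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "biosample": [e.biosample for e in labels],
            "assay": [e.assay for e in labels],
            "performed": ["true" if e.performed else "false" for e in labels],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _is_hdf5(path) -> bool:
    try:
        return h5py.is_hdf5(path)
    except OSError:
        return False


def load_similarity(
    path: str | os.PathLike, labels: ExperimentSet
) -> SimilarityContainer:
    """Load a dense n x n similarity matrix and validate it against labels.

    Validation: dimension match, symmetry within 1e-8 (then symmetrized by
    averaging), entries within [0, 1] up to round-off, no NaN.
    """
    metadata: dict = {}
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            matrix = np.asarray(f["similarity"], dtype=np.float64)
            if "labels" in f:
                stored = [s.split("\t") for s in f["labels"].asstr()[()]]
                given = [[e.biosample, e.assay] for e in labels]
                if stored != given:
                    raise ValueError(
                        f"{path}: stored labels do not match the given "
                        "experiment set (order matters)"
                    )
            metadata = dict(f.attrs)
    else:
        matrix = np.loadtxt(path, dtype=np.float64, ndmin=2)
    if matrix.shape != (len(labels), len(labels)):
        raise ValueError(
            f"{path}: matrix shape {matrix.shape} does not match "
            f"{len(labels)} labels"
        )
    return SimilarityContainer(matrix, labels, metadata)


def save_similarity(container: SimilarityContainer, path: str | os.PathLike) -> None:
    """Write the HDF5 dialect: datasets ``similarity`` and ``labels``."""
    with h5py.File(path, "w") as f:
        f.create_dataset("similarity", data=container.values, dtype=np.float64)
        enc = [f"{e.biosample}\t{e.assay}" for e in container.experiments]
        f.create_dataset("labels", data=enc, dtype=h5py.string_dtype("utf-8"))
        for k, v in container.metadata.items():
            f.attrs[k] = v


def load_weights(
    path: str | os.PathLike, labels: ExperimentSet, default: float = 1.0
) -> np.ndarray:
    """Read per-experiment weights; experiments absent from the file get
    ``default``.  Weights must be non-negative; unknown experiments are an
    error."""
    if default < 0:
        raise ValueError("default weight must be non-negative")
    w = np.full(len(labels), float(default))
    df = pd.read_csv(path, sep="\t", dtype={"biosample": str, "assay": str})
    if df.empty:
        return w
    for col in ("biosample", "assay", "weight"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for r in df.itertuples(index=False):
        try:
            i = labels.index_of(r.biosample, r.assay)
        except KeyError:
            raise ValueError(
                f"{path}: weight given for unknown experiment "
                f"({r.biosample!r}, {r.assay!r})"
            ) from None
        weight = float(r.weight)
        if weight < 0:
            raise ValueError(
                f"{path}: negative weight {weight} for "
                f"({r.biosample!r}, {r.assay!r})"
            )
        w[i] = weight
    return w


def load_seeds(path: str | os.PathLike, labels: ExperimentSet) -> np.ndarray:
    """Read a seed list (TSV columns biosample, assay) into label indices."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("biosample", "assay"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    idx = [labels.index_of(r.biosample, r.assay) for r in df.itertuples(index=False)]
    return np.array(sorted(set(idx)), dtype=np.intp)


_RANKING_COLUMNS = [
    "rank",
    "biosample",
    "assay",
    "marginal_gain",
    "cumulative_objective",
]


def save_ranking(result: "SelectionResult", path: str | os.PathLike) -> None:
    """Write a ranking TSV in selection order with 1-based ranks."""
    df = pd.DataFrame(
        {
            "rank": np.arange(1, len(result.selected) + 1),
            "biosample": [e.biosample for e in result.selected],
            "assay": [e.assay for e in result.selected],
            "marginal_gain": result.gains,
            "cumulative_objective": result.objectives,
        },
        columns=_RANKING_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def load_ranking(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"biosample": str, "assay": str})
    missing = [c for c in _RANKING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: ranking file missing columns {missing}")
    return df
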