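"""Core domain containers.

The atoms of the method are *experiments*: (biosample, assay) pairs that
either have been performed or are candidates.  An ordered collection of
experiments defines the row/column order of every matrix attached to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "Experiment",
    "ExperimentSet",
    "SimilarityContainer",
    "BinnedTrack",
    "GenomicRegion",
]

#: Allowed asymmetry before a similarity matrix is rejected outright.
SYMMETRY_TOL = 1e-8
#: Slack on the [0, 1] range of squared correlations.
RANGE_TOL = 1e-8


@dataclass(frozen=True)
class Experiment:
    """A (biosample, assay) pair with a performed/candidate status."""

    biosample: str
    assay: str
    performed: bool = False

    def __post_init__(self) -> None:
        if not self.biosample or not self.assay:
            raise ValueError("biosample and assay labels must be non-empty")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.biosample, self.assay)


class ExperimentSet:
    """Ordered, duplicate-free collection of experiments.

    The order is stable and defines the row/column order of any similarity
    matrix or weight vector aligned to the set.
    """

    def __init__(self, experiments: Iterable[Experiment]):
        self._experiments: list[Experiment] = list(experiments)
        self._index: dict[tuple[str, str], int] = {}
        for i, e in enumerate(self._experiments):
            if e.pair in self._index:
                raise ValueError(
                    f"duplicate experiment (biosample={e.biosample!r}, "
                    f"assay={e.assay!r})"
                )
            self._index[e.pair] = i

    # -- sequence protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._experiments)

    def __iter__(self) -> Iterator[Experiment]:
        return iter(self._experiments)

    def __getitem__(self, i: int) -> Experiment:
        return self._experiments[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExperimentSet):
            return NotImplemented
        return self._experiments == other._experiments

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self._index

    # -- lookups -----------------------------------------------------------
    def index_of(self, biosample: str, assay: str) -> int:
        try:
            return self._index[(biosample, assay)]
        except KeyError:
            raise KeyError(
                f"unknown experiment (biosample={biosample!r}, assay={assay!r})"
            ) from None

    @property
    def biosamples(self) -> list[str]:
        """Distinct biosamples in first-appearance order."""
        return list(dict.fromkeys(e.biosample for e in self._experiments))

    @property
    def assays(self) -> list[str]:
        """Distinct assays in first-appearance order."""
        return list(dict.fromkeys(e.assay for e in self._experiments))

    def by_biosample(self) -> Mapping[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, e in enumerate(self._experiments):
            out.setdefault(e.biosample, []).append(i)
        return out

    def by_assay(self) -> Mapping[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, e in enumerate(self._experiments):
            out.setdefault(e.assay, []).append(i)
        return out

    def performed_indices(self) -> np.ndarray:
        return np.array(
            [i for i, e in enumerate(self._experiments) if e.performed],
            dtype=np.intp,
        )

    def performed_mask(self) -> np.ndarray:
        return np.array([e.performed for e in self._experiments], dtype=bool)

    def assay_codes(self) -> np.ndarray:
        """Integer assay code per experiment, in first-appearance order."""
        order = {a: j for j, a in enumerate(self.assays)}
        return np.array([order[e.assay] for e in self._experiments], dtype=np.intp)

    def biosample_codes(self) -> np.ndarray:
        order = {b: j for j, b in enumerate(self.biosamples)}
        return np.array(
            [order[e.biosample] for e in self._experiments], dtype=np.intp
        )


@dataclass
class SimilarityContainer:
    """Dense symmetric matrix of squared correlations over an ExperimentSet.

    Entries live in [0, 1]; the matrix dimension equals the experiment
    count.  Construction validates and symmetrizes (averaging M with its
    transpose) when the asymmetry is within floating-point tolerance.
    """

    values: np.ndarray
    experiments: ExperimentSet
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.values, dtype=np.float64)
        n = len(self.experiments)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"similarity matrix must be square, got {m.shape}")
        if m.shape[0] != n:
            raise ValueError(
                f"matrix dimension {m.shape[0]} does not match "
                f"{n} experiment labels"
            )
        if np.isnan(m).any():
            raise ValueError("similarity matrix contains NaN entries")
        asym = np.abs(m - m.T).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            raise ValueError(
                f"similarity matrix asymmetry {asym:.3g} exceeds "
                f"tolerance {SYMMETRY_TOL:g}"
            )
        m = (m + m.T) / 2.0
        lo, hi = m.min(initial=0.0), m.max(initial=0.0)
        if lo < -RANGE_TOL or hi > 1.0 + RANGE_TOL:
            raise ValueError(
                f"similarity entries outside [0, 1]: range [{lo:.6g}, {hi:.6g}]"
            )
        self.values = np.clip(m, 0.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.experiments)


@dataclass(frozen=True)
class GenomicRegion:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"region end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class BinnedTrack:
    """Per-bin signal vector for one experiment over the analysis regions.

    Values are in arcsinh-transformed -log10 p-value units unless stated
    otherwise by the producer.
    """

    experiment: Experiment
    values: np.ndarray
    bin_size: int = 25

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError("track values must be one-dimensional")
        if not np.isfinite(v).all():
            raise ValueError(
                f"track {self.experiment.pair} contains non-finite values"
            )
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.values = v
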