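"""From signal tracks to the experiment x experiment similarity matrix.

Signal tracks are -log10 p-values binned over a fixed region list at 25 bp
resolution, arcsinh-transformed to damp outliers, and compared by squared
Pearson correlation.  Squaring makes the similarity invariant to the sign
of the relationship, which matters because, e.g., repressive and active
marks can be strongly anti-correlated yet equally informative about each
other.

Transcription assays arrive as plus/minus strand pairs; since one cannot
perform a single-stranded experiment, strand pairs are merged by adding
the tracks before any comparison.

Also provided is the assay-averaged baseline similarity: the mean, over
biosamples where both assays were performed, of the per-biosample squared
correlation between the two assays.  That matrix is biosample-agnostic by
construction and serves as the comparison point for biosample-specific
selection.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._types import (
    BinnedTrack,
    Experiment,
    ExperimentSet,
    GenomicRegion,
    SimilarityContainer,
)

__all__ = [
    "transform_signal",
    "merge_strand_tracks",
    "merge_all_strand_pairs",
    "bin_track",
    "pairwise_squared_pearson",
    "AssaySimilarityMatrix",
    "assay_average_similarity",
    "read_bedgraph",
    "read_bed_regions",
]

logger = logging.getLogger(__name__)

STRAND_SUFFIXES = ("+", "-")


def transform_signal(values: np.ndarray) -> np.ndarray:
    """Apply arcsinh(v) = ln(v + sqrt(v^2 + 1)) elementwise.

    Input must be finite and non-negative (-log10 p-values).  The transform
    is strictly increasing, so it preserves signal ordering while
    compressing extreme values.
    """
    v = np.asarray(values, dtype=np.float64)
    if np.isnan(v).any() or not np.isfinite(v).all():
        raise ValueError("signal contains NaN or infinite values")
    if (v < 0).any():
        raise ValueError("-log10 p-value signal must be non-negative")
    return np.arcsinh(v)


def _strand_stem(assay: str) -> tuple[str, str | None]:
    if assay.endswith(STRAND_SUFFIXES):
        return assay[:-1], assay[-1]
    return assay, None


def merge_strand_tracks(plus: BinnedTrack, minus: BinnedTrack) -> BinnedTrack:
    """Sum a plus/minus strand pair into one unstranded track.

    Tracks must share biosample, bin size and length; assay names must be
    a +/- pair of the same stem (e.g. ``RNA-seq+`` / ``RNA-seq-``), or be
    identical already-unstranded names.  Tracks already on the arcsinh
    scale are added as-is, mirroring post-hoc addition of transformed
    signal.
    """
    if plus.experiment.biosample != minus.experiment.biosample:
        raise ValueError(
            "strand pair biosamples differ: "
            f"{plus.experiment.biosample!r} vs {minus.experiment.biosample!r}"
        )
    if plus.bin_size != minus.bin_size:
        raise ValueError("strand pair bin sizes differ")
    if len(plus.values) != len(minus.values):
        raise ValueError("strand pair track lengths differ")
    stem_p, s_p = _strand_stem(plus.experiment.assay)
    stem_m, s_m = _strand_stem(minus.experiment.assay)
    if stem_p != stem_m:
        raise ValueError(
            f"assays {plus.experiment.assay!r} and {minus.experiment.assay!r} "
            "are not a strand pair"
        )
    if {s_p, s_m} not in ({"+", "-"}, {None}):
        raise ValueError(
            f"expected one + and one - strand, got {s_p!r} and {s_m!r}"
        )
    merged = Experiment(
        plus.experiment.biosample,
        stem_p,
        plus.experiment.performed or minus.experiment.performed,
    )
    return BinnedTrack(merged, plus.values + minus.values, plus.bin_size)


def merge_all_strand_pairs(tracks: Sequence[BinnedTrack]) -> list[BinnedTrack]:
    """Merge every +/- assay pair in a track collection.

    Unpaired tracks pass through unchanged; a stranded track whose partner
    is missing is an error.  Output order follows first appearance of each
    (biosample, assay-stem).
    """
    pending: dict[tuple[str, str], dict[str, BinnedTrack]] = {}
    order: list[tuple[str, str]] = []
    for t in tracks:
        stem, strand = _strand_stem(t.experiment.assay)
        key = (t.experiment.biosample, stem)
        if key not in pending:
            pending[key] = {}
            order.append(key)
        slot = strand if strand is not None else "."
        if slot in pending[key]:
            raise ValueError(f"duplicate track for {key} strand {slot!r}")
        pending[key][slot] = t
    out: list[BinnedTrack] = []
    for key in order:
        group = pending[key]
        if "." in group:
            if len(group) > 1:
                raise ValueError(f"mixed stranded/unstranded tracks for {key}")
            out.append(group["."])
        elif set(group) == {"+", "-"}:
            out.append(merge_strand_tracks(group["+"], group["-"]))
        else:
            raise ValueError(f"unpaired stranded track for {key}: {set(group)}")
    return out


def read_bed_regions(path: str | os.PathLike) -> list[GenomicRegion]:
    """Read a BED file (0-based half-open) into an ordered region list."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        comment="#",
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return [GenomicRegion(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]


def read_bedgraph(
    path: str | os.PathLike,
) -> Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Read a bedGraph into per-chromosome (starts, ends, values) arrays."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "value"],
        comment="#",
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": np.float64},
    )
    out = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        out[chrom] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp["value"].to_numpy(),
        )
    return out


def bin_track(
    signal: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    regions: Sequence[GenomicRegion],
    bin_size: int = 25,
    experiment: Experiment | None = None,
) -> BinnedTrack:
    """Bin an interval->value signal map over ordered regions.

    Bins tile each region left to right; the bin value is the
    coverage-weighted mean of the signal over the bin, with uncovered base
    pairs contributing zero.  A trailing partial bin of a region is
    dropped.  A region on a chromosome absent from the track yields
    all-zero bins and a logged warning.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    chunks: list[np.ndarray] = []
    for region in regions:
        n_bins = len(region) // bin_size
        acc = np.zeros(n_bins * bin_size, dtype=np.float64)
        if region.chrom not in signal:
            logger.warning(
                "chromosome %s absent from track; filling %d bins with 0",
                region.chrom,
                n_bins,
            )
        else:
            starts, ends, values = signal[region.chrom]
            span_end = region.start + n_bins * bin_size
            lo = np.clip(starts, region.start, span_end)
            hi = np.clip(ends, region.start, span_end)
            for s, e, v in zip(lo, hi, values):
                if e > s and v != 0.0:
                    acc[s - region.start : e - region.start] += v
        chunks.append(acc.reshape(n_bins, bin_size).mean(axis=1))
    exp = experiment or Experiment("unknown", "unknown")
    return BinnedTrack(exp, np.concatenate(chunks) if chunks else np.empty(0), bin_size)


def _normalized_rows(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm; flag zero-variance rows.

    Two-pass computation (mean, then moments) in float64 so the result
    does not depend on summation order quirks of a one-pass update.
    """
    centered = matrix - matrix.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms <= 1e-300
    safe = np.where(constant, 1.0, norms)
    return centered / safe[:, None], constant


def pairwise_squared_pearson(tracks: Sequence[BinnedTrack]) -> SimilarityContainer:
    """Squared Pearson correlation between all pairs of tracks.

    A zero-variance (flat) track is defined to have similarity 0 with
    every other track and 1 with itself: a flat track shares no
    information, but self-similarity must stay maximal so facility
    location bookkeeping keeps the element covering itself.
    """
    if not tracks:
        raise ValueError("no tracks given")
    lengths = {len(t.values) for t in tracks}
    if len(lengths) != 1:
        raise ValueError(f"tracks have differing lengths: {sorted(lengths)}")
    (n_bins,) = lengths
    if n_bins < 2:
        raise ValueError("at least 2 bins required to correlate tracks")
    matrix = np.stack([t.values for t in tracks]).astype(np.float64)
    unit, constant = _normalized_rows(matrix)
    corr = unit @ unit.T
    phi = np.clip(corr**2, 0.0, 1.0)
    phi[constant, :] = 0.0
    phi[:, constant] = 0.0
    np.fill_diagonal(phi, 1.0)
    phi = (phi + phi.T) / 2.0
    labels = ExperimentSet([t.experiment for t in tracks])
    meta = {"bin_size": tracks[0].bin_size, "n_bins": n_bins}
    return SimilarityContainer(phi, labels, meta)


@dataclass
class AssaySimilarityMatrix:
    """Assay x assay mean similarity with per-pair support counts.

    ``values[i, j]`` is the mean of phi between assays i and j across the
    biosamples where both were performed; ``support[i, j]`` counts those
    biosamples.  Unsupported pairs are NaN with support 0.
    """

    assays: list[str]
    values: np.ndarray
    support: np.ndarray

    def as_experiment_similarity(
        self, labels: ExperimentSet, fill: float | None = None
    ) -> SimilarityContainer:
        """Expand to experiment resolution: phi(x, y) depends only on the
        assay pair.  Missing pairs are filled with ``fill`` (default: the
        global mean of supported off-diagonal entries; a neutral value
        since the average is undefined there)."""
        order = {a: i for i, a in enumerate(self.assays)}
        codes = np.array([order[e.assay] for e in labels], dtype=np.intp)
        m = self.values.copy()
        if np.isnan(m).any():
            if fill is None:
                off = ~np.eye(len(self.assays), dtype=bool)
                known = m[off & (self.support > 0)]
                fill = float(known.mean()) if known.size else 0.0
            m[np.isnan(m)] = fill
        expanded = m[np.ix_(codes, codes)]
        np.fill_diagonal(expanded, 1.0)
        return SimilarityContainer(expanded, labels, {"kind": "assay-averaged"})


def assay_average_similarity(
    sim: SimilarityContainer,
    performed: np.ndarray | None = None,
    exclude_biosample: str | None = None,
) -> AssaySimilarityMatrix:
    """Average experiment similarity per assay pair across biosamples.

    For each assay pair (a, b), averages phi between experiment (s, a) and
    (s, b) over biosamples s where both are performed.  When comparing
    against a target biosample, pass ``exclude_biosample`` so the average
    uses only *other* biosamples.
    """
    labels = sim.experiments
    if performed is None:
        performed = labels.performed_mask()
    performed = np.asarray(performed, dtype=bool)
    assays = labels.assays
    a_index = {a: i for i, a in enumerate(assays)}
    k = len(assays)
    total = np.zeros((k, k))
    support = np.zeros((k, k), dtype=np.intp)
    for biosample, members in labels.by_biosample().items():
        if biosample == exclude_biosample:
            continue
        present = [i for i in members if performed[i]]
        for ii, x in enumerate(present):
            ax = a_index[labels[x].assay]
            for y in present[ii:]:
                ay = a_index[labels[y].assay]
                total[ax, ay] += sim.values[x, y]
                support[ax, ay] += 1
                if ax != ay:
                    total[ay, ax] += sim.values[x, y]
                    support[ay, ax] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(support > 0, total / np.maximum(support, 1), np.nan)
    return AssaySimilarityMatrix(assays, values, support)


def tracks_to_assay_average(
    tracks: Sequence[BinnedTrack], exclude_biosample: str | None = None
) -> AssaySimilarityMatrix:
    """Convenience: correlate performed tracks, then average per assay pair."""
    performed = [t for t in tracks if t.experiment.performed]
    if not performed:
        raise ValueError("no performed tracks to average over")
    sim = pairwise_squared_pearson(performed)
    return assay_average_similarity(
        sim, np.ones(len(performed), dtype=bool), exclude_biosample
    )
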