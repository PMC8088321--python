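"""Synthetic experiment generator.

Real imputed signal tracks arise from a low-rank biosample x assay x
position factorization; the generator emulates exactly that structure so
every other module can be exercised without external downloads:

    signal(b, a, p) = softplus( u_b . (g_p * v_a) ) + Normal(0, noise_sd)

with per-biosample latents u_b, per-position latents g_p and per-assay
latents v_a drawn as a class centroid plus small within-class jitter.
Assays in the same activity class (transcription / histone / binding /
accessibility analogues) therefore produce correlated tracks, while
biosample latents modulate which latent dimensions dominate in each
biosample.  The softplus link keeps signal non-negative like -log10
p-values; Gaussian noise is added after the link.

Also provided: stranded track pairs (a transcription track split in two
by a per-position Bernoulli coin, so their sum recovers the unstranded
signal), an "L-shaped" performed mask (a few deeply assayed biosamples
plus a few broadly run assays), and direct block-structured similarity
matrices as fixtures for the selection engines.

One master seed drives everything; latent draws use sub-streams keyed by
axis and index, so configurations differing only in the number of
positions reuse the same biosample and assay latents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._types import BinnedTrack, Experiment, ExperimentSet, SimilarityContainer

__all__ = [
    "GeneratorConfig",
    "generate_tracks",
    "generate_block_similarity",
    "generate_performed_mask",
]

CLASS_NAMES = ("transcription", "histone", "binding", "accessibility")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults give 20 biosamples x 12 assays (240 experiments) over 2000
    25 bp bins with 4 assay activity classes and post-link Gaussian noise
    of standard deviation 0.3 — small against a softplus signal of order
    one, so class structure survives but tracks are not noise-free.
    """

    n_biosamples: int = 20
    n_assays: int = 12
    n_positions: int = 2000
    n_classes: int = 4
    latent_dim: int = 6
    noise_sd: float = 0.3
    n_stranded_pairs: int = 0
    n_deep_biosamples: int = 3
    n_broad_assays: int = 3
    class_jitter: float = 0.25
    biosample_scale: float = 0.3
    bin_size: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        bounds = {
            "n_biosamples >= 1": self.n_biosamples >= 1,
            "n_assays >= 1": self.n_assays >= 1,
            "n_positions >= 1": self.n_positions >= 1,
            "n_classes >= 1": self.n_classes >= 1,
            "latent_dim >= 1": self.latent_dim >= 1,
            "n_classes <= n_assays": self.n_classes <= self.n_assays,
            "2 * n_stranded_pairs <= n_assays": 2 * self.n_stranded_pairs
            <= self.n_assays,
            "n_stranded_pairs >= 0": self.n_stranded_pairs >= 0,
            "noise_sd >= 0": self.noise_sd >= 0,
            "n_deep_biosamples <= n_biosamples": self.n_deep_biosamples
            <= self.n_biosamples,
            "n_broad_assays <= n_assays": self.n_broad_assays <= self.n_assays,
        }
        violated = [name for name, ok in bounds.items() if not ok]
        if violated:
            raise ValueError(f"invalid generator config: {', '.join(violated)}")


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Independent sub-stream for one latent block of the model."""
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


# axis tags for sub-stream keys
_BIOSAMPLE, _ASSAY, _POSITION, _NOISE, _STRAND, _CENTROID = range(6)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def assay_classes(config: GeneratorConfig) -> np.ndarray:
    """Class index per assay; assays are ordered class-contiguously."""
    return np.arange(config.n_assays) * config.n_classes // config.n_assays


def _latents(config: GeneratorConfig):
    d = config.latent_dim
    # Biosample latents share a common component: tracks of the same assay
    # correlate strongly across cell types, with cell-type identity only
    # modulating (not replacing) the assay signature.
    u = np.stack(
        [
            1.0
            + config.biosample_scale
            * _stream(config.seed, _BIOSAMPLE, b).normal(0.0, 1.0, d)
            for b in range(config.n_biosamples)
        ]
    )
    centroids = np.stack(
        [
            _stream(config.seed, _CENTROID, c).normal(0.0, 1.0, d)
            for c in range(config.n_classes)
        ]
    )
    classes = assay_classes(config)
    v = np.stack(
        [
            centroids[classes[a]]
            + _stream(config.seed, _ASSAY, a).normal(0.0, config.class_jitter, d)
            for a in range(config.n_assays)
        ]
    )
    g = _stream(config.seed, _POSITION).normal(0.0, 1.0, (config.n_positions, d))
    return u, v, g, classes


def generate_tracks(
    config: GeneratorConfig,
) -> tuple[list[BinnedTrack], ExperimentSet, dict[str, int]]:
    """Generate the full synthetic cohort.

    Returns the track list (one per experiment; stranded assays emit two
    tracks whose sum is the unstranded signal), the matching experiment
    set with an L-shaped performed mask, and the assay -> class map.
    The first ``n_stranded_pairs`` assays of the transcription class are
    emitted stranded, named ``<assay>+`` / ``<assay>-``.
    """
    u, v, g, classes = _latents(config)
    performed = generate_performed_mask(config)
    class_map: dict[str, int] = {}
    tracks: list[BinnedTrack] = []
    experiments: list[Experiment] = []
    stranded = set(range(config.n_stranded_pairs))
    for b in range(config.n_biosamples):
        biosample = f"B{b:02d}"
        for a in range(config.n_assays):
            assay = f"{CLASS_NAMES[classes[a] % len(CLASS_NAMES)]}-{a:02d}"
            class_map[assay] = int(classes[a])
            clean = _softplus(g @ (u[b] * v[a]))
            noise_rng = _stream(config.seed, _NOISE, b, a)
            signal = clean + noise_rng.normal(0.0, config.noise_sd, config.n_positions)
            flag = bool(performed[b, a])
            if a in stranded:
                coin = _stream(config.seed, _STRAND, b, a).random(config.n_positions)
                plus = signal * coin
                minus = signal * (1.0 - coin)
                for suffix, vals in (("+", plus), ("-", minus)):
                    exp = Experiment(biosample, assay + suffix, flag)
                    experiments.append(exp)
                    tracks.append(BinnedTrack(exp, vals, config.bin_size))
            else:
                exp = Experiment(biosample, assay, flag)
                experiments.append(exp)
                tracks.append(BinnedTrack(exp, signal, config.bin_size))
    return tracks, ExperimentSet(experiments), class_map


def generate_performed_mask(config: GeneratorConfig) -> np.ndarray:
    """L-shaped performed mask over the biosample x assay grid.

    performed[b, a] is True when biosample b is among the first
    ``n_deep_biosamples`` (deeply assayed) or assay a is among the first
    ``n_broad_assays`` (broadly run).  Every biosample and every assay
    must end up with at least one performed experiment — the premise of
    imputation-based selection.
    """
    mask = np.zeros((config.n_biosamples, config.n_assays), dtype=bool)
    mask[: config.n_deep_biosamples, :] = True
    mask[:, : config.n_broad_assays] = True
    if not mask.any(axis=1).all() or not mask.any(axis=0).all():
        raise ValueError(
            "performed mask leaves a biosample or assay without any "
            "performed experiment; increase n_deep_biosamples or "
            "n_broad_assays"
        )
    return mask


def generate_block_similarity(
    block_sizes: Sequence[int],
    within: float = 0.9,
    between: float = 0.1,
    jitter: float = 0.0,
    seed: int = 0,
) -> SimilarityContainer:
    """Direct block-structured similarity fixture.

    Experiments in the same block have similarity ~``within``, across
    blocks ~``between``, unit diagonal.  Each block is labelled as one
    assay, so concentration-term behavior can be read off block
    membership.  Jitter must be small enough to keep the ordering and the
    [0, 1] range.
    """
    if not 0 <= between < within <= 1:
        raise ValueError("require 0 <= between < within <= 1")
    if jitter < 0 or jitter > min(between, 1 - within, (within - between) / 2):
        raise ValueError(
            "jitter must be small enough to preserve block ordering and range"
        )
    sizes = list(block_sizes)
    n = sum(sizes)
    block_of = np.repeat(np.arange(len(sizes)), sizes)
    m = np.where(block_of[:, None] == block_of[None, :], within, between).astype(
        np.float64
    )
    if jitter > 0:
        rng = np.random.default_rng(seed)
        noise = rng.uniform(-jitter, jitter, (n, n))
        noise = (noise + noise.T) / 2.0
        m = m + noise
    np.fill_diagonal(m, 1.0)
    experiments = [
        Experiment(f"B{i:03d}", f"block{block_of[i]}") for i in range(n)
    ]
    return SimilarityContainer(
        m, ExperimentSet(experiments), {"kind": "block-fixture"}
    )
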