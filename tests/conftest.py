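import numpy as np
import pytest

from episelect import (
    Experiment,
    ExperimentSet,
    SimilarityContainer,
    pairwise_squared_pearson,
)
from episelect.synthetic import GeneratorConfig, generate_tracks


def random_similarity(
    n: int, seed: int, n_assays: int | None = None, n_biosamples: int | None = None
) -> SimilarityContainer:
    """Random valid similarity instance over a small labelled ground set."""
    rng = np.random.default_rng(seed)
    m = rng.uniform(0.0, 1.0, (n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    n_assays = n_assays or max(2, n // 3)
    n_biosamples = n_biosamples or max(2, n // 2)
    exps = [
        Experiment(f"B{i % n_biosamples}", f"A{i % n_assays}_{i // n_biosamples}")
        for i in range(n)
    ]
    return SimilarityContainer(m, ExperimentSet(exps))


@pytest.fixture(scope="session")
def default_cohort():
    """Tracks, labels and assay->class map at generator defaults."""
    return generate_tracks(GeneratorConfig())


@pytest.fixture(scope="session")
def default_sim(default_cohort):
    tracks, _, _ = default_cohort
    return pairwise_squared_pearson(tracks)


@pytest.fixture(scope="session")
def experiment_classes(default_cohort):
    """Per-experiment activity class codes aligned to the label order."""
    _, labels, cmap = default_cohort
    per_assay = np.array([cmap[a] for a in labels.assays])
    return per_assay[labels.assay_codes()]
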