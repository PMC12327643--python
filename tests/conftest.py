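import numpy as np
import pytest

import protrep as pr


@pytest.fixture(scope="session")
def vocab():
    return pr.standard_vocabulary()


@pytest.fixture(scope="session")
def strong_signal_data():
    """Planted-signal two-class dataset: positives carry ~8 signal
    insertions per 100 residues, negatives none. Shared across tests that
    exercise recovery, enrichment and the null test."""
    config = pr.GeneratorConfig(
        n_pos=100,
        n_neg=100,
        length_range=(200, 400),
        insertion_rate_pos=8.0,
        insertion_rate_neg=0.0,
        domain_fraction=0.5,
        signal_in_domain_prob=0.9,
        seed=7,
    )
    records, annotations, truth = pr.generate_classification_dataset(config)
    return config, records, annotations, truth


@pytest.fixture(scope="session")
def strong_signal_features(strong_signal_data):
    _, records, _, truth = strong_signal_data
    fm = pr.build_feature_matrix(records)
    labels = np.array([r.label for r in records])
    truth_indices = {fm.feature_names.index(t) for t in truth}
    return fm, labels, truth_indices


@pytest.fixture(scope="session")
def strong_signal_selection(strong_signal_features):
    fm, labels, _ = strong_signal_features
    return pr.bootstrap_selection(fm.values, labels, seed=1)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(pr.STANDARD_AA), size=length))
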