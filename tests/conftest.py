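import numpy as np
import pytest

from apoploc import (
    LabeledDataset,
    ProteinRecord,
    SyntheticSpec,
    build_matrix,
    generate,
    surrogate_pssm,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset() -> LabeledDataset:
    """Three labeled records with surrogate profiles (deterministic)."""
    seqs = {
        "a1": ("ACDEFGHIKLMNPQRSTVWY" * 4, "alpha"),
        "b1": ("KKKEEEDDDRRRHHHAAAGGG" * 4, "beta"),
        "c1": ("WYFWYFWYFILVILVILVMC" * 4, "gamma"),
    }
    records = [ProteinRecord(id=k, sequence=s, label=lbl) for k, (s, lbl) in seqs.items()]
    profiles = {r.id: surrogate_pssm(r, noise_sd=1.5, seed=i) for i, r in enumerate(records)}
    return LabeledDataset(records=records, profiles=profiles)


@pytest.fixture(scope="session")
def separable_matrix():
    """Well-separated 4-class synthetic feature matrix (n=120, d=255)."""
    data = generate(SyntheticSpec(k=4, n_per_class=30, separation=3.0, seed=7))
    return build_matrix(data, seed=7)
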