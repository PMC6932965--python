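import numpy as np
import pytest

from erloc import (FeatureParams, FixtureSpec, LabeledDataset, SVMParams,
                   featurize_table, generate_dataset, load_scales,
                   one_hot_profile)
from erloc.seqio import ALPHABET


@pytest.fixture(scope="session")
def scales():
    return load_scales()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_sequence(rng, length):
    return "".join(rng.choice(list(ALPHABET), size=length))


@pytest.fixture(scope="session")
def motif_dataset(scales):
    """Separable planted-motif dataset featurized at fixture-scale params."""
    spec = FixtureSpec(n_pos=20, n_neg=60, motif_fraction=1.0, seed=7)
    seqs, labels = generate_dataset(spec)
    params = FeatureParams(k=3.0, lam=4, omega=0.1)
    profiles = [one_hot_profile(s) for s in seqs]
    table = featurize_table(seqs, profiles, params, scales)
    data = LabeledDataset(table.to_numpy(), labels["label"].to_numpy(),
                          list(labels["id"]))
    return data, params, SVMParams(c=1000.0, gamma=8.0, w=1.0)
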