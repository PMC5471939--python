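import numpy as np
import pytest

from dilifp.data_io import CompoundRecord, LabeledFingerprintDataset
from dilifp.synthetic import SyntheticSpec, generate


def make_dataset(X, labels, structure_keys=None) -> LabeledFingerprintDataset:
    """Build a small dataset from a nested list and label list."""
    X = np.asarray(X)
    records = []
    for i, lab in enumerate(labels):
        key = structure_keys[i] if structure_keys else f"key{i}"
        records.append(CompoundRecord(compound_id=f"c{i}", label=lab, structure_key=key))
    return LabeledFingerprintDataset(records=records, X=X, n_bits=X.shape[1])


@pytest.fixture
def tiny_ds():
    """3 compounds x 2 bits, labels (pos, pos, neg)."""
    return make_dataset([[1, 0], [1, 1], [0, 1]], ["positive", "positive", "negative"])


@pytest.fixture
def planted_ds():
    """Moderate planted-signal dataset: 60+50 compounds, 120 bits."""
    return generate(
        SyntheticSpec(n_pos=60, n_neg=50, n_bits=120, causal_bits=tuple(range(8)),
                      p_causal_pos=0.7, p_causal_neg=0.1, p_background=0.1, seed=11)
    )


@pytest.fixture
def separable_ds():
    """Deterministic causal bits: linearly separable classes."""
    return generate(
        SyntheticSpec(n_pos=40, n_neg=40, n_bits=100, causal_bits=tuple(range(6)),
                      p_causal_pos=1.0, p_causal_neg=0.0, p_background=0.05, seed=5)
    )
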