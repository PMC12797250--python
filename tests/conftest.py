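import numpy as np
import pytest

from xsar.dataio import Compound, LabelledDataset
from xsar.fingerprints import FingerprintMatrix, FingerprintParams, fingerprint
from xsar.bitmodel import categorize_bits
from xsar.synthetic import default_spec, generate


def make_bits(rows, ids=None, radius=6):
    """FingerprintMatrix from literal bit strings like '10100'."""
    mat = np.array([[int(ch) for ch in row] for row in rows], dtype=np.uint8)
    ids = ids or [f"c{i}" for i in range(len(rows))]
    return FingerprintMatrix(list(ids), mat, FingerprintParams(mat.shape[1], radius))


def make_labelled(binder_rows, nonbinder_rows, split="all"):
    """(FingerprintMatrix, LabelledDataset) pair from literal bit rows.

    The SMILES are placeholders: bit-model arithmetic only consumes the
    matrix and the id partition.
    """
    n_b, n_n = len(binder_rows), len(nonbinder_rows)
    ids = [f"b{i}" for i in range(n_b)] + [f"n{i}" for i in range(n_n)]
    fps = make_bits(list(binder_rows) + list(nonbinder_rows), ids=ids)
    compounds = [Compound(cid, "C", outcome=cid.startswith("b")) for cid in ids]
    return fps, LabelledDataset(compounds, split=split)


@pytest.fixture(scope="session")
def clean_library():
    """Noise-free default synthetic library with fingerprints and model."""
    spec = default_spec(false_negative_rate=0.0, seed=0)
    dataset, truth = generate(spec)
    fps = fingerprint(dataset)
    model = categorize_bits(fps, dataset)
    return spec, dataset, truth, fps, model


@pytest.fixture(scope="session")
def noisy_library():
    """Default library with 30% false-negative label noise (fixed seed)."""
    spec = default_spec(false_negative_rate=0.3, seed=7)
    dataset, truth = generate(spec)
    fps = fingerprint(dataset)
    model = categorize_bits(fps, dataset)
    return spec, dataset, truth, fps, model
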