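import numpy as np
import pytest

from swgcn.io_formats import DiseaseDAG, SequenceSet


@pytest.fixture
def tiny_seqs() -> SequenceSet:
    return SequenceSet(
        ids=("p0", "p1", "p2", "p3"),
        seqs=("ACGTACGTACGT", "ACGTACGAACGT", "TTTTGGGGCCCC", "TTTTGGGCCCCC"),
    )


@pytest.fixture
def chain_dag() -> DiseaseDAG:
    # d -> p -> root
    return DiseaseDAG(
        terms=("root", "p", "d"), edges=(("d", "p"), ("p", "root")), theta=0.5
    )


@pytest.fixture
def sibling_dag() -> DiseaseDAG:
    return DiseaseDAG(
        terms=("root", "d1", "d2"), edges=(("d1", "root"), ("d2", "root")), theta=0.5
    )


@pytest.fixture
def small_assoc() -> np.ndarray:
    rng = np.random.default_rng(7)
    a = (rng.random((30, 6)) < 0.25).astype(float)
    a[a.sum(axis=1) == 0, 0] = 1  # no empty rows for convenience
    return a
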