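import numpy as np
import pytest

from splicestruct.diffsplice import SpliceStructure
from splicestruct.io import JunctionID


def make_structure(counts, gene="G", n_r=None, samples=None, conditions=None):
    """Build a SpliceStructure from a junctions x samples count array.

    By default the first half of the samples is condition A, the second
    half condition B.
    """
    counts = np.asarray(counts)
    n_j, n_s = counts.shape
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n_s)]
    if conditions is None:
        half = n_s // 2
        conditions = ["A"] * half + ["B"] * (n_s - half)
    junctions = [
        JunctionID("chr1", 1000 + i * 100, 1000 + i * 100 + 50, gene) for i in range(n_j)
    ]
    return SpliceStructure(
        gene=gene,
        junctions=junctions,
        samples=list(samples),
        counts=counts,
        condition_of=dict(zip(samples, conditions)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
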