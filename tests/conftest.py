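import numpy as np
import pytest

from treemotif.background import BackgroundModel
from treemotif.seqio import SequenceDataset

ALPHABET = "ACGT"


def random_dataset(rng, n, t):
    """n i.i.d. uniform sequences of width t."""
    return SequenceDataset([
        (f"s{i}", "".join(ALPHABET[c] for c in rng.integers(0, 4, t)))
        for i in range(n)
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def uniform_bg():
    return BackgroundModel.uniform(order=0)


@pytest.fixture
def fasta_file(tmp_path):
    def _write(text, name="in.fa"):
        p = tmp_path / name
        p.write_text(text)
        return p
    return _write
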