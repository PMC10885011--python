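import numpy as np
import pytest

from enhancerlm.sequence_io import DnaSequence
from enhancerlm.synthetic_data import SyntheticSpec, generate_identification_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_record_fasta(tmp_path):
    path = tmp_path / "two.fa"
    path.write_text(">s1\nacgt\n>s2\nGGCC\n")
    return path


@pytest.fixture
def tiny_corpus():
    """Ten short deterministic sequences over ACGT."""
    gen = np.random.default_rng(99)
    bases = np.array(list("ACGT"))
    return [
        DnaSequence(f"seq{i}", "".join(bases[gen.integers(0, 4, size=40)]))
        for i in range(10)
    ]


@pytest.fixture
def small_identification_dataset():
    """Small easy-mode dataset used by several training tests."""
    return generate_identification_dataset(
        SyntheticSpec(n_per_class=60, length=80, gc_positive=0.6, gc_negative=0.4, seed=7)
    )
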