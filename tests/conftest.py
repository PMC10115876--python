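import pytest

from abequant.damage import train_reference_predictor
from abequant.simulate import gen_accessibility_dataset, make_hbe_like_locus


@pytest.fixture(scope="session")
def locus():
    """(amplicon sequence, guide spec, codon interval) for the HbE-like locus."""
    return make_hbe_like_locus(seed=0)


@pytest.fixture(scope="session")
def reference_model():
    """Reference accessibility CNN trained once per session on the default
    synthetic motif dataset (n=4000, seed 7)."""
    seqs, labels, _ = gen_accessibility_dataset(4000, seed=7)
    return train_reference_predictor(seqs, labels, seed=7)
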