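import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture
def worked_record():
    """25-nt record: editable C at index 3 (codon CAA), NGG PAM at index 22.

    The C sits at PAM-relative -19, so an 18-nt spacer (indices 4..21)
    excludes it — the window extends past the spacer's 5' end.
    """
    return "ATGCAA" + "A" * 16 + "TGG"
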