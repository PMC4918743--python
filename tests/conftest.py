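import numpy as np
import pytest

from sigscar import Signature, SignatureSet


@pytest.fixture
def disjoint_signatures() -> SignatureSet:
    """Two signatures with disjoint channel support (exact mixtures are unique)."""
    v1 = np.zeros(96)
    v1[:48] = 1.0 / 48
    v2 = np.zeros(96)
    v2[48:] = 1.0 / 48
    return SignatureSet(
        signatures=[Signature(name="s1", values=v1), Signature(name="s2", values=v2)]
    )


@pytest.fixture
def toy_reference() -> dict[str, str]:
    return {"chr1": "ACGTA", "chr2": "ANGTA"}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
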