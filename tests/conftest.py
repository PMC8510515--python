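from __future__ import annotations

import numpy as np
import pytest

from recprofiler.reference import load_reference


@pytest.fixture(scope="session")
def model():
    return load_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(20210722)


def random_protein(rng, length: int) -> str:
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aa[i] for i in rng.integers(0, 20, size=length))
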