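from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_sequence():
    def _make(n: int, seed: int = 0, probs=(0.25, 0.25, 0.25, 0.25)) -> str:
        gen = np.random.default_rng(seed)
        codes = gen.choice(4, size=n, p=np.asarray(probs))
        return np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()

    return _make
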