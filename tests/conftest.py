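import numpy as np
import pytest

from regland.intervals import GenomicInterval
from regland.motifrank import PWM


@pytest.fixture(scope="session")
def sharp_pwm() -> PWM:
    return PWM.sharp_example()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_start=5000, max_len=300):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_start))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return out


def decoy_pwm(pwm: PWM, k: int) -> PWM:
    """Column- and row-shuffled decoy of a PWM, deterministic per k."""
    r = np.random.default_rng(100 + k)
    mat = pwm.matrix.copy()
    r.shuffle(mat, axis=0)
    for row in mat:
        r.shuffle(row)
    return PWM(f"decoy_{k:02d}", mat / mat.sum(axis=1, keepdims=True))
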