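import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(length: int, seed: int) -> str:
    """Deterministic random DNA helper shared across tests."""
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate_dna(seq: str, n_subs: int, seed: int) -> str:
    """Apply exactly n substitutions at distinct positions."""
    rng = np.random.default_rng(seed)
    arr = bytearray(seq.encode())
    for i in rng.choice(len(seq), size=n_subs, replace=False):
        arr[i] = rng.choice(_BASES[_BASES != arr[i]])
    return arr.decode()


@pytest.fixture
def random_seq():
    return random_dna


@pytest.fixture
def mutate():
    return mutate_dna
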