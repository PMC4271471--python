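import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate_dna(rng, seq: str, sub_rate: float, indel_rate: float = 0.0) -> str:
    """Substitution/indel mutation used to build realistic test pairs."""
    out = []
    bases = "ACGT"
    for ch in seq:
        u = rng.random()
        if u < indel_rate / 2:
            continue  # deletion
        if u < indel_rate:
            out.append(bases[rng.integers(0, 4)])  # insertion before
        if rng.random() < sub_rate:
            ch = bases[(bases.index(ch) + rng.integers(1, 4)) % 4]
        out.append(ch)
    return "".join(out)
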