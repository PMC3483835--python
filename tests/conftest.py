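import numpy as np
import pytest

from turnoverkit import TurnoverParams, rate_constants


@pytest.fixture
def nondividing_params():
    """A moderately unstable protein in quiescent cells."""
    return TurnoverParams(
        mrna_copies=10, translation_rate=2.0, mrna_half_life=0.5, protein_half_life=2.0
    )


@pytest.fixture
def dividing_params():
    """The same protein in cells doubling every 24 h."""
    return TurnoverParams(
        mrna_copies=10,
        translation_rate=2.0,
        mrna_half_life=0.5,
        protein_half_life=2.0,
        doubling_time=24.0,
    )


def random_params(rng: np.random.Generator) -> TurnoverParams:
    """Draw a turnover parameter set with half-lives log-uniform in [0.1, 100] h."""
    return TurnoverParams(
        mrna_copies=float(rng.uniform(1, 50)),
        translation_rate=float(rng.uniform(0.5, 10)),
        mrna_half_life=float(10 ** rng.uniform(-1, 2)),
        protein_half_life=float(10 ** rng.uniform(-1, 2)),
        doubling_time=None if rng.random() < 0.5 else float(rng.uniform(12, 72)),
    )


def sampling_span(params: TurnoverParams, n: int = 7) -> np.ndarray:
    """Times spanning three of the slower of the mRNA / effective protein half-lives."""
    rc = rate_constants(params)
    slow = max(params.mrna_half_life, rc.effective_half_life)
    return np.linspace(0.0, 3.0 * slow, n)
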