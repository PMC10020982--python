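import numpy as np
import pytest

import hscniche as hn


@pytest.fixture
def example_system() -> hn.SystemParams:
    """Fast illustrative single-clone system: K=100, b=0.1, u=0.2, r=1.0,
    d_A=0.5, d_I=1.0 — closed-form equilibrium (N*, A*, I*, E*) =
    (70, 28/3, 14/3, 30)."""
    return hn.example_system()


@pytest.fixture
def example_eq(example_system) -> hn.EquilibriumResult:
    return hn.monoclonal_equilibrium(example_system)


@pytest.fixture
def murine_system() -> hn.SystemParams:
    """Default murine-like homeostatic system (0.4% vacancy, K=10^4)."""
    return hn.homeostatic_murine_system()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
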