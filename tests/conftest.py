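import numpy as np
import pytest

from glottiflow import (
    FluidProperties,
    FlowConditions,
    PrephonatoryParams,
    VibrationMode,
)
from glottiflow.geometry import DiscretizedChannel


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def conditions():
    return FlowConditions()


@pytest.fixture
def convergent_params():
    return PrephonatoryParams(half_gap_inferior=0.1, half_gap_superior=0.02)


@pytest.fixture
def divergent_params():
    return PrephonatoryParams(half_gap_inferior=0.02, half_gap_superior=0.1)


def make_discretized(A, D=None, As=None, Ac=None, spacing=0.012):
    """Hand-built discretized channel for solver-level tests."""
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float) if D is not None else 2.0 * np.sqrt(A / np.pi)
    Pe = 4.0 * A / D
    n = A.size - 1
    return DiscretizedChannel(
        Y=np.arange(A.size) * spacing,
        A=A,
        Pe=Pe,
        D=D,
        spacing=spacing,
        inlet_area_As=float(As if As is not None else A[0]),
        exit_area_An=float(A[-1]),
        expansion_area_Ac=float(Ac if Ac is not None else A[-1]),
    )


@pytest.fixture
def random_channel_factory():
    def make(rng, n=16):
        A = rng.uniform(0.05, 0.4, size=n + 1)
        D = rng.uniform(0.05, 0.4, size=n + 1)
        return make_discretized(A, D, As=rng.uniform(1.0, 3.0), Ac=rng.uniform(0.5, 3.0))

    return make
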