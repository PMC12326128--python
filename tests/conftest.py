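import numpy as np
import pytest

from avnet import KernelSet, ModelParams, build_kernels


def zero_kernels(n):
    """A KernelSet with every coupling zeroed (isolated-unit oracle)."""
    return KernelSet(*[np.zeros((n, n)) for _ in range(13)])

# 0.2 ms is the working integration step for protocol-scale runs; convergence
# against finer steps is asserted in the dynamics and acceptance tests.
WORK_DT = 0.2


@pytest.fixture(scope="session")
def params():
    return ModelParams(dt_ms=WORK_DT)


@pytest.fixture(scope="session")
def kernels(params):
    return build_kernels(params)


@pytest.fixture(scope="session")
def positions(params):
    return params.positions_deg
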