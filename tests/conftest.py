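import numpy as np
import pytest

from ivimseg.model import IVIMParams, SignalCurve, ivim_signal
from ivimseg.simulate import DEFAULT_BVALUES


@pytest.fixture(scope="session")
def bvalues():
    return DEFAULT_BVALUES.copy()


@pytest.fixture
def noiseless_curve(bvalues):
    """Factory for noiseless bi-exponential curves on the default scheme."""

    def make(D=1.0e-3, Dstar=30e-3, f=0.1, S0=1.0):
        params = IVIMParams(D=D, Dstar=Dstar, f=f)
        return SignalCurve(bvalues, ivim_signal(params, bvalues, S0=S0)), params

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
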