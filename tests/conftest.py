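import numpy as np
import pytest
from hypothesis import settings

from sasri.profiles import ScatteringProfile

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

#: Measured lysozyme-series concentrations, mg/mL.
SERIES_CONCENTRATIONS = (2.45, 4.91, 7.40, 9.94, 14.21, 18.56)
LYSOZYME_MW = 14300.0       # g/mol
LYSOZYME_RHO = 1.46         # g/cm³
B22_REF_ML = -3.80e-20      # mL, weakly attractive reference value
RG0_REF = 13.0              # Å
RI_REF = 38.0               # Å


@pytest.fixture
def exp_profile():
    """Noiseless single-exponential Guinier curve: I0=7.3, Rg=13 Å."""
    q = np.linspace(0.008, 0.12, 150)
    i = 7.3 * np.exp(-(q**2) * 169.0 / 3.0)
    return ScatteringProfile(q=q, i=i, di=np.zeros_like(q), label="exp")


@pytest.fixture
def sphere_profile():
    """Noiseless uniform-sphere form-factor curve, R = 16.77 Å."""
    radius = 16.77
    q = np.linspace(0.005, 0.3, 400)
    x = q * radius
    amp = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    i = 4.2 * amp**2
    return ScatteringProfile(q=q, i=i, di=np.zeros_like(q), label="sphere")
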