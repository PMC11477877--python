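import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from lectinquench.spectra import EmissionSpectrum


def gaussian_spectrum(center=344.3, width=18.0, amplitude=100.0,
                      start=300.0, stop=400.0, step=1.0, meta=None):
    wl = start + step * np.arange(int(round((stop - start) / step)) + 1)
    it = amplitude * np.exp(-(((wl - center) / width) ** 2))
    return EmissionSpectrum(wl, it, meta=meta or {})


@pytest.fixture
def gaussian():
    return gaussian_spectrum
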