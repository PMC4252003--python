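import numpy as np
import pytest

from xicquant.ms_io import LCMSMap, Spectrum
from xicquant.xic import XICTrace, XICWindow


def make_trace(intensities, rts=None, mz=500.0):
    """Build an XICTrace from plain intensity (and optional RT) lists."""
    intensities = np.asarray(intensities, dtype=float)
    if rts is None:
        rts = np.arange(intensities.size, dtype=float)
    rts = np.asarray(rts, dtype=float)
    window = XICWindow(mz, mz, mz, float(rts.min()), float(rts.max()))
    return XICTrace(window, rts, intensities, np.arange(intensities.size))


def make_map(scans, interval=1.0):
    """Build an LCMSMap from [(mz_list, intensity_list), ...] per scan."""
    spectra = [
        Spectrum(i, i * interval, np.asarray(mz, float), np.asarray(inten, float))
        for i, (mz, inten) in enumerate(scans)
    ]
    return LCMSMap(spectra)


@pytest.fixture
def two_apex_trace():
    """Fused double peak: apexes 10 and 8 separated by a valley at 4."""
    return make_trace([0.0, 10.0, 4.0, 8.0, 0.0])
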