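"""Signal-to-noise scoring and the four peak acceptance filters.

The S/N estimator sorts the intensity samples descending (I1 >= ... >= In),
takes the median as the baseline, the root-mean-square deviation about that
median (divisor n) as the noise level, and scores (I1 - baseline) / noise.
By default the samples are the full parent trace of a peak, so the baseline
reflects the local background rather than only the peak itself.

Filters, applied in a fixed order (fwhm, undulation, n_spectra, snratio):
minimum FWHM, maximum undulation, minimum number of spectra, minimum S/N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .peakdetect import XICPeak

__all__ = ["SNREstimate", "FilterConfig", "snr", "apply_filters", "FILTER_ORDER"]

FILTER_ORDER = ("fwhm", "undulation", "n_spectra", "snratio")


@dataclass
class SNREstimate:
    baseline: float
    noise: float
    snratio: float
    n: int
    i_max: float
    zero_noise: bool = False


def snr(intensities) -> SNREstimate:
    """S/N of a set of intensity samples: (max - median) / RMS-about-median.

    The noise term uses divisor n (population-style RMS about the median).
    All-equal samples give zero noise; the ratio is then reported as +inf
    with the ``zero_noise`` flag set.  Requires at least two samples.
    """
    x = np.sort(np.asarray(intensities, dtype=float))[::-1]
    n = x.size
    if n < 2:
        raise ValueError("snr needs at least 2 intensity samples")
    if n % 2:
        baseline = float(x[(n + 1) // 2 - 1])
    else:
        baseline = float((x[n // 2 - 1] + x[n // 2]) / 2.0)
    noise = float(math.sqrt(np.sum((x - baseline) ** 2) / n))
    i_max = float(x[0])
    if noise == 0.0:
        return SNREstimate(baseline, 0.0, math.inf, n, i_max, zero_noise=True)
    return SNREstimate(baseline, noise, (i_max - baseline) / noise, n, i_max)


@dataclass
class FilterConfig:
    """Acceptance thresholds; defaults follow the tool's standard tuning.

    ``min_snratio`` defaults to 2.0: with zero-intensity scans omitted from
    traces, the estimator scores an ideal noiseless Gaussian trace at about
    2.2 whatever its height (the score is a shape constant once the trace is
    pure signal), so a cut-off must sit below that to keep perfect peaks.
    """

    min_fwhm: float = 0.05        # minutes
    max_undulation: int = 3
    min_spectra: int = 3
    min_snratio: float = 2.0
    height_fraction: float = 0.5  # used upstream by detect_peaks

    def __post_init__(self) -> None:
        if min(self.min_fwhm, self.max_undulation, self.min_spectra, self.min_snratio) < 0:
            raise ValueError("filter thresholds must be >= 0")
        if not 0 < self.height_fraction < 1:
            raise ValueError("height_fraction must be in (0, 1)")


def _failures(peak: XICPeak, config: FilterConfig) -> list[str]:
    out = []
    if peak.fwhm < config.min_fwhm:
        out.append("fwhm")
    if peak.undulation > config.max_undulation:
        out.append("undulation")
    if peak.n_spectra < config.min_spectra:
        out.append("n_spectra")
    if not (peak.snratio >= config.min_snratio):  # NaN fails too
        out.append("snratio")
    return out


def apply_filters(
    peaks: list[XICPeak], config: FilterConfig | None = None, verbose: bool = False
) -> tuple[list[XICPeak], list[tuple[XICPeak, str]]]:
    """Split peaks into (accepted, rejected-with-reason).

    A peak passes iff fwhm >= min_fwhm, undulation <= max_undulation,
    n_spectra >= min_spectra and snratio >= min_snratio.  The reason is the
    first failing criterion in that order (all failures, comma-joined, with
    ``verbose=True``).
    """
    config = config or FilterConfig()
    accepted: list[XICPeak] = []
    rejected: list[tuple[XICPeak, str]] = []
    for peak in peaks:
        fails = _failures(peak, config)
        if not fails:
            accepted.append(peak)
        else:
            rejected.append((peak, ",".join(fails) if verbose else fails[0]))
    return accepted, rejected
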