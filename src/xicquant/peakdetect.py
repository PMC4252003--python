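"""Chromatographic peak detection inside one XIC trace.

The detector mirrors the percentage-height test: a local-maximum apex is
accepted as a peak top only if a horizontal line drawn at a configurable
fraction of the apex height (default 50%) is crossed by the trace on both
sides.  The peak's start and end are the first local minima at-or-below that
line walking outward from the apex (the trace end if the walk never rises
again).  Raising the fraction therefore splits fused peaks into their
components; lowering it returns the fused envelope as a single peak.

Quantities per accepted peak: trapezoidal area over all trace points between
the boundaries, FWHM by linear interpolation at half the apex height,
undulation (interior strict local minima, a shape-quality count) and the
number of contributing spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .candidates import local_maximum_indices
from .xic import XICTrace, XICWindow

__all__ = [
    "XICPeak",
    "detect_peaks",
    "peak_area",
    "peak_fwhm",
    "peak_undulation",
]


@dataclass
class XICPeak:
    """One detected chromatographic peak, with its quality measures."""

    mz: float                    # target m/z of the parent trace
    apex_rt: float
    apex_intensity: float
    start_rt: float
    start_intensity: float
    end_rt: float
    end_intensity: float
    area: float = 0.0
    fwhm: float = 0.0
    undulation: int = 0
    n_spectra: int = 0
    snratio: float = float("nan")
    window: XICWindow | None = None
    i_start: int = field(default=-1, compare=False)
    i_apex: int = field(default=-1, compare=False)
    i_end: int = field(default=-1, compare=False)


def _walk_boundary(
    inten: np.ndarray, apex: int, step: int, line: float, claimed: np.ndarray
) -> tuple[int, bool]:
    """Walk outward from the apex to the first local minimum at-or-below the
    line.

    Returns (boundary index, whether any point at-or-below the line was met).
    Minima above the line are walked through; a claimed point (boundary of an
    already-accepted peak) or the trace end stops the walk where it stands.
    """
    n = inten.size
    j = apex
    found = False
    below = False  # currently at-or-below the line
    while True:
        nxt = j + step
        if nxt < 0 or nxt >= n:
            return j, found
        j = nxt
        if inten[j] <= line:
            found = True
            below = True
        if claimed[j]:
            return j, found
        probe = j + step
        if below and 0 <= probe < n and inten[probe] > inten[j]:
            # local minimum below the line: this is the boundary
            return j, found
        if below and inten[j] > line:
            below = False


def detect_peaks(trace: XICTrace, height_fraction: float = 0.5) -> list[XICPeak]:
    """Detect peaks in a trace with the percentage-height crossing test.

    Apexes are visited in descending intensity; the points of an accepted
    peak are claimed and cannot seed further apexes, while boundary points
    may be shared between adjacent peaks.  Result is sorted by apex RT.
    """
    if not 0 < height_fraction < 1:
        raise ValueError("height_fraction must be in (0, 1)")
    n = len(trace)
    if n < 2:
        return []
    inten = trace.intensity
    rt = trace.rt
    apexes = local_maximum_indices(inten)
    # descending apex intensity, ties toward earlier RT
    apexes = apexes[np.lexsort((rt[apexes], -inten[apexes]))]
    claimed = np.zeros(n, dtype=bool)
    peaks: list[XICPeak] = []
    for a in apexes:
        if claimed[a]:
            continue
        line = height_fraction * inten[a]
        left, found_l = _walk_boundary(inten, a, -1, line, claimed)
        right, found_r = _walk_boundary(inten, a, +1, line, claimed)
        if not (found_l and found_r):
            continue
        if not (left < a < right):
            continue
        claimed[left : right + 1] = True
        peak = XICPeak(
            mz=trace.window.target_mz,
            apex_rt=float(rt[a]),
            apex_intensity=float(inten[a]),
            start_rt=float(rt[left]),
            start_intensity=float(inten[left]),
            end_rt=float(rt[right]),
            end_intensity=float(inten[right]),
            window=trace.window,
            i_start=int(left),
            i_apex=int(a),
            i_end=int(right),
        )
        peak.area = peak_area(peak, trace)
        peak.fwhm = peak_fwhm(peak, trace)
        peak.undulation = peak_undulation(peak, trace)
        peak.n_spectra = int(right - left + 1)
        peaks.append(peak)
    peaks.sort(key=lambda p: p.apex_rt)
    return peaks


def _bounds(peak: XICPeak, trace: XICTrace) -> tuple[int, int, int]:
    if 0 <= peak.i_start < len(trace) and peak.i_end < len(trace):
        return peak.i_start, peak.i_apex, peak.i_end
    start = int(np.searchsorted(trace.rt, peak.start_rt, side="left"))
    end = int(np.searchsorted(trace.rt, peak.end_rt, side="right")) - 1
    apex = start + int(np.argmax(trace.intensity[start : end + 1]))
    return start, apex, end


def peak_area(peak: XICPeak, trace: XICTrace, mode: str = "trapezoid") -> float:
    """Intensity integral over RT between the peak boundaries, inclusive.

    "trapezoid" integrates every trace point between the boundaries;
    "triangle" uses only the start/apex/end points.
    """
    start, apex, end = _bounds(peak, trace)
    if mode == "triangle":
        idx = np.array([start, apex, end])
        return float(np.trapezoid(trace.intensity[idx], trace.rt[idx]))
    return float(
        np.trapezoid(trace.intensity[start : end + 1], trace.rt[start : end + 1])
    )


def peak_fwhm(peak: XICPeak, trace: XICTrace) -> float:
    """Full width at half the apex intensity, in minutes.

    Each half-height crossing is located by linear interpolation between the
    bracketing trace points on its side of the apex; a side that never drops
    to half inside the peak is clamped at the peak boundary.
    """
    start, apex, end = _bounds(peak, trace)
    inten = trace.intensity
    rt = trace.rt
    half = inten[apex] / 2.0

    def crossing(side: int) -> float | None:
        j = apex
        while True:
            nxt = j + side
            if nxt < start or nxt > end:
                return None
            if inten[nxt] <= half:
                x0, x1 = rt[j], rt[nxt]
                y0, y1 = inten[j], inten[nxt]
                if y0 == y1:
                    return float(x1)
                return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))
            j = nxt

    t_left = crossing(-1)
    t_right = crossing(+1)
    if t_left is None and t_right is None:
        return float(rt[end] - rt[start])
    if t_left is None:
        t_left = float(rt[start])
    if t_right is None:
        t_right = float(rt[end])
    return float(t_right - t_left)


def peak_undulation(peak: XICPeak, trace: XICTrace) -> int:
    """Number of strict interior local minima between the peak boundaries.

    Each counted minimum is one down-up reversal of the profile; smooth
    unimodal peaks score 0 and bumpier shapes score higher.
    """
    start, _, end = _bounds(peak, trace)
    y = trace.intensity[start : end + 1]
    if y.size < 3:
        return 0
    interior = y[1:-1]
    return int(np.count_nonzero((interior < y[:-2]) & (interior < y[2:])))
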