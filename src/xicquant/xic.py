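"""Greedy extracted-ion-chromatogram (XIC) construction.

The builder repeatedly takes the most intense unconsumed candidate (the
target), gathers every unconsumed candidate within the m/z and RT tolerances
(its neighbours), fixes the m/z window to the min/max m/z of that group,
builds one trace point per scan from the raw map inside the window, and marks
target and neighbours consumed.  A target with no neighbours is consumed
alone and yields no trace, so isolated spikes cannot loop forever.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .candidates import CandidatePeak, CandidateSet, CandidatesExhausted, extract_candidates
from .ms_io import LCMSMap

__all__ = [
    "XICWindow",
    "XICTrace",
    "XICConfig",
    "find_neighbours",
    "fix_window",
    "build_xic",
    "consume",
    "run_xic_extraction",
]


@dataclass
class XICWindow:
    """m/z window [mz_low, mz_high] around a target plus its RT extent."""

    target_mz: float
    mz_low: float
    mz_high: float
    rt_low: float
    rt_high: float

    def __post_init__(self) -> None:
        if not (self.mz_low <= self.target_mz <= self.mz_high):
            raise ValueError("target m/z outside window")


@dataclass
class XICTrace:
    """One chromatogram: RT-ordered per-scan intensities inside a window."""

    window: XICWindow
    rt: np.ndarray
    intensity: np.ndarray
    scan_index: np.ndarray
    source_target: CandidatePeak | None = None

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.scan_index = np.asarray(self.scan_index, dtype=int)
        order = np.argsort(self.rt, kind="stable")
        if np.any(np.diff(order) < 0):
            self.rt = self.rt[order]
            self.intensity = self.intensity[order]
            self.scan_index = self.scan_index[order]

    def __len__(self) -> int:
        return int(self.rt.size)


@dataclass
class XICConfig:
    """Tunables of candidate extraction and XIC construction.

    intensity_threshold defaults to the Orbitrap-style 10000 counts; use 100
    for QTOF-style data.  Tolerances are half-widths: the m/z window never
    exceeds 2*mz_tol and the trace spans rt_tol either side of the target.
    """

    intensity_threshold: float = 10000.0
    mz_tol: float = 0.01
    rt_tol: float = 1.0
    aggregate: str = "max"  # per-scan value inside the window: "max" or "sum"

    def __post_init__(self) -> None:
        if self.aggregate not in ("max", "sum"):
            raise ValueError("aggregate must be 'max' or 'sum'")


def find_neighbours(
    target: CandidatePeak, candidates: CandidateSet, mz_tol: float, rt_tol: float
) -> list[CandidatePeak]:
    """Unconsumed candidates within +-mz_tol and +-rt_tol of the target,
    excluding the target itself."""
    idx = candidates.query_window(
        target.mz - mz_tol, target.mz + mz_tol, target.rt - rt_tol, target.rt + rt_tol
    )
    return [candidates.peak(i) for i in idx if i != target.index]


def fix_window(
    target: CandidatePeak, neighbours: list[CandidatePeak], rt_tol: float
) -> XICWindow:
    """Fix the m/z window to the min/max m/z over target plus neighbours."""
    mzs = [target.mz] + [n.mz for n in neighbours]
    return XICWindow(
        target_mz=target.mz,
        mz_low=min(mzs),
        mz_high=max(mzs),
        rt_low=target.rt - rt_tol,
        rt_high=target.rt + rt_tol,
    )


def build_xic(
    window: XICWindow, lcms_map: LCMSMap, aggregate: str = "max"
) -> XICTrace:
    """One trace point per scan inside the window's RT range.

    The point's intensity is the max (or sum) of raw intensities inside
    [mz_low, mz_high] in that scan; scans with nothing in the window are
    omitted, so the trace can be empty.
    """
    rts, intens, scans = [], [], []
    map_rts = lcms_map.retention_times
    lo = int(np.searchsorted(map_rts, window.rt_low, side="left"))
    hi = int(np.searchsorted(map_rts, window.rt_high, side="right"))
    for spec in lcms_map.spectra[lo:hi]:
        a = np.searchsorted(spec.mz, window.mz_low, side="left")
        b = np.searchsorted(spec.mz, window.mz_high, side="right")
        if b <= a:
            continue
        chunk = spec.intensity[a:b]
        value = float(chunk.max() if aggregate == "max" else chunk.sum())
        if value <= 0:
            continue
        rts.append(spec.retention_time)
        intens.append(value)
        scans.append(spec.scan_index)
    return XICTrace(window, np.array(rts), np.array(intens), np.array(scans, dtype=int))


def consume(
    candidates: CandidateSet, target: CandidatePeak, neighbours: list[CandidatePeak]
) -> None:
    """Mark target and neighbours consumed; they never serve again."""
    candidates.consume_indices([target.index] + [n.index for n in neighbours])


def run_xic_extraction(
    lcms_map: LCMSMap, config: XICConfig | None = None
) -> list[XICTrace]:
    """Drain the candidate pool from most to least intense, emitting XICs.

    Each iteration pops the most intense unconsumed candidate, finds its
    neighbourhood, and consumes the group; groups with at least one neighbour
    produce a trace.  Terminates when the pool is exhausted (each iteration
    consumes at least the target, so iterations are bounded by the candidate
    count).
    """
    config = config or XICConfig()
    candidates = extract_candidates(lcms_map, config.intensity_threshold)
    return extract_xics(candidates, lcms_map, config)


def extract_xics(
    candidates: CandidateSet, lcms_map: LCMSMap, config: XICConfig
) -> list[XICTrace]:
    """Run the greedy loop over an existing candidate pool."""
    traces: list[XICTrace] = []
    while True:
        try:
            target = candidates.pop_most_intense()
        except CandidatesExhausted:
            break
        neighbours = find_neighbours(target, candidates, config.mz_tol, config.rt_tol)
        if not neighbours:
            consume(candidates, target, [])
            continue
        window = fix_window(target, neighbours, config.rt_tol)
        trace = build_xic(window, lcms_map, config.aggregate)
        consume(candidates, target, neighbours)
        if len(trace):
            trace.source_target = target
            traces.append(trace)
    return traces
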