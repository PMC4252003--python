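"""Candidate peak extraction and the intensity-ordered candidate pool.

A candidate is one raw data point that is a local intensity maximum along the
m/z axis of its own scan and exceeds the intensity threshold.  The greedy XIC
builder then drains the pool from the most intense candidate downwards, so the
pool supports max-extraction and windowed (m/z, RT) queries over the
unconsumed candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .ms_io import LCMSMap

__all__ = [
    "CandidatePeak",
    "CandidateSet",
    "CandidatesExhausted",
    "extract_candidates",
    "local_maximum_indices",
]


class CandidatesExhausted(Exception):
    """No unconsumed candidate remains; the main loop terminates on this."""


@dataclass
class CandidatePeak:
    mz: float
    rt: float
    intensity: float
    scan_index: int
    consumed: bool = False
    # position in the owning CandidateSet arrays; -1 for free-standing peaks
    index: int = field(default=-1, compare=False)


def local_maximum_indices(intensity: np.ndarray) -> np.ndarray:
    """Indices of local maxima along a 1-D intensity array.

    A run of equal values counts as a single maximum at its leftmost point.
    Runs touching the array boundary are compared against their single
    neighbouring run only.
    """
    y = np.asarray(intensity, dtype=float)
    n = y.size
    if n == 0:
        return np.empty(0, dtype=int)
    if n == 1:
        return np.array([0])
    # starts of runs of equal value
    starts = np.flatnonzero(np.r_[True, y[1:] != y[:-1]])
    run_vals = y[starts]
    higher_left = np.r_[True, run_vals[1:] > run_vals[:-1]]
    higher_right = np.r_[run_vals[:-1] > run_vals[1:], True]
    return starts[higher_left & higher_right]


def extract_candidates(lcms_map: LCMSMap, intensity_threshold: float) -> "CandidateSet":
    """All per-scan local maxima with intensity strictly above the threshold.

    The result is globally ordered by descending intensity (ties: lower m/z,
    then lower RT) and wrapped in a :class:`CandidateSet`.
    """
    if intensity_threshold < 0:
        raise ValueError("intensity_threshold must be >= 0")
    mzs, rts, intens, scans = [], [], [], []
    for spec in lcms_map.spectra:
        if spec.ms_level != 1:
            continue
        idx = local_maximum_indices(spec.intensity)
        if idx.size == 0:
            continue
        keep = spec.intensity[idx] > intensity_threshold
        idx = idx[keep]
        mzs.append(spec.mz[idx])
        rts.append(np.full(idx.size, spec.retention_time))
        intens.append(spec.intensity[idx])
        scans.append(np.full(idx.size, spec.scan_index, dtype=int))
    if mzs:
        mz = np.concatenate(mzs)
        rt = np.concatenate(rts)
        inten = np.concatenate(intens)
        scan = np.concatenate(scans)
    else:
        mz = rt = inten = np.empty(0)
        scan = np.empty(0, dtype=int)
    return CandidateSet(mz, rt, inten, scan)


class CandidateSet:
    """Pool of candidates with max-extraction and windowed range queries.

    Backed by flat numpy arrays: one permutation sorted by (-intensity, m/z,
    RT) with a moving cursor serves pop-most-intense in amortized O(1); a
    second permutation sorted by m/z serves window queries via binary search.
    """

    def __init__(self, mz, rt, intensity, scan_index):
        self.mz = np.asarray(mz, dtype=float)
        self.rt = np.asarray(rt, dtype=float)
        self.intensity = np.asarray(intensity, dtype=float)
        self.scan_index = np.asarray(scan_index, dtype=int)
        n = self.mz.size
        self.consumed = np.zeros(n, dtype=bool)
        self._pop_order = np.lexsort((self.rt, self.mz, -self.intensity))
        self._cursor = 0
        self._mz_order = np.argsort(self.mz, kind="stable")
        self._mz_sorted = self.mz[self._mz_order]
        self._peaks: list[CandidatePeak | None] = [None] * n

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def n_unconsumed(self) -> int:
        return int(np.count_nonzero(~self.consumed))

    def peak(self, i: int) -> CandidatePeak:
        """Materialise candidate *i* as a :class:`CandidatePeak` object."""
        p = self._peaks[i]
        if p is None:
            p = CandidatePeak(
                float(self.mz[i]),
                float(self.rt[i]),
                float(self.intensity[i]),
                int(self.scan_index[i]),
                bool(self.consumed[i]),
                index=i,
            )
            self._peaks[i] = p
        return p

    def peaks(self) -> list[CandidatePeak]:
        """All candidates in descending-intensity order."""
        return [self.peak(i) for i in self._pop_order]

    def pop_most_intense(self) -> CandidatePeak:
        """Most intense unconsumed candidate (not marked consumed).

        Ties are broken toward lower m/z, then lower RT.  Raises
        :class:`CandidatesExhausted` when every candidate is consumed.
        """
        while self._cursor < len(self._pop_order):
            i = self._pop_order[self._cursor]
            if not self.consumed[i]:
                return self.peak(i)
            self._cursor += 1
        raise CandidatesExhausted

    def query_window(
        self, mz_low: float, mz_high: float, rt_low: float, rt_high: float
    ) -> np.ndarray:
        """Indices of unconsumed candidates inside the closed window."""
        lo = np.searchsorted(self._mz_sorted, mz_low, side="left")
        hi = np.searchsorted(self._mz_sorted, mz_high, side="right")
        idx = self._mz_order[lo:hi]
        if idx.size == 0:
            return idx
        mask = (
            ~self.consumed[idx]
            & (self.rt[idx] >= rt_low)
            & (self.rt[idx] <= rt_high)
        )
        return idx[mask]

    def consume_indices(self, indices: Iterable[int]) -> None:
        idx = np.asarray(list(indices), dtype=int)
        if idx.size == 0:
            return
        if np.any(self.consumed[idx]):
            raise AssertionError("double consumption of candidate peaks")
        self.consumed[idx] = True
        for i in idx:
            p = self._peaks[i]
            if p is not None:
                p.consumed = True
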