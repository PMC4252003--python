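"""Evaluation statistics: feature matching, TPR/FPR, Bland-Altman.

TPR and FPR follow the known-peptide bookkeeping used for benchmarking MS1
feature finders: with x the number of unique known entries matched by at
least one detected feature, t the total number of unique known entries, y
the number of features detected in one run and z the average number of
detected features per group, TPR = x/t and FPR = (y - x)/z.  FPR is kept
exactly as defined (it may exceed 1 when y - x > z).

Replicate agreement is summarised Bland-Altman style on matched quantity
pairs: per-pair percentage difference relative to the pair mean, its mean
and SD, and the count of pairs outside the mean +- 2 SD band.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EvaluationCounts",
    "BlandAltman",
    "match_features",
    "match_coordinates",
    "tpr_fpr",
    "bland_altman",
]


@dataclass
class EvaluationCounts:
    x: int          # unique known entries matched
    y: int          # features detected in the run
    z: float        # average features per group
    t: int          # total unique known entries
    tpr: float
    fpr: float


@dataclass
class BlandAltman:
    pairs: list[tuple[float, float]]
    mean_pct_diff: float
    sd_pct_diff: float
    n_within_2sd: int
    n_outside_2sd: int
    outlier_fraction: float  # percent


def _coords(features) -> tuple[np.ndarray, np.ndarray]:
    mz = np.array([f.mono_mz for f in features], dtype=float)
    rt = np.array([f.apex_rt for f in features], dtype=float)
    return mz, rt


def match_coordinates(
    mz_a: np.ndarray,
    rt_a: np.ndarray,
    mz_b: np.ndarray,
    rt_b: np.ndarray,
    mz_tol: float,
    rt_tol: float,
) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest matching of (m/z, RT) coordinate lists.

    Candidate pairs within both tolerances are taken in ascending combined
    normalised distance; every index is matched at most once.
    """
    mz_a = np.asarray(mz_a, float)
    rt_a = np.asarray(rt_a, float)
    mz_b = np.asarray(mz_b, float)
    rt_b = np.asarray(rt_b, float)
    order_b = np.argsort(mz_b, kind="stable")
    mz_b_sorted = mz_b[order_b]
    cand: list[tuple[float, int, int]] = []
    for i in range(mz_a.size):
        lo = np.searchsorted(mz_b_sorted, mz_a[i] - mz_tol, side="left")
        hi = np.searchsorted(mz_b_sorted, mz_a[i] + mz_tol, side="right")
        for j in order_b[lo:hi]:
            dmz = abs(mz_a[i] - mz_b[j])
            drt = abs(rt_a[i] - rt_b[j])
            if drt > rt_tol:
                continue
            # normalised combined distance; a zero tolerance demands equality
            d = math.hypot(
                dmz / mz_tol if mz_tol > 0 else 0.0,
                drt / rt_tol if rt_tol > 0 else 0.0,
            )
            cand.append((d, i, int(j)))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def match_features(
    list_a, list_b, mz_tol: float = 0.01, rt_tol: float = 0.2
) -> list[tuple]:
    """Greedy one-to-one matching of two feature lists by (mono m/z, apex RT)."""
    if not list_a or not list_b:
        return []
    mz_a, rt_a = _coords(list_a)
    mz_b, rt_b = _coords(list_b)
    idx = match_coordinates(mz_a, rt_a, mz_b, rt_b, mz_tol, rt_tol)
    return [(list_a[i], list_b[j]) for i, j in idx]


def tpr_fpr(
    detected,
    truth: list[tuple[float, float]],
    t: int,
    z: float,
    mz_tol: float = 0.01,
    rt_tol: float = 0.2,
) -> EvaluationCounts:
    """TPR/FPR of a detected feature list against known (m/z, RT) entries.

    x counts truth entries matched by at least one feature (unique over the
    truth side), y is the detected count; TPR = x/t, FPR = (y - x)/z.
    """
    if t <= 0 or z <= 0:
        raise ValueError("t and z must be positive")
    y = len(detected)
    x = 0
    if detected and truth:
        mz_d, rt_d = _coords(detected)
        mz_t = np.array([p[0] for p in truth], float)
        rt_t = np.array([p[1] for p in truth], float)
        matched_truth: set[int] = set()
        for j in range(mz_t.size):
            hit = (np.abs(mz_d - mz_t[j]) <= mz_tol) & (np.abs(rt_d - rt_t[j]) <= rt_tol)
            if np.any(hit):
                matched_truth.add(j)
        x = len(matched_truth)
    return EvaluationCounts(x=x, y=y, z=float(z), t=int(t), tpr=x / t, fpr=(y - x) / z)


def bland_altman(pairs, ddof: int = 0) -> BlandAltman:
    """Bland-Altman summary of matched quantity pairs.

    The per-pair statistic is d = 100 * (a - b) / mean(a, b) percent; pairs
    with a + b == 0 are excluded with a warning.  SD uses the population
    divisor by default (``ddof=1`` for the sample divisor).
    """
    kept = []
    for a, b in pairs:
        if a + b == 0:
            warnings.warn("dropping pair with zero mean quantity", stacklevel=2)
            continue
        kept.append((float(a), float(b)))
    if len(kept) < 2:
        raise ValueError("bland_altman needs at least 2 usable pairs")
    arr = np.array(kept)
    d = 100.0 * (arr[:, 0] - arr[:, 1]) / ((arr[:, 0] + arr[:, 1]) / 2.0)
    mean = float(d.mean())
    sd = float(d.std(ddof=ddof))
    inside = np.abs(d - mean) <= 2.0 * sd
    n_in = int(np.count_nonzero(inside))
    n_out = int(d.size - n_in)
    return BlandAltman(
        pairs=kept,
        mean_pct_diff=mean,
        sd_pct_diff=sd,
        n_within_2sd=n_in,
        n_outside_2sd=n_out,
        outlier_fraction=100.0 * n_out / d.size,
    )
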