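"""Isotope envelope clustering, monoisotopic determination, charge merging.

Peptide ions at charge z produce co-eluting peaks spaced ~1.00335/z Th apart.
Clustering steps a 1/z-wide moving window backward and forward from each
target peak (most intense first), collecting co-eluting peaks until the first
empty window per direction.  The charge whose collected envelope best matches
an averagine-style model wins; the monoisotopic member is chosen by sliding
the model over the members and maximising normalised dot-product similarity.

The averagine model approximates a peptide's isotope abundances with a
Poisson distribution whose mean grows linearly with neutral mass (the +1
isotope probability per Da of the average amino-acid composition); below
~1.9 kDa the monoisotopic peak dominates, above it the +1/+2 isotopes take
over, which is what lets the pattern match recognise a weak monoisotopic
member at high mass.

Clusters whose neutral masses and retention times agree are finally merged
across charge states into single quantified features, summing member areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .peakdetect import XICPeak

__all__ = [
    "PROTON_MASS",
    "ISOTOPE_SPACING",
    "IsotopeCluster",
    "Feature",
    "PeakPool",
    "averagine_envelope",
    "cluster_isotopes",
    "determine_monoisotopic",
    "remove_monoisotopic_from_candidates",
    "merge_charge_states",
]

PROTON_MASS = 1.007276
ISOTOPE_SPACING = 1.00335  # average 13C-12C mass difference, Da

# Expected number of +1 heavy-isotope substitutions per Da of peptide, from
# the averagine composition C4.9384 H7.7583 N1.3577 O1.4773 S0.0417 per
# 111.1254 Da and the natural +1 isotope abundances of each element.
_LAMBDA_PER_DA = (
    4.9384 * 0.0107     # 13C
    + 7.7583 * 0.000115  # 2H
    + 1.3577 * 0.00364   # 15N
    + 1.4773 * 0.00038   # 17O
    + 0.0417 * 0.0076    # 33S
) / 111.1254


def averagine_envelope(neutral_mass: float, n_isotopes: int = 10) -> np.ndarray:
    """Model isotope abundances at a neutral mass, normalised to max 1.

    Index k is the relative abundance of the monoisotopic-plus-k member under
    the Poisson approximation with mean ``_LAMBDA_PER_DA * neutral_mass``.
    """
    lam = max(_LAMBDA_PER_DA * float(neutral_mass), 1e-12)
    k = np.arange(n_isotopes, dtype=float)
    log_pmf = k * math.log(lam) - lam - np.array(
        [math.lgamma(i + 1.0) for i in range(n_isotopes)]
    )
    pmf = np.exp(log_pmf)
    return pmf / pmf.max()


@dataclass
class IsotopeCluster:
    """Co-eluting peaks assigned to one charge's isotope envelope.

    ``charge == 0`` marks a singleton whose charge could not be determined.
    """

    members: list[XICPeak]          # sorted by m/z
    charge: int
    monoisotopic_mz: float
    apex_rt: float                  # RT of the most intense member
    cluster_score: float
    member_indices: list[int] = field(default_factory=list, compare=False)

    @property
    def area(self) -> float:
        return float(sum(p.area for p in self.members))

    @property
    def neutral_mass(self) -> float | None:
        if self.charge < 1:
            return None
        return (self.monoisotopic_mz - PROTON_MASS) * self.charge


@dataclass
class Feature:
    """Final quantified entity: one molecule, possibly several charge states."""

    neutral_mass: float | None
    clusters: list[IsotopeCluster]
    total_area: float
    representative: tuple[float, float, int]  # (mono m/z, apex RT, charge)
    flags: str = "-"

    @property
    def mono_mz(self) -> float:
        return self.representative[0]

    @property
    def apex_rt(self) -> float:
        return self.representative[1]

    @property
    def charge(self) -> int:
        return self.representative[2]

    @property
    def n_isotopes(self) -> int:
        rep = max(self.clusters, key=lambda c: c.area)
        return len(rep.members)

    @property
    def representative_peak(self) -> XICPeak:
        rep = max(self.clusters, key=lambda c: c.area)
        return max(rep.members, key=lambda p: p.apex_intensity)


class PeakPool:
    """Accepted peaks with window queries and the two clustering flags.

    ``in_pool`` — still claimable as a cluster member (cleared only for
    monoisotopic members); ``targetable`` — may still seed a cluster of its
    own (cleared for every member of an emitted cluster, so an envelope's
    tail never re-emits as its own cluster while remaining claimable by a
    genuinely overlapping one).
    """

    def __init__(self, peaks: list[XICPeak]):
        self.peaks = list(peaks)
        n = len(self.peaks)
        self.mz = np.array([p.mz for p in self.peaks], dtype=float)
        self.rt = np.array([p.apex_rt for p in self.peaks], dtype=float)
        self.intensity = np.array([p.apex_intensity for p in self.peaks], dtype=float)
        self.in_pool = np.ones(n, dtype=bool)
        self.targetable = np.ones(n, dtype=bool)
        self._mz_order = np.argsort(self.mz, kind="stable")
        self._mz_sorted = self.mz[self._mz_order]

    def __len__(self) -> int:
        return len(self.peaks)

    def query(self, mz_center: float, mz_tol: float, rt_center: float, rt_tol: float) -> np.ndarray:
        lo = np.searchsorted(self._mz_sorted, mz_center - mz_tol, side="left")
        hi = np.searchsorted(self._mz_sorted, mz_center + mz_tol, side="right")
        idx = self._mz_order[lo:hi]
        if idx.size == 0:
            return idx
        mask = self.in_pool[idx] & (np.abs(self.rt[idx] - rt_center) <= rt_tol)
        return idx[mask]


def _slide_mono(
    mzs: np.ndarray, intens: np.ndarray, charge: int
) -> tuple[int, float]:
    """Best monoisotopic hypothesis by sliding the averagine model.

    Hypothesis j declares member j monoisotopic; the model vector is the
    envelope at the implied neutral mass aligned at j, with zeros below it
    (the model has no isotopes lighter than the monoisotopic one, so members
    a hypothesis abandons count against it).  The full member intensity
    vector is compared by cosine similarity; a hypothesis must keep at least
    two members.  Returns (member index, similarity).
    """
    n = len(mzs)
    v = np.asarray(intens, dtype=float)
    if not np.any(v > 0):
        return 0, 0.0
    norm_v = float(np.linalg.norm(v))
    best_j, best_s = 0, -1.0
    for j in range(max(n - 1, 1)):
        mass = max((mzs[j] - PROTON_MASS) * charge, 1.0)
        model = np.zeros(n)
        model[j:] = averagine_envelope(mass, n_isotopes=n - j)
        s = float(v @ model / (norm_v * np.linalg.norm(model)))
        if s > best_s + 1e-9:
            best_j, best_s = j, s
    return best_j, best_s


def determine_monoisotopic(cluster: IsotopeCluster) -> tuple[float, float]:
    """Monoisotopic m/z and pattern-match score for a multi-member cluster."""
    if len(cluster.members) < 2:
        return cluster.members[0].mz, 0.0
    mzs = np.array([p.mz for p in cluster.members])
    intens = np.array([p.apex_intensity for p in cluster.members])
    z = max(cluster.charge, 1)
    j, score = _slide_mono(mzs, intens, z)
    return float(mzs[j]), max(score, 0.0)


def remove_monoisotopic_from_candidates(cluster: IsotopeCluster, pool: PeakPool) -> None:
    """Retire the cluster: remove its monoisotopic member from the pool and
    bar every member from seeding a future cluster (they stay claimable)."""
    for pos, p in zip(cluster.member_indices, cluster.members):
        pool.targetable[pos] = False
        if p.mz == cluster.monoisotopic_mz:
            pool.in_pool[pos] = False


def _collect_members(
    pool: PeakPool, i: int, z: int, mz_tol: float, rt_tol: float, max_isotopes: int
) -> list[int]:
    members = [i]
    taken = {i}
    for direction in (-1, 1):
        for k in range(1, max_isotopes + 1):
            pos = pool.mz[i] + direction * k * ISOTOPE_SPACING / z
            hits = [
                h
                for h in pool.query(pos, mz_tol, pool.rt[i], rt_tol)
                if h not in taken
            ]
            if not hits:
                break  # first empty window ends the envelope in this direction
            h = max(hits, key=lambda j: pool.intensity[j])
            members.append(h)
            taken.add(h)
    return members


def cluster_isotopes(
    peaks: list[XICPeak],
    charges=range(1, 5),
    mz_tol: float = 0.01,
    rt_tol: float = 0.1,
    max_isotopes: int = 8,
    pool: PeakPool | None = None,
) -> list[IsotopeCluster]:
    """Group peaks into isotope clusters, most intense target first.

    For each candidate charge the 1/z moving window collects co-eluting
    peaks until its first empty step per direction; the winning charge
    maximises (member count, envelope similarity, lower charge).  Targets
    with no partner at any charge become charge-0 singletons.
    """
    if pool is None:
        pool = PeakPool(peaks)
    order = np.argsort(-pool.intensity, kind="stable")
    clusters: list[IsotopeCluster] = []
    for i in order:
        if not (pool.targetable[i] and pool.in_pool[i]):
            continue
        best = None  # (n_members, score, -z, member_idx, mono_j)
        for z in charges:
            member_idx = _collect_members(pool, int(i), z, mz_tol, rt_tol, max_isotopes)
            if len(member_idx) < 2:
                continue
            member_idx.sort(key=lambda j: pool.mz[j])
            mzs = pool.mz[member_idx]
            intens = pool.intensity[member_idx]
            mono_j, score = _slide_mono(mzs, intens, z)
            key = (len(member_idx), score, -z)
            if best is None or key > best[0]:
                best = (key, z, member_idx, mono_j)
        if best is None:
            cluster = IsotopeCluster(
                members=[pool.peaks[i]],
                charge=0,
                monoisotopic_mz=float(pool.mz[i]),
                apex_rt=float(pool.rt[i]),
                cluster_score=0.0,
                member_indices=[int(i)],
            )
        else:
            _, z, member_idx, mono_j = best
            members = [pool.peaks[j] for j in member_idx]
            cluster = IsotopeCluster(
                members=members,
                charge=int(z),
                monoisotopic_mz=float(pool.mz[member_idx[mono_j]]),
                apex_rt=float(pool.rt[member_idx[int(np.argmax(pool.intensity[member_idx]))]]),
                cluster_score=float(best[0][1]),
                member_indices=[int(j) for j in member_idx],
            )
        clusters.append(cluster)
        remove_monoisotopic_from_candidates(cluster, pool)
    return clusters


def merge_charge_states(
    clusters: list[IsotopeCluster], mass_tol: float = 0.02, rt_tol: float = 0.2
) -> list[Feature]:
    """Merge clusters of the same molecule at different charges into features.

    Single-linkage over |neutral mass difference| <= mass_tol and
    |apex RT difference| <= rt_tol; charge-0 singletons pass through
    unmerged.  A feature's area is the sum of all member peak areas; its
    representative coordinates come from its largest-area cluster.
    """
    charged = [c for c in clusters if c.charge >= 1]
    singletons = [c for c in clusters if c.charge < 1]

    parent = list(range(len(charged)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    order = sorted(range(len(charged)), key=lambda i: charged[i].neutral_mass)
    masses = [charged[i].neutral_mass for i in order]
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            if masses[b] - masses[a] > mass_tol:
                break
            ca, cb = charged[order[a]], charged[order[b]]
            if abs(ca.apex_rt - cb.apex_rt) <= rt_tol:
                union(order[a], order[b])

    groups: dict[int, list[IsotopeCluster]] = {}
    for i, c in enumerate(charged):
        groups.setdefault(find(i), []).append(c)

    features: list[Feature] = []
    for group in groups.values():
        rep = max(group, key=lambda c: c.area)
        features.append(
            Feature(
                neutral_mass=rep.neutral_mass,
                clusters=group,
                total_area=float(sum(c.area for c in group)),
                representative=(rep.monoisotopic_mz, rep.apex_rt, rep.charge),
            )
        )
    for c in singletons:
        features.append(
            Feature(
                neutral_mass=None,
                clusters=[c],
                total_area=c.area,
                representative=(c.monoisotopic_mz, c.apex_rt, 0),
            )
        )
    return features
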