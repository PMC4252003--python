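"""Isotope clustering, monoisotopic determination and charge merging."""

import numpy as np
import pytest

from xicquant.isotopes import (
    ISOTOPE_SPACING,
    PROTON_MASS,
    Feature,
    IsotopeCluster,
    PeakPool,
    averagine_envelope,
    cluster_isotopes,
    determine_monoisotopic,
    merge_charge_states,
    remove_monoisotopic_from_candidates,
)
from xicquant.peakdetect import XICPeak


def make_peak(mz, intensity, rt=5.0, area=None):
    return XICPeak(
        mz=mz, apex_rt=rt, apex_intensity=intensity,
        start_rt=rt - 0.1, start_intensity=1.0, end_rt=rt + 0.1, end_intensity=1.0,
        area=intensity if area is None else area,
        fwhm=0.1, undulation=0, n_spectra=10, snratio=5.0,
    )


def envelope_peaks(neutral_mass, charge, rt=5.0, height=1e5, n_iso=None):
    """Peaks following the averagine envelope at a given mass and charge."""
    env = averagine_envelope(neutral_mass, 8)
    if n_iso is None:
        n_iso = max(2, int(np.count_nonzero(env >= 0.05)))
    mono = neutral_mass / charge + PROTON_MASS
    return [
        make_peak(mono + k * ISOTOPE_SPACING / charge, height * env[k] / env[0], rt)
        for k in range(n_iso)
    ]


class TestAveragineEnvelope:
    def test_low_mass_is_monoisotopic_dominant(self):
        env = averagine_envelope(1000.0)
        assert env[0] == 1.0 and env[1] < 1.0

    def test_high_mass_peaks_past_the_mono(self):
        env = averagine_envelope(3000.0)
        assert np.argmax(env) >= 1


class TestClustering:
    def test_half_spacing_is_charge_two(self):
        peaks = [make_peak(500.0, 100.0), make_peak(500.5017, 80.0),
                 make_peak(501.0034, 35.0)]
        clusters = cluster_isotopes(peaks)
        assert len(clusters) == 1
        assert clusters[0].charge == 2
        assert len(clusters[0].members) == 3

    def test_unit_spacing_is_charge_one(self):
        peaks = [make_peak(500.0, 100.0), make_peak(501.0034, 40.0)]
        clusters = cluster_isotopes(peaks)
        assert len(clusters) == 1
        assert clusters[0].charge == 1

    def test_lone_peak_is_undetermined_singleton(self):
        clusters = cluster_isotopes([make_peak(700.0, 50.0)])
        assert len(clusters) == 1
        assert clusters[0].charge == 0
        assert clusters[0].monoisotopic_mz == 700.0

    def test_non_coeluting_peak_is_excluded(self):
        peaks = [make_peak(500.0, 100.0), make_peak(500.5017, 80.0, rt=7.0)]
        clusters = cluster_isotopes(peaks, rt_tol=0.1)
        assert all(len(c.members) == 1 for c in clusters)

    def test_member_spacing_matches_charge(self):
        rng = np.random.default_rng(31)
        peaks = []
        for _ in range(20):
            mass = rng.uniform(800, 3000)
            z = int(rng.integers(1, 5))
            peaks.extend(envelope_peaks(mass, z, rt=float(rng.uniform(1, 20))))
        for c in cluster_isotopes(peaks):
            if c.charge >= 1 and len(c.members) >= 2:
                spacings = np.diff([p.mz for p in c.members])
                assert np.all(
                    np.abs(spacings - ISOTOPE_SPACING / c.charge) <= 2 * 0.01
                )

    def test_charge_and_mono_recovery_on_clean_envelopes(self):
        rng = np.random.default_rng(37)
        correct_z = correct_mono = total = 0
        for _ in range(60):
            mass = rng.uniform(800, 4000)
            z = int(rng.integers(1, 5))
            peaks = envelope_peaks(mass, z, height=1e5)
            # S/N ~ 10 relative perturbation of the envelope
            for p in peaks:
                p.apex_intensity *= float(1 + rng.normal(0, 0.1))
            clusters = [c for c in cluster_isotopes(peaks) if len(c.members) >= 2]
            assert clusters
            total += 1
            correct_z += clusters[0].charge == z
            correct_mono += abs(clusters[0].monoisotopic_mz - peaks[0].mz) < 1e-9
        assert correct_z / total >= 0.95
        assert correct_mono / total >= 0.95


class TestMonoisotopic:
    def test_low_mass_mono_is_most_intense(self):
        cluster = IsotopeCluster(
            members=[make_peak(1001.0, 100.0), make_peak(1002.0034, 80.0),
                     make_peak(1003.0067, 35.0)],
            charge=1, monoisotopic_mz=0.0, apex_rt=5.0, cluster_score=0.0,
        )
        mono, score = determine_monoisotopic(cluster)
        assert mono == 1001.0
        assert score > 0.9

    def test_high_mass_weak_mono_recovered_by_shape(self):
        # at ~3 kDa the model envelope peaks on the +1 isotope, so the weak
        # first member is still recognised as monoisotopic
        members = [make_peak(3001.0 + k * ISOTOPE_SPACING, v)
                   for k, v in enumerate([40.0, 100.0, 90.0, 50.0])]
        cluster = IsotopeCluster(members=members, charge=1, monoisotopic_mz=0.0,
                                 apex_rt=5.0, cluster_score=0.0)
        mono, _ = determine_monoisotopic(cluster)
        assert mono == members[0].mz

    def test_unmodellable_pair_falls_back_to_lowest_mz(self):
        members = [make_peak(500.0, 10.0), make_peak(501.0034, 100.0)]
        cluster = IsotopeCluster(members=members, charge=1, monoisotopic_mz=0.0,
                                 apex_rt=5.0, cluster_score=0.0)
        mono, score = determine_monoisotopic(cluster)
        assert mono == 500.0
        assert score < 0.9

    def test_all_zero_intensities_degenerate(self):
        members = [make_peak(500.0, 0.0), make_peak(501.0034, 0.0)]
        cluster = IsotopeCluster(members=members, charge=1, monoisotopic_mz=0.0,
                                 apex_rt=5.0, cluster_score=0.0)
        mono, score = determine_monoisotopic(cluster)
        assert mono == 500.0 and score == 0.0


class TestPoolBookkeeping:
    def test_single_cluster_removes_exactly_the_mono(self):
        peaks = [make_peak(500.0, 100.0), make_peak(500.5017, 80.0)]
        pool = PeakPool(peaks)
        clusters = cluster_isotopes(peaks, pool=pool)
        assert len(clusters) == 1
        assert int(np.count_nonzero(~pool.in_pool)) == 1
        assert not pool.in_pool[0]          # the mono (lowest m/z, most intense)
        assert not pool.targetable.any()    # no member may seed again

    def test_every_mono_removed_exactly_once(self):
        rng = np.random.default_rng(41)
        peaks = []
        for _ in range(15):
            peaks.extend(
                envelope_peaks(rng.uniform(800, 2000), int(rng.integers(1, 4)),
                               rt=float(rng.uniform(1, 30)))
            )
        pool = PeakPool(peaks)
        clusters = cluster_isotopes(peaks, pool=pool)
        n_removed = int(np.count_nonzero(~pool.in_pool))
        assert n_removed == len(clusters)

    def test_overlapping_clusters_may_share_members(self):
        # two charge-1 envelopes offset by one isotope: the second target may
        # claim a member already belonging to the first cluster
        shared = make_peak(1001.0034, 60.0)
        peaks = [make_peak(1000.0, 100.0), shared, make_peak(1002.0067, 55.0)]
        clusters = cluster_isotopes(peaks)
        owners = [c for c in clusters if shared in c.members]
        assert len(owners) >= 1  # shared membership is permitted


class TestChargeMerging:
    def test_same_molecule_two_charge_states(self):
        c2 = IsotopeCluster([make_peak(500.0, 100.0, area=30.0)], 2, 500.0, 5.0, 1.0)
        c3 = IsotopeCluster([make_peak(333.6692, 60.0, area=20.0)], 3, 333.6692, 5.05, 1.0)
        features = merge_charge_states([c2, c3], mass_tol=0.02, rt_tol=0.2)
        assert len(features) == 1
        feat = features[0]
        assert feat.neutral_mass == pytest.approx(997.985, abs=0.01)
        assert feat.total_area == pytest.approx(50.0)

    def test_distinct_masses_stay_apart(self):
        c1 = IsotopeCluster([make_peak(500.0, 10.0)], 1, 500.0, 5.0, 1.0)
        c2 = IsotopeCluster([make_peak(500.5, 10.0)], 1, 500.5, 5.0, 1.0)
        assert len(merge_charge_states([c1, c2], mass_tol=0.02)) == 2

    def test_empty_input(self):
        assert merge_charge_states([]) == []

    def test_rt_separation_prevents_merge(self):
        c2 = IsotopeCluster([make_peak(500.0, 10.0, rt=5.0)], 2, 500.0, 5.0, 1.0)
        c3 = IsotopeCluster([make_peak(333.6692, 10.0, rt=9.0)], 3, 333.6692, 9.0, 1.0)
        assert len(merge_charge_states([c2, c3], rt_tol=0.2)) == 2

    def test_area_conservation(self):
        rng = np.random.default_rng(43)
        clusters = []
        for _ in range(12):
            mass = rng.uniform(800, 2500)
            z = int(rng.integers(1, 5))
            members = [make_peak(mass / z + PROTON_MASS + k * ISOTOPE_SPACING / z,
                                 rng.uniform(10, 100), rt=float(rng.uniform(0, 30)),
                                 area=float(rng.uniform(5, 50)))
                       for k in range(3)]
            clusters.append(IsotopeCluster(members, z, members[0].mz,
                                           members[0].apex_rt, 1.0))
        features = merge_charge_states(clusters)
        total_in = sum(p.area for c in clusters for p in c.members)
        total_out = sum(f.total_area for f in features)
        assert total_out == pytest.approx(total_in, rel=1e-12)

    def test_charge_zero_singletons_pass_through(self):
        c0 = IsotopeCluster([make_peak(700.0, 10.0)], 0, 700.0, 5.0, 0.0)
        (feat,) = merge_charge_states([c0])
        assert feat.neutral_mass is None
        assert feat.charge == 0
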