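"""Map reading (mzML/mzXML), unit handling and feature list round-trips."""

import subprocess

import numpy as np
import pytest

from xicquant.isotopes import IsotopeCluster, Feature
from xicquant.ms_io import (
    EmptyMapError,
    LCMSMap,
    MapReadError,
    Spectrum,
    read_feature_list,
    read_map,
    write_feature_list,
)
from xicquant.peakdetect import XICPeak
from xicquant.synth import SynthConfig, generate_map, serialize_fixture


@pytest.fixture(scope="module")
def small_map():
    cfg = SynthConfig(
        rt_range=(0.0, 2.0), scan_interval=0.2, n_features=2,
        noise_points_per_scan=5.0, rt_margin=0.5, seed=1,
    )
    return generate_map(cfg)[0]


class TestReadMzml:
    def test_round_trip_identity(self, small_map, tmp_path):
        path = tmp_path / "map.mzML"
        serialize_fixture(small_map, path)
        back = read_map(path)
        assert len(back) == len(small_map)
        for a, b in zip(small_map.spectra, back.spectra):
            assert b.retention_time == pytest.approx(a.retention_time, abs=1e-9)
            np.testing.assert_allclose(b.mz, a.mz)
            np.testing.assert_allclose(b.intensity, a.intensity)

    def test_seconds_are_converted_to_minutes(self, small_map, tmp_path):
        path = tmp_path / "map_s.mzML"
        serialize_fixture(small_map, path, rt_unit="second")
        back = read_map(path)
        got = back.retention_times
        np.testing.assert_allclose(got, small_map.retention_times, atol=1e-9)

    def test_ms_level_filter(self, tmp_path):
        spectra = [Spectrum(i, 0.1 * i, [500.0], [10.0], ms_level=1) for i in range(5)]
        spectra += [
            Spectrum(5 + i, 0.5 + 0.01 * i, [300.0], [5.0], ms_level=2)
            for i in range(20)
        ]
        path = tmp_path / "mixed.mzML"
        serialize_fixture(LCMSMap(spectra), path)
        assert len(read_map(path, ms_level_filter=1)) == 5
        assert len(read_map(path, ms_level_filter=2)) == 20

    def test_no_ms1_raises_empty_map(self, tmp_path):
        path = tmp_path / "ms2only.mzML"
        serialize_fixture(
            LCMSMap([Spectrum(0, 0.0, [300.0], [5.0], ms_level=2)]), path
        )
        with pytest.raises(EmptyMapError):
            read_map(path, ms_level_filter=1)

    def test_garbled_file_names_the_scan(self, tmp_path):
        path = tmp_path / "broken.mzML"
        good = tmp_path / "good.mzML"
        serialize_fixture(
            LCMSMap([Spectrum(i, 0.1 * i, [500.0], [10.0]) for i in range(3)]), good
        )
        text = good.read_text()
        path.write_text(text[: int(len(text) * 0.6)])  # truncated mid-document
        with pytest.raises(MapReadError):
            read_map(path)

    def test_unrecognised_format(self, tmp_path):
        path = tmp_path / "junk.xml"
        path.write_text("<notamap/>")
        with pytest.raises(MapReadError):
            read_map(path)


class TestReadMzxml:
    def test_round_trip_identity(self, small_map, tmp_path):
        path = tmp_path / "map.mzXML"
        serialize_fixture(small_map, path)
        back = read_map(path)
        assert len(back) == len(small_map)
        assert back.metadata["format"] == "mzxml"
        for a, b in zip(small_map.spectra, back.spectra):
            assert b.retention_time == pytest.approx(a.retention_time, abs=1e-9)
            np.testing.assert_allclose(b.mz, a.mz)
            np.testing.assert_allclose(b.intensity, a.intensity)


def test_mzml_fixture_parses_in_external_reader(small_map, tmp_path):
    """Independent oracle: Bioconductor mzR reads the written mzML and sees
    the same scan count, RTs (in seconds) and per-scan point counts."""
    path = tmp_path / "oracle.mzML"
    serialize_fixture(small_map, path)
    script = tmp_path / "read.R"
    script.write_text(
        "suppressMessages(library(mzR))\n"
        f"f <- openMSfile('{path}')\n"
        "h <- header(f)\n"
        "cat(nrow(h), '\\n')\n"
        "cat(h$retentionTime, '\\n')\n"
        "cat(h$peaksCount, '\\n')\n"
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    lines = out.stdout.strip().splitlines()
    assert int(lines[0]) == len(small_map)
    rts = np.array([float(v) for v in lines[1].split()])
    np.testing.assert_allclose(rts, small_map.retention_times * 60.0, atol=1e-6)
    counts = [int(v) for v in lines[2].split()]
    assert counts == [s.n_points for s in small_map.spectra]


def _fake_features(n):
    feats = []
    rng = np.random.default_rng(8)
    for i in range(n):
        mz = float(rng.uniform(400, 1200))
        rt = float(rng.uniform(1, 20))
        peak = XICPeak(
            mz=mz, apex_rt=rt, apex_intensity=float(rng.uniform(1e4, 1e6)),
            start_rt=rt - 0.2, start_intensity=10.0,
            end_rt=rt + 0.2, end_intensity=10.0,
            area=float(rng.uniform(1e3, 1e6)), fwhm=0.1, undulation=1,
            n_spectra=12, snratio=4.5,
        )
        cluster = IsotopeCluster([peak], charge=2, monoisotopic_mz=mz,
                                 apex_rt=rt, cluster_score=0.9)
        feats.append(
            Feature(
                neutral_mass=cluster.neutral_mass, clusters=[cluster],
                total_area=peak.area, representative=(mz, rt, 2),
            )
        )
    return feats


class TestFeatureList:
    def test_empty_list_is_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_feature_list([], path)
        assert len(path.read_text().strip().splitlines()) == 1

    def test_row_count(self, tmp_path):
        path = tmp_path / "three.tsv"
        write_feature_list(_fake_features(3), path)
        assert len(path.read_text().strip().splitlines()) == 4

    def test_round_trip_to_printed_precision(self, tmp_path):
        feats = _fake_features(10)
        path = tmp_path / "feats.tsv"
        write_feature_list(feats, path)
        df = read_feature_list(path)
        assert len(df) == len(feats)
        # deterministic ordering: descending area, ties by ascending m/z
        assert list(df["area"]) == sorted(df["area"], reverse=True)
        by_area = sorted(feats, key=lambda f: (-f.total_area, f.mono_mz))
        for row, feat in zip(df.itertuples(), by_area):
            assert row.mono_mz == pytest.approx(feat.mono_mz, rel=1e-6)
            assert row.area == pytest.approx(feat.total_area, rel=1e-6)
            assert row.apex_rt == pytest.approx(feat.apex_rt, rel=1e-6)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\n1\t2\n")
        with pytest.raises(ValueError):
            read_feature_list(path)
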