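"""Reading LC-MS maps and writing feature lists.

The in-memory representation is a list of :class:`Spectrum` objects (one per
scan, m/z-sorted point arrays) wrapped in an :class:`LCMSMap`.  Retention time
is minutes everywhere inside the package, regardless of the unit used by the
source file.

Both mzML 1.1 and mzXML 3.x are supported for reading.  The parsers here are
deliberately minimal: they understand centroid/profile MS1 point lists with
the standard binary encodings (32/64-bit float, optional zlib), which is all
this pipeline consumes.  Feature lists are written as plain TSV.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "Spectrum",
    "LCMSMap",
    "MapReadError",
    "EmptyMapError",
    "read_map",
    "write_feature_list",
    "read_feature_list",
    "FEATURE_COLUMNS",
]


class MapReadError(ValueError):
    """The file could not be parsed as an LC-MS map."""


class EmptyMapError(MapReadError):
    """The file contained no spectra at the requested MS level."""


@dataclass
class Spectrum:
    """One scan: m/z-sorted point arrays plus retention time in minutes."""

    scan_index: int
    retention_time: float
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.retention_time < 0:
            raise ValueError(f"negative retention time {self.retention_time}")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity in spectrum")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def n_points(self) -> int:
        return int(self.mz.size)


@dataclass
class LCMSMap:
    """A run: spectra sorted by retention time plus source metadata."""

    spectra: list[Spectrum]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [s.retention_time for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            self.spectra = sorted(self.spectra, key=lambda s: s.retention_time)

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def retention_times(self) -> np.ndarray:
        return np.array([s.retention_time for s in self.spectra], dtype=float)

    def ms1(self) -> "LCMSMap":
        """A view of this map keeping only MS1 scans."""
        return LCMSMap(
            [s for s in self.spectra if s.ms_level == 1], dict(self.metadata)
        )


# ---------------------------------------------------------------------------
# binary array decoding shared by mzML / mzXML
# ---------------------------------------------------------------------------

def _decode_array(
    b64_text: str, dtype: str, compressed: bool, byte_order: str = "<"
) -> np.ndarray:
    raw = base64.b64decode(b64_text.encode("ascii"))
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=np.dtype(byte_order + dtype)).astype(float)


def _localname(el) -> str:
    tag = el.tag
    return tag.rsplit("}", 1)[-1] if "}" in tag else tag


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

_MZML_ACC = {
    "ms_level": "MS:1000511",
    "scan_start": "MS:1000016",
    "f64": "MS:1000523",
    "f32": "MS:1000521",
    "zlib": "MS:1000574",
    "no_comp": "MS:1000576",
    "mz_array": "MS:1000514",
    "int_array": "MS:1000515",
}


def _mzml_spectrum(el, ordinal: int) -> Spectrum:
    sid = el.get("id", f"#{ordinal}")
    ms_level = 1
    rt_min = None
    arrays: dict[str, np.ndarray] = {}
    for cv in el.iter():
        name = _localname(cv)
        if name == "cvParam":
            acc = cv.get("accession", "")
            if acc == _MZML_ACC["ms_level"]:
                ms_level = int(cv.get("value"))
            elif acc == _MZML_ACC["scan_start"]:
                val = float(cv.get("value"))
                unit = (cv.get("unitName") or "").lower()
                # mzML may state RT in seconds or minutes; normalise to minutes
                rt_min = val / 60.0 if unit.startswith("second") else val
        elif name == "binaryDataArray":
            dtype = "f8"
            compressed = False
            kind = None
            text = ""
            for sub in cv.iter():
                sname = _localname(sub)
                if sname == "cvParam":
                    acc = sub.get("accession", "")
                    if acc == _MZML_ACC["f32"]:
                        dtype = "f4"
                    elif acc == _MZML_ACC["f64"]:
                        dtype = "f8"
                    elif acc == _MZML_ACC["zlib"]:
                        compressed = True
                    elif acc == _MZML_ACC["mz_array"]:
                        kind = "mz"
                    elif acc == _MZML_ACC["int_array"]:
                        kind = "intensity"
                elif sname == "binary":
                    text = sub.text or ""
            if kind is not None:
                try:
                    arrays[kind] = _decode_array(text, dtype, compressed)
                except Exception as exc:  # noqa: BLE001 - rewrap with scan id
                    raise MapReadError(
                        f"could not decode {kind} array of spectrum {sid!r}: {exc}"
                    ) from exc
    if "mz" not in arrays or "intensity" not in arrays:
        raise MapReadError(f"spectrum {sid!r} lacks m/z or intensity array")
    if arrays["mz"].size != arrays["intensity"].size:
        raise MapReadError(f"spectrum {sid!r} has mismatched array lengths")
    if rt_min is None:
        raise MapReadError(f"spectrum {sid!r} has no scan start time")
    return Spectrum(ordinal, rt_min, arrays["mz"], arrays["intensity"], ms_level)


def _read_mzml(path: Path) -> list[Spectrum]:
    spectra = []
    try:
        for _, el in etree.iterparse(str(path), tag="{*}spectrum"):
            spectra.append(_mzml_spectrum(el, len(spectra)))
            el.clear(keep_tail=True)
    except etree.XMLSyntaxError as exc:
        raise MapReadError(
            f"{path}: malformed mzML near spectrum {len(spectra)}: {exc}"
        ) from exc
    return spectra


# ---------------------------------------------------------------------------
# mzXML
# ---------------------------------------------------------------------------

def _parse_mzxml_rt(text: str, scan_num: str) -> float:
    # xsd:duration, e.g. "PT123.4S" or "PT2.1M"
    t = text.strip()
    if not t.startswith("PT"):
        raise MapReadError(f"scan {scan_num}: unsupported retentionTime {text!r}")
    body, unit = t[2:-1], t[-1]
    val = float(body)
    if unit == "S":
        return val / 60.0
    if unit == "M":
        return val
    raise MapReadError(f"scan {scan_num}: unsupported retentionTime unit {unit!r}")


def _read_mzxml(path: Path) -> list[Spectrum]:
    spectra = []
    try:
        for _, el in etree.iterparse(str(path), tag="{*}scan"):
            num = el.get("num", str(len(spectra)))
            ms_level = int(el.get("msLevel", "1"))
            rt = _parse_mzxml_rt(el.get("retentionTime", ""), num)
            peaks_el = None
            for sub in el:
                if _localname(sub) == "peaks":
                    peaks_el = sub
                    break
            if peaks_el is None:
                raise MapReadError(f"scan {num} has no peaks element")
            precision = peaks_el.get("precision", "32")
            dtype = "f8" if precision == "64" else "f4"
            compressed = peaks_el.get("compressionType", "none") == "zlib"
            try:
                flat = _decode_array(peaks_el.text or "", dtype, compressed, ">")
            except Exception as exc:  # noqa: BLE001
                raise MapReadError(f"could not decode peaks of scan {num}: {exc}") from exc
            if flat.size % 2:
                raise MapReadError(f"scan {num}: odd peaks array length")
            # pairOrder is m/z-int in mzXML 3.x
            spectra.append(Spectrum(len(spectra), rt, flat[0::2], flat[1::2], ms_level))
            el.clear(keep_tail=True)
    except etree.XMLSyntaxError as exc:
        raise MapReadError(
            f"{path}: malformed mzXML near scan {len(spectra)}: {exc}"
        ) from exc
    return spectra


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mzml":
        return "mzml"
    if suffix == ".mzxml":
        return "mzxml"
    with open(path, "rb") as fh:
        head = fh.read(4096).lower()
    if b"<mzxml" in head:
        return "mzxml"
    if b"<mzml" in head or b"<indexedmzml" in head:
        return "mzml"
    raise MapReadError(f"{path}: not recognisable as mzML or mzXML")


def read_map(path, ms_level_filter: int = 1) -> LCMSMap:
    """Read an mzML/mzXML file into an :class:`LCMSMap` of one MS level.

    Parameters
    ----------
    path:
        mzML or mzXML file (format detected from the extension, falling back
        to sniffing the first bytes).
    ms_level_filter:
        MS level to retain, default 1 (survey scans).  Retention times are
        converted to minutes whatever unit the file uses.

    Raises
    ------
    MapReadError
        Malformed file; the message names the offending scan.
    EmptyMapError
        No spectra at the requested MS level.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path)
    spectra = _read_mzml(path) if fmt == "mzml" else _read_mzxml(path)
    kept = [s for s in spectra if s.ms_level == ms_level_filter]
    if not kept:
        raise EmptyMapError(
            f"{path}: no MS{ms_level_filter} spectra (file has {len(spectra)} scans)"
        )
    for i, s in enumerate(kept):
        s.scan_index = i
    return LCMSMap(kept, {"source": str(path), "format": fmt})


# ---------------------------------------------------------------------------
# feature list TSV
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = [
    "mono_mz",
    "charge",
    "apex_rt",
    "rt_start",
    "rt_end",
    "area",
    "snratio",
    "n_isotopes",
    "n_spectra",
    "undulation",
    "flags",
]


def _feature_row(f) -> dict:
    rep = f.representative_peak
    return {
        "mono_mz": f.mono_mz,
        "charge": f.charge,
        "apex_rt": f.apex_rt,
        "rt_start": rep.start_rt,
        "rt_end": rep.end_rt,
        "area": f.total_area,
        "snratio": rep.snratio if np.isfinite(rep.snratio) else np.inf,
        "n_isotopes": f.n_isotopes,
        "n_spectra": rep.n_spectra,
        "undulation": rep.undulation,
        "flags": f.flags or "-",
    }


def write_feature_list(features: Sequence, path) -> None:
    """Write features as a TSV table, descending area (ties: m/z ascending)."""
    rows = [_feature_row(f) for f in features]
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["area", "mono_mz"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_list(path) -> pd.DataFrame:
    """Read a feature list TSV back into a DataFrame."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("mono_mz", "apex_rt", "area") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: feature list lacks columns {missing}")
    return df
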