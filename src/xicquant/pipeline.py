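"""End-to-end feature detection: candidates -> XICs -> peaks -> features.

One :class:`PipelineConfig` object carries every tunable of the stages with
instrument presets for the extraction threshold ("orbitrap": 10000 counts,
"qtof": 100 counts).  The config round-trips through a flat key=value text
file; unknown keys are rejected.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path

from .candidates import extract_candidates
from .filters import FilterConfig, apply_filters, snr
from .isotopes import Feature, cluster_isotopes, merge_charge_states
from .ms_io import LCMSMap
from .peakdetect import XICPeak, detect_peaks
from .xic import XICConfig, extract_xics

__all__ = ["PipelineConfig", "PRESETS", "detect_features"]

PRESETS = {"orbitrap": 10000.0, "qtof": 100.0}


@dataclass
class PipelineConfig:
    """All tunables of the detection pipeline."""

    # candidate extraction / XIC construction
    intensity_threshold: float = 10000.0
    mz_tol: float = 0.01           # Th, half-width of the XIC window
    rt_tol: float = 1.0            # minutes, half-extent of the XIC
    aggregate: str = "max"         # per-scan aggregation inside the window
    # peak detection / filtering
    height_fraction: float = 0.5
    min_fwhm: float = 0.05         # minutes
    max_undulation: int = 3
    min_spectra: int = 3
    min_snratio: float = 2.0
    area_mode: str = "trapezoid"   # or "triangle"
    snr_scope: str = "trace"       # intensity samples fed to snr()
    # isotope clustering / charge merging
    charge_min: int = 1
    charge_max: int = 4
    iso_mz_tol: float = 0.01       # Th
    iso_rt_tol: float = 0.1        # minutes, apex co-elution
    max_isotopes: int = 8
    merge_mass_tol: float = 0.02   # Da on neutral mass
    merge_rt_tol: float = 0.2      # minutes

    def with_preset(self, preset: str) -> "PipelineConfig":
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        return replace(self, intensity_threshold=PRESETS[preset])

    def xic_config(self) -> XICConfig:
        return XICConfig(
            intensity_threshold=self.intensity_threshold,
            mz_tol=self.mz_tol,
            rt_tol=self.rt_tol,
            aggregate=self.aggregate,
        )

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            min_fwhm=self.min_fwhm,
            max_undulation=self.max_undulation,
            min_spectra=self.min_spectra,
            min_snratio=self.min_snratio,
            height_fraction=self.height_fraction,
        )

    # -- flat key=value config file -------------------------------------
    def to_file(self, path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path, base: "PipelineConfig | None" = None) -> "PipelineConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for ln, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{ln}: unknown key {key!r}")
            kwargs[key] = value
        defaults = base if base is not None else cls()
        coerced = {}
        for key, value in kwargs.items():
            current = getattr(cls(), key)
            coerced[key] = type(current)(value)
        return replace(defaults, **coerced)


def detect_features(
    lcms_map: LCMSMap, config: PipelineConfig | None = None
) -> tuple[list[Feature], dict]:
    """Run the full pipeline on one MS1 map.

    Returns the final feature list plus a run report with per-stage counts
    and wall time.
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    ms1 = lcms_map.ms1()

    candidates = extract_candidates(ms1, config.intensity_threshold)
    n_candidates = len(candidates)
    traces = extract_xics(candidates, ms1, config.xic_config())

    peaks: list[XICPeak] = []
    for trace in traces:
        detected = detect_peaks(trace, config.height_fraction)
        if not detected:
            continue
        if len(trace) >= 2:
            trace_snr = snr(trace.intensity)
        else:
            trace_snr = None
        for p in detected:
            if config.area_mode == "triangle":
                from .peakdetect import peak_area

                p.area = peak_area(p, trace, mode="triangle")
            if config.snr_scope == "peak":
                seg = trace.intensity[p.i_start : p.i_end + 1]
                p.snratio = snr(seg).snratio if seg.size >= 2 else float("nan")
            else:
                p.snratio = trace_snr.snratio if trace_snr else float("nan")
        peaks.extend(detected)

    accepted, rejected = apply_filters(peaks, config.filter_config())
    clusters = cluster_isotopes(
        accepted,
        charges=range(config.charge_min, config.charge_max + 1),
        mz_tol=config.iso_mz_tol,
        rt_tol=config.iso_rt_tol,
        max_isotopes=config.max_isotopes,
    )
    features = merge_charge_states(
        clusters, mass_tol=config.merge_mass_tol, rt_tol=config.merge_rt_tol
    )
    report = {
        "n_scans": len(ms1),
        "n_candidates": n_candidates,
        "n_traces": len(traces),
        "n_peaks_detected": len(peaks),
        "n_peaks_accepted": len(accepted),
        "n_peaks_rejected": len(rejected),
        "n_clusters": len(clusters),
        "n_features": len(features),
        "wall_time_s": time.perf_counter() - t0,
    }
    return features, report
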