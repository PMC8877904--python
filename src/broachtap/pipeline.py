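"""End-to-end analysis orchestration.

``run_analysis`` takes a recording (path or in-memory), an optional
per-blow depth table, and an :class:`AnalysisConfig`, and runs the full
chain: blow segmentation -> per-blow ESD -> peak search -> band
assignment -> per-band drift and convergence fits -> pairwise fit
comparisons -> energy bookkeeping.  The result is an
:class:`AnalysisReport` that serialises deterministically to JSON.

When a depth table is present the fits use depth advance (mm, rebased to
the first measurement) as the x variable; otherwise blow index is used
and flagged in the report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .audio_io import Recording, read_wav, read_depth_table
from .errors import ConfigError, EmptyReportError
from .fit_stats import (
    ExpFit,
    LinearFit,
    compare_fits_ftest,
    fit_exponential,
    fit_linear,
)
from .metrics import build_blow_records, energy_per_mm, records_to_frame
from .segmentation import SegmentationConfig, detect_blows, noise_scale, windows_to_frame
from .spectral import (
    NominalBands,
    aggregate_esd,
    assign_bands,
    compute_esd,
    find_esd_peaks,
    observations_to_frame,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "compare_conditions"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunables of an end-to-end run, YAML-serialisable."""

    window_length: float = 0.2
    threshold_factor: float = 12.0
    refractory: float = 0.2
    band_centers: tuple = (1400.0, 2500.0, 3150.0, 4700.0)
    band_half_width: float = 150.0
    min_peak_distance: float = 300.0  # Hz
    min_height_factor: float = 5.0  # x median ESD
    blow_energy_j: float | None = None  # enables the energy summary
    aggregate_last_n: int = 20  # blows pooled for the median/IQR spectrum

    @property
    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            window_length=self.window_length,
            threshold_factor=self.threshold_factor,
            refractory=self.refractory,
        )

    @property
    def bands(self) -> NominalBands:
        return NominalBands(centers=tuple(self.band_centers), half_width=self.band_half_width)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown analysis config keys: {sorted(unknown)}")
        if "band_centers" in data:
            data["band_centers"] = tuple(data["band_centers"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = self.to_dict()
        data["band_centers"] = list(data["band_centers"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _fit_to_dict(fit) -> dict:
    if isinstance(fit, LinearFit):
        return {
            "type": "linear",
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "p_value": fit.p_value,
            "n": fit.n,
        }
    if isinstance(fit, ExpFit):
        return {
            "type": "exponential",
            "y0": fit.y0,
            "k": fit.k,
            "r_squared": fit.r_squared,
            "n": fit.n,
            "converged": fit.converged,
            "r_squared_clipped": fit.r_squared_clipped,
            "n_dropped": fit.n_dropped,
        }
    raise TypeError(f"cannot serialise fit of type {type(fit)!r}")


@dataclass
class AnalysisReport:
    """Everything one end-to-end run produced."""

    observations: pd.DataFrame  # per (blow, band) peak table
    blows: pd.DataFrame  # blow_index, onset_time_s
    drift_fits: dict  # band_id -> LinearFit (frequency vs x)
    convergence_fits: dict  # band_id -> ExpFit (energy vs x)
    band_ftests: dict  # "i_vs_j" -> FTestResult between convergence fits
    fixation_ranking: list  # band_ids ordered by descending convergence R^2
    x_axis: str  # "depth_advance_mm" or "blow_index"
    energy_summary: dict | None
    esd_median: pd.DataFrame | None  # frequency_hz, median, q1, q3
    config: AnalysisConfig = field(default_factory=AnalysisConfig)
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "x_axis": self.x_axis,
            "n_blows": int(len(self.blows)),
            "drift_fits": {str(b): _fit_to_dict(f) for b, f in self.drift_fits.items()},
            "convergence_fits": {
                str(b): _fit_to_dict(f) for b, f in self.convergence_fits.items()
            },
            "band_ftests": {
                key: {"f_statistic": r.f_statistic, "p_value": r.p_value, "df": list(r.df)}
                for key, r in self.band_ftests.items()
            },
            "fixation_ranking": self.fixation_ranking,
            "energy_summary": self.energy_summary,
            "config": {
                **self.config.to_dict(),
                "band_centers": list(self.config.band_centers),
            },
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_json_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def write_outputs(self, out_dir) -> None:
        """Write the report JSON plus peak/blow/ESD CSVs to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_json(out / "report.json")
        self.observations.to_csv(out / "peaks.csv", index=False)
        self.blows.to_csv(out / "blows.csv", index=False)
        if self.esd_median is not None:
            self.esd_median.to_csv(out / "esd_median_iqr.csv", index=False)


def _config_hash(cfg: AnalysisConfig) -> str:
    canon = json.dumps(cfg.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_analysis(
    audio: Recording | str | Path,
    depth_table: pd.DataFrame | str | Path | None = None,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the full blow-to-fits pipeline on one recording.

    Deterministic given inputs and configuration.  Raises
    :class:`EmptyReportError` (with threshold diagnostics) when no blow
    is detected.
    """
    config = config or AnalysisConfig()
    rec = audio if isinstance(audio, Recording) else read_wav(audio)
    if depth_table is not None and not isinstance(depth_table, pd.DataFrame):
        depth_table = read_depth_table(depth_table)

    windows = detect_blows(rec, config.segmentation)
    if not windows:
        scale = noise_scale(rec)
        raise EmptyReportError(
            "no hammer blows detected",
            diagnostics={
                "noise_scale": scale,
                "threshold": config.threshold_factor * scale,
                "duration_s": rec.duration,
            },
        )

    bands = config.bands
    specs = [compute_esd(w) for w in windows]
    observations = []
    for w, spec in zip(windows, specs):
        height = config.min_height_factor * float(np.median(spec.esd))
        peaks = find_esd_peaks(spec, min_height=height, min_distance=config.min_peak_distance)
        observations.extend(assign_bands(peaks, bands, w.blow_index))
    obs_frame = observations_to_frame(observations)

    # x variable per blow
    if depth_table is not None:
        merged = pd.merge(
            windows_to_frame(windows),
            depth_table,
            on="blow_index",
            how="inner",
        )
        x_by_blow = dict(
            zip(merged["blow_index"], merged["depth_mm"] - merged["depth_mm"].iloc[0])
        )
        x_axis = "depth_advance_mm"
    else:
        x_by_blow = {w.blow_index: float(w.blow_index) for w in windows}
        x_axis = "blow_index"

    drift_fits, convergence_fits = {}, {}
    for band_id in range(1, len(bands) + 1):
        rows = obs_frame[(obs_frame.band_id == band_id) & (~obs_frame.missing)]
        rows = rows[rows.blow_index.isin(x_by_blow)]
        x = np.array([x_by_blow[b] for b in rows.blow_index])
        if len(x) >= 3:
            try:
                drift_fits[band_id] = fit_linear(x, rows.peak_frequency_hz.to_numpy())
            except Exception:
                pass
            try:
                convergence_fits[band_id] = fit_exponential(x, rows.peak_energy_rel.to_numpy())
            except Exception:
                pass

    band_ftests = {}
    band_ids = sorted(convergence_fits)
    for i, a in enumerate(band_ids):
        for b in band_ids[i + 1 :]:
            band_ftests[f"{a}_vs_{b}"] = compare_fits_ftest(
                convergence_fits[a], convergence_fits[b]
            )
    ranking = sorted(band_ids, key=lambda b: -convergence_fits[b].r_squared)

    energy_summary = None
    if config.blow_energy_j is not None and depth_table is not None:
        depths = depth_table["depth_mm"].to_numpy(dtype=float)
        records = build_blow_records(depths, config.blow_energy_j)
        advance = float(depths[-1] - depths[0])
        total = records[-1].cumulative_energy
        energy_summary = {
            "hammer_blows": len(records),
            "depth_advance_mm": advance,
            "energy_per_blow_j": config.blow_energy_j,
            "cumulative_energy_j": round(total, 2),
            "energy_per_mm_j": round(energy_per_mm(total, advance), 2) if advance > 0 else None,
        }

    last = specs[-config.aggregate_last_n :]
    med, q1, q3 = aggregate_esd(last)
    esd_median = pd.DataFrame(
        {
            "frequency_hz": med.frequencies,
            "esd_median": med.esd,
            "esd_q1": q1.esd,
            "esd_q3": q3.esd,
        }
    )

    return AnalysisReport(
        observations=obs_frame,
        blows=windows_to_frame(windows),
        drift_fits=drift_fits,
        convergence_fits=convergence_fits,
        band_ftests=band_ftests,
        fixation_ranking=ranking,
        x_axis=x_axis,
        energy_summary=energy_summary,
        esd_median=esd_median,
        config=config,
        provenance={"package_version": _version, "config_hash": _config_hash(config)},
    )


def compare_conditions(report_a: AnalysisReport, report_b: AnalysisReport) -> dict:
    """Per-band F-tests between two runs' convergence fits.

    Mirrors the between-condition comparisons (well-fixated vs loose vs
    fractured): for each band present in both reports, a variance-ratio
    F-test of the exponential-fit residuals plus the R^2 contrast.
    """
    out = {}
    for band_id in sorted(set(report_a.convergence_fits) & set(report_b.convergence_fits)):
        fa = report_a.convergence_fits[band_id]
        fb = report_b.convergence_fits[band_id]
        ft = compare_fits_ftest(fa, fb)
        out[band_id] = {
            "f_statistic": ft.f_statistic,
            "p_value": ft.p_value,
            "df": list(ft.df),
            "r_squared_a": fa.r_squared,
            "r_squared_b": fb.r_squared,
            "better_converged": "a" if fa.r_squared >= fb.r_squared else "b",
        }
    return out
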