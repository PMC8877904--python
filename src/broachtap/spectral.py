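"""Energy spectral densities and resonant-peak extraction.

Each 0.2 s blow window is transformed with an unnormalized forward DFT
and its energy spectral density (ESD) is the squared magnitude,
``|fft(h)|^2``, reported one-sided from DC to Nyquist.  At the nominal
44.1 kHz rate and 0.2 s window this gives a 5 Hz bin spacing.  The ESD of
a hammer blow shows a handful of narrow resonances; peak *frequency* is
the bin location of a local ESD maximum and peak *energy* is its
single-bin height.  Peaks are assigned to nominal resonant bands — the
in vitro quartet near 1400/2500/3150/4700 Hz by default, each ±150 Hz.

Parseval's identity under this convention reads
``sum(two-sided |DFT|^2) == N * sum(x^2)`` and is asserted in the test
suite for every window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .errors import ConfigError, EmptyInputError
from .segmentation import BlowWindow

__all__ = [
    "EsdSpectrum",
    "NominalBands",
    "PeakObservation",
    "IN_VITRO_BANDS",
    "CADAVER_BANDS",
    "compute_esd",
    "find_esd_peaks",
    "assign_bands",
    "aggregate_esd",
    "observations_to_frame",
]


@dataclass(frozen=True)
class EsdSpectrum:
    """One-sided energy spectral density of a single blow window."""

    frequencies: np.ndarray  # Hz, DFT bin centers 0 .. sample_rate/2
    esd: np.ndarray  # squared DFT magnitude per bin, relative units

    @property
    def resolution(self) -> float:
        """Bin spacing in Hz (sample_rate / window sample count)."""
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass(frozen=True)
class NominalBands:
    """Resonant search bands: centers ± half_width.

    Defaults are the four main in vitro resonances with the ~300 Hz band
    width observed around them.
    """

    centers: tuple = (1400.0, 2500.0, 3150.0, 4700.0)
    half_width: float = 150.0

    def validate(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        if len(centers) == 0:
            raise ConfigError("at least one band is required")
        if np.any(np.diff(centers) <= 0):
            raise ConfigError("band centers must be strictly increasing")
        if self.half_width <= 0:
            raise ConfigError("half_width must be positive")
        if np.any(np.diff(centers) < 2 * self.half_width):
            raise ConfigError("configured bands overlap")

    def __len__(self) -> int:
        return len(self.centers)


IN_VITRO_BANDS = NominalBands()
# resonances observed in a cadaveric pilot with a production broach/handle
CADAVER_BANDS = NominalBands(centers=(1900.0, 2900.0, 3850.0, 4400.0, 5550.0, 6650.0))


@dataclass(frozen=True)
class PeakObservation:
    """One (blow, band) measurement: where the band's resonance sat and how tall it was."""

    blow_index: int
    band_id: int  # 1-based
    peak_frequency: float  # Hz; nan when missing
    peak_energy: float  # relative ESD units; nan when missing
    missing: bool = False


def compute_esd(win: BlowWindow) -> EsdSpectrum:
    """Energy spectral density of one blow window.

    Unnormalized forward DFT, squared magnitude, one-sided (DC included).
    No taper is applied by default — the transient decays to near zero
    well inside the window, so leakage from truncation is negligible.
    """
    samples = np.asarray(win.samples, dtype=np.float64)
    if len(samples) == 0:
        raise EmptyInputError("cannot compute ESD of an empty window")
    spectrum = np.fft.rfft(samples)
    esd = np.abs(spectrum) ** 2
    freqs = np.fft.rfftfreq(len(samples), d=1.0 / win.sample_rate)
    return EsdSpectrum(frequencies=freqs, esd=esd)


def default_min_height(spec: EsdSpectrum, factor: float = 5.0) -> float:
    """Adaptive peak-height floor: ``factor`` times the median ESD bin.

    The median of a blow spectrum sits at the broadband/noise level, so
    this rejects noise wiggles while keeping every resonance.
    """
    return factor * float(np.median(spec.esd))


def find_esd_peaks(
    spec: EsdSpectrum,
    min_height: float | None = None,
    min_distance: float = 300.0,
) -> list[tuple[float, float]]:
    """Locate qualifying local maxima of the ESD.

    Candidates are local maxima with height >= ``min_height`` (default:
    5x the spectrum median).  Candidates closer than ``min_distance`` Hz
    are thinned greedily from the highest down, so when two candidates
    conflict the higher-energy one survives (ties break toward the lower
    frequency).

    Returns ``[(frequency_hz, energy), ...]`` sorted by frequency.
    """
    if min_distance <= 0:
        raise ConfigError("min_distance must be positive")
    if min_height is None:
        min_height = default_min_height(spec)
    idx, _ = scipy.signal.find_peaks(spec.esd, height=min_height)
    if len(idx) == 0:
        return []
    freqs = spec.frequencies[idx]
    energies = spec.esd[idx]
    # greedy selection: highest energy first, lower frequency wins ties
    order = sorted(range(len(idx)), key=lambda i: (-energies[i], freqs[i]))
    kept: list[int] = []
    for i in order:
        if all(abs(freqs[i] - freqs[j]) >= min_distance for j in kept):
            kept.append(i)
    kept.sort(key=lambda i: freqs[i])
    return [(float(freqs[i]), float(energies[i])) for i in kept]


def assign_bands(
    peaks: list[tuple[float, float]],
    bands: NominalBands,
    blow_index: int,
) -> list[PeakObservation]:
    """Assign found peaks to nominal bands.

    For each band the highest-energy peak within center ± half_width is
    taken; a band with no qualifying peak yields a flagged missing
    observation (never interpolated — downstream fits drop them).
    """
    bands.validate()
    out = []
    for band_id, center in enumerate(bands.centers, start=1):
        in_band = [p for p in peaks if abs(p[0] - center) <= bands.half_width]
        if in_band:
            freq, energy = max(in_band, key=lambda p: p[1])
            out.append(PeakObservation(blow_index, band_id, freq, energy, missing=False))
        else:
            out.append(PeakObservation(blow_index, band_id, float("nan"), float("nan"), missing=True))
    return out


def aggregate_esd(specs: list[EsdSpectrum]) -> tuple[EsdSpectrum, EsdSpectrum, EsdSpectrum]:
    """Per-bin median and quartile spectra across blows.

    The blow-to-blow ESD distribution is asymmetric, so the summary of a
    set of blows is reported as median with interquartile range rather
    than mean ± sd.  Returns ``(median, lower_quartile, upper_quartile)``.
    """
    if len(specs) == 0:
        raise EmptyInputError("aggregate_esd needs at least one spectrum")
    grid = specs[0].frequencies
    for s in specs[1:]:
        if len(s.frequencies) != len(grid) or not np.allclose(s.frequencies, grid):
            raise ConfigError("aggregate_esd requires identical frequency grids")
    stack = np.vstack([s.esd for s in specs])
    med = np.median(stack, axis=0)
    q1 = np.percentile(stack, 25, axis=0)
    q3 = np.percentile(stack, 75, axis=0)
    return (
        EsdSpectrum(grid, med),
        EsdSpectrum(grid, q1),
        EsdSpectrum(grid, q3),
    )


def observations_to_frame(observations: list[PeakObservation]) -> pd.DataFrame:
    """Tabulate peak observations for CSV export."""
    return pd.DataFrame(
        {
            "blow_index": [o.blow_index for o in observations],
            "band_id": [o.band_id for o in observations],
            "peak_frequency_hz": [o.peak_frequency for o in observations],
            "peak_energy_rel": [o.peak_energy for o in observations],
            "missing": [o.missing for o in observations],
        }
    )
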