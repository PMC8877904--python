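"""Synthetic broaching experiments with exact ground truth.

No raw recordings are deposited for this kind of bench experiment, so the
generator stands in for the physical rig: it emits a WAV-ready recording
of sequential hammer blows plus a per-blow depth table and a ground-truth
record, with the statistical structure the analysis pipeline assumes.

Model
-----
Each blow is a sum of exponentially damped sinusoids, one per resonant
band — the minimal signal model consistent with narrow (~300 Hz) spectral
bands; a damping time of a few milliseconds gives a Lorentzian line width
1/(pi*tau) of that order.  For blow j at insertion depth d_j:

* band frequency drifts linearly with depth advance:
  ``f_b = center_f0 + drift_slope * (d_j - d0)``;
* the band's single-bin ESD peak energy targets
  ``energy_y0 * exp(energy_k * (d_j - d0))`` in expectation, with
  multiplicative lognormal scatter of log-sd ``scatter_sigma_ln``
  (mean-corrected, so the expectation is exact);
* depth advances by ``advance_initial * exp(-(d - d0)/advance_decay)``
  per blow — near-linear at first, flattening to a plateau.

Component amplitudes are *calibrated* rather than assumed: the unit-
amplitude spectrum of each damped sinusoid is computed for the exact
analysis window, and the amplitude vector solving the coupled peak-energy
equations (including cross-band spectral leakage) is found by fixed-point
iteration.  Peak energies measured by the pipeline on a noiseless run
therefore match the configured targets to well under a percent.

Condition presets mirror three bench experiments: a well-fixated
correctly sized broach (70 blows), a loose undersized broach that reaches
the same depth in ~20 blows with ~3x the energy scatter, and a
pre-cracked specimen hammered for 100 blows.  Their trend constants
(y0, k per band; drift slopes and intercepts) are the fitted values
reported for those experiments, used here as generating truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .audio_io import Recording
from .errors import ConfigError
from .spectral import NominalBands

__all__ = [
    "BandParams",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_experiment",
    "preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class BandParams:
    """Generating parameters of one resonant band."""

    center_f0: float  # Hz at the reference (starting) depth
    drift_slope: float  # Hz per mm of depth advance
    energy_y0: float  # target single-bin ESD peak energy at zero advance
    energy_k: float  # per-mm exponential rate of the energy trend
    scatter_sigma_ln: float = 0.0  # lognormal sigma of per-blow energy
    damping_tau: float = 0.008  # s, decay time of the blow transient

    def __post_init__(self):
        if self.center_f0 <= 0:
            raise ConfigError("center_f0 must be positive")
        if not 0.005 < self.damping_tau < 0.2:
            raise ConfigError("damping_tau must lie in (0.005, 0.2) s")
        if self.energy_y0 <= 0:
            raise ConfigError("energy_y0 must be positive")
        if self.scatter_sigma_ln < 0:
            raise ConfigError("scatter_sigma_ln must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Full ground-truth parameterisation of a synthetic insertion run."""

    seed: int = 0
    n_blows: int = 70
    blow_spacing: float = 1.0  # s between onsets
    bands: tuple[BandParams, ...] = ()
    initial_depth: float = 65.0  # mm, depth reached by hand before hammering
    advance_initial: float = 1.5  # mm advance of the first blow
    advance_decay: float = 6.0  # mm, e-folding of advance vs depth
    noise_floor: float = 2e-4  # amplitude sigma of the Gaussian floor
    condition: str = "fixated"
    sample_rate: int = 44100
    window_length: float = 0.2  # s, transient duration per blow
    blow_energy_j: float = 0.24  # nominal hammer energy per blow
    lead_in: float = 0.5  # s of floor before the first blow

    def __post_init__(self):
        if self.n_blows < 1:
            raise ConfigError("n_blows must be >= 1")
        if self.blow_spacing <= 0 or self.sample_rate <= 0 or self.window_length <= 0:
            raise ConfigError("blow_spacing, sample_rate, window_length must be positive")
        if not self.bands:
            raise ConfigError("at least one band is required")
        nyquist = self.sample_rate / 2
        for b in self.bands:
            span = abs(b.drift_slope) * 40.0  # generous depth-advance bound
            if b.center_f0 + span >= nyquist:
                raise ConfigError(
                    f"band at {b.center_f0} Hz can exceed the Nyquist frequency {nyquist} Hz"
                )

    def nominal_bands(self, half_width: float = 150.0) -> NominalBands:
        """Analysis bands centred on each band's mid-run frequency."""
        depths = simulate_depths(self)
        mid = (depths[-1] - self.initial_depth) / 2.0
        centers = tuple(b.center_f0 + b.drift_slope * mid for b in self.bands)
        return NominalBands(centers=centers, half_width=half_width)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulationTruth:
    """Exact per-blow ground truth of a simulated run."""

    onsets: np.ndarray  # s, one per blow
    depths: np.ndarray  # mm, measured after each blow
    frequencies: np.ndarray  # (n_blows, n_bands) Hz
    energies: np.ndarray  # (n_blows, n_bands) target single-bin peak ESD
    config: SimulationConfig

    def to_json(self, path) -> None:
        payload = {
            "onsets_s": self.onsets.tolist(),
            "depths_mm": self.depths.tolist(),
            "frequencies_hz": self.frequencies.tolist(),
            "energies_rel": self.energies.tolist(),
            "config": self.config.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def simulate_depths(cfg: SimulationConfig) -> np.ndarray:
    """Deterministic depth series of the exponential-decay advance model."""
    d = cfg.initial_depth
    out = np.empty(cfg.n_blows)
    for j in range(cfg.n_blows):
        d += cfg.advance_initial * np.exp(-(d - cfg.initial_depth) / cfg.advance_decay)
        out[j] = d
    return out


def _calibrated_blow(cfg: SimulationConfig, freqs, targets) -> np.ndarray:
    """One blow waveform whose per-band single-bin peak ESD hits ``targets``.

    Solves |sum_c A_c S_c[k_b]|^2 = E_b for the amplitude vector A, where
    S_c is the unit-amplitude spectrum of band c's damped sinusoid over
    the analysis window and k_b is band b's peak bin.  Cross-band leakage
    makes the system coupled; a damped fixed-point iteration converges in
    a handful of steps because the coupling is weak.
    """
    win_n = int(round(cfg.window_length * cfg.sample_rate))
    t = np.arange(win_n) / cfg.sample_rate
    n_bands = len(freqs)
    waves = np.empty((n_bands, win_n))
    spectra = []
    peak_bins = np.empty(n_bands, dtype=int)
    for b in range(n_bands):
        waves[b] = np.exp(-t / cfg.bands[b].damping_tau) * np.sin(2 * np.pi * freqs[b] * t)
        s = np.fft.rfft(waves[b])
        spectra.append(s)
        peak_bins[b] = int(np.argmax(np.abs(s) ** 2))
    # coupling matrix M[b, c] = S_c evaluated at band b's peak bin
    M = np.array([[spectra[c][peak_bins[b]] for c in range(n_bands)] for b in range(n_bands)])
    amp = np.sqrt(targets) / np.abs(np.diag(M))
    for _ in range(40):
        achieved = np.abs(M @ amp)
        new = amp * np.sqrt(targets) / achieved
        if np.max(np.abs(new - amp) / amp) < 1e-13:
            amp = new
            break
        amp = new
    return amp @ waves


def simulate_experiment(
    cfg: SimulationConfig,
) -> tuple[Recording, pd.DataFrame, SimulationTruth]:
    """Generate one synthetic broaching run.

    Returns the mono recording, the per-blow depth table (columns
    ``blow_index``, ``depth_mm``), and the exact ground truth.  All
    randomness — per-blow energy scatter and the Gaussian noise floor —
    is drawn from a generator seeded with ``cfg.seed``, so a given config
    reproduces bit-identically.
    """
    rng = np.random.default_rng(cfg.seed)
    depths = simulate_depths(cfg)
    advance = depths - cfg.initial_depth
    n_bands = len(cfg.bands)

    freqs = np.empty((cfg.n_blows, n_bands))
    energies = np.empty((cfg.n_blows, n_bands))
    sigmas = np.array([b.scatter_sigma_ln for b in cfg.bands])
    z = rng.standard_normal((cfg.n_blows, n_bands))
    for b, band in enumerate(cfg.bands):
        freqs[:, b] = band.center_f0 + band.drift_slope * advance
        trend = band.energy_y0 * np.exp(band.energy_k * advance)
        # mean-corrected lognormal scatter: E[exp(sigma z - sigma^2/2)] = 1
        energies[:, b] = trend * np.exp(sigmas[b] * z[:, b] - sigmas[b] ** 2 / 2.0)

    fs = cfg.sample_rate
    onsets = cfg.lead_in + np.arange(cfg.n_blows) * cfg.blow_spacing
    total_n = int(np.ceil((onsets[-1] + cfg.window_length + cfg.lead_in) * fs))
    if cfg.noise_floor > 0:
        samples = rng.normal(0.0, cfg.noise_floor, total_n)
    else:
        samples = np.zeros(total_n)

    win_n = int(round(cfg.window_length * fs))
    for j in range(cfg.n_blows):
        start = int(round(onsets[j] * fs))
        samples[start : start + win_n] += _calibrated_blow(cfg, freqs[j], energies[j])

    rec = Recording(samples=samples, sample_rate=fs)
    depth_table = pd.DataFrame(
        {"blow_index": np.arange(1, cfg.n_blows + 1), "depth_mm": depths}
    )
    truth = SimulationTruth(
        onsets=onsets, depths=depths, frequencies=freqs, energies=energies, config=cfg
    )
    return rec, depth_table, truth


def _bands(centers, slopes, y0s, ks, sigma) -> tuple[BandParams, ...]:
    return tuple(
        BandParams(center_f0=c, drift_slope=s, energy_y0=y, energy_k=k, scatter_sigma_ln=sigma)
        for c, s, y, k in zip(centers, slopes, y0s, ks)
    )


# Generating constants per condition.  Band trend constants (y0, k) and
# frequency drift equations are the reported fitted values for the
# corresponding bench experiments; the energy log-sd 0.32 reproduces the
# well-fixated band-2 goodness of fit of ~0.78, with the loose condition
# at 3x that scatter and the fractured condition in between.
_PRESETS = {
    "fixated_large": dict(
        centers=(1420.0, 2466.0, 3116.0, 4641.0),
        slopes=(0.1314, 1.273, 1.519, 3.812),
        y0s=(1044.0, 2041.0, 624.1, 192.6),
        ks=(-0.0826, -0.1519, -0.1009, -0.04061),
        sigma=0.32,
        n_blows=70,
        advance_initial=1.5,
        advance_decay=6.0,
        blow_energy_j=0.24,
        condition="fixated",
    ),
    "loose_small": dict(
        centers=(1423.0, 2201.0, 3096.0, 4634.0),
        slopes=(0.3982, -0.2705, 1.331, 1.500),
        y0s=(486.7, 491.6, 813.7, 83.88),
        ks=(-0.01864, -0.1399, -0.02262, 0.02983),
        sigma=0.96,
        n_blows=20,
        advance_initial=5.0,
        advance_decay=7.0,
        blow_energy_j=0.24,
        condition="loose",
    ),
    "fractured": dict(
        centers=(1420.0, 2400.0, 3140.0, 4660.0),
        slopes=(0.1314, 1.273, 1.519, 3.812),
        y0s=(285.7, 505.9, 393.7, 145.3),
        ks=(0.001743, -0.06232, -0.07446, -0.0145),
        sigma=0.80,
        n_blows=100,
        advance_initial=1.0,
        advance_decay=9.0,
        blow_energy_j=0.24,
        condition="fractured",
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """A fully populated :class:`SimulationConfig` for a named condition.

    ``fixated_large`` — correctly sized broach, 70 blows at 0.24 J;
    ``loose_small`` — undersized broach, 20 blows, high energy scatter;
    ``fractured`` — pre-cracked specimen, 100 blows.

    Keyword overrides replace any :class:`SimulationConfig` field.
    """
    try:
        p = _PRESETS[name]
    except KeyError:
        raise ConfigError(f"unknown preset {name!r}; choose from {PRESET_NAMES}") from None
    cfg = SimulationConfig(
        seed=seed,
        n_blows=p["n_blows"],
        bands=_bands(p["centers"], p["slopes"], p["y0s"], p["ks"], p["sigma"]),
        advance_initial=p["advance_initial"],
        advance_decay=p["advance_decay"],
        blow_energy_j=p["blow_energy_j"],
        condition=p["condition"],
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
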