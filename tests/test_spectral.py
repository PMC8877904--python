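"""ESD computation, peak search, band assignment, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import broachtap as bt
from broachtap.errors import ConfigError
from broachtap.segmentation import BlowWindow
from broachtap.spectral import (
    NominalBands,
    aggregate_esd,
    assign_bands,
    compute_esd,
    find_esd_peaks,
)

FS = 44100
N = round(0.2 * FS)  # 8820 samples, 5 Hz bins


def _window(samples, fs=FS):
    return BlowWindow(blow_index=1, onset_time=0.0, samples=np.asarray(samples, float), sample_rate=fs)


def _tone(freq, amp=1.0, n=N, fs=FS):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def test_unit_sine_on_bin_has_closed_form_energy():
    """An on-bin unit sine concentrates (N/2)^2 in its bin under the
    unnormalized-DFT ESD convention."""
    spec = compute_esd(_window(_tone(1400.0)))
    peak_bin = int(np.argmax(spec.esd))
    assert spec.frequencies[peak_bin] == pytest.approx(1400.0)
    assert spec.esd[peak_bin] == pytest.approx((N / 2) ** 2, rel=1e-9)
    assert spec.resolution == pytest.approx(5.0)


def test_impulse_has_flat_unit_esd():
    samples = np.zeros(N)
    samples[0] = 1.0
    spec = compute_esd(_window(samples))
    np.testing.assert_allclose(spec.esd, 1.0, rtol=1e-12)


def test_all_zero_window_gives_all_zero_spectrum():
    spec = compute_esd(_window(np.zeros(N)))
    assert np.all(spec.esd == 0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_parseval_identity(seed):
    """Two-sided sum of |DFT|^2 equals N times the signal energy."""
    x = np.random.default_rng(seed).normal(0, 0.3, N)
    spec = compute_esd(_window(x))
    # reconstruct the two-sided sum from the one-sided spectrum
    two_sided = 2 * np.sum(spec.esd) - spec.esd[0] - (spec.esd[-1] if N % 2 == 0 else 0)
    assert two_sided == pytest.approx(N * np.sum(x**2), rel=1e-6)


def test_peak_energy_scales_with_square_of_amplitude():
    lo = compute_esd(_window(_tone(2500.0, amp=0.2)))
    hi = compute_esd(_window(_tone(2500.0, amp=0.6)))
    peaks_lo = find_esd_peaks(lo, min_height=1.0)
    peaks_hi = find_esd_peaks(hi, min_height=1.0)
    assert peaks_lo[0][0] == peaks_hi[0][0]  # frequency invariant to scaling
    assert peaks_hi[0][1] / peaks_lo[0][1] == pytest.approx(9.0, rel=1e-9)


def test_two_separated_tones_both_found():
    spec = compute_esd(_window(_tone(1400.0) + _tone(4700.0, amp=0.5)))
    peaks = find_esd_peaks(spec, min_height=1000.0, min_distance=300.0)
    freqs = [f for f, _ in peaks]
    assert 1400.0 in freqs and 4700.0 in freqs


def test_close_tones_keep_only_the_stronger():
    spec = compute_esd(_window(_tone(2500.0, amp=1.0) + _tone(2600.0, amp=0.4)))
    peaks = find_esd_peaks(spec, min_height=1000.0, min_distance=300.0)
    in_range = [p for p in peaks if 2400 <= p[0] <= 2700]
    assert len(in_range) == 1
    assert in_range[0][0] == pytest.approx(2500.0)


def test_assign_bands_inside_and_outside():
    bands = NominalBands()
    obs = assign_bands([(1450.0, 10.0)], bands, blow_index=3)
    assert not obs[0].missing and obs[0].peak_frequency == 1450.0
    assert obs[0].blow_index == 3
    # 1600 Hz falls in no band: above 1400+150, below 2500-150
    obs = assign_bands([(1600.0, 10.0)], bands, blow_index=1)
    assert all(o.missing for o in obs)


def test_assign_bands_takes_highest_energy_in_band():
    obs = assign_bands([(1350.0, 5.0), (1450.0, 9.0)], NominalBands(), 1)
    assert obs[0].peak_frequency == 1450.0


def test_overlapping_bands_rejected():
    with pytest.raises(ConfigError):
        assign_bands([], NominalBands(centers=(1000.0, 1200.0), half_width=150.0), 1)


def test_aggregate_identical_spectra_has_zero_iqr():
    spec = compute_esd(_window(_tone(1400.0)))
    med, q1, q3 = aggregate_esd([spec] * 5)
    np.testing.assert_array_equal(med.esd, spec.esd)
    np.testing.assert_array_equal(q1.esd, q3.esd)


def test_aggregate_median_of_three():
    grid = np.arange(0.0, 50.0, 5.0)
    specs = [bt.EsdSpectrum(grid, np.full_like(grid, v)) for v in (1.0, 2.0, 9.0)]
    med, _, _ = aggregate_esd(specs)
    assert np.all(med.esd == 2.0)


def test_aggregate_rejects_mismatched_grids():
    a = bt.EsdSpectrum(np.arange(0.0, 50.0, 5.0), np.zeros(10))
    b = bt.EsdSpectrum(np.arange(0.0, 25.0, 2.5), np.zeros(10))
    with pytest.raises(ConfigError):
        aggregate_esd([a, b])


def test_aggregated_peak_location_matches_generator(noiseless_fixated):
    """Median ESD over the last blows peaks within one bin of the
    generating band frequencies."""
    cfg, rec, _, truth = noiseless_fixated
    windows = bt.detect_blows(rec)
    specs = [compute_esd(w) for w in windows]
    med, _, _ = aggregate_esd(specs[-5:])
    resolution = med.resolution
    for b, band in enumerate(cfg.bands):
        center = float(np.median(truth.frequencies[-5:, b]))
        lo, hi = center - 150, center + 150
        mask = (med.frequencies >= lo) & (med.frequencies <= hi)
        peak_freq = med.frequencies[mask][np.argmax(med.esd[mask])]
        assert abs(peak_freq - center) <= resolution + 1e-9


def test_peak_search_stable_under_zero_padding_bins():
    spec = compute_esd(_window(_tone(1400.0)))
    padded = bt.EsdSpectrum(
        np.concatenate([spec.frequencies, spec.frequencies[-1] + 5 * np.arange(1, 11)]),
        np.concatenate([spec.esd, np.zeros(10)]),
    )
    assert find_esd_peaks(spec, min_height=1.0) == find_esd_peaks(padded, min_height=1.0)
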