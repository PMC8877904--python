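# Methods

## Signal model and pipeline

A broaching recording is modelled as a sparse train of short, loud
transients (hammer blows) on a near-silent floor: a contact microphone on
the broach handle picks up structure-borne vibration and very little
ambient sound. All analysis operates per blow on a fixed window of
`window_length` = 0.2 s anchored at the detected onset, which keeps the
whole impulse decay inside the window; at the nominal 44,100 Hz rate this
gives N = 8820 samples and a 5 Hz DFT bin spacing.

**Onset detection.** An onset is the first sample whose absolute
amplitude exceeds `threshold_factor` × the recording's noise scale, taken
as the median absolute amplitude of the whole recording (blows occupy a
tiny fraction of the samples, so the median tracks the floor). A
refractory period (default 0.2 s) suppresses re-triggering within one
transient. The default `threshold_factor` of 12 places the threshold near
8 Gaussian standard deviations of the floor: with a per-sample exceedance
probability around 3·10⁻¹⁶, even hours of audio produce no spurious
onsets, while blow transients in realistic recordings sit 30–45 dB above
the floor and always trigger within a few samples of their true onset. A
truncated final window is zero-padded and flagged rather than discarded.

**Spectra.** The energy spectral density is the squared magnitude of the
unnormalized forward DFT, reported one-sided with the DC bin. Under this
convention Parseval's identity reads Σ|X_k|² (two-sided) = N·Σx², and an
on-bin unit-amplitude sine carries (N/2)² in its bin; both are asserted in
the test suite. No taper is applied by default (the transient decays to
~zero inside the window, so truncation leakage is negligible); a Hann
taper can be added via the window samples if desired.

**Peaks and bands.** Peak *frequency* is the bin location of a local ESD
maximum, peak *energy* its single-bin height (band-integrated energy is
deliberately not the default: the resonances are a few bins wide and the
single-bin height is the quantity the convergence statistic is defined
on). Candidate maxima below `min_height_factor` (default 5) × the
spectrum median are rejected; candidates closer than `min_peak_distance`
(default 300 Hz, one nominal band width) are thinned greedily from the
highest down, ties breaking toward the lower frequency. Each surviving
peak is assigned to a nominal band (centers 1400/2500/3150/4700 Hz,
half-width 150 Hz by default; a six-band set observed with production
components on cadaveric bone is provided as `CADAVER_BANDS`). Bands with
no qualifying peak yield explicitly *missing* observations; fits drop
them pairwise rather than interpolating.

## Statistics

**Drift.** Per band, ordinary least squares of peak frequency on depth
advance, with the standard two-sided t-test of the zero-slope null;
p < 0.05 is read as a real upward (or downward) shift. A constant-y
input is reported as slope 0, R² = 0, p = 1 — the explicit boundary of an
uninformative regression. `fit_linear` is verified against a
hand-coded normal-equations solution to 1e-10 relative error.

**Convergence / fixation.** Per band, nonlinear least squares of
y = y₀·e^{kx} (scipy's Levenberg–Marquardt), initialised from the
log-linear regression of ln y on x — exact for noiseless data — with the
log-linear fallback reported (`converged=False`) if the optimizer fails.
R² = 1 − SS_res/SS_tot is computed on the original, untransformed scale
and clipped at 0 with a flag when the fit explains less than the mean
(possible for non-nested nonlinear fits). R² is used strictly as a
*relative* indicator between conditions; no absolute fixation threshold
is asserted, because peak energies are on a relative scale that depends
on the microphone, its coupling, and the specimen.

**F-test.** Fit comparison uses a plain two-sample variance-ratio test on
residuals, F = s²_larger/s²_smaller with (n−2, n−2) degrees of freedom
and a doubled upper-tail p. Under Gaussian residuals its size is exact
(verified at 1000 simulated null pairs, and its p-values pass a KS
uniformity check); under the generator's multiplicative lognormal scatter
the residuals are heteroscedastic and heavy-tailed, and the test should
be treated as approximate — a known limitation of variance-ratio tests
generally.

**Depth calibration.** ID = a·ln(PE/b) is fitted as OLS of depth on
ln PE (a = slope, b = exp(−intercept/a)). The logarithmic form is the
exact inverse of the exponential energy trend; on a clean synthetic
band-2 track it predicts depth to < 2 mm RMSE over ~18 mm of advance.
The constants of any particular rig (bone model, microphone, energy per
blow) must be fitted, never reused across setups.

**Energy accounting.** The bench rig's swing hammer delivers E = mgh per
blow (m = 1.5 kg default; losses neglected); cumulative energy is the
running sum, and J/mm divides it by total depth advance. The seating
("end point") rule — advance < 0.1 mm per blow over five consecutive
blows — is implemented exactly and is monotone: uniformly smaller
advances can only fire it earlier.

## Beam model

The implant is idealised as a uniform clamped-free Euler–Bernoulli beam:
ω_i = ((i−½)π)²·L⁻²·√(EI/μ), with I = wt³/12 (compliant, x) or
tw³/12 (stiff, y), μ = ρwt, E = 210 GPa, ρ = 7850 kg/m³. Values are
computed in rad/s by default; the reference hand-calculation table for
this geometry is reproduced on that scale (its "Hz" labelling
notwithstanding), and one of its sixteen entries (mode 1, end length, y)
is an order of magnitude below the closed form — `reference_table_check`
flags exactly that entry. The half-integer-π factor approximates the
exact characteristic roots of cos βL·cosh βL = −1, solved numerically in
`exact_cantilever_frequency`; the approximation is ~30% low for mode 1
and within 0.1% from mode 3 on. These eigenvalues are ballpark guidance
for choosing analysis bands, not predictions of the measured resonances:
the real boundary condition is neither perfectly clamped nor free.

## Synthetic-data generator

The generator stands in for a physical bench: a wooden "femur" with a
foam core, a steel broach hammered by a swing hammer at constant energy.
It emulates the *statistical structure* the analysis assumes, per blow j
at depth d_j:

* waveform: Σ_b A_b·e^{−t/τ_b}·sin(2πf_b t) over 0.2 s at onset
  j·spacing (default 1.0 s), plus a Gaussian floor (σ = 2·10⁻⁴ default,
  ≈ 43 dB below blow peaks);
* frequency: f_b = center_f0 + drift_slope·(d_j − d₀);
* energy: the band's single-bin ESD peak targets
  y₀·e^{k(d_j−d₀)}·ε, ε lognormal with log-sd σ_ln, mean-corrected
  (×e^{−σ²/2}) so the expectation equals the trend;
* depth: advance_j = Δ₁·e^{−(d−d₀)/δ} from d₀ = 65 mm, the depth reached
  by hand before hammering — near-linear early, flattening to a plateau.

Damping τ = 8 ms gives a Lorentzian line width 1/(πτ) ≈ 40 Hz, i.e.
narrow resonances of the observed kind. Amplitudes are *calibrated*, not
assumed: the unit-amplitude spectrum of each damped sinusoid is computed
on the exact analysis window and the amplitude vector solving the coupled
single-bin peak-energy equations (cross-band leakage included) is found
by fixed-point iteration, so on a noiseless run the pipeline measures the
configured energies to well under 1% (the documented tolerance is 2%,
covering the one-sample onset ambiguity) and frequencies within one bin.

Preset conditions use the reported fitted constants of three bench
experiments as generating truth — per-band (y₀, k) energy trends and
frequency-drift equations for a well-fixated correctly sized broach
(70 blows, 0.24 J/blow), a loose undersized broach (20 blows to the same
depth), and a pre-cracked specimen (100 blows). The free scatter
parameter was set once by matching the well-fixated band-2 convergence
R² of ≈ 0.78: σ_ln = 0.32, with the loose condition at 3× that and the
fractured condition between (0.8). Depth-model constants (Δ₁, δ) were
chosen so the fixated run advances ~1 mm/blow initially, plateaus at
~18 mm advance, and trips the seating rule around blow 60 — inside its
70-blow run — while the loose preset covers the same depth in 20 blows.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: specimen-to-specimen variability, amplitude
coupling between hammer energy and acoustic output, frequency jitter
within a band (peak frequencies are deterministic given depth, so drift
detection on synthetic data is easier than on bench data, where drift
R² of 0.1–0.2 is typical), overlapping or non-resonant transients, and
any fracture physics (the fractured preset only changes trend/scatter
constants, consistent with fracture having proven acoustically
inconspicuous in bench work).

## Sizes and numerical choices

Statistical acceptance checks run at 100 seeds (segmentation and drift
power), 200 paired seeds (fixation discrimination) and 1000 seeds
(F-test size), with short recordings (5-blow runs) wherever the property
does not need a full insertion; the full suite completes in about two
minutes on one core. Fixed-point amplitude calibration iterates to
1e-13 or 40 iterations; root-finding for characteristic roots uses Brent
bracketing at xtol 1e-13; exponential fits cap at 20,000 function
evaluations. Degenerate inputs (constant y, zero x-variance, all-zero
audio, non-positive energies) take documented explicit paths rather than
relying on library NaN behaviour.

## Known limitations

* Peak energies and the noise floor are on a relative scale; nothing in
  the package calibrates absolute acoustic energy.
* The F-test's nominal size holds for Gaussian residuals only.
* The drift regression treats 5 Hz-quantized frequencies as continuous;
  for drifts below one bin per run (band 1 at default settings) the test
  correctly reports no detectable shift.
* The beam model ignores the actual bone/silicone boundary condition and
  the broach taper; it is guidance for band placement only.
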