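"""End-to-end run: synthesise a broaching experiment, then analyse it.

Generates a well-fixated 70-blow insertion run (contact-microphone audio
plus per-blow caliper depths), pushes it through the full pipeline —
blow segmentation, per-blow energy spectral density, resonant-peak
tracking — and prints the per-band drift and convergence statistics.
"""

from broachtap import AnalysisConfig, preset, run_analysis, simulate_experiment

cfg = preset("fixated_large", seed=1)
recording, depth_table, truth = simulate_experiment(cfg)
print(f"simulated {cfg.n_blows} blows, {recording.duration:.1f} s of audio, "
      f"final depth {truth.depths[-1]:.1f} mm")

report = run_analysis(recording, depth_table=depth_table,
                      config=AnalysisConfig(blow_energy_j=cfg.blow_energy_j))

print(f"\ndetected blows: {len(report.blows)}   x-axis: {report.x_axis}")
print("band | drift slope [Hz/mm]  p(slope=0) | energy y0      k [/mm]   R^2")
for band in sorted(report.convergence_fits):
    d = report.drift_fits[band]
    c = report.convergence_fits[band]
    print(f"  {band}  |   {d.slope:+7.3f}       {d.p_value:9.2e} | "
          f"{c.y0:8.1f} {c.k:+9.4f}  {c.r_squared:.3f}")

es = report.energy_summary
print(f"\nenergy: {es['hammer_blows']} blows x {es['energy_per_blow_j']} J = "
      f"{es['cumulative_energy_j']} J over {es['depth_advance_mm']:.1f} mm advance "
      f"-> {es['energy_per_mm_j']} J/mm")
print("\nA significantly positive drift slope means that band's resonance rises as")
print("the broach seats (shorter free beam); high convergence R^2 means peak")
print("energies follow the exponential trend tightly, indicating firm fixation.")
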