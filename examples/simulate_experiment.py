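"""Generate a synthetic dehydration experiment and inspect its ground truth.

Builds a short (10 h) bench run: an AE hit table with 18 waveform parameters
per hit, a µCT scan schedule (6 x 4-min rotations per run, 6/30-min breaks),
true per-window embolism counts, a dendrometer strain trace and point ψ_x
measurements.
"""

from xylemae import SimulationConfig, simulate_experiment

config = SimulationConfig(
    seed=7,
    total_duration_h=10.0,
    expected_embolisms=80.0,   # expectation of the inhomogeneous Poisson hazard
    background_total=3500.0,   # expected non-embolism hits over the run
)
exp = simulate_experiment(config)

n_scan = sum(1 for w in exp.windows if w.kind == "scan")
print(f"hits registered      : {len(exp.signals)}")
print(f"hidden embolism hits : {exp.n_embolism}")
print(f"windows              : {len(exp.windows)} ({n_scan} scan events, "
      f"{len(exp.windows) - n_scan} breaks)")
print(f"window counts sum    : {sum(w.embolism_count for w in exp.windows)}")
print(f"psi points           : {len(exp.psi_points)} "
      f"({exp.psi_points['psi_mpa'].min():.2f} .. {exp.psi_points['psi_mpa'].max():.2f} MPa)")

# The window counts are the only labels a real experiment would have: the
# per-hit embolism/background truth stays hidden from the analysis and is
# used solely to validate it.
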