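"""Count embolism events in a µCT slice-stack series by image differencing.

Water-filled vessels image grey, air-filled vessels black: a vessel that
empties between two consecutive scans appears as a bright spot in the
difference image.  The detector projects the mid-centered slices, crops and
median-filters, registers consecutive images (translation + scale), and finds
difference maxima above the grayscale threshold of 30.
"""

from xylemae import LabeledWindow, SimulationConfig, count_series, simulate_image_series
from xylemae.uct import SliceStack

planted_counts = [3, 0, 5, 1]
windows = [
    LabeledWindow(index=i, start=i * 240.0, end=(i + 1) * 240.0, kind="scan", embolism_count=c)
    for i, c in enumerate(planted_counts)
]
config = SimulationConfig(seed=3, image_n_vessels=80, image_noise_sd=2.0, image_drift_px=0.5)
series = simulate_image_series(config, windows)

stacks = [SliceStack(window_index=i, slices=s) for i, s in enumerate(series.stacks)]
counts, events = count_series(stacks)

print(f"planted per-window transitions : {planted_counts}")
print(f"detected per-window counts     : {counts.tolist()}")
print(f"total events                   : {len(events)}")
ev = events[0]
print(f"first event                    : window {ev.window_index}, "
      f"(x, y) = ({ev.x:.0f}, {ev.y:.0f}), peak difference {ev.peak_difference:.0f}")
# A matching planted/detected vector means every grey->black vessel transition
# was recovered despite the added noise and inter-scan drift.
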