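"""Normalized distance distributions and peak location.

A bimodal O-O distance series (two pocket arrangements) is histogrammed
at the standard 0.02 A resolution, smoothed with a 15-bin moving average,
and its peaks are read off.
"""

import numpy as np

from pocketdyn import histogram, histogram_peaks

rng = np.random.default_rng(7)
# Two arrangements: a tight H-bond near 2.86 A and a looser one near 3.44 A
values = np.concatenate([rng.normal(2.86, 0.05, 60_000),
                         rng.normal(3.44, 0.06, 30_000)])
hist = histogram(values, resolution=0.02, name="O-O distance", units="A")
area = float(np.sum(hist.density * np.diff(hist.bin_edges)))
print(f"histogram: {hist.n_bins} bins of {hist.resolution} A, area = {area:.9f}")

peaks = histogram_peaks(hist, smooth_window=15, min_separation=5,
                        min_height_fraction=0.1)
for loc, height in zip(peaks.locations, peaks.heights):
    print(f"peak at {loc:.2f} A (density {height:.2f})")
print("Two well-separated maxima indicate two equilibrium H-bond "
      "arrangements explored during the dynamics.")
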