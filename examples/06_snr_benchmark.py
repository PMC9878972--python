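"""Localization accuracy vs SNR: local gradients against two baselines.

Generates 20 noisy Gaussian-spot images per SNR level (the same seeded set
for every localizer) and prints the mean Euclidean localization error in
pixels.  The local-gradient method degrades gracefully at low SNR where
the adjacent-pixel gradient baseline amplifies noise.
"""

from logradient.bench import BenchmarkSpec, run_xy_benchmark

spec = BenchmarkSpec(snr_levels=(2, 5, 10, 20, 50, 200), images_per_level=20, seed=0)
table = run_xy_benchmark(spec, localizers=("log", "centroid", "radial"))

pivot = table.pivot(index="snr", columns="localizer", values="mean_error_px")
print("mean localization error (px) per SNR:")
print(pivot.round(3).to_string())
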