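"""Viability arithmetic: per-image and sample-level APV, MPV, PSI, ratings.

Sample-level APV pools counts before dividing (a count-weighted ratio),
which is not the same as averaging per-image percentages — images with
more grains carry more weight.
"""

import pollenvia as pv

# per-image automatic viability: viable (green) / total (red) counts
print("APV of one image with 80 viable of 120 total grains:",
      f"{pv.apv_image(80, 120):.2f}%")

# manual counterpart: dark-stained grains counted by eye
print("MPV of one image with 30 dark of 40 grains:",
      f"{pv.mpv_image(30, 40):.2f}%")

# sample-level APV pools counts across a sample's images
counts = [(90, 100), (5, 50)]  # (green, red) per image
pooled = pv.apv_sample(counts)
per_image_mean = sum(100 * g / r for g, r in counts) / len(counts)
print(f"sample APV for {counts}: {pooled:.2f}% "
      f"(naive mean of per-image APVs would be {per_image_mean:.2f}%)")

# categorical rating of a sample's APV
for apv in (14.15, 49.9, 75.52, 90.06):
    print(f"APV {apv:5.2f}% rates as {pv.rate_viability(apv).value}")

# pollen size index: share of grains larger than a calibrated threshold
areas = [95, 110, 125, 160, 200, 80]
print(f"PSI of {areas} at the default 118 px² threshold:",
      f"{pv.psi_image(areas):.2f}%")
print("threshold calibrated from smallest-viable-grain areas [100, 181]:",
      pv.psi_threshold_from_calibration([100, 181]), "px²")
print()
print("PSI is provided for completeness; grain-size distributions of viable")
print("and non-viable pollen overlap, so stain-based APV is the better proxy.")
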