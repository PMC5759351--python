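"""Generate a small synthetic batch and run the counting pipeline on it.

Each scene mimics a bright-field micrograph of Alexander-stained pollen:
dark-purple viable grains, pale-turquoise non-viable grains. The
pipeline counts total grains in the red channel and viable grains in
the green channel; with well-separated grains the counts should match
the generator's ground truth exactly.
"""

import tempfile
from pathlib import Path

import pollenvia as pv

workdir = Path(tempfile.mkdtemp(prefix="pollenvia_example_"))
template = pv.SyntheticSceneSpec(n_viable=60, n_nonviable=30)
batch = pv.generate_batch(template, n_images=4, out_dir=workdir / "images",
                          viability_range=(40, 95), seed=11)

cfg = pv.RunConfig(input_dir=workdir / "images", output_dir=workdir / "out")
rows, summaries = pv.run_pipeline(cfg)

print(f"{'image':<14}{'red (total)':>12}{'green (viable)':>15}{'truth':>14}")
truth = {p.name: t for p, t in batch}
for row in rows:
    t = truth[row.image_id]
    print(f"{row.image_id:<14}{row.red_count:>12}{row.green_count:>15}"
          f"{t.true_total:>7}/{t.true_viable}")
print()
for s in summaries:
    print(f"{s.sample_id}: APV = {s.apv:.2f}%  rating = {s.rating.value}")
print()
print("Red counts are total grains, green counts viable grains; the truth")
print("column shows the generator's total/viable counts for comparison.")
print(f"Annotated overlays and tables were written under {workdir/'out'}")
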