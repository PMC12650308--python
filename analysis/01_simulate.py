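"""Generate the demonstration dataset: a longitudinal feature table over the
5-subject x 21-collection design with planted signature events (a ten-fold
reperfusion urea-like surge and a six-fold ischemic citrulline-like plateau),
plus a two-region imaging grid with 21 up- and 29 down-regulated peaks.

Demonstration scale: 1,600 temporal features (the full study scale of
10,529 runs identically, just longer); the imaging grid is 40 x 40 pixels
with 285 peaks, matching the spatial feature count of the study design.
"""

from pathlib import Path

from strokemap import io
from strokemap.schedule import build_schedule
from strokemap.synth import generate_feature_table, generate_pixel_grid

OUT = Path("results/data")
SEED = 1

schedule = build_schedule()
print(f"schedule: {schedule.n_collections} collections/subject x "
      f"{schedule.subject_count} subjects = {schedule.n_samples} samples")

table = generate_feature_table(
    n_features=1600,
    schedule=schedule,
    planted_events=[("F001590", "IV", 10.0), ("F001591", "IIIA+IIIB", 6.0)],
    seed=SEED,
)
paths = io.write_feature_table(table, OUT, "raw")
print(f"temporal table: {table.n_features} features x {table.n_samples} samples "
      f"({table.intensities.isna().to_numpy().mean():.1%} missing)")

grid = generate_pixel_grid(seed=SEED)
paths += io.write_pixel_grid(grid, OUT, "grid")
print(f"pixel grid: {grid.width}x{grid.height}, "
      f"{len(grid.planted)} peaks, "
      f"{int((grid.planted['log2fc'] > 0).sum())} up / "
      f"{int((grid.planted['log2fc'] < 0).sum())} down planted in lesion")

io.write_provenance(OUT, {"seed": SEED, "n_features": 1600}, paths)
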