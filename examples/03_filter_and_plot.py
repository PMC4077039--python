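"""Filter scored results with the query language and draw the circle plot.

Scores a small spike-in screen, keeps significant pairs with a reasonable
effect size via a boolean filter string, removes the bottom 5% of signals
(low-abundance barcodes are a common source of false positives), and
renders the circular bubble plot: one radial axis per B-perturbation,
significance as distance from the center, effect size as bubble area,
reduced fitness in red.
"""

from pathlib import Path

import pairscreen as ps

cfg = ps.SimulationConfig(
    n_a=15, n_b=15, n_replicates=4, n_true_positives=4,
    fold=0.5, seed=7,
)
table, truth = ps.generate_screen(cfg)
res = ps.lm_analyze(table)
print(f"{len(res)} scored pairs")

kept = ps.apply_filter(res, "p_combined < 0.01 & rel_mag_a < 0.8")
print(f'filter "p_combined < 0.01 & rel_mag_a < 0.8" keeps {len(kept)} pairs:')
for row in kept.data.itertuples(index=False):
    mark = "*" if (row.pertA, row.pertB) in truth.spiked_pairs else " "
    print(f" {mark} {row.pertA} x {row.pertB}: p={row.p_combined:.2e}")

trimmed = ps.bottom_signal_filter(res, "abs_mag_a", 0.05)
print(f"\nbottom-5% signal filter: {len(res)} -> {len(trimmed)} rows")

out = Path("scratch")
out.mkdir(exist_ok=True)
spec = ps.PlotSpec(radius_cap=10, label_axis="B")
geom = ps.layout_circle(trimmed, spec)
ps.render(geom, str(out / "circle.pdf"), spec=spec,
          geometry_csv=str(out / "circle_points.csv"))
print(f"\n{len(geom)} bubbles drawn to {out/'circle.pdf'}; the geometry CSV "
      "lists each bubble's pair, so the partner behind any point can be "
      "looked up.")
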