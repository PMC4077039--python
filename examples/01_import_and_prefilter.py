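"""Import a sequencing count table and drop noisy perturbations.

Builds a small gene-gene screen export (cell line; shRNA; read count),
imports it — hairpin names collapse to their target gene, repeated rows
become replicates — then scores every perturbation by how well its fitness
profile correlates with its peers and removes one deliberately scrambled
cell line.
"""

import tempfile
from pathlib import Path

import numpy as np

import pairscreen as ps

rng = np.random.default_rng(0)

# 8 cell lines x 6 genes x 2 hairpins, counts with multiplicative structure;
# cell line c5 is replaced by pure noise to emulate a failed sample
cells = [f"c{i}" for i in range(8)]
genes = ["USP7", "USP14", "UCHL5", "BAP1", "CYLD", "OTUB1"]
cell_eff = rng.normal(0, 0.4, len(cells))
gene_eff = rng.normal(0, 0.4, len(genes))
lines = []
for i, cell in enumerate(cells):
    for j, gene in enumerate(genes):
        for sh in ("sh1", "sh2"):
            mu = 8 + cell_eff[i] + gene_eff[j] + rng.normal(0, 0.05)
            if cell == "c5":
                mu = 8 + rng.normal(0, 0.6)  # no shared structure
            lines.append(f"{cell};{gene}_{sh};{int(np.exp(mu))}")

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "counts.csv"
    path.write_text("\n".join(lines))
    table = ps.import_mps(path)

print(f"imported {len(table)} measurements, "
      f"{table.data.pert_a.nunique()} cell lines x "
      f"{table.data.pert_b.nunique()} genes "
      f"({table.data.rep1.nunique()} hairpins)")

report_a = ps.correlation_report(table, axis="A")
report_b = ps.correlation_report(table, axis="B")
print("\nsummary Spearman correlation per cell line "
      "(low = technically noisy sample):")
for ident, rho in sorted(report_a.per_perturbation.items()):
    print(f"  {ident}: {rho:+.3f}")

filtered = ps.apply_cutoffs(table, report_a, report_b, cutoff_a=0.5, cutoff_b=0.5)
removed = filtered.meta["prefilter"]["removed_a"]
print(f"\ncutoff 0.5 on axis A removed: {removed} "
      f"({len(table) - len(filtered)} measurements)")
print("the scrambled sample correlates poorly with every other cell line, "
      "so it is dropped before analysis.")
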