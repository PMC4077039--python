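"""Benchmark all three scoring methods against spike-in ground truth.

Generates one screen per spike-in fold (0.5 and 0.7 reduce fitness, 1.3
and 1.5 increase it), scores each with the full linear model, the split
linear model and the Mann-Whitney test, and reports the ROC area under the
curve of the combined p-value against the known spiked pairs.
"""

import pairscreen as ps

df = ps.benchmark(
    folds=(0.5, 0.7, 1.3, 1.5),
    methods=("lm", "slm", "ut"),
    n_a=20, n_b=20, n_true_positives=15,
    seed=1,
)
print("ROC AUC by spike-in fold and method:")
print(df.pivot(index="fold", columns="method", values="auc").round(3).to_string())
print(
    "\nAn AUC of 1.0 means every spiked pair outranks every null pair. "
    "Stronger folds (0.5 vs 0.7, 1.5 vs 1.3) are recovered more reliably, "
    "and the three methods behave comparably; the split model trades a "
    "little power for memory."
)
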