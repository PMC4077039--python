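# pairscreen

Statistical analysis, filtering and visualization of **double perturbation
screens** — experiments that measure cellular fitness under all pairwise
combinations of two perturbation sets (gene × drug or gene × gene), read
out as DNA-barcode abundance after a period of exponential growth
(Luminex xMAP bead intensities or sequencing read counts).

In a typical screen almost all combinations leave fitness unchanged, so
the scientific problem is separating the rare genuine interactions
(synthetic lethality, synergy, rescue) from marginal perturbation effects
and replicate noise. `pairscreen` is aimed at the benchtop scientist who
has a pooled-screen export and wants ranked, statistically calibrated hit
lists plus publication figures, and at the analyst who wants to benchmark
scoring algorithms on simulated spike-in truth.

## The models

For scores arranged in an A × B matrix with replicates, two independent
hit-calling models are provided.

**Two-stage robust linear model (LM).** On the log scale a measurement is
modeled additively,

    log intensity_i = β_A[A_i] + β_B[B_i] + s_i ,

fit by Huber M-estimation (IRLS, tuning constant k = 1.345, MAD scale) so
the rare true interactions — outliers under the additive model — do not
distort the marginal effect estimates. The residual signal *s*ᵢ is then
dissected twice: for each fixed level of A, the context's residuals are
regressed on the dummy-coded B levels,

    ∀A :  s_(i|A) = β_(B|A)[B_i] + ε ,

and symmetrically with B fixed. Each coefficient pools a pair's
replicates within its context; its t statistic yields the directional
p-values p_B|A and p_A|B. A **split variant (sLM)** partitions both axes
into blocks (default 50 levels) and runs the whole pipeline per block,
trading statistical power for memory.

**Mann–Whitney U test (UT).** Each value is divided by its row median,
then by its column median, and log10-transformed; a pair's ≥ 3 replicate
values are then compared two-sidedly against the pooled normalized values
of all other pairs in the same column (p_A) and row (p_B). No
distributional assumption is made.

Both models emit two dependent p-values per pair; they are combined into
a single ranking score by **Brown's method** — Fisher's χ² combination
with the reference distribution corrected for the empirical dependence of
−2 ln p_A and −2 ln p_B across the screen — a conservative middle ground
between averaging (which buries one-sided hits) and multiplying (which
overstates significance).

Around the models: Spearman-correlation pre-filtering of noisy
perturbations, a boolean filter-string language over results
(`p_combined < 0.01 & pertA ~ KRAS`, with `& | ! ~` and parentheses), a
circular bubble plot (significance as radius, effect size as bubble area,
fitness direction as color), and a synthetic spike-in generator with ROC
benchmarking.

## Worked example

```python
import pairscreen as ps

cfg = ps.SimulationConfig(n_a=20, n_b=20, n_replicates=4,
                          n_true_positives=5, fold=0.5, seed=42)
table, truth = ps.generate_screen(cfg)
res = ps.lm_analyze(table)
print(res.data.sort_values("p_combined").head(3))
```

Running `python examples/02_score_interactions.py` (which also marks the
known spike-ins) prints, for the linear model:

```
top 5 pairs by combined p-value (linear model):
 * A017 x B013: p_a=2.16e-15 p_b=5.18e-10 p_combined=5.41e-13 rel_mag_a=0.57
 * A009 x B014: p_a=4.39e-12 p_b=3.05e-10 p_combined=2.06e-11 rel_mag_a=0.49
 * A019 x B013: p_a=4.36e-12 p_b=7.37e-08 p_combined=3.44e-10 rel_mag_a=0.73
```

Every top pair is a true spike-in (`*`). `p_a`/`p_b` are the two
directional p-values, `p_combined` the Brown-combined ranking score, and
`rel_mag_a ≈ 0.5` says the pair's signal is about half the median over
all A-perturbations at that B — the combination kills cells that either
perturbation alone spares. The other examples cover import + prefiltering
(`01`), the filter language + circle plot (`03`) and the ROC benchmark
(`04`).

A thin CLI wraps the same functions:

```sh
pairscreen simulate --na 20 --nb 20 --tp 5 --fold 0.5 --seed 42 sim
pairscreen analyze --method lm sim.csv results.csv
pairscreen filter --query "p_combined<0.01" results.csv hits.csv
pairscreen plot --out circle.pdf results.csv
pairscreen roc --truth sim.truth.json results.csv roc.csv
```

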