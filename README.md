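# entrodx

**Entropy removal of diagnostic features** — how much diagnostic
uncertainty does a clinical finding actually resolve?

Conventional 2×2 accuracy metrics (sensitivity, specificity, PPV, NPV,
Youden's J, diagnostic odds ratio) describe how well a test
*discriminates* between disease and non-disease, but not how much they
narrow the differential in a given context. `entrodx` treats a cohort of
patients as the parent node of a one-level decision tree: before
testing, the diagnostic uncertainty is the Shannon entropy of the
disease prevalence,

&nbsp;&nbsp;&nbsp;&nbsp;H(parent) = −p·log₂ p − (1−p)·log₂(1−p),

and a feature splits the cohort into a test-positive child (TP + FP
patients) and a test-negative child (FN + TN). The **entropy removal**

&nbsp;&nbsp;&nbsp;&nbsp;ER = H(parent) − [n₊·H(TP,FP) + n₋·H(FN,TN)] / N

is the information (in bits) the result carries about disease status —
identically the mutual information I(test; disease) — and ER/H(parent)
is the *fraction* of baseline uncertainty removed, the headline quantity
here. A feature can be highly accurate (J ≈ 0.7) yet remove little
uncertainty at low prevalence, and vice versa; plotting ER fraction
against J with cutlines at ER = 0.40 and J = 0.60 sorts features into
four quadrants of diagnostic practicality
(high/low accuracy × high/low information).

The package is for clinical epidemiologists and evidence synthesists
evaluating curated tables of diagnostic features (symptoms, signs,
demographics, labs, imaging), one feature per disease context per row,
given either raw 2×2 counts or (prevalence, sensitivity, specificity, N).

## What's inside

- `contingency` — count derivation (TP = prev·sens·N, FP = (1−prev)·(1−spec)·N,
  FN = prev·(1−sens)·N, TN = (1−prev)·spec·N), its inverse, and all
  conventional accuracy metrics with Haldane–Anscombe handling of
  zero-cell odds ratios.
- `entropy` — Shannon entropy, entropy removal (bits and fraction), and a
  direct mutual-information cross-check.
- `quadrant` — the accuracy-vs-information classification and tallies.
- `correlation` — two-tailed Pearson r of ER fraction against each
  accuracy metric, with per-metric exclusion of undefined rows.
- `io` — CSV feature tables with alias-mapped headers, `%` parsing, and a
  fixed 22-column results schema.
- `synth` — reproducible synthetic cohorts with planted perfect
  (ER = 100 %) and planted independent (ER = 0) control features and
  analytically known ground truth per row.
- `cli` / `plotting` — an `entrodx` command with
  `compute / quadrant / correlate / plot / simulate / replicate`
  subcommands and the quadrant scatter figure.

## Worked example

```python
from entrodx import TestPerformance, derive_counts, accuracy_metrics, entropy_removal

perf = TestPerformance(prevalence=0.2, sensitivity=0.8, specificity=0.9, n_total=1000)
counts = derive_counts(perf)          # TP=160 FP=80 FN=40 TN=720
metrics = accuracy_metrics(counts)
ent = entropy_removal(counts)
```

prints (see `examples/01_single_feature.py`):

```
2x2 table: TP=160 FP=80 FN=40 TN=720
PPV=0.6667  NPV=0.9474  J=0.70  DOR=36.0
parent entropy    : 0.7219 bits  (uncertainty before testing)
entropy removed   : 0.2755 bits
fraction removed  : 0.3816  (38.2% of diagnostic uncertainty)
```

A test with Youden's J = 0.70 — firmly "accurate" — still leaves more
than 60 % of the baseline uncertainty in place: at 20 % prevalence the
parent entropy is only 0.722 bits and the split recovers 0.275 of them.
With J ≥ 0.60 but ER < 0.40 this feature lands in the High Accuracy /
Low Information quadrant.

The `examples/` directory has one short script per capability
(single feature, synthetic cohort + quadrants, correlations, the
quadrant plot, CSV pipeline). The same flows are available from the
shell:

```bash
entrodx simulate --output features.csv --seed 7
entrodx compute  --input features.csv --output results.csv
entrodx quadrant --input results.csv
entrodx correlate --input results.csv
entrodx plot     --input results.csv --output quadrants.svg
```

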