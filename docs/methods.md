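# Methods

## Model

A diagnostic feature applied to a cohort of N patients defines a 2×2
table: TP, FP, FN, TN. When a source reports performance parameters
instead of counts, the cells are derived as

- TP = prevalence · sensitivity · N
- FP = (1 − prevalence) · (1 − specificity) · N
- FN = prevalence · (1 − sensitivity) · N
- TN = (1 − prevalence) · specificity · N

These conserve the disease margin (TP + FN = prevalence · N) and the
healthy margin exactly, which is a prerequisite for any entropy
computed downstream to be meaningful. Cells are kept fractional — every
quantity computed from them depends only on proportions, and rounding
would silently perturb low-order digits.

The cohort is the parent node of a one-level decision-tree split; the
test-positive (TP + FP) and test-negative (FN + TN) subgroups are the
children. With H the binary Shannon entropy in bits,

- H_parent = H(prevalence),
- H₊ = H(TP/(TP+FP)), H₋ = H(FN/(FN+TN)),
- ER_bits = H_parent − [n₊·H₊ + n₋·H₋]/N,
- ER_fraction = ER_bits / H_parent.

ER_bits is identically the mutual information I(test; disease). The
package computes it both ways — node splitting in `entropy_removal`,
the joint-distribution sum in `mutual_information` — and the test suite
holds them to within 1e-10 of each other (and of a third, test-local
brute-force implementation) over 10,000 random tables.

**Assumptions.** One dichotomized feature at a time; a binary disease
state; the published performance parameters describe the cohort they
are applied to. Sequential or joint multi-feature entropy is out of
scope.

## Parameters and conventions

- **Entropy base**: 2 (bits), the decision-tree convention. ER_fraction
  is base-invariant (verified in tests), so nothing downstream depends
  on the choice.
- **0·log 0 := 0**; an empty child node has entropy 0 and weight 0.
  Required for perfect tests, which must reach ER_fraction = 1 exactly.
- **Negative ER from float cancellation** is clamped to 0 below 1e-12;
  information gain is provably non-negative, so anything larger aborts.
- **ER_fraction is undefined at prevalence 0 or 1** (zero parent
  entropy) and raises `ZeroParentEntropyError`; table-level drivers
  report such rows as rejects and continue.
- **Quadrant cutoffs**: J ≥ 0.60 = high accuracy, ER_fraction ≥ 0.40 =
  high information, both inclusive. They are parameters everywhere
  (`j_cut`, `er_cut`) and are echoed into every summary and manifest so
  a sensitivity analysis is a flag change.
- **DOR zero cells**: when any cell is exactly 0 the reported DOR and
  log-DOR (natural log) use the Haldane–Anscombe +0.5 correction on all
  four cells, flagged per row; the raw value is kept as an
  inf/0/nan sentinel. This keeps perfect tests inside the logged-DOR
  correlation instead of dropping them; dropping instead is a one-line
  filter on the flag, and the natural-log choice cannot affect Pearson r
  (affine invariance, verified in tests).
- **Correlations**: x is always ER_fraction (the percentage form of the
  same number); two-tailed p from the t statistic r·√((n−2)/(1−r²)) on
  n − 2 df (scipy's `pearsonr`). Exclusion of undefined rows is
  pairwise per metric, maximizing n for each metric independently; a
  zero-variance metric fails alone without poisoning the report. No
  multiple-comparison adjustment — the analysis is descriptive.
- **CSV dialect**: comma-separated UTF-8, quoted fields allowed, `.`
  decimal point, `%` suffixes divided by 100, empty/`NA` missing.
  Headers are matched case-insensitively against an alias map and can
  be extended with a `header=field` mapping file, because curated
  evidence tables rarely agree on column names. When a row carries both
  counts and performance parameters they are cross-checked at 1e-6
  relative; on disagreement a warning is issued and counts win — counts
  are the primary observable.
- **Results schema**: a fixed 22-column order, floats at 6 significant
  digits, row order = input order, so outputs are diffable and
  write→read round-trips to 1e-6.

## Synthetic cohort generator

`generate_cohort` emulates a curated likelihood-ratio evidence table of
405 clinical features in four categories (Demographics : Imaging :
Lab/Diagnostic Tests : Signs/Symptoms/History at weights
3 : 160 : 65 : 177 over 405). Per row, in a fixed draw order:

- category ~ multinomial(weights);
- prevalence = 0.01 + 0.59 · Beta(2, 4) — right-skewed, median ≈ 0.19,
  bounded inside (0.01, 0.60) so the parent entropy is always positive;
  diagnostic-accuracy cohorts are predominantly low-prevalence;
- sensitivity, specificity ~ Beta(5, 2) (mean ≈ 0.71, right-skewed
  toward clinically typical values), squeezed strictly inside (0, 1);
- N = round(10^Uniform(2, 3.5)), i.e. cohorts of 100–3162 patients.

Three *perfect* rows (sens = spec = 1 → ER_fraction = 1, J = 1) and
three *independent* rows (sens = 1 − spec exactly → ER = 0, J = 0) are
planted by default, mirroring the handful of perfect point-of-care
ultrasound findings and of uninformative demographic risk factors such
tables contain. Planted rows draw from a separate child of the seed's
`SeedSequence`, so changing the number of planted rows leaves every
ordinary row's parameters untouched. Each record carries a ground-truth
block with its ER_fraction computed analytically at generation time
from (prevalence, sens, spec) via the closed-form mutual information —
a code path that never touches the counts pipeline — and
`ground_truth_check` verifies row-by-row recovery to 1e-9.

**What passing says and does not say.** The generator produces
independent (prevalence, sens, spec, N) draws. Real evidence tables are
not independent draws: reviews contribute correlated rows, extreme
specificities cluster in imaging, infinite DORs are common, and N spans
wider ranges. Pipeline correctness (recovery, invariants, determinism)
transfers to real data; *distributional* findings do not. In
particular, on this generator the logged DOR is an almost monotone
transform of ER (r ≈ 0.93–0.95), so the empirical ordering of
correlation strengths seen on real curated tables
(J strongest, then PPV, sensitivity, logged DOR, specificity, NPV) is
not reproduced — a documented limitation of the synthetic conditions,
not of the estimator.

## Design choices

- `replicate` chains compute → quadrant → correlate → plot in one
  command and compares against a user-supplied `--reference` JSON of
  expected quadrant counts and correlations rather than baking any
  study-specific numbers into the code: reference values are data, and
  keeping them external lets the same command validate against any
  published or in-house table.
- The CLI writes a JSON run manifest (command, inputs, outputs,
  thresholds, seed, version, timestamp) next to every primary output;
  logs go to stderr, machine-readable content to files, never mixed.
- Exit codes: 0 success (warnings allowed), 1 input/schema error,
  2 internal error.
- Determinism: a fixed seed makes simulate → compute → quadrant →
  correlate byte-reproducible, and SVG output pins its hash salt and
  omits the date so identical inputs give identical files.
- Problem sizes in the shipped tests: 10,000 random tables for the
  oracle-equivalence sweep, the 405-row default cohort for pipeline
  checks, and one 10,000-row cohort as a stress run — large enough to
  exercise the numerics densely while keeping the whole suite at
  laptop scale (~20 s).

## Known limitations

- Single-feature analysis only; no conditional/sequential entropy over
  feature combinations.
- No confidence intervals on metrics or on r; no non-Pearson
  correlation options.
- The accuracy/information quadrant cutoffs are conventions, not
  estimates; nothing in the package selects them from data.
- Validation of real published tables is limited by their reporting:
  when only rounded performance parameters are available, derived
  fractional counts inherit that rounding, which can move low-order
  digits of ER for small cohorts.
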