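# Methods

This note documents the statistical procedures `sffstree` implements, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate about real data.

## Data model

The pipeline currency is a probes × samples matrix of log2-scale
intensities with exactly two sample classes, `tumor` and `normal`; `tumor`
is the positive class in every metric. Values are assumed already
log2-transformed (a `log2` flag applies the transform at load time; there is
no automatic detection) and must be finite: missing cells are rejected by
default, or imputed with the probe's per-class mean on request, because the
intended inputs are complete post-normalization matrices. Matrix orientation
is fixed; transposed input is a user error. Probes are the unit of feature
selection throughout — when several probes map to one gene they are kept
distinct, and gene symbols are carried as annotation only.

## Array qualification

Spot detection uses the scanner statistics of the 532 nm channel: a spot is
**Present** when `fg_median >= bg_median + 3 * bg_sd`. Array-level basic QC
summarizes each array by three parameters — percentage of Present spots,
mean intensity of Present spots, and the coefficient of variation of
control-spot intensities — and excludes an array only when **two or more**
parameters fall outside `[Q1 - 1.5*IQR, Q3 + 1.5*IQR]` computed across all
arrays (quartiles by linear interpolation between order statistics, the most
common convention; at least four arrays are required for the fences to mean
anything). Replicate reproducibility requires Pearson r > 0.95 and a
"2-fold percentage" below 15% on raw-scale intensities, both strict; a ratio
"exceeds 2-fold" symmetrically (ratio > 2 or < 1/2). The mean Present
intensity deliberately uses the raw foreground median with no background
subtraction, and records that choice in the report metadata. The density
"diagram" inspection has no quantitative criterion, so it is supported as a
histogram-table export for visual review rather than an automated pass/fail.
Downstream analysis includes a probe when it is Present on at least one
qualified array.

## Differential expression and the prefilter

Each probe gets an unpaired two-sample *t*-test of tumor against normal:
pooled-variance Student by default (df = n₁ + n₂ − 2), Welch by flag
(Welch–Satterthwaite df), and a paired variant for matched designs. The
statistic is positive when the tumor mean is higher. Degenerate inputs are
defined, not errors: zero variance in both groups with equal means gives
t = 0, p = 1. P-values are corrected with the Benjamini–Hochberg step-up
procedure (delegated to `statsmodels`; an independent brute-force step-up
oracle guards it in the tests). The prefilter keeps probes with adjusted
P **strictly** below α (default 0.001) that are overexpressed in tumor;
underexpressed probes are excluded regardless of significance because
overexpressed transcripts are the ones sought as diagnostic markers. No
fold-change threshold is applied.

This is an ordinary t-test by design. Empirical-Bayes moderated statistics
(limma-style, as web tools such as GEO2R apply) shrink per-probe variances
and will generally call more probes significant at small n; the gap is
logged every time the prefilter runs, and probe counts from moderated
analyses should not be expected to match.

## Decision trees

Induction is the classic recipe for binary-class, continuous-feature data:

* **Splits** are binary thresholds `probe <= t` / `probe > t` where `t` is
  always a value observed at the node (every distinct observed value except
  the maximum is a candidate; no midpoint interpolation). This matches how
  published marker rules quote thresholds that are actual measured
  intensities.
* **Scoring** is information gain by default — gain ratio is available by
  flag — with gains at or below 1e-12 treated as zero to absorb log2
  rounding noise. For binary threshold splits the two criteria usually rank
  candidates identically.
* **Stopping**: class purity, fewer than `2 * min_leaf` samples, or no
  split with positive gain. Leaf labels follow the majority rule; a tied
  leaf takes the parent's majority, and a tied root takes the
  lexicographically first class (`normal`). Induction is deterministic by
  construction: score ties go to the earlier feature in the caller's order,
  then the smaller threshold.
* **Pruning** is bottom-up subtree replacement (no subtree raising): a
  subtree collapses to its majority leaf when
  `N * ucf(E, N) <= Σ_leaves n_i * ucf(e_i, n_i)` at confidence factor CF
  (default 0.25). `ucf(E, N)` is the **exact** one-sided binomial upper
  bound — the p solving `P(X <= E | N, p) = CF`, i.e. the (1 − CF) quantile
  of Beta(E+1, N−E), with closed form `1 - CF**(1/N)` at E = 0 — rather
  than the historical normal approximation; the tests pin it to a bisection
  of the binomial tail at 1e-9. No MDL correction is applied for the number
  of continuous-split candidates.
* **Rules**: one rule per leaf, conditions in root-to-leaf order, rendered
  with coverage as `If g > 7.523 then tumor (57/4)` (57 samples reach the
  leaf, 4 carry the other label). First-matching-rule evaluation is provably
  equivalent to tree descent because the leaves partition feature space.

An inherent consequence of observed-value thresholds is worth knowing: for a
feature that separates the classes perfectly, LOOCV attains exactly
(n − 1)/n, never 1.0 — the fold holding out the largest sample of the
lower class contracts the learned threshold to the second-largest, so that
one sample is always called wrong. This matches the ≈99% ceilings such
classifiers report on cleanly separated cohorts.

## Cross-validation

LOOCV runs n deterministic folds in sample order and accumulates held-out
predictions into a confusion matrix; its accuracy equals the mean of the n
0/1 outcomes, and repeated runs are byte-identical. Stratified k-fold
(default k = 10) shuffles each class once with a seeded generator and deals
samples round-robin while continuing a global fold counter across classes,
so per-class and total fold sizes each differ by at most one and k = n
reduces *exactly* to LOOCV. A training fold that loses a class degenerates
to a majority leaf and is logged rather than failed. Metrics with zero
denominators are returned as undefined (`None`), never as 0.

By default the feature set handed to cross-validation is treated as fixed —
the protocol evaluates a chosen marker set on the same data that selected
it, which is optimistic; re-running selection inside every fold (nested CV)
gives unbiased estimates at ~k times the cost and is available by calling
the selector inside a custom fold loop.

## Sequential forward selection

From an empty set S, each iteration evaluates the tree LOOCV accuracy of
S ∪ {p} for every remaining candidate p and appends the single argmax
("one probe per iteration"); accuracy ties break by smallest prefilter
adjusted p, then lexicographic probe id, keeping the whole search
deterministic. The search stops after `patience` consecutive iterations
without strict improvement (default 2 — in practice forward selection on
expression data shows exactly two trailing non-improving iterations after
the last useful marker) or at `max_iter` (default 10). The reported
`selected` set is the shortest prefix of the chosen sequence attaining the
best observed accuracy, so trailing non-improving picks are dropped.
Despite the traditional acronym, this is pure forward selection — no
floating removal step.

Candidate evaluations within an iteration are independent; they run through
a compiled (numba) replica of the reference induction — same split scan
order, same arithmetic, same tie-breaks, pruning against a table precomputed
from the same exact-binomial bound — and the test suite asserts
prediction-for-prediction equality between the compiled and reference paths,
as well as equality of whole selection traces against an exhaustive
re-evaluation on small problems.

## Synthetic data

The generator emulates normalized two-class log2-intensity matrices:
background probes iid Normal(μ = 8.0, σ = 1.0) in both classes (typical of
post-normalization log2 microarray signal), and planted markers in four
roles — `single_marker` (+Δσ in every tumor), `down_marker` (−Δσ in every
tumor), and the complementary pair: `pair_A` shifted +Δσ in a seeded random
tumor subset of size round(f·n_tumor) (default f = 0.9) and `pair_B` in
exactly the complementary subset. Complementary subsets (rather than
correlated effects) were chosen because they give an exact ground-truth
optimal tree for assertions. Everything is reproducible from the spec seed,
and the truth object records each planted probe's role and shifted samples.
The canonical desk-scale conditions used across the tests and the acceptance
script are 30/30 samples and 500 probes, which keep a full 20-seed selection
study within a few minutes on one CPU.

Two statistical facts about this design shape what the benchmarks can show:

* With Gaussian noise, a mean shift of Δ = 2σ does **not** separate
  classes; the complementary pair "supports a perfectly separating depth-2
  tree" only for Δ ≫ σ. Because `pair_B` covers just round((1−f)·n_tumor)
  tumors (3 of 30 at the defaults), its maximum possible LOOCV contribution
  is 3/60 = 0.05 accuracy, while the maximum chance LOOCV improvement over
  ~500 competing noise probes is of the same order. Recovery of the full
  pair by forward selection is therefore reliable only at separating effect
  sizes (measured: 0/20 runs at 2σ, 4/20 at 3σ, 15/20 at 4σ, 18/20 at 5σ).
  The mechanism tests accordingly run at 5σ, and the 2σ condition is kept,
  honestly failing, as a sensitivity probe.
* The generator does not emulate probe-level technical artifacts (dye bias,
  spatial effects), heavy-tailed noise, correlated probes, or batch
  structure. Passing tests demonstrate the algorithms' correctness and
  their behavior under the stated noise model — not performance on real
  arrays.

## Parameters at a glance

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.001 | strict threshold on BH-adjusted P in the prefilter |
| t-test `variant` | `pooled` | pooled-variance Student; `welch`, paired by flag |
| `confidence` | 0.25 | pruning confidence factor CF (smaller prunes harder) |
| `min_leaf` | 2 | minimum training samples per leaf |
| `criterion` | `info_gain` | split score; `gain_ratio` by flag |
| `patience` | 2 | non-improving iterations before selection stops |
| `max_iter` | 10 | hard cap on selection iterations |
| `k` | 10 | folds for stratified k-fold |
| `mu_bg`, `sigma_bg` | 8.0, 1.0 | background log2 intensity mean / sd |
| `coverage` (f) | 0.9 | tumor fraction covered by `pair_A` |

## Known limitations

* No moderated-variance testing; probe counts will not match
  empirical-Bayes analyses at small n.
* The default protocol cross-validates markers on the data that selected
  them; nested selection must be arranged by the caller.
* Greedy forward selection cannot enter exactly-XOR interactions (every
  marginal split has zero gain); the depth-2 benchmarks use minimally
  unbalanced layouts where the first split is well-defined.
* Trees handle neither missing values at prediction time nor multiway
  categorical splits; there is no boosting or bagging.
* GEO series-matrix support covers the standard table block; network
  fetching of accessions is intentionally out of scope.
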