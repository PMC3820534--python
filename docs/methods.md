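# Methods

## The problem and the model

Functional annotations (e.g. Gene Ontology biological processes) are
recorded at the gene level, but a gene's alternatively spliced isoforms can
differ in function. `isomil` treats isoform-level function prediction as a
multiple-instance learning (MIL) problem over isoform-level expression
profiles:

* a **bag** is a gene; its **instances** are the gene's transcript isoforms,
  each represented by a feature vector of log2 expression values across
  experiments;
* the bag label `y_i` is observed: 1 if the gene is annotated to the
  function under study, 0 otherwise;
* the instance labels `y_ij` are hidden, constrained by the bag label: a
  positive gene must contain at least one functional isoform (a
  **witness**), and no isoform of a negative gene is functional.

The classifier is a linear soft-margin SVM over the expression features.
Finding the hidden labels jointly with the hyperplane is a mixed-integer
program, so `run_mil` uses the classic alternating heuristic:

1. **Initialisation** — every isoform of every positive gene is labelled
   positive; all isoforms of negative genes are negative.
2. **Model building** — fit the soft-margin SVM on the currently labelled
   instances and score *all* instances with the signed distance to the
   hyperplane.
3. **Label update** — two formulations:
   * **mi-SVM**: inside each positive bag, isoforms scoring strictly above
     a threshold become positive, the rest negative; if none clears the
     threshold, the top-scoring isoform is forced positive (ties broken by
     smallest isoform id) so the bag constraint always holds. The threshold
     is computed from the decision scores of negative-bag instances, with
     three variants of increasing strictness: the **mode** of their
     distribution, their **75th percentile** (the default, which performed
     best in the study this package operationalises), or their **maximum**.
   * **MI-SVM**: exactly one witness per positive bag — the arg-max
     isoform (or a uniformly random one, for the baseline that measures the
     value of informed witness selection). Non-witness isoforms become
     NEUTRAL and are excluded from the next fit.
4. **Stop criterion** — the loop ends when the assignment repeats the
   previous one (fixed point) or any earlier one (cycle), or at
   `max_iterations`. Labelings are compared by a canonical hash.
   The reported iteration count includes the initial assignment, so a run
   whose first update already confirms the initialisation counts 2.

At the end, the model from the final iteration scores every isoform, and a
gene's score is the **maximum** over its isoforms (the gene performs the
function if at least one isoform does).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `formulation` | `mi_svm` | label-imputation formulation; `MI_svm` keeps one witness, `MI_svm_random` is the random-witness baseline |
| `threshold_variant` | `p75` | witness-selection strictness for mi-SVM |
| `regularization_strength` (C) | 1.0 | soft-margin trade-off; `None` selects C once per term by 3-fold inner CV over {0.01, 0.1, 1, 10}. A fixed C is the default because inner CV multiplies the cost of the bagged and cross-validated pipelines severalfold while, on the synthetic benchmarks, the choice of C moves witness recovery by under one point |
| `class_weighting` | off | inverse-frequency class weights. Off by default: with ~1:40 gene imbalance the up-weighted positive class (~100 instances in a ~120-dimensional feature space) gets memorised by the margin, freezing wrong hidden labels in place (measured balanced-accuracy drop from ~0.80 to ~0.62). The knob remains for datasets with many more instances than features |
| `threshold_source` | `negative_bags` | whether the mi-SVM threshold pools scores of negative-bag instances (default) or of all currently negative instances |
| `max_iterations` | 50 | safety cap; deterministic formulations converge in ≤ ~10 assignments in practice |

Numerical conventions, chosen where the procedure itself leaves them open:

* **percentile**: linear interpolation between order statistics;
* **mode**: midpoint of the most populated histogram bin under
  Freedman–Diaconis binning, ties to the lower bin;
* **strict inequality** at the threshold (an at-threshold isoform is
  negative), so the `max` variant leaves exactly one positive per bag;
* **arg-max ties**: lexicographically smallest isoform id, for
  reproducibility independent of hash order;
* the SVM is liblinear's dual hinge-loss solver (tol 1e-3, fixed
  random_state), i.e. the same linear soft margin as the formulation above,
  at roughly two orders of magnitude less cost than an SMO solver on the
  default problem sizes.

## Preprocessing

The pipeline consumes an already-quantified isoform × experiment FPKM
table. Sequencing runs with fewer than 10 million reads or under 50% of
reads mapped are removed (boundary values kept). A gene is *detected* in an
experiment iff at least one of its isoforms has FPKM > 0 there; genes
detected in fewer than half of the experiments are dropped with all their
isoforms. FPKM values are then log2-transformed; missing and zero FPKM
cells both become the sentinel −15 (zero and "not observed" are
indistinguishable in quantifier output, and the sentinel acts as a uniform
floor for unobserved expression). The matrix carries an explicit space flag
so a second transform is rejected.

## Gold standards

Per term, positives are the universe genes annotated to the term **or any
is_a descendant** (transitive closure over the ontology DAG); all remaining
universe genes are negatives. Only `is_a` edges propagate by default
(`part_of` handling is a config switch); all evidence codes are accepted.
Terms are kept when they have 20–300 positives — fewer is too little signal
to fit, more is too unspecific — and can be grouped into size quantiles of
near-equal term counts (ties at boundaries broken by term id).

## Probability scores by bootstrap bagging

Final per-isoform predictions use the 0.632 bootstrap: genes (never bare
isoforms — all isoforms of a gene travel together) are resampled with
replacement; the MIL loop runs on the resample (a gene drawn k times
contributes k bag copies); the resulting model scores the out-of-bag genes.
After 30 rounds, an isoform's decision score is the **median** over the
rounds that held it out. Isoforms never out-of-bag — probability
(1−1/n)^(30n), vanishing but nonzero — are scored by one supplementary
round trained on all other genes, and flagged.

Decision scores are mapped to probabilities by a Platt-style sigmoid
(logistic fit on the score) using the labels of a full-data run's final
labeling; the map is monotone, so ranking by probability equals ranking by
score. Each isoform is also reported as a **fold change** over the term's
background probability, `probability / (|positives| / |universe|)` with the
prior defined over genes. A rank-based calibration alternative sits behind
a config flag.

## Evaluation designs

All partitioning is by gene to prevent leakage between isoforms of one
gene. The package implements:

* **k-fold CV** (5-fold headline; stratified option keeps ≥ 1 positive per
  fold) with pooled out-of-fold gene scores;
* **multi- vs single-isoform comparison**: two-fold CV over all genes;
  evaluation groups split by isoform count with negatives randomly
  downsampled so both groups share the same positive:negative ratio (and
  hence baseline precision). Models are trained on full fold complements,
  not on the subgroups — subgroup-only training leaves too few positives to
  fit;
* **expression stratification**: genes cut into equal thirds by mean
  non-sentinel log2 expression (sentinel-only genes go to the low third),
  evaluated on pooled CV scores;
* **homolog-aware splits**: whole homolog groups are assigned greedily,
  largest first, to the smaller side (seeded shuffle breaks size ties), so
  no group is split across train and test.

Metrics: ROC AUC (Mann–Whitney convention, via scikit-learn); AUPRC as
**average precision** — the mean over positives of the precision at each
positive's rank (rectangular, not trapezoidal; do not mix the two when
comparing); precision at r% recall with ceil semantics at the first
threshold whose recall reaches r. Per-group medians can be aggregated over
terms or over folds-then-terms; both are exposed.

## The synthetic-data generator

`generate_term_dataset` emulates the statistical structure the method
relies on: a co-expression signature shared by the functional isoforms of a
term. For each isoform a baseline log2 expression is drawn (Normal(2, 2²) —
per-isoform heterogeneity in the realistic range of log2-FPKM values, which
also enables the expression-stratification design), cell noise is
Normal(0, noise_sd²), and each witness isoform is shifted by `effect_size`
in a fixed random subset of `signature_dim` experiments. A `missing_rate`
fraction of cells is set to the −15 sentinel. Defaults: 50 positive genes,
2000 negatives, 120 experiments, 30 signature experiments, effect 2.0,
noise 1.0, 5% missing, isoform counts over 1..6 with 60% single-isoform
genes, exactly one witness per positive gene (`witness_fraction` plants
more). The planted truth always satisfies the bag-label constraint, and
generation is bit-reproducible from the seed.

What the generator does **not** emulate: correlated expression between
isoforms of one gene (shared promoters), term-to-term correlation,
library-size artefacts, the dependence of annotation quality on gene
family, and any association between isoform count and expression level.
Passing synthetic benchmarks therefore demonstrates that the implementation
recovers planted structure under the stated noise model — not that the
method attains any particular accuracy on real RNA-seq corpora.

`generate_toy_ontology` builds a random is_a tree with annotation counts
that straddle the 20/300 selection bounds after propagation, to exercise
the gold-standard machinery end to end.

## Known limitations (measured on the synthetic benchmarks)

* **Self-labeling feedback.** The final labeling is a fixed point of
  in-sample scoring: instances the loop labels positive are then trained as
  positive, which inflates their scores. At the default conditions (~100
  positive-bag instances in 120 dimensions) about 35% of non-witness
  isoforms in positive genes remain positive at convergence, versus the
  ~25% the p75 threshold would keep under exchangeability and ~20% for a
  model trained on the planted truth. Witness-recovery balanced accuracy
  within positive genes plateaus around 0.80 (hinge loss; 0.76 with a
  squared-hinge solver; 0.62 with balanced class weights). Out-of-bag
  scores from the bagged pipeline do not suffer this feedback.
* **The heuristic is not a descent method on the joint objective.** On
  exhaustively enumerable problems (≤ 4 positive bags × ≤ 2 isoforms,
  ≤ 10 negatives) the final objective is never worse than the
  initialisation's, and the median run matches the enumerated optimal
  admissible labeling, but 40–50% of runs end in a local optimum more than
  5% above it — typically one extra isoform kept positive, or a wrong
  witness in an ambiguous bag. This is inherent to threshold-based label
  updates, which deliberately keep a fixed quantile of instances positive
  rather than minimising slack.
* **Multi- vs single-isoform ordering.** In the synthetic world both gene
  classes carry equally strong single witnesses while max-aggregation
  inflates the scores of multi-isoform negatives, so multi-isoform genes do
  not outscore single-isoform ones (measured 0.75 vs 0.76 mean AUC at
  defaults). A real-data advantage for multi-isoform genes would rest on
  properties the generator deliberately leaves out (see above).
* The random-witness baseline redraws witnesses every iteration, so its
  loop terminates only by cycle detection or the iteration cap — by design
  it has no fixed point.

## Problem sizes used in the shipped benchmarks

The test suite and `scripts/acceptance.py` run the default study
conditions (2050 genes × 120 experiments) for witness recovery and the
pipeline-vs-baseline comparison (two-fold CV, seed-averaged), a 425-gene ×
60-experiment condition for the bootstrap-vs-CV agreement check, and
100 enumerable tiny problems for the oracle comparison — sizes at which
every result recomputes from scratch in minutes on one CPU.
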