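# Methods

`abcident` implements a sequence-only pipeline for deciding whether a
protein is an ATP-binding cassette (ABC) transporter: encode each sequence
into a fixed 188-dimensional descriptor vector, balance a heavily
imbalanced positive/negative pool by repeated undersampling, benchmark
five classifier families under stratified cross-validation, and visualize
the feature space with exact t-SNE. This note records the model choices,
parameter conventions and their rationale, and what the synthetic data
generator does and does not emulate.

## The 188D feature encoding

Each protein of length *L* over the 20 canonical amino acids is mapped to
188 numbers in [0, 1]:

* **Amino-acid composition (20 features).** `F1..F20 = n_k / L`, the
  frequency of each residue, in fixed alphabetical one-letter order
  `ACDEFGHIKLMNPQRSTVWY`. No standard ordering exists for this block; the
  alphabetical order is frozen so matrices are comparable across runs.

* **CTD descriptors (8 × 21 = 168 features).** For each of eight
  physicochemical attributes — hydrophobicity, normalized van der Waals
  volume, polarity, polarizability, charge, surface tension, secondary
  structure, solvent accessibility, in that order — the 20 residues are
  partitioned into three classes (see `features.PROPERTY_SCHEMES`), and
  the encoder emits:
  * *Composition* (3): fraction of residues in each class, `CS_i / L`.
  * *Distribution* (15): for each class *i* with *m* occurrences at
    1-based positions `p_1 < … < p_m`, the normalized positions
    `p_1 / L` and `p_r / L` with `r = ceil(q · m)` for
    `q ∈ {0.25, 0.5, 0.75, 1.0}`. Percentile ranks are taken over the
    *occurrences of the class*, not over raw chain positions — the
    standard CTD convention, which keeps every entry in [0, 1] and makes
    the five anchors (first, 25%, 50%, 75%, last occurrence) well defined
    for any *m* ≥ 1. An absent class contributes five zeros; zero is the
    common convention and preserves the [0, 1] range.
  * *Transition* (3): frequencies of adjacent residue pairs whose classes
    are {1,2}, {1,3} and {2,3} *in either order*, each divided by `L − 1`.
    The unordered reading is forced by the feature count: only unordered
    between-class pairs yield exactly 3 transition features per attribute
    and hence 3 + 15 + 3 = 21 per scheme.

The minimum sequence length is 2, enforced at ingest, so the `L − 1`
denominator is always positive. Residues outside the 20-letter alphabet
(B, Z, X, U, O, J) are handled by a configurable policy with default
*drop-residue* (remove the character, keep the sequence); the alternative
*reject-sequence* drops the whole record. The descriptor formulas are
only defined on the 20 canonical letters, and no authoritative convention
exists for ambiguity codes, so the policy is explicit rather than silent.

Because no published worked vector exists for this encoding, correctness
is established by a dual-route test: an independent brute-force
position-scanning encoder (plain string arithmetic, no shared code) must
agree with the vectorized implementation to 1e-12 on 200 random sequences
spanning lengths 2–400.

## Dataset protocol

* **Redundancy reduction** (default threshold 0.6 identity). The built-in
  filter is a greedy incremental clustering in descending length order: a
  sequence joins an existing cluster if its identity to the representative
  is ≥ threshold, otherwise it founds a new cluster; only representatives
  are returned. Identity is defined as matching residues at the best
  ungapped offset divided by the shorter length, with candidate offsets
  proposed by shared 3-mers (diagonal voting). This is a deliberate
  approximation of CD-HIT's greedy algorithm, adequate for filtering
  near-duplicates; an adapter (`method="cdhit"`) shells out to a
  user-installed CD-HIT binary when exact behaviour is required. The
  filter is deterministic for fixed input order, never grows its input,
  and is idempotent.

* **Repeated balanced undersampling.** From a pool of *P* positives and
  *N* ≥ *P* negatives, each of *R* repetitions (default 10) draws *P*
  negatives without replacement to form a balanced training set of 2*P*
  records; the *N − P* negatives not drawn form that repetition's test
  set. Repetitions are independent, so a negative may be sampled in
  several training sets. Each repetition uses a sub-seed derived from the
  master seed by a multiplicative hash (`datasets.derive_seed`), recorded
  in the split manifest, so any single split can be regenerated from the
  master seed alone. At the canonical pool sizes (875 / 9736) this yields
  training sets of 1750 and test sets of 8861.

  An evaluation caveat is inherent to this protocol: the held-out test
  sets contain only negatives, so hold-out "accuracy" is specificity on
  unseen negatives. `evaluate_holdout` reports it as such and flags
  SN/MCC/AUC as undefined on single-class data instead of inventing
  values; mixed-class hold-out evaluation is supported and fully reported
  when a test set has both labels.

## Classifier benchmark

Five classifier families are exposed behind one spec interface, with
defaults chosen to mirror a conventional Weka-style benchmark:

| family | estimator | defaults |
|---|---|---|
| `random_forest` | `RandomForestClassifier` | 100 trees, `floor(log2(188)) + 1 = 8` features per split |
| `c45_tree` | `DecisionTreeClassifier` | entropy splits, `min_samples_leaf = 2` (C4.5-style; exact error-based pruning is out of scope) |
| `naive_bayes` | `GaussianNB` | Gaussian class-conditionals on the continuous features |
| `svm` | `StandardScaler` + `SVC` | linear kernel, C = 1, standardized inputs |
| `knn` | `KNeighborsClassifier` | k = 1 (IBk default) |

Cross-validation is stratified k-fold (default 10), seeded, with folds
balanced to within one sample of the global class proportions. Confusion
counts are pooled over folds; out-of-fold decision scores (class-1
probability, or the decision function for the SVM) are pooled into one
ROC curve. An optional small grid search (`DEFAULT_GRIDS`) can be run
inside each fold with 3-fold inner CV; the grids are deliberately small
and documented in code since no authoritative grid exists.

Metrics follow the standard confusion-matrix definitions: ACC, SN
(recall on positives), SP (recall on negatives), and MCC with the
square-root denominator
`(TP·TN − FP·FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))`. A metric whose
denominator is zero is reported as 0 with an explicit `undefined` flag
rather than raising, so aggregation over many splits never aborts. The
ROC sweep groups tied scores into single steps and the trapezoidal AUC
therefore equals the tie-corrected Mann–Whitney statistic; this identity
is asserted in tests against a pairwise-comparison oracle. Reports from
the R balanced splits are combined by a weighted average (weights = per-
report sample counts), with per-split values retained for dispersion.

## t-SNE visualization

`tsne_embed` runs t-SNE with defaults: 2 output dimensions, perplexity
10, theta = 0 (exact, non-Barnes–Hut gradients), 1000 iterations, early
exaggeration factor 8, PCA initialization. The early-exaggeration
*duration* is the solver default, as only the factor is specified by
convention. The seed is a required, echoed parameter (default 42). A
minimum of `ceil(3 · perplexity)` samples is enforced. Features are
embedded raw by default — they already live in [0, 1] on comparable
scales — with standardization available as a flag. Because a t-SNE
embedding is arbitrary up to rotation/translation/scale, all quality
assertions use label-relative statistics only: silhouette score and
k-nearest-neighbor label purity, the latter compared against permuted
labels as a paired null.

## Synthetic data generator

`synthetic.generate_dataset` emulates a two-class protein pool separable
by amino-acid composition bias. Negatives are i.i.d. sequences from a
background residue distribution (uniform over the 20 letters by default;
an average natural-frequency table is available). Positives raise the
total probability of a biased residue set by an effect size δ ∈ [0, 1]
(proportionally within the set, renormalizing the rest). The default
biased set is the hydrophobic class C, V, L, I, M, F, W, so the signal is
visible to the 188D encoder by construction; δ = 0 makes the classes
exchangeable. Defaults: 500 sequences per class, lengths uniform on
50–300 (a realistic span for single-domain proteins while keeping
encoding cheap), δ = 0.3, single seed driving everything.

What the generator does **not** emulate: domain architecture (no NBD/TMD
motifs or any positional structure — residues are i.i.d., so distribution
and transition features carry no extra signal beyond composition),
homology and redundancy structure, length–class correlations, and
ambiguity codes. Passing tests on synthetic data therefore demonstrate
that the pipeline is mechanically correct and that composition signal of
a known size is recovered; they do not certify real-data accuracy for
transporter identification, which depends on curated positive/negative
pools.

## Numerical and design notes

* All randomness flows from explicit seeds; sub-seeds are derived per
  stage and repetition from the master seed with distinct namespaces, and
  are kept below 2^31.
* The pipeline manifest records the config, per-stage summaries, derived
  seeds and a SHA-256 digest of every artifact; it contains no
  timestamps, so a rerun with the same config is byte-identical.
* Feature computation is exact rational arithmetic realized in floating
  point (counts divided by L or L−1); the only tolerance in the encoder
  tests (1e-12) covers float summation order.
* Degenerate inputs: length-1 sequences are rejected at ingest;
  single-class matrices are rejected by `cross_validate` and ROC;
  empty test sets are rejected by `evaluate_holdout`; an absent external
  clustering binary raises a configuration error rather than silently
  falling back.
* Test problem sizes (e.g. 500/500 sequences for classifier power,
  200 samples for embedding checks) are chosen so the full suite
  exercises every stage at statistically meaningful scale while staying
  fast on a single CPU.

## Known limitations

* The built-in redundancy filter is ungapped and greedy; it can keep
  pairs that gapped alignment would merge. Use the CD-HIT adapter when
  fidelity to that tool matters.
* `c45_tree` approximates C4.5 (entropy splits, leaf-size pruning); it is
  not bit-compatible with J48.
* Hold-out evaluation on the protocol's negative-only test sets measures
  specificity only; claims about sensitivity must come from
  cross-validation or a mixed test set.
* Real-data performance numbers depend on the external curated dataset
  and are outside what the synthetic generator can reproduce.
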