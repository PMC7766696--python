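# Methods

## Feature encoding

The residue adjacency matrix for a lysine at 1-based position `k` holds,
in row `i` and column `j`, the absolute index distance from `k` to the
`j`-th nearest residue of type `i`. Conventions fixed by the
implementation:

- **Row order** is alphabetical by full amino-acid name
  (`ARNDCEQGHILKMFPSTWYV`): row 1 Alanine, row 19 Tyrosine.
- **Self-distance**: the target lysine is its own nearest lysine, so the
  K row always starts with 0.
- **Imputation**: a row with `1 <= m < n` observed distances is padded
  with the mean of those `m` values (rule A); a row with no occurrences
  is filled with the mean of *all* observed distances in the matrix,
  excluding rule-A padding (rule B). Rule B's pool is never empty
  because the K row always contributes its 0. An `imputed_mask` records
  which slots were filled.
- **Ties** (equidistant occurrences up- and downstream) contribute equal
  values, so their ordering is immaterial.
- **Non-standard codes** (X, B, Z, U, O) occupy sequence positions —
  they lengthen other residues' distances across them — but contribute
  to no row.
- **Flattening** is row-major (residue type major, neighbor rank minor),
  a pure bookkeeping choice recorded in the schema so vectors from
  different runs are positionally comparable.

`n` defaults to 6; the default retained-row set drops E, D, L, V, F, T
(the published elimination result), giving 84 features.

## Imbalance cleaning

For each positive training sample its `N` nearest *negative* samples
(Euclidean on the current feature schema, unstandardized by default) are
marked; the union of marked negatives is removed. The neighbor search is
restricted to negatives so the per-positive removal budget is exactly
`N`. Ties at the `N`-th neighbor break by input order via a stable sort,
making runs deterministic. The removed set is monotone in `N`, so
tuning scans upward from the observed imbalance ratio until the
negatives-per-positive ratio is at or below the target (2 by default for
tuned runs); the scan always terminates because the ratio reaches 0 when
every negative is removed. Cleaning is recomputed inside each training
fold and, during feature selection, inside each candidate's reduced
schema — the removed set legitimately depends on the metric space it is
computed in.

## Classifier

A linear C-SVC (libsvm through scikit-learn), `C = 1`, no class weights,
no feature scaling by default; standardization (fit on the training fold
only) is available as an option. Calls are derived from the decision
function with the fixed contract *positive iff score > 0*. The solver
tolerance defaults to libsvm's 1e-3; at that tolerance scores can differ
by ~1e-4 under training-row permutation, and a tighter tolerance (1e-7)
restores agreement to ~1e-6 at a substantial fit-time cost on
high-dimensional overlapping data — the default therefore favors speed,
and the tolerance is exposed on `ModelConfig`.

## Evaluation protocol

Sixfold cross-validation, folds stratified by class and shuffled under
the run seed (stratification prevents positive-free test folds under
heavy imbalance). Per fold: clean the union of the other five folds,
train, score the *entire* untouched held-out fold. The five metrics are
computed per fold and arithmetically averaged; a metric with a zero
denominator in some fold is reported as 0, flagged as undefined, and
excluded from that metric's average with a warning. Decision scores are
pooled across folds (each site is scored exactly once) for a single ROC
curve and AUC; per-fold AUCs are also recorded. An internal assertion
enforces that no cleaned-away index ever belongs to the held-out fold.

## Feature selection

Backward elimination over residue-type rows, scored by mean CV
sensitivity. The search always runs to `max_levels` (default 19) and the
best level is chosen afterwards by argmax, because sensitivity beyond a
local peak can only be ruled out by evaluating past it. Fold assignments
are fixed by the seed, so all candidates within a run are compared on
identical splits. Within-level ties break toward the residue earliest in
alphabet order. Candidate evaluations are independent and may run under
joblib parallelism; the selected path is independent of execution order.
A full 19-level run costs `sum(k, k=20..2)` candidate CVs of 6 fits
each.

## Synthetic data generator

Sequences are i.i.d. uniform over the 20 standard residues (so lysines
appear at rate 1/20 and sequence composition carries no confound), with
lengths uniform in a configurable range. All lysines are enumerated as
sites; a configurable fraction is labeled positive (default 0.034,
emulating the ~1:29 benchmark imbalance). The planted signal is *local
compositional enrichment*: within `signal_window` (default 7) of a
positive site, non-lysine residues are replaced by a draw from
`signal_residues` (default A/G/S) with probability
`signal_strength / (1 + signal_strength)`. Enrichment rather than a
motif is planted because adjacency-matrix features measure residue-type
proximity — the signal is expressible in the feature space by
construction. Lysine positions are never rewritten, so the K row carries
no planted signal and annotated sites stay valid.

When `signal_strength > 0`, positives are drawn preferentially from
lysines with no other lysine within twice the window. Without this
isolation rule, negative lysines inside an enriched window would carry
the positive signature themselves — label contamination that caps
attainable AUC near 0.9 regardless of strength. At strength 0 no filter
is applied: null labels must be exchangeable with respect to every
feature, including the K row.

What the generator does *not* emulate: realistic proteome composition,
homology/redundancy structure between sequences (the benchmark was
redundancy-reduced upstream at 40% identity), motif-grammar signals, or
position-specific conservation. Passing tests on synthetic data
demonstrate that the pipeline recovers compositional signals and is
calibrated at chance under the null; they do not certify performance on
real phosphoglycerylation data.

## Calibration test conditions

- **Null calibration** uses a *balanced* signal-free dataset (~400
  sites, positive fraction 0.5). The chance band [0.4, 0.6] for accuracy
  is centered at 0.5 and presumes a balanced test set; under heavy test
  imbalance a chance-level classifier trained at the tuned ~1:2 ratio
  sits near the majority-class rate instead, which measures the class
  prior rather than the classifier.
- **Signal recovery** uses strength 20 (replacement probability ~0.95),
  window 7, positive fraction 0.15, ~70 proteins; pooled AUC lands
  around 0.95-0.98. The noised-row elimination replicates overwrite one
  residue row with uniform(0, 500) noise: the scale is chosen so the
  noise corrupts both the cleaning metric and the SVM margin geometry —
  low-amplitude noise is simply down-weighted by the SVM and its removal
  is undetectable by a sensitivity criterion.

## Numerical choices and degenerate inputs

- Undefined metric ratios report 0 with an explicit flag, never NaN.
- `N >= #negatives` in cleaning removes every negative (warned, defined).
- Cleaning with zero positives removes nothing (warned).
- A training set reduced to a single class by cleaning raises at `train`.
- All randomness flows from explicit integer seeds (numpy `default_rng`,
  scikit-learn `random_state`); identical seeds give identical runs.

## Known limitations

- The published headline metrics are not desk-reproducible: they depend
  on the authors' benchmark files, unstated fold seeds, and unstated
  SVM parameters (`C`, tolerance, weighting). With the benchmark files
  the default configuration reproduces the published pipeline; metric
  agreement is expected only within seed-level variability.
- The encoding ignores residue order beyond distance (no
  directionality), and the cleaning treatment discards informative hard
  negatives by design — both inherited properties of the method.
- Feature selection cost grows quadratically in alphabet size times CV
  cost; full 19-level runs on benchmark-sized data are minutes-scale,
  not interactive.
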