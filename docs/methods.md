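# Methods

This note documents the statistical procedures implemented in
`facscomplexity`, the assumptions behind them, the choices made where
the design was genuinely open, and what the synthetic-data tests do and
do not establish about real observational data.

## Data model

The unit of observation is a 500 ms time block within a social
interaction. The analysis substrate (`AUMatrix`) is a binary matrix
with one row per block and one column per Action Unit (AU) or Action
Descriptor; an entry is 1 iff that AU was active at any point during
the block. Each row carries the interaction, subject, species and
social context (affiliative, aggressive, submissive, or unclear) of
its interaction, and all rows of one interaction share that metadata.

`events_to_blocks` converts an event log (one record per AU activation
interval, with per-interaction durations) into this matrix:

- **Overlap rule.** An AU codes 1 in a block when its half-open
  activation interval [start, stop) intersects the block's half-open
  interval. Any overlap counts, however brief. This is the simplest
  rule consistent with the block-count law below; a majority-overlap
  rule would discard brief activations entirely at some alignments.
- **Block-count law.** An interaction of duration *d* yields
  ⌈d / 0.5 s⌉ rows; the final block may be short so no coded time is
  discarded. For integer-second durations this is exactly 2*d* rows,
  which the test suite asserts on random synthetic logs.
- **Neutral blocks.** Rows with no active AU are retained in the
  matrix. Downstream, a neutral face is not treated as a signal:
  entropy drops all-zero rows by default (option `drop_neutral=False`
  to count the neutral configuration), specificity counts no
  combinations for them, and classification drops them by default
  (`include_neutral=True` to keep them) because an all-zero feature
  vector is identical in every context and only adds irreducible
  error.
- **AU labels** are opaque strings; variant merging (e.g. collapsing
  lip-pucker subtypes into one label) is the caller's responsibility
  upstream.

## Entropy ratio

The repertoire of a data subset (one species × one context, or a
species pooled over all four contexts) is the frequency distribution
of its unique full-row AU configurations. Its plug-in Shannon entropy
is H = −Σᵢ pᵢ ln pᵢ (natural log; the ratio below is base-invariant,
which a test verifies). H alone is incomparable across datasets that
differ in repertoire size and combination-size structure, so it is
normalized by the **expected entropy** under a row-sum-preserving
null: each block's k active AUs are reassigned to k columns drawn
uniformly without replacement from the subset's full column set, and
the plug-in entropy of the randomized matrix is averaged over
`n_rand = 100` replicates. The **entropy ratio** = observed/expected
is ≈0 for a stereotyped repertoire and ≈1 when observed use matches
random recombination at the observed combination sizes. Replacement
columns are drawn uniformly rather than proportionally to marginal AU
frequencies — "random use" is interpreted as uniform access to the
anatomical repertoire.

Both entropies are plug-in estimates on the same number of blocks, so
their finite-sample biases largely cancel in the ratio; no analytic
bias correction (Miller–Madow etc.) is applied. A degenerate subset
whose null entropy is 0 (e.g. a single column, or all columns active
in every row) raises an explicit error rather than returning 0/0.

Uncertainty: the ratio is recomputed on `n_boot = 100` with-replacement
resamples of blocks, each replicate with its own randomization null.
Two repertoires are reported *meaningfully different* iff their
bootstrap [min, max] ranges are disjoint. Blocks are resampled
independently; blocks within an interaction are temporally
autocorrelated, so this bootstrap understates uncertainty somewhat —
an interaction-level bootstrap would be the conservative alternative.
Bootstrap replicates contain on average ~63% of the distinct blocks,
which biases replicate entropies slightly below the point estimate;
comparisons between species are unaffected since all are bootstrapped
identically.

An exactness check: on small matrices the Monte-Carlo expected entropy
is compared against full enumeration of all per-row column choices
(the test holds to within 3 Monte-Carlo standard errors).

## Context specificity and bias correction

For an AU combination *C* (any nonempty subset of co-active AUs, sizes
1–11) and context *c*, specificity is the conditional probability
P(c | C): blocks of *c* containing *C* (subset containment) divided by
blocks containing *C* across the three clear contexts. Unclear-context
rows are excluded from specificity (the published summaries cover three
contexts); an option includes them.

**Imbalance bias.** With unequal context sample sizes the majority
context wins the count ratio by volume alone. The correction keeps all
observations and upsamples each minority context's rows with
replacement to the majority count before computing the conditional
probability. The package's bias experiment
(`bias_correction_experiment`) plants graded activation profiles,
draws 10:5:1-imbalanced datasets, and measures mean absolute error
against the analytic truth: upsampling reduces MAE (≈0.14 vs ≈0.17
over 20 draws at 1000/500/100 rows) and seed-averaged corrected
estimates land within 0.05 of truth for combinations expected ≥50
times in *every* context of a balanced draw. That per-context
qualification matters: for combinations that are common overall but
expected only a handful of times in the minority context's raw sample,
upsampling inflates the minority count's variance tenfold and the
count ratio retains a nonlinearity (Jensen) bias that no amount of
upsampling or seed-averaging removes. Upsampling corrects the
*sample-size* bias, not small-sample noise in the minority context.

**Rarity filter.** Whether a combination is "used" in a context is
decided on the original (pre-upsampling) data: observed frequency ≥1%
of that context's blocks. Deciding on corrected counts would let the
resampling itself change which combinations qualify. Summaries report
mean, SD and count of non-rare combinations per context plus the
proportions with high (>0.8), moderate (0.4–0.8) and low (<0.4)
specificity. A single upsampling draw is used by default (the seed is
recorded in the output); averaging over several draws is available to
reduce resampling noise.

**Bipartite network.** Single AUs and contexts form a bipartite graph;
an edge joins AU and context when the AU clears the 1% threshold
there, weighted by specificity. An AU's degree is the number of
contexts it is used in; the mean degree over AUs (isolated AUs
included) summarizes repertoire flexibility.

## Context classification

Random forest with 500 trees, 4 candidate predictors per split, Gini
impurity, and a minimum of 10 data points for a node to be split
further. Data are the clear-context blocks (features = the binary AU
columns), split 70/30 with per-context stratification. Minority
contexts in the training set are oversampled to the majority count
with SMOTE: each synthetic observation interpolates between a random
minority row and one of its k = 5 nearest same-context neighbors (k is
the algorithm's conventional default). Interpolated features are
fractional in [0, 1] and are fed to the forest unrounded — trees split
on thresholds, so fractional values are valid and preserve the
interpolation geometry.

Performance is reported as the confusion matrix (rows = predicted,
columns = true) with observed accuracy, chance-expected accuracy from
the margins, and Cohen's kappa κ = (p_obs − p_exp)/(1 − p_exp), the
appropriate summary under class imbalance. The package's kappa is
validated against scikit-learn's on random labelings and checked for
invariance under simultaneous row/column permutation.

The inter-coder `agreement_index` (2 × agreements / total AUs scored
by both coders, on multisets) is provided for reliability reporting.

## Synthetic generator

`simulate_matrix` draws blocks independently: within a block each AU
activates with its context's profile probability (independent
Bernoulli), and blocks exceeding the maximum combination size (11, the
cap used throughout) are resampled by rejection. Blocks are grouped
into 40-block synthetic interactions so the matrix carries well-formed
metadata. `simulate_event_log` draws integer-second interactions
(geometric durations around a configurable mean), samples block
activity the same way, and merges consecutive active blocks into
activation intervals — converting the log back to blocks reproduces
the draw exactly, which tests the I/O path end to end.

Defaults encode the canonical bias-correction scenario: 3 contexts,
10 AUs, rows imbalanced 1000/500/100 (10:5:1). Two profile factories
cover the interesting regimes: `graded_profiles` assigns each AU a
home context and a leakage factor ranging from 0 to 0.8, yielding
single-AU true specificities spanning ≈0.4–1.0; `overlap_profiles(o)`
interpolates between perfectly separable contexts (o = 0) and
identical ones (o = 1). Ground-truth specificity is analytic:
spec(C | c) = q_c(C)/Σ_{c'} q_{c'}(C) with q_c(C) = Π_{j∈C} p_{c,j},
ignoring the rejection truncation (with 10 AUs the size cap of 11
never binds, so the formula is exact for the defaults).

What the generator does **not** emulate: temporal autocorrelation
between consecutive blocks of an interaction, subject-level or dyadic
effects, and within-row AU dependence beyond the size cap. Passing
tests therefore establish the estimators' correctness under
independent sampling; on real data, where blocks within an interaction
are strongly dependent, bootstrap ranges will be optimistically narrow
and effective sample sizes smaller than row counts.

## Reproducibility and numerics

- Every public operation with randomness takes a seed; the pipeline
  derives per-stage seeds by hashing the master seed with the stage
  name (SHA-256, reduced below 2³¹), so adding a stage never perturbs
  the others.
- Test and experiment problem sizes (e.g. 20 draws of 1600 rows for
  the bias experiment, 5000 rows for the random-use entropy check,
  ~3000 test blocks for the permuted-label check) were chosen as the
  smallest sizes at which the asymptotic properties under test are
  expected to hold with comfortable margin under the generator's
  defaults.
- Ties and degenerate inputs: zero-total confusion matrices,
  single-class kappa (expected accuracy 1), empty subsets, and
  zero-expected-entropy matrices all raise typed errors rather than
  returning NaN.

## Known limitations

- The row-randomization null assumes all AU columns are anatomically
  available to every subject; species differences in codable AUs are
  handled by building per-species matrices upstream.
- The specificity estimator remains noisy (and slightly biased, see
  above) for combinations that are rare in the minority context even
  after upsampling; the 1% rarity filter removes most but not all of
  that regime.
- Kappa recomputed from a published confusion matrix can differ in the
  second decimal from a kappa computed before rounding/aggregation of
  the underlying predictions; the package reports kappa from counts
  exactly as defined.
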