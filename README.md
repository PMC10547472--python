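# facscomplexity

Quantifying the communicative complexity of facial behavior coded with
the Facial Action Coding System (FACS).

Ethologists studying animal communication — e.g. facial signaling in
macaques coded with MaqFACS — need to compare how *uncertain* (and
therefore how potentially information-rich) different species'
repertoires are. This package implements a complete pipeline for that
question, starting from time-coded annotations of Action Unit (AU)
activity in social interactions:

1. **Block matrix construction.** Interactions are cut into 500 ms
   blocks; each block records the binary configuration of co-active
   AUs. An interaction of *d* whole seconds yields exactly 2*d* rows.
2. **Entropy ratio.** The diversity of configuration use is measured
   by Shannon entropy H = −Σᵢ pᵢ ln pᵢ over the unique AU
   configurations, normalized by the expected entropy under a null in
   which each block's active AUs are reassigned to uniformly random
   columns (preserving per-block combination size, averaged over 100
   randomizations). The ratio is 0 for a fully stereotyped repertoire
   and ≈1 when AU use is indistinguishable from random recombination.
   Uncertainty is quantified by recomputing the ratio on 100 bootstrap
   resamples of blocks; two repertoires differ meaningfully when their
   bootstrap ranges do not overlap.
3. **Context specificity.** For every AU combination *C* (all
   sub-combinations of co-active AUs, sizes 1–11), specificity for
   context *c* is P(c | C) — the blocks of context *c* containing *C*
   divided by the blocks containing *C* across the analyzed contexts
   (affiliative, aggressive, submissive). Because imbalanced context
   sample sizes inflate specificity toward the majority context,
   minority contexts are upsampled to the majority size first.
   Combinations seen in <1% of a context's blocks are flagged rare and
   excluded from summaries. Single-AU specificities are exported as a
   bipartite AU–context network (edge iff the AU clears the 1%
   threshold in that context, weighted by specificity).
4. **Context prediction.** A random forest (500 trees, 4 candidate
   predictors per split, minimum node size 10) predicts context from
   the AU configuration after a 70/30 stratified split and SMOTE
   oversampling of minority contexts in training. Performance is the
   confusion matrix and Cohen's kappa
   κ = (p_obs − p_exp)/(1 − p_exp).

A seeded synthetic generator with planted per-context AU activation
profiles provides ground truth for every stage, including the analytic
specificity of any combination, so the whole pipeline is testable
without observational data.

## Worked example

```python
import facscomplexity as fc

cfg = fc.GeneratorConfig(
    activation_profiles=fc.overlap_profiles(0.4),  # moderate context overlap
    context_row_counts=(1500, 700, 300),           # imbalanced contexts
    seed=21,
)
matrix, truth = fc.simulate_matrix(cfg)

train, test = fc.stratified_split(matrix, fc.SplitSpec(seed=22))
balanced = fc.smote_balance(train, seed=23)
report = fc.train_and_evaluate(balanced, test, fc.ForestSpec(seed=24))
print(report.confusion)
print(report.kappa)
```

prints

```
             affiliative  aggressive  submissive
affiliative          321          63          26
aggressive            60         107          24
submissive            50          26          36
0.376...
```

i.e. with planted profiles that overlap moderately across contexts, the
forest recovers context far better than chance (κ = 0.38 > 0) but far
from perfectly — exactly the intermediate-uncertainty regime. Setting
the overlap to 0 (context-exclusive AUs) drives κ to 1; overlap 1
(identical profiles) drives it to 0.

The `examples/` directory holds one short script per capability
(matrix construction, entropy ratios with bootstrap comparison, the
specificity bias correction, classification, and the one-config
pipeline). A thin CLI mirrors the library:

```bash
facscomplexity simulate --seed 3 --out matrix.csv
facscomplexity entropy --matrix matrix.csv --context affiliative --seed 4 --out entropy.json
facscomplexity specificity --matrix matrix.csv --seed 5 --out spec.csv --network net.json
facscomplexity classify --matrix matrix.csv --seed 6 --out report.json
```

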