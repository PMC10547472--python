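"""Entropy ratio of two planted repertoires, with bootstrap comparison.

A repertoire whose AU combinations are context-exclusive and stereotyped
has low entropy relative to random AU use; one whose AUs are shared
across contexts and used diversely scores higher.  The bootstrap ranges
tell us whether the difference is meaningful (ranges disjoint) or not.
"""

import facscomplexity as fc

results = {}
for name, overlap in [("stereotyped", 0.0), ("flexible", 0.9)]:
    cfg = fc.GeneratorConfig(
        activation_profiles=fc.overlap_profiles(overlap),
        context_row_counts=(800, 800, 800),
        seed=7,
    )
    matrix, _ = fc.simulate_matrix(cfg)
    sub = matrix.subset(contexts="affiliative")
    res = fc.bootstrap_entropy_ratio(sub, n_boot=30, n_rand=30, seed=11)
    s = res.bootstrap_summary
    results[name] = res
    print(f"{name:12s} observed H = {res.observed_H:.3f} nats, "
          f"expected H = {res.expected_H:.3f}, ratio = {res.ratio:.3f} "
          f"(bootstrap mean {s.mean:.3f}, range {s.min:.3f}-{s.max:.3f})")

verdict = fc.compare_ratio_distributions(results["flexible"], results["stereotyped"])
print(f"\ncomparison: {verdict}")
print("ratio near 0 = a few stereotyped combinations dominate; "
      "near 1 = AU use indistinguishable from random recombination.")
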