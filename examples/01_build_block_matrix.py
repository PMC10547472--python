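"""Build the binary 500 ms block matrix from an event-coded annotation log.

Simulates a small annotation log (one record per AU activation interval),
converts it to the block matrix, and checks the block-count law: an
interaction of d whole seconds yields exactly 2d blocks of 500 ms.
"""

import facscomplexity as fc

cfg = fc.GeneratorConfig(context_row_counts=(60, 30, 10), seed=42)
log = fc.simulate_event_log(cfg, mean_interaction_s=10)
matrix = fc.events_to_blocks(log)

print(f"{len(log.interactions)} interactions, {len(log)} AU activation events")
print(f"block matrix: {len(matrix)} rows x {len(matrix.au_columns)} AU columns")
print(f"validation: {fc.validate(matrix)}")

total_seconds = int(log.interactions["duration_s"].sum())
print(f"total duration {total_seconds} s -> {len(matrix)} blocks "
      f"(= 2 x {total_seconds}: each second of interaction is two 500 ms blocks)")
print("\nfirst rows:")
print(matrix.df.head(4).to_string(index=False))
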