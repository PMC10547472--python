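"""Reusable in-silico experiments on the synthetic generator.

These drive the package's own validation studies: most importantly the
specificity bias-correction experiment, which plants graded activation
profiles, draws imbalanced datasets (10:5:1 context ratio), and
measures how far specificity estimates computed with and without
minority-context upsampling deviate from the analytic ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CLEAR_CONTEXTS
from .simulate import GeneratorConfig, GroundTruth, graded_profiles, simulate_matrix
from .specificity import enumerate_combinations, specificity_table


def raw_specificity(matrix, contexts=CLEAR_CONTEXTS, max_size: int = 11) -> pd.DataFrame:
    """Conditional probability of context given combination WITHOUT the
    upsampling correction — the naive estimator the correction fixes."""
    counts = enumerate_combinations(matrix, max_size, contexts=tuple(contexts))
    piv = counts.pivot_table(
        index="combination", columns="context", values="count", fill_value=0
    ).reindex(columns=list(contexts), fill_value=0)
    return piv.div(piv.sum(axis=1), axis=0)


@dataclass
class BiasCorrectionResult:
    """Outcome of the imbalanced-specificity experiment."""

    mae_corrected: float
    mae_uncorrected: float
    n_seeds: int
    n_cells: int
    #: per (combination, context) mean corrected estimate and truth, for
    #: combinations expected at least `min_balanced_occurrences` times in
    #: EVERY context of a balanced draw at the majority size — the regime
    #: where each context contributes enough occurrences for the
    #: conditional-probability estimate to stabilize
    common_estimates: pd.DataFrame = field(repr=False, default=None)

    @property
    def max_error_common(self) -> float:
        d = self.common_estimates
        return float((d["estimate"] - d["truth"]).abs().max())


def bias_correction_experiment(
    n_seeds: int = 20,
    counts: tuple[int, int, int] = (1000, 500, 100),
    profiles: np.ndarray | None = None,
    seed: int = 0,
    max_size: int = 11,
    min_balanced_occurrences: int = 50,
) -> BiasCorrectionResult:
    """Replicate the imbalanced-data specificity bias study.

    Over ``n_seeds`` independent draws with context row counts at the
    given (10:5:1 by default) imbalance, compute the mean absolute
    error of specificity against analytic truth for the corrected
    (upsampled) and naive estimators, plus seed-averaged corrected
    estimates for combinations common enough to estimate reliably
    (expected count >= the threshold in every balanced context draw).
    """
    if profiles is None:
        profiles = graded_profiles()
    err_corr, err_raw = [], []
    acc: dict[tuple, list] = {}
    truth: GroundTruth | None = None
    truth_cache: dict[tuple, pd.Series] = {}
    for i in range(n_seeds):
        cfg = GeneratorConfig(
            activation_profiles=profiles,
            context_row_counts=counts,
            seed=(seed + 7919 * i) % (2**31),
        )
        matrix, truth = simulate_matrix(cfg)
        corrected = specificity_table(
            matrix, max_size=max_size, seed=(seed + 104729 * i) % (2**31)
        )
        naive = raw_specificity(matrix, max_size=max_size)
        corr_piv = corrected.table.pivot_table(
            index="combination", columns="context", values="specificity"
        ).reindex(columns=list(CLEAR_CONTEXTS))
        for combo in corr_piv.index:
            if combo not in truth_cache:
                truth_cache[combo] = truth.specificity(list(combo))
            t = truth_cache[combo]
            for ctx in CLEAR_CONTEXTS:
                tv = t[ctx]
                err_corr.append(abs(corr_piv.at[combo, ctx] - tv))
                err_raw.append(abs(naive.at[combo, ctx] - tv))
                acc.setdefault((combo, ctx), []).append(corr_piv.at[combo, ctx])

    n_majority = max(counts)
    rows = []
    for (combo, ctx), vals in acc.items():
        q = truth_cache[combo]
        # a combination is reliably estimable only if every context is
        # expected to contribute enough occurrences at balanced sizes;
        # otherwise the minority-context ratio stays noise-dominated
        balanced_count = n_majority * truth.containment_probability(list(combo)).min()
        if balanced_count >= min_balanced_occurrences:
            rows.append(
                {
                    "combination": combo,
                    "context": ctx,
                    "estimate": float(np.mean(vals)),
                    "truth": float(q[ctx]),
                    "n_seen": len(vals),
                    "expected_balanced_count": float(balanced_count),
                }
            )
    return BiasCorrectionResult(
        mae_corrected=float(np.mean(err_corr)),
        mae_uncorrected=float(np.mean(err_raw)),
        n_seeds=n_seeds,
        n_cells=len(err_corr),
        common_estimates=pd.DataFrame(rows),
    )
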