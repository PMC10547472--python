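"""Synthetic FACS-like data with known ground truth.

Every pipeline stage can be exercised without observational data by
simulating block matrices in which each social context has a planted
per-AU activation profile.  Within a row (a 500 ms block) AUs activate
independently with the probabilities of the row's context, truncated so
no block exceeds a maximum combination size.  Because the generative
model is fully known, the context specificity of every AU combination
has a closed form, which serves as ground truth for the bias-correction
analysis: with equal context weights,

    spec(C | c) = q_c(C) / sum_c' q_c'(C),   q_c(C) = prod_{j in C} p_{c,j}

where ``p_{c,j}`` is context c's activation probability for AU j and
``q_c(C)`` the probability that a block from context c contains the
combination C (as a subset of its active set).

The canonical imbalance scenario — three contexts with row counts at a
10:5:1 ratio — demonstrates how specificity estimates computed on raw
imbalanced data are inflated toward the majority context, and how
upsampling the minority contexts removes that bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import AUMatrix, EventLog, META_COLUMNS
from .errors import ValidationError

#: Blocks per synthetic interaction (20 s at 500 ms per block).
_BLOCKS_PER_INTERACTION = 40


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic FACS generator.

    Defaults reproduce the canonical bias-correction scenario: three
    contexts (A, B, C) imbalanced at a 10:5:1 ratio (1000/500/100 rows),
    ten AUs with graded context profiles, and combinations capped at
    size 11.
    """

    n_contexts: int = 3
    n_aus: int = 10
    context_row_counts: Sequence[int] = (1000, 500, 100)
    activation_profiles: np.ndarray | None = None  # (n_contexts, n_aus)
    max_combination_size: int = 11
    seed: int | None = None
    context_labels: Sequence[str] | None = None
    au_labels: Sequence[str] | None = None
    species: str = "sim"

    def __post_init__(self):
        if self.n_aus < 1 or self.n_contexts < 1:
            raise ValidationError("need at least one AU and one context")
        if len(self.context_row_counts) != self.n_contexts:
            raise ValidationError("context_row_counts length must equal n_contexts")
        if any(n < 1 for n in self.context_row_counts):
            raise ValidationError("row counts must be >= 1")
        if self.activation_profiles is None:
            self.activation_profiles = graded_profiles(self.n_contexts, self.n_aus)
        self.activation_profiles = np.asarray(self.activation_profiles, dtype=float)
        if self.activation_profiles.shape != (self.n_contexts, self.n_aus):
            raise ValidationError(
                "activation_profiles must have shape (n_contexts, n_aus)"
            )
        if ((self.activation_profiles < 0) | (self.activation_profiles > 1)).any():
            raise ValidationError("activation probabilities must lie in [0, 1]")
        if self.context_labels is None:
            self.context_labels = [chr(ord("A") + i) for i in range(self.n_contexts)]
        if self.au_labels is None:
            self.au_labels = [f"AU{j + 1}" for j in range(self.n_aus)]


def graded_profiles(
    n_contexts: int = 3, n_aus: int = 10, p_lo: float = 0.15, p_hi: float = 0.5
) -> np.ndarray:
    """Planted activation profiles with a gradient of true specificity.

    AU ``j`` is assigned a home context (round-robin) where it activates
    with probability in ``[p_lo, p_hi]`` (increasing across AUs), and
    elsewhere with that probability scaled by a leakage factor that
    ranges from 0 (fully exclusive) to 0.8 (nearly shared).  The
    resulting single-AU true specificities span roughly 0.4–1.0, so the
    planted repertoire contains both context-specific and flexibly used
    elements.
    """
    own = np.linspace(p_lo, p_hi, n_aus)
    leak = np.linspace(0.0, 0.8, n_aus)
    profiles = np.empty((n_contexts, n_aus))
    for j in range(n_aus):
        home = j % n_contexts
        for c in range(n_contexts):
            profiles[c, j] = own[j] if c == home else own[j] * leak[j]
    return profiles


def overlap_profiles(
    overlap: float, n_contexts: int = 3, n_aus: int = 10, p_active: float = 0.4
) -> np.ndarray:
    """Profiles with a single overlap knob in [0, 1].

    At ``overlap=0`` each AU is exclusive to its home context
    (contexts perfectly separable from facial behavior); at
    ``overlap=1`` all contexts share identical profiles (context
    carries no signal).  Used for ladders of increasing communicative
    ambiguity.
    """
    if not 0 <= overlap <= 1:
        raise ValidationError("overlap must lie in [0, 1]")
    profiles = np.full((n_contexts, n_aus), overlap * p_active)
    for j in range(n_aus):
        profiles[j % n_contexts, j] = p_active
    return profiles


@dataclass
class GroundTruth:
    """Analytic context specificity of the planted generative model."""

    activation_profiles: np.ndarray
    context_labels: Sequence[str]
    au_labels: Sequence[str]

    def containment_probability(self, combination: Iterable[str]) -> np.ndarray:
        """Per-context probability that a block contains the combination."""
        idx = [list(self.au_labels).index(a) for a in combination]
        if not idx:
            raise ValidationError("combination must be nonempty")
        return self.activation_profiles[:, idx].prod(axis=1)

    def specificity(self, combination: Iterable[str]) -> pd.Series:
        """True specificity of a combination under equal context weights.

        Values across contexts sum to 1 whenever the combination has
        nonzero probability in at least one context.
        """
        q = self.containment_probability(combination)
        total = q.sum()
        if total == 0:
            return pd.Series(np.nan, index=list(self.context_labels))
        return pd.Series(q / total, index=list(self.context_labels))


def _sample_blocks(
    rng: np.random.Generator, probs: np.ndarray, n_rows: int, max_size: int
) -> np.ndarray:
    """Independent Bernoulli rows; rows exceeding max_size are resampled."""
    out = (rng.random((n_rows, probs.size)) < probs).astype(np.uint8)
    for _ in range(1000):
        bad = out.sum(axis=1) > max_size
        if not bad.any():
            return out
        out[bad] = (rng.random((int(bad.sum()), probs.size)) < probs).astype(np.uint8)
    raise ValidationError(
        "could not satisfy max_combination_size; profiles activate too many AUs"
    )


def simulate_matrix(config: GeneratorConfig) -> tuple[AUMatrix, GroundTruth]:
    """Draw a block matrix from planted per-context activation profiles.

    Rows are independent; within a row each AU activates with its
    context's profile probability, and rows whose active set would
    exceed ``max_combination_size`` are resampled.  Rows are grouped
    into synthetic interactions of 40 blocks so the matrix carries
    well-formed interaction metadata.  Returns the matrix and the
    analytic :class:`GroundTruth`.
    """
    if config.activation_profiles.sum() == 0:
        raise ValidationError("degenerate config: all activation probabilities are 0")
    rng = np.random.default_rng(config.seed)
    frames = []
    for c, ctx in enumerate(config.context_labels):
        n = int(config.context_row_counts[c])
        entries = _sample_blocks(
            rng, config.activation_profiles[c], n, config.max_combination_size
        )
        block_idx = np.arange(n)
        inter = block_idx // _BLOCKS_PER_INTERACTION
        meta = pd.DataFrame(
            {
                "interaction_id": [f"{ctx}-{i:04d}" for i in inter],
                "subject_id": [f"s{(i % 10) + 1:02d}" for i in inter],
                "species": config.species,
                "context": _context_name(ctx),
            }
        )
        frames.append(
            pd.concat(
                [meta, pd.DataFrame(entries, columns=list(config.au_labels))], axis=1
            )
        )
    matrix = AUMatrix(pd.concat(frames, ignore_index=True))
    truth = GroundTruth(
        config.activation_profiles,
        [_context_name(c) for c in config.context_labels],
        list(config.au_labels),
    )
    return matrix, truth


#: Short simulation context labels map onto the three clear social contexts
#: so downstream defaults (which analyze affiliative/aggressive/submissive)
#: apply unchanged.
_CONTEXT_ALIASES: Mapping[str, str] = {
    "A": "affiliative",
    "B": "aggressive",
    "C": "submissive",
}


def _context_name(label: str) -> str:
    return _CONTEXT_ALIASES.get(label, label)


def simulate_event_log(
    config: GeneratorConfig, mean_interaction_s: float = 20.0
) -> EventLog:
    """Simulate an event-coded annotation log.

    Interactions have integer-second durations (geometric around the
    requested mean, at least 1 s).  Block activity is drawn exactly as
    in :func:`simulate_matrix`; runs of consecutive active blocks per
    AU are then merged into activation intervals, so converting the log
    back to blocks reproduces the sampled matrix.  Per context, enough
    interactions are generated to cover at least the configured row
    count.
    """
    if mean_interaction_s <= 0:
        raise ValidationError("mean_interaction_s must be positive")
    rng = np.random.default_rng(config.seed)
    records = []
    for c, ctx in enumerate(config.context_labels):
        blocks_needed = int(config.context_row_counts[c])
        done = 0
        k = 0
        while done < blocks_needed:
            dur = int(max(1, rng.geometric(1.0 / max(mean_interaction_s, 1.0))))
            n_blocks = 2 * dur
            entries = _sample_blocks(
                rng, config.activation_profiles[c], n_blocks, config.max_combination_size
            )
            iid = f"{ctx}-{k:04d}"
            subj = f"s{(k % 10) + 1:02d}"
            base = {
                "interaction_id": iid,
                "subject_id": subj,
                "species": config.species,
                "context": _context_name(ctx),
                "duration_s": float(dur),
            }
            any_event = False
            for j, au in enumerate(config.au_labels):
                col = entries[:, j]
                # runs of consecutive active blocks -> one event each
                edges = np.flatnonzero(np.diff(np.concatenate(([0], col, [0]))))
                for start_b, stop_b in zip(edges[::2], edges[1::2]):
                    records.append(
                        {**base, "au": au, "start_s": start_b * 0.5, "stop_s": stop_b * 0.5}
                    )
                    any_event = True
            if not any_event:
                records.append({**base, "au": "", "start_s": np.nan, "stop_s": np.nan})
            done += n_blocks
            k += 1
    return EventLog(pd.DataFrame.from_records(records))
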