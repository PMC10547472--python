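"""Repertoire uncertainty via entropy ratios.

A facial repertoire is summarized by the frequency distribution of its
unique AU configurations (the full active set of each 500 ms block).
Its Shannon entropy H = -sum p_i ln p_i measures uncertainty: 0 when a
single configuration is used, maximal when many configurations are used
evenly.  Absolute entropy is not comparable across datasets that differ
in repertoire size and combination-size structure, so it is normalized
by the expected entropy under a null in which each block's active AUs
are reassigned to uniformly random columns, preserving the number of
co-active AUs per block.  The resulting entropy ratio lies near 0 for a
fully stereotyped repertoire and near 1 for one indistinguishable from
random AU use.  Uncertainty in the ratio itself is quantified by
bootstrap resampling of blocks; two repertoires are declared
meaningfully different when their bootstrap ranges do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AUMatrix
from .errors import DegenerateInputError, ValidationError


@dataclass
class CombinationDistribution:
    """Counts and probabilities of unique full-row AU configurations."""

    counts: np.ndarray  # count per unique configuration

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def entropy(self, base: float | None = None) -> float:
        """Plug-in Shannon entropy; natural log by default."""
        p = self.probabilities
        h = float(-(p * np.log(p)).sum()) + 0.0  # avoid -0.0
        if base is not None:
            h /= np.log(base)
        return h


@dataclass
class BootstrapSummary:
    mean: float
    min: float
    max: float


@dataclass
class EntropyRatioResult:
    """Observed and null entropy of a repertoire and their ratio."""

    observed_H: float
    expected_H: float
    ratio: float
    n_randomizations: int
    bootstrap: list[float] | None = None

    @property
    def bootstrap_summary(self) -> BootstrapSummary | None:
        if self.bootstrap is None:
            return None
        b = np.asarray(self.bootstrap)
        return BootstrapSummary(float(b.mean()), float(b.min()), float(b.max()))

    def to_dict(self) -> dict:
        out = {
            "observed_H": self.observed_H,
            "expected_H": self.expected_H,
            "ratio": self.ratio,
            "n_randomizations": self.n_randomizations,
        }
        if self.bootstrap is not None:
            s = self.bootstrap_summary
            out["bootstrap"] = {
                "values": list(self.bootstrap),
                "mean": s.mean,
                "min": s.min,
                "max": s.max,
            }
        return out


def _prepare(subset: AUMatrix, drop_neutral: bool) -> np.ndarray:
    vals = subset.values
    if drop_neutral:
        vals = vals[vals.sum(axis=1) > 0]
    if vals.shape[0] == 0:
        raise ValidationError("subset empty (after dropping neutral rows)")
    return vals


def configuration_distribution(
    subset: AUMatrix, drop_neutral: bool = True
) -> CombinationDistribution:
    """Distribution of unique full-row configurations in a subset.

    All-zero (neutral-face) rows are dropped by default: a block with
    no active AU is not a signal.
    """
    vals = _prepare(subset, drop_neutral)
    return CombinationDistribution(_pattern_counts(vals))


def _pattern_counts(vals: np.ndarray) -> np.ndarray:
    packed = np.packbits(vals, axis=1)
    _, counts = np.unique(packed, axis=0, return_counts=True)
    return counts


def observed_entropy(
    subset: AUMatrix, drop_neutral: bool = True, base: float | None = None
) -> float:
    """Shannon entropy of the configuration frequencies (nats by default)."""
    return configuration_distribution(subset, drop_neutral).entropy(base)


def randomize_rows(vals: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One row-sum-preserving randomization of a binary matrix.

    Each row's k active cells are reassigned to k columns drawn
    uniformly without replacement from the full column set; row sums
    (combination sizes) are conserved exactly.
    """
    n_rows, n_cols = vals.shape
    k = vals.sum(axis=1)
    r = rng.random((n_rows, n_cols))
    # threshold each row at its k-th smallest random value
    s = np.sort(r, axis=1)
    thresh = np.where(k > 0, s[np.arange(n_rows), np.maximum(k - 1, 0)], -1.0)
    return (r <= thresh[:, None]).astype(np.uint8)


def expected_entropy(
    subset: AUMatrix,
    n_rand: int = 100,
    seed: int | np.random.Generator | None = None,
    drop_neutral: bool = True,
    base: float | None = None,
) -> float:
    """Mean entropy under the row-sum-preserving null.

    The null repeatedly reassigns each block's co-active AUs to
    uniformly random columns (keeping combination sizes fixed) and
    averages the plug-in entropy over ``n_rand`` randomizations.  The
    column pool is the subset's full column set.
    """
    if n_rand < 1:
        raise ValidationError("n_rand must be >= 1")
    vals = _prepare(subset, drop_neutral)
    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(n_rand):
        total += CombinationDistribution(
            _pattern_counts(randomize_rows(vals, rng))
        ).entropy(base)
    return total / n_rand


def entropy_ratio(
    subset: AUMatrix,
    n_rand: int = 100,
    seed: int | np.random.Generator | None = None,
    drop_neutral: bool = True,
    base: float | None = None,
) -> EntropyRatioResult:
    """Observed / expected entropy; invariant to the log base."""
    obs = observed_entropy(subset, drop_neutral, base)
    exp = expected_entropy(subset, n_rand, seed, drop_neutral, base)
    if exp == 0:
        raise DegenerateInputError(
            "expected entropy is 0 (degenerate matrix: randomization cannot "
            "produce more than one configuration); entropy ratio undefined"
        )
    return EntropyRatioResult(obs, exp, obs / exp, n_rand)


def bootstrap_entropy_ratio(
    subset: AUMatrix,
    n_boot: int = 100,
    n_rand: int = 100,
    seed: int | np.random.Generator | None = None,
    drop_neutral: bool = True,
) -> EntropyRatioResult:
    """Entropy ratio with a bootstrap distribution over row resamples.

    Each bootstrap replicate resamples blocks (rows) with replacement
    and recomputes the full entropy ratio, including its own
    randomization null.  The point estimates in the result are those of
    the original subset; ``bootstrap`` carries the replicate ratios.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    point = entropy_ratio(subset, n_rand, rng, drop_neutral)
    vals = _prepare(subset, drop_neutral)
    ratios = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(vals), size=len(vals))
        resampled = vals[idx]
        obs = CombinationDistribution(_pattern_counts(resampled)).entropy()
        exp = 0.0
        for _ in range(n_rand):
            exp += CombinationDistribution(
                _pattern_counts(randomize_rows(resampled, rng))
            ).entropy()
        exp /= n_rand
        if exp == 0:
            raise DegenerateInputError("expected entropy 0 in bootstrap replicate")
        ratios.append(obs / exp)
    return EntropyRatioResult(
        point.observed_H, point.expected_H, point.ratio, n_rand, bootstrap=ratios
    )


@dataclass
class OverlapVerdict:
    """Comparison of two bootstrap entropy-ratio distributions."""

    meaningful: bool  # True iff bootstrap ranges are disjoint
    direction: str  # "first_higher" | "second_higher" | "equal" (by means)

    def __str__(self) -> str:
        kind = "meaningful" if self.meaningful else "overlapping"
        return f"{kind} ({self.direction})"


def compare_ratio_distributions(
    a: EntropyRatioResult, b: EntropyRatioResult
) -> OverlapVerdict:
    """Two repertoires differ meaningfully iff bootstrap ranges are disjoint."""
    sa, sb = a.bootstrap_summary, b.bootstrap_summary
    if sa is None or sb is None:
        raise ValidationError("both results must carry bootstrap distributions")
    disjoint = sa.max < sb.min or sb.max < sa.min
    if sa.mean > sb.mean:
        direction = "first_higher"
    elif sa.mean < sb.mean:
        direction = "second_higher"
    else:
        direction = "equal"
    return OverlapVerdict(disjoint, direction)
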