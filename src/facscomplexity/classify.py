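"""Predicting social context from facial behavior.

The final uncertainty measure is prediction error: a random forest is
trained to predict the social context (affiliative, aggressive,
submissive) of each 500 ms block from its AU configuration.  The data
are split 70/30 stratified by context, the training set is rebalanced
with SMOTE, and performance is reported as a confusion matrix with
Cohen's kappa — observed accuracy corrected for the accuracy expected
by chance given the class margins.  Kappa near 0 means facial behavior
carries no contextual signal; kappa near 1 means context is almost
fully determined by the face.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .data import AUMatrix, CLEAR_CONTEXTS
from .errors import DegenerateInputError, ValidationError


@dataclass
class SplitSpec:
    """Stratified train/test split parameters."""

    train_fraction: float = 0.70
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must lie in (0, 1)")


@dataclass
class ForestSpec:
    """Random-forest hyperparameters: 500 trees, 4 candidate predictors
    per split, and nodes below 10 data points are not split further."""

    n_trees: int = 500
    predictors_per_split: int = 4
    min_node_size: int = 10
    seed: int | None = None

    def __post_init__(self):
        if min(self.n_trees, self.predictors_per_split, self.min_node_size) < 1:
            raise ValidationError("forest parameters must be positive integers")


@dataclass
class TrainingSet:
    """Feature table + context labels; features may be fractional after
    SMOTE interpolation (trees split on thresholds, so that is valid)."""

    features: pd.DataFrame
    context: pd.Series


@dataclass
class ContextClassifierReport:
    """Confusion matrix (rows = predicted, columns = true) and kappa."""

    confusion: pd.DataFrame
    observed_accuracy: float
    expected_accuracy: float
    kappa: float

    def to_dict(self) -> dict:
        return {
            "confusion": {
                "predicted_labels": list(self.confusion.index),
                "true_labels": list(self.confusion.columns),
                "matrix": self.confusion.to_numpy().tolist(),
            },
            "observed_accuracy": self.observed_accuracy,
            "expected_accuracy": self.expected_accuracy,
            "kappa": self.kappa,
        }


def stratified_split(
    matrix: AUMatrix, spec: SplitSpec | None = None, include_neutral: bool = False
) -> tuple[AUMatrix, AUMatrix]:
    """70/30 split preserving per-context proportions.

    Operates on the clear-context rows of ``matrix``; every context
    must have at least 2 rows.  Neutral blocks (no active AU) carry an
    identical all-zero feature vector in every context and are dropped
    by default; pass ``include_neutral=True`` to keep them.
    """
    spec = spec or SplitSpec()
    df = matrix.df[matrix.df["context"].isin(CLEAR_CONTEXTS)]
    if not include_neutral:
        df = df[df[matrix.au_columns].sum(axis=1) > 0]
    counts = df["context"].value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValidationError(
            f"context(s) with fewer than 2 rows: {list(small.index)}"
        )
    train_idx, test_idx = train_test_split(
        df.index,
        train_size=spec.train_fraction,
        stratify=df["context"],
        random_state=spec.seed,
    )
    return (
        AUMatrix(df.loc[train_idx], provenance=matrix.provenance),
        AUMatrix(df.loc[test_idx], provenance=matrix.provenance),
    )


def smote_balance(
    train: AUMatrix | TrainingSet,
    k_neighbors: int = 5,
    seed: int | np.random.Generator | None = None,
) -> TrainingSet:
    """Oversample minority contexts with SMOTE.

    Each synthetic observation interpolates linearly between a randomly
    chosen minority row and one of its ``k_neighbors`` nearest
    neighbors of the same context: x_new = x + u (x_nn - x), u ~ U(0,1).
    All original rows are kept; every context reaches the majority
    context's count.  Feature values may become fractional.
    """
    if isinstance(train, AUMatrix):
        X = train.df[train.au_columns].astype(float)
        y = train.df["context"].reset_index(drop=True)
        X = X.reset_index(drop=True)
    else:
        X, y = train.features.reset_index(drop=True), train.context.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    counts = y.value_counts()
    target = int(counts.max())
    parts_X, parts_y = [X], [y]
    for ctx, n in counts.items():
        deficit = target - int(n)
        if deficit == 0:
            continue
        Xc = X[y == ctx].to_numpy()
        if len(Xc) <= k_neighbors:
            raise ValidationError(
                f"context {ctx!r} has only {len(Xc)} rows; SMOTE needs more than "
                f"k_neighbors={k_neighbors} — use a smaller k"
            )
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xc)
        _, nbrs = nn.kneighbors(Xc)  # column 0 is the point itself
        base = rng.integers(0, len(Xc), size=deficit)
        pick = rng.integers(1, k_neighbors + 1, size=deficit)
        u = rng.random((deficit, 1))
        x0 = Xc[base]
        x1 = Xc[nbrs[base, pick]]
        synth = x0 + u * (x1 - x0)
        parts_X.append(pd.DataFrame(synth, columns=X.columns))
        parts_y.append(pd.Series([ctx] * deficit))
    return TrainingSet(
        pd.concat(parts_X, ignore_index=True), pd.concat(parts_y, ignore_index=True)
    )


def train_and_evaluate(
    train: AUMatrix | TrainingSet,
    test: AUMatrix,
    forest: ForestSpec | None = None,
) -> ContextClassifierReport:
    """Fit the random forest on train, predict test, report kappa."""
    forest = forest or ForestSpec()
    if isinstance(train, AUMatrix):
        Xtr, ytr = train.df[train.au_columns], train.df["context"]
    else:
        Xtr, ytr = train.features, train.context
    Xte, yte = test.df[test.au_columns], test.df["context"]
    if list(Xtr.columns) != list(Xte.columns):
        raise ValidationError("train and test AU columns differ")
    clf = RandomForestClassifier(
        n_estimators=forest.n_trees,
        max_features=min(forest.predictors_per_split, Xtr.shape[1]),
        min_samples_split=forest.min_node_size,
        criterion="gini",
        random_state=forest.seed,
        n_jobs=1,
    )
    clf.fit(Xtr.to_numpy(), ytr.to_numpy())
    pred = clf.predict(Xte.to_numpy())
    labels = sorted(set(yte) | set(pred))
    confusion = pd.crosstab(
        pd.Categorical(pred, categories=labels),
        pd.Categorical(yte, categories=labels),
        dropna=False,
    )
    confusion.index = labels
    confusion.columns = labels
    return report_from_confusion(confusion)


def cohen_kappa(confusion: pd.DataFrame | np.ndarray) -> float:
    """Cohen's kappa of a square confusion matrix.

    observed = trace/total; expected = sum_c (row_c * col_c) / total^2;
    kappa = (observed - expected) / (1 - expected).
    """
    return report_from_confusion(confusion).kappa


def report_from_confusion(
    confusion: pd.DataFrame | np.ndarray,
) -> ContextClassifierReport:
    """Accuracy, chance-expected accuracy and kappa from a count matrix."""
    if not isinstance(confusion, pd.DataFrame):
        confusion = pd.DataFrame(np.asarray(confusion))
    m = confusion.to_numpy(dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("confusion matrix must be square")
    if (m < 0).any():
        raise ValidationError("confusion matrix entries must be nonnegative")
    total = m.sum()
    if total == 0:
        raise ValidationError("confusion matrix total is zero")
    observed = np.trace(m) / total
    expected = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / total**2
    if expected == 1:
        raise DegenerateInputError(
            "expected accuracy is 1 (single class); kappa undefined"
        )
    kappa = (observed - expected) / (1 - expected)
    return ContextClassifierReport(confusion, float(observed), float(expected), float(kappa))


def agreement_index(coder1_aus: Iterable[str], coder2_aus: Iterable[str]) -> float:
    """Inter-coder agreement: 2 x |agreed AUs| / (total AUs scored by both).

    Inputs are multisets of AU labels scored by each coder; agreements
    are counted with multiplicity.  A rating above 0.7 is conventionally
    considered good.
    """
    c1, c2 = Counter(coder1_aus), Counter(coder2_aus)
    n1, n2 = sum(c1.values()), sum(c2.values())
    if n1 + n2 == 0:
        raise ValidationError("both coders scored no AUs")
    agreed = sum((c1 & c2).values())
    return 2.0 * agreed / (n1 + n2)
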