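"""Context specificity of AU combinations.

Specificity of an AU combination for a social context is the
conditional probability of the context given that the combination is
observed: the number of blocks of that context containing the
combination divided by the number of blocks containing it across all
analyzed contexts.  A combination is "contained" by a block when it is
a subset of the block's active set, so a single AU's specificity
reflects every configuration it participates in.

Raw conditional probabilities are biased when context sample sizes are
imbalanced (the majority context wins ties simply by volume), so
minority contexts are upsampled to the majority size before the
conditional probability is computed.  Whether a combination counts as
"used" in a context is decided on the original data: combinations
occurring in fewer than 1% of a context's blocks are flagged rare and
excluded from summaries, since extremely rare signals do not affect
the predictability of the system.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations as _subsets

import networkx as nx
import numpy as np
import pandas as pd

from .data import AUMatrix, CLEAR_CONTEXTS, upsample_contexts
from .errors import ValidationError

#: Largest combination size analyzed (maximum observed in macaque data).
MAX_COMBINATION_SIZE = 11


def enumerate_combinations(
    matrix: AUMatrix,
    max_size: int = MAX_COMBINATION_SIZE,
    contexts: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Count, per context, the blocks containing each AU combination.

    A combination C is counted once for every block whose active set is
    a superset of C; a block with k active AUs therefore contributes to
    2^k - 1 combinations (sizes capped at ``max_size``).  Returns a
    tidy frame with columns ``combination`` (sorted AU tuple), ``size``,
    ``context``, ``count``.
    """
    if max_size < 1:
        raise ValidationError("max_size must be >= 1")
    df = matrix.df
    if contexts is not None:
        df = df[df["context"].isin(contexts)]
    au_cols = np.array(matrix.au_columns)
    counts: Counter = Counter()
    for ctx, grp in df.groupby("context", sort=False):
        vals = grp[au_cols].to_numpy(dtype=np.uint8)
        # aggregate identical block patterns first; subsets are enumerated
        # once per unique pattern, not once per block
        packed = np.packbits(vals, axis=1)
        uniq, first_idx, mult = np.unique(
            packed, axis=0, return_index=True, return_counts=True
        )
        for i, m in zip(first_idx, mult):
            active = tuple(au_cols[vals[i] == 1])
            for size in range(1, min(len(active), max_size) + 1):
                for combo in _subsets(active, size):
                    counts[(combo, ctx)] += int(m)
    rows = [
        {"combination": combo, "size": len(combo), "context": ctx, "count": n}
        for (combo, ctx), n in counts.items()
    ]
    return pd.DataFrame(rows, columns=["combination", "size", "context", "count"])


@dataclass
class SpecificityTable:
    """Per-(combination, context) specificity with counts and rarity flags.

    ``table`` columns: combination, size, context, count_in_context and
    total_count (on the upsampled data), specificity, observed_frequency
    (pre-upsampling fraction of the context's blocks containing the
    combination), rare (observed_frequency < threshold).
    """

    table: pd.DataFrame
    contexts: tuple[str, ...]
    threshold: float
    seed: int | None = None

    def for_context(self, context: str, include_rare: bool = False) -> pd.DataFrame:
        sub = self.table[self.table["context"] == context]
        if not include_rare:
            sub = sub[~sub["rare"]]
        return sub

    def to_csv(self, path, sep: str = ",") -> None:
        out = self.table.copy()
        out["combination"] = out["combination"].map(lambda c: "+".join(c))
        out.to_csv(path, sep=sep, index=False)


def specificity_table(
    matrix: AUMatrix,
    contexts: tuple[str, ...] = CLEAR_CONTEXTS,
    threshold: float = 0.01,
    max_size: int = MAX_COMBINATION_SIZE,
    seed: int | np.random.Generator | None = None,
) -> SpecificityTable:
    """Specificity of every observed AU combination across contexts.

    Rows outside ``contexts`` are dropped.  Observed frequencies (and
    hence rarity flags) come from the original data; the conditional
    probability itself is computed after upsampling minority contexts
    to the majority size.  Every observed combination gets one row per
    analyzed context, so its specificity values sum to 1.
    """
    for ctx in contexts:
        if ctx not in set(matrix.df["context"]):
            raise ValidationError(f"context {ctx!r} absent from matrix")
    restricted = matrix.subset(contexts=contexts)
    ctx_rows = restricted.context_counts()

    observed = enumerate_combinations(restricted, max_size)
    balanced = upsample_contexts(restricted, contexts, seed=seed)
    up = enumerate_combinations(balanced, max_size)

    combos = observed[["combination", "size"]].drop_duplicates("combination")
    grid = combos.merge(pd.DataFrame({"context": list(contexts)}), how="cross")
    grid = grid.merge(
        up.rename(columns={"count": "count_in_context"}),
        on=["combination", "size", "context"],
        how="left",
    ).fillna({"count_in_context": 0})
    grid["count_in_context"] = grid["count_in_context"].astype(int)
    totals = grid.groupby("combination", sort=False)["count_in_context"].transform("sum")
    grid["total_count"] = totals
    grid["specificity"] = grid["count_in_context"] / grid["total_count"]

    obs = observed.rename(columns={"count": "observed_count"})
    grid = grid.merge(obs, on=["combination", "size", "context"], how="left").fillna(
        {"observed_count": 0}
    )
    grid["observed_frequency"] = grid["observed_count"] / grid["context"].map(ctx_rows)
    grid["rare"] = grid["observed_frequency"] < threshold
    grid = grid.drop(columns="observed_count")
    seed_val = seed if isinstance(seed, (int, np.integer)) or seed is None else None
    return SpecificityTable(grid, tuple(contexts), threshold, seed=seed_val)


@dataclass
class SpecificitySummary:
    context: str
    mean: float
    sd: float
    n: int
    proportion_high: float  # specificity > 0.8
    proportion_moderate: float  # 0.4 <= specificity <= 0.8
    proportion_low: float  # specificity < 0.4

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def summarize_specificity(
    table: SpecificityTable,
    context: str,
    high: float = 0.8,
    low: float = 0.4,
) -> SpecificitySummary:
    """Mean/SD specificity of combinations used in a context, binned.

    Only non-rare combinations (observed frequency >= threshold in that
    context) enter; bins are high (> 0.8), moderate ([0.4, 0.8]), and
    low (< 0.4).
    """
    sub = table.for_context(context)
    if sub.empty:
        raise ValidationError(
            f"no combinations above threshold {table.threshold} in {context!r}"
        )
    s = sub["specificity"].to_numpy()
    return SpecificitySummary(
        context=context,
        mean=float(s.mean()),
        sd=float(s.std(ddof=1)) if len(s) > 1 else 0.0,
        n=len(s),
        proportion_high=float((s > high).mean()),
        proportion_moderate=float(((s >= low) & (s <= high)).mean()),
        proportion_low=float((s < low).mean()),
    )


@dataclass
class BipartiteNetwork:
    """AU–context bipartite graph weighted by specificity.

    An edge links an AU to a context when the AU occurred in at least
    the rarity-threshold fraction of that context's blocks; its weight
    is the AU's specificity for the context.  An AU's degree is the
    number of contexts it is used in.
    """

    graph: nx.Graph
    au_nodes: list[str]
    context_nodes: list[str]

    @property
    def degrees(self) -> pd.Series:
        return pd.Series({au: self.graph.degree(au) for au in self.au_nodes})

    @property
    def mean_degree(self) -> float:
        return float(self.degrees.mean())

    def to_json_dict(self) -> dict:
        data = nx.node_link_data(self.graph, edges="links")
        data["schema_version"] = 1
        return data


def bipartite_network(table: SpecificityTable, size: int = 1) -> BipartiteNetwork:
    """Build the AU–context network from size-1 (or size-k) combinations."""
    sub = table.table[table.table["size"] == size]
    if sub.empty:
        raise ValidationError(f"table contains no size-{size} combinations")
    g = nx.Graph()
    au_nodes = sorted({"+".join(c) for c in sub["combination"]})
    g.add_nodes_from(au_nodes, bipartite="au")
    g.add_nodes_from(table.contexts, bipartite="context")
    for _, row in sub[~sub["rare"]].iterrows():
        g.add_edge(
            "+".join(row["combination"]),
            row["context"],
            weight=float(row["specificity"]),
        )
    return BipartiteNetwork(g, au_nodes, list(table.contexts))
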