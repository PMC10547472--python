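"""Data model and I/O for FACS-coded facial behavior.

The analysis substrate is a binary block-by-AU matrix: facial
interactions are cut into 500 ms time blocks and each block records
which Action Units (AUs) were active at any point during it.  This
module parses event-coded annotation logs (one record per AU activation
interval) into that matrix, validates it, subsets it by species and
social context, and rebalances contexts by upsampling rows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Metadata columns carried alongside the binary AU columns, in order.
META_COLUMNS = ["interaction_id", "subject_id", "species", "context"]

#: The four social-context labels.
CONTEXTS = ("affiliative", "aggressive", "submissive", "unclear")

#: The three unambiguous contexts used for specificity and classification.
CLEAR_CONTEXTS = ("affiliative", "aggressive", "submissive")

EVENT_COLUMNS = [
    "interaction_id",
    "subject_id",
    "species",
    "context",
    "au",
    "start_s",
    "stop_s",
    "duration_s",
]


class EventLog:
    """Event-coded facial-behavior annotations.

    One record per AU activation interval, with the interaction it
    belongs to, the signaler, the species, the social context of the
    interaction and the activation interval ``[start_s, stop_s)`` in
    seconds.  Interactions are declared with a total ``duration_s``;
    records with an empty ``au`` field declare an interaction without
    contributing an event (an interaction may contain no facial
    activity at all).

    Parameters
    ----------
    records
        DataFrame with columns ``interaction_id, subject_id, species,
        context, au, start_s, stop_s, duration_s``.
    validate
        Check invariants on construction (default True).
    """

    def __init__(self, records: pd.DataFrame, validate: bool = True):
        records = records.copy()
        missing = [c for c in EVENT_COLUMNS if c not in records.columns]
        if missing:
            raise ValidationError(f"event log missing columns: {missing}")
        records["au"] = records["au"].fillna("").astype(str)
        self.records = records.reset_index(drop=True)
        if validate:
            self._check()

    def _check(self) -> None:
        r = self.records
        bad_ctx = set(r["context"]) - set(CONTEXTS)
        if bad_ctx:
            raise ValidationError(f"unknown context label(s): {sorted(bad_ctx)}")
        ev = self.events
        if (ev["stop_s"] <= ev["start_s"]).any():
            i = ev.index[(ev["stop_s"] <= ev["start_s"])][0]
            raise ValidationError(f"record {i}: stop_s must exceed start_s")
        out = (ev["start_s"] < 0) | (ev["stop_s"] > ev["duration_s"] + 1e-9)
        if out.any():
            i = ev.index[out][0]
            raise ValidationError(
                f"record {i}: event interval [{ev.at[i, 'start_s']}, "
                f"{ev.at[i, 'stop_s']}) lies outside [0, {ev.at[i, 'duration_s']}] "
                f"of interaction {ev.at[i, 'interaction_id']!r}"
            )
        per = r.groupby("interaction_id")[["subject_id", "species", "context", "duration_s"]].nunique()
        inconsistent = per[(per > 1).any(axis=1)]
        if len(inconsistent):
            raise ValidationError(
                "interaction(s) with inconsistent metadata: "
                f"{list(inconsistent.index[:5])}"
            )

    @property
    def events(self) -> pd.DataFrame:
        """Records that carry an actual AU activation (non-empty label)."""
        return self.records[self.records["au"] != ""]

    @property
    def interactions(self) -> pd.DataFrame:
        """One row per interaction: id, subject, species, context, duration."""
        cols = ["interaction_id", "subject_id", "species", "context", "duration_s"]
        return (
            self.records[cols]
            .drop_duplicates("interaction_id")
            .set_index("interaction_id")
        )

    @property
    def au_labels(self) -> list[str]:
        return sorted(set(self.events["au"]))

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = ",") -> "EventLog":
        return cls(pd.read_csv(path, sep=sep))

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.records.to_csv(path, sep=sep, index=False)

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`; ``passed`` iff no problems found."""

    problems: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.problems

    def __str__(self) -> str:
        if self.passed:
            return "AUMatrix valid"
        return "AUMatrix invalid:\n  " + "\n  ".join(self.problems)


class AUMatrix:
    """Binary block-by-AU matrix with per-row metadata.

    Rows are 500 ms observation blocks; columns are AU labels.  An entry
    is 1 iff the AU was active at any point during the block.  Each row
    carries the interaction, subject, species and social context it
    came from; all rows of one interaction share the same metadata.

    The underlying storage is a single DataFrame whose first columns
    are :data:`META_COLUMNS` followed by one 0/1 column per AU.
    """

    def __init__(self, df: pd.DataFrame, provenance: tuple | None = None):
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"matrix missing metadata columns: {missing}")
        self.df = df.reset_index(drop=True)
        #: (species, contexts) filter this matrix is a view of, if any
        self.provenance = provenance

    # -- basic accessors -------------------------------------------------

    @property
    def au_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in META_COLUMNS]

    @property
    def values(self) -> np.ndarray:
        """Binary AU entries as a (n_rows, n_aus) uint8 array."""
        return self.df[self.au_columns].to_numpy(dtype=np.uint8)

    @property
    def context(self) -> pd.Series:
        return self.df["context"]

    def __len__(self) -> int:
        return len(self.df)

    def context_counts(self) -> pd.Series:
        return self.df["context"].value_counts()

    # -- subsetting ------------------------------------------------------

    def subset(
        self,
        species: str | None = None,
        contexts: str | Sequence[str] | None = None,
    ) -> "AUMatrix":
        """Restrict to one species and/or a context set.

        Raises :class:`ValidationError` if the result is empty.
        """
        if isinstance(contexts, str):
            contexts = (contexts,)
        mask = pd.Series(True, index=self.df.index)
        if species is not None:
            mask &= self.df["species"] == species
        if contexts is not None:
            mask &= self.df["context"].isin(contexts)
        out = self.df[mask]
        if out.empty:
            raise ValidationError(
                f"empty subset for species={species!r}, contexts={contexts!r}"
            )
        return AUMatrix(out, provenance=(species, tuple(contexts) if contexts else None))

    def drop_neutral(self) -> "AUMatrix":
        """Drop all-zero rows (blocks with no active AU)."""
        active = self.values.sum(axis=1) > 0
        return AUMatrix(self.df[active], provenance=self.provenance)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = ",") -> "AUMatrix":
        return cls(pd.read_csv(path, sep=sep))

    def to_csv(self, path: str | Path, sep: str = ",", sidecar: bool = True) -> None:
        """Write the matrix; a JSON sidecar records the AU vocabulary."""
        path = Path(path)
        self.df.to_csv(path, sep=sep, index=False)
        if sidecar:
            meta = {"schema_version": 1, "au_columns": self.au_columns}
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, indent=2)
            )


def events_to_blocks(log: EventLog, block_ms: float = 500.0) -> AUMatrix:
    """Convert an event log into the binary 500 ms block matrix.

    Each interaction of duration ``d`` seconds yields ``ceil(d / block)``
    rows covering ``[0, d)``; the final block may be shorter than the
    nominal block length so that no coded time is discarded.  An AU is
    coded 1 in a block iff its half-open activation interval
    ``[start_s, stop_s)`` intersects the block's half-open interval —
    any overlap, however brief, counts.  For integer-second durations
    and 500 ms blocks the row count per interaction is exactly twice
    the duration in seconds.

    Rows are ordered by (interaction, block index) with interactions in
    their order of first appearance in the log.
    """
    if block_ms <= 0:
        raise ValidationError("block_ms must be positive")
    block = block_ms / 1000.0
    inter = log.interactions
    labels = log.au_labels
    events_by_inter = dict(tuple(log.events.groupby("interaction_id", sort=False)))

    frames = []
    for iid, row in inter.iterrows():
        n_blocks = math.ceil(round(row["duration_s"] / block, 9))
        entries = np.zeros((n_blocks, len(labels)), dtype=np.uint8)
        ev = events_by_inter.get(iid)
        if ev is not None:
            col_of = {a: j for j, a in enumerate(labels)}
            for au, start, stop in zip(ev["au"], ev["start_s"], ev["stop_s"]):
                # overlapping block indices: [start, stop) vs [i*b, (i+1)*b)
                first = int(math.floor(round(start / block, 9)))
                last = int(math.ceil(round(stop / block, 9)))  # exclusive
                entries[first : min(last, n_blocks), col_of[au]] = 1
        meta = pd.DataFrame(
            {
                "interaction_id": iid,
                "subject_id": row["subject_id"],
                "species": row["species"],
                "context": row["context"],
            },
            index=range(n_blocks),
        )
        frames.append(pd.concat([meta, pd.DataFrame(entries, columns=labels)], axis=1))
    if not frames:
        raise ValidationError("event log declares no interactions")
    return AUMatrix(pd.concat(frames, ignore_index=True))


def validate(matrix: AUMatrix, strict: bool = False) -> ValidationReport:
    """Check AUMatrix invariants; report-only by default.

    Reports non-binary entries, duplicate AU column labels, unknown
    context labels, and interactions whose rows disagree on metadata.
    With ``strict=True`` the first violation raises
    :class:`ValidationError` instead.
    """
    problems: list[str] = []
    df = matrix.df
    au_cols = matrix.au_columns

    seen: set[str] = set()
    for c in au_cols:
        if c in seen:
            problems.append(f"duplicate AU column label {c!r}")
        seen.add(c)

    vals = df[au_cols].to_numpy()
    bad = ~np.isin(vals, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        problems.append(
            f"non-binary entry {vals[i, j]!r} at row {i}, column {au_cols[j]!r}"
        )

    unknown = set(df["context"]) - set(CONTEXTS)
    if unknown:
        problems.append(f"unknown context label(s): {sorted(unknown)}")

    per = df.groupby("interaction_id")[["subject_id", "species", "context"]].nunique()
    inconsistent = per[(per > 1).any(axis=1)]
    for iid in inconsistent.index:
        problems.append(f"interaction {iid!r} has rows with inconsistent metadata")

    report = ValidationReport(problems)
    if strict and not report.passed:
        raise ValidationError(report.problems[0])
    return report


def upsample_contexts(
    matrix: AUMatrix,
    contexts: Iterable[str] | None = None,
    seed: int | np.random.Generator | None = None,
) -> AUMatrix:
    """Equalize context sample sizes by upsampling rows with replacement.

    All original rows of every listed context are kept; minority
    contexts additionally receive rows sampled with replacement from
    their own originals until each context matches the majority
    context's row count.  This is the bias correction applied before
    the specificity calculation.  Rows not belonging to ``contexts``
    are dropped.
    """
    rng = np.random.default_rng(seed)
    if contexts is None:
        contexts = list(matrix.df["context"].unique())
    contexts = list(contexts)
    counts = matrix.df["context"].value_counts()
    absent = [c for c in contexts if c not in counts.index]
    if absent:
        raise ValidationError(f"context(s) absent from matrix: {absent}")
    target = int(counts[contexts].max())
    parts = []
    for ctx in contexts:
        rows = matrix.df[matrix.df["context"] == ctx]
        parts.append(rows)
        deficit = target - len(rows)
        if deficit > 0:
            idx = rng.integers(0, len(rows), size=deficit)
            parts.append(rows.iloc[idx])
    return AUMatrix(pd.concat(parts, ignore_index=True), provenance=matrix.provenance)
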