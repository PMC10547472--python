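"""End-to-end orchestration: matrix -> entropy -> specificity -> classifier.

One :class:`RunConfig` drives the full analysis for every requested
species, writing per-stage JSON/CSV outputs plus a combined summary.
Child seeds are derived deterministically from the master seed and the
stage name, so adding or reordering stages never perturbs the others
and the whole run is reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import entropy as ent
from . import specificity as spc
from .classify import ForestSpec, SplitSpec, smote_balance, stratified_split, train_and_evaluate
from .data import AUMatrix, CLEAR_CONTEXTS, EventLog, events_to_blocks, validate
from .errors import ValidationError

logger = logging.getLogger("facscomplexity")

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    matrix_path: str | None = None
    events_path: str | None = None
    out_dir: str = "facscomplexity_out"
    species: list[str] | None = None  # None = all species in the data
    contexts: tuple[str, ...] = CLEAR_CONTEXTS
    rarity_threshold: float = 0.01
    max_combination_size: int = 11
    n_boot: int = 100
    n_rand: int = 100
    train_fraction: float = 0.70
    n_trees: int = 500
    predictors_per_split: int = 4
    min_node_size: int = 10
    smote_k: int = 5
    block_ms: float = 500.0
    seed: int = 0

    def __post_init__(self):
        if self.n_boot < 1 or self.n_rand < 1:
            raise ValidationError("resampling counts must be >= 1")
        if not 0 < self.rarity_threshold < 1:
            raise ValidationError("rarity threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "contexts" in raw:
            raw["contexts"] = tuple(raw["contexts"])
        return cls(**raw)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from master seed + name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _load_matrix(config: RunConfig) -> AUMatrix:
    if config.matrix_path:
        return AUMatrix.from_csv(config.matrix_path)
    if config.events_path:
        return events_to_blocks(EventLog.from_csv(config.events_path), config.block_ms)
    raise ValidationError("config must provide matrix_path or events_path")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every species; write outputs; return the summary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix = _load_matrix(config)
    report = validate(matrix)
    if not report.passed:
        raise ValidationError(str(report))

    all_species = sorted(matrix.df["species"].unique())
    species_list = config.species or all_species
    missing = [s for s in species_list if s not in all_species]
    if missing:
        raise ValidationError(f"species absent from data: {missing}")

    summary: dict = {"schema_version": SCHEMA_VERSION, "seed": config.seed, "species": {}}
    for sp in species_list:
        logger.info("species %s", sp)
        sp_matrix = matrix.subset(species=sp)
        sp_summary: dict = {}

        # -- entropy: per context and pooled over all contexts -----------
        entropy_out: dict = {}
        targets = [(ctx, (ctx,)) for ctx in config.contexts] + [("all", None)]
        for name, ctxs in targets:
            try:
                sub = sp_matrix.subset(contexts=ctxs) if ctxs else sp_matrix
                res = ent.bootstrap_entropy_ratio(
                    sub,
                    n_boot=config.n_boot,
                    n_rand=config.n_rand,
                    seed=stage_seed(config.seed, f"entropy:{sp}:{name}"),
                )
                entropy_out[name] = res.to_dict()
            except ValidationError as e:
                entropy_out[name] = {"error": str(e)}
        (out_dir / f"{sp}_entropy.json").write_text(json.dumps(entropy_out, indent=2))
        sp_summary["entropy"] = entropy_out

        # -- specificity + bipartite network ------------------------------
        try:
            table = spc.specificity_table(
                sp_matrix,
                contexts=config.contexts,
                threshold=config.rarity_threshold,
                max_size=config.max_combination_size,
                seed=stage_seed(config.seed, f"specificity:{sp}"),
            )
            table.to_csv(out_dir / f"{sp}_specificity.csv")
            spec_summary = {}
            for ctx in config.contexts:
                try:
                    spec_summary[ctx] = spc.summarize_specificity(table, ctx).to_dict()
                except ValidationError as e:
                    spec_summary[ctx] = {"error": str(e)}
            net = spc.bipartite_network(table)
            (out_dir / f"{sp}_network.json").write_text(
                json.dumps(net.to_json_dict(), indent=2)
            )
            spec_summary["mean_degree"] = net.mean_degree
            sp_summary["specificity"] = spec_summary
        except ValidationError as e:
            raise ValidationError(f"specificity stage failed for {sp}: {e}") from e

        # -- classification ------------------------------------------------
        try:
            train, test = stratified_split(
                sp_matrix,
                SplitSpec(config.train_fraction, seed=stage_seed(config.seed, f"split:{sp}")),
            )
            balanced = smote_balance(
                train, k_neighbors=config.smote_k,
                seed=stage_seed(config.seed, f"smote:{sp}"),
            )
            clf_report = train_and_evaluate(
                balanced,
                test,
                ForestSpec(
                    config.n_trees,
                    config.predictors_per_split,
                    config.min_node_size,
                    seed=stage_seed(config.seed, f"forest:{sp}"),
                ),
            )
            (out_dir / f"{sp}_classifier.json").write_text(
                json.dumps(clf_report.to_dict(), indent=2)
            )
            sp_summary["classification"] = clf_report.to_dict()
        except ValidationError as e:
            raise ValidationError(f"classification stage failed for {sp}: {e}") from e

        summary["species"][sp] = sp_summary

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
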