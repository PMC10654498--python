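"""The iterative inverse-design loop.

Each iteration: seed the mutation generator from the integrated database,
generate an oversampled batch of unique valid candidates, oracle-evaluate
them, rank-select the generation by property value toward the objective,
apply the data-selection rules to partition the generation into new training
and test records, integrate everything into the database, and retrain the
surrogate from scratch on the enlarged training pool.  The surrogate used to
screen generation X is always the one trained before X existed, so admission
errors measure genuine generalization failure.

The whole loop is a deterministic function of (config, master seed): the
master seed fans out to per-stage seeds through a stable hash of the stage
name and iteration index.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import parse_smiles
from .db import PopulationDB, PropertyRecord
from .errors import FeaturizeError, GapDesignError
from .featurize import featurize
from .generate import GenerationStats, MutationConfig, build_vocabulary, generate_population
from .oracle import STATUS_OK, Oracle, ToyGapOracle, evaluate_population
from .select import SelectionConfig, apply_rules, rank_select, rule_1a_threshold, rule_1b_dedup
from .surrogate import SurrogateConfig, TrainedSurrogate, evaluate as surrogate_evaluate, train as surrogate_train


def stage_seed(master_seed: int, stage: str, iteration: int = 0) -> int:
    """Derive a reproducible per-stage seed (< 2**31) from the master seed."""
    digest = hashlib.sha256(f"{stage}:{iteration}:{master_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class WorkflowConfig:
    """Run configuration for the full loop."""

    n_iterations: int = 6
    generation_target: int = 500
    oversample: float = 3.0  # candidates generated per accepted molecule
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    mutation: MutationConfig = field(default_factory=MutationConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    master_seed: int = 0
    seed_pool: str = "all"  # mutate from the full DB ("all") or train pool only

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.oversample < 1.0:
            raise ValueError("oversample must be >= 1")
        if self.seed_pool not in ("all", "train"):
            raise ValueError("seed_pool must be 'all' or 'train'")


@dataclass
class IterationReport:
    """Per-iteration bookkeeping mirroring the run-table counts.

    Conservation identity: ``n_generated = n_new_train + n_new_test +
    n_duplicates + n_invalid`` where ``n_generated`` is the rank-selected
    generation (candidates dropped by ranking are in ``n_rank_rejected``).
    """

    iteration: int
    n_generated: int
    n_candidates: int  # unique valid candidates before rank selection
    n_rank_rejected: int
    n_new_train: int
    n_new_test: int
    n_duplicates: int
    n_invalid: int
    threshold_used: float
    surrogate_mae: dict
    mean_gap_generation: float
    count_below_seed_min: int
    generator_stats: dict

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class WorkflowResult:
    reports: list[IterationReport]
    db: PopulationDB
    surrogate0: TrainedSurrogate
    final_surrogate: TrainedSurrogate
    seed_min_gap: float


def bootstrap_db(seed_smiles: list[str], oracle: Oracle) -> PopulationDB:
    """Oracle-evaluate the seed population into a generation-0 training DB."""
    db = PopulationDB()
    for res in evaluate_population(seed_smiles, oracle):
        if res.status != STATUS_OK or res.canonical_smiles in db:
            continue
        db.add(PropertyRecord(smiles=res.canonical_smiles, gap=res.gap,
                              generation=0, split="train"))
    if len(db) == 0:
        raise GapDesignError("no valid seed molecules")
    return db


def run_iteration(
    db: PopulationDB,
    surrogate: TrainedSurrogate,
    iteration: int,
    cfg: WorkflowConfig,
    oracle: Oracle,
    seed_min_gap: float,
) -> tuple[IterationReport, TrainedSurrogate]:
    """One loop pass; mutates ``db`` in place and returns the retrained surrogate."""
    seeds = [r.smiles for r in (db.records if cfg.seed_pool == "all" else db.train_pool())]
    rng = np.random.default_rng(stage_seed(cfg.master_seed, "generate", iteration))
    mut_cfg = dataclasses.replace(cfg.mutation, vocabulary=build_vocabulary(seeds))
    n_to_generate = int(round(cfg.oversample * cfg.generation_target))
    candidates, gen_stats = generate_population(seeds, n_to_generate, mut_cfg, rng)

    results = evaluate_population(candidates, oracle)
    ok = [r for r in results if r.status == STATUS_OK]
    n_invalid_pre = len(results) - len(ok)

    evaluated = [
        PropertyRecord(smiles=r.canonical_smiles, gap=r.gap, generation=iteration, split="")
        for r in ok
    ]
    top_k = cfg.selection.top_k or cfg.generation_target
    generation = rank_select(evaluated, top_k, cfg.selection.objective)
    n_rank_rejected = len(evaluated) - len(generation)

    unique, n_duplicates = rule_1b_dedup(generation, db)
    # candidates outside the feature layout (e.g. hypervalent S) are skipped
    featurizable, graphs = [], []
    n_unfeaturizable = 0
    for record in unique:
        try:
            graphs.append(featurize(parse_smiles(record.smiles)))
        except FeaturizeError:
            n_unfeaturizable += 1
            continue
        featurizable.append(record)
    if graphs:
        preds = surrogate.predict_graphs(graphs)
        for record, pred in zip(featurizable, preds):
            record.prediction = float(pred)
            record.abs_error = abs(float(pred) - record.gap)

    threshold = rule_1a_threshold(surrogate.report)
    outcome = apply_rules(featurizable, threshold, cfg.selection,
                          rejected_duplicates=n_duplicates,
                          rejected_invalid=n_invalid_pre + n_unfeaturizable)
    db.add_all(outcome.new_train + outcome.new_test)

    retrain_cfg = dataclasses.replace(
        cfg.surrogate, seed=stage_seed(cfg.master_seed, "train", iteration)
    )
    new_surrogate = surrogate_train(db.train_pool(), retrain_cfg)

    gen_records = db.records_for_generation(iteration)
    gaps = np.array([r.gap for r in gen_records])
    report = IterationReport(
        iteration=iteration,
        n_generated=len(generation) + n_invalid_pre,  # = train+test+dup+invalid
        n_candidates=len(results),
        n_rank_rejected=n_rank_rejected,
        n_new_train=len(outcome.new_train),
        n_new_test=len(outcome.new_test),
        n_duplicates=n_duplicates,
        n_invalid=n_invalid_pre + n_unfeaturizable,
        threshold_used=threshold,
        surrogate_mae={
            "train": new_surrogate.report.mae_train,
            "val": new_surrogate.report.mae_val,
            "test": new_surrogate.report.mae_test,
        },
        mean_gap_generation=float(gaps.mean()) if gaps.size else float("nan"),
        count_below_seed_min=int((gaps < seed_min_gap).sum()),
        generator_stats=gen_stats.as_dict(),
    )
    return report, new_surrogate


def run_workflow(
    cfg: WorkflowConfig,
    seed_smiles: list[str],
    oracle: Oracle | None = None,
    outdir: str | Path | None = None,
) -> WorkflowResult:
    """Run the full iterative design loop from a seed population.

    When ``outdir`` is given, the database, per-iteration JSONL log and
    surrogate checkpoints are written there after every iteration, so an
    aborted run can be inspected and resumed from its last completed state.
    """
    oracle = oracle if oracle is not None else ToyGapOracle()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    db = bootstrap_db(seed_smiles, oracle)
    seed_min_gap = min(r.gap for r in db.records)

    cfg0 = dataclasses.replace(cfg.surrogate, seed=stage_seed(cfg.master_seed, "train", 0))
    surrogate0 = surrogate_train(db.train_pool(), cfg0)

    surrogate = surrogate0
    reports: list[IterationReport] = []
    for iteration in range(1, cfg.n_iterations + 1):
        try:
            report, surrogate = run_iteration(db, surrogate, iteration, cfg, oracle, seed_min_gap)
        except GapDesignError:
            if outdir is not None:
                _checkpoint(outdir, db, reports)
            raise
        reports.append(report)
        if outdir is not None:
            _checkpoint(outdir, db, reports)
            surrogate.save(outdir / f"surrogate_iter{iteration}.npz")
    return WorkflowResult(reports=reports, db=db, surrogate0=surrogate0,
                         final_surrogate=surrogate, seed_min_gap=seed_min_gap)


def _checkpoint(outdir: Path, db: PopulationDB, reports: list[IterationReport]) -> None:
    db.save(outdir / "population.csv", outdir / "population_manifest.json")
    with open(outdir / "iterations.jsonl", "w") as fh:
        for report in reports:
            fh.write(json.dumps(report.as_dict()) + "\n")


def frozen_surrogate_audit(
    surrogate0: TrainedSurrogate,
    latest: TrainedSurrogate,
    db: PopulationDB,
) -> pd.DataFrame:
    """Per-generation MAE of the frozen generation-0 surrogate vs the latest one.

    The frozen model's error drifting upward across generations while the
    retrained model stays flat is the loop's central health indicator: it
    shows the admitted training data kept pace with the moving population.
    """
    rows = []
    for gen in db.generations():
        records = db.records_for_generation(gen)
        mae_frozen, _, _ = surrogate_evaluate(surrogate0, records)
        mae_latest, _, _ = surrogate_evaluate(latest, records)
        rows.append(
            {
                "generation": gen,
                "n_molecules": len(records),
                "mae_frozen_eV": mae_frozen,
                "mae_latest_eV": mae_latest,
            }
        )
    return pd.DataFrame(rows)
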