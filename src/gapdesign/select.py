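"""Data-selection rules admitting generated molecules into the next iteration.

Three rules are applied to each generation after oracle evaluation:

* **Rule 1a** — only molecules whose surrogate prediction error exceeds the
  maximum absolute error seen over the surrogate's own train/validation/test
  data at the end of training are admitted to the training pool; the model is
  assumed to have learned anything it already predicts well.
* **Rule 1b** — only molecules unique with respect to the integrated database
  (by canonical SMILES) are kept.
* **Rule 2** — training additions are restricted to molecules with fewer than
  20 non-hydrogen atoms; larger molecules go to the monitoring test pool so
  extrapolation capability keeps being measured.

Everything passing 1b but failing 1a or 2 becomes test data — the test pool
is deliberately *not* size-restricted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import heavy_atom_count, parse_smiles
from .db import PopulationDB, PropertyRecord


@dataclass
class SelectionConfig:
    """Admission thresholds and ranking direction."""

    heavy_atom_limit: int = 20  # exclusive: training requires < limit heavy atoms
    objective: str = "minimize"  # or "maximize"
    top_k: int | None = None  # None: keep the whole candidate set

    def __post_init__(self) -> None:
        if self.heavy_atom_limit < 2:
            raise ValueError("heavy_atom_limit must be >= 2")
        if self.objective not in ("minimize", "maximize"):
            raise ValueError("objective must be 'minimize' or 'maximize'")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class SelectionOutcome:
    """Partition of one generation's candidates plus bookkeeping counts."""

    new_train: list[PropertyRecord] = field(default_factory=list)
    new_test: list[PropertyRecord] = field(default_factory=list)
    rejected_duplicates: int = 0
    rejected_invalid: int = 0
    threshold_used: float = 0.0


def rule_1b_dedup(
    candidates: list[PropertyRecord], db: PopulationDB
) -> tuple[list[PropertyRecord], int]:
    """Keep candidates unique w.r.t. the database and each other."""
    unique: list[PropertyRecord] = []
    seen: set[str] = set()
    n_dup = 0
    for cand in candidates:
        if cand.smiles in db or cand.smiles in seen:
            n_dup += 1
            continue
        seen.add(cand.smiles)
        unique.append(cand)
    return unique, n_dup


def rule_1a_threshold(report) -> float:
    """Admission threshold: the max |error| over train+val+test at end of training."""
    return float(report.max_abs_error_all)


def apply_rules(
    candidates: list[PropertyRecord],
    threshold: float,
    cfg: SelectionConfig,
    rejected_duplicates: int = 0,
    rejected_invalid: int = 0,
) -> SelectionOutcome:
    """Partition deduplicated, oracle-evaluated candidates by rules 1a and 2.

    ``candidates`` must carry ``abs_error`` (surrogate prediction vs oracle).
    Training admission requires error strictly above the threshold *and* heavy
    atoms strictly below the limit; all remaining candidates become test data.
    """
    outcome = SelectionOutcome(
        rejected_duplicates=rejected_duplicates,
        rejected_invalid=rejected_invalid,
        threshold_used=threshold,
    )
    for cand in candidates:
        if cand.abs_error is None:
            raise ValueError(f"candidate {cand.smiles!r} lacks a prediction error")
        n_heavy = heavy_atom_count(parse_smiles(cand.smiles))
        if cand.abs_error > threshold and n_heavy < cfg.heavy_atom_limit:
            cand.split = "train"
            outcome.new_train.append(cand)
        else:
            cand.split = "test"
            outcome.new_test.append(cand)
    return outcome


def rank_select(
    candidates: list[PropertyRecord], k: int, objective: str = "minimize"
) -> list[PropertyRecord]:
    """Top-k candidates by property value (ties broken by canonical SMILES).

    ``minimize`` keeps the k smallest gaps (the low-gap design objective);
    ``maximize`` the k largest.  Returns the whole sorted population when it
    has fewer than k members.
    """
    if objective not in ("minimize", "maximize"):
        raise ValueError("objective must be 'minimize' or 'maximize'")
    sign = 1.0 if objective == "minimize" else -1.0
    ranked = sorted(candidates, key=lambda r: (sign * r.gap, r.smiles))
    return ranked[:k]


def count_below(db: PopulationDB, threshold_ev: float, generation: int) -> int:
    """Number of generation-tagged records with gap strictly below the threshold."""
    return sum(
        1 for r in db.records_for_generation(generation) if r.gap < threshold_ev
    )
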