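"""The integrated population database accumulated across design iterations."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd


@dataclass
class PropertyRecord:
    """One molecule with its oracle property and bookkeeping tags."""

    smiles: str  # canonical form; the deduplication key
    gap: float  # oracle property, eV
    generation: int  # 0 = seed population
    split: str  # "train" (surrogate training pool) or "test" (monitoring pool)
    prediction: float | None = None  # surrogate prediction at admission time
    abs_error: float | None = None  # |prediction - gap| at admission time


@dataclass
class PopulationDB:
    """Deduplicated store of :class:`PropertyRecord` keyed by canonical SMILES.

    Generation tags are immutable once written: attempting to re-add an
    existing SMILES raises instead of silently overwriting.
    """

    _records: dict[str, PropertyRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, smiles: str) -> bool:
        return smiles in self._records

    def add(self, record: PropertyRecord) -> None:
        if record.smiles in self._records:
            raise ValueError(f"duplicate canonical SMILES {record.smiles!r}")
        self._records[record.smiles] = record

    def add_all(self, records: list[PropertyRecord]) -> None:
        for record in records:
            self.add(record)

    @property
    def records(self) -> list[PropertyRecord]:
        return list(self._records.values())

    def smiles(self) -> list[str]:
        return list(self._records.keys())

    def generations(self) -> list[int]:
        return sorted({r.generation for r in self._records.values()})

    def records_for_generation(self, generation: int) -> list[PropertyRecord]:
        return [r for r in self._records.values() if r.generation == generation]

    def train_pool(self) -> list[PropertyRecord]:
        """Records feeding surrogate training (the seed set plus admitted molecules)."""
        return [r for r in self._records.values() if r.split == "train"]

    def test_pool(self) -> list[PropertyRecord]:
        return [r for r in self._records.values() if r.split == "test"]

    # -- persistence: CSV table plus a small JSON manifest -------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "smiles": r.smiles,
                    "gap_eV": r.gap,
                    "generation": r.generation,
                    "split": r.split,
                    "prediction_eV": r.prediction,
                    "abs_error_eV": r.abs_error,
                }
                for r in self._records.values()
            ]
        )

    def save(self, csv_path: str | Path, manifest_path: str | Path | None = None) -> None:
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        if manifest_path is not None:
            manifest = {
                "n_records": len(self),
                "generations": {
                    str(g): len(self.records_for_generation(g)) for g in self.generations()
                },
                "n_train": len(self.train_pool()),
                "n_test": len(self.test_pool()),
            }
            Path(manifest_path).write_text(json.dumps(manifest, indent=2) + "\n")

    @classmethod
    def load(cls, csv_path: str | Path) -> "PopulationDB":
        frame = pd.read_csv(csv_path)
        db = cls()
        for row in frame.itertuples(index=False):
            pred = None if pd.isna(row.prediction_eV) else float(row.prediction_eV)
            err = None if pd.isna(row.abs_error_eV) else float(row.abs_error_eV)
            db.add(
                PropertyRecord(
                    smiles=row.smiles,
                    gap=float(row.gap_eV),
                    generation=int(row.generation),
                    split=str(row.split),
                    prediction=pred,
                    abs_error=err,
                )
            )
        return db


def with_prediction(record: PropertyRecord, prediction: float) -> PropertyRecord:
    return replace(record, prediction=prediction, abs_error=abs(prediction - record.gap))
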