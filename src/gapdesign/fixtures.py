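"""Synthetic seed populations and frozen worked examples.

The seed generator emulates the size regime and functional-group variety of an
enumerated small-organic database (up to 9 non-hydrogen atoms by default, over
C/H/N/O/F/S): alkyl chains, 5- and 6-membered carbocycles and heterocycles,
carbonyls, nitriles and fluorine substituents, plus a low frequency of
strained 3-/4-membered rings.  Molecules are assembled by randomized fragment
joining; joins that fail valence or round-trip validation are retried rather
than repaired, so every emitted SMILES is valid by construction.

It makes no attempt to reproduce any published database's contents or exact
property distribution — only a spread of toy-oracle gaps wide enough that both
minimization and maximization objectives have headroom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import dbe
from .chem import canonical_smiles, heavy_atom_count, parse_smiles, round_trip_stable
from .errors import ExhaustionError, MoleculeError
from .oracle import toy_gap

# Chain-extendable fragments: concatenating them yields a valid SMILES prefix.
_LINKABLE = [
    "C", "C", "C", "CC", "CCC", "C=C", "C#C", "CO", "CN", "CS",
    "C1CCCCC1", "C1CCCC1", "c1ccccc1", "c1ccoc1", "c1ccsc1", "c1ccncc1",
    "C1CC1", "C1CCC1",  # strained rings, deliberately rare via weights
]
_LINKABLE_WEIGHTS = [6, 6, 6, 5, 4, 4, 2, 3, 3, 2, 3, 2, 4, 2, 2, 2, 1, 1]

# Branch decorations attached in parentheses mid-chain.
_BRANCHES = ["(C)", "(F)", "(=O)", "(O)", "(N)", "(C#N)", "(C=C)"]
_BRANCH_WEIGHTS = [5, 3, 3, 2, 2, 2, 2]

# Terminal groups that may only end a chain.
_TERMINALS = ["", "F", "O", "N", "C#N", "C=O", "S"]
_TERMINAL_WEIGHTS = [8, 3, 2, 2, 2, 2, 1]


@dataclass
class FixtureConfig:
    """Knobs of the synthetic seed generator."""

    n_molecules: int = 300
    max_heavy_atoms: int = 9
    seed: int = 0
    max_attempts_per_molecule: int = 200
    fragments: list[str] = field(default_factory=lambda: list(_LINKABLE))

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        for frag in self.fragments:
            if not round_trip_stable(frag):
                raise ValueError(f"invalid fragment {frag!r}")


def _assemble(rng: np.random.Generator, max_heavy: int) -> str:
    """Draw one candidate SMILES by fragment concatenation."""
    p_link = np.asarray(_LINKABLE_WEIGHTS, dtype=float)
    p_link /= p_link.sum()
    p_branch = np.asarray(_BRANCH_WEIGHTS, dtype=float)
    p_branch /= p_branch.sum()
    p_term = np.asarray(_TERMINAL_WEIGHTS, dtype=float)
    p_term /= p_term.sum()

    parts = [str(rng.choice(_LINKABLE, p=p_link))]
    for _ in range(int(rng.integers(0, 4))):
        if rng.random() < 0.3:
            parts.append(str(rng.choice(_BRANCHES, p=p_branch)))
        else:
            parts.append(str(rng.choice(_LINKABLE, p=p_link)))
    parts.append(str(rng.choice(_TERMINALS, p=p_term)))
    return "".join(parts)


def make_seed_population(cfg: FixtureConfig) -> list[str]:
    """Generate ``cfg.n_molecules`` unique, valid, neutral seed SMILES.

    Deterministic given ``cfg.seed``.  Raises :class:`ExhaustionError` if the
    retry budget is consumed before reaching the requested count.
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[str] = []
    seen: set[str] = set()
    budget = cfg.n_molecules * cfg.max_attempts_per_molecule
    attempts = 0
    while len(out) < cfg.n_molecules:
        if attempts >= budget:
            raise ExhaustionError(
                f"generated {len(out)}/{cfg.n_molecules} unique molecules "
                f"in {attempts} attempts"
            )
        attempts += 1
        text = _assemble(rng, cfg.max_heavy_atoms)
        try:
            mol = parse_smiles(text)
        except MoleculeError:
            continue
        if heavy_atom_count(mol) > cfg.max_heavy_atoms:
            continue
        if not round_trip_stable(text):
            continue
        canon = canonical_smiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        out.append(canon)
    return out


def worked_examples() -> list[dict]:
    """Frozen hand-checkable examples used across module tests.

    Gap values come from direct evaluation of the toy-gap formula; descriptor
    values from the standard composition arithmetic.
    """
    rows = []
    for smiles in ("C", "c1ccccc1", "FC(F)(F)F", "CCO", "c1ccc2ccccc2c1"):
        mol = parse_smiles(smiles)
        rows.append(
            {
                "smiles": canonical_smiles(mol),
                "toy_gap_eV": toy_gap(mol),
                "dbe": dbe(mol),
                "heavy_atoms": heavy_atom_count(mol),
            }
        )
    return rows
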