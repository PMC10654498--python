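"""Molecule parsing, validation and canonicalization.

Every other module consumes the :class:`Molecule` type defined here.  Parsing
and canonical-form generation are delegated to RDKit; this module fixes the
package-wide chemistry contract on top of it:

* hydrogens are implicit — they are never graph nodes, only per-atom counts;
* the element vocabulary is restricted to {C, H, N, O, F, S};
* molecules with nonzero net formal charge are rejected by default;
* stereochemistry annotations are accepted on input but stripped, because the
  property model is purely connectivity-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from rdkit import Chem, RDLogger

from .errors import (
    ChargeError,
    ElementError,
    MoleculeError,
    ParseError,
    ValenceError,
)

RDLogger.DisableLog("rdApp.*")

#: Elements covered by the property oracle's parameterization.
ALLOWED_ELEMENTS = frozenset({"C", "H", "N", "O", "F", "S"})

_HYBRIDIZATION_NAMES = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}

_BOND_TYPE_NAMES = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a molecule.

    ``num_h_neighbors`` counts implicit plus explicit hydrogens; hydrogens are
    never nodes themselves.
    """

    element: str
    atomic_number: int
    aromatic: bool
    hybridization: str  # "sp" | "sp2" | "sp3" | "other"
    num_h_neighbors: int
    formal_charge: int


@dataclass(frozen=True)
class BondRecord:
    """One covalent bond between two heavy atoms (indices into ``atoms``)."""

    endpoints: tuple[int, int]
    bond_type: str  # "single" | "double" | "triple" | "aromatic"


@dataclass
class Molecule:
    """Attributed molecular graph parsed from a SMILES string."""

    atoms: list[AtomRecord]
    bonds: list[BondRecord]
    source_smiles: str
    _rdkit_mol: Chem.Mol = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for bond in self.bonds:
            i, j = bond.endpoints
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise MoleculeError(f"bond endpoints {bond.endpoints} invalid for {n} atoms")
            if bond.bond_type == "aromatic" and not (
                self.atoms[i].aromatic and self.atoms[j].aromatic
            ):
                raise MoleculeError("aromatic bond joining non-aromatic atoms")

    @property
    def rdkit_mol(self) -> Chem.Mol:
        if self._rdkit_mol is None:
            self._rdkit_mol = _rdkit_from_smiles(self.source_smiles)
        return self._rdkit_mol


def _rdkit_from_smiles(text: str) -> Chem.Mol:
    """Parse and sanitize, mapping RDKit failures onto the package errors."""
    if not text or not text.strip():
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(text, sanitize=False)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {text!r}")
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ALLOWED_ELEMENTS:
            raise ElementError(
                f"element {atom.GetSymbol()} outside supported set in {text!r}"
            )
    try:
        Chem.SanitizeMol(mol)
    except Chem.AtomValenceException as exc:
        raise ValenceError(f"impossible valence in {text!r}: {exc}") from exc
    except (Chem.KekulizeException, Chem.AtomKekulizeException) as exc:
        raise ParseError(f"cannot kekulize {text!r}: {exc}") from exc
    except Exception as exc:  # other sanitization failures
        raise ParseError(f"sanitization failed for {text!r}: {exc}") from exc
    Chem.RemoveStereochemistry(mol)
    mol = Chem.RemoveHs(mol)
    return mol


def parse_smiles(text: str, allow_net_charge: bool = False) -> Molecule:
    """Parse a SMILES string into a validated :class:`Molecule`.

    Raises
    ------
    ParseError
        Syntactically invalid input.
    ElementError
        An element outside {C,H,N,O,F,S}.
    ValenceError
        A chemically impossible valence.
    ChargeError
        Nonzero net formal charge (unless ``allow_net_charge``).
    """
    mol = _rdkit_from_smiles(text)
    if not allow_net_charge and Chem.GetFormalCharge(mol) != 0:
        raise ChargeError(f"net formal charge {Chem.GetFormalCharge(mol)} in {text!r}")
    atoms = [
        AtomRecord(
            element=a.GetSymbol(),
            atomic_number=a.GetAtomicNum(),
            aromatic=a.GetIsAromatic(),
            hybridization=_HYBRIDIZATION_NAMES.get(a.GetHybridization(), "other"),
            num_h_neighbors=a.GetTotalNumHs(),
            formal_charge=a.GetFormalCharge(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = [
        BondRecord(
            endpoints=(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
            bond_type=_BOND_TYPE_NAMES[b.GetBondType()],
        )
        for b in mol.GetBonds()
    ]
    return Molecule(atoms=atoms, bonds=bonds, source_smiles=text, _rdkit_mol=mol)


def canonical_smiles(m: Molecule | str) -> str:
    """Deterministic canonical SMILES; the identity used for deduplication."""
    if isinstance(m, str):
        m = parse_smiles(m)
    return Chem.MolToSmiles(m.rdkit_mol)


def heavy_atom_count(m: Molecule) -> int:
    """Number of non-hydrogen atoms (all graph nodes are heavy atoms)."""
    return len(m.atoms)


def round_trip_stable(text: str) -> bool:
    """True iff ``text`` parses and its canonical form re-parses to itself.

    This is the validity filter applied to every generated candidate: a
    molecule whose connectivity cannot survive a canonicalize/re-parse cycle
    is discarded.  All failures (syntax, element, valence, charge) map to
    ``False`` rather than raising.
    """
    try:
        canon = canonical_smiles(parse_smiles(text))
        return canonical_smiles(parse_smiles(canon)) == canon
    except MoleculeError:
        return False


def element_counts(m: Molecule) -> dict[str, int]:
    """Composition counts nC, nH, nN, nO, nF, nS (hydrogens from H-neighbor sums)."""
    counts = {el: 0 for el in ("C", "H", "N", "O", "F", "S")}
    for atom in m.atoms:
        counts[atom.element] += 1
        counts["H"] += atom.num_h_neighbors
    return counts


# ---------------------------------------------------------------------------
# .smi line-file interface: one SMILES per line, optional whitespace-separated
# identifier, '#' comment lines ignored.

def read_smi(path: str | Path) -> list[str]:
    smiles = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles.append(line.split()[0])
    return smiles


def write_smi(path: str | Path, smiles: Iterable[str], ids: Iterable[str] | None = None) -> None:
    path = Path(path)
    lines: Iterator[str]
    if ids is None:
        lines = iter(smiles)
    else:
        lines = (f"{s}\t{i}" for s, i in zip(smiles, ids))
    path.write_text("\n".join(lines) + "\n")
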