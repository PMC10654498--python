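"""Descriptor and chemical-space analyses for a population database.

Covers the composition descriptors plotted against the gap (H/C ratio,
aromaticity ratio, double-bond equivalents, heavy-atom count), 2048-bit
extended-connectivity fingerprints, a two-dimensional principal-component map
of fingerprint space, the 5-/6-membered-ring stability screen, and the
per-generation summary table.

Conventions fixed here because the underlying quantities admit several:

* DBE uses the standard organic-chemistry definition
  ``DBE = nC - (nH + nF)/2 + nN/2 + 1`` (O and S contribute zero).
* The aromaticity ratio divides aromatic heavy atoms by *all* non-aromatic
  heavy atoms (heteroatoms included); fully aromatic molecules, whose
  denominator is zero, are reported as NaN with a separate boolean flag
  rather than as infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit.Chem import rdFingerprintGenerator
from sklearn.decomposition import PCA

from .chem import Molecule, canonical_smiles, element_counts, heavy_atom_count, parse_smiles
from .errors import DegenerateInput, NoCarbonError


def dbe(m: Molecule) -> float:
    """Double-bond equivalents (rings + pi bonds) from the molecular formula."""
    c = element_counts(m)
    return c["C"] - (c["H"] + c["F"]) / 2.0 + c["N"] / 2.0 + 1.0


def hc_ratio(m: Molecule) -> float:
    """Hydrogen-to-carbon ratio nH/nC; raises for carbon-free molecules."""
    c = element_counts(m)
    if c["C"] == 0:
        raise NoCarbonError(f"no carbon in {m.source_smiles!r}")
    return c["H"] / c["C"]


def aromaticity_ratio(m: Molecule) -> float:
    """Aromatic heavy atoms over non-aromatic heavy atoms.

    Returns NaN for fully aromatic molecules (zero denominator); use
    :func:`is_fully_aromatic` to distinguish that case from missing data.
    """
    n_arom = sum(1 for a in m.atoms if a.aromatic)
    n_plain = len(m.atoms) - n_arom
    if n_plain == 0:
        return float("nan")
    return n_arom / n_plain


def is_fully_aromatic(m: Molecule) -> bool:
    return all(a.aromatic for a in m.atoms)


def ecfp(m: Molecule, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """Extended-connectivity fingerprint as a 0/1 vector of length ``n_bits``."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(m.rdkit_mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


@dataclass
class LatentMap:
    """Two-dimensional chemical-space coordinates with explained variance."""

    coordinates: np.ndarray  # (n_molecules, 2)
    explained_variance: np.ndarray  # (2,)


def latent_map(fingerprints: np.ndarray) -> LatentMap:
    """Project a fingerprint matrix to two principal components.

    Deterministic: the sign of each component is fixed by forcing its
    largest-magnitude loading positive.  Raises :class:`DegenerateInput` when
    all fingerprints are identical (no variance to project).
    """
    fp = np.asarray(fingerprints, dtype=float)
    if fp.shape[0] < 3:
        raise DegenerateInput("need at least 3 molecules")
    if np.all(fp == fp[0]):
        raise DegenerateInput("all fingerprints identical")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(fp)
    for k in range(2):
        loading = pca.components_[k]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, k] *= -1
    return LatentMap(coordinates=coords, explained_variance=pca.explained_variance_ratio_)


def ring_screen(m: Molecule) -> bool:
    """Stability screen: every smallest ring has 5 or 6 members.

    Acyclic molecules pass vacuously.  Molecules with 3-/4-membered or
    7-plus-membered rings are flagged as strained and screened out.
    """
    ring_info = m.rdkit_mol.GetRingInfo()
    return all(len(ring) in (5, 6) for ring in ring_info.AtomRings())


def descriptor_table(smiles_with_gaps: list[tuple[str, float]]) -> pd.DataFrame:
    """One descriptor row per molecule (NaN H/C ratio for carbon-free input)."""
    rows = []
    for smiles, gap in smiles_with_gaps:
        mol = parse_smiles(smiles)
        try:
            hc = hc_ratio(mol)
        except NoCarbonError:
            hc = float("nan")
        rows.append(
            {
                "canonical_smiles": canonical_smiles(mol),
                "gap_eV": gap,
                "hc_ratio": hc,
                "aromaticity_ratio": aromaticity_ratio(mol),
                "fully_aromatic": is_fully_aromatic(mol),
                "dbe": dbe(mol),
                "n_heavy": heavy_atom_count(mol),
                "ring_screen": ring_screen(mol),
            }
        )
    return pd.DataFrame(rows)


def generation_summary(db, seed_min: float | None = None) -> pd.DataFrame:
    """Per-generation table: count, mean gap, sub-threshold count, screened count.

    ``db`` is a :class:`~gapdesign.db.PopulationDB`.  The sub-threshold count
    uses the seed generation's minimum gap unless ``seed_min`` is given; the
    comparison is strict, so generation 0 always reports zero.
    """
    if seed_min is None:
        seed_min = min(r.gap for r in db.records_for_generation(0))
    rows = []
    for gen in db.generations():
        records = db.records_for_generation(gen)
        gaps = np.array([r.gap for r in records])
        screened = sum(
            1
            for r in records
            if r.gap < seed_min and ring_screen(parse_smiles(r.smiles))
        )
        rows.append(
            {
                "generation": gen,
                "n_molecules": len(records),
                "mean_gap_eV": float(gaps.mean()),
                "count_below_seed_min": int((gaps < seed_min).sum()),
                "screened_below_seed_min": screened,
            }
        )
    return pd.DataFrame(rows)
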