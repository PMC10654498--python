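"""Fixed-width graph featurization consumed by the surrogate.

Node feature layout (11 slots, fixed and versioned)::

    [atom-type one-hot over (C, N, O, F, S) : 5]
    [atomic number                          : 1 scalar]
    [aromatic flag                          : 1 scalar]
    [hybridization one-hot over (sp, sp2, sp3) : 3]
    [number of hydrogen neighbors           : 1 scalar]

Edge feature layout: one-hot over (single, double, triple, aromatic).

Scalars (atomic number, H count) enter unnormalized by default; pass
``standardize=True`` to :func:`featurize_dataset` to z-score them against the
dataset.  Featurization uses connectivity only — no 3D information ever
reaches the surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import Molecule
from .errors import FeaturizeError

#: Bump whenever the feature layout changes; checked on checkpoint load.
FEATURE_LAYOUT_VERSION = "node11-edge4-v1"

NODE_FEATURE_DIM = 11
EDGE_FEATURE_DIM = 4

_ATOM_TYPES = ("C", "N", "O", "F", "S")
_HYBRIDIZATIONS = ("sp", "sp2", "sp3")
_BOND_TYPES = ("single", "double", "triple", "aromatic")


@dataclass
class MoleculeGraph:
    """A featurized molecular graph.

    ``edge_index`` holds every bond in both directions (shape ``(2, 2*n_bonds)``);
    ``edge_features`` rows are aligned with its columns.
    """

    node_features: np.ndarray  # (n_nodes, 11)
    edge_index: np.ndarray  # (2, 2*n_bonds) int
    edge_features: np.ndarray  # (2*n_bonds, 4)
    target: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_directed_edges(self) -> int:
        return self.edge_index.shape[1]


def featurize(m: Molecule, target: float | None = None) -> MoleculeGraph:
    """Convert a valid neutral :class:`Molecule` into a :class:`MoleculeGraph`.

    Raises :class:`FeaturizeError` when an atom's hybridization falls outside
    {sp, sp2, sp3} (e.g. hypervalent sulfur); callers skip and log such
    molecules rather than truncating features.
    """
    n = len(m.atoms)
    x = np.zeros((n, NODE_FEATURE_DIM), dtype=np.float64)
    for i, atom in enumerate(m.atoms):
        try:
            x[i, _ATOM_TYPES.index(atom.element)] = 1.0
        except ValueError:  # pragma: no cover - parse layer already rejects
            raise FeaturizeError(f"atom type {atom.element} not featurizable")
        x[i, 5] = atom.atomic_number
        x[i, 6] = 1.0 if atom.aromatic else 0.0
        if atom.hybridization not in _HYBRIDIZATIONS:
            raise FeaturizeError(
                f"hybridization {atom.hybridization!r} of {atom.element} "
                f"in {m.source_smiles!r} outside (sp, sp2, sp3)"
            )
        x[i, 7 + _HYBRIDIZATIONS.index(atom.hybridization)] = 1.0
        x[i, 10] = atom.num_h_neighbors

    n_bonds = len(m.bonds)
    edge_index = np.zeros((2, 2 * n_bonds), dtype=np.int64)
    edge_features = np.zeros((2 * n_bonds, EDGE_FEATURE_DIM), dtype=np.float64)
    for k, bond in enumerate(m.bonds):
        i, j = bond.endpoints
        edge_index[:, 2 * k] = (i, j)
        edge_index[:, 2 * k + 1] = (j, i)
        onehot = _BOND_TYPES.index(bond.bond_type)
        edge_features[2 * k, onehot] = 1.0
        edge_features[2 * k + 1, onehot] = 1.0
    return MoleculeGraph(
        node_features=x,
        edge_index=edge_index,
        edge_features=edge_features,
        target=target,
    )


def dump_graph_csv(graph: MoleculeGraph, node_path, edge_path) -> None:
    """Debug dump of node/edge matrices as CSV."""
    np.savetxt(node_path, graph.node_features, delimiter=",", fmt="%.6g")
    edges = np.concatenate([graph.edge_index.T.astype(float), graph.edge_features], axis=1)
    np.savetxt(edge_path, edges, delimiter=",", fmt="%.6g")
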