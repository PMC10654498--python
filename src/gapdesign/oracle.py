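"""Ground-truth property oracles.

The workflow treats the oracle as an opaque callable ``Molecule -> gap (eV)``.
Production use plugs in an external quantum-chemistry backend through
:func:`external_oracle_adapter`; the package ships :class:`ToyGapOracle`, a
deterministic closed-form gap function whose structure-property axes mirror
those of semi-empirical electronic-structure calculations on small organics:
extended conjugation lowers the gap, saturation and fluorination raise it.

Toy gap model
-------------
Let ``U`` be the set of heavy atoms that are aromatic or incident to a double
or triple bond (the conjugation-capable atoms), ``Cmax`` the size of the
largest connected component of the subgraph induced by ``U``, and
``f_F = nF / n_heavy`` the fluorine fraction.  Then::

    gap = g_min + (g0 - g_min) * exp(-alpha * Cmax) + delta * f_F

With the defaults (g0=14, g_min=0.5, alpha=0.25, delta=8 eV) a saturated
molecule sits at 14 eV, benzene at ~3.5 eV, long conjugated chains approach
0.5 eV, and tetrafluoromethane exceeds 20 eV — the saturated-fluorinated
extreme of the high-gap regime.
"""

from __future__ import annotations

import csv
import math
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .chem import Molecule, canonical_smiles, parse_smiles, round_trip_stable
from .errors import MoleculeError

Oracle = Callable[[Molecule], float]

STATUS_OK = "ok"
STATUS_INVALID = "invalid"
STATUS_REJECTED_ROUND_TRIP = "rejected_round_trip"


@dataclass(frozen=True)
class ToyGapParams:
    """Constants of the toy gap model, all in eV except ``alpha``."""

    g0: float = 14.0
    g_min: float = 0.5
    alpha: float = 0.25
    delta: float = 8.0

    def __post_init__(self) -> None:
        if not (self.g0 > self.g_min > 0):
            raise ValueError("require g0 > g_min > 0")
        if self.alpha <= 0 or self.delta < 0:
            raise ValueError("require alpha > 0 and delta >= 0")


@dataclass
class OracleResult:
    """Outcome of evaluating one input SMILES."""

    input_smiles: str
    canonical_smiles: str | None
    gap: float | None
    status: str
    reason: str | None = None


def _conjugated_component_size(m: Molecule) -> int:
    """Size of the largest connected unsaturated fragment (Cmax)."""
    unsat = set()
    for atom_idx, atom in enumerate(m.atoms):
        if atom.aromatic:
            unsat.add(atom_idx)
    for bond in m.bonds:
        if bond.bond_type in ("double", "triple"):
            unsat.update(bond.endpoints)
    if not unsat:
        return 0
    adj: dict[int, list[int]] = {i: [] for i in unsat}
    for bond in m.bonds:
        i, j = bond.endpoints
        if i in unsat and j in unsat:
            adj[i].append(j)
            adj[j].append(i)
    best, seen = 0, set()
    for start in unsat:
        if start in seen:
            continue
        stack, comp = [start], 0
        seen.add(start)
        while stack:
            node = stack.pop()
            comp += 1
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        best = max(best, comp)
    return best


def toy_gap(m: Molecule, params: ToyGapParams = ToyGapParams()) -> float:
    """Closed-form stand-in gap in eV; see the module docstring for the model."""
    n_heavy = len(m.atoms)
    cmax = _conjugated_component_size(m)
    f_f = sum(1 for a in m.atoms if a.element == "F") / n_heavy
    return params.g_min + (params.g0 - params.g_min) * math.exp(-params.alpha * cmax) + params.delta * f_f


@dataclass
class ToyGapOracle:
    """Callable oracle wrapping :func:`toy_gap`."""

    params: ToyGapParams = field(default_factory=ToyGapParams)

    def __call__(self, m: Molecule) -> float:
        return toy_gap(m, self.params)


def evaluate_population(
    smiles_list: Sequence[str],
    oracle: Oracle,
    allow_net_charge: bool = False,
    cache: "OracleCache | None" = None,
) -> list[OracleResult]:
    """Evaluate every SMILES, mapping each input to exactly one result.

    The round-trip canonicalization filter is applied before the oracle is
    called: a molecule whose SMILES does not survive a canonicalize/re-parse
    cycle is rejected (mirroring the discard of structures whose connectivity
    changes under geometry optimization).  Backend failures surface as
    ``status=invalid`` with a reason, never as silent drops.
    """
    results: list[OracleResult] = []
    for text in smiles_list:
        try:
            mol = parse_smiles(text, allow_net_charge=allow_net_charge)
        except MoleculeError as exc:
            results.append(OracleResult(text, None, None, STATUS_INVALID, str(exc)))
            continue
        canon = canonical_smiles(mol)
        if not round_trip_stable(text):
            results.append(
                OracleResult(text, canon, None, STATUS_REJECTED_ROUND_TRIP, "canonical form unstable")
            )
            continue
        if cache is not None and canon in cache:
            results.append(OracleResult(text, canon, cache[canon], STATUS_OK))
            continue
        try:
            gap = float(oracle(mol))
        except Exception as exc:  # backend errors surface as status codes
            results.append(OracleResult(text, canon, None, STATUS_INVALID, f"oracle failure: {exc}"))
            continue
        if cache is not None:
            cache[canon] = gap
        results.append(OracleResult(text, canon, gap, STATUS_OK))
    return results


def external_oracle_adapter(
    command_template: str,
    parser: Callable[[str], float],
) -> Oracle:
    """Wrap an external electronic-structure program as an oracle.

    ``command_template`` is formatted with ``smiles=<canonical SMILES>`` and run
    through the shell; ``parser`` maps its stdout to a gap in eV.  A real
    backend would embed the SMILES in 3D (e.g. with a force field), relax the
    geometry with a tight SCF/SCC convergence threshold, and report the
    frontier-orbital gap; all of that lives behind the command.  Subprocess or
    parse failures propagate as exceptions, which
    :func:`evaluate_population` converts to ``status=invalid``.
    """

    def oracle(m: Molecule) -> float:
        cmd = command_template.format(smiles=canonical_smiles(m))
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True, check=True)
        return parser(proc.stdout)

    return oracle


class OracleCache:
    """CSV-backed oracle result cache keyed by canonical SMILES.

    Columns: smiles, gap_eV, status.  Only ``ok`` results are cached so that
    transient backend failures are retried on the next run.
    """

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self._data: dict[str, float] = {}
        if self.path is not None and self.path.exists():
            with open(self.path, newline="") as fh:
                for row in csv.DictReader(fh):
                    if row["status"] == STATUS_OK:
                        self._data[row["smiles"]] = float(row["gap_eV"])

    def __contains__(self, smiles: str) -> bool:
        return smiles in self._data

    def __getitem__(self, smiles: str) -> float:
        return self._data[smiles]

    def __setitem__(self, smiles: str, gap: float) -> None:
        self._data[smiles] = gap

    def __len__(self) -> int:
        return len(self._data)

    def save(self) -> None:
        if self.path is None:
            raise ValueError("cache constructed without a path")
        with open(self.path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["smiles", "gap_eV", "status"])
            for smiles, gap in sorted(self._data.items()):
                writer.writerow([smiles, f"{gap:.10g}", STATUS_OK])


def results_summary(results: Iterable[OracleResult]) -> dict[str, int]:
    """Status counts for reporting; statuses conserve the input count."""
    counts = {STATUS_OK: 0, STATUS_INVALID: 0, STATUS_REJECTED_ROUND_TRIP: 0}
    for res in results:
        counts[res.status] += 1
    return counts
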