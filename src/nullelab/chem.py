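"""Molecular states, the enumerable edit action space, and fingerprint primitives.

A molecule is represented by its canonical SMILES string; the Q-learning
generator treats each molecule as a state and each single chemical edit
(atom addition, bond addition/order increment, bond removal, or no change)
as an action.  All emitted states are valence-valid, canonical and
deduplicated.  Fingerprints are folded Morgan circular fingerprints
(ECFP4 by default: radius 2, 2048 bits) compared by Tanimoto similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

# Default valences used to compute free valence for neutral organics.
_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "S": 2, "P": 3, "Cl": 1, "Br": 1, "I": 1, "H": 1}

_BOND_TYPES = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a valid molecule."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES to an RDKit Mol, raising :class:`SmilesParseError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Return the unique canonical SMILES for ``smiles``.

    Idempotent: ``canonicalize(canonicalize(s)) == canonicalize(s)``.  The
    canonical writer (RDKit's default aromatic canonical SMILES) is fixed per
    run and recorded in run manifests.
    """
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def is_valid(smiles: str) -> bool:
    """True if ``smiles`` parses and passes RDKit sanitization (valence check)."""
    return Chem.MolFromSmiles(smiles) is not None


@dataclass(frozen=True)
class MoleculeState:
    """A molecular graph (canonical SMILES) plus the episode step counter."""

    structure: str
    steps_taken: int = 0
    terminal: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "structure", canonicalize(self.structure))
        if self.steps_taken < 0:
            raise ValueError("steps_taken must be non-negative")

    @property
    def mol(self) -> Chem.Mol:
        return mol_from_smiles(self.structure)


@dataclass(frozen=True)
class ActionSpace:
    """Configuration of the legal single-edit modifications.

    ``allow_ring_formation`` controls whether a new bond may be created
    between two atoms that are already connected through the graph (every
    such bond closes a ring); the generator the pipeline mirrors leaves this
    unstated, so it is exposed here.
    """

    allowed_elements: frozenset[str] = frozenset({"C", "N", "O"})
    max_steps: int = 10
    allow_bond_removal: bool = True
    allow_no_modification: bool = True
    allow_ring_formation: bool = True

    def __post_init__(self) -> None:
        if not self.allowed_elements:
            raise ValueError("allowed_elements must be non-empty")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        unknown = set(self.allowed_elements) - set(_MAX_VALENCE)
        if unknown:
            raise ValueError(f"unsupported elements: {sorted(unknown)}")


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length folded circular (Morgan) fingerprint."""

    bits: np.ndarray
    radius: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))

    def __len__(self) -> int:
        return int(self.bits.size)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def fingerprint(state: MoleculeState | str, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    """Folded Morgan fingerprint of a molecule (ECFP4 for radius 2)."""
    smiles = state.structure if isinstance(state, MoleculeState) else state
    mol = mol_from_smiles(smiles)
    gen = _fp_generator(radius, n_bits)
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=bool)
    arr[list(bv.GetOnBits())] = True
    return Fingerprint(arr, radius)


_GEN_CACHE: dict[tuple[int, int], object] = {}


def _fp_generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _GEN_CACHE:
        _GEN_CACHE[key] = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return _GEN_CACHE[key]


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| between two equal-length fingerprints.

    Two all-zero fingerprints are defined to have similarity 0.
    """
    if len(a) != len(b):
        raise ValueError(f"fingerprint length mismatch: {len(a)} vs {len(b)}")
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        return 0.0
    inter = int(np.logical_and(a.bits, b.bits).sum())
    return inter / union


# ---------------------------------------------------------------------------
# Action enumeration
# ---------------------------------------------------------------------------

def _free_valence(atom: Chem.Atom) -> int:
    return int(atom.GetTotalNumHs())


def _sanitize_to_smiles(rwmol: Chem.RWMol) -> str | None:
    """Sanitize an edited molecule (re-perceiving aromaticity); None if invalid."""
    try:
        mol = rwmol.GetMol()
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    # neutral-species policy: sanitization cleanup can charge-separate some
    # N-oxide-like motifs; those leave the action space
    if any(a.GetFormalCharge() != 0 for a in mol.GetAtoms()):
        return None
    smi = Chem.MolToSmiles(mol)
    # connectivity: generated compounds must be single molecules
    if "." in smi:
        return None
    return smi


def _kekulized_copy(mol: Chem.Mol) -> Chem.RWMol:
    m = Chem.Mol(mol)
    Chem.Kekulize(m, clearAromaticFlags=True)
    return Chem.RWMol(m)


def _atom_additions(mol: Chem.Mol, elements: Iterable[str]) -> set[str]:
    out: set[str] = set()
    for idx in range(mol.GetNumAtoms()):
        fv = _free_valence(mol.GetAtomWithIdx(idx))
        if fv <= 0:
            continue
        for el in elements:
            for order in (1, 2, 3):
                if order > fv or order > _MAX_VALENCE[el]:
                    continue
                rw = _kekulized_copy(mol)
                new_idx = rw.AddAtom(Chem.Atom(el))
                rw.AddBond(idx, new_idx, _BOND_TYPES[order])
                smi = _sanitize_to_smiles(rw)
                if smi is not None:
                    out.add(smi)
    return out


def _bond_additions(mol: Chem.Mol, allow_ring_formation: bool) -> set[str]:
    out: set[str] = set()
    n = mol.GetNumAtoms()
    for i in range(n):
        fv_i = _free_valence(mol.GetAtomWithIdx(i))
        if fv_i <= 0:
            continue
        for j in range(i + 1, n):
            fv_j = _free_valence(mol.GetAtomWithIdx(j))
            if fv_j <= 0:
                continue
            existing = mol.GetBondBetweenAtoms(i, j)
            max_incr = min(fv_i, fv_j)
            for incr in range(1, max_incr + 1):
                rw = _kekulized_copy(mol)
                bond = rw.GetBondBetweenAtoms(i, j)
                if bond is None:
                    if not allow_ring_formation:
                        continue
                    if incr > 3:
                        continue
                    rw.AddBond(i, j, _BOND_TYPES[incr])
                else:
                    cur = int(round(bond.GetBondTypeAsDouble()))
                    new_order = cur + incr
                    if new_order > 3:
                        continue
                    bond.SetBondType(_BOND_TYPES[new_order])
                smi = _sanitize_to_smiles(rw)
                if smi is not None:
                    out.add(smi)
            # existing var unused beyond None check; kept implicit
            del existing
    return out


def _bond_removals(mol: Chem.Mol) -> set[str]:
    """Decrement-order-or-delete for every bond; disconnecting deletions rejected."""
    out: set[str] = set()
    kek = _kekulized_copy(mol).GetMol()
    for bond in kek.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        cur = int(round(bond.GetBondTypeAsDouble()))
        for new_order in range(cur - 1, -1, -1):
            rw = Chem.RWMol(kek)
            b = rw.GetBondBetweenAtoms(i, j)
            if new_order == 0:
                rw.RemoveBond(i, j)
            else:
                b.SetBondType(_BOND_TYPES[new_order])
            smi = _sanitize_to_smiles(rw)  # rejects multi-fragment results
            if smi is not None:
                out.add(smi)
    return out


def enumerate_actions(state: MoleculeState, space: ActionSpace) -> set[MoleculeState]:
    """All states reachable from ``state`` by one legal modification.

    Returns the union of atom additions, bond additions / order increments,
    bond removals (if enabled) and the unmodified state (if enabled), each
    valence-valid, canonical, deduplicated, with ``steps_taken`` incremented.
    An empty set (with the input flagged terminal by the caller) corresponds
    to exhausted steps.
    """
    if state.steps_taken >= space.max_steps:
        return set()
    mol = state.mol
    smiles: set[str] = set()
    smiles |= _atom_additions(mol, sorted(space.allowed_elements))
    smiles |= _bond_additions(mol, space.allow_ring_formation)
    if space.allow_bond_removal:
        smiles |= _bond_removals(mol)
    if space.allow_no_modification:
        smiles.add(state.structure)
    step = state.steps_taken + 1
    return {
        MoleculeState(s, steps_taken=step, terminal=step >= space.max_steps)
        for s in smiles
    }


# ---------------------------------------------------------------------------
# SMILES file round-trip (.smi: one record per line, optional identifier)
# ---------------------------------------------------------------------------

def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read a .smi file into (canonical_smiles, identifier) pairs.

    Lines are ``SMILES [whitespace identifier]``; blank lines and ``#``
    comments are skipped; a missing identifier defaults to ``mol<line>``.
    """
    records: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = canonicalize(parts[0])
            ident = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            records.append((smi, ident))
    return records


def write_smiles_file(path, records: Sequence[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for smi, ident in records:
            fh.write(f"{smi}\t{ident}\n")
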