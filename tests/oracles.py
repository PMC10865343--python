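"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own prefiltering logic: every
candidate edit is attempted blindly on an RDKit editable molecule and kept
only if sanitization succeeds and the result is a single fragment.
"""

from itertools import combinations, product

from rdkit import Chem

_BOND = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def _try_smiles(rw: Chem.RWMol) -> str | None:
    try:
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    if any(a.GetFormalCharge() != 0 for a in mol.GetAtoms()):
        return None  # neutral organics only
    smi = Chem.MolToSmiles(mol)
    return None if "." in smi else smi


def _kekulized(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return mol


def brute_force_actions(
    smiles: str,
    elements=("C", "N", "O"),
    allow_bond_removal: bool = True,
    allow_no_modification: bool = True,
    allow_ring_formation: bool = True,
) -> set[str]:
    """Try every (element, site, order), (pair, order-change) and removal."""
    base = _kekulized(smiles)
    n = base.GetNumAtoms()
    out: set[str] = set()

    # atom additions: blindly attach every element with every order
    for i, el, order in product(range(n), elements, (1, 2, 3)):
        rw = Chem.RWMol(base)
        j = rw.AddAtom(Chem.Atom(el))
        rw.AddBond(i, j, _BOND[order])
        smi = _try_smiles(rw)
        if smi is not None:
            out.add(smi)

    # bond additions / order increments between every atom pair
    for i, j in combinations(range(n), 2):
        existing = base.GetBondBetweenAtoms(i, j)
        cur = int(round(existing.GetBondTypeAsDouble())) if existing else 0
        for new_order in range(cur + 1, 4):
            if cur == 0 and not allow_ring_formation:
                continue
            rw = Chem.RWMol(base)
            if cur == 0:
                rw.AddBond(i, j, _BOND[new_order])
            else:
                rw.GetBondBetweenAtoms(i, j).SetBondType(_BOND[new_order])
            smi = _try_smiles(rw)
            if smi is not None:
                out.add(smi)

    # bond removals: decrement or delete, rejecting disconnections
    if allow_bond_removal:
        for bond in base.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            cur = int(round(bond.GetBondTypeAsDouble()))
            for new_order in range(cur):
                rw = Chem.RWMol(base)
                if new_order == 0:
                    rw.RemoveBond(i, j)
                else:
                    rw.GetBondBetweenAtoms(i, j).SetBondType(_BOND[new_order])
                smi = _try_smiles(rw)
                if smi is not None:
                    out.add(smi)

    if allow_no_modification:
        out.add(Chem.MolToSmiles(Chem.MolFromSmiles(smiles)))
    return out


def enumerate_small_molecules(max_atoms: int = 4, elements=("C", "N", "O")) -> set[str]:
    """Every connected neutral molecule with <= max_atoms heavy atoms.

    Exhaustive over labelled graphs: all element assignments times all edge
    order assignments (0-3 per possible edge), validated by sanitization.
    """
    found: set[str] = set()
    for n in range(1, max_atoms + 1):
        edges = list(combinations(range(n), 2))
        for elems in product(elements, repeat=n):
            for orders in product(range(4), repeat=len(edges)):
                rw = Chem.RWMol()
                for el in elems:
                    rw.AddAtom(Chem.Atom(el))
                for (i, j), order in zip(edges, orders):
                    if order:
                        rw.AddBond(i, j, _BOND[order])
                smi = _try_smiles(rw)
                if smi is not None:
                    found.add(smi)
    return found
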