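"""CNS MPO desirability scoring, synthetic accessibility, and the composite reward.

The CNS multiparameter-optimization (MPO) score is the sum of six
desirability functions, one per physicochemical parameter (MW, ClogP,
ClogD at pH 7.4, TPSA, HBD count, most basic pKa), each mapped to [0, 1],
so the total lies in [0, 6]; >= 4 is the conventional CNS-penetrant cutoff.
Five parameters use monotone-decreasing piecewise-linear ramps; TPSA uses a
trapezoidal hump (too little polarity hurts permeability-driven efflux
balance as much as too much).  Breakpoints are data, not code: see
``data/cns_mpo.yaml``.

The synthetic-accessibility (SA) score is a fragment-contribution score
with complexity penalties, oriented so lower = easier to make.  The
composite reward is a weighted sum of per-component benefits, each first
normalized to [0, 1].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Protocol

import yaml
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .chem import MoleculeState, mol_from_smiles


class PropertyUnavailableError(KeyError):
    """A property provider has no value for the requested molecule/parameter."""


@dataclass(frozen=True)
class PropertyVector:
    """The six CNS MPO inputs for one molecule."""

    mw: float          # molecular weight, Da
    clogp: float       # computed octanol-water logP
    clogd: float       # computed logD at pH 7.4
    tpsa: float        # topological polar surface area, A^2
    hbd: int           # hydrogen-bond donor count
    pka_basic: float   # most basic predicted pKa

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        if self.tpsa < 0:
            raise ValueError("tpsa must be non-negative")
        if self.hbd < 0:
            raise ValueError("hbd must be non-negative")


# ---------------------------------------------------------------------------
# Property providers (clogp / clogd / pka_basic are predictor-dependent)
# ---------------------------------------------------------------------------

class PropertyProvider(Protocol):
    def clogp(self, smiles: str) -> float: ...
    def clogd(self, smiles: str) -> float: ...
    def pka_basic(self, smiles: str) -> float: ...

    @property
    def name(self) -> str: ...


# SMARTS -> approximate basic pKa of the matched center (rule-based estimate).
_PKA_RULES: tuple[tuple[str, float], ...] = (
    ("[NX3;H0,H1,H2;!$(N=*);!$(N-C=[O,N,S]);!$(N-a);!$(N#*)]", 10.0),  # aliphatic amine
    ("[nX2;$(n1ccccc1)]", 5.2),                                        # pyridine-like
    ("[NX3;$(N-a);!$(N-C=[O,N,S])]", 4.6),                             # aniline-like
    ("[NX2]=[CX3][NX3]", 12.0),                                        # amidine/guanidine
)


class BuiltinPropertyProvider:
    """Simple built-in estimator for ClogP / ClogD / basic pKa.

    ClogP is the Crippen atom-contribution estimate; the most basic pKa is a
    SMARTS rule lookup (molecules with no basic nitrogen get 0, i.e. no basic
    center); ClogD at pH 7.4 follows from ClogP by the Henderson-Hasselbalch
    correction for a monoprotic base,
    ``clogd = clogp - log10(1 + 10^(pka - 7.4))``.
    """

    name = "builtin-atom-contribution"

    def clogp(self, smiles: str) -> float:
        return float(Crippen.MolLogP(mol_from_smiles(smiles)))

    def pka_basic(self, smiles: str) -> float:
        mol = mol_from_smiles(smiles)
        best = 0.0
        for smarts, pka in _PKA_RULES:
            patt = Chem.MolFromSmarts(smarts)
            if mol.HasSubstructMatch(patt):
                best = max(best, pka)
        return best

    def clogd(self, smiles: str) -> float:
        pka = self.pka_basic(smiles)
        return self.clogp(smiles) - math.log10(1.0 + 10.0 ** (pka - 7.4))


class TablePropertyProvider:
    """Lookup provider backed by a CSV table (identifier or smiles keyed).

    Missing molecules raise :class:`PropertyUnavailableError` — never a
    silent default.
    """

    name = "table-lookup"

    def __init__(self, table: Mapping[str, Mapping[str, float]]):
        from .chem import canonicalize

        self._table = {canonicalize(k): dict(v) for k, v in table.items()}

    @classmethod
    def from_csv(cls, path) -> "TablePropertyProvider":
        import pandas as pd

        df = pd.read_csv(path)
        key = "smiles" if "smiles" in df.columns else df.columns[0]
        table = {
            str(row[key]): {c: float(row[c]) for c in ("clogp", "clogd", "pka_basic")}
            for _, row in df.iterrows()
        }
        return cls(table)

    def _get(self, smiles: str, prop: str) -> float:
        from .chem import canonicalize

        smi = canonicalize(smiles)
        if smi not in self._table or prop not in self._table[smi]:
            raise PropertyUnavailableError(f"property {prop!r} unavailable for {smiles!r}")
        return self._table[smi][prop]

    def clogp(self, smiles: str) -> float:
        return self._get(smiles, "clogp")

    def clogd(self, smiles: str) -> float:
        return self._get(smiles, "clogd")

    def pka_basic(self, smiles: str) -> float:
        return self._get(smiles, "pka_basic")


def compute_properties(
    state: MoleculeState | str, provider: PropertyProvider | None = None
) -> PropertyVector:
    """Compute the six-parameter property vector for a molecule.

    MW, TPSA and HBD come from the molecular graph; ClogP/ClogD/pKa from the
    provider (built-in estimator by default).
    """
    provider = provider or BuiltinPropertyProvider()
    smiles = state.structure if isinstance(state, MoleculeState) else state
    mol = mol_from_smiles(smiles)
    # donor-H convention: each H on N or O counts (water has 2 donors)
    hbd = sum(a.GetTotalNumHs() for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O"))
    return PropertyVector(
        mw=float(Descriptors.MolWt(mol)),
        clogp=provider.clogp(smiles),
        clogd=provider.clogd(smiles),
        tpsa=float(rdMolDescriptors.CalcTPSA(mol)),
        hbd=hbd,
        pka_basic=provider.pka_basic(smiles),
    )


# ---------------------------------------------------------------------------
# Desirability functions and CNS MPO
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesirabilityConfig:
    """Per-parameter piecewise-linear breakpoint tables for the six parameters."""

    tables: Mapping[str, Mapping[str, float]]

    PARAMS = ("mw", "clogp", "clogd", "tpsa", "hbd", "pka_basic")

    def __post_init__(self) -> None:
        for p in self.PARAMS:
            if p not in self.tables:
                raise ValueError(f"missing desirability table for {p!r}")
            t = self.tables[p]
            if t["kind"] == "ramp_down":
                if not t["favorable"] < t["unfavorable"]:
                    raise ValueError(f"{p}: breakpoints must be strictly ordered")
            elif t["kind"] == "hump":
                pts = [t["zero_low"], t["one_low"], t["one_high"], t["zero_high"]]
                if not all(a < b for a, b in zip(pts, pts[1:])):
                    raise ValueError(f"{p}: hump breakpoints must be strictly ordered")
            else:
                raise ValueError(f"{p}: unknown table kind {t['kind']!r}")

    @classmethod
    def default(cls) -> "DesirabilityConfig":
        text = resources.files("nullelab.data").joinpath("cns_mpo.yaml").read_text()
        return cls(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path) -> "DesirabilityConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def desirability(value: float, table: Mapping[str, float]) -> float:
    """Piecewise-linear desirability in [0, 1]: plateau-ramp-plateau (or hump)."""
    if table["kind"] == "ramp_down":
        lo, hi = table["favorable"], table["unfavorable"]
        if value <= lo:
            return 1.0
        if value >= hi:
            return 0.0
        return (hi - value) / (hi - lo)
    # trapezoidal hump: 0 below zero_low, rises to 1 at one_low, plateau to
    # one_high, falls to 0 at zero_high
    z0, o0, o1, z1 = table["zero_low"], table["one_low"], table["one_high"], table["zero_high"]
    if value <= z0 or value >= z1:
        return 0.0
    if o0 <= value <= o1:
        return 1.0
    if value < o0:
        return (value - z0) / (o0 - z0)
    return (z1 - value) / (z1 - o1)


def cns_mpo(pv: PropertyVector, config: DesirabilityConfig | None = None) -> float:
    """CNS MPO score: the sum of the six desirability values, in [0, 6]."""
    config = config or DesirabilityConfig.default()
    return sum(
        desirability(getattr(pv, p), config.tables[p]) for p in DesirabilityConfig.PARAMS
    )


# ---------------------------------------------------------------------------
# Synthetic accessibility
# ---------------------------------------------------------------------------

_SA_TABLE: dict[int, float] | None = None
_SA_DEFAULT: float | None = None


def _sa_table() -> tuple[dict[int, float], float]:
    global _SA_TABLE, _SA_DEFAULT
    if _SA_TABLE is None:
        text = resources.files("nullelab.data").joinpath("sa_fragments.json").read_text()
        raw = json.loads(text)
        _SA_TABLE = {int(k): float(v) for k, v in raw["scores"].items()}
        _SA_DEFAULT = float(raw["unknown_score"])
    return _SA_TABLE, _SA_DEFAULT


def sa_score(state: MoleculeState | str) -> float:
    """Synthetic-accessibility score: lower = easier to synthesize.

    Fragment-contribution term (mean log-frequency of the molecule's radius-2
    circular substructures in the shipped frequency table; rare or unseen
    fragments score low) minus complexity penalties for size, ring
    fusion/bridging/spiro centers, macrocycles and stereocenters, rescaled to
    roughly 1 (easy) .. 10 (hard).
    """
    from rdkit.Chem import rdMolDescriptors as rd

    smiles = state.structure if isinstance(state, MoleculeState) else state
    mol = mol_from_smiles(smiles)
    table, unknown = _sa_table()

    fp = rd.GetMorganFingerprint(mol, 2)
    elements = fp.GetNonzeroElements()
    nfrag = sum(elements.values())
    frag_score = sum(table.get(bid, unknown) * cnt for bid, cnt in elements.items())
    frag_score /= max(nfrag, 1)

    n_atoms = mol.GetNumHeavyAtoms()
    ri = mol.GetRingInfo()
    n_bridge = rd.CalcNumBridgeheadAtoms(mol)
    n_spiro = rd.CalcNumSpiroAtoms(mol)
    n_fused = _fused_bond_count(ri)
    n_stereo = len(Chem.FindMolChiralCenters(mol, includeUnassigned=True))
    n_macro = sum(1 for ring in ri.AtomRings() if len(ring) > 8)

    size_penalty = n_atoms ** 1.005 - n_atoms
    ring_penalty = math.log10(n_bridge + 1) + math.log10(n_spiro + 1) + 0.5 * math.log10(n_fused + 1)
    stereo_penalty = math.log10(n_stereo + 1)
    macro_penalty = math.log10(2) * n_macro

    raw = -frag_score + size_penalty + ring_penalty + stereo_penalty + macro_penalty
    # affine rescale chosen so simple acyclic organics land near 1-3
    score = 1.0 + raw * 1.2
    return max(score, 1.0)


def _fused_bond_count(ring_info) -> int:
    """Number of bonds shared by two or more rings (a ring-fusion measure)."""
    from collections import Counter

    counts = Counter(b for ring in ring_info.BondRings() for b in ring)
    return sum(1 for c in counts.values() if c > 1)


# ---------------------------------------------------------------------------
# Composite reward
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreBundle:
    """The multiparameter reward components for one molecule."""

    cns_mpo: float
    sa_score: float
    potency_pred: float      # predicted normalized aggregation half-time (ratio)
    binding_pred: float      # predicted binding energy, kcal/mol (more negative = better)
    composite_reward: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cns_mpo <= 6.0:
            raise ValueError("cns_mpo must lie in [0, 6]")


@dataclass(frozen=True)
class RewardWeights:
    """Non-negative component weights plus per-component normalization ranges.

    Each raw component is mapped to a [0, 1] benefit before weighting:
    potency benefit rises with predicted normalized half-time over
    ``potency_range``; MPO benefit is cns_mpo / 6; SA benefit rises as the
    score falls over ``sa_range``; binding benefit rises as predicted energy
    becomes more negative over ``binding_range`` (kcal/mol).
    """

    w_potency: float = 1.0
    w_mpo: float = 1.0
    w_sa: float = 0.5
    w_binding: float = 0.5
    potency_range: tuple[float, float] = (1.0, 3.0)
    mpo_range: tuple[float, float] = (0.0, 6.0)
    sa_range: tuple[float, float] = (1.0, 10.0)
    binding_range: tuple[float, float] = (-12.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("w_potency", "w_mpo", "w_sa", "w_binding"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _benefit_up(x: float, lo: float, hi: float) -> float:
    return min(max((x - lo) / (hi - lo), 0.0), 1.0)


def benefits(bundle: ScoreBundle, weights: RewardWeights) -> dict[str, float]:
    """Per-component [0, 1] benefit values under the configured ranges."""
    return {
        "potency": _benefit_up(bundle.potency_pred, *weights.potency_range),
        "mpo": _benefit_up(bundle.cns_mpo, *weights.mpo_range),
        "sa": 1.0 - _benefit_up(bundle.sa_score, *weights.sa_range),
        "binding": 1.0 - _benefit_up(bundle.binding_pred, *weights.binding_range),
    }


def composite_reward(bundle: ScoreBundle, weights: RewardWeights) -> float:
    """Weighted sum of component benefits: sum_i w_i * benefit_i."""
    b = benefits(bundle, weights)
    return (
        weights.w_potency * b["potency"]
        + weights.w_mpo * b["mpo"]
        + weights.w_sa * b["sa"]
        + weights.w_binding * b["binding"]
    )
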