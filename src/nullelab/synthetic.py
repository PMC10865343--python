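"""Synthetic fixture generation: toy molecule libraries, surrogate property
labels, and kinetic traces with planted parameters.

Every generator is a pure function of its seed and spec, so planted-parameter
recovery tests close the loop for the QSAR and kinetics modules without any
external dataset.  The molecule libraries emulate small drug-like organics
(heavy atoms capped at 20, elements C/N/O/F/S by default); the kinetic traces
emulate sigmoidal seeded-aggregation time courses; the surrogate labels stand
in for external binding-score, CNS MPO and aggregation-half-time datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem import ActionSpace, MoleculeState, enumerate_actions
from .kinetics import KineticTrace

DEFAULT_LIBRARY_SPACE = ActionSpace(
    allowed_elements=frozenset({"C", "N", "O", "F", "S"}),
    max_steps=1_000_000,  # walks are bounded by walk_length, not the space
    allow_bond_removal=True,
    allow_no_modification=False,
)

_START_FRAGMENTS = ("C", "CC", "CCO", "CN", "CCC")
MAX_HEAVY_ATOMS = 20


def gen_molecule_library(
    seed: int,
    n: int,
    space: ActionSpace = DEFAULT_LIBRARY_SPACE,
    walk_length: int = 8,
    retry_budget: int = 50,
    starts: tuple[str, ...] = _START_FRAGMENTS,
) -> list[MoleculeState]:
    """Generate ``n`` distinct valid molecules by seeded random action walks.

    Each walk starts from one of the ``starts`` fragments and applies
    ``walk_length`` random legal edits; products exceeding
    ``MAX_HEAVY_ATOMS`` heavy atoms are rejected.  Raises if ``n`` distinct
    molecules cannot be reached within ``retry_budget * n`` walks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: dict[str, MoleculeState] = {}
    attempts = 0
    while len(seen) < n and attempts < retry_budget * n:
        attempts += 1
        start = starts[rng.integers(len(starts))]
        state = MoleculeState(start)
        for _ in range(walk_length):
            candidates = [
                c
                for c in sorted(enumerate_actions(state, space), key=lambda s: s.structure)
                if c.mol.GetNumHeavyAtoms() <= MAX_HEAVY_ATOMS
            ]
            if not candidates:
                break
            state = candidates[rng.integers(len(candidates))]
        final = MoleculeState(state.structure)
        seen.setdefault(final.structure, final)
    if len(seen) < n:
        raise RuntimeError(
            f"could not reach {n} distinct molecules within the retry budget "
            f"(achieved {len(seen)})"
        )
    return list(seen.values())[:n]


# ---------------------------------------------------------------------------
# Surrogate property labels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateSpec:
    """Deterministic surrogate label generator for QSAR fixtures.

    ``linear_descriptor``: affine in (MW, TPSA, HBD) with the given
    coefficients; ``nonlinear_descriptor``: smooth sinusoid of a descriptor
    projection; ``motif_potency``: a normalized-half-time-like label elevated
    by ``motif_effect`` for molecules containing the planted substructure.
    """

    name: str = "linear_descriptor"
    coefficients: tuple[float, ...] = (0.5, 0.01, -0.02, 0.1)  # intercept, mw, tpsa, hbd
    motif_smarts: str = "[#16]"          # planted potency motif: a sulfur atom
    motif_base: float = 1.0              # inert normalized half-time
    motif_effect: float = 1.0            # label lift for motif carriers
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in {"linear_descriptor", "nonlinear_descriptor", "motif_potency"}:
            raise ValueError(f"unknown surrogate {self.name!r}")


def descriptor_block(states: list[MoleculeState]) -> np.ndarray:
    """(MW, TPSA, HBD) rows used by the descriptor surrogates."""
    from rdkit.Chem import Descriptors, rdMolDescriptors

    rows = []
    for st in states:
        mol = st.mol
        rows.append(
            [
                Descriptors.MolWt(mol),
                rdMolDescriptors.CalcTPSA(mol),
                rdMolDescriptors.CalcNumHBD(mol),
            ]
        )
    return np.asarray(rows, dtype=float)


def surrogate_targets(states: list[MoleculeState], spec: SurrogateSpec) -> np.ndarray:
    """Noise-free + seeded-noise surrogate labels for a list of molecules."""
    rng = np.random.default_rng(spec.seed)
    if spec.name == "motif_potency":
        patt = Chem.MolFromSmarts(spec.motif_smarts)
        y = np.array(
            [
                spec.motif_base + (spec.motif_effect if st.mol.HasSubstructMatch(patt) else 0.0)
                for st in states
            ]
        )
    else:
        d = descriptor_block(states)
        if spec.name == "linear_descriptor":
            c = spec.coefficients
            y = c[0] + d @ np.asarray(c[1:4])
        else:  # nonlinear_descriptor
            # standardized projection keeps the sinusoid in a learnable band
            z = (d - d.mean(axis=0)) / (d.std(axis=0) + 1e-9)
            proj = z @ np.asarray(spec.coefficients[1:4])
            y = spec.coefficients[0] + np.sin(proj) + 0.3 * proj
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=len(states))
    return y


def gen_property_labels(states: list[MoleculeState], spec: SurrogateSpec, endpoint: str = "normalized_half_time"):
    """Build a :class:`~nullelab.qsar.QsarDataset` with surrogate targets."""
    from .qsar import QsarDataset

    y = surrogate_targets(states, spec)
    ids = [f"mol{i}" for i in range(len(states))]
    return QsarDataset(ids=ids, smiles=[s.structure for s in states], y=y, endpoint=endpoint)


# ---------------------------------------------------------------------------
# Kinetic traces with planted parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceSpec:
    """Logistic aggregation trace with a planted half-time.

    The noiseless normalized curve crosses 0.5 exactly at ``t_half`` hours.
    Noise is multiplicative Gaussian with fractional sd ``noise_sd``.
    """

    t_half: float = 20.0
    steepness: float = 1.5        # logistic rate, 1/h
    baseline: float = 0.0
    plateau: float = 1.0
    t_max: float = 60.0
    n_points: int = 121
    noise_sd: float = 0.0
    seed: int = 0
    condition: str = ""
    concentration_um: float = 0.0
    replicate: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.t_half < self.t_max:
            raise ValueError("t_half must lie inside the sampling grid")
        if self.n_points < 5:
            raise ValueError("need >= 5 samples")


def gen_kinetic_trace(spec: TraceSpec) -> KineticTrace:
    """Sample a logistic transition with the planted half-time plus seeded noise."""
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, spec.t_max, spec.n_points)
    y01 = 1.0 / (1.0 + np.exp(-spec.steepness * (t - spec.t_half)))
    y = spec.baseline + (spec.plateau - spec.baseline) * y01
    if spec.noise_sd > 0:
        y = y * (1.0 + rng.normal(0.0, spec.noise_sd, size=t.size))
    return KineticTrace(
        times=t,
        signal=y,
        condition=spec.condition,
        concentration_um=spec.concentration_um,
        replicate=spec.replicate,
    )


def gen_dose_series(
    kic50_true: float,
    hill_slope: float = 1.5,
    concentrations: tuple[float, ...] = (3.125, 6.25, 12.5, 25.0, 50.0, 100.0),
    control_t_half: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 1,
    steepness: float = 1.5,
) -> list[KineticTrace]:
    """Concentration series with a planted KIC50.

    Half-times follow t1/2(c) = control * (1 + 0.5 * (c / KIC50)^h), so the
    half-time at c = KIC50 is exactly 1.5x the control — the KIC50 definition
    holds by construction.  A control trace at concentration 0 is included.
    """
    if kic50_true <= 0:
        raise ValueError("kic50_true must be positive")
    traces: list[KineticTrace] = []
    t_max_needed = control_t_half * (1.0 + 0.5 * (max(concentrations) / kic50_true) ** hill_slope)
    t_max = max(3.0 * control_t_half, 2.0 * t_max_needed)
    sub = np.random.default_rng(seed)
    for ci, c in enumerate((0.0, *concentrations)):
        th = control_t_half * (1.0 + 0.5 * (c / kic50_true) ** hill_slope)
        for rep in range(1, replicates + 1):
            traces.append(
                gen_kinetic_trace(
                    TraceSpec(
                        t_half=th,
                        steepness=steepness,
                        t_max=t_max,
                        n_points=201,
                        noise_sd=noise_sd,
                        seed=int(sub.integers(2**31 - 1)),
                        condition="control" if c == 0 else "compound",
                        concentration_um=c,
                        replicate=rep,
                    )
                )
            )
    return traces
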