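"""QSAR featurization, training, prediction and cross-validated benchmarking.

Four model families serve as reward oracles and post-screen filters: linear
regression, decision tree, random forest and a feed-forward network.  The
benchmark harness reports the mean train/test MSE of every family on every
endpoint (predicted binding energy, CNS MPO, normalized aggregation
half-time) across shuffled k-fold cross-validation, mirroring the standard
4-family x 3-endpoint comparison matrix.

Featurizers satisfy a single contract (list of molecules -> fixed-width
matrix): folded Morgan fingerprints (default), a plain physicochemical
descriptor block, and a dense substructure-embedding featurizer trained on a
molecule library by factorizing the substructure co-occurrence matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.linear_model import LinearRegression
from sklearn.tree import DecisionTreeRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .chem import MoleculeState, canonicalize, fingerprint
from .nnet import NumpyMLP

ENDPOINTS = ("binding_energy", "cns_mpo", "normalized_half_time")
FAMILIES = ("linear", "tree", "forest", "feedforward")


def _as_states(states: Sequence[MoleculeState | str]) -> list[MoleculeState]:
    out = []
    for i, s in enumerate(states):
        try:
            out.append(s if isinstance(s, MoleculeState) else MoleculeState(s))
        except ValueError as exc:
            raise ValueError(f"invalid molecule at index {i}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Featurizers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorganFeaturizer:
    """Folded circular fingerprint featurizer (ECFP4 default)."""

    radius: int = 2
    n_bits: int = 2048

    @property
    def width(self) -> int:
        return self.n_bits

    def transform(self, states: Sequence[MoleculeState | str]) -> np.ndarray:
        sts = _as_states(states)
        X = np.zeros((len(sts), self.n_bits), dtype=float)
        for i, st in enumerate(sts):
            X[i] = fingerprint(st, self.radius, self.n_bits).bits
        return X

    def spec(self) -> dict:
        return {"kind": "morgan", "radius": self.radius, "n_bits": self.n_bits}


@dataclass(frozen=True)
class DescriptorFeaturizer:
    """Physicochemical descriptor block: MW, TPSA, HBD, HBA, clogp, heavy atoms, rings, rotatable bonds."""

    NAMES = ("mw", "tpsa", "hbd", "hba", "clogp", "heavy_atoms", "rings", "rot_bonds")

    @property
    def width(self) -> int:
        return len(self.NAMES)

    def transform(self, states: Sequence[MoleculeState | str]) -> np.ndarray:
        from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

        sts = _as_states(states)
        rows = []
        for st in sts:
            mol = st.mol
            rows.append(
                [
                    Descriptors.MolWt(mol),
                    rdMolDescriptors.CalcTPSA(mol),
                    rdMolDescriptors.CalcNumHBD(mol),
                    rdMolDescriptors.CalcNumHBA(mol),
                    Crippen.MolLogP(mol),
                    mol.GetNumHeavyAtoms(),
                    rdMolDescriptors.CalcNumRings(mol),
                    rdMolDescriptors.CalcNumRotatableBonds(mol),
                ]
            )
        return np.asarray(rows, dtype=float)

    def spec(self) -> dict:
        return {"kind": "descriptor"}


class EmbeddingFeaturizer:
    """Dense substructure embeddings from co-occurrence factorization.

    Radius-0..2 circular substructure identifiers are collected over a
    training library; the (substructure x substructure) within-molecule
    co-occurrence matrix is factorized by truncated SVD, giving each
    substructure a dense vector.  A molecule is featurized as the
    count-weighted mean of its substructure vectors.  This plays the role of
    a pretrained structural embedding while depending only on the library it
    is fitted to.
    """

    def __init__(self, dim: int = 32, radius: int = 2):
        self.dim = int(dim)
        self.radius = int(radius)
        self._vocab: dict[int, int] | None = None
        self._vectors: np.ndarray | None = None

    @property
    def width(self) -> int:
        return self.dim

    def _substructures(self, st: MoleculeState) -> dict[int, int]:
        from rdkit.Chem import rdMolDescriptors as rd

        fp = rd.GetMorganFingerprint(st.mol, self.radius)
        return dict(fp.GetNonzeroElements())

    def fit(self, library: Sequence[MoleculeState | str]) -> "EmbeddingFeaturizer":
        sts = _as_states(library)
        per_mol = [self._substructures(st) for st in sts]
        vocab = sorted({k for d in per_mol for k in d})
        index = {k: i for i, k in enumerate(vocab)}
        n = len(vocab)
        cooc = np.zeros((n, n))
        for d in per_mol:
            keys = [index[k] for k in d]
            for a in keys:
                for b in keys:
                    cooc[a, b] += 1.0
        # log-damped counts stabilize the spectrum
        cooc = np.log1p(cooc)
        dim = min(self.dim, n)
        U, S, _ = np.linalg.svd(cooc, full_matrices=False)
        vectors = U[:, :dim] * S[:dim]
        if dim < self.dim:  # pad so the contract width is honored
            vectors = np.pad(vectors, ((0, 0), (0, self.dim - dim)))
        self._vocab = index
        self._vectors = vectors
        return self

    def transform(self, states: Sequence[MoleculeState | str]) -> np.ndarray:
        if self._vectors is None:
            raise RuntimeError("EmbeddingFeaturizer must be fitted before use")
        sts = _as_states(states)
        X = np.zeros((len(sts), self.dim))
        for i, st in enumerate(sts):
            subs = self._substructures(st)
            total = 0
            for k, cnt in subs.items():
                j = self._vocab.get(k)
                if j is not None:
                    X[i] += cnt * self._vectors[j]
                    total += cnt
            if total:
                X[i] /= total
        return X

    def spec(self) -> dict:
        return {"kind": "embedding", "dim": self.dim, "radius": self.radius}


def featurize_set(states: Sequence[MoleculeState | str], featurizer=None) -> np.ndarray:
    """Deterministic fixed-width features for a list of molecules."""
    featurizer = featurizer or MorganFeaturizer()
    return featurizer.transform(states)


# ---------------------------------------------------------------------------
# Datasets and model specs
# ---------------------------------------------------------------------------

@dataclass
class QsarDataset:
    """Molecules with a single regression endpoint."""

    ids: list[str]
    smiles: list[str]
    y: np.ndarray
    endpoint: str

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.ids) == len(self.smiles) == self.y.size):
            raise ValueError("ids, smiles and targets must have equal length")
        if np.any(np.isnan(self.y)):
            raise ValueError("missing targets are not allowed")
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r} (expected one of {ENDPOINTS})")
        self.smiles = [canonicalize(s) for s in self.smiles]

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_csv(cls, path) -> "QsarDataset":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            ids=[str(v) for v in df["identifier"]],
            smiles=[str(v) for v in df["smiles"]],
            y=df["target"].to_numpy(dtype=float),
            endpoint=str(df["endpoint"].iloc[0]),
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "identifier": self.ids,
                "smiles": self.smiles,
                "endpoint": self.endpoint,
                "target": self.y,
            }
        ).to_csv(path, index=False)


# Per-endpoint feed-forward defaults: (hidden layers, activation, output, lr).
# The 32-unit tail layer is part of the hidden stack; epochs default to 1000.
FEEDFORWARD_DEFAULTS = {
    "binding_energy": {"hidden_layers": (256, 256, 32), "activation": "relu",
                       "output": "sigmoid_scaled", "learning_rate": 1e-3},
    "cns_mpo": {"hidden_layers": (256, 256, 32), "activation": "relu6",
                "output": "linear", "learning_rate": 1e-3},
    "normalized_half_time": {"hidden_layers": (128, 128, 128, 32), "activation": "relu",
                             "output": "sigmoid_scaled", "learning_rate": 5e-4},
}


@dataclass(frozen=True)
class ModelSpec:
    """Model family plus (for the feed-forward family) its hyperparameters."""

    family: str = "forest"
    hidden_layers: tuple[int, ...] = (256, 256, 32)
    activation: str = "relu"
    output: str = "sigmoid_scaled"
    learning_rate: float = 1e-3
    epochs: int = 1000
    n_estimators: int = 100   # forest only

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r} (expected one of {FAMILIES})")

    @classmethod
    def feedforward_for(cls, endpoint: str, epochs: int = 1000) -> "ModelSpec":
        d = FEEDFORWARD_DEFAULTS[endpoint]
        return cls(family="feedforward", epochs=epochs, **d)


@dataclass
class TrainedQsarModel:
    """A fitted model bound to its featurizer, endpoint and target transform."""

    model: object
    featurizer: object
    endpoint: str
    spec: ModelSpec
    seed: int
    log_target: bool = False

    def predict(self, states: Sequence[MoleculeState | str]) -> np.ndarray:
        X = self.featurizer.transform(states)
        if self.spec.family == "feedforward":
            pred = self.model.predict(X)
        else:
            pred = self.model.predict(X)
        if self.log_target:
            pred = np.exp(pred)
        return np.asarray(pred, dtype=float)

    def save(self, path) -> None:
        """Serialize model + sidecar metadata (featurizer spec, seed, endpoint)."""
        import joblib

        path = str(path)
        joblib.dump({"model": self.model, "featurizer": self.featurizer}, path)
        meta = {
            "endpoint": self.endpoint,
            "seed": self.seed,
            "log_target": self.log_target,
            "spec": asdict(self.spec),
            "featurizer": self.featurizer.spec(),
        }
        with open(path + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, path) -> "TrainedQsarModel":
        import joblib

        path = str(path)
        blob = joblib.load(path)
        with open(path + ".meta.json") as fh:
            meta = json.load(fh)
        spec_d = meta["spec"]
        spec_d["hidden_layers"] = tuple(spec_d["hidden_layers"])
        return cls(
            model=blob["model"],
            featurizer=blob["featurizer"],
            endpoint=meta["endpoint"],
            spec=ModelSpec(**spec_d),
            seed=meta["seed"],
            log_target=meta["log_target"],
        )


def train(
    spec: ModelSpec,
    data: QsarDataset,
    seed: int = 0,
    featurizer=None,
    log_target: bool | None = None,
) -> TrainedQsarModel:
    """Fit one model family on a dataset.

    The aggregation endpoint (normalized half-time) is log-transformed before
    fitting and back-transformed on prediction: half-time ratios are positive
    and right-skewed.  Fixed seed implies reproducible weights/predictions.
    """
    if len(data) == 0:
        raise ValueError("cannot train on an empty dataset")
    featurizer = featurizer or MorganFeaturizer()
    if log_target is None:
        log_target = data.endpoint == "normalized_half_time"
    X = featurizer.transform(data.smiles)
    y = np.log(data.y) if log_target else data.y

    if spec.family == "linear":
        model = LinearRegression().fit(X, y)
    elif spec.family == "tree":
        model = DecisionTreeRegressor(random_state=seed).fit(X, y)
    elif spec.family == "forest":
        model = RandomForestRegressor(n_estimators=spec.n_estimators, random_state=seed).fit(X, y)
    else:
        lo, hi = float(y.min()), float(y.max())
        margin = 0.1 * max(hi - lo, 1e-6)
        net = NumpyMLP(
            n_inputs=X.shape[1],
            hidden_layers=spec.hidden_layers,
            activation=spec.activation,
            output=spec.output,
            output_range=(lo - margin, hi + margin),
            learning_rate=spec.learning_rate,
            seed=seed,
        )
        # standardize inputs inside a closure-free wrapper for stability
        mu, sd = X.mean(axis=0), X.std(axis=0) + 1e-9
        net_wrapped = _StandardizedNet(net, mu, sd)
        net.fit((X - mu) / sd, y, epochs=spec.epochs)
        model = net_wrapped
    return TrainedQsarModel(
        model=model, featurizer=featurizer, endpoint=data.endpoint,
        spec=spec, seed=seed, log_target=log_target,
    )


class _StandardizedNet:
    """Input-standardizing wrapper so the MLP sees zero-mean unit-variance features."""

    def __init__(self, net: NumpyMLP, mu: np.ndarray, sd: np.ndarray):
        self.net = net
        self.mu = mu
        self.sd = sd

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict((np.asarray(X, float) - self.mu) / self.sd)


def predict(model: TrainedQsarModel, states: Sequence[MoleculeState | str]) -> np.ndarray:
    """One value per molecule, endpoint units preserved, input order kept."""
    return model.predict(states)


# ---------------------------------------------------------------------------
# Cross-validated benchmarking
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    """Mean train/test MSE per (family, endpoint) over k shuffled folds."""

    table: dict[tuple[str, str], dict[str, float]]
    k: int
    seed: int

    def __post_init__(self) -> None:
        for v in self.table.values():
            if v["train_mse"] < 0 or v["test_mse"] < 0:
                raise ValueError("MSE must be non-negative")

    def to_frame(self):
        """Wide matrix: one row per family, train/test columns per endpoint."""
        import pandas as pd

        endpoints = sorted({e for (_, e) in self.table})
        rows = {}
        for fam in FAMILIES:
            row = {}
            for ep in endpoints:
                if (fam, ep) in self.table:
                    row[f"{ep}_train"] = self.table[(fam, ep)]["train_mse"]
                    row[f"{ep}_test"] = self.table[(fam, ep)]["test_mse"]
            if row:
                rows[fam] = row
        return pd.DataFrame.from_dict(rows, orient="index")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="model")


def crossval_benchmark(
    specs: Sequence[ModelSpec],
    datasets: Sequence[QsarDataset],
    k: int = 5,
    seed: int = 0,
    featurizer=None,
) -> BenchmarkResult:
    """k-fold cross-validated train/test MSE for every (family, endpoint) pair.

    Folds are shuffled with the given seed and identical across families, so
    the matrix compares models on the same splits.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    table: dict[tuple[str, str], dict[str, float]] = {}
    for data in datasets:
        if len(data) < k:
            raise ValueError(f"dataset {data.endpoint!r} smaller than k={k}")
        idx = np.arange(len(data))
        splits = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(idx))
        for spec in specs:
            tr_mses, te_mses = [], []
            for fold_i, (tr, te) in enumerate(splits):
                sub = QsarDataset(
                    ids=[data.ids[i] for i in tr],
                    smiles=[data.smiles[i] for i in tr],
                    y=data.y[tr],
                    endpoint=data.endpoint,
                )
                model = train(spec, sub, seed=seed + fold_i, featurizer=featurizer)
                pred_tr = model.predict([data.smiles[i] for i in tr])
                pred_te = model.predict([data.smiles[i] for i in te])
                tr_mses.append(float(np.mean((pred_tr - data.y[tr]) ** 2)))
                te_mses.append(float(np.mean((pred_te - data.y[te]) ** 2)))
            table[(spec.family, data.endpoint)] = {
                "train_mse": float(np.mean(tr_mses)),
                "test_mse": float(np.mean(te_mses)),
            }
    return BenchmarkResult(table=table, k=k, seed=seed)
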