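"""End-to-end orchestration: fixtures -> QSAR -> generate -> screen -> kinetics.

A run is described by a validated :class:`RunConfig` (YAML/JSON on disk).
Stages execute in order, each persisting its artifacts under the output
directory; a rerun skips any stage whose outputs already exist, so a run is
resumable from the last completed stage.  The manifest written at the end
snapshots the config, software version, per-stage output checksums, seeds
and timings — enough to re-execute deterministic stages bit-identically.

The single global seed derives per-stage seeds by fixed offsets (fixtures
+1, QSAR +2, generator +3, kinetics +4), so stages are reproducible
independently of one another.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .chem import ActionSpace, MoleculeState, read_smiles_file, write_smiles_file
from .generator import QLearningConfig, RewardFunction, surrogate_binding_provider, train_generator
from .kinetics import analyze_dose_series, read_traces_csv, write_traces_csv
from .mpo import DesirabilityConfig, RewardWeights
from .qsar import ModelSpec, QsarDataset, TrainedQsarModel, crossval_benchmark, train
from .screen import potency_filter, similarity_search
from .synthetic import SurrogateSpec, gen_dose_series, gen_molecule_library, gen_property_labels

logger = logging.getLogger("nullelab")

STAGE_SEED_OFFSETS = {"fixtures": 1, "qsar": 2, "generate": 3, "kinetics": 4}


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""


_DEFAULTS = {
    "outdir": "runs/demo",
    "seed": 0,
    "start_smiles": "CCOC(=O)c1ccccc1N",   # inert-parent-style small ester aniline
    "library_path": None,                   # None -> fixtures stage generates one
    "aggregation_csv": None,                # None -> fixtures stage generates labels
    "kinetics_csv": None,                   # None -> fixtures stage generates traces
    "desirability_yaml": None,              # None -> shipped defaults
    "weights": {"w_potency": 1.0, "w_mpo": 1.0, "w_sa": 0.5, "w_binding": 0.5},
    "qlearning": {
        "episodes": 300,
        "max_steps": 4,
        "gamma": 0.9,
        "fingerprint_bits": 512,
        "hidden_layers": [64, 32],
        "batch_size": 64,
        "learn_start": 100,
        "target_sync_period": 10,
        "top_n": 50,
    },
    "action_space": {
        "allowed_elements": ["C", "N", "O", "F", "S"],
        "allow_bond_removal": True,
        "allow_no_modification": True,
        "allow_ring_formation": True,
    },
    "screen": {"threshold": 0.40, "potency_cutoff": 1.5},
    "fixtures": {
        "n_library": 60,
        "walk_length": 6,
        "kic50_true_uM": 25.0,
        "hill_slope": 1.5,
        "trace_noise_sd": 0.03,
        "motif_smarts": "[#16]",
    },
    "qsar_model": {"family": "forest", "epochs": 300},
    "benchmark": {"enabled": True, "k": 3, "n_molecules": 60},
}


@dataclass
class RunConfig:
    """Validated, fully-defaulted run configuration."""

    raw: dict

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def outdir(self) -> Path:
        return Path(self.raw["outdir"])

    def stage_seed(self, stage: str) -> int:
        return int(self.raw["seed"]) + STAGE_SEED_OFFSETS[stage]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=True)


def _merge_defaults(raw: dict, defaults: dict, prefix: str, filled: list, errors: list) -> dict:
    out = {}
    for key, default in defaults.items():
        if key not in raw:
            out[key] = default
            filled.append(f"{prefix}{key} = {default!r}")
        elif isinstance(default, dict) and isinstance(raw[key], dict):
            out[key] = _merge_defaults(raw[key], default, f"{prefix}{key}.", filled, errors)
        else:
            out[key] = raw[key]
    for key in raw:
        if key not in defaults:
            errors.append(f"unknown key: {prefix}{key}")
    return out


def validate_config(raw: dict | str | Path) -> RunConfig:
    """Normalize a raw YAML/JSON config: fill defaults, check keys and ranges.

    Every filled default is logged; all problems are aggregated into a single
    :class:`ConfigError`.  Idempotent: a normalized config re-validates to
    itself.
    """
    if not isinstance(raw, dict):
        with open(raw) as fh:
            raw = yaml.safe_load(fh) or {}
    filled: list[str] = []
    errors: list[str] = []
    cfg = _merge_defaults(raw, _DEFAULTS, "", filled, errors)

    for wname, wval in cfg["weights"].items():
        if wval < 0:
            errors.append(f"weights.{wname} must be non-negative, got {wval}")
    if not any(v > 0 for v in cfg["weights"].values()):
        errors.append("at least one reward weight must be positive")
    if not 0.0 <= cfg["screen"]["threshold"] <= 1.0:
        errors.append("screen.threshold must lie in [0, 1]")
    if cfg["qlearning"]["episodes"] < 0:
        errors.append("qlearning.episodes must be non-negative")
    if cfg["fixtures"]["kic50_true_uM"] <= 0:
        errors.append("fixtures.kic50_true_uM must be positive")
    for key in ("library_path", "aggregation_csv", "kinetics_csv", "desirability_yaml"):
        path = cfg[key]
        if path is not None and not Path(path).exists():
            errors.append(f"{key}: path does not exist: {path}")
    try:
        MoleculeState(cfg["start_smiles"])
    except ValueError as exc:
        errors.append(f"start_smiles: {exc}")

    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    for line in filled:
        logger.info("config default filled: %s", line)
    return RunConfig(raw=cfg)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _action_space(cfg: RunConfig, max_steps: int) -> ActionSpace:
    a = cfg["action_space"]
    return ActionSpace(
        allowed_elements=frozenset(a["allowed_elements"]),
        max_steps=max_steps,
        allow_bond_removal=a["allow_bond_removal"],
        allow_no_modification=a["allow_no_modification"],
        allow_ring_formation=a["allow_ring_formation"],
    )


def stage_fixtures(cfg: RunConfig) -> dict[str, Path]:
    """Generate the demo workspace: library, QSAR labels, kinetic traces."""
    out = cfg.outdir / "fixtures"
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.stage_seed("fixtures")
    fx = cfg["fixtures"]
    outputs = {
        "library": out / "library.smi",
        "aggregation": out / "aggregation.csv",
        "traces": out / "traces.csv",
    }
    if all(p.exists() for p in outputs.values()):
        logger.info("fixtures: outputs exist, skipping")
        return outputs

    space = _action_space(cfg, max_steps=1_000_000)
    # half the purchasable library are near relatives of the start compound so
    # the similarity screen has a populated neighborhood, half are unrelated
    n_lib = fx["n_library"]
    relatives = gen_molecule_library(
        seed, n_lib // 2, space=space, walk_length=max(2, fx["walk_length"] // 2),
        starts=(cfg["start_smiles"],),
    )
    unrelated = gen_molecule_library(seed + 1, n_lib - n_lib // 2, space=space,
                                     walk_length=fx["walk_length"])
    library = relatives + unrelated
    write_smiles_file(outputs["library"], [(st.structure, f"lib{i}") for i, st in enumerate(library)])

    spec = SurrogateSpec(name="motif_potency", motif_smarts=fx["motif_smarts"],
                         noise_sd=0.05, seed=seed)
    gen_property_labels(library, spec).to_csv(outputs["aggregation"])

    traces = gen_dose_series(
        kic50_true=fx["kic50_true_uM"], hill_slope=fx["hill_slope"],
        noise_sd=fx["trace_noise_sd"], seed=seed,
    )
    write_traces_csv(outputs["traces"], traces)
    logger.info("fixtures: wrote %d molecules, %d traces", len(library), len(traces))
    return outputs


def stage_qsar(cfg: RunConfig, fixture_paths: dict[str, Path]) -> dict[str, Path]:
    """Train the potency model (and optionally the family-by-endpoint benchmark)."""
    out = cfg.outdir / "qsar"
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.stage_seed("qsar")
    outputs = {"model": out / "potency_model.joblib", "benchmark": out / "benchmark.csv"}
    agg_path = cfg["aggregation_csv"] or fixture_paths["aggregation"]
    data = QsarDataset.from_csv(agg_path)

    if not outputs["model"].exists():
        qm = cfg["qsar_model"]
        if qm["family"] == "feedforward":
            spec = ModelSpec.feedforward_for(data.endpoint, epochs=qm["epochs"])
        else:
            spec = ModelSpec(family=qm["family"])
        model = train(spec, data, seed=seed)
        model.save(outputs["model"])
        logger.info("qsar: trained %s potency model on %d molecules", spec.family, len(data))
    else:
        logger.info("qsar: model exists, skipping training")

    if cfg["benchmark"]["enabled"] and not outputs["benchmark"].exists():
        bench = run_benchmark(seed=seed, k=cfg["benchmark"]["k"],
                              n_molecules=cfg["benchmark"]["n_molecules"])
        bench.to_csv(outputs["benchmark"])
        logger.info("qsar: benchmark matrix written")
    return outputs


def run_benchmark(seed: int, k: int = 5, n_molecules: int = 150, ffnn_epochs: int = 200):
    """The 4-family x 3-endpoint cross-validated MSE matrix on fixture data."""
    from .mpo import cns_mpo, compute_properties

    library = gen_molecule_library(seed, n_molecules, walk_length=6)
    smiles = [st.structure for st in library]
    ids = [f"mol{i}" for i in range(len(library))]

    binding = QsarDataset(
        ids=ids, smiles=smiles,
        y=np.array([surrogate_binding_provider(s) for s in smiles]),
        endpoint="binding_energy",
    )
    mpo = QsarDataset(
        ids=ids, smiles=smiles,
        y=np.array([cns_mpo(compute_properties(s)) for s in smiles]),
        endpoint="cns_mpo",
    )
    agg = gen_property_labels(
        library, SurrogateSpec(name="motif_potency", noise_sd=0.05, seed=seed)
    )
    specs = [
        ModelSpec(family="linear"),
        ModelSpec(family="tree"),
        ModelSpec(family="forest"),
    ]
    datasets = [binding, mpo, agg]
    result = crossval_benchmark(specs, datasets, k=k, seed=seed)
    # the feed-forward family honors its per-endpoint hyperparameter defaults
    for data in datasets:
        ff = ModelSpec.feedforward_for(data.endpoint, epochs=ffnn_epochs)
        ff_result = crossval_benchmark([ff], [data], k=k, seed=seed)
        result.table.update(ff_result.table)
    return result


def stage_generate(cfg: RunConfig, qsar_paths: dict[str, Path]) -> dict[str, Path]:
    out = cfg.outdir / "generate"
    out.mkdir(parents=True, exist_ok=True)
    outputs = {"generated": out / "generated.csv", "curve": out / "training_curve.csv"}
    if all(p.exists() for p in outputs.values()):
        logger.info("generate: outputs exist, skipping")
        return outputs

    ql = cfg["qlearning"]
    config = QLearningConfig(
        episodes=ql["episodes"], max_steps=ql["max_steps"], gamma=ql["gamma"],
        fingerprint_bits=ql["fingerprint_bits"],
        hidden_layers=tuple(ql["hidden_layers"]), batch_size=ql["batch_size"],
        learn_start=ql["learn_start"], target_sync_period=ql["target_sync_period"],
        top_n=ql["top_n"], seed=cfg.stage_seed("generate"),
    )
    weights = RewardWeights(**cfg["weights"])
    mpo_config = (
        DesirabilityConfig.from_yaml(cfg["desirability_yaml"])
        if cfg["desirability_yaml"] else DesirabilityConfig.default()
    )
    potency_model = TrainedQsarModel.load(qsar_paths["model"])
    reward = RewardFunction(
        weights=weights, mpo_config=mpo_config,
        potency_model=potency_model, binding_provider=surrogate_binding_provider,
    )
    space = _action_space(cfg, max_steps=ql["max_steps"])
    gs = train_generator(config, reward, space, MoleculeState(cfg["start_smiles"]))
    gs.to_frame().to_csv(outputs["generated"], index=False)
    import pandas as pd

    pd.DataFrame(
        {"episode": range(len(gs.best_so_far)), "best_reward": gs.best_so_far}
    ).to_csv(outputs["curve"], index=False)
    logger.info("generate: %d distinct molecules, best reward %.3f",
                len(gs.molecules), gs.molecules[0][1].composite_reward)
    return outputs


def stage_screen(cfg: RunConfig, gen_paths: dict[str, Path],
                 qsar_paths: dict[str, Path], fixture_paths: dict[str, Path]) -> dict[str, Path]:
    out = cfg.outdir / "screen"
    out.mkdir(parents=True, exist_ok=True)
    outputs = {"report": out / "screen_report.csv"}
    if outputs["report"].exists():
        logger.info("screen: outputs exist, skipping")
        return outputs

    import pandas as pd

    gen_df = pd.read_csv(gen_paths["generated"])
    queries = [(row.smiles, f"gen{row.rank}") for row in gen_df.itertuples()][:20]
    lib_path = cfg["library_path"] or fixture_paths["library"]
    library = read_smiles_file(lib_path)
    hits = similarity_search(queries, library, threshold=cfg["screen"]["threshold"])
    model = TrainedQsarModel.load(qsar_paths["model"])
    result = potency_filter(hits, model, cutoff=cfg["screen"]["potency_cutoff"])
    result.to_frame().to_csv(outputs["report"], index=False)
    logger.info("screen: %d hits, %d retained", len(result.hits), len(result.retained))
    return outputs


def stage_kinetics(cfg: RunConfig, fixture_paths: dict[str, Path]) -> dict[str, Path]:
    out = cfg.outdir / "kinetics"
    out.mkdir(parents=True, exist_ok=True)
    outputs = {"summary": out / "kinetics_summary.json"}
    if outputs["summary"].exists():
        logger.info("kinetics: outputs exist, skipping")
        return outputs
    traces = read_traces_csv(cfg["kinetics_csv"] or fixture_paths["traces"])
    summary = analyze_dose_series(traces)
    outputs["summary"].write_text(json.dumps(summary, indent=2))
    logger.info("kinetics: KIC50 = %s uM (extrapolated=%s)",
                summary["kic50_uM"], summary["kic50_extrapolated"])
    return outputs


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict[str, dict]
    total_seconds: float

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute all stages in order; resumable; manifest written last.

    A stage failure is recorded in the manifest (with the failing stage's
    error) before the exception propagates.
    """
    t0 = time.time()
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    (cfg.outdir / "config.yaml").write_text(cfg.to_yaml())
    stages: dict[str, dict] = {}

    def run_stage(name, fn, *args):
        t = time.time()
        try:
            outputs = fn(cfg, *args)
        except Exception as exc:
            stages[name] = {"status": "failed", "error": repr(exc),
                            "seconds": round(time.time() - t, 3)}
            manifest = RunManifest(config=cfg.raw, version=__version__,
                                   stages=stages, total_seconds=time.time() - t0)
            manifest.write(cfg.outdir / "manifest.json")
            raise
        stages[name] = {
            "status": "ok",
            "seconds": round(time.time() - t, 3),
            "outputs": {k: str(p) for k, p in outputs.items()},
            "checksums": {k: _sha256(p) for k, p in outputs.items() if p.exists()},
        }
        return outputs

    fixture_paths = run_stage("fixtures", stage_fixtures)
    qsar_paths = run_stage("qsar", stage_qsar, fixture_paths)
    gen_paths = run_stage("generate", stage_generate, qsar_paths)
    run_stage("screen", stage_screen, gen_paths, qsar_paths, fixture_paths)
    run_stage("kinetics", stage_kinetics, fixture_paths)

    manifest = RunManifest(config=cfg.raw, version=__version__,
                           stages=stages, total_seconds=round(time.time() - t0, 3))
    manifest.write(cfg.outdir / "manifest.json")
    logger.info("pipeline complete in %.1f s", manifest.total_seconds)
    return manifest
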