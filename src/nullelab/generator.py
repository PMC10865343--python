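"""Deep Q-learning elaboration of a starting molecule under the composite reward.

Each molecule is a state; each legal single edit is an action, identified
with the state it produces.  A value network scores candidate next-states
(featurization of the resulting molecule concatenated with normalized
steps-remaining); action selection is epsilon-greedy with deterministic
tie-breaking; learning is temporal-difference regression on replayed
transitions against a periodically synced target network, with the double-Q
target (online argmax, target evaluation) to tame overestimation.  Per-step
reward is the composite reward of the new state discounted by
gamma^(steps_remaining), so terminal-adjacent improvements dominate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .chem import ActionSpace, MoleculeState, enumerate_actions
from .mpo import RewardWeights, ScoreBundle, composite_reward
from .nnet import NumpyMLP
from .qsar import MorganFeaturizer


@dataclass(frozen=True)
class QLearningConfig:
    episodes: int = 2000
    max_steps: int = 10
    gamma: float = 0.9
    epsilon_start: float = 1.0
    epsilon_end: float = 0.01
    epsilon_decay_fraction: float = 0.5   # linear decay over this fraction of episodes
    replay_capacity: int = 5000
    batch_size: int = 128
    target_sync_period: int = 20          # episodes between target-network syncs
    learning_rate: float = 1e-3
    hidden_layers: tuple[int, ...] = (64, 32)
    fingerprint_bits: int = 2048
    fingerprint_radius: int = 2
    learn_start: int = 200                # transitions before updates begin
    top_n: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must lie in (0, 1]")
        for name in ("episodes",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("max_steps", "replay_capacity", "batch_size", "target_sync_period"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for eps in (self.epsilon_start, self.epsilon_end):
            if not 0 <= eps <= 1:
                raise ValueError("epsilon must lie in [0, 1]")

    def epsilon_at(self, episode: int) -> float:
        horizon = max(1, int(self.episodes * self.epsilon_decay_fraction))
        frac = min(episode / horizon, 1.0)
        return self.epsilon_start + frac * (self.epsilon_end - self.epsilon_start)


@dataclass(frozen=True)
class EpisodeRecord:
    """One rollout: ordered (state, chosen action, reward) triples."""

    steps: tuple[tuple[MoleculeState, MoleculeState, float], ...]
    terminal_state: MoleculeState
    terminal_reward: float

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class GeneratedSet:
    """Deduplicated best molecules with score bundles plus the training curve."""

    molecules: list[tuple[MoleculeState, ScoreBundle]]
    best_so_far: list[float]            # episode index -> best reward seen so far
    config: QLearningConfig
    episodes_aborted: int = 0
    value_net: "ValueNetwork | None" = None

    def top(self, n: int) -> list[tuple[MoleculeState, ScoreBundle]]:
        return self.molecules[:n]

    def to_frame(self):
        import pandas as pd

        rows = []
        for rank, (st, b) in enumerate(self.molecules, start=1):
            rows.append(
                {
                    "rank": rank,
                    "smiles": st.structure,
                    "cns_mpo": b.cns_mpo,
                    "sa_score": b.sa_score,
                    "potency_pred": b.potency_pred,
                    "binding_pred": b.binding_pred,
                    "composite_reward": b.composite_reward,
                }
            )
        return pd.DataFrame(rows)


class ValueNetwork:
    """MLP over (molecule fingerprint, normalized steps-remaining)."""

    def __init__(self, config: QLearningConfig, seed: int | None = None):
        self.featurizer = MorganFeaturizer(config.fingerprint_radius, config.fingerprint_bits)
        self.max_steps = config.max_steps
        self.net = NumpyMLP(
            n_inputs=config.fingerprint_bits + 1,
            hidden_layers=config.hidden_layers,
            activation="relu",
            output="linear",
            learning_rate=config.learning_rate,
            seed=config.seed if seed is None else seed,
        )

    def features(self, states: Sequence[MoleculeState], steps_remaining: int) -> np.ndarray:
        X = self.featurizer.transform(states)
        frac = np.full((X.shape[0], 1), steps_remaining / max(self.max_steps, 1))
        return np.hstack([X, frac])

    def values(self, states: Sequence[MoleculeState], steps_remaining: int) -> np.ndarray:
        return self.net.predict(self.features(states, steps_remaining))

    def clone_target(self) -> "NumpyMLP":
        return self.net.clone()


def action_values(
    value_net: ValueNetwork, candidates: Sequence[MoleculeState], steps_remaining: int
) -> np.ndarray:
    """One scalar value per candidate next-state."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("action_values requires a non-empty candidate set")
    return value_net.values(candidates, steps_remaining)


def select_action(
    candidates: Sequence[MoleculeState],
    values: np.ndarray,
    epsilon: float,
    rng: np.random.Generator,
) -> MoleculeState:
    """Epsilon-greedy selection with deterministic lowest-canonical-order tie-break."""
    candidates = list(candidates)
    values = np.asarray(values, dtype=float)
    if len(candidates) != values.size:
        raise ValueError("values must align with candidates")
    if rng.random() < epsilon:
        return candidates[int(rng.integers(len(candidates)))]
    best = np.flatnonzero(values == values.max())
    if best.size == 1:
        return candidates[int(best[0])]
    tied = sorted((candidates[int(i)] for i in best), key=lambda s: s.structure)
    return tied[0]


def _sorted_candidates(state: MoleculeState, space: ActionSpace) -> list[MoleculeState]:
    return sorted(enumerate_actions(state, space), key=lambda s: s.structure)


class _Replay:
    def __init__(self, capacity: int):
        self.capacity = capacity
        self.buffer: list[tuple] = []
        self.pos = 0

    def push(self, item: tuple) -> None:
        if len(self.buffer) < self.capacity:
            self.buffer.append(item)
        else:
            self.buffer[self.pos] = item
            self.pos = (self.pos + 1) % self.capacity

    def sample(self, batch_size: int, rng: np.random.Generator) -> list[tuple]:
        idx = rng.integers(len(self.buffer), size=min(batch_size, len(self.buffer)))
        return [self.buffer[int(i)] for i in idx]

    def __len__(self) -> int:
        return len(self.buffer)


def _bundle_for(reward_fn, state: MoleculeState, value: float) -> ScoreBundle:
    if hasattr(reward_fn, "bundle"):
        return reward_fn.bundle(state)
    return ScoreBundle(cns_mpo=0.0, sa_score=0.0, potency_pred=0.0,
                       binding_pred=0.0, composite_reward=value)


def train_generator(
    config: QLearningConfig,
    reward_fn: Callable[[MoleculeState], float],
    space: ActionSpace,
    start: MoleculeState,
) -> GeneratedSet:
    """Run Q-learning episodes from ``start`` and return the best molecules found.

    ``reward_fn`` maps a molecule to its composite reward (a
    :class:`RewardFunction` also supplies full score bundles).  An episode
    whose reward evaluation fails is aborted and logged; the run continues.
    Same config + seed implies an identical result.
    """
    rng = np.random.default_rng(config.seed)
    online = ValueNetwork(config)
    target = online.clone_target()
    replay = _Replay(config.replay_capacity)

    seen: dict[str, float] = {}
    best_curve: list[float] = []
    aborted = 0

    def record(state: MoleculeState, value: float) -> None:
        key = state.structure
        if key not in seen or value > seen[key]:
            seen[key] = value

    start = MoleculeState(start.structure)  # reset step counter
    start_reward = reward_fn(start)
    record(start, start_reward)
    best = start_reward

    for episode in range(config.episodes):
        epsilon = config.epsilon_at(episode)
        state = start
        try:
            for step in range(config.max_steps):
                candidates = _sorted_candidates(state, space)
                if not candidates:
                    break
                steps_remaining = config.max_steps - state.steps_taken - 1
                values = action_values(online, candidates, steps_remaining)
                nxt = select_action(candidates, values, epsilon, rng)
                raw = reward_fn(nxt)
                reward = raw * config.gamma ** steps_remaining
                record(nxt, raw)
                done = steps_remaining == 0
                next_candidates = None if done else _sorted_candidates(nxt, space)
                if next_candidates is not None and not next_candidates:
                    done, next_candidates = True, None
                replay.push(
                    (
                        online.features([nxt], steps_remaining)[0],
                        reward,
                        done,
                        None if done else online.features(next_candidates, steps_remaining - 1),
                    )
                )
                state = nxt
                if len(replay) >= min(config.learn_start, config.replay_capacity):
                    _learn_step(online, target, replay, config, rng)
        except Exception:
            aborted += 1
        best = max(best, max(seen.values()))
        best_curve.append(best)
        if (episode + 1) % config.target_sync_period == 0:
            target.set_weights(online.net.get_weights())

    ranked = sorted(seen.items(), key=lambda kv: (-kv[1], kv[0]))[: config.top_n]
    molecules = [
        (MoleculeState(smi), _with_composite(reward_fn, MoleculeState(smi), val))
        for smi, val in ranked
    ]
    return GeneratedSet(
        molecules=molecules, best_so_far=best_curve, config=config,
        episodes_aborted=aborted, value_net=online,
    )


def _with_composite(reward_fn, state: MoleculeState, value: float) -> ScoreBundle:
    bundle = _bundle_for(reward_fn, state, value)
    return replace(bundle, composite_reward=value)


def _learn_step(online: ValueNetwork, target: NumpyMLP, replay: _Replay,
                config: QLearningConfig, rng: np.random.Generator) -> None:
    batch = replay.sample(config.batch_size, rng)
    X = np.stack([b[0] for b in batch])
    y = np.empty(len(batch))
    for i, (_, reward, done, next_feats) in enumerate(batch):
        if done:
            y[i] = reward
        else:
            # double-Q: online picks the argmax, target evaluates it
            online_vals = online.net.predict(next_feats)
            a_star = int(np.argmax(online_vals))
            y[i] = reward + config.gamma * float(target.predict(next_feats[a_star : a_star + 1])[0])
    online.net.train_batch(X, y)


def evaluate_policy(
    value_net: ValueNetwork,
    start: MoleculeState,
    space: ActionSpace,
    reward_fn: Callable[[MoleculeState], float] | None = None,
    max_steps: int | None = None,
) -> EpisodeRecord:
    """Deterministic greedy (epsilon = 0) rollout of a trained value network."""
    rng = np.random.default_rng(0)  # unused at epsilon 0; determinism by construction
    state = MoleculeState(start.structure)
    steps: list[tuple[MoleculeState, MoleculeState, float]] = []
    max_steps = value_net.max_steps if max_steps is None else max_steps
    for _ in range(max_steps):
        candidates = _sorted_candidates(state, space)
        if not candidates:
            break
        steps_remaining = max_steps - state.steps_taken - 1
        values = action_values(value_net, candidates, steps_remaining)
        nxt = select_action(candidates, values, 0.0, rng)
        reward = reward_fn(nxt) if reward_fn is not None else 0.0
        steps.append((state, nxt, reward))
        state = nxt
    terminal_reward = steps[-1][2] if steps else (reward_fn(state) if reward_fn else 0.0)
    return EpisodeRecord(steps=tuple(steps), terminal_state=state, terminal_reward=terminal_reward)


# ---------------------------------------------------------------------------
# Reward function over score bundles
# ---------------------------------------------------------------------------

class RewardFunction:
    """Composite-reward closure bundling the component scorers.

    Components: CNS MPO (desirability sum), SA score, predicted potency
    (normalized half-time from a QSAR model; constant 1.0 if absent) and a
    predicted binding energy from a pluggable provider (None disables the
    component).  Scores are cached per canonical structure.
    """

    def __init__(
        self,
        weights: RewardWeights | None = None,
        mpo_config=None,
        property_provider=None,
        potency_model=None,
        binding_provider: Callable[[str], float] | None = None,
    ):
        from .mpo import BuiltinPropertyProvider, DesirabilityConfig

        self.weights = weights or RewardWeights()
        self.mpo_config = mpo_config or DesirabilityConfig.default()
        self.provider = property_provider or BuiltinPropertyProvider()
        self.potency_model = potency_model
        self.binding_provider = binding_provider
        self._cache: dict[str, ScoreBundle] = {}

    def bundle(self, state: MoleculeState) -> ScoreBundle:
        from .mpo import cns_mpo as _cns_mpo, compute_properties, sa_score as _sa

        key = state.structure
        if key in self._cache:
            return self._cache[key]
        pv = compute_properties(state, self.provider)
        mpo = _cns_mpo(pv, self.mpo_config)
        sa = _sa(state)
        potency = (
            float(self.potency_model.predict([state])[0])
            if self.potency_model is not None
            else 1.0
        )
        binding = (
            float(self.binding_provider(state.structure))
            if self.binding_provider is not None
            else 0.0
        )
        partial = ScoreBundle(cns_mpo=mpo, sa_score=sa, potency_pred=potency, binding_pred=binding)
        full = replace(partial, composite_reward=composite_reward(partial, self.weights))
        self._cache[key] = full
        return full

    def __call__(self, state: MoleculeState) -> float:
        return self.bundle(state).composite_reward


def surrogate_binding_provider(smiles: str) -> float:
    """Synthetic stand-in for a docking engine: a deterministic descriptor score.

    Returns a pseudo binding energy in kcal/mol (more negative = better)
    computed from size, rings and polarity; it has the shape of a docking
    score but no structural basis, and exists so the binding component of
    the reward is exercised without an external engine.
    """
    from rdkit.Chem import rdMolDescriptors as rd

    from .chem import mol_from_smiles

    mol = mol_from_smiles(smiles)
    heavy = mol.GetNumHeavyAtoms()
    rings = rd.CalcNumRings(mol)
    tpsa = rd.CalcTPSA(mol)
    score = -0.25 * min(heavy, 30) - 0.6 * rings + 0.02 * tpsa
    return float(max(score, -12.0))
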