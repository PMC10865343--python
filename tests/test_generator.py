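import numpy as np
import pytest
from scipy.stats import chisquare

from nullelab.chem import ActionSpace, MoleculeState, enumerate_actions
from nullelab.generator import (
    GeneratedSet,
    QLearningConfig,
    RewardFunction,
    ValueNetwork,
    action_values,
    evaluate_policy,
    select_action,
    surrogate_binding_provider,
    train_generator,
)
from nullelab.mpo import RewardWeights
from rdkit.Chem import Descriptors


MICRO_CFG = dict(max_steps=2, fingerprint_bits=256, hidden_layers=(32, 16),
                 batch_size=64, learn_start=50, target_sync_period=10)


def mw_reward(state: MoleculeState) -> float:
    return float(Descriptors.MolWt(state.mol))


def brute_force_reachable(start: str, space: ActionSpace, depth: int) -> set[str]:
    frontier = {MoleculeState(start)}
    seen = {MoleculeState(start).structure}
    for _ in range(depth):
        nxt = set()
        for s in frontier:
            for c in enumerate_actions(s, space):
                if c.structure not in seen:
                    seen.add(c.structure)
                    nxt.add(c)
        frontier = nxt
    return seen


class TestActionValues:
    def setup_method(self):
        self.cfg = QLearningConfig(episodes=1, **MICRO_CFG, seed=0)
        self.net = ValueNetwork(self.cfg)
        self.space = ActionSpace(allowed_elements=frozenset({"C", "N", "O"}), max_steps=2)
        self.candidates = sorted(
            enumerate_actions(MoleculeState("C"), self.space), key=lambda s: s.structure
        )

    def test_one_value_per_candidate(self):
        vals = action_values(self.net, self.candidates, 1)
        assert vals.shape == (len(self.candidates),)

    def test_identical_candidates_identical_values(self):
        doubled = [self.candidates[0], self.candidates[0]]
        vals = action_values(self.net, doubled, 1)
        assert vals[0] == vals[1]

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            action_values(self.net, [], 1)


class TestSelectAction:
    CANDS = [MoleculeState(s) for s in ("CC", "C=C", "C#C", "CO")]

    def test_greedy_picks_unique_maximum(self, rng):
        vals = np.array([0.1, 0.9, 0.3, 0.2])
        assert select_action(self.CANDS, vals, 0.0, rng) == self.CANDS[1]

    def test_tie_breaks_by_canonical_order(self, rng):
        vals = np.array([1.0, 1.0, 1.0, 1.0])
        chosen = select_action(self.CANDS, vals, 0.0, rng)
        assert chosen.structure == min(c.structure for c in self.CANDS)

    def test_full_exploration_is_uniform(self):
        rng = np.random.default_rng(42)
        vals = np.zeros(len(self.CANDS))
        counts = {c.structure: 0 for c in self.CANDS}
        for _ in range(10_000):
            counts[select_action(self.CANDS, vals, 1.0, rng).structure] += 1
        _, p = chisquare(list(counts.values()))
        assert p > 0.01

    def test_misaligned_values_rejected(self, rng):
        with pytest.raises(ValueError):
            select_action(self.CANDS, np.zeros(3), 0.0, rng)


class TestTrainGenerator:
    SPACE = ActionSpace(allowed_elements=frozenset({"C", "N", "O"}), max_steps=2)

    def test_zero_episodes_returns_start_only(self):
        cfg = QLearningConfig(episodes=0, **MICRO_CFG, seed=0)
        gs = train_generator(cfg, mw_reward, self.SPACE, MoleculeState("C"))
        assert len(gs.molecules) == 1
        assert gs.molecules[0][0].structure == "C"
        assert gs.molecules[0][1].composite_reward == pytest.approx(mw_reward(MoleculeState("C")))

    def test_seeded_determinism(self):
        cfg = QLearningConfig(episodes=30, **MICRO_CFG, seed=9)
        a = train_generator(cfg, mw_reward, self.SPACE, MoleculeState("C"))
        b = train_generator(cfg, mw_reward, self.SPACE, MoleculeState("C"))
        assert [(m.structure, s.composite_reward) for m, s in a.molecules] == [
            (m.structure, s.composite_reward) for m, s in b.molecules
        ]
        assert a.best_so_far == b.best_so_far

    def test_best_so_far_curve_non_decreasing(self):
        cfg = QLearningConfig(episodes=50, **MICRO_CFG, seed=2)
        gs = train_generator(cfg, mw_reward, self.SPACE, MoleculeState("C"))
        assert all(b >= a for a, b in zip(gs.best_so_far, gs.best_so_far[1:]))

    def test_greedy_rollout_attains_micro_space_optimum(self):
        opt = max(
            mw_reward(MoleculeState(s)) for s in brute_force_reachable("C", self.SPACE, 2)
        )
        cfg = QLearningConfig(episodes=600, **MICRO_CFG, seed=1)
        gs = train_generator(cfg, mw_reward, self.SPACE, MoleculeState("C"))
        rec = evaluate_policy(gs.value_net, MoleculeState("C"), self.SPACE, mw_reward)
        assert max(r for _, _, r in rec.steps) == pytest.approx(opt)

    def test_aborted_reward_failures_do_not_kill_run(self):
        calls = {"n": 0}

        def flaky(state):
            calls["n"] += 1
            if calls["n"] % 17 == 0:
                raise RuntimeError("scoring backend hiccup")
            return mw_reward(state)

        cfg = QLearningConfig(episodes=20, **MICRO_CFG, seed=3)
        gs = train_generator(cfg, flaky, self.SPACE, MoleculeState("C"))
        assert gs.episodes_aborted > 0
        assert len(gs.best_so_far) == 20


class TestEvaluatePolicy:
    SPACE = ActionSpace(allowed_elements=frozenset({"C", "N", "O"}), max_steps=2)

    def test_zero_steps_gives_empty_record(self):
        net = ValueNetwork(QLearningConfig(episodes=1, **MICRO_CFG, seed=0))
        rec = evaluate_policy(net, MoleculeState("C"), self.SPACE, mw_reward, max_steps=0)
        assert len(rec) == 0 and rec.terminal_state.structure == "C"

    def test_rollout_states_connected_by_legal_actions(self):
        cfg = QLearningConfig(episodes=50, **MICRO_CFG, seed=4)
        gs = train_generator(cfg, mw_reward, self.SPACE, MoleculeState("C"))
        rec = evaluate_policy(gs.value_net, MoleculeState("C"), self.SPACE, mw_reward)
        for state, action, _ in rec.steps:
            legal = {s.structure for s in enumerate_actions(state, self.SPACE)}
            assert action.structure in legal

    def test_trained_policy_beats_random_baseline(self):
        cfg = QLearningConfig(episodes=600, **MICRO_CFG, seed=5)
        gs = train_generator(cfg, mw_reward, self.SPACE, MoleculeState("C"))
        rec = evaluate_policy(gs.value_net, MoleculeState("C"), self.SPACE, mw_reward)
        greedy = max(r for _, _, r in rec.steps)

        rng = np.random.default_rng(0)
        finals = []
        for _ in range(100):
            state = MoleculeState("C")
            best = mw_reward(state)
            for _ in range(2):
                cands = sorted(enumerate_actions(state, self.SPACE), key=lambda s: s.structure)
                state = cands[int(rng.integers(len(cands)))]
                best = max(best, mw_reward(state))
            finals.append(best)
        assert greedy >= np.mean(finals)


class TestRewardFunction:
    def test_bundle_components_populated(self):
        fn = RewardFunction(weights=RewardWeights(),
                            binding_provider=surrogate_binding_provider)
        b = fn.bundle(MoleculeState("CCO"))
        assert 0 <= b.cns_mpo <= 6
        assert b.sa_score >= 1.0
        assert b.binding_pred <= 0.0
        assert b.composite_reward == pytest.approx(fn(MoleculeState("CCO")))

    def test_cache_is_structure_keyed(self):
        fn = RewardFunction()
        assert fn(MoleculeState("OCC")) == fn(MoleculeState("CCO"))
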