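"""Episode orchestration: baselines, DQN loops, evaluation, constrained runs."""

import numpy as np
import pytest
from rdkit import Chem

import moldqn as m
from moldqn.training import _evaluation_index

SMALL_CONFIG = m.MDPConfig(element_set=frozenset({"C", "O", "N"}),
                           max_steps=6, allowed_ring_sizes=frozenset({5, 6}))
QED_SPEC = m.RewardSpec(kind="single_property", property_names=("qed",),
                        gamma=0.9, horizon=6)


def tiny_agent(seed=0, heads=2, **overrides):
    defaults = dict(network=m.QNetworkSpec(hidden_sizes=(16, 8), num_heads=heads),
                    learning_rate=1e-3, replay_capacity=200, batch_size=8,
                    target_sync_every=10, warmup_steps=10, mask_prob=0.5)
    defaults.update(overrides)
    return m.DQNAgent(m.AgentConfig(**defaults), seed=seed)


class TestBaselines:
    def test_greedy_is_deterministic_end_to_end(self):
        r1, eps1 = m.run_baseline("greedy", SMALL_CONFIG, QED_SPEC, 2, seed=0,
                                  return_episodes=True)
        r2, eps2 = m.run_baseline("greedy", SMALL_CONFIG, QED_SPEC, 2, seed=99,
                                  return_episodes=True)
        assert r1.terminal_molecules == r2.terminal_molecules
        assert [s.action for e in eps1 for s in e.steps] == \
               [s.action for e in eps2 for s in e.steps]

    def test_greedy_improves_on_the_property_each_step_or_stays(self):
        _, [episode] = m.run_baseline("greedy", SMALL_CONFIG, QED_SPEC, 1,
                                      return_episodes=True)
        values = [m.qed(s.action.result_molecule) for s in episode.steps]
        assert values == sorted(values)  # myopic argmax never goes down

    def test_random_walk_reaches_valid_terminals(self):
        report = m.run_baseline("random", SMALL_CONFIG, QED_SPEC, 5, seed=1)
        assert report.validity_fraction == 1.0
        assert len(report.terminal_molecules) == 5
        for s in report.terminal_molecules:
            assert m.is_valid_smiles(s)

    def test_eps_greedy_zero_epsilon_equals_greedy(self):
        greedy = m.run_baseline("greedy", SMALL_CONFIG, QED_SPEC, 1, seed=0)
        eps0 = m.run_baseline("eps_greedy", SMALL_CONFIG, QED_SPEC, 1, seed=0,
                              epsilon=0.0)
        assert greedy.terminal_molecules == eps0.terminal_molecules

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            m.run_baseline("boltzmann", SMALL_CONFIG, QED_SPEC, 1)

    def test_undiscounted_return_is_plain_reward_sum(self):
        spec = m.RewardSpec(kind="single_property", property_names=("qed",),
                            gamma=1.0, horizon=6)
        _, [ep] = m.run_baseline("greedy", SMALL_CONFIG, spec, 1,
                                 return_episodes=True)
        raw_sum = sum(s.raw_reward for s in ep.steps)
        assert ep.episode_return == pytest.approx(raw_sum)


class TestRunReport:
    def test_top_unique_is_order_invariant_and_deduplicated(self):
        molecules = ("CC", "CCO", "CC", "CCC")
        scores = (0.3, 0.9, 0.3, 0.5)
        a = m.RunReport(molecules, scores, (0.0,) * 4, 1.0)
        perm = [3, 0, 2, 1]
        b = m.RunReport(tuple(molecules[i] for i in perm),
                        tuple(scores[i] for i in perm), (0.0,) * 4, 1.0)
        assert a.top_unique(3) == b.top_unique(3)
        assert a.top_unique(3) == [("CCO", 0.9), ("CCC", 0.5), ("CC", 0.3)]

    def test_report_window_covers_last_episodes(self):
        report = m.run_baseline("random", SMALL_CONFIG, QED_SPEC, 7, seed=3,
                                last_n=4)
        assert len(report.terminal_molecules) == 4


class TestTrain:
    def test_horizon_mismatch_is_a_config_error(self):
        agent = tiny_agent()
        bad_spec = m.RewardSpec(kind="single_property", property_names=("qed",),
                                horizon=9)
        with pytest.raises(ValueError):
            m.train(SMALL_CONFIG, bad_spec, agent, 1)

    def test_short_run_produces_valid_molecules_and_logs(self, tmp_path):
        agent = tiny_agent()
        csv = tmp_path / "log.csv"
        ckpt = tmp_path / "ckpt.npz"
        report = m.train(SMALL_CONFIG, QED_SPEC, agent, 4, seed=5,
                         log_csv=csv, checkpoint_path=ckpt)
        assert report.validity_fraction == 1.0
        assert csv.exists() and ckpt.exists()
        import pandas as pd
        log = pd.read_csv(csv)
        assert list(log.columns) == ["episode", "epsilon", "head",
                                     "final_molecule", "final_score",
                                     "episode_return"]
        assert len(log) == 4
        assert log["epsilon"].iloc[0] == pytest.approx(1.0)
        assert log["epsilon"].iloc[-1] == pytest.approx(0.01)

    def test_replay_rewards_carry_the_reverse_discount(self):
        agent = tiny_agent(warmup_steps=10_000)  # learn nothing, just fill
        spec = m.RewardSpec(kind="single_property", property_names=("qed",),
                            gamma=0.5, horizon=6)
        _, [ep] = m.train(SMALL_CONFIG, spec, agent, 1, seed=2,
                          return_episodes=True)
        for t, s in enumerate(ep.steps):
            assert s.discounted_reward == pytest.approx(
                s.raw_reward * 0.5 ** (6 - (t + 1)))
        assert ep.steps[-1].discounted_reward == pytest.approx(
            ep.steps[-1].raw_reward)  # terminal state undiscounted

    def test_full_exploration_matches_random_walk_statistics(self):
        """With ε pinned to 1 the learner's behaviour policy is the uniform
        random walk (the Q-network never influences action choice)."""
        agent = tiny_agent(seed=4, warmup_steps=10_000,
                           epsilon_points=((0.0, 1.0), (1.0, 1.0)))
        report, episodes = m.train(SMALL_CONFIG, QED_SPEC, agent, 10, seed=4,
                                   return_episodes=True)
        assert report.validity_fraction == 1.0
        sizes = [Chem.MolFromSmiles(e.final_molecule).GetNumAtoms()
                 for e in episodes if e.final_molecule]
        assert len(set(sizes)) > 1  # genuinely random trajectories


class TestTwoStepQed:
    def test_phase_two_restarts_from_phase_one_top_molecules(self):
        agent = tiny_agent(seed=6)
        report = m.train_two_step_qed(SMALL_CONFIG, agent, seed=6,
                                      n_episodes_phase1=6, n_episodes_phase2=4,
                                      last_n=10)
        assert len(report.terminal_molecules) == 10
        assert report.validity_fraction == 1.0

    def test_degenerate_phase_one_uses_all_available_starts(self):
        # force phase 1 to a single deterministic trajectory: ε=0 throughout
        agent = tiny_agent(seed=7, epsilon_points=((0.0, 0.0), (1.0, 0.0)),
                           warmup_steps=10_000)
        report = m.train_two_step_qed(SMALL_CONFIG, agent, seed=7,
                                      n_episodes_phase1=2, n_episodes_phase2=2,
                                      last_n=4)
        assert len(report.terminal_molecules) == 4


class TestEvaluate:
    def test_argmax_mode_is_deterministic(self):
        agent = tiny_agent(seed=8)
        runs = [m.evaluate(agent, SMALL_CONFIG, QED_SPEC, diversity_mode="argmax",
                           n_episodes=1, seed=s)[0].final_molecule
                for s in (0, 123)]
        assert runs[0] == runs[1]

    def test_eps_mode_with_zero_epsilon_equals_argmax(self):
        agent = tiny_agent(seed=9)
        argmax = m.evaluate(agent, SMALL_CONFIG, QED_SPEC, n_episodes=1)[0]
        eps0 = m.evaluate(agent, SMALL_CONFIG, QED_SPEC, diversity_mode="eps",
                          epsilon=0.0, n_episodes=1)[0]
        assert argmax.final_molecule == eps0.final_molecule

    def test_q_proportional_sampling_on_flat_values_is_uniform(self):
        rng = np.random.default_rng(0)
        q = np.array([2.0, 2.0])
        n = 10_000
        counts = np.bincount(
            [_evaluation_index(q, "softmax_q", 0.0, rng) for _ in range(n)],
            minlength=2)
        sigma = np.sqrt(n * 0.25)
        assert abs(counts[0] - n / 2) < 3 * sigma

    def test_q_proportional_sampling_weights_by_shifted_values(self):
        rng = np.random.default_rng(1)
        q = np.array([-1.0, 0.0, 3.0])  # shifted: 0, 1, 4 -> p = 0, .2, .8
        n = 10_000
        counts = np.bincount(
            [_evaluation_index(q, "softmax_q", 0.0, rng) for _ in range(n)],
            minlength=3)
        assert counts[0] == 0
        assert counts[1] / n == pytest.approx(0.2, abs=0.02)

    def test_per_episode_head_draws_heads(self):
        agent = tiny_agent(seed=10, heads=8)
        records = m.evaluate(agent, SMALL_CONFIG, QED_SPEC,
                             diversity_mode="per_episode_head",
                             n_episodes=6, seed=3)
        assert len(records) == 6
        for r in records:
            assert m.is_valid_smiles(r.final_molecule)

    def test_unknown_mode_rejected(self):
        agent = tiny_agent()
        with pytest.raises(ValueError):
            m.evaluate(agent, SMALL_CONFIG, QED_SPEC, diversity_mode="beam")


class TestConstrainedExperiment:
    def test_zero_delta_makes_every_molecule_a_success(self):
        agent = tiny_agent(seed=12)
        frame = m.constrained_experiment(["CCO", "CCCC"], agent, SMALL_CONFIG,
                                         delta=0.0, n_train_episodes=3)
        assert frame["success"].all()
        assert set(frame.columns) == {"start", "final", "improvement",
                                      "similarity", "success"}

    def test_unchanged_molecule_has_zero_improvement_and_succeeds(self):
        frame_row_sim = m.similarity("CCO", "CCO")
        assert frame_row_sim == pytest.approx(1.0)
        assert m.penalized_logp("CCO") - m.penalized_logp("CCO") == 0.0

    def test_empty_start_set_rejected(self):
        agent = tiny_agent()
        with pytest.raises(ValueError):
            m.constrained_experiment([], agent, SMALL_CONFIG)


def test_read_smiles_file(tmp_path):
    path = tmp_path / "mols.smi"
    path.write_text("CCO ethanol\nc1ccccc1\n\nCC\n")
    assert m.read_smiles_file(path) == ["CCO", "c1ccccc1", "", "CC"]
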