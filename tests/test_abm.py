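"""Agent-based simulator: network, initialisation, dynamics, strategies."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import trustdelay as td
from trustdelay.abm import apply_broadcast, apply_reward, apply_rewire
from conftest import constant_risk_model, records_from_arrays


def quiet_config(**kw) -> td.ABMConfig:
    """A configuration with every dynamic term switched off."""
    base = dict(n_agents=50, degree_k=4, days=3, trials=1,
                delta_delay_trust=0.0, delta_delay_freq=0.0,
                delta_nodelay_trust=0.0, peer_gain=0.0,
                peer_delay_penalty=0.0, trust_decay=0.0)
    base.update(kw)
    return td.ABMConfig(**base)


class TestBuildNetwork:
    def test_ring_lattice_without_rewiring(self):
        net = td.build_network(10, 4, 0.0, seed=1)
        assert net.n_edges == 10 * 4 // 2
        assert (net.degrees == 4).all()

    def test_survey_sized_network(self):
        net = td.build_network(2460, 4, 0.2, seed=3)
        assert net.n_edges == 2460 * 4 // 2
        assert net.degrees.mean() == 4.0

    def test_full_rewiring_valid_edge_set(self):
        net = td.build_network(10, 4, 1.0, seed=7)
        assert net.n_edges == 20
        edges = {tuple(sorted(e)) for e in net.edges}
        assert len(edges) == 20                      # no duplicates
        assert all(u != v for u, v in edges)         # no self-loops

    @pytest.mark.parametrize("n,k", [(10, 3), (10, 10), (4, 0)])
    def test_invalid_degree_rejected(self, n, k):
        with pytest.raises(ValueError):
            td.build_network(n, k, 0.2, seed=1)


def _cfg5(**kw) -> td.ABMConfig:
    return td.ABMConfig(n_agents=5, degree_k=4, **kw)


class TestInitializeAgents:
    def test_high_risk_agents_reduced(self):
        records = records_from_arrays([3] * 5, [3] * 5, [0] * 5)
        fit = constant_risk_model(5, 0.25)
        agents = td.initialize_agents(records, fit, _cfg5())
        assert (agents.trust == 2.0).all()
        assert (agents.frequency == 2.0).all()
        assert agents.high_risk.all()

    def test_threshold_is_strict(self):
        records = records_from_arrays([3] * 5, [3] * 5, [0] * 5)
        fit = constant_risk_model(5, 0.20)  # exactly at the threshold
        agents = td.initialize_agents(records, fit, _cfg5())
        assert (agents.trust == 3.0).all() and not agents.high_risk.any()

    def test_never_user_maps_to_scale_floor(self):
        records = records_from_arrays([0] * 5, [0] * 5, [0] * 5)
        fit = constant_risk_model(5, 0.05)
        agents = td.initialize_agents(records, fit, _cfg5())
        assert (agents.trust == 1.0).all()
        assert (agents.frequency == 1.0).all()

    def test_count_mismatch_rejected(self, small_population, delay_model):
        with pytest.raises(ValueError):
            td.initialize_agents(small_population, delay_model,
                                 td.ABMConfig(n_agents=2460))

    def test_initial_trust_mean_shift(self, default_population, delay_model):
        cfg = td.ABMConfig(initial_trust_mean=3.0)
        agents = td.initialize_agents(default_population, delay_model, cfg)
        # shift happens before the vulnerability reduction, so the final
        # mean sits below the requested one but well above the default
        base = td.initialize_agents(default_population, delay_model,
                                    td.ABMConfig())
        assert agents.trust.mean() > base.trust.mean() + 0.5


class TestDailyStep:
    def _isolated(self, trust, freq, risk):
        """Five identical agents with no edges, no peer terms, no decay."""
        records = records_from_arrays([trust] * 5, [freq] * 5, [0] * 5)
        fit = constant_risk_model(5, risk)
        cfg = dataclasses.replace(quiet_config(), n_agents=5,
                                  delta_delay_trust=0.2,
                                  delta_delay_freq=0.3,
                                  delta_nodelay_trust=0.1,
                                  init_reduction=0.0)
        agents = td.initialize_agents(records, fit, cfg)
        net = td.Network(5, np.empty((0, 2), dtype=np.int64))
        return agents, net, fit, cfg

    def test_delaying_agent_updates(self):
        agents, net, fit, cfg = self._isolated(3.0, 3.0, risk=1 - 1e-12)
        td.daily_step(agents, net, fit, cfg, 1, np.random.default_rng(0))
        assert np.isclose(agents.trust[0], 2.8)
        assert np.isclose(agents.frequency[0], 2.7)

    def test_non_delaying_agent_updates(self):
        agents, net, fit, cfg = self._isolated(3.0, 3.0, risk=1e-12)
        td.daily_step(agents, net, fit, cfg, 1, np.random.default_rng(0))
        assert np.isclose(agents.trust[0], 3.1)
        assert np.isclose(agents.frequency[0], 3.0)

    def test_trust_clamped_at_ceiling(self):
        agents, net, fit, cfg = self._isolated(5.0, 3.0, risk=1e-12)
        td.daily_step(agents, net, fit, cfg, 1, np.random.default_rng(0))
        assert agents.trust[0] == 5.0

    def test_stats_describe_start_of_day(self):
        agents, net, fit, cfg = self._isolated(3.0, 3.0, risk=1e-12)
        _, _, stats = td.daily_step(agents, net, fit, cfg, 1,
                                    np.random.default_rng(0))
        assert stats["mean_trust"] == 3.0  # pre-update value

    def test_bounds_hold_every_day(self, delay_model):
        """Trust and frequency stay inside [1, 5] after every daily step."""
        records = td.generate_population(
            td.GeneratorConfig(n_respondents=300, seed=8))
        fit = td.published_delay_model(records)
        cfg = td.ABMConfig(n_agents=300, days=12, trials=1)
        agents = td.initialize_agents(records, fit, cfg)
        net = td.build_network(300, 4, 0.2, seed=2)
        rng = np.random.default_rng(3)
        window = None
        for day in range(1, 13):
            net, window, _ = td.daily_step(agents, net, fit, cfg, day, rng,
                                           window)
            assert agents.trust.min() >= 1.0 and agents.trust.max() <= 5.0
            assert agents.frequency.min() >= 1.0
            assert agents.frequency.max() <= 5.0


class TestInterventions:
    def test_broadcast_penalty(self):
        cfg = td.ABMConfig(broadcast_penalty=0.10)
        out = apply_broadcast(np.array([3.0, 1.0]), cfg)
        assert np.allclose(out, [2.9, 0.9])  # clamp applied later

    def test_broadcast_zero_penalty_noop(self):
        cfg = td.ABMConfig(broadcast_penalty=0.0)
        assert np.allclose(apply_broadcast(np.array([2.0]), cfg), [2.0])

    def test_reward_applies_on_cycle_days_only(self):
        cfg = td.ABMConfig(reward_magnitude=0.05, reward_interval_days=2)
        t = np.array([3.0, 3.0])
        f = np.array([2.0, 2.0])
        clean = np.array([True, False])  # second agent delayed in window
        t3, f3, w3 = apply_reward(t, f, clean, day=3, config=cfg)
        assert np.allclose(t3, t) and np.allclose(f3, f)  # off-cycle
        t4, f4, w4 = apply_reward(t, f, clean, day=4, config=cfg)
        assert np.allclose(t4, [3.05, 3.0])
        assert np.allclose(f4, [2.05, 2.0])
        assert w4.all()  # window reset after a reward day

    def test_rewire_off_cycle_unchanged(self):
        net = td.build_network(12, 4, 0.2, seed=1)
        cfg = td.ABMConfig(n_agents=12, rewire_interval_days=5)
        same = apply_rewire(net, np.ones(12), day=3, config=cfg,
                            rng=np.random.default_rng(0))
        assert same is net

    def test_rewire_conserves_edge_count(self):
        net = td.build_network(100, 4, 0.2, seed=1)
        cfg = td.ABMConfig(n_agents=100)
        trust = np.random.default_rng(1).uniform(1, 5, 100)
        new = apply_rewire(net, trust, day=5, config=cfg,
                           rng=np.random.default_rng(2))
        assert new.n_edges == net.n_edges == 200
        edges = {tuple(sorted(e)) for e in new.edges}
        assert len(edges) == 200 and all(u != v for u, v in edges)

    def test_rewire_ties_resolved_and_terminates(self):
        """All-equal trust: the top decile falls back to lowest ids."""
        net = td.build_network(12, 4, 0.0, seed=1)
        cfg = td.ABMConfig(n_agents=12, rewire_fraction=0.5)
        new = apply_rewire(net, np.full(12, 3.0), day=5, config=cfg,
                           rng=np.random.default_rng(3))
        assert new.n_edges == net.n_edges
        # with 12 agents the decile set is agent 0 only; every rewired
        # edge must now touch agent 0
        changed = {tuple(sorted(e)) for e in new.edges} \
            - {tuple(sorted(e)) for e in net.edges}
        assert all(0 in e for e in changed)


class TestRunExperiment:
    def test_deterministic_given_seed(self, delay_model):
        records = td.generate_population(
            td.GeneratorConfig(n_respondents=200, seed=6))
        fit = td.published_delay_model(records)
        cfg = td.ABMConfig(n_agents=200, days=5, trials=3, base_seed=42)
        a = td.run_experiment(records, fit, cfg)
        b = td.run_experiment(records, fit, cfg)
        assert a.to_frame().to_csv() == b.to_frame().to_csv()
        assert np.array_equal(a.per_trial_delay_rate, b.per_trial_delay_rate)

    def test_null_dynamics_flat_trajectory(self):
        """With all update terms off, the delay rate stays at the
        initialised mean probability."""
        records = td.generate_population(
            td.GeneratorConfig(n_respondents=500, seed=9))
        fit = td.published_delay_model(records)
        cfg = dataclasses.replace(quiet_config(), n_agents=500, days=10,
                                  trials=30, base_seed=0)
        agents = td.initialize_agents(records, fit, cfg)
        expected = np.mean(
            td.abm._predict(fit.coefficients, agents.trust,
                            agents.frequency, agents.chronic))
        summary = td.run_experiment(records, fit, cfg)
        mc_se = np.sqrt(expected * (1 - expected) / (500 * 30))
        assert np.all(np.abs(summary.delay_rate - expected) < 4 * mc_se)
        assert np.allclose(summary.mean_trust, summary.mean_trust[0])

    def test_monotone_link_in_initial_trust(self):
        """Raising initial trust weakly increases the day-1 delay rate."""
        records = td.generate_population(
            td.GeneratorConfig(n_respondents=400, seed=10))
        fit = td.published_delay_model(records)
        base = td.ABMConfig(n_agents=400, days=1, trials=40, base_seed=1)
        lifted = dataclasses.replace(base, initial_trust_mean=float(
            np.maximum(records["trust"], 1).mean() + 1.0))
        r_base = td.run_experiment(records, fit, base)
        r_lift = td.run_experiment(records, fit, lifted)
        assert r_lift.delay_rate[0] >= r_base.delay_rate[0]

    def test_broadcast_erodes_trust_every_day(self, default_population,
                                              delay_model):
        cfg = td.ABMConfig(trials=5, base_seed=0)
        arms = {
            s: td.run_experiment(default_population, delay_model,
                                 dataclasses.replace(cfg, strategy=s))
            for s in ("baseline", "broadcast")}
        diff = arms["baseline"].mean_trust - arms["broadcast"].mean_trust
        assert (diff[1:] > 0).all()


class TestCompareStrategies:
    def test_identical_arms_give_unit_or(self, default_population,
                                         delay_model):
        cfg = td.ABMConfig(trials=2, days=3, base_seed=5)
        one = td.run_experiment(default_population, delay_model, cfg)
        two = td.run_experiment(default_population, delay_model, cfg)
        table = td.compare_strategies({"baseline": one, "clone": two})
        assert abs(table.loc[0, "or"] - 1.0) < 1e-9

    def test_missing_baseline_rejected(self, default_population,
                                       delay_model):
        cfg = td.ABMConfig(trials=1, days=2)
        res = td.run_experiment(default_population, delay_model, cfg)
        with pytest.raises(ValueError):
            td.compare_strategies({"broadcast": res})

    def test_direction_broadcast_below_rewire(self, default_population,
                                              delay_model):
        """Broadcast suppresses delay odds; rewiring does not."""
        cfg = td.ABMConfig(trials=30, base_seed=0)
        arms = {
            s: td.run_experiment(default_population, delay_model,
                                 dataclasses.replace(cfg, strategy=s))
            for s in ("baseline", "broadcast", "rewire")}
        table = td.compare_strategies(arms).set_index("strategy")
        assert table.loc["broadcast", "or"] < 1.0
        assert table.loc["broadcast", "or"] < table.loc["rewire", "or"]


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"days": 0}, {"trials": 0}, {"degree_k": 3},
        {"degree_k": 2460}, {"strategy": "unknown"},
        {"trust_decay": -0.1},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            td.ABMConfig(**kw)
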