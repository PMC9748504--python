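"""Discrete SDE simulator: initialisation, forces, stepping, limit laws."""

import math

import numpy as np
import pytest

from tetherswarm.discrete import (
    AgentState,
    ObstacleState,
    SimConfig,
    compute_forces,
    compute_forces_bruteforce,
    init_state,
    mean_direction,
    run,
    step,
)
from tetherswarm.params import ModelParams


def _free_params(M=1, **kw):
    """Agents with effectively no interactions (tiny radii)."""
    base = dict(N=0, M=M, rR=1e-9, rA=1e-9, mu=1e-12, ds=0.02, nu=2.0)
    base.update(kw)
    return ModelParams(**base)


class TestInit:
    def test_seed_determinism(self, table_params):
        a1, o1 = init_state(table_params, 7)
        a2, o2 = init_state(table_params, 7)
        assert np.array_equal(a1.Z, a2.Z)
        assert np.array_equal(a1.theta, a2.theta)
        assert np.array_equal(o1.X, o2.X)
        assert np.array_equal(o1.Y, o2.Y)

    def test_initial_angle_is_quarter_pi(self, table_params):
        a, _ = init_state(table_params, 0)
        assert np.all(a.theta == math.pi / 4)

    def test_obstacles_start_at_anchors(self, table_params):
        _, o = init_state(table_params, 0)
        assert np.array_equal(o.X, o.Y)
        _, o2 = init_state(table_params, 0, obstacles_at_anchor=False)
        assert not np.array_equal(o2.X, o2.Y)

    def test_uniform_positions_clt_bound(self):
        p = ModelParams(N=10, M=3000)
        a, _ = init_state(p, 11)
        sigma = math.sqrt(1 / 12 / 3000)
        assert np.all(np.abs(a.Z.mean(axis=0) - 0.5) < 3 * sigma)


class TestMeanDirection:
    def test_isolated_agent_keeps_orientation(self):
        a = AgentState(Z=np.array([[0.1, 0.1], [0.9, 0.9]]),
                       theta=np.array([0.3, 2.0]))
        ab = mean_direction(a, rA=0.05)
        assert np.allclose(ab, a.alpha)

    def test_two_agent_hand_computation(self):
        # agents at angles 0 and pi/2 within rA: J = (1,0)+(0,1)
        a = AgentState(Z=np.array([[0.5, 0.5], [0.52, 0.5]]),
                       theta=np.array([0.0, math.pi / 2]))
        ab = mean_direction(a, rA=0.1)
        expected = np.array([1.0, 1.0]) / math.sqrt(2)
        assert np.allclose(ab[0], expected)
        assert np.allclose(ab[1], expected)

    def test_antipodal_tie_break_keeps_current(self):
        # exactly cancelling pair: each agent's J = alpha_self + alpha_other = 0
        a = AgentState(Z=np.array([[0.5, 0.5], [0.51, 0.5]]),
                       theta=np.array([0.0, math.pi]))
        ab = mean_direction(a, rA=0.1)
        assert np.allclose(ab, a.alpha)

    def test_matches_all_pairs_oracle(self, rng):
        M = 40
        a = AgentState(Z=rng.uniform(0, 1, (M, 2)),
                       theta=rng.uniform(0, 2 * math.pi, M))
        rA = 0.2
        ab = mean_direction(a, rA)
        alpha = a.alpha
        for k in range(M):
            dx = a.Z - a.Z[k]
            dx -= np.round(dx)
            near = np.linalg.norm(dx, axis=1) <= rA
            J = alpha[near].sum(axis=0)
            assert np.allclose(ab[k], J / np.linalg.norm(J), atol=1e-12)


class TestStep:
    def test_free_streaming(self):
        p = _free_params(ds=1e-15)
        a = AgentState(Z=np.array([[0.3, 0.3]]), theta=np.array([math.pi / 4]))
        o = ObstacleState(X=np.zeros((0, 2)), Y=np.zeros((0, 2)))
        rng = np.random.default_rng(0)
        dt = 1e-3
        a2, _ = step(a, o, p, dt, rng)
        expected = a.Z + dt * np.array([[math.cos(math.pi / 4),
                                         math.sin(math.pi / 4)]])
        assert np.allclose(a2.Z, expected, atol=1e-12)

    def test_spring_contraction_factor(self):
        p = ModelParams(N=1, M=0, kappa=100.0, eta=1.0, d0=0.0)
        o = ObstacleState(X=np.array([[0.5, 0.5]]), Y=np.array([[0.45, 0.45]]))
        a = AgentState(Z=np.zeros((0, 2)), theta=np.zeros(0))
        dt = 1e-3
        _, o2 = step(a, o, p, dt, np.random.default_rng(0))
        expected = o.Y + (1 - p.kappa * dt / p.eta) * (o.X - o.Y)
        assert np.allclose(o2.X, expected, atol=1e-14)

    def test_forces_tree_equals_bruteforce(self, rng):
        p = ModelParams(N=50, M=50, mu=0.01, kappa=100.0)
        a, o = init_state(p, 5)
        Fa1, Fo1 = compute_forces(a, o, p)
        Fa2, Fo2 = compute_forces_bruteforce(a, o, p)
        assert np.max(np.abs(Fa1 - Fa2)) < 1e-12
        assert np.max(np.abs(Fo1 - Fo2)) < 1e-12

    def test_invalid_dt_rejected(self):
        p = _free_params()
        a, o = init_state(p, 0)
        with pytest.raises(ValueError):
            step(a, o, p, -1e-3, np.random.default_rng(0))

    def test_nonfinite_state_aborts(self):
        p = _free_params()
        a, o = init_state(p, 0)
        a.Z[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            step(a, o, p, 1e-3, np.random.default_rng(0))

    def test_alignment_relaxes_towards_mean(self):
        # two neighbours at 0 and pi/2 with negligible noise align to pi/4
        p = ModelParams(N=0, M=2, rA=0.2, rR=1e-9, mu=1e-12, nu=2.0, ds=1e-15,
                        u0=1e-9)
        a = AgentState(Z=np.array([[0.5, 0.5], [0.52, 0.5]]),
                       theta=np.array([0.0, math.pi / 2]))
        o = ObstacleState(X=np.zeros((0, 2)), Y=np.zeros((0, 2)))
        rng = np.random.default_rng(0)
        for _ in range(6000):
            a, o = step(a, o, p, 1e-3, rng)
        assert np.allclose(a.theta, math.pi / 4, atol=1e-3)


class TestRun:
    def test_pinned_obstacle_limit(self):
        # very stiff springs: obstacles stay glued to their anchors
        p = ModelParams(N=50, M=50, kappa=1e6, eta=1.0, mu=2e-3, zeta=0.5)
        cfg = SimConfig(dt=1e-6, T=1e-5, seed=3, save_every=10)
        res = run(p, cfg)
        disp = np.linalg.norm(res.final_obstacles.X - res.final_obstacles.Y,
                              axis=1)
        assert np.max(disp) < 1e-5

    def test_deterministic_trajectories(self):
        p = ModelParams(N=30, M=30, mu=2e-3, zeta=0.5, kappa=100.0,
                        ds=0.02, d0=0.0)
        cfg = SimConfig(dt=1e-3, T=0.05, seed=9, save_every=10)
        r1 = run(p, cfg)
        r2 = run(p, cfg)
        assert np.array_equal(r1.final_agents.Z, r2.final_agents.Z)
        assert np.array_equal(r1.final_agents.theta, r2.final_agents.theta)
        assert np.array_equal(r1.final_obstacles.X, r2.final_obstacles.X)

    def test_displacement_monitor_bounds_steps(self):
        # adaptive stepping keeps every step below half the neighbour cell
        p = ModelParams(N=0, M=5, u0=500.0, rR=1e-9, rA=1e-9, mu=1e-12)
        cfg = SimConfig(dt=1e-3, T=0.01, seed=0, save_every=100)
        res = run(p, cfg)
        cell = max(p.rA, p.rR, p.tau)
        assert res.max_displacement <= 0.5 * cell


class TestLimitLaws:
    def test_angular_variance_grows_like_2_ds_t(self):
        # no neighbours: pure angular Brownian motion, Var = 2 ds t
        M, T, dt = 2000, 1.0, 2e-3
        p = _free_params(M=M, ds=0.02, nu=2.0)
        a, o = init_state(p, 0)
        rng = np.random.default_rng(0)
        acc = np.zeros(M)
        prev = a.theta.copy()
        for _ in range(int(T / dt)):
            a, o = step(a, o, p, dt, rng)
            acc += np.angle(np.exp(1j * (a.theta - prev)))
            prev = a.theta.copy()
        assert acc.var() == pytest.approx(2 * p.ds * T, rel=0.10)

    def test_obstacle_ou_stationary_variance(self):
        # without agents: X - Y is an OU process with variance d0 eta / kappa
        p = ModelParams(N=200, M=0, kappa=10.0, eta=1.0, d0=0.05)
        a, o = init_state(p, 4)
        rng = np.random.default_rng(4)
        dt, T_burn, T = 1e-3, 1.0, 5.0
        for _ in range(int(T_burn / dt)):
            a, o = step(a, o, p, dt, rng)
        samples = []
        for n in range(int(T / dt)):
            a, o = step(a, o, p, dt, rng)
            if n % 100 == 0:
                d = o.X - o.Y
                d -= np.round(d)
                samples.append(d.ravel())
        var = np.concatenate(samples).var()
        assert var == pytest.approx(p.d0 * p.eta / p.kappa, rel=0.10)
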