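"""Discrete agent/obstacle simulator on the periodic unit square.

``M`` self-propelled agents ``(Z_k, alpha_k)`` and ``N`` obstacles ``X_i``
tethered to fixed anchors ``Y_i`` evolve by the coupled SDE system

    ``dX_i = -(kappa/eta)(X_i - Y_i) dt - (1/(eta M)) sum_k grad phi(X_i - Z_k) dt
             + sqrt(2 d0) dB_i``
    ``dZ_k = u0 alpha_k dt - (1/(zeta N)) sum_i grad phi(Z_k - X_i) dt
             - (1/(zeta M)) sum_{l != k} grad psi(Z_k - Z_l) dt``

and a Stratonovich alignment/noise equation for the orientations.  In
angle coordinates the projected orientation equation is exactly

    ``d theta_k = nu sin(thetabar_k - theta_k) dt + sqrt(2 ds) dW_k``

(the Stratonovich projected noise is additive on the circle), where
``thetabar_k`` is the angle of the mean flux ``J_k = sum_{|Z_j - Z_k| <= rA}
alpha_j`` (self included).  Integration is Euler-Maruyama with periodic
minimum-image interactions; neighbour searches use periodic k-d trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.spatial import cKDTree

from .params import ModelParams

__all__ = [
    "AgentState",
    "ObstacleState",
    "SimConfig",
    "SimResult",
    "init_state",
    "mean_direction",
    "compute_forces",
    "compute_forces_bruteforce",
    "step",
    "run",
]


@dataclass
class AgentState:
    """Positions ``Z`` in ``[0, L)^2`` and orientation angles ``theta``."""

    Z: np.ndarray          # (M, 2)
    theta: np.ndarray      # (M,) in [0, 2 pi)

    @property
    def alpha(self) -> np.ndarray:
        """Unit orientation vectors (cos theta, sin theta)."""
        return np.stack([np.cos(self.theta), np.sin(self.theta)], axis=-1)

    def copy(self) -> "AgentState":
        return AgentState(Z=self.Z.copy(), theta=self.theta.copy())


@dataclass
class ObstacleState:
    """Obstacle positions ``X`` and immutable anchor positions ``Y``."""

    X: np.ndarray          # (N, 2)
    Y: np.ndarray          # (N, 2), never modified by stepping

    def copy(self) -> "ObstacleState":
        return ObstacleState(X=self.X.copy(), Y=self.Y.copy())


@dataclass
class SimConfig:
    """Time stepping configuration.

    ``cell_size`` bounds the per-step displacement for the stability
    monitor and must cover the largest interaction radius.
    """

    dt: float = 1e-3
    T: float = 10.0
    seed: int = 0
    cell_size: Optional[float] = None      # default: max(rA, rR, tau)
    save_every: int = 1000                 # snapshot cadence in steps

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def init_state(params: ModelParams, seed: Optional[int],
               *, obstacles_at_anchor: bool = True):
    """Seeded initial condition: uniform positions, all agents at angle pi/4.

    Anchors are i.i.d. uniform on the domain; by default obstacles start at
    their anchors (one uniform draw realises both "uniform obstacles" and
    "uniform anchors", with the spring initially relaxed).  Pass
    ``obstacles_at_anchor=False`` for an independent uniform obstacle draw.
    """
    rng = np.random.default_rng(seed)
    Z = rng.uniform(0.0, params.L, size=(params.M, 2))
    Y = rng.uniform(0.0, params.L, size=(params.N, 2))
    X = Y.copy() if obstacles_at_anchor else rng.uniform(0.0, params.L,
                                                         size=(params.N, 2))
    theta = np.full(params.M, math.pi / 4)
    return AgentState(Z=Z, theta=theta), ObstacleState(X=X, Y=Y)


def _wrap(x: np.ndarray, L: float) -> np.ndarray:
    return np.mod(x, L)


def _min_image(dx: np.ndarray, L: float) -> np.ndarray:
    return dx - L * np.round(dx / L)


def _agent_tree(agents: AgentState, L: float) -> cKDTree:
    return cKDTree(_wrap(agents.Z, L), boxsize=L)


def mean_direction(agents: AgentState, rA: float, L: float = 1.0,
                   tree: Optional[cKDTree] = None) -> np.ndarray:
    """Normalised mean flux ``alphabar_k = J_k / |J_k|`` over the rA-ball.

    The sum includes the agent itself, so an isolated agent keeps its own
    orientation.  On exact cancellation (``|J_k| < 1e-12``, a measure-zero
    event) the current orientation is kept.
    """
    tree = tree or _agent_tree(agents, L)
    alpha = agents.alpha
    J = alpha.copy()                       # self term
    pairs = tree.query_pairs(rA, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        np.add.at(J, i, alpha[j])
        np.add.at(J, j, alpha[i])
    norm = np.linalg.norm(J, axis=1, keepdims=True)
    tie = norm[:, 0] < 1e-12
    out = np.where(tie[:, None], alpha, J / np.where(norm > 0, norm, 1.0))
    return out


def _pair_force(dx: np.ndarray, r: np.ndarray, radius: float,
                amplitude: float) -> np.ndarray:
    """-grad of A (1 - r/R)_+^2 evaluated at dx (rows), i.e. the repulsive
    force direction along +dx; zero at r = 0."""
    s = np.clip(1.0 - r / radius, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        coef = np.where(r > 0, amplitude * s / np.where(r > 0, r, 1.0), 0.0)
    return coef[:, None] * dx


def compute_forces(agents: AgentState, obstacles: ObstacleState,
                   params: ModelParams,
                   tree: Optional[cKDTree] = None):
    """Interaction forces ``(F_agents, F_obstacles)`` including friction
    prefactors ``1/(zeta N)``, ``1/(zeta M)``, ``1/(eta M)`` of the model."""
    L = params.L
    M, N = len(agents.Z), len(obstacles.X)
    Fa = np.zeros((M, 2))
    Fo = np.zeros((N, 2))
    atree = tree or _agent_tree(agents, L)

    # agent-agent repulsion via psi
    pairs = atree.query_pairs(params.rR, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        dx = _min_image(agents.Z[i] - agents.Z[j], L)
        r = np.linalg.norm(dx, axis=1)
        amp_psi = 12.0 * params.mu / (math.pi * params.rR**3)
        f = _pair_force(dx, r, params.rR, amp_psi) / (params.zeta * M)
        np.add.at(Fa, i, f)
        np.add.at(Fa, j, -f)

    # agent-obstacle repulsion via phi (action-reaction up to frictions)
    if N > 0:
        otree = cKDTree(_wrap(obstacles.X, L), boxsize=L)
        hits = atree.sparse_distance_matrix(otree, params.tau,
                                            output_type="ndarray")
        if len(hits):
            k = hits["i"]
            i = hits["j"]
            dx = _min_image(agents.Z[k] - obstacles.X[i], L)
            r = hits["v"]
            amp_phi = 3.0 * params.Cphi / (math.pi * params.tau**2)
            f = _pair_force(dx, r, params.tau, amp_phi)
            np.add.at(Fa, k, f / (params.zeta * N))
            np.add.at(Fo, i, -f / (params.eta * M))
    return Fa, Fo


def compute_forces_bruteforce(agents: AgentState, obstacles: ObstacleState,
                              params: ModelParams):
    """All-pairs O(M^2 + NM) reference force computation (test oracle)."""
    L = params.L
    M, N = len(agents.Z), len(obstacles.X)
    amp_psi = 12.0 * params.mu / (math.pi * params.rR**3)
    amp_phi = 3.0 * params.Cphi / (math.pi * params.tau**2)
    Fa = np.zeros((M, 2))
    Fo = np.zeros((N, 2))
    dx = _min_image(agents.Z[:, None, :] - agents.Z[None, :, :], L)
    r = np.linalg.norm(dx, axis=-1)
    s = np.clip(1.0 - r / params.rR, 0.0, None)
    np.fill_diagonal(s, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        coef = np.where(r > 0, amp_psi * s / np.where(r > 0, r, 1.0), 0.0)
    Fa += (coef[..., None] * dx).sum(axis=1) / (params.zeta * M)
    if N > 0:
        dxo = _min_image(agents.Z[:, None, :] - obstacles.X[None, :, :], L)
        ro = np.linalg.norm(dxo, axis=-1)
        so = np.clip(1.0 - ro / params.tau, 0.0, None)
        with np.errstate(invalid="ignore", divide="ignore"):
            co = np.where(ro > 0, amp_phi * so / np.where(ro > 0, ro, 1.0), 0.0)
        f = co[..., None] * dxo
        Fa += f.sum(axis=1) / (params.zeta * N)
        Fo -= f.sum(axis=0) / (params.eta * M)
    return Fa, Fo


def step(agents: AgentState, obstacles: ObstacleState, params: ModelParams,
         dt: float, rng: np.random.Generator):
    """One Euler-Maruyama step; returns new (agents, obstacles) states."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (np.all(np.isfinite(agents.Z)) and np.all(np.isfinite(obstacles.X))):
        raise FloatingPointError("non-finite state; aborting step")
    L = params.L
    M, N = len(agents.Z), len(obstacles.X)
    tree = _agent_tree(agents, L)
    Fa, Fo = compute_forces(agents, obstacles, params, tree=tree)

    # orientations: angle form of the projected Stratonovich equation
    abar = mean_direction(agents, params.rA, L, tree=tree)
    theta_bar = np.arctan2(abar[:, 1], abar[:, 0])
    dtheta = params.nu * np.sin(theta_bar - agents.theta) * dt
    dtheta += math.sqrt(2.0 * params.ds * dt) * rng.standard_normal(M)
    theta_new = np.mod(agents.theta + dtheta, 2.0 * math.pi)

    Z_new = agents.Z + dt * (params.u0 * agents.alpha + Fa)
    # spring through the minimum-image displacement (tether on the torus)
    spring = _min_image(obstacles.X - obstacles.Y, L)
    X_new = obstacles.X + dt * (-(params.kappa / params.eta) * spring + Fo)
    if params.d0 > 0 and N > 0:
        X_new = X_new + math.sqrt(2.0 * params.d0 * dt) * \
            rng.standard_normal((N, 2))
    return (AgentState(Z=_wrap(Z_new, L), theta=theta_new),
            ObstacleState(X=_wrap(X_new, L), Y=obstacles.Y))


@dataclass
class SimResult:
    """Trajectory of snapshots plus stability diagnostics."""

    times: list
    agents: list               # AgentState copies
    obstacles: list            # ObstacleState copies
    max_displacement: float
    seed: int

    @property
    def final_agents(self) -> AgentState:
        return self.agents[-1]

    @property
    def final_obstacles(self) -> ObstacleState:
        return self.obstacles[-1]


def _max_displacement(new_a, new_o, agents, obstacles, L: float) -> float:
    disp = 0.0
    if len(new_a.Z):
        disp = float(np.max(np.linalg.norm(
            _min_image(new_a.Z - agents.Z, L), axis=1)))
    if len(new_o.X):
        disp = max(disp, float(np.max(np.linalg.norm(
            _min_image(new_o.X - obstacles.X, L), axis=1))))
    return disp


def run(params: ModelParams, config: SimConfig,
        callbacks: Optional[list[Callable]] = None) -> SimResult:
    """Integrate to ``T``, emitting snapshots every ``save_every`` nominal steps.

    The per-step displacement is monitored against ``cell_size``.  In dense
    cluster phases the repulsion forces can transiently exceed what the
    nominal ``dt`` supports; the step is then retried with a halved ``dt``
    (and relaxed back toward the nominal value when the dynamics allow).
    If the required ``dt`` falls below ``dt / 1024`` the run aborts — the
    state is effectively singular.
    """
    rng = np.random.default_rng(config.seed)
    agents, obstacles = init_state(params, config.seed)
    cell = config.cell_size or max(params.rA, params.rR, params.tau)
    if cell < max(params.rA, params.rR, params.tau):
        raise ValueError("cell_size must cover the largest interaction radius")
    t = 0.0
    save_dt = config.save_every * config.dt
    next_save = save_dt
    times = [0.0]
    snaps_a = [agents.copy()]
    snaps_o = [obstacles.copy()]
    max_disp = 0.0
    dt_eff = config.dt
    dt_min = config.dt / 1024.0
    while t < config.T - 1e-12:
        dt_step = min(dt_eff, config.T - t)
        new_a, new_o = step(agents, obstacles, params, dt_step, rng)
        disp = _max_displacement(new_a, new_o, agents, obstacles, params.L)
        if disp > 0.5 * cell:
            dt_eff = dt_step / 2.0
            if dt_eff < dt_min:
                raise RuntimeError(
                    f"per-step displacement {disp:.3g} still exceeds half the "
                    f"cell size {cell:.3g} at dt={dt_step:.3g} (t={t:.3f}); "
                    "state is effectively singular"
                )
            continue                      # reject, retry with smaller dt
        max_disp = max(max_disp, disp)
        agents, obstacles = new_a, new_o
        t += dt_step
        if disp < 0.15 * cell and dt_eff < config.dt:
            dt_eff = min(config.dt, dt_eff * 1.5)
        if callbacks:
            for cb in callbacks:
                cb(t, agents, obstacles)
        if t >= next_save - 1e-12 or t >= config.T - 1e-12:
            times.append(t)
            snaps_a.append(agents.copy())
            snaps_o.append(obstacles.copy())
            while next_save <= t + 1e-12:
                next_save += save_dt
    return SimResult(times=times, agents=snaps_a, obstacles=snaps_o,
                     max_displacement=max_disp, seed=config.seed)
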