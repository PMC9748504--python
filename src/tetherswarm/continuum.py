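"""Continuum solver for the agent density / mean-orientation system.

The macroscopic model evolves the agent density ``rho_g`` and the unit
orientation field ``Omega`` on the periodic square:

    ``dt rho_g + div(U rho_g) = 0``
    ``rho_g dt Omega + rho_g (V . grad) Omega + d3 P_perp grad rho_g
        = gamma_s P_perp Lap(rho_g Omega)``

with ``U = d1 Omega - (1/zeta) grad rhobar_f - (mu/zeta) grad rho_g`` and
``V`` the same with ``d2``.  ``P_perp`` projects onto the orthogonal
complement of ``Omega`` so ``|Omega| = 1`` is preserved.  The obstacle
density is slaved to the convolved agent density ``rhobar_g = rho_g * phi``
through the stiff-spring closure

    ``rho_f / rho_A = 1 + Lap(rhobar_g)/kappa + det H(rhobar_g)/kappa^2
                       - (eta/kappa^2) dt Lap(rhobar_g)``

(higher orders in ``eta/kappa`` dropped), and feeds back through
``rhobar_f = rho_f * phi``.  Solutions may concentrate and blow up, or
drive ``rho_f`` negative; both are detected and stop the run with the last
valid state retained.

Numerics: cell-centred periodic grid; convolutions and all derivatives are
spectral (FFT); time stepping is explicit Euler on fluxes written in
conservative form, so the total agent mass is conserved to round-off.  A
first-order upwind advection variant is available (``scheme="upwind"``) for
positivity-critical runs; the spectral scheme is the default because the
growth/decay of small perturbations must track the dispersion relation
closely, which first-order upwinding's numerical diffusion destroys at
moderate resolution.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Optional

import numpy as np

from .alignment import compute_constants
from .params import ModelParams, phi_eval

__all__ = [
    "Grid",
    "ContinuumState",
    "ContinuumConfig",
    "Status",
    "CFLError",
    "init_continuum",
    "convolve_phi",
    "obstacle_density",
    "step_continuum",
    "blowup_check",
    "run_continuum",
]


class CFLError(RuntimeError):
    """Raised when an explicit step would violate the CFL conditions."""

    def __init__(self, msg: str, suggested_dt: float):
        super().__init__(msg)
        self.suggested_dt = suggested_dt


@dataclass(frozen=True)
class Grid:
    """Cell-centred periodic grid on ``[0, L)^2`` with ``Nx`` points per side."""

    Nx: int
    L: float = 1.0

    def __post_init__(self):
        if self.Nx < 16:
            raise ValueError("Nx must be >= 16")

    @property
    def h(self) -> float:
        return self.L / self.Nx

    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.Nx) + 0.5) * self.h

    def meshgrid(self):
        return np.meshgrid(self.x, self.x, indexing="ij")

    @property
    def k(self) -> np.ndarray:
        """Angular wavenumbers 2 pi n / L along one axis (FFT order)."""
        return 2.0 * math.pi * np.fft.fftfreq(self.Nx, d=self.h)


@lru_cache(maxsize=16)
def _spectral(Nx: int, L: float):
    k = 2.0 * math.pi * np.fft.fftfreq(Nx, d=L / Nx)
    kx = k[:, None]
    ky = k[None, :]
    return kx, ky, kx**2 + ky**2


def _ddx(fh, kx):
    return np.fft.ifft2(1j * kx * fh).real


def _grad(f, grid: Grid):
    kx, ky, _ = _spectral(grid.Nx, grid.L)
    fh = np.fft.fft2(f)
    return _ddx(fh, kx), _ddx(fh, ky)


def _lap(f, grid: Grid):
    kx, ky, k2 = _spectral(grid.Nx, grid.L)
    return np.fft.ifft2(-k2 * np.fft.fft2(f)).real


@lru_cache(maxsize=16)
def _phi_kernel_hat(Cphi: float, tau: float, Nx: int, L: float) -> np.ndarray:
    """FFT of the phi kernel sampled on the displacement lattice.

    The samples are rescaled so the discrete integral equals the analytic
    ``integral phi = Cphi tau / 4`` exactly.
    """
    h = L / Nx
    d = np.arange(Nx) * h
    d = np.where(d > L / 2, d - L, d)        # minimum-image displacements
    r = np.hypot(d[:, None], d[None, :])
    p = ModelParams(Cphi=Cphi, tau=tau, L=L)
    ker = phi_eval(r, p)
    target = Cphi * tau / 4.0
    ker *= target / (ker.sum() * h * h)
    return np.fft.fft2(ker)


def convolve_phi(fld: np.ndarray, params: ModelParams, grid: Grid,
                 *, warn: bool = True) -> np.ndarray:
    """Periodic convolution ``fld * phi`` computed spectrally."""
    if warn and params.tau < 2 * grid.h:
        import warnings

        warnings.warn(
            f"phi kernel under-resolved: tau={params.tau} < 2 h={2 * grid.h}",
            stacklevel=2,
        )
    khat = _phi_kernel_hat(params.Cphi, params.tau, grid.Nx, grid.L)
    return np.fft.ifft2(np.fft.fft2(fld) * khat).real * grid.h**2


@dataclass
class ContinuumState:
    """Gridded fields at time ``t``.

    ``prev_lap_rho_bar`` stores the previous step's ``Lap(rhobar_g)`` for
    the backward-difference time derivative in the obstacle closure (zero
    history at the first step).
    """

    rho_g: np.ndarray                 # (Nx, Nx) nonnegative
    Omega: np.ndarray                 # (Nx, Nx, 2) unit vectors
    rho_f: np.ndarray                 # (Nx, Nx) diagnostic obstacle density
    t: float = 0.0
    prev_lap_rho_bar: Optional[np.ndarray] = None

    def copy(self) -> "ContinuumState":
        return ContinuumState(
            rho_g=self.rho_g.copy(),
            Omega=self.Omega.copy(),
            rho_f=self.rho_f.copy(),
            t=self.t,
            prev_lap_rho_bar=None if self.prev_lap_rho_bar is None
            else self.prev_lap_rho_bar.copy(),
        )


def init_continuum(params: ModelParams, grid: Grid, seed: Optional[int],
                   amplitude: float = 1e-2, *, n_band: int = 8,
                   theta0: float = math.pi / 4) -> ContinuumState:
    """Uniform state plus a band-limited random density perturbation.

    ``rho_g = 1 + amplitude * xi`` with ``xi`` a mean-zero smooth random
    field built from Fourier modes ``|n| <= n_band`` and normalised to
    ``max |xi| = 1``; the density is then rescaled to unit total mass.
    ``Omega`` is uniform at angle ``theta0``.  ``amplitude = 0`` gives the
    exactly uniform state.
    """
    rho = np.ones((grid.Nx, grid.Nx))
    if amplitude != 0.0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(size=(grid.Nx, grid.Nx))
        nh = np.fft.fft2(noise)
        n = np.fft.fftfreq(grid.Nx) * grid.Nx
        mask = (np.abs(n[:, None]) <= n_band) & (np.abs(n[None, :]) <= n_band)
        mask[0, 0] = False                       # mean-zero
        xi = np.fft.ifft2(nh * mask).real
        xi /= np.max(np.abs(xi))
        rho = 1.0 + amplitude * xi
    rho /= rho.mean() * grid.L**2               # unit mass: sum rho h^2 = 1
    om = np.empty((grid.Nx, grid.Nx, 2))
    om[..., 0] = math.cos(theta0)
    om[..., 1] = math.sin(theta0)
    rho_f = _obstacle_density_fields(rho, None, params, grid, dt=1.0)[0]
    return ContinuumState(rho_g=rho, Omega=om, rho_f=rho_f, t=0.0,
                          prev_lap_rho_bar=None)


def _obstacle_density_fields(rho_g, prev_lap_rho_bar, params: ModelParams,
                             grid: Grid, dt: float, *,
                             include_dt_term: bool = True):
    """Return ``(rho_f, lap_rho_bar)`` from the stiff-spring closure."""
    kx, ky, k2 = _spectral(grid.Nx, grid.L)
    rb_hat = np.fft.fft2(convolve_phi(rho_g, params, grid, warn=False))
    lap = np.fft.ifft2(-k2 * rb_hat).real
    dxx = np.fft.ifft2(-(kx**2) * rb_hat).real
    dyy = np.fft.ifft2(-(ky**2) * rb_hat).real
    dxy = np.fft.ifft2(-(kx * ky) * rb_hat).real
    det_hess = dxx * dyy - dxy**2
    rho_f = 1.0 + lap / params.kappa + det_hess / params.kappa**2
    if include_dt_term and prev_lap_rho_bar is not None:
        rho_f = rho_f - (params.eta / params.kappa**2) * (lap - prev_lap_rho_bar) / dt
    return params.rhoA * rho_f, lap


def obstacle_density(state: ContinuumState, params: ModelParams, grid: Grid,
                     dt: float, *, include_dt_term: bool = True) -> np.ndarray:
    """Obstacle density slaved to ``rho_g`` (see module docstring)."""
    rho_f, _ = _obstacle_density_fields(
        state.rho_g, state.prev_lap_rho_bar, params, grid, dt,
        include_dt_term=include_dt_term)
    return rho_f


def _velocities(state, params, grid, dt, include_dt_term):
    """Shared advection fields: returns (U, V, rho_f, lap_rho_bar, grad rho)."""
    c = compute_constants(params.ratio, params.u0, params.rA)
    rho_f, lap_rb = _obstacle_density_fields(
        state.rho_g, state.prev_lap_rho_bar, params, grid, dt,
        include_dt_term=include_dt_term)
    rbf = convolve_phi(rho_f, params, grid, warn=False)
    gbx, gby = _grad(rbf, grid)
    grx, gry = _grad(state.rho_g, grid)
    common_x = -(gbx / params.zeta) - params.mu / params.zeta * grx
    common_y = -(gby / params.zeta) - params.mu / params.zeta * gry
    Ux = c.d1 * state.Omega[..., 0] + common_x
    Uy = c.d1 * state.Omega[..., 1] + common_y
    Vx = c.d2 * state.Omega[..., 0] + common_x
    Vy = c.d2 * state.Omega[..., 1] + common_y
    return c, (Ux, Uy), (Vx, Vy), rho_f, lap_rb, (grx, gry)


def _check_cfl(params, grid, dt, Ux, Uy, rho_g, gamma_s):
    umax = float(np.max(np.hypot(Ux, Uy)))
    diff = max(params.mu * float(rho_g.max()) / params.zeta, gamma_s)
    adv_ok = dt * umax / grid.h < 0.5
    diff_ok = dt * diff / grid.h**2 < 0.25
    if adv_ok and diff_ok:
        return
    dt_sugg = 0.8 * min(
        0.5 * grid.h / umax if umax > 0 else np.inf,
        0.25 * grid.h**2 / diff if diff > 0 else np.inf,
    )
    raise CFLError(
        f"CFL violated: max|U|={umax:.3g}, "
        f"diffusive rate={diff:.3g}; try dt <= {dt_sugg:.3g}",
        suggested_dt=dt_sugg,
    )


def _upwind_div(Ux, Uy, rho, grid: Grid):
    """First-order upwind divergence of the advective flux U rho."""
    h = grid.h

    def axis_flux(u, axis):
        # u at cell centres; face velocity = average of neighbours
        uf = 0.5 * (u + np.roll(u, -1, axis=axis))
        rho_up = np.where(uf > 0, rho, np.roll(rho, -1, axis=axis))
        return uf * rho_up

    fx = axis_flux(Ux, 0)
    fy = axis_flux(Uy, 1)
    return (fx - np.roll(fx, 1, axis=0)) / h + (fy - np.roll(fy, 1, axis=1)) / h


def step_continuum(state: ContinuumState, params: ModelParams, grid: Grid,
                   dt: float, *, scheme: str = "spectral",
                   include_dt_term: bool = True,
                   check_cfl: bool = True) -> ContinuumState:
    """One explicit Euler step; returns a new state (input untouched).

    ``rho_g`` is advanced in conservative flux form; ``Omega`` by projecting
    the full right-hand side onto ``Omega_perp`` node-wise, then
    renormalising to unit length.  Nodes with ``rho_g < 1e-8`` freeze their
    orientation (the equation degenerates in vacuum).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.all(np.isfinite(state.rho_g)):
        raise FloatingPointError("non-finite rho_g; aborting step")
    c, (Ux, Uy), (Vx, Vy), rho_f, lap_rb, (grx, gry) = _velocities(
        state, params, grid, dt, include_dt_term)
    if check_cfl:
        _check_cfl(params, grid, dt, Ux, Uy, state.rho_g, c.gamma_s)

    rho = state.rho_g
    if scheme == "spectral":
        kx, ky, _ = _spectral(grid.Nx, grid.L)
        div = (_ddx(np.fft.fft2(Ux * rho), kx)
               + _ddx(np.fft.fft2(Uy * rho), ky))
    elif scheme == "upwind":
        # split: advective part upwinded, pressure part (mu/zeta) rho grad rho
        # as central flux of grad(rho^2)/2
        ax = Ux + params.mu / params.zeta * grx
        ay = Uy + params.mu / params.zeta * gry
        div = _upwind_div(ax, ay, rho, grid)
        kx, ky, k2 = _spectral(grid.Nx, grid.L)
        div -= params.mu / (2 * params.zeta) * _lap(rho * rho, grid)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    rho_new = rho - dt * div

    om = state.Omega
    # transport term (V . grad) Omega
    dox_x, dox_y = _grad(om[..., 0], grid)
    doy_x, doy_y = _grad(om[..., 1], grid)
    adv_x = Vx * dox_x + Vy * dox_y
    adv_y = Vx * doy_x + Vy * doy_y
    lap_ro_x = _lap(rho * om[..., 0], grid)
    lap_ro_y = _lap(rho * om[..., 1], grid)
    safe = rho > 1e-8
    rho_safe = np.where(safe, rho, 1.0)
    rhs_x = -adv_x + (-c.d3 * grx + c.gamma_s * lap_ro_x) / rho_safe
    rhs_y = -adv_y + (-c.d3 * gry + c.gamma_s * lap_ro_y) / rho_safe
    # project the full right-hand side onto Omega_perp
    dot = rhs_x * om[..., 0] + rhs_y * om[..., 1]
    rhs_x -= dot * om[..., 0]
    rhs_y -= dot * om[..., 1]
    om_new = om.copy()
    om_new[..., 0] += np.where(safe, dt * rhs_x, 0.0)
    om_new[..., 1] += np.where(safe, dt * rhs_y, 0.0)
    norm = np.sqrt(om_new[..., 0] ** 2 + om_new[..., 1] ** 2)
    om_new /= np.where(norm > 0, norm, 1.0)[..., None]

    rho_f_new, _ = _obstacle_density_fields(
        rho_new, lap_rb, params, grid, dt, include_dt_term=include_dt_term)
    # store the pre-step level so the next step's backward difference spans
    # one time level: (lap rhobar^{n+1} - lap rhobar^{n}) / dt
    return ContinuumState(rho_g=rho_new, Omega=om_new, rho_f=rho_f_new,
                          t=state.t + dt, prev_lap_rho_bar=lap_rb)


def mode_amplitude(state: ContinuumState, grid: Grid, mode) -> complex:
    """Complex Fourier amplitude of ``rho_g`` at lattice mode ``(n1, n2)``."""
    F = np.fft.fft2(state.rho_g) / grid.Nx**2
    return complex(F[mode[0] % grid.Nx, mode[1] % grid.Nx])


def measure_mode_growth(params: ModelParams, grid: Grid, mode,
                        *, dt: float = 2e-4, T: float = 0.8,
                        amplitude: float = 1e-6, n_exp: int = 1) -> float:
    """Measured exponential growth/decay rate of a seeded single mode.

    Seeds ``rho_g = 1 + amplitude cos(2 pi mode . x)`` on the uniform state
    and tracks the complex Fourier amplitude while it stays within a decade
    of the seed (so the dynamics remain linear), then fits ``n_exp``
    exponentials by a linear-recurrence (Prony) least-squares fit and
    returns the largest real part.  Use ``n_exp=2`` for wavevectors not
    parallel to ``Omega0``, whose perturbations mix two branches.
    """
    st = init_continuum(params, grid, seed=0, amplitude=0.0)
    X, Y = grid.meshgrid()
    st.rho_g = 1.0 + amplitude * np.cos(
        2.0 * math.pi * (mode[0] * X + mode[1] * Y))
    st.rho_g /= st.rho_g.mean() * grid.L**2
    st.rho_f = obstacle_density(st, params, grid, dt)
    seed_amp = amplitude / 2.0            # cos splits into two conjugate modes
    amps = []
    for _ in range(int(round(T / dt))):
        st = step_continuum(st, params, grid, dt)
        amps.append(mode_amplitude(st, grid, mode))
        if abs(amps[-1]) > 12.0 * seed_amp:
            break
    a = np.array(amps)
    ratio = np.abs(a) / seed_amp
    growing = ratio[-1] > 1.0
    sel = ((ratio > 1.5) & (ratio < 10.0)) if growing else \
          ((ratio < 0.67) & (ratio > 0.1))
    a = a[sel]
    if len(a) < n_exp + 2:
        raise RuntimeError("too few samples in the linear fit window; "
                           "adjust dt or T")
    if n_exp == 1:
        lam = [np.linalg.lstsq(a[:-1, None], a[1:], rcond=None)[0][0]]
    elif n_exp == 2:
        A = np.column_stack([a[1:-1], a[:-2]])
        c1, c0 = np.linalg.lstsq(A, a[2:], rcond=None)[0]
        lam = np.roots([1.0, -c1, -c0])
    else:
        raise ValueError("n_exp must be 1 or 2")
    return max(float(np.log(np.abs(l)) / dt) for l in lam)


class Status(enum.Enum):
    CONTINUE = "continue"
    STOP_NEGATIVE_RHO_F = "stop_negative_rho_f"
    STOP_BLOWUP = "stop_blowup"


def blowup_check(state: ContinuumState, params: ModelParams,
                 *, blowup_factor: float = 50.0) -> Status:
    """Detect loss of validity: negative obstacle density or concentration
    of ``rho_g`` beyond ``blowup_factor`` times its mean."""
    if not np.all(np.isfinite(state.rho_g)) or not np.all(np.isfinite(state.rho_f)):
        return Status.STOP_BLOWUP
    if float(state.rho_f.min()) < 0.0:
        return Status.STOP_NEGATIVE_RHO_F
    if float(state.rho_g.max()) > blowup_factor * float(state.rho_g.mean()):
        return Status.STOP_BLOWUP
    return Status.CONTINUE


@dataclass
class ContinuumConfig:
    """Run configuration for :func:`run_continuum`."""

    T: float = 10.0
    dt: Optional[float] = None        # None: adaptive from CFL each step
    seed: int = 0
    amplitude: float = 1e-2
    save_every: float = 1.0           # snapshot cadence in time units
    scheme: str = "spectral"
    include_dt_term: bool = True
    blowup_factor: float = 50.0
    cfl: float = 0.4


@dataclass
class ContinuumRun:
    snapshots: list            # list of ContinuumState copies
    status: Status
    final: ContinuumState      # last valid state

    @property
    def times(self):
        return [s.t for s in self.snapshots]


def _auto_dt(state, params, grid, cfl, gamma_s, include_dt_term):
    _, (Ux, Uy), _, _, _, _ = _velocities(state, params, grid, 1.0,
                                          include_dt_term)
    umax = float(np.max(np.hypot(Ux, Uy)))
    diff = max(params.mu * float(state.rho_g.max()) / params.zeta, gamma_s)
    dt = cfl * min(0.5 * grid.h / max(umax, 1e-12),
                   0.25 * grid.h**2 / max(diff, 1e-12))
    return min(dt, 5e-3)


def run_continuum(params: ModelParams, grid: Grid,
                  config: Optional[ContinuumConfig] = None,
                  callbacks: Optional[list] = None) -> ContinuumRun:
    """Integrate to ``T`` or early stop; snapshots of ``(rho_g, Omega, rho_f)``.

    The last valid state before a stop is preserved in ``final``.
    """
    cfg = config or ContinuumConfig()
    c = compute_constants(params.ratio, params.u0, params.rA)
    state = init_continuum(params, grid, cfg.seed, cfg.amplitude)
    snapshots = [state.copy()]
    next_save = cfg.save_every
    status = Status.CONTINUE
    last_valid = state
    while state.t < cfg.T - 1e-12:
        dt = cfg.dt or _auto_dt(state, params, grid, cfg.cfl, c.gamma_s,
                                cfg.include_dt_term)
        dt = min(dt, cfg.T - state.t)
        try:
            new = step_continuum(state, params, grid, dt, scheme=cfg.scheme,
                                 include_dt_term=cfg.include_dt_term,
                                 check_cfl=cfg.dt is not None)
        except (FloatingPointError, CFLError):
            status = Status.STOP_BLOWUP
            break
        status = blowup_check(new, params, blowup_factor=cfg.blowup_factor)
        if status is not Status.CONTINUE:
            break
        state = new
        last_valid = state
        if callbacks:
            for cb in callbacks:
                cb(state)
        if state.t >= next_save - 1e-12:
            snapshots.append(state.copy())
            next_save += cfg.save_every
    if snapshots[-1].t < last_valid.t:
        snapshots.append(last_valid.copy())
    return ContinuumRun(snapshots=snapshots, status=status, final=last_valid)
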