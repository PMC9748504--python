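"""Measured pattern sizes from a gridded density via the 2-D DFT.

The realized pattern size along a direction is read off the discrete
Fourier spectrum of the density: among lattice modes ``k = 2 pi (n1, n2)``
within an angular tolerance of the reference direction (``Omega0`` or its
perpendicular), the modulus-maximising mode ``k*`` gives ``S = 2 pi / |k*|``.
A direction reports no pattern when its best mode does not rise above
``noise_floor`` times the mean nonzero-mode modulus.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np

__all__ = ["measured_sizes"]


def _direction_best(modulus: np.ndarray, nx: np.ndarray, ny: np.ndarray,
                    direction: np.ndarray, angle_tol: float,
                    noise_floor: float, mean_mod: float, L: float
                    ) -> Optional[float]:
    nn = np.hypot(nx, ny)
    nonzero = nn > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.abs(nx * direction[0] + ny * direction[1]) / np.where(
            nonzero, nn, 1.0)
    sel = nonzero & (cosang >= math.cos(angle_tol))
    if not np.any(sel):
        return None
    mods = modulus[sel]
    best = float(mods.max())
    if best <= noise_floor * mean_mod:       # catches the all-zero spectrum too
        return None
    nn_best = nn[sel][int(np.argmax(mods))]
    return L / float(nn_best)          # S = 2 pi / |k| = L / |n|


def measured_sizes(rho: np.ndarray, Omega0, *, L: float = 1.0,
                   angle_tol_deg: float = 10.0, noise_floor: float = 5.0
                   ) -> Tuple[Optional[float], Optional[float]]:
    """Pattern sizes ``(S1, S2)`` along ``Omega0`` and ``Omega0_perp``.

    ``None`` means no mode above the noise floor in that direction (e.g.
    travelling bands give ``S2 = None``; a uniform field gives both).  The
    modulus spectrum makes the measurement invariant under cyclic shifts of
    the field.
    """
    rho = np.asarray(rho, dtype=float)
    if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
        raise ValueError("rho must be a square 2-D field")
    if np.any(rho <= 0) or not np.all(np.isfinite(rho)):
        raise ValueError("rho must be strictly positive and finite")
    om = np.asarray(Omega0, dtype=float)
    om = om / np.linalg.norm(om)
    om_perp = np.array([-om[1], om[0]])

    Nx = rho.shape[0]
    F = np.fft.fft2(rho)
    modulus = np.abs(F)
    n = np.fft.fftfreq(Nx) * Nx
    nx, ny = np.meshgrid(n, n, indexing="ij")
    nonzero = np.hypot(nx, ny) > 0
    mean_mod = float(modulus[nonzero].mean())
    tol = math.radians(angle_tol_deg)
    S1 = _direction_best(modulus, nx, ny, om, tol, noise_floor, mean_mod, L)
    S2 = _direction_best(modulus, nx, ny, om_perp, tol, noise_floor, mean_mod, L)
    return S1, S2
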