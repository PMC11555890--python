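"""Numba-compiled inner loops for the Monte Carlo sampler.

These mirror the vectorized reference in :mod:`nanosolv.forcefield` exactly
(same cutoff convention, same minimum image); equality of the two paths is
asserted in the test suite.  All energies kcal/mol, distances angstrom.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def _min_image_comp(d: float, edge: float) -> float:
    return d - edge * np.floor(d / edge + 0.5)


@njit(cache=True, fastmath=False)
def water_water_one(
    waters: np.ndarray,  # (Nw, 3, 3)
    index: int,
    coords: np.ndarray,  # (3, 3)
    box: np.ndarray,  # (3,)
    periodic: bool,
    cutoff2: float,
    qw: np.ndarray,  # (3,)
    sigma_o: float,
    eps_o: float,
    k_coulomb: float,
) -> float:
    """Water-water energy of one molecule at given coordinates vs all others."""
    nw = waters.shape[0]
    energy = 0.0
    ox, oy, oz = coords[0, 0], coords[0, 1], coords[0, 2]
    s2 = sigma_o * sigma_o
    for j in range(nw):
        if j == index:
            continue
        dx = waters[j, 0, 0] - ox
        dy = waters[j, 0, 1] - oy
        dz = waters[j, 0, 2] - oz
        if periodic:
            dx = _min_image_comp(dx, box[0])
            dy = _min_image_comp(dy, box[1])
            dz = _min_image_comp(dz, box[2])
        r2_oo = dx * dx + dy * dy + dz * dz
        if r2_oo > cutoff2:
            continue
        for a in range(3):
            for b in range(3):
                ddx = coords[a, 0] - waters[j, b, 0]
                ddy = coords[a, 1] - waters[j, b, 1]
                ddz = coords[a, 2] - waters[j, b, 2]
                if periodic:
                    ddx = _min_image_comp(ddx, box[0])
                    ddy = _min_image_comp(ddy, box[1])
                    ddz = _min_image_comp(ddz, box[2])
                r2 = ddx * ddx + ddy * ddy + ddz * ddz
                r = np.sqrt(r2)
                energy += k_coulomb * qw[a] * qw[b] / r
                if a == 0 and b == 0:
                    sr6 = (s2 / r2) ** 3
                    energy += 4.0 * eps_o * (sr6 * sr6 - sr6)
    return energy


@njit(cache=True, fastmath=False)
def solute_water_one(
    coords: np.ndarray,  # (3, 3) water sites
    solute_pos: np.ndarray,  # (Ns, 3)
    solute_q: np.ndarray,
    mixed_sigma: np.ndarray,
    mixed_eps: np.ndarray,
    qw: np.ndarray,
    box: np.ndarray,
    periodic: bool,
    k_coulomb: float,
    charge_scale: float,
    lj_lambda: float,
    alpha: float,
) -> np.ndarray:
    """Solute-water (vdw, elec) for one water; supports alchemical scaling."""
    ns = solute_pos.shape[0]
    vdw = 0.0
    elec = 0.0
    for s in range(ns):
        for a in range(3):
            dx = coords[a, 0] - solute_pos[s, 0]
            dy = coords[a, 1] - solute_pos[s, 1]
            dz = coords[a, 2] - solute_pos[s, 2]
            if periodic:
                dx = _min_image_comp(dx, box[0])
                dy = _min_image_comp(dy, box[1])
                dz = _min_image_comp(dz, box[2])
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            if r > 1e-12:
                elec += charge_scale * k_coulomb * qw[a] * solute_q[s] / r
            if a == 0 and mixed_eps[s] > 0.0:
                s6 = mixed_sigma[s] ** 6
                denom = alpha * s6 * (1.0 - lj_lambda) + r2 * r2 * r2
                if denom > 0.0:
                    frac = s6 / denom
                    vdw += 4.0 * mixed_eps[s] * lj_lambda * (frac * frac - frac)
    out = np.empty(2)
    out[0] = vdw
    out[1] = elec
    return out


@njit(cache=True, fastmath=False)
def total_water_water(
    waters: np.ndarray,
    box: np.ndarray,
    periodic: bool,
    cutoff2: float,
    qw: np.ndarray,
    sigma_o: float,
    eps_o: float,
    k_coulomb: float,
) -> float:
    """Full water-water sum over unique pairs (molecule-based O-O cutoff)."""
    nw = waters.shape[0]
    energy = 0.0
    s2 = sigma_o * sigma_o
    for i in range(nw - 1):
        for j in range(i + 1, nw):
            dx = waters[j, 0, 0] - waters[i, 0, 0]
            dy = waters[j, 0, 1] - waters[i, 0, 1]
            dz = waters[j, 0, 2] - waters[i, 0, 2]
            if periodic:
                dx = _min_image_comp(dx, box[0])
                dy = _min_image_comp(dy, box[1])
                dz = _min_image_comp(dz, box[2])
            r2_oo = dx * dx + dy * dy + dz * dz
            if r2_oo > cutoff2:
                continue
            for a in range(3):
                for b in range(3):
                    ddx = waters[i, a, 0] - waters[j, b, 0]
                    ddy = waters[i, a, 1] - waters[j, b, 1]
                    ddz = waters[i, a, 2] - waters[j, b, 2]
                    if periodic:
                        ddx = _min_image_comp(ddx, box[0])
                        ddy = _min_image_comp(ddy, box[1])
                        ddz = _min_image_comp(ddz, box[2])
                    r2 = ddx * ddx + ddy * ddy + ddz * ddz
                    r = np.sqrt(r2)
                    energy += k_coulomb * qw[a] * qw[b] / r
                    if a == 0 and b == 0:
                        sr6 = (s2 / r2) ** 3
                        energy += 4.0 * eps_o * (sr6 * sr6 - sr6)
    return energy


@njit(cache=True, fastmath=False)
def total_solute_water(
    waters: np.ndarray,
    solute_pos: np.ndarray,
    solute_q: np.ndarray,
    mixed_sigma: np.ndarray,
    mixed_eps: np.ndarray,
    qw: np.ndarray,
    box: np.ndarray,
    periodic: bool,
    k_coulomb: float,
    charge_scale: float,
    lj_lambda: float,
    alpha: float,
) -> np.ndarray:
    """Solute-water (vdw, elec) summed over all waters."""
    out = np.zeros(2)
    for i in range(waters.shape[0]):
        part = solute_water_one(
            waters[i], solute_pos, solute_q, mixed_sigma, mixed_eps, qw,
            box, periodic, k_coulomb, charge_scale, lj_lambda, alpha,
        )
        out[0] += part[0]
        out[1] += part[1]
    return out
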