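"""Pairwise intermolecular energy model.

TIP3P water-water interactions plus Lennard-Jones + Coulomb solute-water
terms with Lorentz-Berthelot mixing, evaluated under the minimum-image
convention in an origin-centered periodic box.  Only intermolecular terms
exist: molecules are rigid and carry no internal energy.

Cutoff convention: water-water pairs interact (all nine site terms) if and
only if the minimum-image O-O distance is within the cutoff, which keeps a
water's energy well defined under whole-molecule moves.  Solute-water terms
are always evaluated -- the solutes of interest (nanotubes and their drug
complexes) span a large fraction of the box, so a single-reference-site
cutoff would be meaningless for them.

No Ewald summation and no tail corrections are applied: the sampling
protocol this mirrors uses plain truncated minimum-image electrostatics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structures import SolvatedSystem

__all__ = [
    "COULOMB_CONSTANT",
    "LJPair",
    "FFConfig",
    "EnergyBreakdown",
    "tip3p_parameters",
    "combine_lorentz_berthelot",
    "lj_energy",
    "softcore_lj_energy",
    "coulomb_energy",
    "minimum_image",
    "pack_system",
    "intermolecular_energy",
    "molecule_delta_energy",
    "water_interaction_energy",
]

#: Coulomb prefactor in kcal angstrom mol^-1 e^-2 (vacuum permittivity,
#: dielectric constant 1 -- the solvent is explicit).
COULOMB_CONSTANT = 332.0636


@dataclass(frozen=True)
class LJPair:
    """Lennard-Jones parameters (sigma in angstrom, epsilon in kcal/mol)."""

    sigma: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.epsilon < 0:
            raise ValueError("LJ parameters must be non-negative")

    @property
    def a_coefficient(self) -> float:
        """Repulsive 12-power coefficient A = 4 eps sigma^12."""
        return 4.0 * self.epsilon * self.sigma ** 12

    @property
    def c_coefficient(self) -> float:
        """Attractive 6-power coefficient C = 4 eps sigma^6."""
        return 4.0 * self.epsilon * self.sigma ** 6


@dataclass(frozen=True)
class FFConfig:
    """Evaluation settings for the pair potential."""

    cutoff: float = 12.0
    coulomb_constant: float = COULOMB_CONSTANT
    use_minimum_image: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def validate_box(self, box) -> None:
        if self.use_minimum_image and box.periodic:
            if self.cutoff > min(box.edge_lengths) / 2 + 1e-9:
                raise ValueError("cutoff exceeds half the smallest box edge")


@dataclass(frozen=True)
class EnergyBreakdown:
    """Intermolecular energy decomposition (kcal/mol).

    ``solute_water`` always equals ``vdw_solute_water + elec_solute_water``
    and ``total`` equals ``solute_water + water_water`` by construction.
    """

    solute_water: float
    water_water: float
    vdw_solute_water: float
    elec_solute_water: float

    @property
    def total(self) -> float:
        return self.solute_water + self.water_water


def tip3p_parameters() -> dict:
    """Standard TIP3P site parameters (charges e; sigma A; epsilon kcal/mol)."""
    return {
        "O": {"charge": -0.834, "sigma": 3.15061, "epsilon": 0.1521},
        "H": {"charge": 0.417, "sigma": 0.0, "epsilon": 0.0},
    }


def combine_lorentz_berthelot(p1: LJPair, p2: LJPair) -> LJPair:
    """Arithmetic-mean sigma, geometric-mean epsilon cross parameters."""
    return LJPair(0.5 * (p1.sigma + p2.sigma), math.sqrt(p1.epsilon * p2.epsilon))


def lj_energy(pair: LJPair, r: float) -> float:
    """4 eps [(sigma/r)^12 - (sigma/r)^6] at separation r > 0."""
    if r <= 0:
        raise ValueError("separation must be positive")
    sr6 = (pair.sigma / r) ** 6
    return 4.0 * pair.epsilon * (sr6 * sr6 - sr6)


def softcore_lj_energy(pair: LJPair, r: float, lam: float, alpha: float = 0.5) -> float:
    """Soft-core LJ used for alchemical decoupling.

    U(lambda) = 4 eps lambda [ (sigma^6 / (alpha sigma^6 (1-lambda) + r^6))^2
                               - sigma^6 / (alpha sigma^6 (1-lambda) + r^6) ]
    Reduces to the plain potential at lambda = 1 and stays finite at r -> 0
    for lambda < 1.
    """
    if r < 0:
        raise ValueError("separation must be non-negative")
    s6 = pair.sigma ** 6
    denom = alpha * s6 * (1.0 - lam) + r ** 6
    if denom <= 0:
        raise ValueError("soft-core denominator vanished")
    frac = s6 / denom
    return 4.0 * pair.epsilon * lam * (frac * frac - frac)


def coulomb_energy(q1: float, q2: float, r: float, config: FFConfig = FFConfig()) -> float:
    """Point-charge interaction k q1 q2 / r in kcal/mol."""
    if r <= 0:
        raise ValueError("separation must be positive")
    return config.coulomb_constant * q1 * q2 / r


def minimum_image(displacement: np.ndarray, box) -> np.ndarray:
    """Map a displacement vector into the nearest periodic image."""
    disp = np.asarray(displacement, dtype=float)
    if not box.periodic:
        return disp
    edges = box.edges_array()
    # floor-based wrap keeps the result in [-L/2, L/2) even at the boundary
    return disp - edges * np.floor(disp / edges + 0.5)


# ---------------------------------------------------------------------------
# packed-array evaluation
# ---------------------------------------------------------------------------


@dataclass
class PackedSystem:
    """Flat-array view of a SolvatedSystem for vectorized/numba evaluation."""

    waters: np.ndarray  # (Nw, 3, 3) sites: O, H, H
    water_charges: np.ndarray  # (3,)
    water_sigma_o: float
    water_eps_o: float
    solute_pos: np.ndarray  # (Ns, 3)
    solute_charges: np.ndarray  # (Ns,)
    mixed_sigma: np.ndarray  # (Ns,) LB sigma with water O
    mixed_eps: np.ndarray  # (Ns,)
    box_edges: np.ndarray  # (3,)
    periodic: bool
    cutoff: float
    coulomb_constant: float
    temperature: float


def pack_system(system: SolvatedSystem, config: FFConfig = FFConfig()) -> PackedSystem:
    config.validate_box(system.box)
    waters = system.water_array()
    for w in system.waters:
        if w.positions.shape != (3, 3) or w.elements[0] != "O":
            raise ValueError("waters must be 3-site molecules with O first")
    tip = tip3p_parameters()
    if system.waters:
        first = system.waters[0]
        wq = first.charges.astype(float).copy()
        w_sigma = float(first.lj_sigma[0])
        w_eps = float(first.lj_epsilon[0])
        for w in system.waters:
            if (not np.array_equal(w.charges, wq)
                    or w.lj_sigma[0] != w_sigma or w.lj_epsilon[0] != w_eps):
                raise ValueError("all waters must share identical site parameters")
    else:
        wq = np.array([tip["O"]["charge"], tip["H"]["charge"], tip["H"]["charge"]])
        w_sigma = tip["O"]["sigma"]
        w_eps = tip["O"]["epsilon"]
    if system.solute is not None:
        spos = system.solute.positions.astype(float)
        sq = system.solute.charges.astype(float)
        o_pair = LJPair(w_sigma, w_eps)
        mixed = [
            combine_lorentz_berthelot(LJPair(s, e), o_pair)
            for s, e in zip(system.solute.lj_sigma, system.solute.lj_epsilon)
        ]
        msig = np.array([m.sigma for m in mixed])
        meps = np.array([m.epsilon for m in mixed])
    else:
        spos = np.zeros((0, 3))
        sq = np.zeros(0)
        msig = np.zeros(0)
        meps = np.zeros(0)
    return PackedSystem(
        waters=waters,
        water_charges=wq,
        water_sigma_o=w_sigma,
        water_eps_o=w_eps,
        solute_pos=spos,
        solute_charges=sq,
        mixed_sigma=msig,
        mixed_eps=meps,
        box_edges=system.box.edges_array(),
        periodic=system.box.periodic,
        cutoff=config.cutoff,
        coulomb_constant=config.coulomb_constant,
        temperature=system.temperature,
    )


def _min_image_array(delta: np.ndarray, packed: PackedSystem) -> np.ndarray:
    if not packed.periodic:
        return delta
    return delta - packed.box_edges * np.floor(delta / packed.box_edges + 0.5)


def _water_water_energy(packed: PackedSystem) -> tuple[float, float]:
    """Total water-water (vdw, elec) with the molecule-based O-O cutoff."""
    W = packed.waters
    nw = W.shape[0]
    if nw < 2:
        return 0.0, 0.0
    oxy = W[:, 0, :]
    d_oo = _min_image_array(oxy[:, None, :] - oxy[None, :, :], packed)
    r2_oo = np.einsum("ijk,ijk->ij", d_oo, d_oo)
    iu, ju = np.triu_indices(nw, k=1)
    mask = r2_oo[iu, ju] <= packed.cutoff ** 2
    i_sel, j_sel = iu[mask], ju[mask]
    if i_sel.size == 0:
        return 0.0, 0.0
    # site-site distances for all nine pairs of the selected molecule pairs
    a = W[i_sel][:, :, None, :]  # (P, 3, 1, 3)
    b = W[j_sel][:, None, :, :]  # (P, 1, 3, 3)
    delta = _min_image_array(a - b, packed)
    r2 = np.einsum("pijk,pijk->pij", delta, delta)
    if np.any(r2 < 1e-12):
        raise ValueError("overlapping sites encountered")
    r = np.sqrt(r2)
    qq = packed.water_charges[:, None] * packed.water_charges[None, :]
    elec = packed.coulomb_constant * np.sum(qq[None, :, :] / r)
    sr6 = (packed.water_sigma_o ** 2 / r2[:, 0, 0]) ** 3
    vdw = float(np.sum(4.0 * packed.water_eps_o * (sr6 * sr6 - sr6)))
    return vdw, float(elec)


def _solute_water_energy(
    packed: PackedSystem,
    water_coords: np.ndarray | None = None,
    charge_scale: float = 1.0,
    lj_lambda: float = 1.0,
    alpha: float = 0.5,
) -> tuple[float, float]:
    """Solute-water (vdw, elec); optionally alchemically scaled."""
    if packed.solute_pos.shape[0] == 0:
        return 0.0, 0.0
    W = packed.waters if water_coords is None else water_coords
    if W.ndim == 2:
        W = W[None, :, :]
    if W.shape[0] == 0:
        return 0.0, 0.0
    sites = W.reshape(-1, 3)
    delta = _min_image_array(sites[:, None, :] - packed.solute_pos[None, :, :], packed)
    r2 = np.einsum("ijk,ijk->ij", delta, delta)
    if np.any(r2 < 1e-12) and lj_lambda >= 1.0:
        raise ValueError("overlapping sites encountered")
    r = np.sqrt(r2)
    qw = np.tile(packed.water_charges, W.shape[0])
    elec = charge_scale * packed.coulomb_constant * float(
        np.sum(qw[:, None] * packed.solute_charges[None, :] / np.maximum(r, 1e-12))
    )
    # LJ acts on water oxygens only (H sites have zero parameters)
    r2_o = r2[0::3, :]
    s6 = packed.mixed_sigma[None, :] ** 6
    denom = alpha * s6 * (1.0 - lj_lambda) + r2_o ** 3
    frac = np.where(s6 > 0, s6 / np.maximum(denom, 1e-300), 0.0)
    vdw = float(np.sum(4.0 * packed.mixed_eps[None, :] * lj_lambda * (frac * frac - frac)))
    return vdw, elec


def intermolecular_energy(
    system: SolvatedSystem | PackedSystem, config: FFConfig = FFConfig()
) -> EnergyBreakdown:
    """Full intermolecular energy decomposition of a solvated system."""
    packed = system if isinstance(system, PackedSystem) else pack_system(system, config)
    ww_vdw, ww_elec = _water_water_energy(packed)
    sw_vdw, sw_elec = _solute_water_energy(packed)
    return EnergyBreakdown(
        solute_water=sw_vdw + sw_elec,
        water_water=ww_vdw + ww_elec,
        vdw_solute_water=sw_vdw,
        elec_solute_water=sw_elec,
    )


def water_interaction_energy(
    packed: PackedSystem,
    index: int,
    coords: np.ndarray,
    charge_scale: float = 1.0,
    lj_lambda: float = 1.0,
    alpha: float = 0.5,
) -> float:
    """Energy of water ``index`` at ``coords`` with everything else (kcal/mol)."""
    nw = packed.waters.shape[0]
    if not 0 <= index < nw:
        raise IndexError("water index out of range")
    coords = np.asarray(coords, float).reshape(3, 3)
    total = 0.0
    if nw > 1:
        others = np.delete(packed.waters, index, axis=0)
        d_oo = _min_image_array(others[:, 0, :] - coords[0], packed)
        near = np.einsum("ij,ij->i", d_oo, d_oo) <= packed.cutoff ** 2
        sel = others[near]
        if sel.shape[0]:
            delta = _min_image_array(coords[None, :, None, :] - sel[:, None, :, :], packed)
            r2 = np.einsum("pijk,pijk->pij", delta, delta)
            if np.any(r2 < 1e-12):
                raise ValueError("overlapping sites encountered")
            r = np.sqrt(r2)
            qq = packed.water_charges[:, None] * packed.water_charges[None, :]
            total += packed.coulomb_constant * float(np.sum(qq[None] / r))
            sr6 = (packed.water_sigma_o ** 2 / r2[:, 0, 0]) ** 3
            total += float(np.sum(4.0 * packed.water_eps_o * (sr6 * sr6 - sr6)))
    sw_vdw, sw_elec = _solute_water_energy(
        packed, coords, charge_scale=charge_scale, lj_lambda=lj_lambda, alpha=alpha
    )
    return total + sw_vdw + sw_elec


def molecule_delta_energy(
    system: SolvatedSystem,
    molecule_index: int,
    trial_coordinates: np.ndarray,
    config: FFConfig = FFConfig(),
) -> float:
    """Energy change from moving one water to trial coordinates.

    Identical (to numerical precision) to the difference of two full
    recomputations, but evaluated from the moved molecule's interactions only.
    """
    packed = pack_system(system, config)
    e_old = water_interaction_energy(packed, molecule_index, packed.waters[molecule_index])
    e_new = water_interaction_energy(packed, molecule_index, trial_coordinates)
    return e_new - e_old
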