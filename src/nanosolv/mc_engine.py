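"""Canonical-ensemble Metropolis Monte Carlo over rigid waters.

A fixed rigid solute sits in a periodic box of rigid TIP3P waters; each step
translates one randomly chosen water by up to +-0.13 angstrom per axis and
rotates it by up to +-10 degrees about a random axis through its oxygen (the
step sizes that give roughly 50% acceptance in bulk water).  Acceptance is
the textbook Metropolis criterion; the sampler reports the realized
acceptance ratio rather than enforcing one.

Incremental energies are used throughout; the running totals are resynced
against a full recomputation periodically and the worst observed drift is
reported, so bookkeeping errors cannot silently bias the averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .forcefield import EnergyBreakdown, FFConfig, PackedSystem, pack_system
from .geometry import rotation_about_axis
from .qm_records import GAS_CONSTANT_KCAL
from .structures import SolvatedSystem

__all__ = [
    "MCConfig",
    "MCResult",
    "CouplingState",
    "propose_move",
    "metropolis_accept",
    "run_mc",
    "mean_energy_report",
]


@dataclass(frozen=True)
class CouplingState:
    """Alchemical scaling of the solute-water interaction.

    ``charge_scale`` multiplies solute charges linearly; ``lj_lambda`` drives
    the soft-core Lennard-Jones decoupling.  (1, 1) is the physical state.
    """

    charge_scale: float = 1.0
    lj_lambda: float = 1.0
    softcore_alpha: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.charge_scale <= 1.0 and 0.0 <= self.lj_lambda <= 1.0):
            raise ValueError("coupling scales must lie in [0, 1]")


@dataclass(frozen=True)
class MCConfig:
    """Sampling protocol settings."""

    n_steps: int
    temperature: float = 298.0
    translation_step: float = 0.13  # angstrom, per axis
    rotation_step: float = 10.0  # degrees
    seed: int = 0
    equilibration_fraction: float = 0.2
    snapshot_stride: int = 1000
    energy_stride: int = 10
    resync_stride: int = 100_000
    #: optional larger moves during equilibration only -- any step size
    #: satisfies detailed balance, and wider moves melt the initial lattice
    #: configuration far faster than the production step sizes
    equil_translation_step: float | None = None
    equil_rotation_step: float | None = None

    def __post_init__(self) -> None:
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if self.translation_step < 0 or self.rotation_step < 0:
            raise ValueError("step sizes must be non-negative")
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise ValueError("equilibration fraction must be in [0, 1)")
        if self.snapshot_stride <= 0 or self.energy_stride <= 0:
            raise ValueError("strides must be positive")

    @property
    def n_equilibration(self) -> int:
        return int(self.n_steps * self.equilibration_fraction)

    @property
    def n_production(self) -> int:
        return self.n_steps - self.n_equilibration


@dataclass
class MCResult:
    """Outputs of one Markov chain."""

    mean_breakdown: EnergyBreakdown
    acceptance_ratio: float
    trajectory: list[np.ndarray]
    final_state: SolvatedSystem
    rng_provenance: str
    n_production: int
    series: pd.DataFrame = field(repr=False, default=None)
    max_drift: float = 0.0


def propose_move(
    system: SolvatedSystem | np.ndarray,
    water_index: int,
    config: MCConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Trial coordinates for one rigid water move.

    Uniform translation in [-t, +t] per axis plus rotation by a uniform angle
    in [-rot, +rot] about a random axis (isotropic via a normalized Gaussian
    triple) through the water oxygen.  Internal geometry is exactly preserved.
    """
    coords = (
        system.waters[water_index].positions
        if isinstance(system, SolvatedSystem)
        else np.asarray(system, float)[water_index]
    )
    return _propose(coords, config.translation_step, config.rotation_step, rng)


def _propose(
    coords: np.ndarray, trans_step: float, rot_step_deg: float, rng: np.random.Generator
) -> np.ndarray:
    shift = rng.uniform(-trans_step, trans_step, size=3)
    axis = rng.normal(size=3)
    while np.linalg.norm(axis) < 1e-12:  # pragma: no cover - measure zero
        axis = rng.normal(size=3)
    angle = math.radians(rng.uniform(-rot_step_deg, rot_step_deg))
    rot = rotation_about_axis(axis, angle)
    oxygen = coords[0]
    return (coords - oxygen) @ rot.T + oxygen + shift


def metropolis_accept(
    delta_e: float,
    temperature: float,
    rng: np.random.Generator,
    gas_constant: float = GAS_CONSTANT_KCAL,
) -> bool:
    """Accept downhill moves always, uphill with probability exp(-dE/RT)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0.0:
        return True
    exponent = -delta_e / (gas_constant * temperature)
    if exponent < -700.0:
        return False
    return rng.random() < math.exp(exponent)


def _wrap_molecule(coords: np.ndarray, box: np.ndarray, periodic: bool) -> np.ndarray:
    """Wrap by the oxygen position, shifting the whole molecule rigidly."""
    if not periodic:
        return coords
    o = coords[0]
    wrapped = (o + box / 2) % box - box / 2
    return coords + (wrapped - o)


def run_mc(
    system: SolvatedSystem,
    config: MCConfig,
    ff_config: FFConfig = FFConfig(),
    coupling: CouplingState = CouplingState(),
) -> MCResult:
    """Run a Metropolis chain of single-water moves around a fixed solute."""
    if config.n_production <= 0:
        raise ValueError("no production steps")
    if system.n_waters == 0:
        raise ValueError("system has no waters to move")
    packed = pack_system(system, ff_config)
    rng = np.random.default_rng(config.seed)
    temperature = config.temperature

    W = packed.waters.copy()
    box = packed.box_edges
    periodic = packed.periodic
    cutoff2 = packed.cutoff ** 2
    qw = packed.water_charges
    sig_o, eps_o = packed.water_sigma_o, packed.water_eps_o
    k_c = packed.coulomb_constant
    cs, lj_l, alpha = coupling.charge_scale, coupling.lj_lambda, coupling.softcore_alpha
    has_solute = packed.solute_pos.shape[0] > 0

    def full_ww() -> float:
        return _kernels.total_water_water(W, box, periodic, cutoff2, qw, sig_o, eps_o, k_c)

    def full_sw() -> np.ndarray:
        if not has_solute:
            return np.zeros(2)
        return _kernels.total_solute_water(
            W, packed.solute_pos, packed.solute_charges, packed.mixed_sigma,
            packed.mixed_eps, qw, box, periodic, k_c, cs, lj_l, alpha,
        )

    e_ww = full_ww()
    sw = full_sw()
    if not (math.isfinite(e_ww) and np.all(np.isfinite(sw))):
        raise RuntimeError("non-finite energy in the initial configuration")

    nw = W.shape[0]
    n_accept = 0
    acc_ww = acc_sw_vdw = acc_sw_elec = 0.0
    n_prod_seen = 0
    snapshots: list[np.ndarray] = []
    series_rows: list[tuple] = []
    max_drift = 0.0

    n_equil = config.n_equilibration
    eq_trans = (config.equil_translation_step
                if config.equil_translation_step is not None
                else config.translation_step)
    eq_rot = (config.equil_rotation_step
              if config.equil_rotation_step is not None
              else config.rotation_step)

    for step in range(1, config.n_steps + 1):
        i = int(rng.integers(nw))
        if step <= n_equil:
            trial = _propose(W[i], eq_trans, eq_rot, rng)
        else:
            trial = _propose(W[i], config.translation_step, config.rotation_step, rng)
        trial = _wrap_molecule(trial, box, periodic)

        e_old = _kernels.water_water_one(
            W, i, W[i], box, periodic, cutoff2, qw, sig_o, eps_o, k_c
        )
        e_new = _kernels.water_water_one(
            W, i, trial, box, periodic, cutoff2, qw, sig_o, eps_o, k_c
        )
        if has_solute:
            sw_old = _kernels.solute_water_one(
                W[i], packed.solute_pos, packed.solute_charges, packed.mixed_sigma,
                packed.mixed_eps, qw, box, periodic, k_c, cs, lj_l, alpha,
            )
            sw_new = _kernels.solute_water_one(
                trial, packed.solute_pos, packed.solute_charges, packed.mixed_sigma,
                packed.mixed_eps, qw, box, periodic, k_c, cs, lj_l, alpha,
            )
        else:
            sw_old = sw_new = np.zeros(2)

        delta = (e_new - e_old) + (sw_new[0] - sw_old[0]) + (sw_new[1] - sw_old[1])
        if not math.isfinite(delta):
            raise RuntimeError(
                f"non-finite trial energy at step {step} (water {i}); "
                "configuration snapshot preserved in final_state"
            )
        if metropolis_accept(delta, temperature, rng):
            W[i] = trial
            e_ww += e_new - e_old
            sw = sw + (sw_new - sw_old)
            if step > n_equil:
                n_accept += 1

        if config.resync_stride and step % config.resync_stride == 0:
            exact_ww = full_ww()
            exact_sw = full_sw()
            max_drift = max(
                max_drift,
                abs(exact_ww - e_ww),
                float(np.max(np.abs(exact_sw - sw))),
            )
            e_ww, sw = exact_ww, exact_sw

        if step > config.n_equilibration:
            n_prod_seen += 1
            acc_ww += e_ww
            acc_sw_vdw += sw[0]
            acc_sw_elec += sw[1]
            if n_prod_seen % config.energy_stride == 0:
                series_rows.append((step, e_ww, sw[0], sw[1]))
            if n_prod_seen % config.snapshot_stride == 0:
                snapshots.append(W.copy())

    mean = EnergyBreakdown(
        solute_water=(acc_sw_vdw + acc_sw_elec) / n_prod_seen,
        water_water=acc_ww / n_prod_seen,
        vdw_solute_water=acc_sw_vdw / n_prod_seen,
        elec_solute_water=acc_sw_elec / n_prod_seen,
    )
    series = pd.DataFrame(
        series_rows, columns=["step", "water_water", "sw_vdw", "sw_elec"]
    )
    return MCResult(
        mean_breakdown=mean,
        acceptance_ratio=n_accept / config.n_production,
        trajectory=snapshots,
        final_state=system.with_water_array(W),
        rng_provenance=f"numpy.default_rng(PCG64), seed={config.seed}",
        n_production=n_prod_seen,
        series=series,
        max_drift=max_drift,
    )


def _block_stderr(values: np.ndarray, n_blocks: int = 10) -> float:
    values = np.asarray(values, float)
    if values.size < n_blocks:
        n_blocks = max(2, values.size)
    if values.size < 2:
        return float("nan")
    blocks = np.array_split(values, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / math.sqrt(len(means)))


def mean_energy_report(result: MCResult) -> dict:
    """Summary record: water count, mean energies and block-averaged errors."""
    if result.n_production <= 0 or result.series is None or len(result.series) == 0:
        raise ValueError("no production samples to report")
    s = result.series
    sw = s["sw_vdw"] + s["sw_elec"]
    total = sw + s["water_water"]
    return {
        "n_h2o": result.final_state.n_waters,
        "e_solute_water": result.mean_breakdown.solute_water,
        "e_total": result.mean_breakdown.total,
        "vdw_contribution": result.mean_breakdown.vdw_solute_water,
        "elec_contribution": result.mean_breakdown.elec_solute_water,
        "stderr_solute_water": _block_stderr(sw.to_numpy()),
        "stderr_total": _block_stderr(total.to_numpy()),
        "stderr_vdw": _block_stderr(s["sw_vdw"].to_numpy()),
        "stderr_elec": _block_stderr(s["sw_elec"].to_numpy()),
        "acceptance_ratio": result.acceptance_ratio,
    }
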