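import numpy as np
import pytest

from nanosolv.forcefield import FFConfig
from nanosolv.structures import (
    SimulationBox,
    assign_charges,
    build_drug_surrogate,
    build_water_box,
    solvate,
)


@pytest.fixture(scope="session")
def small_water_box():
    """~57 TIP3P waters in a 12 A periodic cube."""
    return build_water_box(SimulationBox.cubic(12.0), density=0.993, seed=7)


@pytest.fixture(scope="session")
def charged_drug():
    return assign_charges(
        build_drug_surrogate(), {"O4": -0.821, "N_py": -0.640}, neutralize=True
    )


@pytest.fixture(scope="session")
def solvated_drug(small_water_box, charged_drug):
    return solvate(charged_drug, small_water_box, clash_cutoff=2.6)


@pytest.fixture(scope="session")
def ff_small():
    return FFConfig(cutoff=6.0)


def brute_force_energy(system, cfg):
    """Plain-python O(n^2) double-loop oracle for the intermolecular energy.

    Independent of the package's vectorized and numba paths: explicit loops,
    explicit Lorentz-Berthelot mixing, explicit minimum image.
    """
    import math

    mols = ([system.solute] if system.solute is not None else []) + system.waters
    n_solute = 1 if system.solute is not None else 0
    edges = system.box.edges_array()

    def mi(d):
        if not system.box.periodic:
            return d
        return d - edges * np.floor(d / edges + 0.5)

    sw_vdw = sw_elec = ww = 0.0
    for i in range(len(mols)):
        for j in range(i + 1, len(mols)):
            a, b = mols[i], mols[j]
            both_water = i >= n_solute and j >= n_solute
            if both_water:
                if np.linalg.norm(mi(a.positions[0] - b.positions[0])) > cfg.cutoff:
                    continue
            v = e = 0.0
            for sa in range(a.n_atoms):
                for sb in range(b.n_atoms):
                    r = float(np.linalg.norm(mi(a.positions[sa] - b.positions[sb])))
                    e += cfg.coulomb_constant * a.charges[sa] * b.charges[sb] / r
                    eps = math.sqrt(a.lj_epsilon[sa] * b.lj_epsilon[sb])
                    if eps > 0:
                        sig = 0.5 * (a.lj_sigma[sa] + b.lj_sigma[sb])
                        sr6 = (sig / r) ** 6
                        v += 4.0 * eps * (sr6 * sr6 - sr6)
            if both_water:
                ww += v + e
            else:
                sw_vdw += v
                sw_elec += e
    return sw_vdw, sw_elec, ww
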