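"""Pair potential: TIP3P, mixing rules, minimum image, energy decomposition."""

import numpy as np
import pytest
from dataclasses import replace

from hypothesis import given, settings
from hypothesis import strategies as st

from nanosolv import _kernels
from nanosolv.forcefield import (
    EnergyBreakdown,
    FFConfig,
    LJPair,
    combine_lorentz_berthelot,
    coulomb_energy,
    intermolecular_energy,
    lj_energy,
    minimum_image,
    molecule_delta_energy,
    pack_system,
    softcore_lj_energy,
    tip3p_parameters,
)
from nanosolv.mc_engine import MCConfig, propose_move
from nanosolv.structures import SimulationBox, SolvatedSystem, make_tip3p_water

from conftest import brute_force_energy


class TestTip3p:
    def test_water_is_neutral(self):
        p = tip3p_parameters()
        assert p["O"]["charge"] + 2 * p["H"]["charge"] == pytest.approx(0.0)

    def test_oxygen_repulsion_coefficient(self):
        p = tip3p_parameters()
        pair = LJPair(p["O"]["sigma"], p["O"]["epsilon"])
        assert pair.a_coefficient == pytest.approx(5.82e5, rel=0.01)

    def test_hydrogen_has_no_lj(self):
        p = tip3p_parameters()
        pair = LJPair(p["H"]["sigma"], p["H"]["epsilon"])
        assert lj_energy(pair, 1.0) == 0.0


class TestMixingAndPairTerms:
    def test_lorentz_berthelot_idempotent_on_diagonal(self):
        p = LJPair(3.15, 0.152)
        assert combine_lorentz_berthelot(p, p) == p

    def test_lorentz_berthelot_cross_terms(self):
        mixed = combine_lorentz_berthelot(LJPair(3.15, 0.152), LJPair(3.40, 0.086))
        assert mixed.sigma == pytest.approx(3.275)
        assert mixed.epsilon == pytest.approx(np.sqrt(0.152 * 0.086))

    def test_zero_epsilon_partner_kills_interaction(self):
        mixed = combine_lorentz_berthelot(LJPair(3.15, 0.152), LJPair(2.0, 0.0))
        assert mixed.epsilon == 0.0

    def test_lj_zero_crossing_and_minimum(self):
        pair = LJPair(3.0, 0.2)
        assert lj_energy(pair, 3.0) == pytest.approx(0.0, abs=1e-12)
        assert lj_energy(pair, 2 ** (1 / 6) * 3.0) == pytest.approx(-0.2)
        assert -1e-6 < lj_energy(pair, 50.0) < 0.0
        with pytest.raises(ValueError):
            lj_energy(pair, 0.0)

    def test_softcore_limits(self):
        pair = LJPair(3.0, 0.2)
        # full coupling reduces to the plain potential
        assert softcore_lj_energy(pair, 2.7, 1.0) == pytest.approx(lj_energy(pair, 2.7))
        # partial coupling stays finite at contact
        assert np.isfinite(softcore_lj_energy(pair, 0.0, 0.5))

    def test_coulomb_sign_and_scale(self):
        cfg = FFConfig()
        assert coulomb_energy(1.0, -1.0, 332.0636, cfg) == pytest.approx(-1.0)
        assert coulomb_energy(0.0, 1.0, 2.0, cfg) == 0.0
        assert coulomb_energy(0.5, 0.5, 3.0, cfg) > 0


class TestMinimumImage:
    @pytest.mark.parametrize(
        "disp,expected",
        [
            ((26.0, 0.0, 0.0), (-24.0, 0.0, 0.0)),
            ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
            ((25.0, -25.0, 49.0), (-25.0, -25.0, -1.0)),
        ],
    )
    def test_wrap_examples(self, disp, expected):
        box = SimulationBox.cubic(50.0)
        assert np.allclose(minimum_image(np.array(disp), box), expected)

    def test_never_longer_than_input(self):
        rng = np.random.default_rng(3)
        box = SimulationBox.cubic(20.0)
        d = rng.uniform(-60, 60, size=(100, 3))
        wrapped = minimum_image(d, box)
        assert np.all(np.abs(wrapped) <= np.abs(d) + 1e-12)
        assert np.all(wrapped >= -10.0) and np.all(wrapped < 10.0)

    def test_non_periodic_passthrough(self):
        box = SimulationBox.cubic(10.0, periodic=False)
        assert np.allclose(minimum_image(np.array([8.0, 0, 0]), box), [8.0, 0, 0])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        disp=st.lists(st.floats(-200.0, 200.0, allow_nan=False), min_size=3,
                      max_size=3),
        edge=st.floats(2.0, 60.0),
    )
    def test_wrap_lands_in_primary_cell(self, disp, edge):
        box = SimulationBox.cubic(edge)
        wrapped = minimum_image(np.array(disp), box)
        assert np.all(wrapped >= -edge / 2 - 1e-9)
        assert np.all(wrapped < edge / 2 + 1e-9)
        assert np.all(np.abs(wrapped) <= np.abs(disp) + 1e-9)


class TestIntermolecularEnergy:
    def test_lone_water_has_no_energy(self):
        box = SimulationBox.cubic(20.0)
        system = SolvatedSystem(box, [make_tip3p_water()])
        bd = intermolecular_energy(system, FFConfig(cutoff=9.0))
        assert bd.total == 0.0

    def test_dimer_matches_double_loop(self):
        box = SimulationBox.cubic(30.0)
        w1 = make_tip3p_water(0)
        w2 = make_tip3p_water(1)
        w2 = replace(w2, positions=w2.positions + np.array([2.75, 0.3, -0.2]))
        system = SolvatedSystem(box, [w1, w2])
        cfg = FFConfig(cutoff=12.0)
        bd = intermolecular_energy(system, cfg)
        _, _, ww = brute_force_energy(system, cfg)
        assert bd.water_water == pytest.approx(ww, abs=1e-10)
        assert bd.solute_water == 0.0

    def test_matches_brute_force_with_solute(self, solvated_drug, ff_small):
        bd = intermolecular_energy(solvated_drug, ff_small)
        sw_vdw, sw_elec, ww = brute_force_energy(solvated_drug, ff_small)
        assert bd.vdw_solute_water == pytest.approx(sw_vdw, abs=1e-8)
        assert bd.elec_solute_water == pytest.approx(sw_elec, abs=1e-8)
        assert bd.water_water == pytest.approx(ww, abs=1e-8)

    def test_numba_kernels_match_reference(self, solvated_drug, ff_small):
        packed = pack_system(solvated_drug, ff_small)
        bd = intermolecular_energy(solvated_drug, ff_small)
        ww = _kernels.total_water_water(
            packed.waters, packed.box_edges, packed.periodic, packed.cutoff ** 2,
            packed.water_charges, packed.water_sigma_o, packed.water_eps_o,
            packed.coulomb_constant,
        )
        sw = _kernels.total_solute_water(
            packed.waters, packed.solute_pos, packed.solute_charges,
            packed.mixed_sigma, packed.mixed_eps, packed.water_charges,
            packed.box_edges, packed.periodic, packed.coulomb_constant,
            1.0, 1.0, 0.5,
        )
        assert ww == pytest.approx(bd.water_water, abs=1e-9)
        assert sw[0] == pytest.approx(bd.vdw_solute_water, abs=1e-9)
        assert sw[1] == pytest.approx(bd.elec_solute_water, abs=1e-9)

    def test_decoupled_ghost_waters_give_zero(self, charged_drug):
        box = SimulationBox.cubic(20.0)
        waters = []
        for k, pos in enumerate([(5.0, 0, 0), (-5.0, 2, 1)]):
            w = make_tip3p_water(k)
            w = replace(
                w,
                positions=w.positions + np.array(pos),
                charges=np.zeros(3),
                lj_epsilon=np.zeros(3),
            )
            waters.append(w)
        system = SolvatedSystem(box, waters, charged_drug.translated([0.0, 0, 0]))
        bd = intermolecular_energy(system, FFConfig(cutoff=9.0))
        assert bd.total == pytest.approx(0.0, abs=1e-12)

    def test_breakdown_additivity(self, solvated_drug, ff_small):
        bd = intermolecular_energy(solvated_drug, ff_small)
        assert bd.solute_water == pytest.approx(
            bd.vdw_solute_water + bd.elec_solute_water, abs=1e-9
        )
        assert bd.total == pytest.approx(bd.solute_water + bd.water_water, abs=1e-9)

    def test_global_translation_invariance(self, solvated_drug, ff_small):
        bd0 = intermolecular_energy(solvated_drug, ff_small)
        shift = np.array([3.1, -2.2, 0.7])
        moved = solvated_drug.with_water_array(solvated_drug.water_array() + shift)
        moved.solute = solvated_drug.solute.translated(shift)
        bd1 = intermolecular_energy(moved, ff_small)
        assert bd1.total == pytest.approx(bd0.total, abs=1e-7)

    def test_water_relabeling_invariance(self, solvated_drug, ff_small):
        rng = np.random.default_rng(11)
        perm = rng.permutation(solvated_drug.n_waters)
        shuffled = SolvatedSystem(
            solvated_drug.box,
            [solvated_drug.waters[i] for i in perm],
            solvated_drug.solute,
        )
        bd0 = intermolecular_energy(solvated_drug, ff_small)
        bd1 = intermolecular_energy(shuffled, ff_small)
        assert bd1.total == pytest.approx(bd0.total, abs=1e-7)

    def test_overlapping_sites_rejected(self):
        box = SimulationBox.cubic(20.0)
        w1, w2 = make_tip3p_water(0), make_tip3p_water(1)
        system = SolvatedSystem(box, [w1, w2])
        with pytest.raises(ValueError, match="overlap"):
            intermolecular_energy(system, FFConfig(cutoff=9.0))

    def test_cutoff_wider_than_box_rejected(self, small_water_box):
        with pytest.raises(ValueError, match="cutoff"):
            intermolecular_energy(small_water_box, FFConfig(cutoff=10.0))


class TestDeltaEnergy:
    def test_null_move_is_zero(self, solvated_drug, ff_small):
        coords = solvated_drug.waters[4].positions.copy()
        assert molecule_delta_energy(solvated_drug, 4, coords, ff_small) == 0.0

    def test_matches_full_recompute(self, solvated_drug, ff_small):
        rng = np.random.default_rng(2)
        cfg = MCConfig(n_steps=1, translation_step=0.4, rotation_step=25.0)
        e0 = intermolecular_energy(solvated_drug, ff_small).total
        for idx in (0, 7, 19):
            trial = propose_move(solvated_drug, idx, cfg, rng)
            delta = molecule_delta_energy(solvated_drug, idx, trial, ff_small)
            W = solvated_drug.water_array().copy()
            W[idx] = trial
            e1 = intermolecular_energy(
                solvated_drug.with_water_array(W), ff_small
            ).total
            assert delta == pytest.approx(e1 - e0, abs=1e-8)

    def test_out_of_range_index(self, solvated_drug, ff_small):
        with pytest.raises(IndexError):
            molecule_delta_energy(
                solvated_drug, 10_000, np.zeros((3, 3)), ff_small
            )


def test_energy_breakdown_total_identity():
    bd = EnergyBreakdown(solute_water=-3.0, water_water=-7.5,
                         vdw_solute_water=-1.0, elec_solute_water=-2.0)
    assert bd.total == -10.5
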