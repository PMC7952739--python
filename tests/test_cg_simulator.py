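"""Energy/force correctness and Langevin sampling behaviour."""

import dataclasses
import math

import numpy as np
import pytest

from cgsaxs.cg_builder import DomainDefinition, build_cg_chain, build_topology, \
    define_domains
from cgsaxs.cg_simulator import (SimulationParams, expected_frame_count,
                                 forces, merge_trajectories,
                                 native_contact_fraction, potential_energy,
                                 run_langevin)
from cgsaxs.domain_geometry import domain_com
from cgsaxs.structure_io import Structure

GO_ONLY = SimulationParams(excluded_volume=False, electrostatics=False,
                           generic_angles=False)


def slow_energy(chain, top, coords, params):
    """Independent scalar re-implementation of every energy term."""
    e = 0.0
    for (i, j), r0, k in zip(top.bond_idx, top.bond_r0, top.bond_k):
        r = math.dist(coords[i], coords[j])
        e += 0.5 * k * (r - r0) ** 2
    rows = range(len(top.angle_idx)) if params.generic_angles else \
        np.nonzero(top.angle_native)[0]
    for row in rows:
        i, j, k = top.angle_idx[row]
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        cos = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        e += 0.5 * top.angle_kcos[row] * (cos - math.cos(top.angle_theta0[row])) ** 2
    for row in range(len(top.dihedral_idx)):
        i, j, k, l = top.dihedral_idx[row]
        b1, b2, b3 = coords[j] - coords[i], coords[k] - coords[j], coords[l] - coords[k]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        phi = math.atan2(float(np.dot(m1, n2)), float(np.dot(n1, n2)))
        e += top.dihedral_k[row] * (1 - math.cos(phi - top.dihedral_phi0[row]))
    if params.contacts:
        for (i, j), r0, eps in zip(top.contact_idx, top.contact_r0,
                                   top.contact_eps):
            s = r0 / math.dist(coords[i], coords[j])
            e += eps * (5 * s ** 12 - 6 * s ** 10)
    n = len(coords)
    lb = params.bjerrum_length
    kappa = 1.0 / params.debye_length
    for i in range(n):
        for j in range(i + 1, n):
            r = math.dist(coords[i], coords[j])
            if params.excluded_volume and (i, j) not in top.exclusions:
                e += params.eps_ev * (params.sigma_ev / r) ** 12
            qq = chain.charge[i] * chain.charge[j]
            if params.electrostatics and qq != 0 and j - i > 2:
                e += lb * qq * math.exp(-kappa * r) / r
    return e


class TestEnergies:
    def test_native_is_go_minimum(self, toy_system):
        _, chain, _, top = toy_system
        comp = potential_energy(chain, top, chain.coord, GO_ONLY)
        assert comp["bond"] == pytest.approx(0.0, abs=1e-12)
        assert comp["angle"] == pytest.approx(0.0, abs=1e-12)
        assert comp["dihedral"] == pytest.approx(0.0, abs=1e-12)
        assert comp["contact"] == pytest.approx(
            -float(top.contact_eps.sum()), rel=1e-12)

    def test_screened_coulomb_closed_form(self):
        lam_chain = build_cg_chain(Structure(
            atom_name=np.array(["CA", "CA"], dtype=object),
            res_id=np.array([1, 2]),
            res_name=np.array(["LYS", "GLU"], dtype=object),
            chain_id=np.array(["A", "A"], dtype=object),
            coord=np.zeros((2, 3)),
        ))
        lam_chain = define_domains(lam_chain,
                                   DomainDefinition(ranges={"a": [(1, 2)]}))
        lam_chain.charge[:] = [1.0, -1.0]
        params = SimulationParams(contacts=False, excluded_volume=False,
                                  generic_angles=False)
        lam = params.debye_length
        coords = np.array([[0.0, 0.0, 0.0], [lam, 0.0, 0.0]])
        top = build_topology(lam_chain)
        top.bond_k[:] = 0.0
        comp = potential_energy(lam_chain, top, coords, params)
        # electrostatics use pairs separated by |i-j| > 2; a 2-bead chain has
        # none, so evaluate the closed form through the module constants
        expected = -params.bjerrum_length * math.e ** -1 / lam
        assert comp["electrostatic"] == pytest.approx(0.0)
        # place the pair as beads 0 and 4 of a 5-bead chain instead
        chain5 = build_cg_chain(Structure(
            atom_name=np.array(["CA"] * 5, dtype=object),
            res_id=np.arange(1, 6),
            res_name=np.array(["LYS", "GLY", "GLY", "GLY", "GLU"], dtype=object),
            chain_id=np.array(["A"] * 5, dtype=object),
            coord=np.column_stack([np.arange(5) * lam / 4,
                                   np.zeros(5), np.zeros(5)]),
        ))
        chain5 = define_domains(chain5, DomainDefinition(ranges={"a": [(1, 5)]}))
        chain5.charge[:] = [1, 0, 0, 0, -1]
        top5 = build_topology(chain5)
        top5.bond_k[:] = 0.0
        top5.angle_k[:] = 0.0
        top5.angle_kcos[:] = 0.0
        top5.dihedral_k[:] = 0.0
        comp = potential_energy(chain5, top5, chain5.coord, params)
        assert comp["electrostatic"] == pytest.approx(expected, rel=1e-12)

    def test_total_matches_independent_oracle(self, toy_system):
        _, chain, _, top = toy_system
        rng = np.random.default_rng(2)
        coords = chain.coord + rng.normal(0, 0.3, chain.coord.shape)
        params = SimulationParams()
        comp = potential_energy(chain, top, coords, params)
        assert comp["total"] == pytest.approx(
            slow_energy(chain, top, coords, params), rel=1e-10)

    def test_components_sum_to_total(self, toy_system):
        _, chain, _, top = toy_system
        rng = np.random.default_rng(3)
        coords = chain.coord + rng.normal(0, 0.2, chain.coord.shape)
        comp = potential_energy(chain, top, coords)
        parts = sum(v for k, v in comp.items() if k != "total")
        assert comp["total"] == pytest.approx(parts, rel=1e-12)

    def test_overlapping_beads_rejected(self, toy_system):
        _, chain, _, top = toy_system
        coords = chain.coord.copy()
        coords[1] = coords[0]
        with pytest.raises(ValueError, match="overlap"):
            potential_energy(chain, top, coords)


class TestForces:
    def test_native_is_stationary_for_go_terms(self, toy_system):
        _, chain, _, top = toy_system
        f = forces(chain, top, chain.coord, GO_ONLY)
        assert np.abs(f).max() < 1e-8

    def test_forces_match_central_differences(self, toy_system):
        _, chain, _, top = toy_system
        rng = np.random.default_rng(7)
        coords = chain.coord + rng.normal(0, 0.3, chain.coord.shape)
        params = SimulationParams()
        f = forces(chain, top, coords, params)
        h = 1e-5
        picks = [(i, c) for i in range(0, chain.n_beads, 11) for c in range(3)]
        for i, c in picks:
            xp, xm = coords.copy(), coords.copy()
            xp[i, c] += h
            xm[i, c] -= h
            fd = -(potential_energy(chain, top, xp, params)["total"]
                   - potential_energy(chain, top, xm, params)["total"]) / (2 * h)
            assert f[i, c] == pytest.approx(fd, rel=1e-6, abs=1e-7)

    def test_translation_invariance(self, toy_system):
        _, chain, _, top = toy_system
        rng = np.random.default_rng(8)
        coords = chain.coord + rng.normal(0, 0.2, chain.coord.shape)
        f0 = forces(chain, top, coords)
        f1 = forces(chain, top, coords + np.array([11.0, -3.0, 7.0]))
        assert np.allclose(f0, f1, atol=1e-9)


class TestLangevin:
    def test_zero_steps_yields_no_frames(self, toy_system):
        _, chain, _, top = toy_system
        traj = run_langevin(chain, top, SimulationParams(n_steps=0, seed=1))
        assert traj.n_frames == 0

    def test_same_seed_is_bitwise_identical(self, toy_system):
        _, chain, _, top = toy_system
        p = SimulationParams(n_steps=600, save_interval=200, seed=42)
        t1 = run_langevin(chain, top, p)
        t2 = run_langevin(chain, top, p)
        assert np.array_equal(t1.frames, t2.frames)

    def test_frame_count_rule(self, toy_system):
        _, chain, _, top = toy_system
        p = SimulationParams(n_steps=1000, save_interval=300, seed=1)
        traj = run_langevin(chain, top, p)
        assert traj.n_frames == expected_frame_count(1000, 300) == 3
        assert list(traj.steps) == [300, 600, 900]

    def test_blowup_aborts_with_step_index(self, toy_system):
        _, chain, _, top = toy_system
        p = SimulationParams(n_steps=500, save_interval=100, dt=0.5, seed=1)
        with pytest.raises(RuntimeError, match="step"):
            run_langevin(chain, top, p)

    def test_thermostat_holds_300K(self, free_trajectory):
        mean_t = free_trajectory.temperature.mean()
        assert abs(mean_t - 300.0) / 300.0 < 0.03

    def test_temperature_fluctuations_match_equipartition(self, free_trajectory):
        n_dof = 3 * free_trajectory.frames.shape[1]
        expected_sd = 300.0 * np.sqrt(2.0 / n_dof)
        sd = free_trajectory.temperature.std(ddof=1)
        assert 0.5 * expected_sd < sd < 2.0 * expected_sd

    def test_nve_limit_energy_conservation(self, toy_system):
        _, chain, _, top = toy_system
        p = SimulationParams(n_steps=10000, save_interval=1000, friction=0.0,
                             dt=0.002, seed=3)
        traj = run_langevin(chain, top, p)
        total = traj.potential + traj.kinetic
        drift = abs(total[-1] - total[0]) / abs(total[0])
        assert drift < 1e-3

    def test_domains_stay_folded_while_D_fluctuates(self, toy_system,
                                                    free_trajectory):
        _, chain, _, top = toy_system
        for frame in free_trajectory.frames:
            assert native_contact_fraction(top, frame) > 0.8
        d = [np.linalg.norm(domain_com(chain, f, "a") - domain_com(chain, f, "ap"))
             for f in free_trajectory.frames]
        assert np.std(d) > 0.5  # inter-domain geometry is genuinely mobile

    def test_merge_preserves_frames_and_run_ids(self, toy_system):
        _, chain, _, top = toy_system
        t1 = run_langevin(chain, top,
                          SimulationParams(n_steps=400, save_interval=200,
                                           seed=1), run_id=0)
        t2 = run_langevin(chain, top,
                          SimulationParams(n_steps=400, save_interval=200,
                                           seed=2), run_id=1)
        merged = merge_trajectories([t1, t2])
        assert merged.n_frames == 4
        assert set(merged.run_ids) == {0, 1}

    def test_save_and_load_round_trip(self, toy_system, tmp_path):
        _, chain, _, top = toy_system
        traj = run_langevin(chain, top,
                            SimulationParams(n_steps=400, save_interval=200,
                                             seed=9))
        base = str(tmp_path / "traj")
        traj.save(base)
        back = traj.load(base)
        assert np.allclose(back.frames, traj.frames, atol=1e-4)
        assert back.params.seed == traj.params.seed


class TestProtocolArithmetic:
    def test_expected_frame_count_validates_interval(self):
        with pytest.raises(ValueError):
            expected_frame_count(100, 0)

    def test_production_protocol_snapshot_count(self):
        # 40 runs x 1e8 steps saved every 5000 -> 8e5 snapshots
        assert expected_frame_count(10 ** 8, 5000, n_runs=40) == 800_000
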