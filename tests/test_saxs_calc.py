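"""Scattering math against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cgsaxs.saxs_calc import (MixtureComponent, MixtureSpec, chi_square,
                              coordinate_rg, debye_profile,
                              distance_distribution, extract_monomer_profile,
                              guinier_fit, mixture_profile)
from cgsaxs.structure_io import SAXSProfile

Q = np.linspace(0.01, 0.3, 60)


def brute_force_debye(coords, f, q_grid):
    out = []
    for q in q_grid:
        total = 0.0
        for i in range(len(coords)):
            for j in range(len(coords)):
                r = math.dist(coords[i], coords[j])
                total += f[i] * f[j] * (1.0 if q * r == 0
                                        else math.sin(q * r) / (q * r))
        out.append(total)
    return np.array(out)


class TestDebye:
    def test_single_bead_is_flat(self):
        p = debye_profile(np.zeros((1, 3)), q_grid=Q)
        assert np.allclose(p.I, 1.0)

    def test_two_bead_closed_form(self):
        d = 10.0
        p = debye_profile(np.array([[0, 0, 0], [d, 0, 0.0]]), q_grid=Q)
        expected = 2 + 2 * np.sin(Q * d) / (Q * d)
        assert np.allclose(p.I, expected, rtol=1e-12)

    def test_forward_intensity_is_squared_amplitude_sum(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(0, 5, (12, 3))
        f = rng.uniform(0.5, 2.0, 12)
        p = debye_profile(coords, f, q_grid=np.array([1e-6, 0.01]))
        assert p.I[0] == pytest.approx(f.sum() ** 2, rel=1e-6)

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(0, 8, (10, 3))
        f = rng.uniform(0.5, 2.0, 10)
        p = debye_profile(coords, f, q_grid=Q)
        assert np.allclose(p.I, brute_force_debye(coords, f, Q), rtol=1e-10)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(0, 6, (15, 3))
        from scipy.spatial.transform import Rotation
        moved = coords @ Rotation.random(rng=rng).as_matrix().T \
            + rng.normal(0, 20, 3)
        p0 = debye_profile(coords, q_grid=Q)
        p1 = debye_profile(moved, q_grid=Q)
        assert np.allclose(p0.I, p1.I, rtol=1e-10)


class TestRg:
    def test_single_bead(self):
        assert coordinate_rg(np.zeros((1, 3))) == 0.0

    def test_two_beads_two_angstrom(self):
        assert coordinate_rg(np.array([[0, 0, 0], [2.0, 0, 0]])) == \
            pytest.approx(1.0)

    def test_definition_by_sum_oracle(self, toy_system):
        _, chain, _, _ = toy_system
        com = chain.coord.mean(axis=0)
        expected = math.sqrt(
            sum(np.sum((x - com) ** 2) for x in chain.coord) / chain.n_beads)
        assert coordinate_rg(chain.coord) == pytest.approx(expected, rel=1e-12)


class TestGuinier:
    def test_gaussian_profile_closed_form(self):
        q = np.linspace(0.05, 1.0, 80)
        res = guinier_fit(SAXSProfile(q=q, I=np.exp(-q ** 2)))
        assert res.rg == pytest.approx(math.sqrt(3), rel=1e-6)
        assert res.i0 == pytest.approx(1.0, rel=1e-6)

    def test_recovers_coordinate_rg_of_ideal_profile(self, toy_system):
        _, chain, _, _ = toy_system
        rg_true = coordinate_rg(chain.coord)
        q = np.linspace(0.005, 0.1, 200)
        profile = debye_profile(chain.coord, q_grid=q)
        res = guinier_fit(profile, q_rg_max=0.8)
        assert abs(res.rg - rg_true) / rg_true < 0.01

    def test_too_few_points_rejected(self):
        p = SAXSProfile(q=np.array([0.01, 0.02]), I=np.array([1.0, 0.9]))
        with pytest.raises(ValueError, match="3 points"):
            guinier_fit(p)

    def test_nonpositive_intensity_rejected(self):
        q = np.linspace(0.01, 0.05, 6)
        with pytest.raises(ValueError, match="non-positive"):
            guinier_fit(SAXSProfile(q=q, I=np.array([1, 0.9, -0.1, 0.5, 0.4, 0.3])))


class TestDistanceDistribution:
    def test_two_beads_single_bin(self):
        centers, p, dmax = distance_distribution(
            np.array([[0, 0, 0], [10.0, 0, 0]]), bin_width=1.0)
        assert dmax == pytest.approx(10.0)
        occupied = centers[p > 0]
        assert len(occupied) == 1 and abs(occupied[0] - 10.0) < 1.0

    def test_normalized_to_unit_area(self, toy_system):
        _, chain, _, _ = toy_system
        centers, p, _ = distance_distribution(chain.coord, bin_width=2.0)
        assert np.sum(p) * 2.0 == pytest.approx(1.0, abs=1e-9)

    def test_dmax_is_brute_force_maximum(self, toy_system):
        _, chain, _, _ = toy_system
        _, _, dmax = distance_distribution(chain.coord)
        expected = max(math.dist(a, b) for a in chain.coord for b in chain.coord)
        assert dmax == pytest.approx(expected, rel=1e-12)


class TestChiSquare:
    def _target(self, rg=30.0, sigma=1.0):
        I = 100 * np.exp(-(rg * Q) ** 2 / 3)
        return SAXSProfile(q=Q, I=I, sigma=np.full_like(Q, sigma))

    def test_identical_profiles_give_zero(self):
        t = self._target()
        chi2, c = chi_square(t, t)
        assert chi2 == pytest.approx(0.0, abs=1e-20)
        assert c == pytest.approx(1.0)

    def test_scale_invariance(self):
        t = self._target()
        double = SAXSProfile(q=Q, I=2 * t.I)
        chi2, c = chi_square(double, t)
        assert chi2 == pytest.approx(0.0, abs=1e-20)
        assert c == pytest.approx(0.5)

    def test_noisy_target_gives_reduced_chi2_near_one(self):
        rng = np.random.default_rng(12)
        model = self._target()
        sigma = 0.5
        noisy = SAXSProfile(q=Q, I=model.I + rng.normal(0, sigma, len(Q)),
                            sigma=np.full_like(Q, sigma))
        chi2, _ = chi_square(model, noisy)
        assert abs(chi2 - 1.0) < 3.0 / math.sqrt(len(Q))

    def test_closed_form_scale_beats_grid_search(self):
        rng = np.random.default_rng(5)
        model = self._target()
        target = SAXSProfile(q=Q, I=3.7 * model.I + rng.normal(0, 1, len(Q)),
                             sigma=np.full_like(Q, 1.0))
        chi2, c = chi_square(model, target)
        grid = np.linspace(0.5 * c, 2.0 * c, 4001)
        chis = [np.mean(((g * model.I - target.I) / target.sigma) ** 2)
                * len(Q) / (len(Q) - 1) for g in grid]
        best = grid[int(np.argmin(chis))]
        assert c == pytest.approx(best, rel=1e-3)
        assert chi2 <= min(chis) + 1e-9

    def test_missing_sigma_rejected_without_flag(self):
        t = self._target()
        bare = SAXSProfile(q=Q, I=t.I)
        with pytest.raises(ValueError, match="sigma"):
            chi_square(t, bare)
        chi2, _ = chi_square(t, bare, unit_weights=True)
        assert chi2 == pytest.approx(0.0, abs=1e-20)


class TestMixture:
    def _components(self, weights=(0.96, 0.03, 0.01)):
        return MixtureSpec(components=[
            MixtureComponent(order=k, weight=w, mass=50000.0 * k)
            for k, w in zip((1, 2, 3), weights)])

    def _profiles(self):
        rng = np.random.default_rng(3)
        mono = rng.normal(0, 10, (20, 3))
        out = []
        for k in (1, 2, 3):
            coords = np.concatenate([mono + [60.0 * i, 0, 0] for i in range(k)])
            out.append(debye_profile(coords, q_grid=Q))
        return out

    def test_single_component_identity(self):
        spec = MixtureSpec(components=[
            MixtureComponent(order=1, weight=1.0, mass=50000.0)])
        p = self._profiles()[0]
        mixed = mixture_profile([p], spec)
        assert np.allclose(mixed.I, p.I)

    def test_hand_computed_weighted_sum(self):
        profiles = self._profiles()
        spec = self._components()
        mixed = mixture_profile(profiles, spec)
        expected = (0.96 * profiles[0].I + 0.03 / 2 * profiles[1].I
                    + 0.01 / 3 * profiles[2].I)
        assert np.allclose(mixed.I, expected, rtol=1e-12)

    def test_identical_components_collapse(self):
        p = self._profiles()[0]
        spec = MixtureSpec(components=[
            MixtureComponent(order=1, weight=0.3, mass=50000.0),
            MixtureComponent(order=1, weight=0.7, mass=50000.0)])
        mixed = mixture_profile([p, p], spec)
        assert np.allclose(mixed.I, p.I, rtol=1e-12)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            self._components(weights=(0.9, 0.03, 0.01))


class TestMonomerExtraction:
    def test_no_aggregates_is_identity(self):
        q = np.linspace(0.01, 0.3, 80)
        obs = SAXSProfile(q=q, I=np.exp(-(30 * q) ** 2 / 3))
        spec = MixtureSpec(components=[
            MixtureComponent(order=1, weight=1.0, mass=50000.0)])
        assert extract_monomer_profile(obs, spec, 30.0) is obs

    def test_minor_monomer_rejected(self):
        q = np.linspace(0.01, 0.3, 80)
        obs = SAXSProfile(q=q, I=np.exp(-(30 * q) ** 2 / 3))
        spec = MixtureSpec(components=[
            MixtureComponent(order=1, weight=0.4, mass=5e4),
            MixtureComponent(order=2, weight=0.6, mass=1e5)])
        with pytest.raises(ValueError, match="monomer fraction"):
            extract_monomer_profile(obs, spec, 30.0)

    def test_more_trimer_in_spec_lowers_recovered_low_q(self):
        q = np.linspace(0.01, 0.3, 120)
        obs = SAXSProfile(q=q, I=1000 * np.exp(-(31 * q) ** 2 / 3) + 5)
        def spec(w3):
            return MixtureSpec(components=[
                MixtureComponent(order=1, weight=1 - 0.02 - w3, mass=5e4),
                MixtureComponent(order=2, weight=0.02, mass=1e5),
                MixtureComponent(order=3, weight=w3, mass=1.5e5)])
        lo = extract_monomer_profile(obs, spec(0.01), 30.0)
        hi = extract_monomer_profile(obs, spec(0.02), 30.0)
        low_q = q < 0.05
        assert np.all(hi.I[low_q] < lo.I[low_q])
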