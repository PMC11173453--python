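"""Ring-polymer PIMD: normal modes, estimators, finite-P quantum statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from protonfes.constants import FORCE_TO_ACCEL, HBAR, KB, MECH_TO_KCAL, thermal_beta
from protonfes.coords import CartesianComponent, ReactionCoordinateSet
from protonfes.modelsys import HarmonicSurface, harmonic_system
from protonfes.pimd import (
    RingPolymerState,
    centroid_bias,
    degree_of_expansion,
    initialize_ring_polymer,
    normal_mode_matrix,
    pimd_step,
    rp_dynamic_frequencies,
    rp_energy_forces,
    spring_frequency,
    virial_energy_sample,
)
from protonfes.sampling import UmbrellaWindow, bias_energy_forces, langevin_step
from protonfes.benchmarks import harmonic_pimd_observables, harmonic_rp_moments_exact

from _numeric import fd_gradient

RC1 = ReactionCoordinateSet([CartesianComponent("X", 0)], ("X",))


def _state(P, rng, n=1, dim=1, T=298.0):
    x = rng.standard_normal((P, n, dim))
    v = rng.standard_normal((P, n, dim)) * 0.01
    return RingPolymerState(x, v, T)


class TestNormalModes:
    @pytest.mark.parametrize("P", [1, 2, 3, 6, 7, 8])
    def test_transform_is_orthonormal(self, P):
        C = normal_mode_matrix(P)
        np.testing.assert_allclose(C @ C.T, np.eye(P), atol=1e-12)

    @pytest.mark.parametrize("P", [2, 4, 6, 9])
    def test_diagonalizes_ring_laplacian(self, P):
        """C L C^T is diagonal with eigenvalues 4 sin^2(pi k / P) (DFT check)."""
        C = normal_mode_matrix(P)
        L = 2 * np.eye(P) - np.roll(np.eye(P), 1, 0) - np.roll(np.eye(P), -1, 0)
        D = C @ L @ C.T
        np.testing.assert_allclose(D - np.diag(np.diag(D)), 0, atol=1e-12)
        beta = thermal_beta(298.0)
        w = rp_dynamic_frequencies(P, beta)
        lam = (w / spring_frequency(P, beta)) ** 2
        np.testing.assert_allclose(np.sort(np.diag(D)), np.sort(lam), atol=1e-12)


class TestRingPolymerEnergy:
    def test_coincident_beads_have_zero_spring_energy(self, rng):
        x = np.repeat(rng.standard_normal((1, 2, 3)), 6, axis=0)
        st_ = RingPolymerState(x, np.zeros_like(x), 298.0)
        surf = HarmonicSurface(1.0, 0.1, dim=3)

        class Zero(HarmonicSurface):
            def energy(self, p):
                return np.zeros(np.asarray(p).shape[:-2])
            def gradient(self, p):
                return np.zeros_like(np.asarray(p, float))

        e, _ = rp_energy_forces(st_, Zero(1.0, 0.1, dim=3), np.array([1.0, 1.0]))
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_single_bead_reduces_to_classical(self, rng):
        surf = HarmonicSurface(1.0, 0.1)
        x = rng.standard_normal((1, 1, 1))
        st_ = RingPolymerState(x, np.zeros_like(x), 298.0)
        e, f = rp_energy_forces(st_, surf, np.array([1.0]))
        assert e == pytest.approx(float(surf.energy(x[0])))
        np.testing.assert_allclose(f[0], surf.forces(x[0]), atol=1e-12)

    def test_forces_match_finite_difference(self, rng):
        """Bead forces are the negated gradient of spring + mean potential."""
        surf = HarmonicSurface(1.2, 0.08, dim=2)
        masses = np.array([1.2])
        P = 5
        x = rng.standard_normal((P, 1, 2)) * 0.4
        st_ = RingPolymerState(x, np.zeros_like(x), 298.0)
        _, f = rp_energy_forces(st_, surf, masses)

        def energy_of(flat):
            s2 = RingPolymerState(flat.reshape(P, 1, 2), np.zeros((P, 1, 2)), 298.0)
            return rp_energy_forces(s2, surf, masses)[0]

        fd = fd_gradient(lambda y: energy_of(np.asarray(y)), x.reshape(P, 2)).reshape(x.shape)
        np.testing.assert_allclose(f, -fd, atol=1e-5)

    def test_energy_invariant_under_cyclic_relabeling(self, rng):
        surf = HarmonicSurface(1.0, 0.1)
        st_ = _state(6, rng)
        e, _ = rp_energy_forces(st_, surf, np.array([1.0]))
        rolled = RingPolymerState(np.roll(st_.positions, 2, axis=0),
                                  np.roll(st_.velocities, 2, axis=0), 298.0)
        e2, _ = rp_energy_forces(rolled, surf, np.array([1.0]))
        assert e == pytest.approx(e2, rel=1e-12)


class TestDegreeOfExpansion:
    def test_collapsed_beads_give_zero(self):
        x = np.ones((6, 2, 3))
        assert degree_of_expansion(x, 0) == pytest.approx(0.0)

    def test_two_beads_symmetric(self):
        x = np.zeros((2, 1, 3))
        x[0, 0, 0] = 0.1
        x[1, 0, 0] = -0.1
        assert degree_of_expansion(x, 0) == pytest.approx(0.1)

    @given(st.integers(0, 1000))
    def test_matches_bruteforce_mean_distance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((6, 3, 2))
        got = degree_of_expansion(x, 1)
        r = x[:, 1, :]
        c = r.mean(axis=0)
        expected = np.mean([np.linalg.norm(b - c) for b in r])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_nonnegative(self, rng):
        x = rng.standard_normal((8, 2, 3))
        assert degree_of_expansion(x, 0) >= 0


class TestCentroidBias:
    W = UmbrellaWindow((0.3,), 200.0)

    def test_coincident_beads_equal_classical_bias(self):
        x = np.full((4, 1, 1), 0.55)
        st_ = RingPolymerState(x, np.zeros_like(x), 298.0)
        e, f = centroid_bias(st_, self.W, RC1)
        ec, fc = bias_energy_forces(x[0], self.W, RC1)
        assert e == pytest.approx(float(ec))
        np.testing.assert_allclose(f.sum(axis=0), fc, atol=1e-12)

    def test_centroid_at_center_gives_zero_even_if_beads_differ(self):
        x = np.array([0.1, 0.5][::1]).reshape(2, 1, 1)
        x = x - x.mean() + 0.3  # centroid exactly at the window center
        st_ = RingPolymerState(x, np.zeros_like(x), 298.0)
        e, _ = centroid_bias(st_, self.W, RC1)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_bead_force_sum_equals_classical_force_at_centroid(self, rng):
        x = rng.standard_normal((6, 1, 1))
        st_ = RingPolymerState(x, np.zeros_like(x), 298.0)
        _, f = centroid_bias(st_, self.W, RC1)
        _, fc = bias_energy_forces(st_.centroid(), self.W, RC1)
        np.testing.assert_allclose(f.sum(axis=0), fc, atol=1e-12)


class TestPropagation:
    def test_free_ring_polymer_conserves_energy(self, rng):
        """Exact normal-mode propagator: V=0, thermostat off, drift < 1e-8."""
        P, m = 8, np.array([1.0])
        st_ = _state(P, rng)

        def zero_force(x):
            return np.zeros_like(x)

        def total_energy(s):
            e_spr, _ = rp_energy_forces(
                s, HarmonicSurface(1.0, 1e-30), m)  # omega ~ 0: pure springs
            ke = 0.5 * np.sum(m[:, None] * s.velocities**2) * MECH_TO_KCAL
            return float(e_spr) + ke

        e0 = total_energy(st_)
        for _ in range(10_000):
            st_, _ = pimd_step(st_, zero_force, m, 0.5, rng, thermostat=False)
        assert abs(total_energy(st_) - e0) / abs(e0) < 1e-8

    def test_single_bead_trajectory_equals_classical_baoab(self):
        """P = 1 with a centroid thermostat is bit-compatible with BAOAB."""
        surf = HarmonicSurface(1.0, 0.1)
        m = np.array([1.0])
        x0 = np.array([[[0.4]]])  # (P=1, N=1, dim=1)
        v0 = np.array([[[0.01]]])
        st_ = RingPolymerState(x0.copy(), v0.copy(), 298.0)
        rng1 = np.random.default_rng(7)
        rng2 = np.random.default_rng(7)
        xc, vc = x0[0].copy(), v0[0].copy()
        fc = surf.forces(xc)
        f = None
        for _ in range(200):
            st_, f = pimd_step(st_, lambda y: surf.forces(y), m, 0.25, rng1,
                               centroid_gamma=0.005, f=f)
            xc, vc, fc = langevin_step(xc, vc, surf.forces, m, 0.25, 0.005, 298.0,
                                       rng2, f=fc)
        np.testing.assert_allclose(st_.positions[0], xc, atol=1e-10)

    @pytest.mark.parametrize("P", [1, 6])
    def test_sampled_x2_matches_exact_finite_P(self, P):
        """Thermostatted sampling reproduces the exact finite-P <x^2> (3 SE)."""
        r = harmonic_pimd_observables(P, n_replicas=32, equil_steps=2500,
                                      prod_steps=7500, seed=21)
        assert abs(r["x2"] - r["x2_exact"]) < 3 * r["x2_se"]

    def test_virial_estimator_classical_limit(self):
        """P = 1 virial energy equals kB T (1D potential + kinetic)."""
        r = harmonic_pimd_observables(1, n_replicas=32, equil_steps=2500,
                                      prod_steps=7500, seed=22)
        assert r["virial_energy_exact"] == pytest.approx(KB * 298.0)
        assert abs(r["virial_energy"] - KB * 298.0) < 3 * r["virial_energy_se"]


class TestExactMoments:
    """The Gaussian-algebra oracle itself against analytic limits."""

    def test_p1_is_classical(self):
        m = harmonic_rp_moments_exact(1, 1.0, 0.1, 298.0)
        assert m["x2"] == pytest.approx(KB * 298.0 * FORCE_TO_ACCEL / (1.0 * 0.01))
        assert m["virial_energy"] == pytest.approx(KB * 298.0)

    def test_large_P_reaches_quantum_limit(self):
        """P = 256 moments agree with hbar*w/2 coth(beta hbar w/2) forms."""
        mass, w, T = 1.0, 0.1, 298.0
        beta = thermal_beta(T)
        m = harmonic_rp_moments_exact(256, mass, w, T)
        x2_q = HBAR / (2 * mass * w) / np.tanh(beta * HBAR * w / 2) * FORCE_TO_ACCEL
        e_q = HBAR * w / 2 / np.tanh(beta * HBAR * w / 2)
        assert m["x2"] == pytest.approx(x2_q, rel=1e-4)
        assert m["virial_energy"] == pytest.approx(e_q, rel=1e-3)

    def test_high_temperature_limit_is_classical(self):
        """beta -> 0 at fixed P: quantum <x^2> -> kB T/(m w^2)."""
        mass, w, T = 1.0, 0.1, 20_000.0
        m = harmonic_rp_moments_exact(6, mass, w, T)
        classical = KB * T * FORCE_TO_ACCEL / (mass * w**2)
        assert m["x2"] == pytest.approx(classical, rel=1e-2)

    def test_zero_point_energy_at_low_temperature(self):
        """Low T, large P: virial energy approaches hbar*w/2."""
        mass, w, T = 1.0, 0.1, 30.0
        m = harmonic_rp_moments_exact(512, mass, w, T)
        assert m["virial_energy"] == pytest.approx(HBAR * w / 2, rel=1e-2)


def test_virial_sample_shape_and_batching(rng):
    surf = HarmonicSurface(1.0, 0.1, dim=2)
    x = rng.standard_normal((3, 6, 1, 2))  # batch of 3 ring polymers
    out = virial_energy_sample(x, surf, 298.0)
    assert out.shape == (3,)


def test_initialize_ring_polymer_centroid_preserved(rng):
    x = rng.standard_normal((4, 2, 3))
    st_ = initialize_ring_polymer(x, 6, np.ones(2), 298.0, rng, spread=0.05)
    np.testing.assert_allclose(st_.centroid(), x, atol=1e-12)
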