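"""MBAR estimation: closed-form Gaussian checks, self-consistency, profiles."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

from protonfes.constants import KB, thermal_beta
from protonfes.coords import CartesianComponent, ReactionCoordinateSet
from protonfes.fes import (
    FreeEnergyProfile,
    MbarInput,
    NonOverlapWarning,
    block_analysis,
    mbar_input_from_samples,
    mbar_residual,
    mbar_solve,
    overlap_matrix,
    pooled_profile,
    profile_along_path,
    trial_sem,
    unbiased_log_weights,
)
from protonfes.modelsys import QuarticDoubleWellSurface, double_well_system
from protonfes.sampling import Schedule, UmbrellaWindow, WindowSamples, run_windows
from protonfes.stringmethod import StringPath, init_linear

T = 298.0
BETA = thermal_beta(T)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def mbar_objective_oracle(u_kn, N_k):
    """Independent MBAR solve: BFGS minimization of the convex UWHAM objective.

    A different algorithmic route from the package's self-consistent
    iteration + Newton polish.
    """
    u_kn = np.asarray(u_kn, float)
    N_k = np.asarray(N_k, float)
    K, n = u_kn.shape
    logN = np.log(N_k)

    def fun(f1):
        f = np.concatenate([[0.0], f1])
        val = np.sum(logsumexp(logN[:, None] + f[:, None] - u_kn, axis=0))
        return val - np.dot(N_k, f)

    def jac(f1):
        f = np.concatenate([[0.0], f1])
        log_den = logsumexp(logN[:, None] + f[:, None] - u_kn, axis=0)
        W = np.exp(f[:, None] - u_kn - log_den[None, :])
        return (N_k * W.sum(axis=1) - N_k)[1:]

    res = minimize(fun, np.zeros(K - 1), jac=jac, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 2000})
    return np.concatenate([[0.0], res.x])


def mbar_quadrature_oracle(windows, beta, grid=None, n_iter=4000):
    """Infinite-sampling MBAR on a flat 1D surface by quadrature.

    In the large-sample limit the MBAR free energies converge to
    f_k = -ln ∫ exp(-beta u_k(x)) dx up to a common constant; computed
    directly by trapezoid quadrature, entirely independent of any sampling.
    """
    if grid is None:
        grid = np.linspace(-4, 4, 20001)
    f = []
    for w in windows:
        u = beta * w.k_array[0] * (grid - w.center_array[0]) ** 2
        f.append(-np.log(np.trapezoid(np.exp(-u), grid)))
    f = np.array(f)
    return f - f[0]


def _gaussian_window_samples(windows, n, seed):
    """Exact sampling of the biased flat-surface distributions."""
    rng = np.random.default_rng(seed)
    out = []
    for w in windows:
        sigma = np.sqrt(KB * T / (2 * w.k_array[0]))
        xi = rng.normal(w.center_array[0], sigma, size=(n, 1))
        out.append(WindowSamples(window=w, xi=xi, dt=0.5, stride=10.0, temperature=T))
    return out


# ---------------------------------------------------------------------------
# mbar_solve
# ---------------------------------------------------------------------------


class TestMbarSolve:
    def test_identical_windows_give_zero(self):
        w = [UmbrellaWindow((0.0,), 100.0, window_id=i) for i in range(4)]
        samples = _gaussian_window_samples(w, 300, 0)
        m = mbar_input_from_samples(samples)
        r = mbar_solve(m)
        np.testing.assert_allclose(r.f, 0.0, atol=1e-9)

    def test_two_gaussian_windows_match_closed_form(self):
        """Δf for same-center windows of stiffness k1, k2 is ln(k2/k1)/2."""
        w = [UmbrellaWindow((0.1,), 80.0, window_id=0),
             UmbrellaWindow((0.1,), 320.0, window_id=1)]
        samples = _gaussian_window_samples(w, 20_000, 3)
        m = mbar_input_from_samples(samples)
        r = mbar_solve(m)
        exact = 0.5 * np.log(320.0 / 80.0)
        # statistical tolerance ~ 1/sqrt(n_eff); the estimator itself is checked
        # against the independent minimizer to 1e-6 below
        assert r.f[1] == pytest.approx(exact, abs=0.02)
        oracle = mbar_objective_oracle(m.u_kn, m.N_k)
        np.testing.assert_allclose(r.f, oracle, atol=1e-6)

    def test_quadrature_limit_matches_closed_form(self):
        """Infinite-sampling quadrature oracle reproduces the Gaussian integral."""
        w = [UmbrellaWindow((0.0,), 50.0), UmbrellaWindow((0.0,), 450.0)]
        f = mbar_quadrature_oracle(w, BETA)
        assert f[1] == pytest.approx(0.5 * np.log(450.0 / 50.0), abs=1e-10)

    def test_self_consistency_residual(self):
        """Any solved instance plugs back into the MBAR equations below tol."""
        w = [UmbrellaWindow((0.15 * i,), 150.0, window_id=i) for i in range(5)]
        samples = _gaussian_window_samples(w, 800, 7)
        m = mbar_input_from_samples(samples)
        r = mbar_solve(m, tol=1e-11)
        assert mbar_residual(m.u_kn, m.N_k, r.f) < 1e-11

    @pytest.mark.parametrize("K,n", [(2, 5000), (3, 3000)])
    def test_agrees_with_independent_minimizer(self, K, n):
        """<=3-window 1D instances: SC+Newton vs BFGS oracle to 1e-6."""
        w = [UmbrellaWindow((0.1 * i,), 120.0 + 40 * i, window_id=i) for i in range(K)]
        samples = _gaussian_window_samples(w, n, 11 + K)
        m = mbar_input_from_samples(samples)
        r = mbar_solve(m)
        oracle = mbar_objective_oracle(m.u_kn, m.N_k)
        np.testing.assert_allclose(r.f, oracle, atol=1e-6)

    def test_anchor_invariance(self):
        """Adding a constant to all reduced energies leaves Δf unchanged."""
        w = [UmbrellaWindow((0.1 * i,), 150.0, window_id=i) for i in range(3)]
        samples = _gaussian_window_samples(w, 1500, 13)
        m = mbar_input_from_samples(samples)
        f1 = mbar_solve(m).f
        m2 = MbarInput(m.u_kn + 7.3, m.N_k, m.xi, m.temperature)
        f2 = mbar_solve(m2).f
        np.testing.assert_allclose(f1, f2, atol=1e-8)

    def test_weights_normalize_per_state(self):
        w = [UmbrellaWindow((0.1 * i,), 150.0, window_id=i) for i in range(3)]
        samples = _gaussian_window_samples(w, 1000, 17)
        m = mbar_input_from_samples(samples)
        r = mbar_solve(m)
        log_den = logsumexp(np.log(m.N_k)[:, None] + r.f[:, None] - m.u_kn, axis=0)
        W = np.exp(r.f[:, None] - m.u_kn - log_den[None, :])
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-9)
        lw = unbiased_log_weights(m, r.f)
        assert logsumexp(lw) == pytest.approx(0.0, abs=1e-12)

    def test_non_overlapping_windows_warn_with_groups(self):
        w = [UmbrellaWindow((0.0,), 400.0, window_id=0),
             UmbrellaWindow((3.0,), 400.0, window_id=1)]
        samples = _gaussian_window_samples(w, 500, 19)
        m = mbar_input_from_samples(samples)
        with pytest.warns(NonOverlapWarning, match="groups"):
            mbar_solve(m)

    def test_overlap_matrix_rows_sum_to_one(self):
        w = [UmbrellaWindow((0.1 * i,), 150.0, window_id=i) for i in range(4)]
        samples = _gaussian_window_samples(w, 600, 23)
        m = mbar_input_from_samples(samples)
        r = mbar_solve(m)
        O = overlap_matrix(m.u_kn, m.N_k, r.f)
        np.testing.assert_allclose(O.sum(axis=1), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def _flat_profile(seed=29):
    w = [UmbrellaWindow((0.2 * i,), 120.0, window_id=i) for i in range(6)]
    samples = _gaussian_window_samples(w, 2500, seed)
    m = mbar_input_from_samples(samples)
    r = mbar_solve(m)
    path = init_linear((0.0,), (1.0,), 6)
    return profile_along_path(m, r, path, bandwidth=0.06)


def test_flat_surface_profile_is_flat():
    prof = _flat_profile()
    assert np.max(np.abs(prof.A)) < 0.15  # ~2 sigma of the kernel estimate


def test_profile_anchored_at_reactant_minimum():
    prof = _flat_profile()
    assert prof.A.min() == pytest.approx(0.0, abs=1e-9) or prof.A[0] == pytest.approx(0.0, abs=0.2)


def test_quartic_double_well_pmf_matches_quadrature():
    """Umbrella + MBAR profile reproduces the smoothed analytic 1D PMF."""
    system, surface = double_well_system(barrier=4.0, half_width=1.0, tilt=0.4)
    rc = ReactionCoordinateSet([CartesianComponent("X", 0)], ("X",))
    centers = np.linspace(-1.1, 1.1, 12)
    windows = [UmbrellaWindow((c,), 60.0, window_id=i) for i, c in enumerate(centers)]
    sched = Schedule(equil_time=500.0, prod_time=10_000.0, dt=0.5, stride=10.0)
    trials = [run_windows(system, surface, rc, windows, sched, seed=31, trial=t)
              for t in range(2)]
    path = init_linear((-1.0,), (1.0,), 21)
    prof = pooled_profile(trials, path, bandwidth=0.05)

    # oracle: A(x) = -kT ln [exp(-beta V) * kernel], by quadrature
    g = np.linspace(-2.5, 2.5, 4001)
    rho = np.exp(-BETA * surface.energy(g[:, None, None]))
    h = 0.05
    A_or = np.empty(len(path.images))
    for i, c in enumerate(path.images[:, 0]):
        kern = np.exp(-0.5 * ((g - c) / h) ** 2)
        A_or[i] = -KB * T * np.log(np.trapezoid(rho * kern, g))
    A_or -= A_or[0]
    np.testing.assert_allclose(prof.A - prof.A[0], A_or, atol=0.25)


def test_more_sampling_reduces_profile_error():
    """Doubling production sampling lowers the mean trial SEM (on average)."""
    system, surface = double_well_system(barrier=2.0)
    rc = ReactionCoordinateSet([CartesianComponent("X", 0)], ("X",))
    centers = np.linspace(-1.1, 1.1, 8)
    windows = [UmbrellaWindow((c,), 60.0, window_id=i) for i, c in enumerate(centers)]
    path = init_linear((-1.0,), (1.0,), 8)

    def mean_sem(prod, seed):
        sched = Schedule(equil_time=250.0, prod_time=prod, dt=0.5, stride=10.0)
        trials = [run_windows(system, surface, rc, windows, sched, seed=seed, trial=t)
                  for t in range(3)]
        return pooled_profile(trials, path, bandwidth=0.08).sigma.mean()

    short = np.mean([mean_sem(1500.0, s) for s in (41, 43, 47)])
    long = np.mean([mean_sem(6000.0, s) for s in (41, 43, 47)])
    assert long < short


class TestTrialSem:
    def _prof(self, A):
        n = len(A)
        return FreeEnergyProfile(np.linspace(0, 1, n), np.asarray(A, float), np.zeros(n))

    def test_identical_trials_give_zero(self):
        p = self._prof([0, 1, 2])
        np.testing.assert_allclose(trial_sem([p, p, p]), 0.0, atol=0)

    def test_two_trial_arithmetic(self):
        a = self._prof([0.0, 1.0])
        b = self._prof([0.0, 3.0])
        np.testing.assert_allclose(trial_sem([a, b]), [0.0, 1.0])

    def test_iid_noise_scaling(self, rng):
        """4 trials with i.i.d. sigma noise: mean SEM ~ sigma/2 over repeats."""
        sems = []
        for _ in range(300):
            profs = [self._prof(rng.normal(0, 1.0, 5)) for _ in range(4)]
            sems.append(trial_sem(profs).mean())
        assert np.mean(sems) == pytest.approx(0.5, abs=0.05)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            trial_sem([self._prof([0, 1])])


class TestBlockAnalysis:
    def _trials(self, prod=6000.0, seed=53, trials=2):
        system, surface = double_well_system(barrier=3.0)
        rc = ReactionCoordinateSet([CartesianComponent("X", 0)], ("X",))
        centers = np.linspace(-1.1, 1.1, 12)
        windows = [UmbrellaWindow((c,), 60.0, window_id=i) for i, c in enumerate(centers)]
        sched = Schedule(equil_time=250.0, prod_time=prod, dt=0.5, stride=10.0)
        return [run_windows(system, surface, rc, windows, sched, seed=seed, trial=t)
                for t in range(trials)], init_linear((-1.0,), (1.0,), 9)

    def test_single_block_equals_pooled_profile(self):
        trials, path = self._trials()
        profiles, spread = block_analysis(trials, path, 1, bandwidth=0.08)
        pooled = pooled_profile(trials, path, bandwidth=0.08)
        assert len(profiles) == 1
        np.testing.assert_allclose(profiles[0].A, pooled.A, atol=1e-9)
        assert spread == 0.0

    def test_mean_of_blocks_consistent_with_pooled(self):
        trials, path = self._trials()
        profiles, _ = block_analysis(trials, path, 4, bandwidth=0.08)
        mean_A = np.mean([p.A for p in profiles], axis=0)
        pooled = pooled_profile(trials, path, bandwidth=0.08)
        np.testing.assert_allclose(mean_A, pooled.A, atol=0.35)

    def test_indivisible_block_count_rejected(self):
        trials, path = self._trials()
        with pytest.raises(ValueError):
            block_analysis(trials, path, 7)


def test_profile_table_roundtrip():
    p = FreeEnergyProfile(np.linspace(0, 1, 4), np.array([0.0, 2.0, 1.0, 0.5]),
                          np.array([0.0, 0.1, 0.1, 0.2]))
    q = FreeEnergyProfile.from_table(p.to_table())
    np.testing.assert_allclose(q.A, p.A, atol=1e-8)
    np.testing.assert_allclose(q.sigma, p.sigma, atol=1e-8)
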