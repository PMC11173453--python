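"""Standard validation experiments exercising the whole toolkit.

Each function here is a self-contained numerical experiment with a known
answer or a strong physical expectation: exact finite-P harmonic-oscillator
statistics for the PIMD engine, the Muller-Brown saddle for the string
method, recovery of a known truth correction for Δ-learning, the
classical-vs-quantum barrier comparison on the toy double-proton-transfer
surface, and block re-analysis of sampling sensitivity.  The experiments
are deterministic given their seed and sized for a single desktop core
(problem sizes are stated in docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import dcorr, fes, kinetics, pimd, sampling, stringmethod
from .constants import KB, MECH_TO_KCAL, ROOM_T, thermal_beta
from .coords import CartesianComponent, ReactionCoordinateSet
from .modelsys import (
    MuellerBrownSurface,
    Surface,
    build_gt_toy,
    gt_reaction_coordinates,
    harmonic_system,
    minimize_on_surface,
    muller_brown_system,
)

__all__ = [
    "harmonic_rp_moments_exact",
    "harmonic_pimd_observables",
    "mueller_brown_saddle",
    "mueller_brown_string_benchmark",
    "gt_delta_recovery",
    "gt_nqe_comparison",
    "gt_block_sensitivity",
]


# --------------------------------------------------------------------------
# exact finite-P harmonic oscillator statistics (Gaussian algebra)
# --------------------------------------------------------------------------


def harmonic_rp_moments_exact(P: int, mass: float, omega: float, temperature: float) -> dict:
    """Exact finite-P ring-polymer moments of a 1D harmonic oscillator.

    Built directly from the multivariate-Gaussian Boltzmann distribution of
    the P-bead ring (precision-matrix inversion) - independent of the
    normal-mode machinery of the dynamics engine.  Returns ⟨x²⟩ (Å²),
    ⟨x_c²⟩ and the centroid-virial total energy (kcal/mol).
    """
    beta = thermal_beta(temperature)
    wsp = pimd.spring_frequency(P, beta)
    L = 2.0 * np.eye(P) - np.roll(np.eye(P), 1, 0) - np.roll(np.eye(P), -1, 0)
    if P == 1:
        L = np.zeros((1, 1))
    prec = beta * mass * MECH_TO_KCAL * (wsp**2 * L + (omega**2 / P) * np.eye(P))
    cov = np.linalg.inv(prec)
    x2 = float(np.mean(np.diag(cov)))
    xc2 = float(np.sum(cov)) / P**2
    a = 0.5 * mass * omega**2 * MECH_TO_KCAL  # V = a x^2
    e_vir = 0.5 * KB * temperature + 2.0 * a * x2 - a * xc2
    return {"x2": x2, "xc2": xc2, "virial_energy": e_vir}


def harmonic_pimd_observables(
    P: int,
    mass: float = 1.0,
    omega: float = 0.1,
    temperature: float = ROOM_T,
    n_replicas: int = 64,
    equil_steps: int = 4000,
    prod_steps: int = 12000,
    dt: float = 0.5,
    stride: int = 10,
    seed: int = 0,
) -> dict:
    """Sampled ⟨x²⟩ and virial energy of the harmonic oscillator at P beads.

    Runs ``n_replicas`` independent thermostatted ring polymers in one
    batch; standard errors are over replica means.  Returns sampled values,
    standard errors and the exact finite-P references.
    """
    system, surface = harmonic_system(mass, omega)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(P,)))
    x0 = np.zeros((n_replicas, 1, 1))
    state = pimd.initialize_ring_polymer(x0, P, system.masses, temperature, rng)

    def force(x):
        return surface.forces(x) / P

    f = force(state.positions)
    x2_acc, ev_acc = [], []
    for step in range(1, equil_steps + prod_steps + 1):
        state, f = pimd.pimd_step(state, force, system.masses, dt, rng,
                                  centroid_gamma=0.01, f=f)
        if step > equil_steps and step % stride == 0:
            x2_acc.append(np.mean(state.positions[..., 0, 0] ** 2, axis=-1))
            ev_acc.append(pimd.virial_energy_sample(state.positions, surface, temperature))
    x2 = np.array(x2_acc)  # (n_frames, n_replicas)
    ev = np.array(ev_acc)
    exact = harmonic_rp_moments_exact(P, mass, omega, temperature)
    rep_x2 = x2.mean(axis=0)
    rep_ev = ev.mean(axis=0)
    return {
        "P": P,
        "x2": float(rep_x2.mean()),
        "x2_se": float(rep_x2.std(ddof=1) / np.sqrt(n_replicas)),
        "x2_exact": exact["x2"],
        "virial_energy": float(rep_ev.mean()),
        "virial_energy_se": float(rep_ev.std(ddof=1) / np.sqrt(n_replicas)),
        "virial_energy_exact": exact["virial_energy"],
        "n": n_replicas * (prod_steps // stride),
    }


# --------------------------------------------------------------------------
# Muller-Brown string benchmark
# --------------------------------------------------------------------------


def mueller_brown_saddle(guess=(-0.7, 0.55)) -> tuple[np.ndarray, float]:
    """Newton search for a saddle: root of the gradient with one negative
    Hessian eigenvalue (checked).  Independent of the string machinery."""
    surf = MuellerBrownSurface()

    def grad(v):
        return surf.gradient(v.reshape(1, 2)).ravel()

    sol = optimize.root(grad, np.asarray(guess, float), method="hybr", tol=1e-12)
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"saddle search failed: {sol.message}")
    x = sol.x
    h = 1e-5
    H = np.empty((2, 2))
    for i in range(2):
        e = np.zeros(2)
        e[i] = h
        H[:, i] = (grad(x + e) - grad(x - e)) / (2 * h)
    ev = np.linalg.eigvalsh(H)
    if not (ev[0] < 0 < ev[1]):  # pragma: no cover - defensive
        raise RuntimeError(f"stationary point is not a first-order saddle: {ev}")
    return x.reshape(1, 2), float(surf.energy(x.reshape(1, 2)))


def _polyline_distance(points: np.ndarray, target: np.ndarray) -> float:
    """Min distance from a polyline (M, D) to a point (D,)."""
    best = np.inf
    for a, b in zip(points[:-1], points[1:]):
        ab = b - a
        t = np.clip(np.dot(target - a, ab) / np.dot(ab, ab), 0.0, 1.0)
        best = min(best, float(np.linalg.norm(a + t * ab - target)))
    return best


def mueller_brown_string_benchmark(
    seed: int = 0,
    n_images: int = 32,
    iterations: int = 40,
    string_temperature: float = 500.0,
    prod_temperature: float = 1000.0,
    k_umbrella: float = 800.0,
    prod_trials: int = 4,
    prod_time: float = 800.0,
    dt: float = 0.1,
) -> dict:
    """String optimization A -> C on the Muller-Brown surface.

    Returns the distance from the converged string to the independently
    located rate-controlling saddle, and the MBAR profile maximum compared
    with the potential-energy barrier at that saddle.  The ~106-unit
    barrier is steep (forces up to ~200 units/Å along the path), which
    dictates the ladder design: the string phase runs cold (kB*T ≈ 1) so
    the restrained clouds stay harmonic and the mean-displacement update
    tracks the true valley floor instead of leaking over the ridge, while
    production runs at kB*T ≈ 2 so that adjacent windows overlap for MBAR.
    The profile tracks the potential along the path up to O(kB*T)
    transverse-entropy and kernel-smoothing corrections.
    """
    system, surface = muller_brown_system()
    rc = ReactionCoordinateSet(
        [CartesianComponent("X", 0), CartesianComponent("X", 1)], system.labels
    )
    # polish endpoints to the true minima
    xa, _ = minimize_on_surface(surface, system.named_states["A"])
    xc, _ = minimize_on_surface(surface, system.named_states["C"])
    path0 = stringmethod.init_linear(xa.ravel(), xc.ravel(), n_images)
    sched = sampling.Schedule(equil_time=20.0, prod_time=100.0, dt=dt, stride=1.0,
                              temperature=string_temperature, gamma=0.02)
    res = stringmethod.run_string(system, surface, rc, path0, iterations=iterations,
                                  schedule=sched, eta=0.5, kappa=0.05,
                                  k_umbrella=k_umbrella, seed=seed)
    saddle, e_saddle = mueller_brown_saddle()
    e_a = float(surface.energy(xa))
    dist = _polyline_distance(res.path.images, saddle.ravel())

    windows = [sampling.UmbrellaWindow(tuple(img), k_umbrella, window_id=i)
               for i, img in enumerate(res.path.images)]
    x0 = res.final_positions
    prod = sampling.Schedule(equil_time=50.0, prod_time=prod_time, dt=dt, stride=2.0,
                             temperature=prod_temperature, gamma=0.02)
    trials = [
        sampling.run_windows(system, surface, rc, windows, prod, seed=seed, trial=t, x0=x0)
        for t in range(prod_trials)
    ]
    profile = fes.pooled_profile(trials, res.path, prod_temperature, bandwidth=0.03)
    rep = kinetics.extract_stationary_points(profile, min_prominence=1.0, label="A->C")
    return {
        "saddle": saddle.ravel(),
        "saddle_barrier": e_saddle - e_a,
        "string_saddle_distance": dist,
        "profile_barrier": rep.forward_barrier,
        "profile_barrier_err": rep.forward_barrier_err,
        "rms_history": res.rms_displacement,
        "profile": profile,
        "path": res.path,
    }


# --------------------------------------------------------------------------
# G-T toy experiments
# --------------------------------------------------------------------------


@dataclass
class _GTRun:
    """Shared artifacts of a production umbrella run on the toy cluster."""

    path: stringmethod.StringPath
    trials: list = field(default_factory=list)
    profile: fes.FreeEnergyProfile | None = None
    report: kinetics.StationaryReport | None = None


def _gt_string_and_production(
    system,
    surface,
    rc,
    reaction: tuple[str, str],
    seed: int,
    n_images: int = 16,
    iterations: int = 25,
    trials: int = 2,
    prod_time: float = 8000.0,
    path0: stringmethod.StringPath | None = None,
    bandwidth: float = 0.05,
    min_prominence: float = 0.5,
) -> _GTRun:
    ra, pb = reaction
    if path0 is None:
        path0 = stringmethod.init_linear(
            rc.values(system.named_states[ra]),
            rc.values(system.named_states[pb]),
            n_images,
        )
    sched = sampling.Schedule(equil_time=50.0, prod_time=300.0, dt=0.5, stride=5.0)
    res = stringmethod.run_string(system, surface, rc, path0, iterations=iterations,
                                  schedule=sched, seed=seed)
    windows = [sampling.UmbrellaWindow(tuple(img), 200.0, window_id=i)
               for i, img in enumerate(res.path.images)]
    prod = sampling.Schedule(equil_time=500.0, prod_time=prod_time, dt=0.5, stride=10.0)
    x0 = res.final_positions
    run = _GTRun(path=res.path)
    for t in range(trials):
        run.trials.append(
            sampling.run_windows(system, surface, rc, windows, prod,
                                 seed=seed, trial=t, x0=x0)
        )
    run.profile = fes.pooled_profile(run.trials, res.path, bandwidth=bandwidth)
    run.report = kinetics.extract_stationary_points(
        run.profile, min_prominence, label=f"{ra}->{pb}")
    return run


def gt_delta_recovery(seed: int = 0, trials: int = 2, prod_time: float = 6000.0) -> dict:
    """End-to-end Δ-learning recovery on the wGT -> GT* toy step.

    Protocol: optimize the string and run production on the *base* surface;
    harvest configurations as training frames labelled with
    reference-minus-base energy/force residuals; fit the RBF-ridge
    correction; re-profile the same reaction on the base, corrected and
    reference surfaces (strings for the latter two warm-started from the
    base-optimized path).  Success means the corrected barrier lands within
    the reference barrier while the raw base barrier misses it by the
    truth-correction amplitude.
    """
    system, reference, base = build_gt_toy()
    rc = gt_reaction_coordinates()
    reaction = ("wGT", "GT*")

    base_run = _gt_string_and_production(system, base, rc, reaction, seed,
                                         trials=trials, prod_time=prod_time)
    # harvest training configurations from a dedicated archiving pass
    windows = [sampling.UmbrellaWindow(tuple(img), 200.0, window_id=i)
               for i, img in enumerate(base_run.path.images)]
    arch = sampling.Schedule(equil_time=250.0, prod_time=1500.0, dt=0.5, stride=10.0)
    archived = sampling.run_windows(
        system, base, rc, windows, arch, seed=seed + 1, trial=9,
        extra_observables={"pos": lambda x: x},
    )
    trajs = [s.extras["pos"] for s in archived]
    ts = dcorr.make_training_set(trajs, base, reference, stride=1,
                                 provenance=[f"window{i}" for i in range(len(trajs))])
    model = dcorr.train(ts, system, rc, seed=seed)
    corrected = dcorr.corrected_surface(base, model, guard=False)

    corr_run = _gt_string_and_production(system, corrected, rc, reaction, seed,
                                         trials=trials, prod_time=prod_time,
                                         path0=base_run.path)
    ref_run = _gt_string_and_production(system, reference, rc, reaction, seed,
                                        trials=trials, prod_time=prod_time,
                                        path0=base_run.path)
    b_ref = ref_run.report.forward_barrier
    return {
        "holdout_energy_rmse": model.fit_report["val_energy_rmse"],
        "holdout_force_rmse": model.fit_report["val_force_rmse"],
        "n_training_frames": ts.n_frames,
        "reference_barrier": b_ref,
        "base_barrier": base_run.report.forward_barrier,
        "corrected_barrier": corr_run.report.forward_barrier,
        "corrected_barrier_error": abs(corr_run.report.forward_barrier - b_ref),
        "base_barrier_error": abs(base_run.report.forward_barrier - b_ref),
        "model": model,
        "runs": {"base": base_run, "corrected": corr_run, "reference": ref_run},
    }


def _curve_peak(s: np.ndarray, y: np.ndarray, half_window: int = 3) -> float:
    """Peak location via a local quadratic fit around the grid maximum.

    More robust than the raw argmax for broad, noisy curves sampled at the
    window positions.
    """
    i = int(np.argmax(y))
    lo, hi = max(0, i - half_window), min(len(y), i + half_window + 1)
    if hi - lo < 3:
        return float(s[i])
    c2, c1, _ = np.polyfit(s[lo:hi], y[lo:hi], 2)
    if c2 >= 0:
        return float(s[i])
    vertex = -c1 / (2.0 * c2)
    return float(np.clip(vertex, s[lo], s[hi - 1]))


def _zero_crossing(s: np.ndarray, y: np.ndarray) -> float:
    """Progress coordinate where the (monotone-trend) series y crosses zero."""
    sign_change = np.where(np.diff(np.sign(y)) != 0)[0]
    if len(sign_change) == 0:
        raise ValueError("series does not cross zero")
    i = int(sign_change[0])
    return float(s[i] + (s[i + 1] - s[i]) * (0.0 - y[i]) / (y[i + 1] - y[i]))


def gt_nqe_comparison(
    seed: int = 0,
    n_beads: int = 16,
    trials: int = 4,
    pimd_trials: int = 2,
    classical_prod: float = 10000.0,
    pimd_prod: float = 2500.0,
    n_images: int = 16,
) -> dict:
    """Classical vs path-integral barriers for the concerted GT* -> G*T step.

    The rate-controlling transition state of this step is the double proton
    transfer itself, so zero-point motion of the two protons lowers the
    quantum barrier well outside the trial-to-trial noise.  Also returns,
    per transferring proton, the progress coordinate of its ring-polymer
    expansion maximum and of its donor-H/acceptor-H distance-curve crossing
    (where the corresponding xi changes sign).
    """
    system, reference, _ = build_gt_toy()
    rc = gt_reaction_coordinates()
    run = _gt_string_and_production(
        system, reference, rc, ("GT*", "G*T"), seed,
        n_images=n_images, iterations=25, trials=trials, prod_time=classical_prod,
    )
    windows = [sampling.UmbrellaWindow(tuple(img), 200.0, window_id=i)
               for i, img in enumerate(run.path.images)]
    psched = sampling.Schedule(equil_time=500.0, prod_time=pimd_prod, dt=0.25, stride=10.0)
    pimd_runs = [
        pimd.run_pimd_windows(system, reference, rc, windows, psched, n_beads,
                              seed=seed, trial=t)
        for t in range(pimd_trials)
    ]
    pprofile = fes.pooled_profile(pimd_runs, run.path)
    preport = kinetics.extract_stationary_points(pprofile, 0.5, label="GT*->G*T (PIMD)")

    s = run.path.progress
    crossings, peaks, drh_curves = {}, {}, {}
    for j, (donor, h, acceptor) in enumerate(system.donor_acceptor):
        xi_mean = np.array([
            np.mean(np.concatenate([tr[i].xi[:, j] for tr in pimd_runs]))
            for i in range(len(windows))
        ])
        crossings[h] = _zero_crossing(s, xi_mean)
        drh = np.array([
            np.mean(np.concatenate([tr[i].extras[f"drh_{h}"] for tr in pimd_runs]))
            for i in range(len(windows))
        ])
        drh_curves[h] = drh
        peaks[h] = _curve_peak(s, drh)
    image_spacing = float(np.mean(np.diff(s)))
    return {
        "classical_barrier": run.report.forward_barrier,
        "classical_barrier_err": run.report.forward_barrier_err,
        "pimd_barrier": preport.forward_barrier,
        "pimd_barrier_err": preport.forward_barrier_err,
        "barrier_reduction": run.report.forward_barrier - preport.forward_barrier,
        "classical_delta_A": run.report.delta_A,
        "pimd_delta_A": preport.delta_A,
        "expansion_peak_s": peaks,
        "distance_crossing_s": crossings,
        "expansion_curves": drh_curves,
        "image_spacing": image_spacing,
        "classical_run": run,
        "pimd_profile": pprofile,
    }


def gt_block_sensitivity(
    seed: int = 0,
    classical_run: _GTRun | None = None,
    block_counts: tuple[int, ...] = (16, 4),
) -> dict:
    """Block re-analysis of the GT* -> G*T production sampling.

    Divides the pooled production series into non-overlapping blocks and
    reports the spread (max - min) of the rate-controlling barrier for each
    block count.  Short blocks (many of them) show a strictly larger spread
    than long blocks - the sampling-sensitivity effect.
    """
    if classical_run is None:
        system, reference, _ = build_gt_toy()
        rc = gt_reaction_coordinates()
        classical_run = _gt_string_and_production(
            system, reference, rc, ("GT*", "G*T"), seed,
            n_images=16, iterations=20, trials=4, prod_time=10000.0,
        )
    spreads = {}
    for nb in block_counts:
        _, spread = fes.block_analysis(classical_run.trials, classical_run.path, nb)
        spreads[nb] = spread
    return {"spreads": spreads, "run": classical_run}
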