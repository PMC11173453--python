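"""Ring-polymer path-integral molecular dynamics.

A particle at inverse temperature beta is represented by a cyclic ring
polymer of P beads.  The sampled potential (kcal/mol) is

    U_P(r_1..r_P) = sum_n  1/2 m w_sp^2 |r_n - r_{n+1}|^2  +  (1/P) sum_n V(r_n)

with the inter-bead spring frequency ``w_sp = sqrt(P)/(beta*hbar)``, and the
thermostat held at the *physical* temperature T.  This is the convention in
which the classical Boltzmann distribution of the ring polymer reproduces
the quantum (imaginary-time discretized) position statistics at finite P;
it is algebraically equivalent to the often-quoted form with spring
frequency P/(beta*hbar), full V per bead, and sampling at temperature P*T.
For P = 1 the Hamiltonian and the integrator reduce exactly to classical
Langevin MD.

Integration uses the exact normal-mode propagator for the free ring polymer
(so the stiff springs impose no time-step limit by themselves) in a
BAOAB-type splitting, with a PILE thermostat: an Ornstein-Uhlenbeck step
per normal mode with friction 2*w_k on internal modes (w_k the ring-polymer
normal-mode dynamic frequencies) and a configurable centroid friction.

Umbrella restraints act on the *centroid* coordinates; reaction-coordinate
values are likewise evaluated at the centroid.  The "degree of expansion"
diagnostic is the mean bead-centroid distance of a tagged particle - a
direct measure of the delocalization of its thermal wave packet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .constants import FORCE_TO_ACCEL, HBAR, KB, thermal_beta
from .coords import ReactionCoordinateSet
from .modelsys import ModelSystem, Surface
from .sampling import Schedule, UmbrellaWindow, WindowSamples, _StackedRNG, window_rng

__all__ = [
    "RingPolymerState",
    "normal_mode_matrix",
    "rp_dynamic_frequencies",
    "spring_frequency",
    "rp_energy_forces",
    "centroid_bias",
    "degree_of_expansion",
    "pimd_step",
    "initialize_ring_polymer",
    "virial_energy_sample",
    "run_pimd_window",
    "run_pimd_windows",
]


@dataclass
class RingPolymerState:
    """Bead positions/velocities ``(..., P, N, dim)`` plus thermodynamic state."""

    positions: np.ndarray
    velocities: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.velocities = np.asarray(self.velocities, float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions/velocities shape mismatch")
        if self.positions.ndim < 3:
            raise ValueError("state arrays must have shape (..., P, N, dim)")
        if self.n_beads < 1:
            raise ValueError("P >= 1 required")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[-3]

    @property
    def beta(self) -> float:
        return thermal_beta(self.temperature)

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=-3)


def normal_mode_matrix(P: int) -> np.ndarray:
    """Orthonormal real transform C (P x P) from beads to ring normal modes.

    Row 0 is the centroid mode 1/sqrt(P); cos/sin pairs follow; for even P
    the last row is the alternating mode.  C @ C.T = I exactly.
    """
    C = np.empty((P, P))
    n = np.arange(P)
    C[0] = 1.0 / np.sqrt(P)
    for k in range(1, (P - 1) // 2 + 1):
        C[2 * k - 1] = np.sqrt(2.0 / P) * np.cos(2.0 * np.pi * k * n / P)
        C[2 * k] = np.sqrt(2.0 / P) * np.sin(2.0 * np.pi * k * n / P)
    if P % 2 == 0:
        C[P - 1] = (-1.0) ** n / np.sqrt(P)
    return C


def _mode_indices(P: int) -> np.ndarray:
    """Ring wavenumber k for each row of :func:`normal_mode_matrix`."""
    k = np.empty(P, dtype=int)
    k[0] = 0
    for j in range(1, (P - 1) // 2 + 1):
        k[2 * j - 1] = j
        k[2 * j] = j
    if P % 2 == 0:
        k[P - 1] = P // 2
    return k


def spring_frequency(P: int, beta: float) -> float:
    """Inter-bead spring frequency sqrt(P)/(beta*hbar), fs^-1."""
    return np.sqrt(P) / (beta * HBAR)


def rp_dynamic_frequencies(P: int, beta: float) -> np.ndarray:
    """Dynamic normal-mode frequencies 2*w_sp*sin(pi k/P) for each mode row."""
    k = _mode_indices(P)
    return 2.0 * spring_frequency(P, beta) * np.sin(np.pi * k / P)


def rp_energy_forces(
    state: RingPolymerState, surface: Surface, masses: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Ring-polymer potential (spring + mean physical) and bead forces.

    Returns ``(energy, forces)`` with energy of shape ``batch`` and forces
    of the full bead shape.  Forces include both the spring and the (1/P)
    physical contributions.
    """
    x = state.positions
    P = state.n_beads
    wsp = spring_frequency(P, state.beta)
    ksp = masses[:, None] * wsp**2 / FORCE_TO_ACCEL  # kcal/mol/Å^2 per particle
    e_phys = surface.energy(x).mean(axis=-1)
    f_phys = surface.forces(x) / P
    if P > 1:
        d = x - np.roll(x, -1, axis=-3)
        e_spr = 0.5 * np.sum(ksp * d * d, axis=(-3, -2, -1))
        f_spr = -ksp * (2.0 * x - np.roll(x, -1, axis=-3) - np.roll(x, 1, axis=-3))
    else:
        e_spr = np.zeros(x.shape[:-3])
        f_spr = np.zeros_like(x)
    return e_spr + e_phys, f_spr + f_phys


def centroid_bias(
    state: RingPolymerState,
    window: UmbrellaWindow,
    rc: ReactionCoordinateSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Umbrella bias on the centroid coordinates.

    xi is evaluated at the centroid; by the chain rule each bead receives
    1/P of the classical bias force evaluated there.
    """
    k = window.k_array
    if len(k) != rc.ndim:
        raise ValueError("window/coordinate dimension mismatch")
    u = state.centroid()
    xi, jac = rc.values_jacobian(u)
    d = xi - window.center_array
    e = np.sum(k * d * d, axis=-1)
    f_cent = -np.einsum("...k,...kij->...ij", 2.0 * k * d, jac)
    P = state.n_beads
    f_beads = np.repeat(np.expand_dims(f_cent / P, -3), P, axis=-3)
    return e, f_beads


def degree_of_expansion(positions: np.ndarray, particle_index: int) -> np.ndarray:
    """Mean bead-centroid distance (Å) of one particle.

    ``positions`` has shape ``(..., P, N, dim)``; returns the batch shape.
    Zero iff all beads of the particle coincide.
    """
    r = positions[..., :, particle_index, :]
    u = r.mean(axis=-2, keepdims=True)
    return np.linalg.norm(r - u, axis=-1).mean(axis=-1)


def initialize_ring_polymer(
    x_classical: np.ndarray,
    P: int,
    masses: np.ndarray,
    temperature: float,
    rng,
    spread: float = 0.02,
) -> RingPolymerState:
    """Ring polymer started from a classical configuration.

    Beads are jittered by ``spread`` Å around the classical point and
    velocities drawn from Maxwell-Boltzmann at T.
    """
    x = np.asarray(x_classical, float)
    beads = np.repeat(np.expand_dims(x, -3), P, axis=-3)
    beads = beads + spread * rng.standard_normal(beads.shape)
    # keep the centroid exactly at the classical start
    beads -= beads.mean(axis=-3, keepdims=True) - x[..., None, :, :].mean(axis=-3, keepdims=True)
    sigma = np.sqrt(KB * temperature * FORCE_TO_ACCEL / masses)[:, None]
    v = rng.standard_normal(beads.shape) * sigma
    return RingPolymerState(beads, v, temperature)


def _nm_propagators(P: int, beta: float, dt: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """cos/sin coefficient tables for the exact half-step free-RP evolution."""
    w = rp_dynamic_frequencies(P, beta)
    th = w * dt
    c = np.cos(th)
    # sin(w t)/w with the w->0 limit t
    s_over = np.where(w > 0, np.sin(th) / np.where(w > 0, w, 1.0), dt)
    return w, c, s_over, np.sin(th) * w


def pimd_step(
    state: RingPolymerState,
    force_fn: Callable[[np.ndarray], np.ndarray],
    masses: np.ndarray,
    dt: float,
    rng,
    centroid_gamma: float = 0.005,
    thermostat: bool = True,
    f: np.ndarray | None = None,
) -> tuple[RingPolymerState, np.ndarray]:
    """One BAOAB-type PIMD update with exact normal-mode free-RP propagation.

    ``force_fn`` must return the *non-spring* bead forces (mean physical
    force + any centroid bias), shaped like the bead positions.  The spring
    forces are handled exactly in normal-mode coordinates.  With
    ``thermostat=True`` a PILE scheme is applied: friction 2*w_k on internal
    modes, ``centroid_gamma`` (fs^-1) on the centroid.  Checks dt against
    the physical-force stability limit is the caller's concern; the spring
    part is exact for any dt.
    """
    P = state.n_beads
    beta = state.beta
    C = normal_mode_matrix(P)
    w, cos_h, sinw_h, wsin_h = _nm_propagators(P, beta, 0.5 * dt)
    m = masses[:, None]
    x, v = state.positions, state.velocities
    if f is None:
        f = force_fn(x)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite forces")

    # B: half kick from physical + bias forces
    v = v + 0.5 * dt * f * FORCE_TO_ACCEL / m

    # A: exact free-RP half step in normal modes
    q = np.einsum("kn,...nij->...kij", C, x)
    p = np.einsum("kn,...nij->...kij", C, v)
    q, p = (
        cos_h[:, None, None] * q + sinw_h[:, None, None] * p,
        cos_h[:, None, None] * p - wsin_h[:, None, None] * q,
    )

    # O: PILE Ornstein-Uhlenbeck per mode (full dt)
    if thermostat:
        gam = 2.0 * w
        gam[0] = centroid_gamma
        c1 = np.exp(-gam * dt)[:, None, None]
        sig = np.sqrt(KB * state.temperature * FORCE_TO_ACCEL / m)
        p = c1 * p + np.sqrt(1.0 - c1 * c1) * sig * rng.standard_normal(p.shape)

    # A: second exact half step
    q, p = (
        cos_h[:, None, None] * q + sinw_h[:, None, None] * p,
        cos_h[:, None, None] * p - wsin_h[:, None, None] * q,
    )
    x = np.einsum("nk,...nij->...kij", C, q)
    v = np.einsum("nk,...nij->...kij", C, p)

    # B: final half kick
    f = force_fn(x)
    v = v + 0.5 * dt * f * FORCE_TO_ACCEL / m
    return RingPolymerState(x, v, state.temperature), f


def virial_energy_sample(
    positions: np.ndarray, surface: Surface, temperature: float
) -> np.ndarray:
    """Centroid-virial total-energy estimator for one configuration.

    E_cv = (d N / 2) kB T + (1/P) sum_n [ V(r_n) + 1/2 (r_n - u_c) . dV/dr_n ]

    Averaged over an equilibrated trajectory this converges to the exact
    finite-P quantum total energy (kcal/mol).
    """
    x = np.asarray(positions, float)
    P, N, dim = x.shape[-3:]
    u = x.mean(axis=-3, keepdims=True)
    V = surface.energy(x)
    g = surface.gradient(x)
    vir = 0.5 * np.sum((x - u) * g, axis=(-2, -1))
    return 0.5 * dim * N * KB * temperature + (V + vir).mean(axis=-1)


def _pimd_force(surface, rc, windows, P):
    centers = np.stack([w.center_array for w in windows])
    ks = np.stack([w.k_array for w in windows])

    def force(x):  # x: (W, P, N, dim)
        f = surface.forces(x) / P
        u = x.mean(axis=-3)
        xi, jac = rc.values_jacobian(u)
        d = xi - centers
        fc = -np.einsum("...k,...kij->...ij", 2.0 * ks * d, jac)
        return f + fc[:, None, :, :] / P

    return force


def run_pimd_window(
    system: ModelSystem,
    surface: Surface,
    rc: ReactionCoordinateSet,
    window: UmbrellaWindow,
    schedule: Schedule,
    P: int,
    seed: int = 0,
    trial: int = 0,
    x0: np.ndarray | None = None,
    track_expansion: bool = True,
) -> WindowSamples:
    """PIMD umbrella sampling of one window (centroid restraint)."""
    return run_pimd_windows(
        system, surface, rc, [window], schedule, P, seed, trial,
        None if x0 is None else np.asarray(x0)[None], track_expansion,
    )[0]


def run_pimd_windows(
    system: ModelSystem,
    surface: Surface,
    rc: ReactionCoordinateSet,
    windows: Sequence[UmbrellaWindow],
    schedule: Schedule,
    P: int,
    seed: int = 0,
    trial: int = 0,
    x0: np.ndarray | None = None,
    track_expansion: bool = True,
) -> list[WindowSamples]:
    """Vectorized PIMD umbrella sampling over a window ladder.

    Records centroid reaction-coordinate values every stride; when
    ``track_expansion`` is set, the per-sample degree of expansion of each
    transferring proton is stored in ``extras['drh_<label>']`` along with
    the per-sample virial energy term in ``extras['virial']``.
    """
    from .sampling import prepare_window_positions

    W = len(windows)
    if x0 is None:
        x0 = prepare_window_positions(system, surface, rc, windows)
    rngs = [window_rng(seed, w.window_id, trial) for w in windows]
    rng = _StackedRNG(rngs)
    state = initialize_ring_polymer(np.asarray(x0, float), P, system.masses,
                                    schedule.temperature, rng)
    force = _pimd_force(surface, rc, windows, P)

    protons = system.transferring_protons() if track_expansion else ()
    proton_idx = {h: system.index(h) for h in protons}
    n_keep = schedule.prod_steps // schedule.stride_steps
    xi_out = np.empty((n_keep, W, rc.ndim))
    drh_out = {h: np.empty((n_keep, W)) for h in protons}
    vir_out = np.empty((n_keep, W))
    f = force(state.positions)
    k_out = 0
    total = schedule.equil_steps + schedule.prod_steps
    for step in range(1, total + 1):
        try:
            state, f = pimd_step(state, force, system.masses, schedule.dt, rng,
                                 centroid_gamma=schedule.gamma, f=f)
        except (FloatingPointError, ValueError) as e:
            raise RuntimeError(f"PIMD sampling failed at step {step}: {e}") from e
        prod_step = step - schedule.equil_steps
        if prod_step > 0 and prod_step % schedule.stride_steps == 0:
            xi_out[k_out] = rc.values(state.centroid())
            for h, ih in proton_idx.items():
                drh_out[h][k_out] = degree_of_expansion(state.positions, ih)
            vir_out[k_out] = virial_energy_sample(state.positions, surface,
                                                  schedule.temperature)
            k_out += 1

    out = []
    for i, w in enumerate(windows):
        extras = {f"drh_{h}": drh_out[h][:, i] for h in protons}
        extras["virial"] = vir_out[:, i]
        out.append(
            WindowSamples(
                window=w, xi=xi_out[:, i, :], dt=schedule.dt,
                stride=schedule.stride_steps * schedule.dt,
                temperature=schedule.temperature, seed=seed, trial=trial,
                equil_time=schedule.equil_time, extras=extras,
            )
        )
    return out
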