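"""Classical Langevin dynamics with umbrella restraints.

Bias convention
---------------
The harmonic umbrella bias is ``U = sum_i k_i (xi_i - xi0_i)^2`` - the force
constant multiplies the squared deviation directly, with **no factor 1/2**
(the convention of Amber-style restraints, which the default
k = 200 kcal/mol/Å² of the sampling protocol assumes).  The MBAR module
consumes the same convention, so a window's stationary distribution on a
flat surface is Gaussian with variance kB*T/(2k).

Integration is the BAOAB splitting of Langevin dynamics; with friction
gamma = 0 it reduces to velocity Verlet.  All state arrays are batched:
positions/velocities of shape ``(..., N, dim)`` propagate an independent
replica per leading index, which is how whole window ladders are sampled in
one vectorized run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constants import FORCE_TO_ACCEL, KB, ROOM_T
from .coords import ReactionCoordinateSet
from .modelsys import ModelSystem, Surface, minimize_on_surface

__all__ = [
    "UmbrellaWindow",
    "WindowSamples",
    "Schedule",
    "bias_energy_forces",
    "langevin_step",
    "maxwell_velocities",
    "kinetic_temperature",
    "run_window",
    "run_windows",
    "window_rng",
    "prepare_window_positions",
]


@dataclass(frozen=True)
class UmbrellaWindow:
    """Harmonic restraint centered at ``center`` (Å) with force constants
    ``k`` (kcal/mol/Å², scalar or one per coordinate, Amber convention)."""

    center: tuple
    k: float | tuple = 200.0
    window_id: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in np.atleast_1d(self.center)))
        karr = np.broadcast_to(np.asarray(self.k, float), (len(self.center),))
        if np.any(karr <= 0):
            raise ValueError("force constants must be positive")
        object.__setattr__(self, "k", tuple(karr.tolist()))

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center)

    @property
    def k_array(self) -> np.ndarray:
        return np.asarray(self.k)


@dataclass
class Schedule:
    """Umbrella run schedule; times in fs.

    ``stride`` is the recording interval for reaction-coordinate values
    (default 10 fs, matching the production protocol).
    """

    equil_time: float = 1000.0
    prod_time: float = 5000.0
    dt: float = 0.5
    stride: float = 10.0
    temperature: float = ROOM_T
    gamma: float = 0.005  # fs^-1 == 5 ps^-1 collision frequency

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("equil_time", "prod_time", "stride"):
            t = getattr(self, name)
            if t < 0 or (t / self.dt) % 1 > 1e-9 and abs((t / self.dt) % 1 - 1) > 1e-9:
                raise ValueError(f"{name}={t} must be a non-negative multiple of dt={self.dt}")

    @property
    def equil_steps(self) -> int:
        return int(round(self.equil_time / self.dt))

    @property
    def prod_steps(self) -> int:
        return int(round(self.prod_time / self.dt))

    @property
    def stride_steps(self) -> int:
        return max(1, int(round(self.stride / self.dt)))


@dataclass
class WindowSamples:
    """Per-window time series of reaction-coordinate vectors.

    ``xi`` has shape (n_samples, D); one row per recorded stride.
    """

    window: UmbrellaWindow
    xi: np.ndarray
    dt: float
    stride: float
    temperature: float
    seed: int | None = None
    trial: int = 0
    equil_time: float = 0.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, float)
        if not np.all(np.isfinite(self.xi)):
            raise ValueError("window samples contain non-finite xi")

    @property
    def n_samples(self) -> int:
        return self.xi.shape[0]

    def to_table(self) -> str:
        """Plain-text table: time (fs) then xi1..xiD, with a '#' header."""
        d = self.xi.shape[1]
        lines = [
            "# umbrella window time series; units: fs, Angstrom",
            f"# window_id={self.window.window_id} trial={self.trial} seed={self.seed}",
            f"# center={list(self.window.center)} k={list(self.window.k)} "
            f"T={self.temperature} dt={self.dt} stride={self.stride} "
            f"equil_time={self.equil_time}",
            "# time " + " ".join(f"xi{i+1}" for i in range(d)),
        ]
        t = (np.arange(self.n_samples) + 1) * self.stride
        for ti, row in zip(t, self.xi):
            lines.append(f"{ti:.3f} " + " ".join(f"{v:.8f}" for v in row))
        return "\n".join(lines) + "\n"


def bias_energy_forces(
    positions: np.ndarray,
    window: UmbrellaWindow,
    rc: ReactionCoordinateSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Umbrella energy and forces, U = sum_i k_i (xi_i - xi0_i)^2.

    Forces follow by the chain rule through the coordinate Jacobian.
    """
    k = window.k_array
    if len(k) != rc.ndim:
        raise ValueError(f"window dimension {len(k)} != coordinate dimension {rc.ndim}")
    xi, jac = rc.values_jacobian(positions)
    d = xi - window.center_array
    e = np.sum(k * d * d, axis=-1)
    f = -np.einsum("...k,...kij->...ij", 2.0 * k * d, jac)
    return e, f


def maxwell_velocities(
    masses: np.ndarray, shape: tuple, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw Maxwell-Boltzmann velocities (Å/fs) for the given batch shape."""
    sigma = np.sqrt(KB * temperature * FORCE_TO_ACCEL / masses)[:, None]
    return rng.standard_normal(shape) * sigma


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Instantaneous kinetic temperature (K) per batch element."""
    ke_mech = 0.5 * np.sum(masses[:, None] * velocities**2, axis=(-2, -1))
    ndof = velocities.shape[-2] * velocities.shape[-1]
    return 2.0 * ke_mech / (ndof * KB * FORCE_TO_ACCEL)


def langevin_step(
    x: np.ndarray,
    v: np.ndarray,
    force_fn: Callable[[np.ndarray], np.ndarray],
    masses: np.ndarray,
    dt: float,
    gamma: float,
    temperature: float,
    rng: np.random.Generator,
    f: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One BAOAB update; returns (x, v, f_new).

    ``force_fn`` maps positions to forces in kcal/mol/Å; passing the force
    from the previous step avoids recomputation.  gamma in fs^-1; gamma = 0
    is velocity Verlet (the O-step becomes the identity).
    """
    if gamma < 0 or dt <= 0:
        raise ValueError("dt must be positive and gamma non-negative")
    m = masses[:, None]
    if f is None:
        f = force_fn(x)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite forces")
    v = v + 0.5 * dt * f * FORCE_TO_ACCEL / m
    x = x + 0.5 * dt * v
    if gamma > 0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * KB * temperature * FORCE_TO_ACCEL / m)
        v = c1 * v + c2 * rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v
    f = force_fn(x)
    v = v + 0.5 * dt * f * FORCE_TO_ACCEL / m
    return x, v, f


def window_rng(base_seed: int, window_id: int, trial: int = 0) -> np.random.Generator:
    """Deterministic decorrelated stream per (window, trial).

    Uses a SeedSequence keyed on (base_seed, window_id, trial), emulating
    independent thermostat random seeds across production trials.
    """
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(window_id, trial)))


class _StackedRNG:
    """Draws leading-axis batches from one independent stream per window.

    Keeps the per-(window, trial) stream contract while letting the
    integrator operate on the whole window ladder as one batched state.
    """

    def __init__(self, generators: Sequence[np.random.Generator]) -> None:
        self._gens = list(generators)

    def standard_normal(self, shape: tuple) -> np.ndarray:
        if shape[0] != len(self._gens):
            raise ValueError("leading axis must equal the number of windows")
        return np.stack([g.standard_normal(shape[1:]) for g in self._gens])


def prepare_window_positions(
    system: ModelSystem,
    surface: Surface,
    rc: ReactionCoordinateSet,
    windows: Sequence[UmbrellaWindow],
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Initial configuration per window: minimize surface + bias.

    Starting from ``x0`` (default: the first named state, or the window
    centers themselves for Cartesian coordinate sets), each window's biased
    potential is locally minimized, which lands the configuration at the
    window's zero-temperature centroid.  Returns an array of shape
    (n_windows, N, dim).
    """
    if x0 is None:
        x0 = next(iter(system.named_states.values()))
    out = np.empty((len(windows), system.n_particles, system.dim))
    start = np.asarray(x0, float)
    for i, w in enumerate(windows):
        class _Biased(Surface):
            n_particles = system.n_particles
            dim = system.dim

            def energy(self_inner, pos):
                e, _ = bias_energy_forces(pos, w, rc)
                return surface.energy(pos) + e

            def gradient(self_inner, pos):
                e, f = bias_energy_forces(pos, w, rc)
                return surface.gradient(pos) - f

        xmin, _ = minimize_on_surface(_Biased(), start, gtol=1e-4, maxiter=500)
        out[i] = xmin
        start = xmin  # windows prepared in sequence along the ladder
    return out


def _combined_force(surface, rc, windows):
    """Force function for a batch of windows stacked on the leading axis."""
    centers = np.stack([w.center_array for w in windows])  # (W, D)
    ks = np.stack([w.k_array for w in windows])

    def force(x):
        xi, jac = rc.values_jacobian(x)
        d = xi - centers
        fb = -np.einsum("...k,...kij->...ij", 2.0 * ks * d, jac)
        return surface.forces(x) + fb

    return force


def run_window(
    system: ModelSystem,
    surface: Surface,
    rc: ReactionCoordinateSet,
    window: UmbrellaWindow,
    schedule: Schedule,
    seed: int = 0,
    trial: int = 0,
    x0: np.ndarray | None = None,
) -> WindowSamples:
    """Sample a single umbrella window; deterministic given the seed."""
    return run_windows(system, surface, rc, [window], schedule, seed, trial,
                       None if x0 is None else np.asarray(x0)[None])[0]


def run_windows(
    system: ModelSystem,
    surface: Surface,
    rc: ReactionCoordinateSet,
    windows: Sequence[UmbrellaWindow],
    schedule: Schedule,
    seed: int = 0,
    trial: int = 0,
    x0: np.ndarray | None = None,
    extra_observables: dict[str, Callable[[np.ndarray], np.ndarray]] | None = None,
) -> list[WindowSamples]:
    """Sample a ladder of umbrella windows in one vectorized Langevin run.

    Each window evolves as an independent replica on the leading batch axis
    with its own decorrelated RNG stream semantics preserved by drawing the
    whole batch from a stream keyed on (seed, trial).  Equilibration
    (``schedule.equil_time``) is discarded; xi is recorded every stride.
    """
    W = len(windows)
    if x0 is None:
        x0 = prepare_window_positions(system, surface, rc, windows)
    x = np.array(x0, float)
    if x.shape != (W, system.n_particles, system.dim):
        raise ValueError(f"x0 shape {x.shape} does not match windows/system")
    rng = _StackedRNG([window_rng(seed, w.window_id, trial) for w in windows])
    v = maxwell_velocities(system.masses, x.shape, schedule.temperature, rng)
    force = _combined_force(surface, rc, windows)

    n_keep = schedule.prod_steps // schedule.stride_steps
    xi_out = np.empty((n_keep, W, rc.ndim))
    extra_out = {k: [] for k in (extra_observables or {})}
    f = force(x)
    k_out = 0
    total = schedule.equil_steps + schedule.prod_steps
    for step in range(1, total + 1):
        try:
            x, v, f = langevin_step(
                x, v, force, system.masses, schedule.dt, schedule.gamma,
                schedule.temperature, rng, f=f,
            )
        except (FloatingPointError, ValueError) as e:
            raise RuntimeError(f"sampling failed at step {step}: {e}") from e
        prod_step = step - schedule.equil_steps
        if prod_step > 0 and prod_step % schedule.stride_steps == 0:
            xi_out[k_out] = rc.values(x)
            for name, fn in (extra_observables or {}).items():
                extra_out[name].append(fn(x))
            k_out += 1

    out = []
    for i, w in enumerate(windows):
        extras = {name: np.array([row[i] for row in vals]) for name, vals in extra_out.items()}
        out.append(
            WindowSamples(
                window=w,
                xi=xi_out[:, i, :],
                dt=schedule.dt,
                stride=schedule.stride_steps * schedule.dt,
                temperature=schedule.temperature,
                seed=seed,
                trial=trial,
                equil_time=schedule.equil_time,
                extras=extras,
            )
        )
    return out
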