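"""Finite-temperature string method in reaction-coordinate space.

A string is an ordered set of M images in the D-dimensional space of the
reaction coordinates, reparametrized to uniform arc length so each image
carries a progress variable s in [0, 1].  Iteration follows the
mean-displacement variant of the finite-temperature string method: umbrella
windows are spawned at the images, sampled briefly, and each interior image
moves a fraction eta toward its window's sampled mean, after which the
string is smoothed (three-point average, weight kappa) and reparametrized.
At convergence the images trace the minimum free energy path: the window
mean equals the window center when the bias force balances the mean force,
which on the MFEP has no component transverse to the path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coords import ReactionCoordinateSet
from .modelsys import ModelSystem, Surface
from .sampling import Schedule, UmbrellaWindow, prepare_window_positions, run_windows

__all__ = [
    "StringPath",
    "init_linear",
    "update_images",
    "smooth_images",
    "reparametrize",
    "run_string",
    "StringResult",
]


@dataclass
class StringPath:
    """Ordered images in reaction-coordinate space with arc-length progress."""

    images: np.ndarray  # (M, D)
    iteration: int = 0

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, float)
        if self.images.ndim != 2 or self.images.shape[0] < 3:
            raise ValueError("a string needs at least 3 images of shape (M, D)")

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    @property
    def ndim(self) -> int:
        return self.images.shape[1]

    @property
    def arc_length(self) -> np.ndarray:
        """Cumulative chord length per image, Å."""
        seg = np.linalg.norm(np.diff(self.images, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def progress(self) -> np.ndarray:
        """Normalized arc length s in [0, 1]."""
        arc = self.arc_length
        total = arc[-1]
        if total <= 0:
            raise ValueError("degenerate path of zero length")
        return arc / total

    def to_table(self) -> str:
        lines = ["# string path: index s xi1..xiD (Å)"]
        for i, (s, row) in enumerate(zip(self.progress, self.images)):
            lines.append(f"{i} {s:.8f} " + " ".join(f"{v:.8f}" for v in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str) -> "StringPath":
        rows = [
            [float(v) for v in line.split()[2:]]
            for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        ]
        return cls(np.array(rows))


def init_linear(reactant: np.ndarray, product: np.ndarray, n_images: int) -> StringPath:
    """Linear interpolation between the reactant and product coordinates."""
    if n_images < 3:
        raise ValueError("need at least 3 images")
    reactant = np.atleast_1d(np.asarray(reactant, float))
    product = np.atleast_1d(np.asarray(product, float))
    if np.allclose(reactant, product):
        raise ValueError("reactant and product coincide")
    t = np.linspace(0.0, 1.0, n_images)[:, None]
    return StringPath((1.0 - t) * reactant + t * product)


def update_images(
    path: StringPath,
    window_means: np.ndarray,
    step_size: float,
    move_endpoints: bool = False,
) -> StringPath:
    """Move images toward their umbrella-window sample means.

    ``window_means`` holds one mean per image (endpoints included; they are
    ignored unless ``move_endpoints``).  ``step_size`` (eta) in (0, 1]:
    eta = 1 jumps to the means, means == images is a fixed point.
    """
    if not 0.0 < step_size <= 1.0:
        raise ValueError("step_size must be in (0, 1]")
    means = np.asarray(window_means, float)
    if means.shape != path.images.shape:
        raise ValueError("one mean per image required")
    if not np.all(np.isfinite(means)):
        raise ValueError("NaN in window means")
    new = path.images + step_size * (means - path.images)
    if not move_endpoints:
        new[0] = path.images[0]
        new[-1] = path.images[-1]
    return StringPath(new, iteration=path.iteration)


def smooth_images(path: StringPath, kappa: float) -> StringPath:
    """Three-point weighted smoothing of the interior images.

    x_i <- (1-kappa) x_i + kappa/2 (x_{i-1} + x_{i+1}); endpoints fixed.
    Suppresses the sawtooth instability of noisy mean-displacement updates.
    """
    if kappa < 0 or kappa > 1:
        raise ValueError("kappa must be in [0, 1]")
    x = path.images
    new = x.copy()
    new[1:-1] = (1.0 - kappa) * x[1:-1] + 0.5 * kappa * (x[:-2] + x[2:])
    return StringPath(new, iteration=path.iteration)


def reparametrize(path: StringPath) -> StringPath:
    """Redistribute images to equal arc length by piecewise-linear resampling.

    Endpoints are unchanged and every new image lies exactly on the old
    polyline; the chord length of the new discretization agrees with the
    old one to O(spacing^2) for smooth paths.
    """
    arc = path.arc_length
    if arc[-1] <= 0:
        raise ValueError("degenerate path of zero length")
    target = np.linspace(0.0, arc[-1], path.n_images)
    new = np.empty_like(path.images)
    for d in range(path.ndim):
        new[:, d] = np.interp(target, arc, path.images[:, d])
    new[0], new[-1] = path.images[0], path.images[-1]
    return StringPath(new, iteration=path.iteration)


@dataclass
class StringResult:
    """Converged path plus the per-iteration history."""

    path: StringPath
    history: list[StringPath] = field(default_factory=list)
    rms_displacement: np.ndarray = field(default_factory=lambda: np.empty(0))
    final_positions: np.ndarray | None = None  # last sampled configurations/window

    @property
    def converged_rms(self) -> float:
        return float(self.rms_displacement[-1]) if len(self.rms_displacement) else np.nan


def run_string(
    system: ModelSystem,
    surface: Surface,
    rc: ReactionCoordinateSet,
    path0: StringPath,
    iterations: int = 50,
    schedule: Schedule | None = None,
    eta: float = 0.3,
    kappa: float = 0.1,
    k_umbrella: float = 200.0,
    seed: int = 0,
    rms_threshold: float = 0.01,
) -> StringResult:
    """Iteratively optimize a string with umbrella-window sampling.

    Per iteration: spawn a window at every image (force constant
    ``k_umbrella``), sample for ``schedule.prod_time``, move interior images
    toward the window means (step eta), smooth (kappa), reparametrize.
    Windows warm-start from the previous iteration's final configurations,
    so only a short equilibration per iteration is needed.  The RMS image
    displacement per iteration (Å) is recorded; iterations always run to
    the scheduled count, ``rms_threshold`` is reported, not enforced.

    Deterministic given the seed.
    """
    if schedule is None:
        schedule = Schedule(equil_time=100.0, prod_time=400.0, dt=0.5, stride=5.0)
    path = path0
    history = [path]
    rms = []
    x_start: np.ndarray | None = None
    for it in range(iterations):
        windows = [
            UmbrellaWindow(tuple(img), k_umbrella, window_id=i)
            for i, img in enumerate(path.images)
        ]
        if x_start is None:
            x_start = prepare_window_positions(system, surface, rc, windows)
        try:
            samples = run_windows(
                system, surface, rc, windows, schedule,
                seed=seed, trial=it, x0=x_start,
                extra_observables={"pos": lambda x: x},
            )
        except RuntimeError as e:
            raise RuntimeError(f"string iteration {it}: {e}") from e
        means = np.stack([s.xi.mean(axis=0) for s in samples])
        x_start = np.stack([s.extras["pos"][-1] for s in samples])
        old = path.images
        path = update_images(path, means, eta)
        path = smooth_images(path, kappa)
        path = reparametrize(path)
        path.iteration = it + 1
        rms.append(float(np.sqrt(np.mean((path.images - old) ** 2))))
        history.append(path)
    return StringResult(
        path=path,
        history=history,
        rms_displacement=np.array(rms),
        final_positions=x_start,
    )
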