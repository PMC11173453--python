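"""Reaction coordinates: distance differences and Cartesian components.

The physical reaction coordinates used for proton-transfer work are distance
differences xi = R(a,b) - R(c,d) between labelled particle pairs, tracking
the migration of a proton from a donor to an acceptor heavy atom (xi < 0:
bound to the first pair's partner; xi > 0: transferred).  Benchmark
potentials defined directly on Cartesian coordinates (Muller-Brown, 1D
double wells) use :class:`CartesianComponent` instead, so that the umbrella
sampling, string and MBAR machinery is agnostic to the coordinate type.

All evaluation routines are batched: positions may carry arbitrary leading
axes, ``positions.shape == (..., n_particles, dim)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CoincidentParticlesError",
    "DistanceDifference",
    "CartesianComponent",
    "ReactionCoordinateSet",
]

#: Pair distances below this (Å) make the distance gradient ill-defined.
_COINCIDENT_TOL = 1e-8


class CoincidentParticlesError(ValueError):
    """Raised when a distance-based coordinate hits a zero interparticle distance."""


@dataclass(frozen=True)
class DistanceDifference:
    """xi = R(a, b) - R(c, d) for particle labels a, b, c, d (Å)."""

    a: str
    b: str
    c: str
    d: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"R({self.a},{self.b})-R({self.c},{self.d})"


@dataclass(frozen=True)
class CartesianComponent:
    """xi = the ``axis`` Cartesian component of particle ``label`` (Å)."""

    label: str
    axis: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.label}[{self.axis}]"


def _pair_distance(x: np.ndarray, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
    """Distance and unit separation vector between particles i and j.

    Returns ``(r, u)`` with ``r.shape == x.shape[:-2]`` and u the normalized
    (ri - rj) vector.
    """
    d = x[..., i, :] - x[..., j, :]
    r = np.linalg.norm(d, axis=-1)
    if np.any(r < _COINCIDENT_TOL):
        raise CoincidentParticlesError(
            f"particles {i} and {j} are coincident (distance < {_COINCIDENT_TOL} Å); "
            "distance gradient undefined"
        )
    return r, d / r[..., None]


class ReactionCoordinateSet:
    """An ordered list of D reaction coordinates bound to a particle label list.

    Parameters
    ----------
    coordinates:
        Sequence of :class:`DistanceDifference` / :class:`CartesianComponent`.
    labels:
        Particle labels of the model system, in storage order.  Every label
        referenced by a coordinate must resolve here.
    """

    def __init__(
        self,
        coordinates: Sequence[DistanceDifference | CartesianComponent],
        labels: Sequence[str],
    ) -> None:
        if len(coordinates) < 1:
            raise ValueError("need at least one reaction coordinate")
        self.coordinates = tuple(coordinates)
        self.labels = tuple(labels)
        index = {lab: i for i, lab in enumerate(labels)}
        if len(index) != len(labels):
            raise ValueError("duplicate particle labels")
        self._resolved: list[tuple] = []
        for c in coordinates:
            if isinstance(c, DistanceDifference):
                try:
                    self._resolved.append(
                        ("dd", index[c.a], index[c.b], index[c.c], index[c.d])
                    )
                except KeyError as e:  # pragma: no cover - defensive
                    raise KeyError(f"coordinate {c} references unknown label {e}") from e
            elif isinstance(c, CartesianComponent):
                if c.label not in index:
                    raise KeyError(f"coordinate {c} references unknown label {c.label}")
                self._resolved.append(("cc", index[c.label], c.axis))
            else:
                raise TypeError(f"unsupported coordinate type {type(c)!r}")

    @property
    def ndim(self) -> int:
        """Number of reaction coordinates D."""
        return len(self.coordinates)

    def values(self, positions: np.ndarray) -> np.ndarray:
        """Evaluate xi; output shape ``positions.shape[:-2] + (D,)``."""
        x = np.asarray(positions, dtype=float)
        out = np.empty(x.shape[:-2] + (self.ndim,))
        for k, spec in enumerate(self._resolved):
            if spec[0] == "dd":
                _, i, j, m, n = spec
                r1, _ = _pair_distance(x, i, j)
                r2, _ = _pair_distance(x, m, n)
                out[..., k] = r1 - r2
            else:
                _, i, ax = spec
                out[..., k] = x[..., i, ax]
        return out

    def values_jacobian(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """xi and its Jacobian d(xi_k)/d(r_i).

        Returns ``(xi, jac)`` with ``jac.shape == batch + (D, n_particles, dim)``.
        """
        x = np.asarray(positions, dtype=float)
        batch = x.shape[:-2]
        n, dim = x.shape[-2:]
        xi = np.empty(batch + (self.ndim,))
        jac = np.zeros(batch + (self.ndim, n, dim))
        for k, spec in enumerate(self._resolved):
            if spec[0] == "dd":
                _, i, j, m, p = spec
                r1, u1 = _pair_distance(x, i, j)
                r2, u2 = _pair_distance(x, m, p)
                xi[..., k] = r1 - r2
                jac[..., k, i, :] += u1
                jac[..., k, j, :] -= u1
                jac[..., k, m, :] -= u2
                jac[..., k, p, :] += u2
            else:
                _, i, ax = spec
                xi[..., k] = x[..., i, ax]
                jac[..., k, i, ax] = 1.0
        return xi, jac
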