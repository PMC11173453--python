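"""Model systems and analytic potential-energy surfaces.

The centrepiece is a desk-scale planar cluster that emulates a G-T mispair
with two transferable protons.  Eight particles carry the labels of the
hydrogen-bonding atoms of a wobble G-T pair (N3, H3, O6, O4, N1, H1, N2,
O2).  Proton H3 shuttles between N3 and O6 and proton H1 between N1 and O4;
the two distance-difference coordinates

    xi1 = R(N3,H3) - R(O6,H3),    xi2 = R(N1,H1) - R(O4,H1)

span a triple-well free-energy landscape whose named minima play the roles
of the wobble state (wGT), the thymine-enol Watson-Crick-like state (GT*)
and the guanine-enol state (G*T):

    wGT  ~ (-0.8, -0.8) Å      both protons on their donors
    GT*  ~ (+0.8, -0.8) Å      H3 transferred
    G*T  ~ (-0.8, +0.8) Å      H1 transferred

so wGT->GT* and wGT->G*T are single proton transfers while GT* <-> G*T is a
concerted double proton transfer, mirroring the topology of the real
tautomerization network.

Two surfaces are built per system: an accurate "reference" surface (the
stand-in for an ab initio QM/MM potential) and a cheap "base" surface (the
stand-in for a semiempirical potential) defined as reference minus a smooth
truth correction - a small sum of Gaussians in reaction-coordinate space
placed near the saddle regions, so the base model systematically
overestimates the barriers.  The Δ-learning module recovers exactly this
correction from energy/force residuals.

Surfaces accept batched positions of shape ``(..., n_particles, dim)`` and
return energies in kcal/mol and gradients in kcal/mol/Å.
"""

from __future__ import annotations

import io
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import minimize

from .constants import MECH_TO_KCAL
from .coords import DistanceDifference, ReactionCoordinateSet

__all__ = [
    "ModelSystem",
    "Surface",
    "HarmonicSurface",
    "MuellerBrownSurface",
    "QuarticDoubleWellSurface",
    "GTClusterSurface",
    "GaussianBumps",
    "ShiftedSurface",
    "build_gt_toy",
    "gt_reaction_coordinates",
    "harmonic_system",
    "double_well_system",
    "muller_brown_system",
    "find_minima",
    "minimize_on_surface",
]


# --------------------------------------------------------------------------
# model system container
# --------------------------------------------------------------------------


@dataclass
class ModelSystem:
    """Particles, topology and named reference states of a model cluster.

    Attributes
    ----------
    labels:
        Particle labels in storage order (e.g. ``("N3", "H3", ...)``).
    masses:
        Particle masses, amu; all positive.
    dim:
        Spatial dimensionality of the cluster (1, 2 or 3).
    named_states:
        Mapping state name -> Cartesian coordinates (n_particles, dim), Å.
        For the G-T toy these are the wGT/GT*/G*T analogues, polished to be
        local minima of the reference surface.
    donor_acceptor:
        Triples ``(donor, hydrogen, acceptor)`` of labels describing each
        transferable proton.
    """

    labels: tuple[str, ...]
    masses: np.ndarray
    dim: int
    named_states: dict[str, np.ndarray] = field(default_factory=dict)
    donor_acceptor: tuple[tuple[str, str, str], ...] = ()

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (len(self.labels),):
            raise ValueError("one mass per label required")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        for name, x in self.named_states.items():
            x = np.asarray(x, dtype=float)
            if x.shape != (len(self.labels), self.dim):
                raise ValueError(f"state {name!r} has shape {x.shape}")
            self.named_states[name] = x

    @property
    def n_particles(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def transferring_protons(self) -> tuple[str, ...]:
        return tuple(h for _, h, _ in self.donor_acceptor)

    def state_xyz(self, name: str) -> str:
        """Named state as an XYZ block (element, x, y, z); comment = state name."""
        x = self.named_states[name]
        buf = io.StringIO()
        buf.write(f"{self.n_particles}\n{name}\n")
        for lab, row in zip(self.labels, x):
            elem = "".join(ch for ch in lab if ch.isalpha()) or "X"
            xyz = np.zeros(3)
            xyz[: self.dim] = row
            buf.write(f"{elem:2s} {xyz[0]:14.8f} {xyz[1]:14.8f} {xyz[2]:14.8f}\n")
        return buf.getvalue()


# --------------------------------------------------------------------------
# surface contract
# --------------------------------------------------------------------------


class Surface(ABC):
    """Analytic potential with an energy + gradient contract.

    ``energy`` maps positions ``(..., N, dim)`` to kcal/mol with the leading
    batch axes preserved; ``gradient`` returns dE/dr in kcal/mol/Å with the
    full input shape.  Forces are the negated gradient.
    """

    n_particles: int
    dim: int

    @abstractmethod
    def energy(self, positions: np.ndarray) -> np.ndarray: ...

    @abstractmethod
    def gradient(self, positions: np.ndarray) -> np.ndarray: ...

    def energy_gradient(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.energy(positions), self.gradient(positions)

    def forces(self, positions: np.ndarray) -> np.ndarray:
        positions = _check_positions(positions)
        return -self.gradient(positions)

    def energy_forces(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        positions = _check_positions(positions)
        e, g = self.energy_gradient(positions)
        return e, -g


def _check_positions(positions: np.ndarray) -> np.ndarray:
    positions = np.asarray(positions, dtype=float)
    if not np.all(np.isfinite(positions)):
        raise ValueError("positions contain NaN/Inf")
    return positions


class HarmonicSurface(Surface):
    """V(x) = 1/2 m omega^2 |x - x0|^2 with omega in fs^-1, V in kcal/mol."""

    def __init__(self, mass: float, omega: float, dim: int = 1, center=None) -> None:
        if mass <= 0 or omega <= 0:
            raise ValueError("mass and omega must be positive")
        self.mass = float(mass)
        self.omega = float(omega)
        self.n_particles = 1
        self.dim = dim
        self.center = np.zeros((1, dim)) if center is None else np.asarray(center, float)
        # force constant in kcal/mol/Å^2
        self.k = self.mass * self.omega**2 * MECH_TO_KCAL

    def energy(self, positions: np.ndarray) -> np.ndarray:
        d = _check_positions(positions) - self.center
        return 0.5 * self.k * np.sum(d * d, axis=(-2, -1))

    def gradient(self, positions: np.ndarray) -> np.ndarray:
        d = _check_positions(positions) - self.center
        return self.k * d


class MuellerBrownSurface(Surface):
    """The Muller-Brown two-dimensional benchmark potential.

    A single particle in 2D; the potential is the canonical sum of four
    anisotropic Gaussians.  Energies are treated as kcal/mol and lengths as
    Å so the sampling machinery applies unchanged.
    """

    A = np.array([-200.0, -100.0, -170.0, 15.0])
    a = np.array([-1.0, -1.0, -6.5, 0.7])
    b = np.array([0.0, 0.0, 11.0, 0.6])
    c = np.array([-10.0, -10.0, -6.5, 0.7])
    x0 = np.array([1.0, 0.0, -0.5, -1.0])
    y0 = np.array([0.0, 0.5, 1.5, 1.0])

    n_particles = 1
    dim = 2

    def _terms(self, positions: np.ndarray) -> np.ndarray:
        x = positions[..., 0, 0][..., None] - self.x0
        y = positions[..., 0, 1][..., None] - self.y0
        return self.A * np.exp(self.a * x * x + self.b * x * y + self.c * y * y)

    def energy(self, positions: np.ndarray) -> np.ndarray:
        return np.sum(self._terms(_check_positions(positions)), axis=-1)

    def gradient(self, positions: np.ndarray) -> np.ndarray:
        positions = _check_positions(positions)
        x = positions[..., 0, 0][..., None] - self.x0
        y = positions[..., 0, 1][..., None] - self.y0
        t = self._terms(positions)
        gx = np.sum(t * (2.0 * self.a * x + self.b * y), axis=-1)
        gy = np.sum(t * (self.b * x + 2.0 * self.c * y), axis=-1)
        return np.stack([gx, gy], axis=-1)[..., None, :]


class QuarticDoubleWellSurface(Surface):
    """1D symmetric quartic double well V(x) = h ((x/a)^2 - 1)^2 + t*x.

    ``h`` is the barrier height (kcal/mol), ``a`` the half well separation
    (Å) and ``t`` an optional linear tilt making the wells inequivalent.
    """

    n_particles = 1
    dim = 1

    def __init__(self, barrier: float = 5.0, half_width: float = 1.0, tilt: float = 0.0):
        if barrier <= 0 or half_width <= 0:
            raise ValueError("barrier and half_width must be positive")
        self.h = float(barrier)
        self.a = float(half_width)
        self.t = float(tilt)

    def energy(self, positions: np.ndarray) -> np.ndarray:
        x = _check_positions(positions)[..., 0, 0]
        u = (x / self.a) ** 2 - 1.0
        return self.h * u * u + self.t * x

    def gradient(self, positions: np.ndarray) -> np.ndarray:
        x = _check_positions(positions)[..., 0, 0]
        u = (x / self.a) ** 2 - 1.0
        g = self.h * 4.0 * u * x / self.a**2 + self.t
        return g[..., None, None]


# --------------------------------------------------------------------------
# reaction-coordinate-space potentials: G-T toy cluster
# --------------------------------------------------------------------------


class GaussianBumps:
    """Sum of isotropic Gaussians in reaction-coordinate space.

    Used both as the triple-well carving of the toy potential (negative
    amplitudes = wells) and as the smooth truth correction separating the
    base and reference surfaces (the residual a Δ-learning model must
    recover).
    """

    def __init__(self, centers: np.ndarray, amplitudes: np.ndarray, sigma: float | np.ndarray):
        self.centers = np.atleast_2d(np.asarray(centers, float))
        self.amplitudes = np.atleast_1d(np.asarray(amplitudes, float))
        self.sigma = np.broadcast_to(np.asarray(sigma, float), self.amplitudes.shape).copy()
        if len(self.centers) != len(self.amplitudes):
            raise ValueError("one amplitude per center required")

    def value(self, xi: np.ndarray) -> np.ndarray:
        d2 = np.sum((xi[..., None, :] - self.centers) ** 2, axis=-1)
        return np.sum(self.amplitudes * np.exp(-0.5 * d2 / self.sigma**2), axis=-1)

    def grad(self, xi: np.ndarray) -> np.ndarray:
        d = xi[..., None, :] - self.centers
        d2 = np.sum(d * d, axis=-1)
        w = self.amplitudes * np.exp(-0.5 * d2 / self.sigma**2) / self.sigma**2
        return -np.sum(w[..., None] * d, axis=-2)

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "amplitudes": self.amplitudes.tolist(),
            "sigma": self.sigma.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GaussianBumps":
        return cls(np.array(d["centers"]), np.array(d["amplitudes"]), np.array(d["sigma"]))


class GTClusterSurface(Surface):
    """Distance-based potential of the toy G-T cluster.

    Three contributions, all functions of interparticle distances only (so
    the energy is exactly invariant under rigid translations/rotations):

    * a reaction-coordinate potential ``V_rc(xi1, xi2)``: confining quartic
      bowl + three Gaussian wells at the named states + a bilinear shear
      coupling ``gamma * xi1 * xi2``;
    * stiff harmonic scaffold bonds between all heavy-atom pairs, holding
      the donor/acceptor frame near its reference geometry;
    * a collinearity term ``k_col * (R(d,H) + R(a,H) - R(d,a))`` per proton
      keeping it near its donor-acceptor axis (quadratic in the
      perpendicular displacement for interior positions).
    """

    def __init__(
        self,
        labels: Sequence[str],
        dim: int,
        rc: ReactionCoordinateSet,
        rc_bumps: GaussianBumps,
        bowl_height: float,
        bowl_scale: float,
        shear_coupling: float,
        scaffold_pairs: Sequence[tuple[int, int, float]],
        scaffold_k: float,
        collinear_triples: Sequence[tuple[int, int, int]],
        collinear_k: float,
        correction: GaussianBumps | None = None,
    ) -> None:
        self.n_particles = len(labels)
        self.dim = dim
        self.rc = rc
        self.rc_bumps = rc_bumps
        self.bowl_height = float(bowl_height)
        self.bowl_scale = float(bowl_scale)
        self.shear_coupling = float(shear_coupling)
        self.scaffold_pairs = list(scaffold_pairs)
        self.scaffold_k = float(scaffold_k)
        self.collinear_triples = list(collinear_triples)
        self.collinear_k = float(collinear_k)
        #: optional extra RC-space term (the *negated* truth correction on the
        #: base surface); None on the reference surface.
        self.correction = correction
        # flattened pair tables so energy/gradient are single gather+einsum ops
        pi, pj, r0 = [], [], []
        for i, j, r in self.scaffold_pairs:
            pi.append(i); pj.append(j); r0.append(r)
        self._ns = len(pi)
        lin_coef = []
        for d, h, a in self.collinear_triples:
            for (u, v), c in (((d, h), 1.0), ((a, h), 1.0), ((d, a), -1.0)):
                pi.append(u); pj.append(v); lin_coef.append(self.collinear_k * c)
        self._pi = np.array(pi, dtype=int)
        self._pj = np.array(pj, dtype=int)
        self._r0 = np.array(r0)
        self._lin = np.array(lin_coef)
        S = np.zeros((self.n_particles, len(pi)))
        for p, (i, j) in enumerate(zip(self._pi, self._pj)):
            S[i, p] += 1.0
            S[j, p] -= 1.0
        self._scatter = S

    # -- RC-space scalar potential -------------------------------------
    def _v_rc(self, xi: np.ndarray) -> np.ndarray:
        r2 = np.sum(xi * xi, axis=-1) / self.bowl_scale**2
        v = self.bowl_height * r2 * r2 + self.rc_bumps.value(xi)
        v = v + self.shear_coupling * xi[..., 0] * xi[..., 1]
        if self.correction is not None:
            v = v - self.correction.value(xi)
        return v

    def _dv_rc(self, xi: np.ndarray) -> np.ndarray:
        r2 = np.sum(xi * xi, axis=-1, keepdims=True) / self.bowl_scale**2
        g = self.bowl_height * 4.0 * r2 * xi / self.bowl_scale**2 + self.rc_bumps.grad(xi)
        g = g + self.shear_coupling * np.stack([xi[..., 1], xi[..., 0]], axis=-1)
        if self.correction is not None:
            g = g - self.correction.grad(xi)
        return g

    # -- full surface ----------------------------------------------------
    def _pair_distances(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = x[..., self._pi, :] - x[..., self._pj, :]
        return d, np.linalg.norm(d, axis=-1)

    def energy(self, positions: np.ndarray) -> np.ndarray:
        x = _check_positions(positions)
        e = self._v_rc(self.rc.values(x))
        _, r = self._pair_distances(x)
        ns = self._ns
        e = e + 0.5 * self.scaffold_k * np.sum((r[..., :ns] - self._r0) ** 2, axis=-1)
        e = e + np.sum(self._lin * r[..., ns:], axis=-1)
        return e

    def gradient(self, positions: np.ndarray) -> np.ndarray:
        x = _check_positions(positions)
        xi, jac = self.rc.values_jacobian(x)
        g = np.einsum("...k,...kij->...ij", self._dv_rc(xi), jac)
        d, r = self._pair_distances(x)
        ns = self._ns
        coef = np.empty(r.shape)
        coef[..., :ns] = self.scaffold_k * (r[..., :ns] - self._r0)
        coef[..., ns:] = self._lin
        g = g + np.einsum("np,...pd->...nd", self._scatter, (coef / r)[..., None] * d)
        return g


class ShiftedSurface(Surface):
    """A surface plus a scalar offset (used to re-zero energies)."""

    def __init__(self, inner: Surface, offset: float) -> None:
        self.inner = inner
        self.offset = float(offset)
        self.n_particles = inner.n_particles
        self.dim = inner.dim

    def energy(self, positions: np.ndarray) -> np.ndarray:
        return self.inner.energy(positions) + self.offset

    def gradient(self, positions: np.ndarray) -> np.ndarray:
        return self.inner.gradient(positions)


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------

_GT_LABELS = ("N3", "H3", "O6", "O4", "N1", "H1", "N2", "O2")
_GT_MASSES = {"N": 14.007, "O": 15.999, "H": 1.008}

#: Named-state reaction-coordinate centers (xi1, xi2) in Å.
GT_STATE_CENTERS = {
    "wGT": (-0.8, -0.8),
    "GT*": (0.8, -0.8),
    "G*T": (-0.8, 0.8),
}

#: Approximate saddle locations in (xi1, xi2) used to place the default
#: truth-correction bumps (base surface overestimates these barriers).
_GT_SADDLES = ((0.0, -0.8), (-0.8, 0.0), (0.0, 0.0))


def gt_reaction_coordinates(labels: Sequence[str] = _GT_LABELS) -> ReactionCoordinateSet:
    """The two proton-transfer distance-difference coordinates of the toy."""
    return ReactionCoordinateSet(
        [
            DistanceDifference("N3", "H3", "O6", "H3"),
            DistanceDifference("N1", "H1", "O4", "H1"),
        ],
        labels,
    )


def _gt_reference_geometry(da_rest: float) -> np.ndarray:
    """Planar heavy-atom frame; protons midway shifted onto their donors."""
    span = da_rest
    x = np.array(
        [
            [0.0, 0.0],  # N3
            [0.5 * (span - 0.8), 0.0],  # H3 at xi1 = -0.8
            [span, 0.0],  # O6
            [span, 3.0],  # O4
            [0.0, 3.0],  # N1
            [0.5 * (span - 0.8), 3.0],  # H1 at xi2 = -0.8
            [-1.2, 1.5],  # N2 (spectator)
            [span + 1.2, 1.5],  # O2 (spectator)
        ]
    )
    return x


def _gt_state_geometry(frame: np.ndarray, center: tuple[float, float], da_rest: float) -> np.ndarray:
    """Place protons collinearly so that xi matches ``center`` exactly."""
    x = frame.copy()
    x[1, 0] = 0.5 * (da_rest + center[0])  # H3 between N3(0) and O6(da_rest)
    x[5, 0] = 0.5 * (da_rest + center[1])  # H1 between N1 and O4
    return x


def build_gt_toy(
    well_depths: tuple[float, float, float] = (13.0, 10.5, 11.0),
    da_rest_length: float = 2.6,
    shear_coupling: float = 0.5,
    well_sigma: float = 0.38,
    ridge_heights: tuple[float, float] = (6.0, 6.0),
    ridge_sigma: float = 0.35,
    bowl_height: float = 4.0,
    bowl_scale: float = 1.2,
    scaffold_k: float = 300.0,
    collinear_k: float = 100.0,
    correction_amplitudes: tuple[float, ...] = (-2.5, -2.5, -2.5),
    correction_sigma: float = 0.45,
    minimum_gtol: float = 1e-6,
) -> tuple[ModelSystem, Surface, Surface]:
    """Build the toy G-T cluster with its reference and base surfaces.

    Parameters mirror the physically meaningful knobs: Gaussian well depths
    for (wGT, GT*, G*T) in kcal/mol, donor-acceptor rest length in Å, the
    bilinear shear coupling (kcal/mol/Å²) and the truth-correction bump
    amplitudes (kcal/mol; negative values make the base surface
    *overestimate* the barriers, emulating a semiempirical model).

    Returns ``(system, reference_surface, base_surface)``.  The reference
    surface is shifted so the wGT minimum sits at zero energy; the base
    surface is exactly ``reference - truth_correction``.  Raises
    ``ValueError`` when the requested parameters do not produce three
    distinct minima.
    """
    if len(well_depths) != 3:
        raise ValueError("three well depths required (wGT, GT*, G*T)")
    if any(d <= 0 for d in well_depths):
        raise ValueError("well depths must be positive")

    labels = _GT_LABELS
    masses = np.array([_GT_MASSES[lab[0]] for lab in labels])
    rc = gt_reaction_coordinates(labels)
    centers = np.array([GT_STATE_CENTERS[s] for s in ("wGT", "GT*", "G*T")])
    # wells at the named states plus positive ridges at the two
    # single-proton-transfer saddles: the wobble->enol steps carry much
    # higher barriers than the concerted GT*<->G*T interconversion, so the
    # double-transfer channel through (0, 0) is the low route between the
    # enol states.
    all_centers = np.vstack([centers, [[0.0, -0.8], [-0.8, 0.0]]])
    amps = np.concatenate([-np.asarray(well_depths, float), np.asarray(ridge_heights, float)])
    sigmas = np.array([well_sigma] * 3 + [ridge_sigma] * 2)
    wells = GaussianBumps(all_centers, amps, sigmas)

    frame = _gt_reference_geometry(da_rest_length)
    heavy = [i for i, lab in enumerate(labels) if not lab.startswith("H")]
    scaffold = []
    for ii, i in enumerate(heavy):
        for j in heavy[ii + 1 :]:
            scaffold.append((i, j, float(np.linalg.norm(frame[i] - frame[j]))))
    collinear = [
        (labels.index("N3"), labels.index("H3"), labels.index("O6")),
        (labels.index("N1"), labels.index("H1"), labels.index("O4")),
    ]

    def make(correction: GaussianBumps | None) -> GTClusterSurface:
        return GTClusterSurface(
            labels,
            2,
            rc,
            wells,
            bowl_height,
            bowl_scale,
            shear_coupling,
            scaffold,
            scaffold_k,
            collinear,
            collinear_k,
            correction=correction,
        )

    reference = make(None)
    correction = GaussianBumps(
        np.array(_GT_SADDLES),
        np.asarray(correction_amplitudes, float),
        correction_sigma,
    )

    # polish named states into true minima of the reference surface
    named = {}
    for name, c in GT_STATE_CENTERS.items():
        x0 = _gt_state_geometry(frame, c, da_rest_length)
        xmin, gnorm = minimize_on_surface(reference, x0, gtol=minimum_gtol)
        if gnorm > minimum_gtol * 10:
            raise ValueError(f"state {name} failed to converge to a minimum (|g|={gnorm:.2e})")
        named[name] = xmin

    # reject parameter sets without three distinct minima
    xis = np.array([rc.values(named[s]) for s in ("wGT", "GT*", "G*T")])
    if np.min(
        [np.linalg.norm(xis[i] - xis[j]) for i in range(3) for j in range(i + 1, 3)]
    ) < 0.3:
        raise ValueError("parameters yield fewer than three distinct minima")

    e0 = float(reference.energy(named["wGT"]))
    reference_shifted = ShiftedSurface(reference, -e0)
    base_inner = make(correction)
    base = ShiftedSurface(base_inner, -e0)

    system = ModelSystem(
        labels=labels,
        masses=masses,
        dim=2,
        named_states=named,
        donor_acceptor=(("N3", "H3", "O6"), ("N1", "H1", "O4")),
    )
    return system, reference_shifted, base


def harmonic_system(mass: float = 1.0, omega: float = 0.1) -> tuple[ModelSystem, HarmonicSurface]:
    """1D harmonic oscillator; the validation fixture for the PIMD engine."""
    surf = HarmonicSurface(mass, omega, dim=1)
    sys_ = ModelSystem(
        labels=("X",),
        masses=np.array([mass]),
        dim=1,
        named_states={"min": np.zeros((1, 1))},
    )
    return sys_, surf


def double_well_system(
    barrier: float = 5.0, half_width: float = 1.0, tilt: float = 0.0, mass: float = 1.0
) -> tuple[ModelSystem, QuarticDoubleWellSurface]:
    """Single particle in a 1D quartic double well (pipeline smoke system)."""
    surf = QuarticDoubleWellSurface(barrier, half_width, tilt)
    a = surf.a
    sys_ = ModelSystem(
        labels=("X",),
        masses=np.array([mass]),
        dim=1,
        named_states={"L": np.array([[-a]]), "R": np.array([[a]])},
    )
    return sys_, surf


def muller_brown_system(mass: float = 1.0) -> tuple[ModelSystem, MuellerBrownSurface]:
    """Single 2D particle on the Muller-Brown benchmark surface."""
    surf = MuellerBrownSurface()
    sys_ = ModelSystem(
        labels=("X",),
        masses=np.array([mass]),
        dim=2,
        named_states={
            "A": np.array([[-0.558, 1.442]]),
            "B": np.array([[-0.050, 0.467]]),
            "C": np.array([[0.623, 0.028]]),
        },
    )
    return sys_, surf


# --------------------------------------------------------------------------
# optimization helpers
# --------------------------------------------------------------------------


def minimize_on_surface(
    surface: Surface, x0: np.ndarray, gtol: float = 1e-6, maxiter: int = 2000
) -> tuple[np.ndarray, float]:
    """Local minimization with analytic gradients.

    Returns ``(x_min, grad_norm)`` where grad_norm is the max-abs gradient
    component (kcal/mol/Å) at the solution.
    """
    x0 = np.asarray(x0, float)
    shape = x0.shape

    def f(v):
        x = v.reshape(shape)
        e, g = surface.energy_gradient(x)
        return float(e), g.ravel()

    v = x0.ravel()
    res = minimize(f, v, jac=True, method="L-BFGS-B",
                   options={"gtol": gtol * 1e-3, "ftol": 1e-16, "maxiter": maxiter})
    v = res.x
    if np.max(np.abs(res.jac)) > gtol:
        # L-BFGS stalls near machine-precision f changes; polish the
        # stationarity condition directly with Levenberg-Marquardt
        from scipy.optimize import root

        sol = root(lambda y: surface.gradient(y.reshape(shape)).ravel(), v,
                   method="lm", options={"xtol": 1e-14, "maxiter": 500})
        cand = sol.x.reshape(shape)
        if np.max(np.abs(surface.gradient(cand))) < np.max(np.abs(res.jac)):
            v = sol.x
    x = v.reshape(shape)
    g = surface.gradient(x)
    return x, float(np.max(np.abs(g)))


def find_minima(
    surface: Surface,
    rc: ReactionCoordinateSet,
    starts: np.ndarray,
    round_tol: float = 0.15,
    gtol: float = 1e-5,
) -> np.ndarray:
    """Brute-force basin search: minimize from many starts, cluster by xi.

    Returns the distinct minima as an array of reaction-coordinate vectors,
    sorted lexicographically.  Starts that fail to reach ``gtol`` are
    dropped.
    """
    found: list[np.ndarray] = []
    for x0 in starts:
        xmin, gnorm = minimize_on_surface(surface, x0, gtol=gtol)
        if gnorm > gtol * 100:
            continue
        xi = rc.values(xmin)
        if not any(np.linalg.norm(xi - f) < round_tol for f in found):
            found.append(xi)
    return np.array(sorted(found, key=tuple))


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------


def system_to_yaml(system: ModelSystem) -> str:
    """Serialize a model system (labels, masses, states) to YAML."""
    doc = {
        "labels": list(system.labels),
        "masses": system.masses.tolist(),
        "dim": system.dim,
        "donor_acceptor": [list(t) for t in system.donor_acceptor],
        "named_states": {k: v.tolist() for k, v in system.named_states.items()},
    }
    return yaml.safe_dump(doc, sort_keys=False)


def system_from_yaml(text: str) -> ModelSystem:
    doc = yaml.safe_load(text)
    return ModelSystem(
        labels=tuple(doc["labels"]),
        masses=np.array(doc["masses"]),
        dim=int(doc["dim"]),
        named_states={k: np.array(v) for k, v in doc["named_states"].items()},
        donor_acceptor=tuple(tuple(t) for t in doc.get("donor_acceptor", [])),
    )
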