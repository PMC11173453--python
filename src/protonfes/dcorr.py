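"""Δ-learning: a smooth correction from a cheap to a reference surface.

The correction model predicts the residual energy E_ref - E_base (and, by
analytic differentiation, the residual forces) from a translation- and
rotation-invariant descriptor: inverse distances of a configured set of
particle pairs plus the reaction coordinates.  The regressor is ridge
regression over Gaussian radial basis features of the descriptor - linear
in its weights, so the fit is a deterministic closed-form solve on energy
*and* force labels jointly, and the predicted force is exactly the negated
analytic gradient of the predicted energy (no finite differences at run
time).

An extrapolation guard flags evaluations outside the (slightly inflated)
bounding box of the training descriptors, since a fitted correction has no
authority outside the ensemble it was trained on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coords import ReactionCoordinateSet
from .modelsys import ModelSystem, Surface

__all__ = [
    "TrainingSet",
    "CorrectionModel",
    "CorrectedSurface",
    "ExtrapolationWarning",
    "make_training_set",
    "train",
    "corrected_surface",
    "default_descriptor_pairs",
]


class ExtrapolationWarning(UserWarning):
    """Model evaluated outside the training ensemble's descriptor range."""


@dataclass
class TrainingSet:
    """Configurations with residual energy/force labels.

    ``positions``: (n, N, dim) Å; ``denergy``: (n,) kcal/mol residuals
    E_ref - E_base; ``dforces``: (n, N, dim) kcal/mol/Å residual forces;
    ``provenance``: one tag per frame recording which trajectory/window
    produced it (the training ensemble is part of the model's meaning).
    """

    positions: np.ndarray
    denergy: np.ndarray
    dforces: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.denergy = np.asarray(self.denergy, float)
        self.dforces = np.asarray(self.dforces, float)
        n = len(self.positions)
        if self.denergy.shape != (n,) or self.dforces.shape != self.positions.shape:
            raise ValueError("label shapes inconsistent with positions")
        if not (np.all(np.isfinite(self.denergy)) and np.all(np.isfinite(self.dforces))):
            raise ValueError("non-finite residuals")

    @property
    def n_frames(self) -> int:
        return len(self.positions)


def default_descriptor_pairs(system: ModelSystem) -> list[tuple[int, int]]:
    """Donor-H, acceptor-H and donor-acceptor index pairs of each proton."""
    pairs = []
    for d, h, a in system.donor_acceptor:
        i, j, k = system.index(d), system.index(h), system.index(a)
        pairs.extend([(i, j), (k, j), (i, k)])
    return pairs


class _Descriptor:
    """Inverse pair distances + reaction coordinates, with analytic Jacobian."""

    def __init__(self, pairs: Sequence[tuple[int, int]], rc: ReactionCoordinateSet):
        self.pairs = [tuple(p) for p in pairs]
        self.rc = rc

    @property
    def size(self) -> int:
        return len(self.pairs) + self.rc.ndim

    def value(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        feats = []
        for i, j in self.pairs:
            r = np.linalg.norm(x[..., i, :] - x[..., j, :], axis=-1)
            feats.append(1.0 / r)
        feats = np.stack(feats, axis=-1) if feats else np.zeros(x.shape[:-2] + (0,))
        return np.concatenate([feats, self.rc.values(x)], axis=-1)

    def value_jacobian(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, float)
        batch = x.shape[:-2]
        n, dim = x.shape[-2:]
        q = self.size
        val = np.empty(batch + (q,))
        jac = np.zeros(batch + (q, n, dim))
        for m, (i, j) in enumerate(self.pairs):
            d = x[..., i, :] - x[..., j, :]
            r = np.linalg.norm(d, axis=-1)
            val[..., m] = 1.0 / r
            g = -d / r[..., None] ** 3  # d(1/r)/d r_i
            jac[..., m, i, :] = g
            jac[..., m, j, :] = -g
        xi, jxi = self.rc.values_jacobian(x)
        val[..., len(self.pairs):] = xi
        jac[..., len(self.pairs):, :, :] = jxi
        return val, jac

    def to_dict(self) -> dict:
        return {"pairs": [list(p) for p in self.pairs]}


@dataclass
class CorrectionModel:
    """RBF-ridge correction: E(x) = sum_j w_j exp(-|d(x)-c_j|^2 / (2 l^2)).

    ``bounds`` is the training descriptor bounding box (with margin) used
    by the extrapolation guard.  ``fit_report`` carries the training
    metadata (loss weights, seed, RMSEs).
    """

    descriptor: _Descriptor
    centers: np.ndarray  # (M, q)
    length_scale: float
    weights: np.ndarray  # (M,)
    bounds: tuple[np.ndarray, np.ndarray]
    fit_report: dict = field(default_factory=dict)

    def _features(self, d: np.ndarray) -> np.ndarray:
        d2 = np.sum((d[..., None, :] - self.centers) ** 2, axis=-1)
        return np.exp(-0.5 * d2 / self.length_scale**2)

    def predict_energy(self, positions: np.ndarray) -> np.ndarray:
        d = self.descriptor.value(positions)
        return self._features(d) @ self.weights

    def predict_energy_gradient(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d, jd = self.descriptor.value_jacobian(positions)
        phi = self._features(d)  # (..., M)
        e = phi @ self.weights
        # dE/dd_q = sum_j w_j phi_j * -(d_q - c_jq)/l^2
        diff = d[..., None, :] - self.centers  # (..., M, q)
        dE_dd = -np.einsum("...m,...mq->...q", phi * self.weights, diff) / self.length_scale**2
        g = np.einsum("...q,...qij->...ij", dE_dd, jd)
        return e, g

    def in_domain(self, positions: np.ndarray) -> np.ndarray:
        """True where the descriptor lies inside the training bounding box."""
        d = self.descriptor.value(positions)
        lo, hi = self.bounds
        return np.all((d >= lo) & (d <= hi), axis=-1)

    def to_json(self) -> str:
        doc = {
            "descriptor": self.descriptor.to_dict(),
            "centers": self.centers.tolist(),
            "length_scale": self.length_scale,
            "weights": self.weights.tolist(),
            "bounds": [self.bounds[0].tolist(), self.bounds[1].tolist()],
            "fit_report": self.fit_report,
        }
        return json.dumps(doc, indent=1)


def make_training_set(
    trajectories: Sequence[np.ndarray],
    base: Surface,
    reference: Surface,
    stride: int = 1,
    provenance: Sequence[str] | None = None,
) -> TrainingSet:
    """Label retained frames with residual energies and forces.

    ``trajectories`` is a sequence of position arrays (n_i, N, dim), e.g.
    archived umbrella-window configurations sampled on the base surface.
    Deterministic: frames are taken every ``stride`` in order.
    """
    if base.n_particles != reference.n_particles or base.dim != reference.dim:
        raise ValueError("base and reference surfaces describe different systems")
    frames, tags = [], []
    names = list(provenance) if provenance is not None else [f"traj{i}" for i in range(len(trajectories))]
    for name, traj in zip(names, trajectories):
        t = np.asarray(traj, float)[::stride]
        frames.append(t)
        tags.extend([name] * len(t))
    x = np.concatenate(frames, axis=0)
    de = reference.energy(x) - base.energy(x)
    df = reference.forces(x) - base.forces(x)
    return TrainingSet(x, de, df, tags)


def train(
    ts: TrainingSet,
    system: ModelSystem,
    rc: ReactionCoordinateSet,
    w_energy: float = 1.0,
    w_force: float = 0.1,
    ridge: float = 1e-8,
    n_centers: int = 250,
    seed: int = 0,
    holdout_fraction: float = 0.2,
    pairs: Sequence[tuple[int, int]] | None = None,
) -> CorrectionModel:
    """Closed-form ridge fit of the RBF correction on energies and forces.

    Minimizes ``w_E * MSE(energy) + w_F * MSE(force) + ridge * |w|^2``.
    Centers are a deterministic (seeded) random subset of training
    descriptors; the length scale is the median pairwise center distance.
    A seeded held-out split reports validation RMSEs in ``fit_report``.
    Ill-conditioned designs are reported via the returned condition number,
    not silently re-regularized.
    """
    if ts.n_frames < 50:
        raise ValueError(f"need >= 50 frames to fit, got {ts.n_frames}")
    desc = _Descriptor(pairs if pairs is not None else default_descriptor_pairs(system), rc)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ts.n_frames)
    n_val = max(1, int(round(holdout_fraction * ts.n_frames)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    d_all, j_all = desc.value_jacobian(ts.positions)
    d_tr = d_all[tr_idx]
    M = min(n_centers, len(tr_idx))
    centers = d_tr[rng.choice(len(tr_idx), size=M, replace=False)]
    pd = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    off = pd[np.triu_indices(M, 1)]
    ell = float(np.median(off[off > 0])) if np.any(off > 0) else 1.0

    lo = d_all[tr_idx].min(axis=0)
    hi = d_all[tr_idx].max(axis=0)
    margin = 0.05 * (hi - lo + 1e-12)
    model = CorrectionModel(desc, centers, ell, np.zeros(M), (lo - margin, hi + margin))

    def design(idx):
        d = d_all[idx]
        diff = d[:, None, :] - centers  # (n, M, q)
        phi = np.exp(-0.5 * np.sum(diff**2, axis=-1) / ell**2)
        dphi_dd = -phi[..., None] * diff / ell**2  # (n, M, q)
        # force rows: F = -dE/dx = -(dphi/dd . dd/dx) w
        j = j_all[idx]  # (n, q, N, dim)
        gphi = np.einsum("nmq,nqij->nmij", dphi_dd, j)  # (n, M, N, dim)
        frows = -gphi.reshape(len(idx), M, -1).transpose(0, 2, 1).reshape(-1, M)
        return phi, frows

    phi_tr, frows_tr = design(tr_idx)
    ndof = ts.positions.shape[1] * ts.positions.shape[2]
    A = np.vstack([
        np.sqrt(w_energy) * phi_tr,
        np.sqrt(w_force) * frows_tr,
        np.sqrt(ridge) * np.eye(M),
    ])
    b = np.concatenate([
        np.sqrt(w_energy) * ts.denergy[tr_idx],
        np.sqrt(w_force) * ts.dforces[tr_idx].reshape(-1),
        np.zeros(M),
    ])
    w, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if rank < M:
        warnings.warn(f"ill-conditioned fit: rank {rank} < {M} features", stacklevel=2)
    model.weights = w

    def rmse(idx):
        e, g = model.predict_energy_gradient(ts.positions[idx])
        e_r = float(np.sqrt(np.mean((e - ts.denergy[idx]) ** 2)))
        f_r = float(np.sqrt(np.mean((-g - ts.dforces[idx]) ** 2)))
        return e_r, f_r

    etr, ftr = rmse(tr_idx)
    eva, fva = rmse(val_idx)
    model.fit_report = {
        "w_energy": w_energy, "w_force": w_force, "ridge": ridge,
        "n_centers": M, "length_scale": ell, "seed": seed,
        "n_train": len(tr_idx), "n_val": len(val_idx),
        "train_energy_rmse": etr, "train_force_rmse": ftr,
        "val_energy_rmse": eva, "val_force_rmse": fva,
        "condition_number": cond,
    }
    return model


class CorrectedSurface(Surface):
    """base + correction model; a drop-in :class:`Surface`.

    Emits :class:`ExtrapolationWarning` (at most once per call) when
    evaluated outside the training descriptor range.
    """

    def __init__(self, base: Surface, model: CorrectionModel, guard: bool = True):
        self.base = base
        self.model = model
        self.guard = guard
        self.n_particles = base.n_particles
        self.dim = base.dim

    def _check(self, positions: np.ndarray) -> None:
        if self.guard and not np.all(self.model.in_domain(positions)):
            warnings.warn(
                "correction model evaluated outside its training descriptor range",
                ExtrapolationWarning,
                stacklevel=3,
            )

    def energy(self, positions: np.ndarray) -> np.ndarray:
        self._check(positions)
        return self.base.energy(positions) + self.model.predict_energy(positions)

    def gradient(self, positions: np.ndarray) -> np.ndarray:
        self._check(positions)
        e, g = self.model.predict_energy_gradient(positions)
        return self.base.gradient(positions) + g


def corrected_surface(base: Surface, model: CorrectionModel, guard: bool = True) -> CorrectedSurface:
    """Compose a base surface with a trained correction model."""
    return CorrectedSurface(base, model, guard)
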