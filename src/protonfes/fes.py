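"""MBAR free-energy estimation and profiles along a path.

The multistate Bennett acceptance ratio (MBAR) estimator combines samples
from all umbrella windows into a single set of unbiased statistical
weights.  Because every window samples the same physical surface, the
reduced potential of state k at sample n is just the reduced bias

    u_kn = beta * sum_i k_i (xi_ni - xi0_ki)^2

(the Amber-style no-1/2 convention of the sampling module), and the
unbiased target state has u = 0.  The self-consistent MBAR equations

    f_k = -ln sum_n exp(-u_kn) / sum_l N_l exp(f_l - u_ln)

are solved by damped self-consistent iteration with Newton polishing on the
equivalent convex objective; all arithmetic is in log space.

Free-energy profiles along a string are computed by evaluating the
MBAR-reweighted unbiased density in a product-Gaussian kernel neighborhood
(default bandwidth 0.05 Å per coordinate) centered on each path image, then
A(s) = -kB T ln rho(s), anchored so the reactant-side minimum is zero.
Standard errors are the SEM over independent production trials; block
re-analysis splits each window's series into non-overlapping time blocks
and re-solves MBAR per block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import KB, ROOM_T, thermal_beta
from .sampling import UmbrellaWindow, WindowSamples
from .stringmethod import StringPath

__all__ = [
    "MbarInput",
    "MbarResult",
    "FreeEnergyProfile",
    "mbar_input_from_samples",
    "mbar_solve",
    "mbar_residual",
    "overlap_matrix",
    "unbiased_log_weights",
    "profile_along_path",
    "pooled_profile",
    "trial_sem",
    "block_analysis",
    "NonOverlapWarning",
]


class NonOverlapWarning(UserWarning):
    """Adjacent umbrella windows share too little configuration-space support."""


@dataclass
class MbarInput:
    """Reduced bias energies for all (state, sample) pairs.

    Attributes
    ----------
    u_kn:
        (K, n_total) reduced bias energy of every pooled sample in every
        window's biased state (dimensionless, beta included).
    N_k:
        Samples contributed by each window; all > 0.
    xi:
        (n_total, D) pooled reaction-coordinate vectors, window-major order.
    temperature:
        Temperature at which beta was applied (K).
    """

    u_kn: np.ndarray
    N_k: np.ndarray
    xi: np.ndarray
    temperature: float = ROOM_T

    def __post_init__(self) -> None:
        self.u_kn = np.asarray(self.u_kn, float)
        self.N_k = np.asarray(self.N_k, int)
        self.xi = np.atleast_2d(np.asarray(self.xi, float))
        K, n = self.u_kn.shape
        if self.N_k.shape != (K,) or self.N_k.sum() != n:
            raise ValueError("N_k inconsistent with u_kn")
        if np.any(self.N_k <= 0):
            raise ValueError("every included window needs samples")
        if not np.all(np.isfinite(self.u_kn)):
            raise ValueError("non-finite reduced energies")


@dataclass
class MbarResult:
    """Per-window dimensionless free energies (f[0] = 0) and diagnostics."""

    f: np.ndarray
    residual: float
    iterations: int
    overlap_min_adjacent: float


@dataclass
class FreeEnergyProfile:
    """Free energy vs progress variable with per-point standard errors."""

    s: np.ndarray
    A: np.ndarray  # kcal/mol, reactant minimum anchored to 0
    sigma: np.ndarray  # per-point standard error (kcal/mol), >= 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, float)
        self.A = np.asarray(self.A, float)
        self.sigma = np.asarray(self.sigma, float)
        if not (self.s.shape == self.A.shape == self.sigma.shape):
            raise ValueError("s, A, sigma must be congruent")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")

    def to_table(self) -> str:
        lines = [
            "# free energy profile: s A sigma (kcal/mol); reactant minimum = 0",
            f"# metadata: {self.metadata}",
        ]
        for s, a, e in zip(self.s, self.A, self.sigma):
            lines.append(f"{s:.8f} {a:.8f} {e:.8f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str) -> "FreeEnergyProfile":
        rows = [
            [float(v) for v in line.split()]
            for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        ]
        arr = np.array(rows)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2])


def _reduced_bias(xi: np.ndarray, windows: Sequence[UmbrellaWindow], beta: float) -> np.ndarray:
    """u_kn matrix for pooled samples xi (n, D)."""
    centers = np.stack([w.center_array for w in windows])  # (K, D)
    ks = np.stack([w.k_array for w in windows])
    d = xi[None, :, :] - centers[:, None, :]  # (K, n, D)
    return beta * np.sum(ks[:, None, :] * d * d, axis=-1)


def mbar_input_from_samples(
    samples: Sequence[WindowSamples],
    temperature: float | None = None,
) -> MbarInput:
    """Pool window time series into an MBAR input."""
    if not samples:
        raise ValueError("no samples")
    T = temperature if temperature is not None else samples[0].temperature
    beta = thermal_beta(T)
    xi = np.concatenate([s.xi for s in samples], axis=0)
    windows = [s.window for s in samples]
    return MbarInput(
        u_kn=_reduced_bias(xi, windows, beta),
        N_k=np.array([s.n_samples for s in samples]),
        xi=xi,
        temperature=T,
    )


def mbar_residual(u_kn: np.ndarray, N_k: np.ndarray, f: np.ndarray) -> float:
    """Max abs violation of the self-consistent MBAR equations at f."""
    log_den = logsumexp(np.log(N_k)[:, None] + f[:, None] - u_kn, axis=0)
    f_new = -logsumexp(-u_kn - log_den, axis=1)
    f_new -= f_new[0]
    return float(np.max(np.abs(f_new - f)))


def mbar_solve(
    mbar: MbarInput | None = None,
    tol: float = 1e-10,
    max_iter: int = 10000,
    *,
    u_kn: np.ndarray | None = None,
    N_k: np.ndarray | None = None,
    overlap_threshold: float = 0.01,
) -> MbarResult:
    """Solve the MBAR equations; f normalized so f[0] = 0.

    Self-consistent iteration, switching to Newton steps on the convex
    objective once the iteration is in its basin.  Raises ``RuntimeError``
    on non-convergence; emits :class:`NonOverlapWarning` when the smallest
    adjacent-window overlap falls below ``overlap_threshold``.
    """
    if mbar is not None:
        u_kn, N_k = mbar.u_kn, mbar.N_k
    u_kn = np.asarray(u_kn, float)
    N_k = np.asarray(N_k, float)
    K, n = u_kn.shape
    logN = np.log(N_k)

    # warm start: chain of one-sided exponential averages between
    # neighbouring states, evaluated on the samples of the earlier state
    f = np.zeros(K)
    edges = np.concatenate([[0], np.cumsum(N_k)]).astype(int)
    for k in range(1, K):
        sl = slice(edges[k - 1], edges[k])
        du = u_kn[k, sl] - u_kn[k - 1, sl]
        f[k] = f[k - 1] - (logsumexp(-du) - np.log(sl.stop - sl.start))

    def sc_update(f):
        log_den = logsumexp(logN[:, None] + f[:, None] - u_kn, axis=0)
        f_new = -logsumexp(-u_kn - log_den, axis=1)
        return f_new - f_new[0]

    def grad_hess(f):
        # W[k, n] = exp(f_k - u_kn - log_den_n); rows sum to 1 at the solution
        log_den = logsumexp(logN[:, None] + f[:, None] - u_kn, axis=0)
        W = np.exp(f[:, None] - u_kn - log_den[None, :])
        c = N_k * np.sum(W, axis=1)
        g = c - N_k  # gradient of the convex UWHAM objective
        H = np.diag(c) - (W * N_k[:, None]) @ W.T * N_k[None, :]
        return g, H

    # short self-consistent phase to land in the Newton basin
    it = 0
    for it in range(1, min(200, max_iter) + 1):
        f_new = sc_update(f)
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < 1e-3:
            break
    # Newton on the convex objective (f[0] fixed at 0), with damping,
    # until the residual meets tol
    for _ in range(200):
        res = mbar_residual(u_kn, N_k, f)
        if res < tol:
            break
        g, H = grad_hess(f)
        try:
            step = np.linalg.solve(H[1:, 1:] + 1e-10 * np.eye(K - 1), g[1:])
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            step = g[1:] / np.maximum(np.diag(H)[1:], 1e-10)
        norm = np.max(np.abs(step))
        if norm > 2.0:  # damp long extrapolations far from the solution
            step *= 2.0 / norm
        f = f.copy()
        f[1:] -= step
        f -= f[0]
        it += 1
    res = mbar_residual(u_kn, N_k, f)
    if res > max(tol, 1e-8):
        raise RuntimeError(f"MBAR failed to converge: residual {res:.3e} > tol {tol:.1e}")

    O = overlap_matrix(u_kn, N_k, f)
    adj = np.diag(O, 1)
    min_adj = float(adj.min()) if len(adj) else 1.0
    if min_adj < overlap_threshold:
        groups = _disconnected_groups(O, overlap_threshold)
        warnings.warn(
            f"smallest adjacent-window overlap {min_adj:.4f} < {overlap_threshold}; "
            f"weakly connected groups: {groups}",
            NonOverlapWarning,
            stacklevel=2,
        )
    return MbarResult(f=f, residual=res, iterations=it, overlap_min_adjacent=min_adj)


def _disconnected_groups(O: np.ndarray, threshold: float) -> list[list[int]]:
    """Connected components of the window graph with edges O_kl >= threshold."""
    K = O.shape[0]
    seen, groups = set(), []
    for start in range(K):
        if start in seen:
            continue
        stack, comp = [start], []
        while stack:
            i = stack.pop()
            if i in seen:
                continue
            seen.add(i)
            comp.append(i)
            stack.extend(j for j in range(K) if j != i and O[i, j] >= threshold and j not in seen)
        groups.append(sorted(comp))
    return groups


def overlap_matrix(u_kn: np.ndarray, N_k: np.ndarray, f: np.ndarray) -> np.ndarray:
    """MBAR overlap matrix O_kl = sum_n W_kn N_l W_ln (rows sum to 1)."""
    log_den = logsumexp(np.log(N_k)[:, None] + f[:, None] - u_kn, axis=0)
    W = np.exp(f[:, None] - u_kn - log_den[None, :])  # (K, n)
    return W @ W.T * np.asarray(N_k, float)[None, :]


def unbiased_log_weights(mbar: MbarInput, f: np.ndarray) -> np.ndarray:
    """Log statistical weights of every pooled sample in the unbiased state.

    Normalized so logsumexp(log_w) = 0.
    """
    log_den = logsumexp(np.log(mbar.N_k)[:, None] + f[:, None] - mbar.u_kn, axis=0)
    log_w = -log_den
    return log_w - logsumexp(log_w)


def profile_along_path(
    mbar: MbarInput,
    result: MbarResult,
    path: StringPath,
    bandwidth: float = 0.05,
    min_neighborhood: int = 1,
) -> FreeEnergyProfile:
    """Free energy along the path from the MBAR-reweighted density.

    A(s) = -kB T ln sum_n w_n K_h(xi_n - path(s)) with a product Gaussian
    kernel of width ``bandwidth`` per coordinate; anchored so the
    reactant-side (first-basin) minimum is zero.  Raises ``RuntimeError``
    when fewer than ``min_neighborhood`` samples lie within three
    bandwidths of a path point (a coverage gap; no extrapolation is
    attempted).
    """
    log_w = unbiased_log_weights(mbar, result.f)
    pts = path.images
    log_rho = np.empty(len(pts))
    for i, c in enumerate(pts):
        d2 = np.sum((mbar.xi - c) ** 2, axis=1) / bandwidth**2
        log_rho[i] = logsumexp(log_w - 0.5 * d2)
        if np.count_nonzero(d2 < 9.0) < min_neighborhood:
            raise RuntimeError(f"empty kernel neighborhood at s={path.progress[i]:.3f}")
    kT = KB * mbar.temperature
    A = -kT * log_rho
    A -= _reactant_anchor(A)
    return FreeEnergyProfile(
        s=path.progress,
        A=A,
        sigma=np.zeros_like(A),
        metadata={"bandwidth": bandwidth, "temperature": mbar.temperature,
                  "mbar_residual": result.residual},
    )


def _reactant_anchor(A: np.ndarray) -> float:
    """Value at the first local minimum (the reactant basin) of a profile."""
    for i in range(len(A)):
        left = A[i - 1] if i > 0 else np.inf
        right = A[i + 1] if i < len(A) - 1 else np.inf
        if A[i] <= left and A[i] <= right:
            return float(A[i])
    return float(A[0])  # monotone profile


def pooled_profile(
    samples_by_trial: Sequence[Sequence[WindowSamples]],
    path: StringPath,
    temperature: float | None = None,
    bandwidth: float = 0.05,
) -> FreeEnergyProfile:
    """Mean profile from pooled trials with SEM error bars across trials.

    The headline curve pools all trials into one MBAR solve (maximum
    statistical efficiency); sigma is the standard error of the mean of the
    per-trial profiles, requiring >= 2 trials (set to 0 for a single
    trial).
    """
    trial_profiles = []
    for trial in samples_by_trial:
        m = mbar_input_from_samples(list(trial), temperature)
        r = mbar_solve(m)
        trial_profiles.append(profile_along_path(m, r, path, bandwidth))
    pooled = _pool_trials(samples_by_trial)
    m = mbar_input_from_samples(pooled, temperature)
    r = mbar_solve(m)
    prof = profile_along_path(m, r, path, bandwidth)
    if len(trial_profiles) >= 2:
        prof.sigma = trial_sem(trial_profiles)
    prof.metadata["n_trials"] = len(samples_by_trial)
    return prof


def _pool_trials(samples_by_trial: Sequence[Sequence[WindowSamples]]) -> list[WindowSamples]:
    """Concatenate trials window-wise (windows must align across trials)."""
    n_win = len(samples_by_trial[0])
    pooled = []
    for i in range(n_win):
        base = samples_by_trial[0][i]
        xi = np.concatenate([trial[i].xi for trial in samples_by_trial], axis=0)
        pooled.append(
            WindowSamples(
                window=base.window, xi=xi, dt=base.dt, stride=base.stride,
                temperature=base.temperature, seed=base.seed, trial=-1,
                equil_time=base.equil_time,
            )
        )
    return pooled


def trial_sem(profiles: Sequence[FreeEnergyProfile]) -> np.ndarray:
    """Per-point standard error of the mean across independent trials."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 trials for a standard error")
    stack = np.stack([p.A for p in profiles])
    return stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])


def block_analysis(
    samples_by_trial: Sequence[Sequence[WindowSamples]],
    path: StringPath,
    n_blocks: int,
    temperature: float | None = None,
    bandwidth: float = 0.05,
) -> tuple[list[FreeEnergyProfile], float]:
    """Re-analyze the production sampling in non-overlapping time blocks.

    The pooled production series of every window (trials concatenated in
    time) is divided into ``n_blocks`` equal blocks; each block is analyzed
    independently, giving one profile per block.  Returns the profiles and
    the spread (max - min) of the rate-controlling barrier across blocks.
    """
    pooled = _pool_trials(samples_by_trial)
    n = pooled[0].n_samples
    if any(s.n_samples != n for s in pooled):
        raise ValueError("windows have unequal sample counts")
    if n_blocks < 1 or n % n_blocks != 0:
        raise ValueError(f"{n} samples not divisible into {n_blocks} whole blocks")
    size = n // n_blocks
    profiles = []
    for b in range(n_blocks):
        chunk = [
            WindowSamples(
                window=s.window, xi=s.xi[b * size : (b + 1) * size], dt=s.dt,
                stride=s.stride, temperature=s.temperature, seed=s.seed,
                trial=b, equil_time=s.equil_time,
            )
            for s in pooled
        ]
        m = mbar_input_from_samples(chunk, temperature)
        r = mbar_solve(m)
        profiles.append(profile_along_path(m, r, path, bandwidth))
    from .kinetics import extract_stationary_points  # lazy: avoids module cycle

    barriers = []
    for p in profiles:
        rep = extract_stationary_points(p)
        if rep.forward_barrier is not None:
            barriers.append(rep.forward_barrier)
    spread = float(np.max(barriers) - np.min(barriers)) if len(barriers) >= 2 else 0.0
    return profiles, spread
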