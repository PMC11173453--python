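"""Stationary-point extraction, TST rates, populations, comparison tables.

A 1D free-energy profile along the minimum free energy path yields the
thermodynamic bookkeeping of a reaction step: ΔA (product minus reactant),
the forward barrier ΔAf‡ to the rate-controlling transition state, and the
reverse barrier ΔAr‡, with ΔAf‡ - ΔAr‡ = ΔA holding identically when all
three come from the same profile.  Transition-state-theory rate factors use
a unit transmission coefficient, so a barrier change ΔΔA‡ between two
methods translates into a rate factor exp(ΔΔA‡ / kB T); equilibrium
populations follow exp(-ΔA / kB T).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .constants import KB
from .fes import FreeEnergyProfile

__all__ = [
    "StationaryPoint",
    "StationaryReport",
    "extract_stationary_points",
    "tst_ratio",
    "population_ratio",
    "report_table",
    "format_table",
]


@dataclass(frozen=True)
class StationaryPoint:
    """A labelled extremum of the profile: kind, progress s, free energy A."""

    kind: str  # "reactant" | "TS" | "intermediate" | "product"
    s: float
    A: float
    sigma: float = 0.0


@dataclass
class StationaryReport:
    """Free-energy bookkeeping of one reaction profile.

    ``delta_A``, ``forward_barrier`` (ΔAf‡) and ``reverse_barrier`` (ΔAr‡)
    are kcal/mol; barriers are None for a monotone profile with no
    transition state (reported, never fabricated).
    """

    label: str
    points: list[StationaryPoint] = field(default_factory=list)
    delta_A: float = 0.0
    delta_A_err: float = 0.0
    forward_barrier: float | None = None
    forward_barrier_err: float | None = None
    reverse_barrier: float | None = None
    reverse_barrier_err: float | None = None
    ts_progress: float | None = None
    suppressed_extrema: list[StationaryPoint] = field(default_factory=list)

    @property
    def transition_states(self) -> list[StationaryPoint]:
        return [p for p in self.points if p.kind == "TS"]

    @property
    def intermediates(self) -> list[StationaryPoint]:
        return [p for p in self.points if p.kind == "intermediate"]


def extract_stationary_points(
    profile: FreeEnergyProfile,
    min_prominence: float = 0.25,
    label: str = "",
) -> StationaryReport:
    """Locate transition states and intermediates on a profile.

    Interior maxima with topographic prominence >= ``min_prominence``
    (kcal/mol) are transition states; interior minima between consecutive
    transition states are intermediates.  The reactant (product) free
    energy is the minimum over the segment before the first (after the
    last) transition state.  The rate-controlling TS is the global interior
    maximum; ties break toward smaller s.  Sub-prominence extrema are
    logged in ``suppressed_extrema``.
    """
    A, s, sig = profile.A, profile.s, profile.sigma
    if len(A) < 3:
        raise ValueError("profile needs at least 3 points")
    peaks, props = find_peaks(A, prominence=min_prominence)
    weak, _ = find_peaks(A)
    suppressed = [
        StationaryPoint("TS", float(s[i]), float(A[i]), float(sig[i]))
        for i in weak if i not in set(peaks)
    ]
    rep = StationaryReport(label=label, suppressed_extrema=suppressed)

    if len(peaks) == 0:
        # monotone or barrier-free profile: report ΔA only
        rep.delta_A = float(A[-1] - A[0])
        rep.delta_A_err = float(np.hypot(sig[-1], sig[0]))
        rep.points = [
            StationaryPoint("reactant", float(s[0]), float(A[0]), float(sig[0])),
            StationaryPoint("product", float(s[-1]), float(A[-1]), float(sig[-1])),
        ]
        return rep

    i_react = int(np.argmin(A[: peaks[0] + 1]))
    i_prod = peaks[-1] + int(np.argmin(A[peaks[-1] :]))
    # rate-controlling TS: global interior max, ties toward smaller s
    i_ts = int(peaks[np.argmax(A[peaks])])

    pts = [StationaryPoint("reactant", float(s[i_react]), float(A[i_react]), float(sig[i_react]))]
    for a, b in zip(peaks, peaks[1:]):
        pts.append(StationaryPoint("TS", float(s[a]), float(A[a]), float(sig[a])))
        i_mid = a + int(np.argmin(A[a : b + 1]))
        pts.append(StationaryPoint("intermediate", float(s[i_mid]), float(A[i_mid]), float(sig[i_mid])))
    pts.append(StationaryPoint("TS", float(s[peaks[-1]]), float(A[peaks[-1]]), float(sig[peaks[-1]])))
    pts.append(StationaryPoint("product", float(s[i_prod]), float(A[i_prod]), float(sig[i_prod])))

    rep.points = pts
    rep.delta_A = float(A[i_prod] - A[i_react])
    rep.delta_A_err = float(np.hypot(sig[i_prod], sig[i_react]))
    rep.forward_barrier = float(A[i_ts] - A[i_react])
    rep.forward_barrier_err = float(np.hypot(sig[i_ts], sig[i_react]))
    rep.reverse_barrier = float(A[i_ts] - A[i_prod])
    rep.reverse_barrier_err = float(np.hypot(sig[i_ts], sig[i_prod]))
    rep.ts_progress = float(s[i_ts])
    return rep


def tst_ratio(dA1: float, dA2: float, temperature: float = 298.0) -> float:
    """Rate factor between two barriers: exp((ΔA1‡ - ΔA2‡)/(kB T)).

    Transition-state theory with unit transmission coefficient: the factor
    by which the rate increases when the barrier drops from dA1 to dA2.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp((dA1 - dA2) / (KB * temperature)))


def population_ratio(dA: float, temperature: float = 298.0) -> float:
    """Equilibrium constant K = exp(-ΔA/(kB T)) for a reaction free energy."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp(-dA / (KB * temperature)))


def _as_entry(obj) -> dict:
    """Accept a StationaryReport or a plain mapping of dA/dAf/dAr values."""
    if isinstance(obj, StationaryReport):
        return {
            "dA": obj.delta_A, "dA_err": obj.delta_A_err,
            "dAf": obj.forward_barrier, "dAf_err": obj.forward_barrier_err,
            "dAr": obj.reverse_barrier, "dAr_err": obj.reverse_barrier_err,
        }
    return dict(obj)


def report_table(
    reports: Mapping[str, Mapping[str, object]],
    reference_method: str,
    reactions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Method-comparison table with Δ columns against a reference method.

    ``reports[method][reaction]`` is a :class:`StationaryReport` or a dict
    with keys dA/dAf/dAr (and optional *_err).  Emits one row per
    (reaction, method) with ΔA(σerr), ΔAf‡(σerr), ΔAr‡(σerr) and Δ columns
    (method value minus reference value); missing entries appear as NaN.
    The frame carries summary attributes ``max_abs_delta_dA`` and
    ``max_abs_delta_barrier`` over all non-reference methods.
    """
    if reference_method not in reports:
        raise ValueError(f"reference method {reference_method!r} missing from reports")
    if reactions is None:
        reactions = list(reports[reference_method].keys())
    rows = []
    for rxn in reactions:
        ref = _as_entry(reports[reference_method][rxn]) if rxn in reports[reference_method] else {}
        for method, per_rxn in reports.items():
            if rxn not in per_rxn:
                rows.append({"reaction": rxn, "method": method})
                continue
            e = _as_entry(per_rxn[rxn])
            row = {"reaction": rxn, "method": method}
            for key, dkey in (("dA", "delta_dA"), ("dAf", "delta_dAf"), ("dAr", "delta_dAr")):
                v = e.get(key)
                row[key] = np.nan if v is None else v
                row[key + "_err"] = np.nan if e.get(key + "_err") is None else e.get(key + "_err")
                rv = ref.get(key)
                row[dkey] = (
                    np.nan if (v is None or rv is None or method == reference_method)
                    else v - rv
                )
            rows.append(row)
    df = pd.DataFrame(rows)
    non_ref = df[df["method"] != reference_method]
    df.attrs["max_abs_delta_dA"] = float(np.nanmax(np.abs(non_ref["delta_dA"]))) if len(non_ref) else np.nan
    df.attrs["max_abs_delta_barrier"] = float(
        np.nanmax(np.abs(non_ref[["delta_dAf", "delta_dAr"]].to_numpy()))
    ) if len(non_ref) else np.nan
    return df


def format_table(df: pd.DataFrame) -> str:
    """Human-readable text table: ΔA(σerr) Δ ΔAf‡(σerr) Δ ΔAr‡(σerr) Δ."""

    def cell(v, err):
        if np.isnan(v):
            return "N/A"
        return f"{v:.2f} ({err:.2f})" if not np.isnan(err) else f"{v:.2f}"

    def delta(v):
        return "" if np.isnan(v) else f"{v:+.2f}"

    lines = [f"{'reaction':<10} {'method':<14} {'dA(err)':<14} {'D':>6}  "
             f"{'dAf(err)':<14} {'D':>6}  {'dAr(err)':<14} {'D':>6}"]
    for _, r in df.iterrows():
        if "dA" not in r or np.all(pd.isna(r.drop(["reaction", "method"]))):
            lines.append(f"{r['reaction']:<10} {r['method']:<14} {'N/A':<14}")
            continue
        lines.append(
            f"{r['reaction']:<10} {r['method']:<14} "
            f"{cell(r['dA'], r['dA_err']):<14} {delta(r['delta_dA']):>6}  "
            f"{cell(r['dAf'], r['dAf_err']):<14} {delta(r['delta_dAf']):>6}  "
            f"{cell(r['dAr'], r['dAr_err']):<14} {delta(r['delta_dAr']):>6}"
        )
    return "\n".join(lines) + "\n"
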