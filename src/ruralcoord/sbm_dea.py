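"""Slack-based-measure DEA efficiency with Tone-style super-efficiency.

The non-oriented SBM score of an evaluated unit k against a reference
technology (X, Y) is

    rho = min (1 - (1/m) sum_i s_i^- / x_ik) / (1 + (1/s) sum_r s_r^+ / y_rk)
    s.t. x_k = X lam + s^-,  y_k = Y lam - s^+,  lam, s^-, s^+ >= 0
         (sum lam = 1 under VRS)

and lies in (0, 1].  Units scoring 1 are re-ranked with the super-efficiency
variant, which excludes the unit from its own reference set and measures the
minimal proportional worsening (input additions w^-, output reductions w^+)
needed to reach the remaining technology:

    delta = min (1 + (1/m) sum_i w_i^- / x_ik) / (1 - (1/s) sum_r w_r^+ / y_rk)
    s.t. x_k + w^- >= X lam,  y_k - w^+ <= Y lam,  0 <= w_r^+ < y_rk

with delta >= 1.  Both fractional programs are solved exactly through the
Charnes-Cooper transformation (multiply all variables by a scalar t > 0 that
normalizes the denominator), which turns them into ordinary LPs handled by
scipy's HiGHS solver.  SBM is units-invariant: rescaling any input or output
column leaves every score unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .panel_io import PanelDataset

__all__ = [
    "DeaProblem",
    "EfficiencyScores",
    "SolverError",
    "sbm_score",
    "super_sbm_score",
    "efficiency_panel",
]

#: a unit counts as efficient when rho >= 1 - EFFICIENT_TOL
EFFICIENT_TOL = 1e-6
#: strict cap keeping the super-efficiency denominator positive
_OUTPUT_CAP = 1.0 - 1e-9


class SolverError(RuntimeError):
    """The LP behind a score was infeasible or failed to converge."""


@dataclass(frozen=True)
class DeaProblem:
    """One evaluated DMU against a reference technology."""

    X: np.ndarray  # m x n inputs, strictly positive
    Y: np.ndarray  # s x n outputs, strictly positive
    k: int  # evaluated DMU (column index)
    rts: str = "CRS"  # "CRS" | "VRS"
    frontier: Sequence[int] | None = None  # reference DMU indices (default all)

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if X.shape[1] != Y.shape[1]:
            raise ValueError("X and Y must have the same number of DMUs")
        if (X <= 0).any() or (Y <= 0).any():
            raise ValueError("DEA data must be strictly positive")
        if not (0 <= self.k < X.shape[1]):
            raise ValueError(f"DMU index {self.k} out of range")
        if self.rts not in ("CRS", "VRS"):
            raise ValueError(f"rts must be CRS or VRS, got {self.rts!r}")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(
            self,
            "frontier",
            tuple(range(X.shape[1])) if self.frontier is None else tuple(self.frontier),
        )


@dataclass(frozen=True)
class EfficiencyScores:
    """TE plus slacks for one DMU (or, from the panel driver, a table)."""

    TE: float
    slacks_in: np.ndarray
    slacks_out: np.ndarray
    status: str  # sbm_inefficient | super_efficient | infeasible
    lam: np.ndarray = field(default_factory=lambda: np.empty(0))


def _solve(c, A_eq, b_eq, A_ub, b_ub, bounds):
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs"
    )
    return res


def sbm_score(problem: DeaProblem) -> EfficiencyScores:
    """Non-oriented SBM efficiency rho in (0, 1] of the evaluated DMU.

    Charnes-Cooper variables: ``v = [t, Lam (n_f), S- (m), S+ (s)]`` with
    ``Lam = t*lam`` etc.; the denominator is normalized to 1 and the
    numerator minimized.
    """
    X, Y, k = problem.X, problem.Y, problem.k
    m, _ = X.shape
    s, _ = Y.shape
    ref = list(problem.frontier)
    if k not in ref:
        raise ValueError("evaluated DMU must belong to its own SBM reference set")
    XF, YF = X[:, ref], Y[:, ref]
    nf = len(ref)
    xk, yk = X[:, k], Y[:, k]

    nvar = 1 + nf + m + s
    c = np.zeros(nvar)
    c[0] = 1.0
    c[1 + nf : 1 + nf + m] = -1.0 / (m * xk)

    rows = []
    rhs = []
    # denominator normalization: t + (1/s) sum S+/y = 1
    row = np.zeros(nvar)
    row[0] = 1.0
    row[1 + nf + m :] = 1.0 / (s * yk)
    rows.append(row)
    rhs.append(1.0)
    # t*x_k = XF Lam + S-
    for i in range(m):
        row = np.zeros(nvar)
        row[0] = xk[i]
        row[1 : 1 + nf] = -XF[i]
        row[1 + nf + i] = -1.0
        rows.append(row)
        rhs.append(0.0)
    # t*y_k = YF Lam - S+
    for r in range(s):
        row = np.zeros(nvar)
        row[0] = yk[r]
        row[1 : 1 + nf] = -YF[r]
        row[1 + nf + m + r] = 1.0
        rows.append(row)
        rhs.append(0.0)
    if problem.rts == "VRS":
        row = np.zeros(nvar)
        row[0] = -1.0
        row[1 : 1 + nf] = 1.0
        rows.append(row)
        rhs.append(0.0)

    res = _solve(c, np.array(rows), np.array(rhs), None, None, [(0, None)] * nvar)
    if not res.success:
        raise SolverError(f"SBM LP failed for DMU {k}: {res.message}")
    t = res.x[0]
    if t <= 0:
        raise SolverError(f"SBM LP returned t <= 0 for DMU {k}")
    rho = float(res.fun)
    slacks_in = res.x[1 + nf : 1 + nf + m] / t
    slacks_out = res.x[1 + nf + m :] / t
    lam = res.x[1 : 1 + nf] / t
    status = "super_efficient" if rho >= 1.0 - EFFICIENT_TOL else "sbm_inefficient"
    return EfficiencyScores(min(rho, 1.0), slacks_in, slacks_out, status, lam)


def super_sbm_score(problem: DeaProblem) -> EfficiencyScores:
    """Super-efficiency delta >= 1 of an SBM-efficient DMU.

    The evaluated DMU is removed from the reference set; output reductions
    are capped strictly below y_rk so the denominator stays positive.  Under
    VRS the reduced reference set can make the LP infeasible, in which case
    the score falls back to 1.0 with status ``infeasible``.
    """
    X, Y, k = problem.X, problem.Y, problem.k
    m, _ = X.shape
    s, _ = Y.shape
    ref = [j for j in problem.frontier if j != k]
    xk, yk = X[:, k], Y[:, k]
    if not ref:
        # no peer to compare against: score 1 by convention
        return EfficiencyScores(1.0, np.zeros(m), np.zeros(s), "super_efficient")
    XR, YR = X[:, ref], Y[:, ref]
    nf = len(ref)

    nvar = 1 + nf + m + s
    c = np.zeros(nvar)
    c[0] = 1.0
    c[1 + nf : 1 + nf + m] = 1.0 / (m * xk)

    # equality: t - (1/s) sum W+/y = 1
    row = np.zeros(nvar)
    row[0] = 1.0
    row[1 + nf + m :] = -1.0 / (s * yk)
    A_eq = [row]
    b_eq = [1.0]
    if problem.rts == "VRS":
        row = np.zeros(nvar)
        row[0] = -1.0
        row[1 : 1 + nf] = 1.0
        A_eq.append(row)
        b_eq.append(0.0)

    A_ub = []
    b_ub = []
    # XR Lam - t*x_k - W- <= 0
    for i in range(m):
        row = np.zeros(nvar)
        row[0] = -xk[i]
        row[1 : 1 + nf] = XR[i]
        row[1 + nf + i] = -1.0
        A_ub.append(row)
        b_ub.append(0.0)
    # t*y_k - W+ - YR Lam <= 0
    for r in range(s):
        row = np.zeros(nvar)
        row[0] = yk[r]
        row[1 : 1 + nf] = -YR[r]
        row[1 + nf + m + r] = -1.0
        A_ub.append(row)
        b_ub.append(0.0)
    # W+ <= t * y_rk * cap  (keeps denominator positive)
    for r in range(s):
        row = np.zeros(nvar)
        row[0] = -yk[r] * _OUTPUT_CAP
        row[1 + nf + m + r] = 1.0
        A_ub.append(row)
        b_ub.append(0.0)

    res = _solve(
        c, np.array(A_eq), np.array(b_eq), np.array(A_ub), np.array(b_ub),
        [(0, None)] * nvar,
    )
    if not res.success:
        return EfficiencyScores(1.0, np.zeros(m), np.zeros(s), "infeasible")
    t = res.x[0]
    if t <= 0:
        return EfficiencyScores(1.0, np.zeros(m), np.zeros(s), "infeasible")
    delta = max(float(res.fun), 1.0)
    slacks_in = res.x[1 + nf : 1 + nf + m] / t
    slacks_out = res.x[1 + nf + m :] / t
    lam = res.x[1 : 1 + nf] / t
    return EfficiencyScores(delta, slacks_in, slacks_out, "super_efficient", lam)


def score_dmu(problem: DeaProblem) -> EfficiencyScores:
    """SBM score, upgraded to super-efficiency when the DMU is efficient."""
    base = sbm_score(problem)
    if base.status != "super_efficient":
        return base
    return super_sbm_score(problem)


def efficiency_panel(
    panel: PanelDataset,
    frontier_mode: str = "per_year",
    rts: str = "CRS",
) -> pd.DataFrame:
    """Score every unit-year; returns columns unit, year, TE, status and slacks.

    ``frontier_mode="per_year"`` (default) compares each unit against all
    units of the same year; ``"pooled"`` uses every unit-year as reference.
    """
    if frontier_mode not in ("per_year", "pooled"):
        raise ValueError(f"unknown frontier mode {frontier_mode!r}")
    Xall = panel.dea_inputs
    Yall = panel.dea_outputs
    idx = Xall.index  # (unit, year)
    records = []
    if frontier_mode == "per_year":
        for year in panel.years:
            sel = idx.get_level_values(1) == year
            X = Xall[sel].to_numpy().T
            Y = Yall[sel].to_numpy().T
            names = idx[sel]
            for j, (unit, _) in enumerate(names):
                records.append((unit, year, X, Y, j))
    else:
        X = Xall.to_numpy().T
        Y = Yall.to_numpy().T
        for j, (unit, year) in enumerate(idx):
            records.append((unit, year, X, Y, j))

    rows = []
    for unit, year, X, Y, j in records:
        try:
            sc = score_dmu(DeaProblem(X=X, Y=Y, k=j, rts=rts))
        except SolverError as exc:  # annotate with the panel address
            raise SolverError(f"{unit}/{year}: {exc}") from exc
        rows.append(
            {
                "unit": unit,
                "year": year,
                "TE": sc.TE,
                "status": sc.status,
                **{f"slack_in_{i}": v for i, v in enumerate(sc.slacks_in)},
                **{f"slack_out_{r}": v for r, v in enumerate(sc.slacks_out)},
            }
        )
    out = pd.DataFrame(rows).sort_values(["unit", "year"]).reset_index(drop=True)
    return out
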