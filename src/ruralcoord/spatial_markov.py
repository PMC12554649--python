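"""Quartile-state Markov dynamics, spatial conditioning and Moran's I.

The coordination degree D is discretised into four states (I low .. IV high)
at the pooled 25/50/75 percentiles; transitions over a lag of L years are
counted across all units and overlapping year pairs and normalized row-wise
(P_ij = n_ij / n_i).  The spatial variant conditions each transition on the
unit's spatial-lag state — the state of the neighbour-mean D at the start
year, classified with the same thresholds — yielding one conditional matrix
per lag state; their counts partition the traditional counts exactly.

Global Moran's I uses row-standardized binary contiguity weights and a
random-permutation test (one-sided, greater; the observed arrangement is
included in the null count).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import AdjacencyMatrix

__all__ = [
    "StatePanel",
    "TransitionMatrix",
    "MoranResult",
    "STATE_LABELS",
    "classify_quartiles",
    "transition_matrix",
    "spatial_lag",
    "spatial_lag_state",
    "spatial_transition_matrices",
    "morans_i",
]

STATE_LABELS = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class StatePanel:
    """Unit x year state labels (1..4) with the quartile cut points used."""

    states: pd.DataFrame  # integer codes 1..4, index=units, columns=years
    thresholds: tuple[float, float, float]

    def label(self, code: int) -> str:
        return STATE_LABELS[code - 1]


@dataclass(frozen=True)
class TransitionMatrix:
    counts: np.ndarray  # k x k integer n_ij
    probs: np.ndarray  # k x k row-stochastic (zero rows where n_i = 0)
    lag: int
    condition: str | None = None  # spatial-lag state, if conditioned

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=STATE_LABELS, columns=STATE_LABELS)


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    p_value: float
    z: float
    n_permutations: int


def _assign(values: np.ndarray, thresholds: tuple[float, float, float]) -> np.ndarray:
    """State 1..4 with right-closed intervals: ties at a cut go to the lower state."""
    v = np.asarray(values, dtype=float)
    return (
        1
        + (v > thresholds[0]).astype(int)
        + (v > thresholds[1]).astype(int)
        + (v > thresholds[2]).astype(int)
    )


def classify_quartiles(
    D_panel: pd.DataFrame, pooling: str = "pooled"
) -> StatePanel:
    """Discretise a units x years table of D into quartile states.

    ``pooled`` (default) computes one set of cut points from all unit-years,
    so state membership is comparable across years; ``per_year`` re-computes
    the cut points within each year.
    """
    vals = D_panel.to_numpy(dtype=float)
    if vals.size < 4:
        raise ValueError("need at least 4 observations to form quartiles")
    if pooling == "pooled":
        pool = vals.ravel()
        if len(np.unique(pool)) < 4:
            raise ValueError("fewer than 4 distinct values: degenerate thresholds")
        q = tuple(np.percentile(pool, [25, 50, 75]))
        states = _assign(vals, q)
    elif pooling == "per_year":
        states = np.empty_like(vals, dtype=int)
        q = None
        for t in range(vals.shape[1]):
            col = vals[:, t]
            if len(np.unique(col)) < 4:
                raise ValueError(
                    f"fewer than 4 distinct values in year column {t}: "
                    "degenerate thresholds"
                )
            q = tuple(np.percentile(col, [25, 50, 75]))
            states[:, t] = _assign(col, q)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    return StatePanel(
        states=pd.DataFrame(states, index=D_panel.index, columns=D_panel.columns),
        thresholds=q,
    )


def transition_matrix(states: StatePanel, lag: int = 1) -> TransitionMatrix:
    """Traditional k x k transition counts/probabilities at lag L."""
    S = states.states.to_numpy()
    n_years = S.shape[1]
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if lag >= n_years:
        raise ValueError(f"lag {lag} needs more than {n_years} years of data")
    k = len(STATE_LABELS)
    counts = np.zeros((k, k), dtype=int)
    for t in range(n_years - lag):
        np.add.at(counts, (S[:, t] - 1, S[:, t + lag] - 1), 1)
    return TransitionMatrix(counts, _row_normalize(counts), lag)


def _row_normalize(counts: np.ndarray) -> np.ndarray:
    probs = np.zeros_like(counts, dtype=float)
    row_sums = counts.sum(axis=1)
    nz = row_sums > 0
    probs[nz] = counts[nz] / row_sums[nz, None]
    return probs


def spatial_lag(
    D_values: pd.Series | np.ndarray, W: AdjacencyMatrix
) -> pd.Series:
    """Row-standardized neighbour mean of D per unit (NaN for isolated units)."""
    v = np.asarray(D_values, dtype=float)
    if v.shape[0] != len(W.units):
        raise ValueError("D values do not align with the adjacency units")
    deg = W.degrees
    if (deg == 0).all():
        raise ValueError("no unit has any neighbour")
    lag_val = W.row_standardized() @ v
    lag_val[deg == 0] = np.nan
    return pd.Series(lag_val, index=list(W.units), name="lag_value")


def spatial_lag_state(
    D_values: pd.Series | np.ndarray,
    W: AdjacencyMatrix,
    thresholds: tuple[float, float, float],
) -> pd.Series:
    """Neighbour-mean D per unit, classified with the focal thresholds.

    Isolated units get a missing lag state (excluded from conditioning).
    """
    lag_val = spatial_lag(D_values, W).to_numpy()
    deg = W.degrees
    codes = _assign(np.nan_to_num(lag_val), thresholds).astype(float)
    codes[deg == 0] = np.nan
    return pd.Series(codes, index=list(W.units), name="lag_state")


def spatial_transition_matrices(
    states: StatePanel,
    D_panel: pd.DataFrame,
    W: AdjacencyMatrix,
    lag: int = 1,
) -> dict[str, TransitionMatrix]:
    """One conditional transition matrix per spatial-lag state at time t.

    Each (unit, t -> t+L) transition is binned by the unit's lag state in the
    start year; summing the four conditional count matrices reproduces the
    traditional counts (for units with neighbours).
    """
    S = states.states
    units = list(S.index)
    if list(W.units) != units:
        W = W.subset(units)
    n_years = S.shape[1]
    if lag >= n_years:
        raise ValueError(f"lag {lag} needs more than {n_years} years of data")
    k = len(STATE_LABELS)
    counts = {lab: np.zeros((k, k), dtype=int) for lab in STATE_LABELS}
    years = list(S.columns)
    for t in range(n_years - lag):
        lag_states = spatial_lag_state(
            D_panel[years[t]].to_numpy(), W, states.thresholds
        )
        s_now = S[years[t]].to_numpy()
        s_next = S[years[t + lag]].to_numpy()
        for ls, a, b in zip(lag_states.to_numpy(), s_now, s_next):
            if np.isnan(ls):
                continue
            counts[STATE_LABELS[int(ls) - 1]][a - 1, b - 1] += 1
    return {
        lab: TransitionMatrix(c, _row_normalize(c), lag, condition=lab)
        for lab, c in counts.items()
    }


def morans_i(
    values: pd.Series | np.ndarray,
    W: AdjacencyMatrix,
    n_permutations: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Global Moran's I with row-standardized weights and a permutation test."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 3:
        raise ValueError("Moran's I needs at least 3 units")
    if n != len(W.units):
        raise ValueError("values do not align with the adjacency units")
    keep = W.degrees > 0
    if keep.sum() < 3:
        raise ValueError("fewer than 3 units with neighbours")
    if not keep.all():  # drop isolated units from the statistic
        W = W.subset([u for u, k_ in zip(W.units, keep) if k_])
        v = v[keep]
        n = v.size
    if np.allclose(v, v[0]):
        raise ValueError("zero variance: Moran's I undefined")
    Wrs = W.row_standardized()
    S0 = Wrs.sum()
    z = v - v.mean()

    def stat(zz: np.ndarray) -> float:
        return float(n / S0 * (zz @ Wrs @ zz) / (zz @ zz))

    I_obs = stat(z)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for b in range(n_permutations):
        perms[b] = stat(rng.permutation(z))
    # observed arrangement counted in the null
    p = (1.0 + np.sum(perms >= I_obs - 1e-12)) / (n_permutations + 1.0)
    sd = perms.std(ddof=1)
    z_score = (I_obs - perms.mean()) / sd if sd > 0 else np.inf
    return MoranResult(
        I=I_obs,
        expected=-1.0 / (n - 1),
        p_value=float(p),
        z=float(z_score),
        n_permutations=n_permutations,
    )
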