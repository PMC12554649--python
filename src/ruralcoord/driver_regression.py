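"""Quantile regression of the coordination degree on driver covariates.

The tau-th conditional quantile coefficients minimise the pinball loss

    sum_i rho_tau(y_i - x_i' beta),   rho_tau(u) = u * (tau - 1{u < 0})

which is a linear program: writing the residual as u+ - u-, minimise
tau * 1'u+ + (1 - tau) * 1'u- subject to X beta + u+ - u- = y with
u+, u- >= 0 and beta free.  scipy's HiGHS solver gives an exact vertex
solution, deterministic for fixed inputs.  At an optimum the usual
subgradient conditions hold: the share of strictly negative residuals is at
most tau and the share of non-positive residuals at least tau, up to p/n.

Inference is by xy-pair bootstrap (robust to heteroscedasticity):
t = beta_hat / sd_boot and percentile confidence intervals.  Separate per-tau
fits are used, so quantile crossing is possible by design.

The table driver fits all requested quantiles on the six drivers after the
configured transform — by default natural log of the monetary covariates
(LED, HNL, GOV) followed by z-standardisation of all six — and emits
coefficients, bootstrap t statistics and significance stars.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.optimize import linprog

from .panel_io import COVARIATE_COLS, PanelDataset

__all__ = [
    "QuantileFit",
    "quantile_fit",
    "pinball_loss",
    "bootstrap_inference",
    "quantile_table",
    "DEFAULT_TAUS",
]

DEFAULT_TAUS: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))
LOG_COLS = ("LED", "HNL", "GOV")


@dataclass(frozen=True)
class QuantileFit:
    tau: float
    beta: np.ndarray  # includes the intercept as the first element
    n_obs: int
    loss: float
    residuals: np.ndarray
    columns: tuple[str, ...]
    t_stats: np.ndarray | None = None
    ci: np.ndarray | None = None  # p x 2 percentile intervals
    sd_boot: np.ndarray | None = None
    stars: tuple[str, ...] = field(default=())


def pinball_loss(residuals: np.ndarray, tau: float) -> float:
    u = np.asarray(residuals, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def _check_rank(X: np.ndarray, columns: tuple[str, ...]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = qr(X, pivoting=True)
        dropped = [columns[j] for j in piv[rank:]]
        raise ValueError(
            f"design matrix is rank deficient; collinear column(s): "
            f"{', '.join(map(str, dropped))}"
        )


def quantile_fit(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    tau: float,
    add_intercept: bool = True,
) -> QuantileFit:
    """Exact LP fit of the tau-th conditional quantile."""
    if not (0.0 < tau < 1.0):
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    if isinstance(X, pd.DataFrame):
        columns = tuple(map(str, X.columns))
        X = X.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and np.asarray(y).size > 1:
            X = X.T
        columns = tuple(f"x{j}" for j in range(X.shape[1]))
    y = np.asarray(y, dtype=float).ravel()
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        columns = ("const",) + columns
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    _check_rank(X, columns)

    # variables: [beta (p, free), u+ (n), u- (n)]
    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
    A_eq = np.hstack([X, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    beta = res.x[:p]
    resid = y - X @ beta
    return QuantileFit(
        tau=tau,
        beta=beta,
        n_obs=n,
        loss=pinball_loss(resid, tau),
        residuals=resid,
        columns=columns,
    )


def bootstrap_inference(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    tau: float,
    n_boot: int = 1000,
    seed: int = 0,
    add_intercept: bool = True,
) -> QuantileFit:
    """xy-pair bootstrap t statistics and percentile CIs around the LP fit."""
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    base = quantile_fit(X, y, tau, add_intercept=add_intercept)
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    ya = np.asarray(y, dtype=float).ravel()
    n = len(ya)
    rng = np.random.default_rng(seed)
    betas = np.empty((n_boot, len(base.beta)))
    for b in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, n, n)
            try:
                fit = quantile_fit(
                    Xa[idx], ya[idx], tau, add_intercept=add_intercept
                )
                break
            except ValueError:  # rank-deficient resample: redraw
                continue
        else:
            raise RuntimeError("bootstrap kept drawing rank-deficient resamples")
        betas[b] = fit.beta
    sd = betas.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, base.beta / sd, np.inf * np.sign(base.beta))
    ci = np.percentile(betas, [2.5, 97.5], axis=0).T
    stars = tuple(_stars(abs(ti)) for ti in t)
    return QuantileFit(
        tau=base.tau,
        beta=base.beta,
        n_obs=base.n_obs,
        loss=base.loss,
        residuals=base.residuals,
        columns=base.columns,
        t_stats=t,
        ci=ci,
        sd_boot=sd,
        stars=stars,
    )


def _stars(abs_t: float) -> str:
    if abs_t > 2.576:
        return "***"
    if abs_t > 1.96:
        return "**"
    if abs_t > 1.645:
        return "*"
    return ""


def transform_drivers(
    covariates: pd.DataFrame, transform: str = "log-z"
) -> pd.DataFrame:
    """Apply the configured covariate transform.

    ``log-z``: natural log of the monetary drivers (LED, HNL, GOV) then
    z-standardisation of all columns; ``z``: standardise only; ``none``: raw.
    """
    X = covariates.copy().astype(float)
    if transform == "log-z":
        for col in LOG_COLS:
            if col in X.columns:
                if (X[col] <= 0).any():
                    raise ValueError(f"cannot log non-positive values in {col!r}")
                X[col] = np.log(X[col])
        X = (X - X.mean()) / X.std(ddof=1)
    elif transform == "z":
        X = (X - X.mean()) / X.std(ddof=1)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    return X


def quantile_table(
    panel: PanelDataset,
    D: pd.Series,
    taus: tuple[float, ...] = DEFAULT_TAUS,
    transform: str = "log-z",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Driver x quantile table of coefficients, t statistics and stars.

    ``D`` must be indexed by (unit, year); drivers are aligned on the same
    index, transformed, and fitted separately at each tau with bootstrap
    inference.  Output rows: one per driver plus a constant row; columns are
    MultiIndexed (tau, {beta, t, stars}); the observation count is attached
    as ``df.attrs["n_obs"]``.
    """
    cov = panel.covariates
    merged = cov.join(D.rename("D"), how="inner")
    if merged["D"].isna().any() or len(merged) != len(cov):
        raise ValueError("D does not align with the panel's unit-years")
    X = transform_drivers(merged[list(COVARIATE_COLS)], transform)
    y = merged["D"]
    blocks = {}
    for i, tau in enumerate(taus):
        fit = bootstrap_inference(
            X, y, tau, n_boot=n_boot, seed=seed + i, add_intercept=True
        )
        order = list(COVARIATE_COLS) + ["const"]
        pos = {name: j for j, name in enumerate(fit.columns)}
        blocks[(tau, "beta")] = [fit.beta[pos[c]] for c in order]
        blocks[(tau, "t")] = [fit.t_stats[pos[c]] for c in order]
        blocks[(tau, "stars")] = [fit.stars[pos[c]] for c in order]
    out = pd.DataFrame(blocks, index=list(COVARIATE_COLS) + ["const"])
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["tau", "stat"])
    out.attrs["n_obs"] = len(y)
    return out
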