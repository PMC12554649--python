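"""Coupling degree C, comprehensive index N, coordination degree D, tiers.

For two subsystem scores u1, u2 >= 0 the coupling degree is

    C = sqrt( u1*u2 / ((u1 + u2)/2)^2 ) = 2*sqrt(u1*u2) / (u1 + u2)

which is 1 exactly when the systems are balanced (u1 = u2 > 0) and 0 when
either vanishes.  The comprehensive index N = alpha*u1 + beta*u2 (equal
contribution alpha = beta = 0.5 by default) blends the levels, and the
coupling coordination degree is D = sqrt(C*N) — the conventional form, whose
magnitudes match published gradings; the plain product form D = C*N is
selectable.  D in [0, 1] whenever u1, u2 in [0, 1] and is graded into ten
tiers across three periods (Antagonistic / Break-in / Coordination).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "coupling_degree",
    "ccd",
    "classify_ccd",
    "ccd_table",
    "region_year_means",
    "CCDRecord",
    "TIERS",
]

#: (upper bound, tier label, period); intervals are right-closed, the first
#: one also contains 0.
TIERS: tuple[tuple[float, str, str], ...] = (
    (0.1, "Extreme dysregulation and decline", "Antagonistic period"),
    (0.2, "Severe dysregulation and decline", "Antagonistic period"),
    (0.3, "Moderate dysfunctional decline", "Antagonistic period"),
    (0.4, "Minor disorder", "Antagonistic period"),
    (0.5, "Proximity coordination", "Break-in period"),
    (0.6, "Barely coordinated", "Break-in period"),
    (0.7, "Primary coordination", "Coordination period"),
    (0.8, "Intermediate coordination", "Coordination period"),
    (0.9, "Well-coordination", "Coordination period"),
    (1.0, "High-quality coordination", "Coordination period"),
)


@dataclass(frozen=True)
class CCDRecord:
    unit: str
    year: int
    U1: float
    U2: float
    C: float
    N: float
    D: float
    tier: str
    period: str


def coupling_degree(u1: float, u2: float) -> float:
    """Coupling degree C in [0, 1]; 0 if either score is 0."""
    if u1 < 0 or u2 < 0:
        raise ValueError(f"subsystem scores must be non-negative, got ({u1}, {u2})")
    total = u1 + u2
    if total == 0:
        return 0.0
    return min(1.0, 2.0 * math.sqrt(u1 * u2) / total)


def ccd(
    u1: float,
    u2: float,
    alpha: float = 0.5,
    beta: float = 0.5,
    form: str = "sqrt_product",
) -> tuple[float, float, float]:
    """Return (C, N, D) for one observation."""
    if alpha < 0 or beta < 0 or not math.isclose(alpha + beta, 1.0, abs_tol=1e-12):
        raise ValueError(f"alpha + beta must equal 1, got {alpha} + {beta}")
    C = coupling_degree(u1, u2)
    N = alpha * u1 + beta * u2
    if form == "sqrt_product":
        D = math.sqrt(C * N)
    elif form == "product":
        D = C * N
    else:
        raise ValueError(f"unknown CCD form {form!r}")
    return C, N, D


def classify_ccd(D: float) -> tuple[str, str]:
    """Map D in [0, 1] to its (tier, period); boundaries go to the lower tier."""
    if not (0.0 <= D <= 1.0):
        raise ValueError(f"D must lie in [0, 1], got {D}")
    for hi, tier, period in TIERS:
        if D <= hi:
            return tier, period
    return TIERS[-1][1], TIERS[-1][2]  # pragma: no cover


def ccd_table(
    u1: pd.Series,
    u2: pd.Series,
    alpha: float = 0.5,
    beta: float = 0.5,
    form: str = "sqrt_product",
    clip_u2: bool = True,
) -> pd.DataFrame:
    """Join U1 and U2 on (unit, year) and compute the full CCD table.

    Super-efficiency can push U2 above 1; by default it is clipped to 1 for
    the CCD computation so D stays within the graded range, with the
    ``u2_clipped`` flag recording which rows were affected.
    """
    df = pd.concat(
        [u1.rename("U1"), u2.rename("U2")], axis=1, join="inner"
    ).reset_index()
    if df[["U1", "U2"]].isna().any().any():
        raise ValueError("U1/U2 do not align on (unit, year)")
    df["u2_clipped"] = clip_u2 & (df["U2"] > 1.0)
    u2_eff = df["U2"].clip(upper=1.0) if clip_u2 else df["U2"]
    vals = [ccd(a, b, alpha, beta, form) for a, b in zip(df["U1"], u2_eff)]
    df[["C", "N", "D"]] = pd.DataFrame(vals, index=df.index)
    tiers = [classify_ccd(min(d, 1.0)) for d in df["D"]]
    df[["tier", "period"]] = pd.DataFrame(tiers, index=df.index)
    return df


def region_year_means(
    table: pd.DataFrame, region_of: dict[str, str], value: str = "D"
) -> pd.DataFrame:
    """Region x year mean table (plus a National column) of one CCD column.

    Regional values are means of provincial values, national the mean over
    all units.
    """
    df = table.copy()
    df["region"] = df["unit"].map(region_of)
    by_region = df.pivot_table(index="year", columns="region", values=value)
    by_region["National"] = df.groupby("year")[value].mean()
    return by_region
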