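"""CRITIC objective weighting and the composite development score U1.

CRITIC (Criteria Importance Through Intercriteria Correlation) weights each
indicator by the product of its contrast intensity (sample standard
deviation of the range-normalized column, n-1 denominator) and its conflict
with the other indicators (sum of one minus the pairwise Pearson
correlations).  The composite score of an observation is the weighted sum
of its normalized indicator values, so it lives in [0, 1].

Normalization is pooled over all unit-years by default so scores are
comparable across years; a per-year option is available for sensitivity.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .panel_io import PanelDataset

__all__ = [
    "NormalizedMatrix",
    "CriticWeights",
    "normalize_range",
    "critic_weights",
    "composite_score",
    "score_panel",
]


class DegenerateIndicatorError(ValueError):
    """A column carries no usable information (constant, or all-zero C_j)."""


@dataclass(frozen=True)
class NormalizedMatrix:
    """Range-normalized indicator block; every entry in [0, 1]."""

    X: pd.DataFrame
    directions: tuple[str, ...]  # "positive" | "negative" per column


@dataclass(frozen=True)
class CriticWeights:
    S: pd.Series  # contrast intensity (std, ddof=1)
    R: pd.Series  # conflict sum_i (1 - r_ij)
    C: pd.Series  # information amount S * R
    W: pd.Series  # normalized weights, sum to 1
    corr: pd.DataFrame


def normalize_range(
    raw: pd.DataFrame | np.ndarray,
    directions: Sequence[str] | None = None,
) -> NormalizedMatrix:
    """Min-max normalize each column onto [0, 1].

    Positive-direction columns map ``(x - min) / (max - min)``; negative
    ones ``(max - x) / (max - min)``.  A constant column is an error — it
    cannot be oriented and would produce a zero-division — named explicitly.
    """
    df = pd.DataFrame(raw).astype(float)
    if directions is None:
        directions = ["positive"] * df.shape[1]
    directions = tuple(directions)
    if len(directions) != df.shape[1]:
        raise ValueError(
            f"{len(directions)} directions for {df.shape[1]} columns"
        )
    bad = set(directions) - {"positive", "negative"}
    if bad:
        raise ValueError(f"unknown direction(s): {sorted(bad)}")
    lo, hi = df.min(axis=0), df.max(axis=0)
    span = hi - lo
    const = span[span == 0]
    if len(const):
        raise DegenerateIndicatorError(
            f"constant indicator column(s): {', '.join(map(str, const.index))}"
        )
    out = (df - lo) / span
    for j, d in enumerate(directions):
        if d == "negative":
            out.iloc[:, j] = 1.0 - out.iloc[:, j]
    return NormalizedMatrix(out, directions)


def critic_weights(norm: NormalizedMatrix) -> CriticWeights:
    """Compute CRITIC weights from a normalized matrix (needs >= 3 rows)."""
    X = norm.X
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if p < 2:
        raise ValueError(f"need at least 2 indicators, got {p}")
    S = X.std(axis=0, ddof=1)
    corr = X.corr(method="pearson")
    R = (1.0 - corr).sum(axis=0)  # self term contributes 0
    C = S * R
    total = C.sum()
    if total <= 0:
        raise DegenerateIndicatorError(
            "all information amounts are zero (perfectly correlated indicators)"
        )
    W = C / total
    return CriticWeights(S=S, R=R, C=C, W=W, corr=corr)


def composite_score(norm: NormalizedMatrix, weights: CriticWeights) -> pd.Series:
    """Weighted sum of normalized indicators per observation; in [0, 1]."""
    if list(norm.X.columns) != list(weights.W.index):
        raise ValueError("indicator columns do not match the weight index")
    return norm.X @ weights.W


def score_panel(
    panel: PanelDataset,
    directions: Sequence[str] | None = None,
    pooling: str = "pooled",
) -> tuple[CriticWeights, pd.Series]:
    """Score the panel's indicator block: weights plus per-unit-year U1.

    ``pooling="pooled"`` (default) normalizes over all unit-years jointly and
    computes one weight vector; ``"per_year"`` normalizes and weights within
    each year separately (scores are then not comparable across years).
    """
    block = panel.indicators
    if pooling == "pooled":
        norm = normalize_range(block, directions)
        w = critic_weights(norm)
        scores = composite_score(norm, w)
    elif pooling == "per_year":
        pieces = []
        w = None
        year_level = block.index.get_level_values(1)
        for year in sorted(set(year_level)):
            sub = block[year_level == year]
            norm = normalize_range(sub, directions)
            w = critic_weights(norm)
            pieces.append(composite_score(norm, w))
        scores = pd.concat(pieces).sort_index()
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    scores.name = "U1"
    return w, scores
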