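"""Canonical panel data model and CSV I/O shared by every pipeline stage.

The on-disk layout is long format: one row per (unit, year) with a region
label and the indicator / DEA / covariate columns side by side.  Panels must
be balanced — every declared unit observed in every declared year — and DEA
blocks strictly positive; anything else is rejected with an actionable
message rather than imputed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "PanelSchema",
    "PanelDataset",
    "AdjacencyMatrix",
    "DEFAULT_REGIONS",
    "INDICATOR_COLS",
    "DEA_INPUT_COLS",
    "DEA_OUTPUT_COLS",
    "COVARIATE_COLS",
    "load_panel",
    "write_panel",
    "load_adjacency",
    "write_adjacency",
    "melt_wide",
]


class SchemaError(ValueError):
    """A required column (or column configuration) is missing or malformed."""


class ValidationError(ValueError):
    """The table parses but violates a panel invariant (balance, positivity...)."""


DEFAULT_REGIONS: tuple[str, ...] = ("East", "Central", "West")

#: Eleven-indicator system for the digital-village composite (index layer).
INDICATOR_COLS: tuple[str, ...] = (
    "computers_per_100hh",
    "smartphones_per_100hh",
    "televisions_per_100hh",
    "broadband_per_10khh",
    "postal_route_km",
    "transport_comm_expenditure",
    "rural_electricity_use",
    "village_committees",
    "village_medical_institutions",
    "health_expenditure_per_capita",
    "digital_finance_index",
)

#: Four inputs of the rural-healthcare DEA stage.
DEA_INPUT_COLS: tuple[str, ...] = (
    "township_health_centers",
    "village_clinics",
    "rural_health_technicians",
    "beds",
)

#: Two outputs of the rural-healthcare DEA stage.
DEA_OUTPUT_COLS: tuple[str, ...] = ("treatment_visits", "discharges")

#: Driver covariates: economic level, health needs, digital innovation,
#: government health spending, health human capital, urbanisation rate.
COVARIATE_COLS: tuple[str, ...] = ("LED", "HNL", "DIN", "GOV", "HHC", "URB")


@dataclass(frozen=True)
class PanelSchema:
    """Column-name configuration mapping a CSV onto the panel blocks."""

    unit_col: str = "unit"
    year_col: str = "year"
    region_col: str = "region"
    indicator_cols: tuple[str, ...] = INDICATOR_COLS
    input_cols: tuple[str, ...] = DEA_INPUT_COLS
    output_cols: tuple[str, ...] = DEA_OUTPUT_COLS
    covariate_cols: tuple[str, ...] = COVARIATE_COLS
    regions: tuple[str, ...] = DEFAULT_REGIONS

    @property
    def value_cols(self) -> tuple[str, ...]:
        return (
            self.indicator_cols
            + self.input_cols
            + self.output_cols
            + self.covariate_cols
        )

    @property
    def all_cols(self) -> tuple[str, ...]:
        return (self.unit_col, self.year_col, self.region_col) + self.value_cols


DEFAULT_SCHEMA = PanelSchema()


@dataclass(frozen=True)
class PanelDataset:
    """A balanced unit x year panel with indicator, DEA and covariate blocks.

    ``frame`` is the canonical long table, sorted by (unit, year); blocks are
    exposed as DataFrames indexed by a (unit, year) MultiIndex.
    """

    frame: pd.DataFrame
    schema: PanelSchema = field(default=DEFAULT_SCHEMA)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, schema: PanelSchema = DEFAULT_SCHEMA
    ) -> "PanelDataset":
        """Validate a long table and return the canonical sorted panel."""
        missing = [c for c in schema.all_cols if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = frame.loc[:, list(schema.all_cols)].copy()
        df[schema.year_col] = df[schema.year_col].astype(int)
        df = df.sort_values([schema.unit_col, schema.year_col], kind="mergesort")
        df = df.reset_index(drop=True)
        ds = cls(frame=df, schema=schema)
        ds._validate()
        return ds

    def _validate(self) -> None:
        s = self.schema
        df = self.frame
        units = self.units
        years = self.years
        # duplicates
        dup = df.duplicated([s.unit_col, s.year_col])
        if dup.any():
            pair = df.loc[dup.idxmax(), [s.unit_col, s.year_col]]
            raise ValidationError(
                f"duplicate observation for {pair[s.unit_col]}/{pair[s.year_col]}"
            )
        # balance
        expected = len(units) * len(years)
        if len(df) != expected:
            have = set(zip(df[s.unit_col], df[s.year_col]))
            holes = [
                f"{u}/{y}" for u in units for y in years if (u, y) not in have
            ]
            raise ValidationError(
                "unbalanced panel; missing (unit, year) pairs: " + ", ".join(holes)
            )
        # one region per unit, drawn from the configured region set
        per_unit = df.groupby(s.unit_col)[s.region_col].nunique()
        bad = per_unit[per_unit != 1]
        if len(bad):
            raise ValidationError(
                f"unit {bad.index[0]!r} carries {bad.iloc[0]} region labels"
            )
        unknown = set(df[s.region_col]) - set(s.regions)
        if unknown:
            raise ValidationError(
                f"unknown region label(s) {sorted(unknown)}; expected {s.regions}"
            )
        # numeric blocks
        for col in s.value_cols:
            if not np.issubdtype(df[col].dtype, np.number):
                raise ValidationError(f"column {col!r} is not numeric")
            if df[col].isna().any():
                row = df.loc[df[col].isna().idxmax()]
                raise ValidationError(
                    f"missing value in {col!r} at {row[s.unit_col]}/{row[s.year_col]}"
                )
        for col in s.input_cols + s.output_cols:
            nonpos = df[col] <= 0
            if nonpos.any():
                row = df.loc[nonpos.idxmax()]
                raise ValidationError(
                    f"non-positive DEA value in {col!r} at "
                    f"{row[s.unit_col]}/{row[s.year_col]}"
                )
        neg = df[list(s.indicator_cols)] < 0
        if neg.to_numpy().any():
            col = neg.any()[neg.any()].index[0]
            raise ValidationError(f"negative indicator value in {col!r}")

    # -- views ------------------------------------------------------------

    @property
    def units(self) -> list[str]:
        return sorted(self.frame[self.schema.unit_col].unique())

    @property
    def years(self) -> list[int]:
        return sorted(int(y) for y in self.frame[self.schema.year_col].unique())

    @property
    def region_of(self) -> dict[str, str]:
        s = self.schema
        return dict(
            self.frame.groupby(s.unit_col)[s.region_col].first()
        )

    def _block(self, cols: Sequence[str]) -> pd.DataFrame:
        s = self.schema
        return self.frame.set_index([s.unit_col, s.year_col])[list(cols)]

    @property
    def indicators(self) -> pd.DataFrame:
        return self._block(self.schema.indicator_cols)

    @property
    def dea_inputs(self) -> pd.DataFrame:
        return self._block(self.schema.input_cols)

    @property
    def dea_outputs(self) -> pd.DataFrame:
        return self._block(self.schema.output_cols)

    @property
    def covariates(self) -> pd.DataFrame:
        return self._block(self.schema.covariate_cols)

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    def with_regions(self, region_of: Mapping[str, str]) -> "PanelDataset":
        s = self.schema
        df = self.frame.copy()
        df[s.region_col] = df[s.unit_col].map(dict(region_of))
        return PanelDataset.from_frame(df, s)


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric binary spatial contiguity matrix aligned to a unit order."""

    units: tuple[str, ...]
    W: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W)
        n = len(self.units)
        if W.shape != (n, n):
            raise ValidationError(
                f"adjacency shape {W.shape} does not match {n} units"
            )
        if not np.isin(W, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0/1")
        if np.diag(W).any():
            i = int(np.flatnonzero(np.diag(W))[0])
            raise ValidationError(f"nonzero diagonal at unit {self.units[i]!r}")
        asym = W != W.T
        if asym.any():
            i, j = map(int, np.argwhere(asym)[0])
            raise ValidationError(
                f"asymmetric adjacency between {self.units[i]!r} and "
                f"{self.units[j]!r}"
            )
        object.__setattr__(self, "W", W.astype(np.int8))
        isolated = self.isolated
        if isolated:
            warnings.warn(
                f"isolated unit(s) with no neighbours: {', '.join(isolated)}; "
                "they are excluded from spatial operations",
                stacklevel=3,
            )

    @property
    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1)

    @property
    def isolated(self) -> list[str]:
        return [u for u, d in zip(self.units, self.degrees) if d == 0]

    def row_standardized(self) -> np.ndarray:
        """Row-stochastic float weights; isolated units keep an all-zero row."""
        W = self.W.astype(float)
        deg = W.sum(axis=1)
        nz = deg > 0
        W[nz] = W[nz] / deg[nz, None]
        return W

    def subset(self, units: Sequence[str]) -> "AdjacencyMatrix":
        idx = [self.units.index(u) for u in units]
        return AdjacencyMatrix(tuple(units), self.W[np.ix_(idx, idx)])


# -- file I/O -------------------------------------------------------------


def load_panel(path: str | Path, schema: PanelSchema = DEFAULT_SCHEMA) -> PanelDataset:
    """Read a long-format CSV and return a validated :class:`PanelDataset`."""
    df = pd.read_csv(path)
    return PanelDataset.from_frame(df, schema)


def write_panel(panel: PanelDataset, path: str | Path) -> None:
    panel.frame.to_csv(path, index=False)


def load_adjacency(path: str | Path, units: Sequence[str]) -> AdjacencyMatrix:
    """Read a labelled square CSV and align it to ``units`` order."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    missing = [u for u in units if u not in df.index or u not in df.columns]
    if missing:
        raise SchemaError(
            f"adjacency file lacks row/column label(s): {', '.join(missing)}"
        )
    W = df.loc[list(units), list(units)].to_numpy()
    return AdjacencyMatrix(tuple(units), W)


def write_adjacency(adj: AdjacencyMatrix, path: str | Path) -> None:
    pd.DataFrame(adj.W, index=adj.units, columns=adj.units).to_csv(path)


def melt_wide(
    wide: pd.DataFrame,
    unit_col: str = "unit",
    value_name: str = "value",
) -> pd.DataFrame:
    """Convenience: melt a yearbook-style wide table (units x year columns)
    into long (unit, year, value) rows.  Not part of the pipeline contract."""
    out = wide.melt(id_vars=[unit_col], var_name="year", value_name=value_name)
    out["year"] = out["year"].astype(int)
    return out.sort_values([unit_col, "year"]).reset_index(drop=True)
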