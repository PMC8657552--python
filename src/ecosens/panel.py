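"""Region x year panel container, CSV I/O and normalization.

The panel is the pipeline's universal carrier: one row per (region, year),
with named numeric columns for the health outcomes (VTH, OWT, NOI, in
visit counts), the climate variables (temperature, humidity, precipitation,
sunshine, native units), the eco-efficiency score REE in (0, 1], and the
six regional controls (GDPPC, UL, PD, MP, LAD, NHCI).

Normalization removes the incommensurate units before kernel regression:
predictors are min-max mapped to [0, 1] (or z-scored), while outcomes are
scaled by their column maximum so they stay strictly positive — the mean
percentage error divides by observed outcomes, which must never be zero.
The fitted scaling state supports an exact inverse transform of
predictions back to the raw outcome scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OUTCOMES", "CLIMATE", "CONTROLS", "PREDICTORS",
    "PanelDataset", "Normalizer", "read_panel", "write_table", "normalize",
]

OUTCOMES = ["VTH", "OWT", "NOI"]
CLIMATE = ["temperature", "humidity", "precipitation", "sunshine"]
CONTROLS = ["GDPPC", "UL", "PD", "MP", "LAD", "NHCI"]
#: the 11 predictors of the full model: 4 climate + REE + 6 controls
PREDICTORS = CLIMATE + ["REE"] + CONTROLS


class PanelDataset:
    """Validated wrapper over a region x year DataFrame.

    Enforces unique (region, year) keys, numeric data columns, and a
    contiguous year range within each region.
    """

    def __init__(self, frame: pd.DataFrame):
        if "region" not in frame.columns or "year" not in frame.columns:
            raise ValueError("panel needs 'region' and 'year' columns")
        if len(frame) == 0:
            raise ValueError("no rows")
        df = frame.copy()
        df["year"] = df["year"].astype(int)
        dup = df.duplicated(subset=["region", "year"])
        if dup.any():
            r = df.loc[dup.idxmax()]
            raise ValueError(
                f"duplicate (region, year) key: ({r['region']!r}, {int(r['year'])})"
            )
        for col in df.columns:
            if col == "region":
                continue
            if not pd.api.types.is_numeric_dtype(df[col]):
                bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
                row = bad.index[0] if len(bad) else "?"
                raise ValueError(f"non-numeric cell in column {col!r} (row {row})")
            if df[col].isna().any():
                row = int(df[df[col].isna()].index[0])
                raise ValueError(f"missing value in column {col!r} (row {row})")
        for region, grp in df.groupby("region"):
            yrs = np.sort(grp["year"].to_numpy())
            if not np.array_equal(yrs, np.arange(yrs[0], yrs[-1] + 1)):
                raise ValueError(f"years not contiguous for region {region!r}")
        self.frame = df.sort_values(["region", "year"]).reset_index(drop=True)

    @property
    def regions(self) -> list[str]:
        return sorted(self.frame["region"].unique().tolist())

    @property
    def years(self) -> tuple[int, int]:
        return int(self.frame["year"].min()), int(self.frame["year"].max())

    @property
    def columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("region", "year")]

    def region_rows(self, region: str) -> pd.DataFrame:
        out = self.frame[self.frame["region"] == region]
        if len(out) == 0:
            raise KeyError(f"unknown region {region!r}")
        return out.sort_values("year")

    def national_rows(self, outcome_agg: str = "sum",
                      predictor_agg: str = "mean") -> pd.DataFrame:
        """Nation-level series: outcomes aggregated (default summed) and
        predictors averaged across regions, per year."""
        agg = {c: (outcome_agg if c in OUTCOMES else predictor_agg)
               for c in self.columns}
        out = self.frame.groupby("year", as_index=False).agg(agg)
        out.insert(0, "region", "national")
        return out

    def require_columns(self, cols: list[str]) -> None:
        missing = [c for c in cols if c not in self.frame.columns]
        if missing:
            raise ValueError(f"panel is missing required columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)


def read_panel(path) -> PanelDataset:
    """Read a panel CSV (header row, one row per region-year)."""
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"no rows in {path}")
    return PanelDataset(df)


def write_table(table, path) -> None:
    """Write a PanelDataset or DataFrame as CSV (UTF-8, '.' decimal)."""
    df = table.frame if isinstance(table, PanelDataset) else table
    df.to_csv(path, index=False)


@dataclass
class Normalizer:
    """Per-column affine scaling ``x' = (x - shift) / scale`` with exact
    inverse.  Scope is global (one scaling per column) or per-region."""

    method: str = "minmax"
    fit_scope: str = "global"
    params: dict = field(default_factory=dict)  # key -> (shift, scale)

    def _key(self, col: str, region=None):
        return (region, col) if self.fit_scope == "per-region" else col

    def _fit_column(self, values: np.ndarray, col: str, key) -> None:
        if self.method == "minmax":
            lo, hi = float(values.min()), float(values.max())
            if hi - lo == 0:
                warnings.warn(f"zero-range column {col!r}: mapped to 0",
                              stacklevel=3)
                self.params[key] = (lo, 1.0)
            else:
                self.params[key] = (lo, hi - lo)
        elif self.method == "zscore":
            mu, sd = float(values.mean()), float(values.std(ddof=0))
            if sd == 0:
                warnings.warn(f"zero-sd column {col!r}: mapped to 0",
                              stacklevel=3)
                self.params[key] = (mu, 1.0)
            else:
                self.params[key] = (mu, sd)
        elif self.method == "maxscale":
            # positive-preserving: divide by the column maximum
            self.params[key] = (0.0, float(values.max()))
        else:
            raise ValueError(f"unknown method {self.method!r}")

    def fit(self, df: pd.DataFrame, columns: list[str]) -> "Normalizer":
        if self.fit_scope == "per-region":
            for region, grp in df.groupby("region"):
                for col in columns:
                    self._fit_column(grp[col].to_numpy(float), col,
                                     (region, col))
        else:
            for col in columns:
                self._fit_column(df[col].to_numpy(float), col, col)
        return self

    def transform_column(self, values, col: str, region=None) -> np.ndarray:
        shift, scale = self.params[self._key(col, region)]
        return (np.asarray(values, dtype=float) - shift) / scale

    def inverse_column(self, values, col: str, region=None) -> np.ndarray:
        shift, scale = self.params[self._key(col, region)]
        return np.asarray(values, dtype=float) * scale + shift

    def transform(self, df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
        out = df.copy()
        if self.fit_scope == "per-region":
            for region, grp in out.groupby("region"):
                for col in columns:
                    out.loc[grp.index, col] = self.transform_column(
                        grp[col], col, region)
        else:
            for col in columns:
                out[col] = self.transform_column(out[col], col)
        return out

    def inverse(self, df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
        out = df.copy()
        if self.fit_scope == "per-region":
            for region, grp in out.groupby("region"):
                for col in columns:
                    out.loc[grp.index, col] = self.inverse_column(
                        grp[col], col, region)
        else:
            for col in columns:
                out[col] = self.inverse_column(out[col], col)
        return out


def normalize(panel: PanelDataset, method: str = "minmax",
              fit_scope: str = "global",
              columns: list[str] | None = None) -> tuple[PanelDataset, Normalizer]:
    """Normalize predictor columns of a panel; returns the transformed panel
    and the fitted state needed to invert predictions exactly."""
    if fit_scope not in ("global", "per-region"):
        raise ValueError("fit_scope must be 'global' or 'per-region'")
    cols = columns if columns is not None else \
        [c for c in panel.columns if c not in OUTCOMES]
    panel.require_columns(cols)
    norm = Normalizer(method=method, fit_scope=fit_scope)
    norm.fit(panel.frame, cols)
    return PanelDataset(norm.transform(panel.frame, cols)), norm
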