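"""Forecast-accuracy metrics and the five-setting model comparison.

Three in-sample accuracy measures over a T-year series of observed
outcomes ``y_t`` and model forecasts ``yhat_t``:

    MPE = (1/T) sum_t (y_t - yhat_t) / y_t      (signed relative error)
    MSE = (1/T) sum_t (y_t - yhat_t)^2
    SDE = sqrt(MSE)                             (root mean squared error)

The model comparison fits five variable settings per outcome — one model
per single climate variable (temperature / humidity / precipitation /
sunshine, each plus REE and the six controls: 8 predictors) and one with
all four climate variables together (11 predictors) — tunes each by direct
search, and averages the metrics over regions.  The four-indicator setting
is the designated basic model for the downstream elasticity analysis.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lssvr import LSSVR, LSSVRResults, KernelParams
from .panel import CLIMATE, CONTROLS, Normalizer, PanelDataset
from .search import SearchConfig, SearchTrace, search

__all__ = [
    "SETTINGS", "ErrorMetrics", "ComparisonTable", "FittedSetting",
    "mpe", "mse", "sde", "setting_predictors", "fit_setting",
    "evaluate_model", "compare_models", "child_seed",
]

#: the five model settings of the comparison stage
SETTINGS = ["temperature", "humidity", "precipitation", "sunshine", "four"]


def setting_predictors(variable_set: str) -> list[str]:
    """Predictor columns of a setting: its climate variable(s) plus REE and
    the six controls (8 columns single-factor, 11 four-factor)."""
    if variable_set == "four":
        climate = list(CLIMATE)
    elif variable_set in CLIMATE:
        climate = [variable_set]
    else:
        raise ValueError(f"unknown variable set {variable_set!r}; "
                         f"expected one of {SETTINGS}")
    return climate + ["REE"] + list(CONTROLS)


def child_seed(base: int | None, *keys: str) -> int:
    """Deterministic per-task seed derived from a base seed and string keys
    (stable CRC32 hashing; result < 2**31)."""
    entropy = [0 if base is None else int(base) % (2**31)]
    entropy += [zlib.crc32(k.encode()) for k in keys]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


# -- metrics -----------------------------------------------------------------

def mpe(y, yhat) -> float:
    """Mean percentage error with the signed numerator (y - yhat) / y."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    zero = np.nonzero(y == 0)[0]
    if zero.size:
        raise ValueError(f"y contains zero at index {int(zero[0])}; "
                         "MPE undefined")
    return float(np.mean((y - yhat) / y))


def mse(y, yhat) -> float:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    return float(np.mean((y - yhat) ** 2))


def sde(y, yhat) -> float:
    """Standard deviation of prediction errors, defined as sqrt(MSE)."""
    return float(np.sqrt(mse(y, yhat)))


@dataclass(frozen=True)
class ErrorMetrics:
    """(MPE, MSE, SDE) for one model on one region's series."""

    mpe: float
    mse: float
    sde: float

    @classmethod
    def from_series(cls, y, yhat, absolute_mpe: bool = False) -> "ErrorMetrics":
        if absolute_mpe:
            y_ = np.asarray(y, dtype=float)
            m = float(np.mean(np.abs((y_ - np.asarray(yhat, float)) / y_)))
        else:
            m = mpe(y, yhat)
        return cls(mpe=m, mse=mse(y, yhat), sde=sde(y, yhat))


# -- fitting one setting -----------------------------------------------------

@dataclass
class FittedSetting:
    """A tuned LS-SVR for one (outcome, variable set, region): the raw rows
    it was fitted on, the normalization state, and the fitted results."""

    outcome: str
    variable_set: str
    region: str
    predictors: list[str]
    rows: pd.DataFrame          # raw (un-normalized) data, sorted by year
    normalizer: Normalizer      # predictor scaling (fit on the full panel)
    y_scale: float              # outcome divided by this before fitting
    params: KernelParams
    trace: SearchTrace
    results: LSSVRResults

    def design(self, raw_rows: pd.DataFrame) -> np.ndarray:
        """Normalized predictor matrix for raw rows."""
        cols = [self.normalizer.transform_column(raw_rows[c], c)
                for c in self.predictors]
        return np.column_stack(cols)

    def predict_raw(self, raw_rows: pd.DataFrame) -> np.ndarray:
        """Predictions on the original outcome scale."""
        return self.results.predict(self.design(raw_rows)) * self.y_scale

    @property
    def y_norm(self) -> np.ndarray:
        return self.rows[self.outcome].to_numpy(float) / self.y_scale

    @property
    def fitted_norm(self) -> np.ndarray:
        return self.results.predict(self.design(self.rows))


def fit_setting(panel: PanelDataset, outcome: str, variable_set: str,
                region: str, search_cfg: SearchConfig | None = None,
                method: str = "minmax") -> FittedSetting:
    """Build the design for one setting, tune (sigma, gamma) by direct
    search and fit the LS-SVR.

    Predictors are normalized with parameters fitted on the whole panel
    (global scope); the outcome is divided by the maximum of the modelled
    series so normalized outcomes stay strictly positive.  ``region`` may
    be a region id, ``"national"`` (summed outcomes, averaged predictors)
    or ``"pooled"`` (all region-year rows stacked into one sample).
    """
    if search_cfg is None:
        search_cfg = SearchConfig()
    predictors = setting_predictors(variable_set)
    panel.require_columns(predictors + [outcome])

    norm = Normalizer(method=method, fit_scope="global")
    norm.fit(panel.frame, predictors)

    if region == "national":
        rows = panel.national_rows().sort_values("year")
    elif region == "pooled":
        rows = panel.frame.sort_values(["region", "year"])
    else:
        rows = panel.region_rows(region).sort_values("year")
    if len(rows) < 3:
        raise ValueError(f"fewer than 3 rows for region {region!r}")
    y_raw = rows[outcome].to_numpy(float)
    if np.any(y_raw <= 0):
        raise ValueError(f"non-positive outcome value in region {region!r}")
    y_scale = float(y_raw.max())

    X = np.column_stack([norm.transform_column(rows[c], c)
                         for c in predictors])
    y = y_raw / y_scale
    params, trace = search(X, y, search_cfg)
    results = LSSVR(y, X).fit(params)
    return FittedSetting(outcome, variable_set, region, predictors, rows,
                         norm, y_scale, params, trace, results)


def evaluate_model(panel: PanelDataset, outcome: str, variable_set: str,
                   region: str = "national",
                   search_cfg: SearchConfig | None = None,
                   absolute_mpe: bool = False) -> ErrorMetrics:
    """Tune, fit and score one setting in-sample.

    Metrics are computed on the normalized outcome scale (outcome divided
    by the series maximum), keeping MPE's denominator strictly positive.
    """
    fs = fit_setting(panel, outcome, variable_set, region, search_cfg)
    return ErrorMetrics.from_series(fs.y_norm, fs.fitted_norm,
                                    absolute_mpe=absolute_mpe)


# -- five-setting comparison -------------------------------------------------

@dataclass
class ComparisonTable:
    """Per-region detail and region-averaged metrics for the five settings."""

    outcome: str
    detail: pd.DataFrame     # columns: setting, region, mpe, mse, sde
    averages: pd.DataFrame   # one row per setting, averaged over regions
    selected: str = "four"

    def summary(self) -> str:
        lines = [f"Model comparison for outcome {self.outcome}",
                 "=" * 56]
        for _, r in self.averages.iterrows():
            mark = " <- basic model" if r["setting"] == self.selected else ""
            lines.append(f"{r['setting']:>14s}  MPE {r['mpe']:>10.6f}  "
                         f"MSE {r['mse']:>10.6f}  SDE {r['sde']:>10.6f}{mark}")
        lines.append("=" * 56)
        return "\n".join(lines)


def compare_models(panel: PanelDataset, outcome: str,
                   regions: list[str] | None = None,
                   search_cfg: SearchConfig | None = None,
                   selected: str = "four") -> ComparisonTable:
    """Evaluate all five settings on every region and average the metrics.

    Each (setting, region) pair gets an independent direct search seeded
    deterministically from the base seed.  Averages cover the supplied
    regions (by default all panel regions; the national series is not
    included in the averages unless listed explicitly).
    """
    if search_cfg is None:
        search_cfg = SearchConfig()
    if regions is None:
        regions = panel.regions
    records = []
    for setting in SETTINGS:
        for region in regions:
            cfg = SearchConfig(
                sigma0=search_cfg.sigma0, gamma0=search_cfg.gamma0,
                epsilon=search_cfg.epsilon, max_iter=search_cfg.max_iter,
                seed=child_seed(search_cfg.seed, outcome, setting, region),
                step_mode=search_cfg.step_mode,
            )
            m = evaluate_model(panel, outcome, setting, region, cfg)
            records.append({"setting": setting, "region": region,
                            "mpe": m.mpe, "mse": m.mse, "sde": m.sde})
    detail = pd.DataFrame(records)
    averages = (detail.groupby("setting", sort=False, as_index=False)
                [["mpe", "mse", "sde"]].mean())
    return ComparisonTable(outcome=outcome, detail=detail,
                           averages=averages, selected=selected)
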