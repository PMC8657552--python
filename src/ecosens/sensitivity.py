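"""Elasticity analysis of a fitted model by 1% perturbation.

The elasticity of the outcome with respect to predictor *j* is the mean
relative change in the model's predictions when column *j* is multiplied
by ``1 + delta`` (delta = 0.01 by default) with all other columns held
fixed:

    E_j = (1/m) sum_i [ yhat(x_i with x_ij * (1+delta)) - yhat(x_i) ]
                      / yhat(x_i)

Multiplying E_j by 100 reads as "percent change in the outcome per 1%
increase in the predictor".  Perturbations are one-at-a-time; predictions
are compared on the raw outcome scale, so the result does not depend on
how the pipeline normalized the data.

The table-level routine fits the four-indicator model (11 predictors)
independently for the national series and each region — each with its own
direct search — and assembles the region x predictor elasticity grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import child_seed, fit_setting
from .panel import PREDICTORS, PanelDataset
from .search import SearchConfig

__all__ = ["perturb", "elasticity", "elasticity_table", "ElasticityTable"]

_BASE_TOL = 1e-12


def perturb(X: np.ndarray, j: int, delta: float = 0.01) -> np.ndarray:
    """Return a copy of ``X`` with column ``j`` multiplied by ``1 + delta``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not 0 <= j < X.shape[1]:
        raise IndexError(f"predictor index {j} out of range for "
                         f"{X.shape[1]} columns")
    if delta <= -1:
        raise ValueError("delta must be > -1")
    out = X.copy()
    out[:, j] *= 1.0 + delta
    return out


def elasticity(model, X, j: int, delta: float = 0.01) -> float:
    """Mean relative prediction change under a ``(1+delta)`` scaling of
    column ``j``.  ``model`` is anything exposing ``predict(X)`` (a fitted
    LS-SVR or any prediction pipeline)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    base = np.asarray(model.predict(X), dtype=float).ravel()
    small = np.nonzero(np.abs(base) <= _BASE_TOL)[0]
    if small.size:
        raise ValueError(
            f"base prediction ~0 at row {int(small[0])}; relative change "
            "undefined")
    pert = np.asarray(model.predict(perturb(X, j, delta)), dtype=float).ravel()
    return float(np.mean((pert - base) / base))


class _RawScaleModel:
    """Prediction on the raw outcome scale for a FittedSetting, consuming
    raw predictor rows (normalization applied internally)."""

    def __init__(self, fitted):
        self.fitted = fitted

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        df = pd.DataFrame(np.atleast_2d(X_raw), columns=self.fitted.predictors)
        return self.fitted.predict_raw(df)


@dataclass
class ElasticityTable:
    """Region x predictor grid of elasticities for one outcome.

    ``table`` rows: 'national' plus each region; columns: the fitted
    predictors.  ``params`` records the tuned (sigma, gamma) per row.
    """

    outcome: str
    table: pd.DataFrame
    params: dict = field(default_factory=dict)  # region -> (sigma, gamma)
    seed: int | None = None
    delta: float = 0.01
    failures: dict = field(default_factory=dict)  # region -> error message

    def to_dataframe(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "region", out.index)
        return out.reset_index(drop=True)

    def summary(self) -> str:
        lines = [f"Elasticities for outcome {self.outcome} "
                 f"(fraction per +{self.delta:.0%} in each predictor)",
                 "=" * 72]
        with pd.option_context("display.float_format", "{:10.6f}".format,
                               "display.width", 200):
            lines.append(str(self.table))
        if self.failures:
            lines.append(f"failed regions: {sorted(self.failures)}")
        lines.append("=" * 72)
        return "\n".join(lines)


def elasticity_table(panel: PanelDataset, outcome: str,
                     regions: list[str] | None = None,
                     search_cfg: SearchConfig | None = None,
                     delta: float = 0.01,
                     variable_set: str = "four") -> ElasticityTable:
    """Fit the basic (four-indicator) model per region and tabulate E_j for
    every predictor.

    Rows: the national aggregate first, then each region.  Per-region
    failures are recorded and flagged (row of NaN) without aborting the
    run.  Reproducible: row seeds derive from ``search_cfg.seed``.
    """
    if search_cfg is None:
        search_cfg = SearchConfig()
    if regions is None:
        regions = panel.regions
    from .evaluation import setting_predictors
    predictors = setting_predictors(variable_set)

    rows = {}
    params: dict = {}
    failures: dict = {}
    for region in ["national"] + list(regions):
        cfg = SearchConfig(
            sigma0=search_cfg.sigma0, gamma0=search_cfg.gamma0,
            epsilon=search_cfg.epsilon, max_iter=search_cfg.max_iter,
            seed=child_seed(search_cfg.seed, "elasticity", outcome, region),
            step_mode=search_cfg.step_mode,
        )
        try:
            fs = fit_setting(panel, outcome, variable_set, region, cfg)
            raw = _RawScaleModel(fs)
            X_raw = fs.rows[predictors].to_numpy(float)
            rows[region] = [elasticity(raw, X_raw, j, delta)
                            for j in range(len(predictors))]
            params[region] = (fs.params.sigma, fs.params.gamma)
        except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
            failures[region] = str(exc)
            rows[region] = [np.nan] * len(predictors)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=predictors)
    return ElasticityTable(outcome=outcome, table=table, params=params,
                           seed=search_cfg.seed, delta=delta,
                           failures=failures)
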