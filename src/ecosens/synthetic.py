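"""Synthetic regional panel and DEA tables with known ground truth.

The generator emulates the statistical shape of a Chinese-style provincial
panel: roughly 30 regions observed over 15 years (2002-2016), with

* climate series (temperature, humidity, precipitation, sunshine) built as
  a region-specific mean plus AR(1) fluctuation — the climate columns
  fluctuate visibly more than the outcomes do;
* six control variables (GDPPC, UL, PD, MP, LAD, NHCI) and the REE
  eco-efficiency score following smooth regional trends;
* health outcomes (VTH, OWT, NOI) generated from a known response surface
  applied to the predictors, plus Gaussian observation noise, floored at a
  small positive constant so relative errors are always well defined.

Because the response surface is known analytically, the generator also
returns the true elasticity of the outcome with respect to every predictor
(evaluated at the panel mean), recorded as a fraction per 1% predictor
increase: a proportional response yields exactly 0.01.  These ground
truths anchor every downstream parameter-recovery test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dea import DEATable
from .panel import CLIMATE, CONTROLS, OUTCOMES, PREDICTORS, PanelDataset

__all__ = ["ResponseSpec", "GeneratorConfig", "GroundTruth",
           "generate_panel", "generate_dea_table"]

_FAMILIES = ("constant", "linear", "log-linear", "smooth-nonlinear")

#: positive floor applied to generated outcomes (visit counts)
_OUTCOME_FLOOR = 1e-3

#: relative scale of the three outcomes (VTH > OWT > NOI, as for hospital
#: visits vs emergency outpatients vs inpatients)
_OUTCOME_SCALE = {"VTH": 1.0, "OWT": 0.6, "NOI": 0.25}


@dataclass(frozen=True)
class ResponseSpec:
    """Named response family with one coefficient per predictor it uses.

    families
    --------
    constant          f(x) = intercept
    linear            f(x) = intercept + sum_j beta_j x_j
    log-linear        f(x) = exp(intercept + sum_j beta_j ln x_j)
    smooth-nonlinear  f(x) = intercept + sum_j beta_j x_j + q_j x_j^2
    """

    family: str = "log-linear"
    coefficients: dict = field(default_factory=dict)
    intercept: float = 0.0
    quadratic: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown response family {self.family!r}")
        unknown = [k for k in {**self.coefficients, **self.quadratic}
                   if k not in PREDICTORS]
        if unknown:
            raise ValueError(f"response_spec references unknown predictors: "
                             f"{unknown}")

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        if self.family == "constant":
            return np.full(n, float(self.intercept))
        if self.family == "linear":
            out = np.full(n, float(self.intercept))
            for k, b in self.coefficients.items():
                out = out + b * df[k].to_numpy(float)
            return out
        if self.family == "log-linear":
            out = np.full(n, float(self.intercept))
            for k, b in self.coefficients.items():
                out = out + b * np.log(df[k].to_numpy(float))
            return np.exp(out)
        # smooth-nonlinear
        out = np.full(n, float(self.intercept))
        for k, b in self.coefficients.items():
            out = out + b * df[k].to_numpy(float)
        for k, q in self.quadratic.items():
            out = out + q * df[k].to_numpy(float) ** 2
        return out

    def elasticities_at(self, mean_row: pd.Series) -> dict:
        """Analytic elasticity per predictor at the given evaluation point,
        as fraction per 1% increase: 0.01 * x_j f'_j(x) / f(x)."""
        out = {p: 0.0 for p in PREDICTORS}
        if self.family == "constant":
            return out
        if self.family == "log-linear":
            for k, b in self.coefficients.items():
                out[k] = 0.01 * b
            return out
        f0 = float(self.evaluate(pd.DataFrame([mean_row]))[0])
        if f0 == 0:
            raise ValueError("response is zero at the panel mean; "
                             "elasticities undefined")
        for k in set(self.coefficients) | set(self.quadratic):
            x = float(mean_row[k])
            deriv = self.coefficients.get(k, 0.0)
            if self.family == "smooth-nonlinear":
                deriv += 2.0 * self.quadratic.get(k, 0.0) * x
            out[k] = 0.01 * deriv * x / f0
        return out


def _default_response() -> ResponseSpec:
    # log-linear baseline: demand driven mostly by the smooth economic and
    # demographic controls, modestly by climate, so outcome series stay
    # visibly smoother than the climate series; outcomes land around O(250)
    return ResponseSpec(
        family="log-linear",
        coefficients={
            "temperature": 0.20, "humidity": 0.15, "precipitation": 0.05,
            "sunshine": 0.08, "REE": 0.25, "GDPPC": 0.40, "UL": 0.20,
            "PD": 0.10, "MP": 0.15, "LAD": 0.10, "NHCI": 0.05,
        },
        intercept=-2.0,
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design knobs for the generator.

    ``years`` is an inclusive range; ``noise_sd`` is the additive Gaussian
    observation noise on the outcome scale (absolute units of the VTH
    response); ``climate_volatility`` is the relative fluctuation amplitude
    of the climate series around their regional means.
    """

    n_regions: int = 30
    years: tuple[int, int] = (2002, 2016)
    response_spec: ResponseSpec = field(default_factory=_default_response)
    noise_sd: float = 5.0
    climate_volatility: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        y0, y1 = self.years
        if y1 - y0 + 1 < 3:
            raise ValueError("need at least 3 years")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """True elasticity (fraction per 1% increase) per predictor, at the
    panel mean of the noiseless response; exactly 0 for unused predictors."""

    elasticities: dict

    def __getitem__(self, predictor: str) -> float:
        return self.elasticities[predictor]


def _ar1(rng: np.random.Generator, n: int, phi: float = 0.3) -> np.ndarray:
    """Stationary AR(1) innovations with unit marginal variance."""
    z = np.empty(n)
    z[0] = rng.standard_normal()
    w = np.sqrt(1.0 - phi**2)
    for t in range(1, n):
        z[t] = phi * z[t - 1] + w * rng.standard_normal()
    return z


def _region_frames(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    n_t = years.size
    t = np.arange(n_t)
    frames = []
    for r in range(config.n_regions):
        region = f"R{r + 1:02d}"
        row = {"region": region, "year": years}
        # climate: regional mean * (1 + volatility * AR(1)); clipped positive
        means = {
            "temperature": rng.uniform(5.0, 24.0),
            "humidity": rng.uniform(45.0, 80.0),
            "precipitation": rng.uniform(400.0, 1800.0),
            "sunshine": rng.uniform(1200.0, 2800.0),
        }
        for col, mu in means.items():
            series = mu * (1.0 + config.climate_volatility * _ar1(rng, n_t))
            row[col] = np.clip(series, 0.05 * mu, None)
        # controls: smooth regional trends with tiny jitter (much less
        # volatile than climate)
        growth = rng.uniform(0.06, 0.12)
        gdppc0 = rng.uniform(8_000.0, 30_000.0)
        row["GDPPC"] = gdppc0 * np.exp(growth * t) * \
            (1.0 + 0.01 * _ar1(rng, n_t))
        ul0, ul1 = rng.uniform(0.30, 0.45), rng.uniform(0.55, 0.85)
        row["UL"] = ul0 + (ul1 - ul0) * t / max(n_t - 1, 1)
        row["PD"] = rng.uniform(50.0, 900.0) * (1.0 + 0.003 * t) * \
            (1.0 + 0.005 * _ar1(rng, n_t))
        row["MP"] = rng.uniform(10.0, 60.0) * np.exp(0.04 * t) * \
            (1.0 + 0.01 * _ar1(rng, n_t))
        row["LAD"] = rng.uniform(5.0, 30.0) * np.exp(0.035 * t) * \
            (1.0 + 0.01 * _ar1(rng, n_t))
        row["NHCI"] = rng.uniform(300.0, 3000.0) * (1.0 + 0.01 * t) * \
            (1.0 + 0.005 * _ar1(rng, n_t))
        # eco-efficiency: smooth rise within (0, 1]
        ree0 = rng.uniform(0.20, 0.45)
        ree1 = rng.uniform(0.50, 0.95)
        row["REE"] = np.clip(
            ree0 + (ree1 - ree0) * t / max(n_t - 1, 1)
            + 0.01 * _ar1(rng, n_t),
            0.01, 1.0,
        )
        frames.append(pd.DataFrame(row))
    return pd.concat(frames, ignore_index=True)


def generate_panel(config: GeneratorConfig) -> tuple[PanelDataset, GroundTruth]:
    """Generate a complete panel plus the analytic ground-truth
    elasticities of its (noiseless) response at the panel mean.

    All three outcomes share the response surface up to a positive
    per-outcome scale factor, so they share one set of elasticities.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0x9A3E])
    df = _region_frames(config, rng)
    response = config.response_spec.evaluate(df)
    for outcome in OUTCOMES:
        scale = _OUTCOME_SCALE[outcome]
        noise = rng.standard_normal(len(df)) * config.noise_sd * scale
        df[outcome] = np.maximum(scale * response + noise, _OUTCOME_FLOOR)
    ordered = ["region", "year"] + OUTCOMES + PREDICTORS
    df = df[ordered]
    mean_row = df[PREDICTORS].mean()
    truth = GroundTruth(config.response_spec.elasticities_at(mean_row))
    return PanelDataset(df), truth


def generate_dea_table(config: GeneratorConfig) -> DEATable:
    """Generate a per-region-year DEA table: three inputs (labor, capital,
    energy), one desirable output (GDP) and two undesirable outputs (waste
    gas, wastewater), all strictly positive.

    The first DMU is planted on the efficient frontier: its inputs and
    undesirable outputs are below, and its desirable output above, those of
    every other DMU, so no combination can dominate it.
    """
    rng = np.random.default_rng([config.seed, 0xDEA])
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    ids, rows = [], []
    for r in range(config.n_regions):
        region = f"R{r + 1:02d}"
        labor0 = rng.uniform(200.0, 900.0)
        capital0 = rng.uniform(1_000.0, 9_000.0)
        energy0 = rng.uniform(500.0, 5_000.0)
        gdp0 = rng.uniform(1_000.0, 8_000.0)
        eff = rng.uniform(0.4, 1.0)  # cleaner regions emit less per GDP
        for i, yr in enumerate(years):
            grow = np.exp(0.05 * i)
            labor = labor0 * (1.0 + 0.01 * i) * rng.uniform(0.95, 1.05)
            capital = capital0 * grow * rng.uniform(0.95, 1.05)
            energy = energy0 * grow * rng.uniform(0.95, 1.05)
            gdp = gdp0 * grow * rng.uniform(0.95, 1.05)
            gas = energy * (1.2 - eff) * rng.uniform(0.9, 1.1)
            water = gdp * (1.1 - eff) * 0.3 * rng.uniform(0.9, 1.1)
            ids.append(f"{region}:{yr}")
            rows.append([labor, capital, energy, gdp, gas, water])
    arr = np.array(rows)
    if len(ids) > 1:
        # plant DMU 0 strictly undominated (and dominating): fewer inputs
        # and bads than anyone, more good output than anyone
        others = arr[1:]
        arr[0, :3] = 0.9 * others[:, :3].min(axis=0)
        arr[0, 3] = 1.1 * others[:, 3].max()
        arr[0, 4:] = 0.9 * others[:, 4:].min(axis=0)
    return DEATable(dmu_ids=ids, X=arr[:, :3], Yg=arr[:, 3:4], Yb=arr[:, 4:])
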