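"""Slacks-based measure (SBM) DEA with undesirable outputs.

Each region-year is a decision-making unit (DMU) consuming inputs
(labor, capital, energy, ...) and producing one or more desirable outputs
(e.g. GDP) alongside undesirable ones (waste gas, wastewater, ...).  The
non-oriented SBM efficiency of DMU *o* is the optimum of the fractional
program

    rho_o = min  [1 - (1/m) sum_i s_i^- / x_io]
                 ------------------------------------------------------
                 [1 + 1/(s1+s2) (sum_r s_r^g / y_ro^g + sum_r s_r^b / y_ro^b)]

    s.t.  x_o  = X  lam + s^-        (input excesses)
          y_o^g = Yg lam - s^g       (desirable shortfalls)
          y_o^b = Yb lam + s^b       (undesirable excesses)
          lam, s^-, s^g, s^b >= 0
          [ sum lam = 1 under variable returns to scale ]

solved per DMU through the Charnes–Cooper transformation, which turns the
fractional objective into a linear program (scipy HiGHS).  Scores lie in
(0, 1]; rho = 1 iff every slack is zero, i.e. the DMU sits on the frontier.
The measure is invariant to the units of every column because each slack is
normalized by the DMU's own observed value.

By default the reference set pools all DMUs (all regions, all years); a
per-year frontier is available via ``frontier="per-year"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = ["DEATable", "EfficiencyResult", "SBMEfficiency", "sbm_score", "attach_ree"]

_SLACK_TOL = 1e-9


@dataclass
class DEATable:
    """Per-DMU inputs, desirable outputs and undesirable outputs.

    All entries must be strictly positive: SBM normalizes each slack by the
    observed value of its own column.
    """

    dmu_ids: list[str]
    X: np.ndarray   # (n, m_in) inputs
    Yg: np.ndarray  # (n, s_g) desirable outputs
    Yb: np.ndarray  # (n, s_b) undesirable outputs

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Yg = np.atleast_2d(np.asarray(self.Yg, dtype=float))
        self.Yb = np.atleast_2d(np.asarray(self.Yb, dtype=float))
        n = len(self.dmu_ids)
        for name, M in (("X", self.X), ("Yg", self.Yg), ("Yb", self.Yb)):
            if M.shape[0] != n:
                raise ValueError(f"{name} has {M.shape[0]} rows, expected {n}")
            if not np.all(M > 0):
                raise ValueError(f"{name} must be strictly positive")
        if len(set(self.dmu_ids)) != n:
            raise ValueError("duplicate dmu_ids")

    @property
    def n_dmus(self) -> int:
        return len(self.dmu_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DEATable":
        """Build from a table with columns ``dmu_id, input:*, good:*, bad:*``."""
        if "dmu_id" not in df.columns:
            raise ValueError("missing dmu_id column")
        ins = [c for c in df.columns if c.startswith("input:")]
        goods = [c for c in df.columns if c.startswith("good:")]
        bads = [c for c in df.columns if c.startswith("bad:")]
        if not ins or not goods or not bads:
            raise ValueError("need at least one input:, good: and bad: column")
        return cls(
            dmu_ids=[str(v) for v in df["dmu_id"]],
            X=df[ins].to_numpy(float),
            Yg=df[goods].to_numpy(float),
            Yb=df[bads].to_numpy(float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"dmu_id": self.dmu_ids}
        for i in range(self.X.shape[1]):
            cols[f"input:x{i + 1}"] = self.X[:, i]
        for i in range(self.Yg.shape[1]):
            cols[f"good:y{i + 1}"] = self.Yg[:, i]
        for i in range(self.Yb.shape[1]):
            cols[f"bad:u{i + 1}"] = self.Yb[:, i]
        return pd.DataFrame(cols)


@dataclass
class EfficiencyResult:
    """SBM score and optimal slacks for one DMU."""

    dmu_id: str
    score: float
    input_slacks: np.ndarray
    desirable_slacks: np.ndarray
    undesirable_slacks: np.ndarray
    status: str = "optimal"

    @property
    def efficient(self) -> bool:
        return bool(
            self.input_slacks.max(initial=0.0) <= _SLACK_TOL
            and self.desirable_slacks.max(initial=0.0) <= _SLACK_TOL
            and self.undesirable_slacks.max(initial=0.0) <= _SLACK_TOL
        )


def _solve_one(table: DEATable, o: int, ref: np.ndarray, rts: str) -> EfficiencyResult:
    """Charnes–Cooper linearization of the SBM fractional program for DMU o.

    Variables z = [t, Lam (n_ref), S- (m), Sg (sg), Sb (sb)], all >= 0, with
    Lam = t*lam, S = t*s.  Objective min t - (1/m) sum S-_i / x_io; the
    denominator is pinned to 1 by an equality row.
    """
    m = table.X.shape[1]
    sg = table.Yg.shape[1]
    sb = table.Yb.shape[1]
    n_ref = ref.size
    xo, ygo, ybo = table.X[o], table.Yg[o], table.Yb[o]

    nvar = 1 + n_ref + m + sg + sb
    i_t = 0
    i_lam = slice(1, 1 + n_ref)
    i_sm = slice(1 + n_ref, 1 + n_ref + m)
    i_sg = slice(1 + n_ref + m, 1 + n_ref + m + sg)
    i_sb = slice(1 + n_ref + m + sg, nvar)

    c = np.zeros(nvar)
    c[i_t] = 1.0
    c[i_sm] = -1.0 / (m * xo)

    rows = []
    rhs = []
    # denominator = 1
    row = np.zeros(nvar)
    row[i_t] = 1.0
    row[i_sg] = 1.0 / ((sg + sb) * ygo)
    row[i_sb] = 1.0 / ((sg + sb) * ybo)
    rows.append(row)
    rhs.append(1.0)
    # t*x_o = X'Lam + S-
    for i in range(m):
        row = np.zeros(nvar)
        row[i_lam] = table.X[ref, i]
        row[i_sm.start + i] = 1.0
        row[i_t] = -xo[i]
        rows.append(row)
        rhs.append(0.0)
    # t*yg_o = Yg'Lam - Sg
    for r in range(sg):
        row = np.zeros(nvar)
        row[i_lam] = table.Yg[ref, r]
        row[i_sg.start + r] = -1.0
        row[i_t] = -ygo[r]
        rows.append(row)
        rhs.append(0.0)
    # t*yb_o = Yb'Lam + Sb
    for r in range(sb):
        row = np.zeros(nvar)
        row[i_lam] = table.Yb[ref, r]
        row[i_sb.start + r] = 1.0
        row[i_t] = -ybo[r]
        rows.append(row)
        rhs.append(0.0)
    if rts == "vrs":
        row = np.zeros(nvar)
        row[i_lam] = 1.0
        row[i_t] = -1.0
        rows.append(row)
        rhs.append(0.0)

    res = linprog(c, A_eq=np.array(rows), b_eq=np.array(rhs),
                  bounds=[(0, None)] * nvar, method="highs")
    if not res.success or res.x[i_t] <= 0:
        return EfficiencyResult(
            dmu_id=table.dmu_ids[o], score=np.nan,
            input_slacks=np.full(m, np.nan),
            desirable_slacks=np.full(sg, np.nan),
            undesirable_slacks=np.full(sb, np.nan),
            status=f"infeasible: {res.message}",
        )
    t = res.x[i_t]
    score = min(1.0, float(res.fun))
    slacks = [res.x[sl] / t for sl in (i_sm, i_sg, i_sb)]
    slacks = [np.where(s <= _SLACK_TOL, 0.0, s) for s in slacks]
    return EfficiencyResult(table.dmu_ids[o], score, *slacks)


def sbm_score(table: DEATable, returns_to_scale: str = "crs",
              frontier: str = "pooled") -> list[EfficiencyResult]:
    """Non-oriented SBM efficiency with undesirable outputs, one LP per DMU.

    Parameters
    ----------
    returns_to_scale : {"crs", "vrs"}
        Constant (default) or variable returns to scale.
    frontier : {"pooled", "per-year"}
        Reference set: all DMUs pooled (default), or only DMUs sharing the
        year suffix of a ``region:year`` id.
    """
    rts = returns_to_scale.lower()
    if rts not in ("crs", "vrs"):
        raise ValueError("returns_to_scale must be 'crs' or 'vrs'")
    if frontier not in ("pooled", "per-year"):
        raise ValueError("frontier must be 'pooled' or 'per-year'")
    n = table.n_dmus
    if frontier == "per-year":
        years = [d.rsplit(":", 1)[-1] for d in table.dmu_ids]
        refs = {yr: np.array([i for i, y in enumerate(years) if y == yr])
                for yr in set(years)}
        return [_solve_one(table, o, refs[years[o]], rts) for o in range(n)]
    ref = np.arange(n)
    return [_solve_one(table, o, ref, rts) for o in range(n)]


class SBMEfficiency:
    """Model-object wrapper: ``SBMEfficiency(table).fit()`` scores every DMU."""

    def __init__(self, table: DEATable, returns_to_scale: str = "crs",
                 frontier: str = "pooled"):
        self.table = table
        self.returns_to_scale = returns_to_scale
        self.frontier = frontier

    def fit(self) -> "SBMResults":
        return SBMResults(self, sbm_score(self.table, self.returns_to_scale,
                                          self.frontier))


class SBMResults:
    def __init__(self, model: SBMEfficiency, results: list[EfficiencyResult]):
        self.model = model
        self.results = results

    @property
    def scores(self) -> pd.Series:
        return pd.Series({r.dmu_id: r.score for r in self.results}, name="REE")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dmu_id": [r.dmu_id for r in self.results],
             "score": [r.score for r in self.results],
             "efficient": [r.efficient for r in self.results],
             "status": [r.status for r in self.results]}
        )

    def summary(self) -> str:
        s = self.scores
        lines = [
            "SBM-DEA Efficiency Results",
            "=" * 46,
            f"DMUs                  {len(self.results):>12d}",
            f"returns to scale      {self.model.returns_to_scale:>12s}",
            f"frontier              {self.model.frontier:>12s}",
            f"mean score            {s.mean():>12.4f}",
            f"efficient DMUs        {sum(r.efficient for r in self.results):>12d}",
            "=" * 46,
        ]
        return "\n".join(lines)


def attach_ree(panel, results: list[EfficiencyResult], column: str = "REE"):
    """Join SBM scores onto a panel as its REE column.

    DMU ids follow the ``region:year`` convention.  Every (region, year) in
    the panel must have a score; a missing one raises with the offending key.
    """
    from .panel import PanelDataset

    scores = {r.dmu_id: r.score for r in results}
    df = panel.frame.copy()
    vals = []
    for region, year in zip(df["region"], df["year"]):
        key = f"{region}:{year}"
        if key not in scores:
            raise KeyError(f"no efficiency result for region-year {key!r}")
        vals.append(scores[key])
    df[column] = vals
    if not ((df[column] > 0) & (df[column] <= 1)).all():
        raise ValueError("REE scores must lie in (0, 1]")
    return PanelDataset(df)
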