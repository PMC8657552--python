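"""SBM-DEA: frontier scores, slacks, units invariance, LP-vs-fractional oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from ecosens.dea import DEATable, attach_ree, sbm_score, SBMEfficiency
from ecosens.panel import PanelDataset


def _fractional_sbm_oracle(table: DEATable, o: int, n_starts: int = 12,
                           seed: int = 0) -> float:
    """Independent route: minimize the SBM fractional objective directly
    over the intensity vector lambda (slacks eliminated through the
    envelopment equalities), via multi-start SLSQP."""
    X, Yg, Yb = table.X, table.Yg, table.Yb
    xo, ygo, ybo = X[o], Yg[o], Yb[o]
    m, sg, sb = X.shape[1], Yg.shape[1], Yb.shape[1]

    def rho(lam):
        s_in = xo - lam @ X
        s_g = lam @ Yg - ygo
        s_b = ybo - lam @ Yb
        num = 1.0 - np.mean(s_in / xo)
        den = 1.0 + (np.sum(s_g / ygo) + np.sum(s_b / ybo)) / (sg + sb)
        return num / den

    cons = [
        {"type": "ineq", "fun": lambda lam: xo - lam @ X},
        {"type": "ineq", "fun": lambda lam: lam @ Yg - ygo},
        {"type": "ineq", "fun": lambda lam: ybo - lam @ Yb},
    ]
    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [np.eye(table.n_dmus)[o]] + \
        [rng.uniform(0, 1.5, table.n_dmus) for _ in range(n_starts)]
    for lam0 in starts:
        res = minimize(rho, lam0, method="SLSQP",
                       bounds=[(0, None)] * table.n_dmus,
                       constraints=cons,
                       options={"maxiter": 300, "ftol": 1e-12})
        if res.success and res.fun < best:
            best = res.fun
    return float(best)


def _dominates(a_in, a_g, a_b, b_in, b_g, b_b) -> bool:
    """a dominates b: no worse in every coordinate, strictly better in one."""
    no_worse = (np.all(a_in <= b_in) and np.all(a_g >= b_g)
                and np.all(a_b <= b_b))
    strictly = (np.any(a_in < b_in) or np.any(a_g > b_g)
                or np.any(a_b < b_b))
    return no_worse and strictly


@pytest.fixture
def two_dmu_doubled():
    """B consumes exactly double every input of A with identical outputs."""
    return DEATable(
        dmu_ids=["A", "B"],
        X=np.array([[2.0, 3.0], [4.0, 6.0]]),
        Yg=np.array([[5.0], [5.0]]),
        Yb=np.array([[1.0], [1.0]]),
    )


class TestScores:
    def test_single_dmu_is_efficient(self):
        table = DEATable(["only"], X=[[2.0, 1.0]], Yg=[[3.0]], Yb=[[0.5]])
        (res,) = sbm_score(table)
        assert res.score == pytest.approx(1.0, abs=1e-9)
        assert res.efficient

    def test_doubled_inputs_dominated(self, two_dmu_doubled):
        res = {r.dmu_id: r for r in sbm_score(two_dmu_doubled)}
        assert res["A"].score == pytest.approx(1.0, abs=1e-9)
        assert res["B"].score < 1.0
        # analytic optimum of the 2-DMU system: lambda=(1,0) leaves half of
        # each input as slack, rho = 1 - mean(1/2) = 0.5
        assert res["B"].score == pytest.approx(0.5, abs=1e-6)
        np.testing.assert_allclose(res["B"].input_slacks, [2.0, 3.0],
                                   atol=1e-6)

    def test_matches_fractional_program_oracle(self, two_dmu_doubled):
        lp = {r.dmu_id: r.score for r in sbm_score(two_dmu_doubled)}
        for o, d in enumerate(["A", "B"]):
            assert lp[d] == pytest.approx(
                _fractional_sbm_oracle(two_dmu_doubled, o), abs=1e-6)

    def test_matches_oracle_on_random_small_instance(self):
        rng = np.random.default_rng(5)
        table = DEATable(
            dmu_ids=[f"D{i}" for i in range(4)],
            X=rng.uniform(1, 5, size=(4, 2)),
            Yg=rng.uniform(1, 5, size=(4, 1)),
            Yb=rng.uniform(1, 5, size=(4, 1)),
        )
        for o in range(4):
            lp = sbm_score(table)[o].score
            assert lp == pytest.approx(_fractional_sbm_oracle(table, o),
                                       abs=1e-6)

    def test_units_invariance(self, two_dmu_doubled):
        base = [r.score for r in sbm_score(two_dmu_doubled)]
        scaled = DEATable(
            dmu_ids=two_dmu_doubled.dmu_ids,
            X=two_dmu_doubled.X * np.array([1000.0, 1.0]),
            Yg=two_dmu_doubled.Yg * 7.0,
            Yb=two_dmu_doubled.Yb * 0.001,
        )
        np.testing.assert_allclose([r.score for r in sbm_score(scaled)],
                                   base, atol=1e-9)

    def test_monotone_in_input_inflation(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(1, 4, size=(5, 2))
        Yg = rng.uniform(1, 4, size=(5, 1))
        Yb = rng.uniform(1, 4, size=(5, 1))
        ids = [f"D{i}" for i in range(5)]
        base = sbm_score(DEATable(ids, X, Yg, Yb))[0].score
        for factor in (1.2, 2.0, 5.0):
            X2 = X.copy()
            X2[0, 0] *= factor
            worse = sbm_score(DEATable(ids, X2, Yg, Yb))[0].score
            assert worse <= base + 1e-9

    def test_scores_in_unit_interval(self):
        rng = np.random.default_rng(9)
        table = DEATable(
            dmu_ids=[f"D{i}" for i in range(8)],
            X=rng.uniform(1, 9, size=(8, 3)),
            Yg=rng.uniform(1, 9, size=(8, 2)),
            Yb=rng.uniform(1, 9, size=(8, 2)),
        )
        for rts in ("crs", "vrs"):
            scores = [r.score for r in sbm_score(table, rts)]
            assert all(0 < s <= 1 for s in scores)
        # efficiency: score 1 iff all slacks ~ 0
        for r in sbm_score(table):
            assert (r.score >= 1 - 1e-9) == r.efficient

    def test_vrs_never_below_crs(self, two_dmu_doubled):
        crs = [r.score for r in sbm_score(two_dmu_doubled, "crs")]
        vrs = [r.score for r in sbm_score(two_dmu_doubled, "vrs")]
        assert all(v >= c - 1e-9 for c, v in zip(crs, vrs))


class TestTable:
    def test_rejects_nonpositive_entries(self):
        with pytest.raises(ValueError, match="positive"):
            DEATable(["a"], X=[[0.0]], Yg=[[1.0]], Yb=[[1.0]])

    def test_dataframe_round_trip(self, two_dmu_doubled):
        df = two_dmu_doubled.to_dataframe()
        back = DEATable.from_dataframe(df)
        np.testing.assert_allclose(back.X, two_dmu_doubled.X)
        np.testing.assert_allclose(back.Yg, two_dmu_doubled.Yg)
        np.testing.assert_allclose(back.Yb, two_dmu_doubled.Yb)
        assert back.dmu_ids == two_dmu_doubled.dmu_ids

    def test_model_object_summary(self, two_dmu_doubled):
        res = SBMEfficiency(two_dmu_doubled).fit()
        assert "SBM-DEA" in res.summary()
        assert res.scores["A"] == pytest.approx(1.0, abs=1e-9)


class TestAttachRee:
    def _panel(self):
        return PanelDataset(pd.DataFrame({
            "region": ["R1", "R1", "R2", "R2"],
            "year": [2002, 2003, 2002, 2003],
            "VTH": [1.0, 2.0, 3.0, 4.0],
        }))

    def _results(self, scores):
        from ecosens.dea import EfficiencyResult
        z = np.zeros(1)
        return [EfficiencyResult(k, s, z, z, z) for k, s in scores.items()]

    def test_all_ones_constant_column(self):
        scores = {f"R{r}:{y}": 1.0 for r in (1, 2) for y in (2002, 2003)}
        panel = attach_ree(self._panel(), self._results(scores))
        assert (panel.frame["REE"] == 1.0).all()

    def test_join_order_independent(self):
        scores = {"R1:2002": 0.4, "R1:2003": 0.5, "R2:2002": 0.6,
                  "R2:2003": 0.7}
        fwd = attach_ree(self._panel(), self._results(scores))
        rev = attach_ree(self._panel(),
                         list(reversed(self._results(scores))))
        assert fwd.frame.equals(rev.frame)

    def test_missing_dmu_named_in_error(self):
        scores = {"R1:2002": 0.4, "R1:2003": 0.5, "R2:2002": 0.6}
        with pytest.raises(KeyError, match="R2:2003"):
            attach_ree(self._panel(), self._results(scores))


def test_planted_frontier_dmu_undominated_and_efficient():
    """Brute-force pairwise dominance over the generated DEA table: the
    planted DMU must be undominated and scored 1 by the LP."""
    from ecosens.synthetic import GeneratorConfig, generate_dea_table
    table = generate_dea_table(GeneratorConfig(n_regions=4,
                                               years=(2002, 2005), seed=21))
    for j in range(1, table.n_dmus):
        assert not _dominates(table.X[j], table.Yg[j], table.Yb[j],
                              table.X[0], table.Yg[0], table.Yb[0])
    assert sbm_score(table)[0].score == pytest.approx(1.0, abs=1e-9)
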