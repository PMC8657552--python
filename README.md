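# ecosens

Eco-efficiency scoring and elasticity analysis of regional climate–health
panels with least-squares support vector regression (LS-SVR).

## The problem

How sensitive is regional health-care demand — hospital visits (VTH),
emergency outpatients (OWT), inpatient numbers (NOI) — to climate
conditions and to a region's eco-efficiency?  `ecosens` answers this for
annual region × year panel data in three stages:

1. **Eco-efficiency (REE).**  Each region-year is scored with the
   non-oriented slacks-based measure (SBM) DEA model with undesirable
   outputs: inputs (labor, capital, energy), a desirable output (GDP) and
   undesirable outputs (waste gas, wastewater) enter one linear program per
   decision-making unit, yielding a units-invariant efficiency ρ ∈ (0, 1].
2. **Nonlinear regression.**  Each outcome is modelled by LS-SVR with an
   RBF kernel, `ŷ(x) = Σᵢ αᵢ K(x, xᵢ) + b`,
   `K(x, x′) = exp(−‖x − x′‖² / 2σ²)`.  The dual coefficients solve the
   linear system `A = Ω + γ⁻¹I`, `b = 1ᵀA⁻¹y / 1ᵀA⁻¹1`,
   `α = A⁻¹(y − b·1)` — a closed form, no iterative training.  The
   hyperparameters (σ, γ) are tuned by a seeded random direct search that
   accepts a proposed step only if the in-sample objective
   `G(σ, γ) = (1/m) Σⱼ (yⱼ − ŷ(xⱼ))²` does not increase.  Five variable
   settings are compared per outcome (each single climate variable, and
   all four together, always alongside REE and six regional controls)
   using MPE, MSE and SDE = √MSE.
3. **Elasticities.**  For the selected four-indicator model, each
   predictor column is multiplied by 1.01 one at a time and the mean
   relative change of the predictions is reported:
   `E_j = (1/m) Σᵢ (ŷ(xᵢ; x_{ij}·1.01) − ŷ(xᵢ)) / ŷ(xᵢ)` — ×100 reads as
   "percent outcome change per 1% predictor increase" — for the national
   aggregate and each region.

Because the provincial yearbook data behind such studies are rarely
deposited, the package ships a synthetic panel generator with a *known*
response surface, so the true elasticity of every predictor is available
analytically and the whole pipeline can be validated by parameter
recovery.

## Worked example

```python
from ecosens import (GeneratorConfig, PanelDataset, generate_panel,
                     generate_dea_table, sbm_score, attach_ree,
                     SearchConfig, compare_models, elasticity_table)

gen = GeneratorConfig(n_regions=6, years=(2002, 2011), seed=42)
panel, truth = generate_panel(gen)
dea = generate_dea_table(gen)

scores = sbm_score(dea, returns_to_scale="crs")
panel = attach_ree(PanelDataset(panel.frame.drop(columns=["REE"])), scores)

cfg = SearchConfig(seed=42, max_iter=200)
print(compare_models(panel, "VTH", search_cfg=cfg).summary())
```

```
Model comparison for outcome VTH
========================================================
   temperature  MPE  -0.004782  MSE   0.000210  SDE   0.014394
      humidity  MPE  -0.005771  MSE   0.000311  SDE   0.017330
 precipitation  MPE  -0.006261  MSE   0.000369  SDE   0.018748
      sunshine  MPE  -0.005423  MSE   0.000296  SDE   0.016805
          four  MPE  -0.004898  MSE   0.000213  SDE   0.014464 <- basic model
========================================================
```

Each row is one variable setting, with MPE/MSE/SDE averaged over the six
regions (metrics are on the normalized outcome scale, so an SDE of 0.014
means a typical in-sample prediction error of about 1.4% of the series
maximum).  The four-indicator setting is the basic model handed to the
elasticity stage:

```python
el = elasticity_table(panel, "VTH", search_cfg=cfg)
print(el.table.loc[["national"]].round(6).to_string())
```

```
          temperature  humidity  precipitation  sunshine       REE     GDPPC        UL        PD        MP       LAD      NHCI
national     0.000142   0.00026      -0.000079  -0.00156 -0.000085  0.001412  0.004933  0.000069  0.000502  0.001393  0.001267
```

Reading the UL cell: a 1% rise in urbanization level raises predicted
national hospital visits by about 0.49%.

The same pipeline is scriptable from the shell:

```sh
ecosens simulate --seed 1 --out data/
ecosens run-all --panel data/panel.csv --dea data/dea.csv --seed 1 --out results/
```

which writes `scores.csv`, three `comparison_<outcome>.csv` tables, three
`elasticity_<outcome>.csv` tables and a `run_log.json` (re-running with
the same seed reproduces every CSV byte for byte).

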