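"""End-to-end orchestration: efficiency -> REE join -> comparison ->
elasticities, from raw CSV tables to output tables plus a run log.

Stages:

1. score the DEA table with SBM and attach the REE column to the panel;
2. for each outcome, run the five-setting model comparison;
3. for each outcome, build the elasticity table of the four-indicator
   basic model (national + per region).

All randomness derives from one seed; two runs with the same inputs and
seed produce byte-identical CSVs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dea import DEATable, sbm_score
from .evaluation import SETTINGS, compare_models, setting_predictors
from .panel import CONTROLS, OUTCOMES, PanelDataset, read_panel, write_table
from .search import SearchConfig
from .sensitivity import elasticity_table

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Run-wide settings: variable roles, normalization, search, scope."""

    outcomes: list[str] = field(default_factory=lambda: list(OUTCOMES))
    controls: list[str] = field(default_factory=lambda: list(CONTROLS))
    normalization: str = "minmax"
    returns_to_scale: str = "crs"
    frontier: str = "pooled"
    delta: float = 0.01
    regions: list[str] | None = None
    sigma0: float = 1.0
    gamma0: float = 1.0
    epsilon: float = 1e-6
    max_iter: int = 500
    step_mode: str = "signed"
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.outcomes) & set(self.controls)
        if overlap:
            raise ValueError(f"variable roles overlap: {sorted(overlap)}")

    def search_config(self) -> SearchConfig:
        return SearchConfig(sigma0=self.sigma0, gamma0=self.gamma0,
                            epsilon=self.epsilon, max_iter=self.max_iter,
                            seed=self.seed, step_mode=self.step_mode)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_all(panel_path, dea_path, config: RunConfig, out_dir) -> Path:
    """Execute the full pipeline and write outputs under ``out_dir``.

    Emits ``scores.csv``, ``comparison_<outcome>.csv`` (5-setting
    averages), ``comparison_<outcome>_detail.csv``, ``elasticity_
    <outcome>.csv`` and ``run_log.json``.  Validates all required columns
    before any model is fitted (fail-fast).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": []}

    panel = read_panel(panel_path)
    import pandas as pd
    dea = DEATable.from_dataframe(pd.read_csv(dea_path))

    # fail fast: every column any stage will touch must exist up front
    needed = sorted(set(config.outcomes)
                    | {c for s in SETTINGS for c in setting_predictors(s)
                       if c != "REE"})
    panel.require_columns([c for c in needed if c != "REE"])

    results = sbm_score(dea, returns_to_scale=config.returns_to_scale,
                        frontier=config.frontier)
    bad = [r.dmu_id for r in results if r.status != "optimal"]
    if bad:
        raise RuntimeError(f"SBM LP failed for DMUs: {bad[:5]}")
    from .dea import attach_ree
    panel = attach_ree(panel, results)
    scores = pd.DataFrame({"dmu_id": [r.dmu_id for r in results],
                           "score": [r.score for r in results]})
    write_table(scores, out / "scores.csv")
    log["stages"].append({"stage": "efficiency", "n_dmus": len(results)})

    search_cfg = config.search_config()
    regions = config.regions if config.regions is not None else panel.regions

    for outcome in config.outcomes:
        comp = compare_models(panel, outcome, regions=regions,
                              search_cfg=search_cfg)
        write_table(comp.averages, out / f"comparison_{outcome}.csv")
        write_table(comp.detail, out / f"comparison_{outcome}_detail.csv")
        log["stages"].append({"stage": f"comparison:{outcome}",
                              "selected": comp.selected})

        el = elasticity_table(panel, outcome, regions=regions,
                              search_cfg=search_cfg, delta=config.delta)
        write_table(el.to_dataframe(), out / f"elasticity_{outcome}.csv")
        log["stages"].append({
            "stage": f"elasticity:{outcome}",
            "params": {r: list(p) for r, p in el.params.items()},
            "failures": el.failures,
        })

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return out
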