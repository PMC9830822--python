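"""End-to-end orchestration: simulate -> derive -> fit -> validate -> report.

A :class:`PipelineConfig` (loadable from YAML) fully determines every output:
the single global seed fans out to per-stage seeds, and rerunning the same
config reproduces the output files byte for byte.  Each run directory carries
the config hash and a plain-text log with per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .data import Dataset, write_dataset
from .models import (
    CalibrationModel,
    ModelSpec,
    enumerate_model_grid,
    fit_calibration,
    importance_rank,
    TRAITS,
)
from .traits import derive_traits, engineer_covariates, qc_filter
from .validate import run_external, run_within_herd

__all__ = ["PipelineConfig", "prepare_trial", "run_pipeline", "report"]


@dataclasses.dataclass
class PipelineConfig:
    """Knobs for one pipeline run; defaults reproduce the bundled demo."""

    seed: int = 0
    out_dir: str = "milknue_run"
    traits: tuple[str, ...] = tuple(TRAITS)
    predictor_sets: tuple[str, ...] | None = None  # None = full grid
    treatments: tuple[str, ...] | None = None
    algorithms: tuple[str, ...] | None = None
    n_repeats: int = 5
    test_fraction: float = 0.25
    max_lv: int = 15
    ridge_penalty: float = 1.0
    n_compress: int = 7
    n_pcs_gh: int = 5
    t1_cows: int = 60
    t1_days: int = 10
    t2_cows: int = 52
    t2_days: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("traits", "predictor_sets", "treatments", "algorithms"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def grid(self) -> list[ModelSpec]:
        specs = enumerate_model_grid(self.traits)
        if self.predictor_sets:
            specs = [s for s in specs if s.predictor_set in self.predictor_sets]
        if self.treatments:
            specs = [s for s in specs if s.treatment in self.treatments or s.treatment == "none"]
        if self.algorithms:
            specs = [s for s in specs if s.algorithm in self.algorithms]
        return specs


def prepare_trial(ds: Dataset) -> tuple[Dataset, "object"]:
    """Derive traits + covariates and apply QC; returns (dataset, QC report)."""
    ds = engineer_covariates(derive_traits(ds))
    return qc_filter(ds)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage and write datasets, reports and logs to out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config_hash: {cfg.config_hash()}"]

    t1 = sim.generate_trial(sim.t1_like_config(cfg.seed, cfg.t1_cows, cfg.t1_days))
    t2 = sim.generate_trial(sim.t2_like_config(cfg.seed + 1, cfg.t2_cows, cfg.t2_days))
    log_lines += [f"simulated: T1 {len(t1)} records, T2 {len(t2)} records"]

    t1_qc, rep1 = prepare_trial(t1)
    t2_qc, rep2 = prepare_trial(t2)
    log_lines += [f"T1 {rep1}", f"T2 {rep2}"]
    write_dataset(t1_qc, out / "t1_like")
    write_dataset(t2_qc, out / "t2_like")

    specs = cfg.grid()
    within = run_within_herd(
        t1_qc,
        specs,
        n_repeats=cfg.n_repeats,
        test_fraction=cfg.test_fraction,
        seed=cfg.seed + 2,
        max_lv=cfg.max_lv,
        ridge_penalty=cfg.ridge_penalty,
        n_compress=cfg.n_compress,
    )
    within.to_csv(out / "within_herd.csv", index=False)
    log_lines.append(f"within-herd: {len(within)} grid cells x {cfg.n_repeats} repeats")

    models = [
        fit_calibration(
            t1_qc,
            s,
            max_lv=cfg.max_lv,
            ridge_penalty=cfg.ridge_penalty,
            n_compress=cfg.n_compress,
            seed=cfg.seed + 2,
        )
        for s in specs
    ]
    overall, per_group = run_external(models, t2_qc, n_pcs=cfg.n_pcs_gh)
    overall.to_csv(out / "external.csv", index=False)
    per_group.to_csv(out / "external_per_group.csv", index=False)
    log_lines.append(f"external: {len(overall)} cells, {len(per_group)} group rows")

    report(within, models, out)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def format_mean_sd(df: pd.DataFrame, metric: str, decimals: int = 2) -> pd.Series:
    """Render '<mean>(<sd>)' strings, the conventional report format."""
    return df.apply(
        lambda r: f"{r[f'{metric}_mean']:.{decimals}f}({r[f'{metric}_sd']:.{decimals}f})", axis=1
    )


def report(
    within: pd.DataFrame, models: list[CalibrationModel], out_dir: str | Path
) -> pd.DataFrame:
    """Best model per trait by mean R^2, plus importance export for PLS.

    Ties on R^2 keep the first cell in canonical grid order.  Writes
    ``best_models.csv`` and, for each trait whose best PLS model exists,
    ``importance_<trait>.csv`` with one (predictor, score) row per predictor.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scored = within[~within.get("skipped", pd.Series(index=within.index, dtype=object)).notna()]
    if "r2_mean" not in scored.columns or scored.empty:
        return pd.DataFrame()
    best_rows = []
    for trait, sub in scored.groupby("trait", sort=False):
        best = sub.loc[sub["r2_mean"].idxmax()]
        row = best.to_dict()
        row["r2"] = f"{best['r2_mean']:.2f}({best['r2_sd']:.2f})"
        best_rows.append(row)
    best_df = pd.DataFrame(best_rows)
    best_df.to_csv(out / "best_models.csv", index=False)

    by_spec = {(m.spec.trait, m.spec.predictor_set, m.spec.treatment, m.spec.algorithm): m for m in models}
    for row in best_rows:
        trait_col = {v: k for k, v in TRAITS.items()}[row["trait"]]
        key = (trait_col, row["model"], row["spectra"], row["algorithm"])
        model = by_spec.get(key)
        if model is not None and row["algorithm"] == "pls":
            importance_rank(model).to_csv(out / f"importance_{row['trait']}.csv", index=False)
    return best_df
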