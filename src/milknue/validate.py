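"""Within-herd and external validation with the three-term MSPE split.

Within-herd validation partitions **cows** (never records) of the calibration
trial into test and training sides at a 1:3 ratio, five independent times;
all preprocessing and model state is refit on each training side and applied
to the masked test side.  External validation applies the calibration-trial
model, with its fitted preprocessing state unchanged, to a second trial, and
additionally reports per-diet-group accuracy together with the mean GH
distance of each group from the calibration spectra.

The mean squared prediction error is split into Theil-type components:

    MSPE       = mean((X_i - Y_i)^2)           X = predictions, Y = truths
    error_bias  = (mean X - mean Y)^2
    error_slope = (1 - beta)^2 * mean((X - Xbar)^2)
    error_random = (1 - R^2) * mean((Y - Ybar)^2)

with beta the least-squares slope of Y on X and R^2 their squared
correlation.  Under population (divisor-n) moments the three terms are
non-negative and sum exactly to the MSPE.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset
from .models import CalibrationModel, ModelSpec, fit_calibration, TRAITS
from .preprocess import gh_distance, mask_regions

__all__ = [
    "SplitPlan",
    "split_within_herd",
    "metrics",
    "MSPEDecomposition",
    "mspe_decompose",
    "run_within_herd",
    "run_external",
]


@dataclasses.dataclass
class SplitPlan:
    """Cow-level test/train partitions for each repeat."""

    repeats: list[tuple[np.ndarray, np.ndarray]]  # (test_cows, train_cows)
    test_fraction: float
    seed: int


def split_within_herd(
    cow_ids: np.ndarray,
    test_fraction: float = 0.25,
    n_repeats: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Random cow-level partitions: each cow is wholly test or wholly train."""
    cows = np.unique(np.asarray(cow_ids))
    if len(cows) < 8:
        raise ValueError(f"need at least 8 cows for a 1:3 split, got {len(cows)}")
    n_test = max(1, int(round(test_fraction * len(cows))))
    rng = np.random.default_rng(seed)
    repeats = []
    for _ in range(n_repeats):
        perm = rng.permutation(cows)
        repeats.append((np.sort(perm[:n_test]), np.sort(perm[n_test:])))
    return SplitPlan(repeats=repeats, test_fraction=test_fraction, seed=seed)


def metrics(predictions: np.ndarray, truths: np.ndarray) -> dict[str, float]:
    """R^2 (squared Pearson r), RMSPE, RE = RMSPE/mean truth, Spearman r."""
    X = np.asarray(predictions, dtype=float)
    Y = np.asarray(truths, dtype=float)
    if X.shape != Y.shape or X.ndim != 1 or len(X) < 3:
        raise ValueError("predictions and truths must be equal-length 1-D, n >= 3")
    if np.std(Y) == 0:
        raise ValueError("constant truths: metrics undefined")
    rmspe = float(np.sqrt(np.mean((X - Y) ** 2)))
    r2 = float(np.corrcoef(X, Y)[0, 1] ** 2) if np.std(X) > 0 else 0.0
    spear = float(stats.spearmanr(X, Y).statistic) if np.std(X) > 0 else 0.0
    return {"r2": r2, "rmspe": rmspe, "re": rmspe / float(np.mean(Y)), "spear_r": spear}


@dataclasses.dataclass
class MSPEDecomposition:
    """Bias / slope / random split of the mean squared prediction error."""

    mspe: float
    error_bias: float
    error_slope: float
    error_random: float
    bias_pct: float
    slope_pct: float
    random_pct: float
    slope_beta: float
    r2: float
    n: int
    degenerate: bool = False  # zero MSPE: percentages set to (0, 0, 100)


def mspe_decompose(predictions: np.ndarray, truths: np.ndarray) -> MSPEDecomposition:
    """Split MSPE into bias, slope and random components (see module docs)."""
    X = np.asarray(predictions, dtype=float)
    Y = np.asarray(truths, dtype=float)
    if X.shape != Y.shape or X.ndim != 1 or len(X) < 3:
        raise ValueError("predictions and truths must be equal-length 1-D, n >= 3")
    n = len(X)
    sxx = float(np.mean((X - X.mean()) ** 2))
    syy = float(np.mean((Y - Y.mean()) ** 2))
    if sxx == 0:
        raise ValueError("constant predictions: slope undefined")
    sxy = float(np.mean((X - X.mean()) * (Y - Y.mean())))
    beta = sxy / sxx
    r2 = sxy**2 / (sxx * syy) if syy > 0 else 1.0
    mspe = float(np.mean((X - Y) ** 2))
    e_bias = float((X.mean() - Y.mean()) ** 2)
    e_slope = sxx * (1.0 - beta) ** 2
    # (1 - R^2) * syy, written as the regression residual variance: identical
    # in exact arithmetic but non-negative and stable when R^2 ~ 1
    resid = (Y - Y.mean()) - beta * (X - X.mean())
    e_random = float(np.mean(resid**2))
    if mspe == 0:
        return MSPEDecomposition(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 100.0, beta, r2, n, degenerate=True)
    return MSPEDecomposition(
        mspe=mspe,
        error_bias=e_bias,
        error_slope=e_slope,
        error_random=e_random,
        bias_pct=100.0 * e_bias / mspe,
        slope_pct=100.0 * e_slope / mspe,
        random_pct=100.0 * e_random / mspe,
        slope_beta=beta,
        r2=r2,
        n=n,
    )


_METRIC_KEYS = ("r2", "rmspe", "re", "spear_r", "mspe", "bias_pct", "slope_pct", "random_pct")


def _evaluate(model: CalibrationModel, ds: Dataset) -> dict[str, float]:
    pred = model.predict(ds)
    truth = ds.table[model.spec.trait].to_numpy(dtype=float)
    m = metrics(pred, truth)
    d = mspe_decompose(pred, truth)
    return {**m, "mspe": d.mspe, "bias_pct": d.bias_pct, "slope_pct": d.slope_pct,
            "random_pct": d.random_pct}


def _spec_row(spec: ModelSpec) -> dict[str, str]:
    return {
        "trait": TRAITS[spec.trait],
        "model": spec.predictor_set,
        "spectra": spec.treatment,
        "algorithm": spec.algorithm,
    }


def run_within_herd(
    ds: Dataset,
    grid_specs: list[ModelSpec],
    n_repeats: int = 5,
    test_fraction: float = 0.25,
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Repeated cow-wise hold-out validation on the calibration trial.

    Returns one row per grid cell with across-repeat means and SDs of each
    metric (columns ``<metric>_mean`` / ``<metric>_sd``).  Cells whose
    training side cannot support the fit are skipped with a logged reason.
    """
    plan = split_within_herd(
        ds.table["cow_id"].to_numpy(), test_fraction, n_repeats, seed
    )
    rows = []
    for spec in grid_specs:
        per_repeat: list[dict[str, float]] = []
        reason = None
        for test_cows, train_cows in plan.repeats:
            in_test = ds.table["cow_id"].isin(test_cows).to_numpy()
            train, test = ds.subset(~in_test), ds.subset(in_test)
            try:
                model = fit_calibration(train, spec, seed=seed, **fit_kwargs)
                per_repeat.append(_evaluate(model, test))
            except (ValueError, np.linalg.LinAlgError) as exc:
                reason = str(exc)
                break
        row = _spec_row(spec)
        if reason is not None:
            row["skipped"] = reason
        else:
            for k in _METRIC_KEYS:
                vals = np.array([r[k] for r in per_repeat])
                row[f"{k}_mean"] = vals.mean()
                row[f"{k}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def run_external(
    models: list[CalibrationModel],
    external: Dataset,
    n_pcs: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply calibration-trial models, state unchanged, to an external trial.

    Returns (overall, per_group): overall metrics per grid cell, and a
    per-diet-group breakdown with group R^2 and the group's mean GH distance
    from the calibration spectra (computed on region-masked spectra).
    """
    if not models:
        raise ValueError("no fitted models supplied")
    overall_rows, group_rows = [], []
    for model in models:
        row = _spec_row(model.spec)
        row.update(_evaluate(model, external))
        overall_rows.append(row)
        pred = model.predict(external)
        truth = external.table[model.spec.trait].to_numpy(dtype=float)
        for diet_id, idx in external.table.groupby("diet_id", sort=True).groups.items():
            pos = external.table.index.get_indexer(idx)
            grow = _spec_row(model.spec)
            grow["diet_id"] = diet_id
            grow["n"] = len(pos)
            if len(pos) >= 3 and np.std(truth[pos]) > 0:
                grow.update({f"group_{k}": v for k, v in metrics(pred[pos], truth[pos]).items()})
            group_rows.append(grow)
    # mean GH per diet group against the calibration spectra (masked scale)
    ref = models[0]
    cal_masked = ref.training_spectra_masked
    ext_masked, _ = mask_regions(external.spectra, external.grid, ref.mask)
    gh = gh_distance(ext_masked, cal_masked, n_pcs=n_pcs)
    gh_by_group = (
        pd.DataFrame({"diet_id": external.table["diet_id"], "gh": gh})
        .groupby("diet_id", sort=True)["gh"]
        .mean()
    )
    per_group = pd.DataFrame(group_rows)
    per_group["mean_gh"] = per_group["diet_id"].map(gh_by_group)
    return pd.DataFrame(overall_rows), per_group
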