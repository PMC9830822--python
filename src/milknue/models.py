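"""Calibration model grid: predictor sets x spectra treatments x algorithms.

Six predictor sets are crossed with three spectra pre-treatments (original,
MSC, SNV) and three regression algorithms (PLS, ridge, epsilon-SVR on
PLS-compressed scores).  Sets M1-M5 nest: M1 is the masked MIR spectrum
alone, and M2-M5 add milk yield + parity group, BCS, DIM group, and days in
pregnancy.  M6 drops the spectrum and uses the nine non-MIR covariates, which
isolates the added value of MIR.  45 spectral cells + 3 non-MIR cells = 48
models per trait.

PLS is the univariate NIPALS algorithm with deflation; the number of latent
variables is picked by cow-wise cross-validated RMSPE (first non-improving
step).  Ridge is the closed-form penalized least squares.  SVR compresses the
design matrix to 7 PLS scores first, then fits an RBF epsilon-SVR by dual
coordinate ascent.  All algorithms operate on z-scored predictors and
response; predictions are transformed back to the trait scale.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .data import Dataset, SpectrumGrid
from .preprocess import (
    RegionMask,
    ScalerState,
    mask_regions,
    msc_apply,
    msc_fit,
    snv,
    zscore_apply,
    zscore_fit,
)

__all__ = [
    "PREDICTOR_SETS",
    "TRAITS",
    "ModelSpec",
    "enumerate_model_grid",
    "build_design_matrix",
    "PLSModel",
    "pls_fit",
    "first_non_improving",
    "select_n_lv",
    "ridge_fit",
    "SVRModel",
    "svr_fit",
    "svr_fit_compressed",
    "CalibrationModel",
    "importance_rank",
]

#: trait column name -> short label
TRAITS = {"nue_pct": "NUE", "nl_kg": "NL", "dmi_a_kg": "DMI_a"}

#: covariates added on top of the spectrum for each nested set
_M_COVARIATES = {
    "M1": [],
    "M2": ["my_kg", "parity_group"],
    "M3": ["my_kg", "parity_group", "bcs"],
    "M4": ["my_kg", "parity_group", "bcs", "dim_g"],
    "M5": ["my_kg", "parity_group", "bcs", "dim_g", "dip_d"],
}
_M6_COLUMNS = [
    "my_kg",
    "parity_group",
    "bcs",
    "dim_g",
    "dip_d",
    "protein_pct",
    "fat_pct",
    "lactose_pct",
    "mun_mg_dl",
]
PREDICTOR_SETS = ("M1", "M2", "M3", "M4", "M5", "M6")
_TREATMENTS = ("original", "msc", "snv")
_ALGORITHMS = ("pls", "rr", "svr")


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """One cell of the calibration grid."""

    predictor_set: str
    treatment: str
    algorithm: str
    trait: str

    def __post_init__(self) -> None:
        if self.predictor_set not in PREDICTOR_SETS:
            raise ValueError(f"unknown predictor set {self.predictor_set!r}")
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.predictor_set == "M6":
            if self.treatment != "none":
                raise ValueError("M6 excludes MIR: treatment must be 'none'")
        elif self.treatment not in _TREATMENTS:
            raise ValueError(f"unknown spectra treatment {self.treatment!r}")

    @property
    def uses_spectra(self) -> bool:
        return self.predictor_set != "M6"

    def label(self) -> str:
        return f"{TRAITS[self.trait]}/{self.predictor_set}/{self.treatment}/{self.algorithm}"


def enumerate_model_grid(traits: Sequence[str] = tuple(TRAITS)) -> list[ModelSpec]:
    """All 48 specs per trait: M1-M5 x 3 treatments x 3 algorithms + M6 x 3."""
    grid = []
    for trait in traits:
        for pset in PREDICTOR_SETS[:5]:
            for treat in _TREATMENTS:
                for algo in _ALGORITHMS:
                    grid.append(ModelSpec(pset, treat, algo, trait))
        for algo in _ALGORITHMS:
            grid.append(ModelSpec("M6", "none", algo, trait))
    return grid


def build_design_matrix(
    ds: Dataset, spec: ModelSpec, spectra: np.ndarray | None = None, grid: SpectrumGrid | None = None
) -> pd.DataFrame:
    """Assemble the named predictor matrix for one grid cell.

    ``spectra``/``grid`` are the pre-treated, region-masked spectra aligned to
    ``ds`` (ignored for M6).  parity_group is encoded 0 = primiparous,
    1 = multiparous; dim_g is the integer 5-day DIM bin.
    """
    t = ds.table
    covs = _M6_COLUMNS if spec.predictor_set == "M6" else _M_COVARIATES[spec.predictor_set]
    for c in covs:
        if c not in t.columns:
            raise KeyError(f"model {spec.predictor_set} requires column {c!r}")
        if t[c].isna().any():
            raise ValueError(f"model {spec.predictor_set}: column {c!r} has missing values")

    parts: list[pd.DataFrame] = []
    if spec.uses_spectra:
        if spectra is None or grid is None:
            raise ValueError("spectral models need treated spectra and their grid")
        parts.append(pd.DataFrame(np.asarray(spectra, dtype=float), columns=grid.header()))
    cov = pd.DataFrame(index=range(len(t)))
    for c in covs:
        if c == "parity_group":
            cov[c] = (t[c].to_numpy() == "multiparous").astype(float)
        else:
            cov[c] = t[c].to_numpy(dtype=float)
    parts.append(cov)
    X = pd.concat(parts, axis=1)
    return X


# ---------------------------------------------------------------------------
# PLS (univariate NIPALS with deflation)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PLSModel:
    """Fitted PLS state on standardized data.

    ``coef_path[k]`` is the coefficient vector using the first k+1 latent
    variables; ``coef`` is the full-``n_lv`` vector used for prediction.
    """

    weights: np.ndarray  # (n_lv, p) X-weights w
    loadings: np.ndarray  # (n_lv, p) X-loadings p
    y_loadings: np.ndarray  # (n_lv,)
    coef: np.ndarray  # (p,)
    coef_path: list[np.ndarray]
    n_lv: int

    def predict(self, X_std: np.ndarray) -> np.ndarray:
        return np.asarray(X_std, dtype=float) @ self.coef


def pls_fit(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """NIPALS PLS1 on standardized X (n x p) and y (n,).

    Each component takes the weight vector proportional to X'y (the direction
    of maximal covariance with the current response residual), computes
    scores, X- and y-loadings, and deflates X and y.  Deterministic; stops
    early if the residual covariance vanishes (rank exhausted).
    """
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y must be 1-D and match X rows")
    if np.std(y) == 0:
        raise ValueError("zero-variance response")
    if n_lv < 1 or n_lv > min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")

    W, P, Q = [], [], []
    coef_path: list[np.ndarray] = []
    for _ in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p_load = X.T @ t / tt
        q = float(y @ t) / tt
        X -= np.outer(t, p_load)
        y = y - q * t
        W.append(w)
        P.append(p_load)
        Q.append(q)
        Wm = np.column_stack(W)
        Pm = np.column_stack(P)
        b = Wm @ np.linalg.solve(Pm.T @ Wm, np.asarray(Q))
        coef_path.append(b)
    if not W:
        raise ValueError("X carries no covariance with y: cannot extract a component")
    return PLSModel(
        weights=np.array(W),
        loadings=np.array(P),
        y_loadings=np.array(Q),
        coef=coef_path[-1],
        coef_path=coef_path,
        n_lv=len(W),
    )


def _kfold_groups(groups: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Group-wise (cow-wise) K-fold: returns test-row index arrays."""
    uniq = np.unique(groups)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    folds = []
    for f in range(n_folds):
        test_groups = set(uniq[order[f::n_folds]])
        folds.append(np.flatnonzero([g in test_groups for g in groups]))
    return [f for f in folds if len(f)]


def first_non_improving(rmspe: Sequence[float]) -> int:
    """Smallest k (1-based) at which RMSPE(k+1) >= RMSPE(k); else len(rmspe)."""
    for k in range(len(rmspe) - 1):
        if rmspe[k + 1] >= rmspe[k]:
            return k + 1
    return len(rmspe)


def select_n_lv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = 15,
    groups: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> int:
    """Pick the number of latent variables by cross-validated RMSPE.

    Computes RMSPE for 1..max_lv components under cow-wise K-fold CV
    (within-fold standardization) and returns the smallest k at which adding
    a component stops reducing the RMSPE; if RMSPE decreases throughout,
    returns max_lv.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if groups is None:
        groups = np.arange(n)
    max_lv = min(max_lv, X.shape[1], n - 1)
    sq_err = np.zeros((max_lv, n))
    hit = np.zeros(n, dtype=bool)
    for test_idx in _kfold_groups(np.asarray(groups), n_folds, seed):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        keep = np.std(X[train_idx], axis=0) > 0
        xs = zscore_fit(X[train_idx][:, keep])
        ys_mean, ys_sd = y[train_idx].mean(), y[train_idx].std(ddof=1)
        Xtr = zscore_apply(X[train_idx][:, keep], xs)
        Xte = zscore_apply(X[test_idx][:, keep], xs)
        ytr = (y[train_idx] - ys_mean) / ys_sd
        k_max = min(max_lv, len(train_idx) - 1, int(keep.sum()))
        model = pls_fit(Xtr, ytr, k_max)
        for k, b in enumerate(model.coef_path):
            pred = Xte @ b * ys_sd + ys_mean
            sq_err[k, test_idx] = (pred - y[test_idx]) ** 2
        for k in range(len(model.coef_path), max_lv):
            sq_err[k, test_idx] = sq_err[len(model.coef_path) - 1, test_idx]
        hit[test_idx] = True
    rmspe = np.sqrt(sq_err[:, hit].mean(axis=1))
    return first_non_improving(rmspe)


# ---------------------------------------------------------------------------
# Ridge regression
# ---------------------------------------------------------------------------


def ridge_fit(X: np.ndarray, y: np.ndarray, penalty: float = 1.0) -> np.ndarray:
    """Closed-form ridge coefficients on standardized data (no intercept).

    Minimizes ||y - Xb||^2 + penalty * ||b||^2.  penalty = 0 reduces to OLS
    (requires full column rank).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    p = X.shape[1]
    return np.linalg.solve(X.T @ X + penalty * np.eye(p), X.T @ y)


# ---------------------------------------------------------------------------
# Epsilon-SVR with RBF kernel (dual coordinate ascent, regularized bias)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SVRModel:
    """Fitted epsilon-SVR state: dual coefficients over the training points.

    The bias is absorbed into the kernel (k + 1), so the decision function is
    f(x) = sum_i beta_i * (rbf(x_i, x) + 1).
    """

    X_train: np.ndarray
    beta: np.ndarray
    gamma: float
    C: float
    epsilon: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        K = _rbf_kernel(np.atleast_2d(np.asarray(X, dtype=float)), self.X_train, self.gamma)
        return (K + 1.0) @ self.beta


def _rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    sq = (A**2).sum(axis=1)[:, None] + (B**2).sum(axis=1)[None, :] - 2.0 * A @ B.T
    return np.exp(-gamma * np.maximum(sq, 0.0))


def svr_fit(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    epsilon: float = 0.1,
    gamma: float | None = None,
    max_passes: int = 2000,
    tol: float = 1e-6,
) -> SVRModel:
    """Epsilon-insensitive RBF support-vector regression.

    Solves the dual with the bias folded into the kernel (adds a constant 1,
    i.e. a regularized intercept), which removes the equality constraint and
    admits exact coordinate-wise updates: each dual coefficient is a
    soft-thresholded, box-clipped Newton step.  Deterministic given the data.
    Default kernel width gamma = 1 / (n_features x mean feature variance).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if gamma is None:
        v = X.var()
        gamma = 1.0 / (p * v) if v > 0 else 1.0 / p
    Q = _rbf_kernel(X, X, gamma) + 1.0
    beta = np.zeros(n)
    Qbeta = np.zeros(n)
    diag = np.diag(Q)
    for _ in range(max_passes):
        max_delta = 0.0
        for j in range(n):
            r = y[j] - (Qbeta[j] - Q[j, j] * beta[j])
            t = np.sign(r) * max(abs(r) - epsilon, 0.0) / diag[j]
            t = min(max(t, -C), C)
            delta = t - beta[j]
            if delta != 0.0:
                Qbeta += delta * Q[:, j]
                beta[j] = t
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    return SVRModel(X_train=X, beta=beta, gamma=gamma, C=C, epsilon=epsilon)


@dataclasses.dataclass
class CompressedSVR:
    """PLS compression to a few score columns followed by epsilon-SVR."""

    pls: PLSModel
    svr: SVRModel
    n_compress: int

    def scores(self, X_std: np.ndarray) -> np.ndarray:
        # scores T = X W (P'W)^-1  (the standard PLS score reconstruction)
        W = self.pls.weights.T
        P = self.pls.loadings.T
        R = W @ np.linalg.inv(P.T @ W)
        return np.asarray(X_std, dtype=float) @ R

    def predict(self, X_std: np.ndarray) -> np.ndarray:
        return self.svr.predict(self.scores(X_std))


def svr_fit_compressed(
    X: np.ndarray, y: np.ndarray, n_compress: int = 7, **svr_params
) -> CompressedSVR:
    """PLS-compress standardized X to ``n_compress`` scores, then fit SVR."""
    n_compress = min(n_compress, X.shape[1], X.shape[0] - 1)
    pls = pls_fit(X, y, n_compress)
    model = CompressedSVR(pls=pls, svr=None, n_compress=pls.n_lv)  # type: ignore[arg-type]
    T = model.scores(X)
    model.svr = svr_fit(T, np.asarray(y, dtype=float), **svr_params)
    return model


# ---------------------------------------------------------------------------
# End-to-end calibration model (preprocessing + scaling + algorithm)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CalibrationModel:
    """One fitted grid cell: preprocessing state + scalers + regressor.

    All state (region mask, MSC reference, z-scalers, algorithm parameters)
    is learned on the training data and applied unchanged to new data, so
    prediction is a pure function of a raw input record.
    """

    spec: ModelSpec
    mask: RegionMask
    masked_grid: SpectrumGrid | None
    msc_reference: np.ndarray | None
    x_scaler: ScalerState
    y_mean: float
    y_sd: float
    columns: list[str]
    model: PLSModel | CompressedSVR | np.ndarray  # ridge stores coefficients
    n_lv: int | None = None
    #: region-masked raw training spectra, kept for GH applicability checks
    training_spectra_masked: np.ndarray | None = None

    @property
    def coef(self) -> np.ndarray:
        """Standardized-scale coefficient vector (PLS and ridge only)."""
        if isinstance(self.model, PLSModel):
            return self.model.coef
        if isinstance(self.model, np.ndarray):
            return self.model
        raise TypeError("SVR has no linear coefficient vector")

    def _design(self, ds: Dataset) -> np.ndarray:
        spectra = grid = None
        if self.spec.uses_spectra:
            spectra, grid = mask_regions(ds.spectra, ds.grid, self.mask)
            if grid != self.masked_grid:
                raise ValueError("dataset grid does not match the calibration grid")
            if self.spec.treatment == "msc":
                spectra = msc_apply(spectra, self.msc_reference)
            elif self.spec.treatment == "snv":
                spectra = snv(spectra)
        X = build_design_matrix(ds, self.spec, spectra, grid)
        if list(X.columns) != self.columns:
            raise ValueError("design-matrix columns do not match the fitted model")
        return X.to_numpy(dtype=float)

    def predict(self, ds: Dataset) -> np.ndarray:
        """Predict the trait (original scale) for every record in ``ds``."""
        Xs = zscore_apply(self._design(ds), self.x_scaler)
        if isinstance(self.model, np.ndarray):
            yhat = Xs @ self.model
        else:
            yhat = self.model.predict(Xs)
        return yhat * self.y_sd + self.y_mean


def fit_calibration(
    ds: Dataset,
    spec: ModelSpec,
    mask: RegionMask = RegionMask(),
    max_lv: int = 15,
    ridge_penalty: float = 1.0,
    svr_params: dict | None = None,
    n_compress: int = 7,
    seed: int = 0,
) -> CalibrationModel:
    """Fit one grid cell on a QC-passed, trait-derived training dataset."""
    spectra = grid = None
    msc_reference = None
    raw_masked, _ = mask_regions(ds.spectra, ds.grid, mask)
    if spec.uses_spectra:
        spectra, grid = mask_regions(ds.spectra, ds.grid, mask)
        if spec.treatment == "msc":
            msc_reference = msc_fit(spectra)
            spectra = msc_apply(spectra, msc_reference)
        elif spec.treatment == "snv":
            spectra = snv(spectra)
    Xdf = build_design_matrix(ds, spec, spectra, grid)
    columns = list(Xdf.columns)
    X = Xdf.to_numpy(dtype=float)
    y = ds.table[spec.trait].to_numpy(dtype=float)

    x_scaler = zscore_fit(X, columns)
    y_mean, y_sd = float(y.mean()), float(y.std(ddof=1))
    if y_sd == 0:
        raise ValueError(f"trait {spec.trait} has zero variance in training data")
    Xs = zscore_apply(X, x_scaler)
    ys = (y - y_mean) / y_sd

    n_lv = None
    if spec.algorithm == "pls":
        n_lv = select_n_lv(X, y, max_lv=max_lv, groups=ds.table["cow_id"].to_numpy(), seed=seed)
        model: PLSModel | CompressedSVR | np.ndarray = pls_fit(Xs, ys, n_lv)
    elif spec.algorithm == "rr":
        model = ridge_fit(Xs, ys, penalty=ridge_penalty)
    else:
        model = svr_fit_compressed(Xs, ys, n_compress=n_compress, **(svr_params or {}))
        n_lv = model.n_compress
    return CalibrationModel(
        spec=spec,
        mask=mask,
        masked_grid=grid,
        msc_reference=msc_reference,
        x_scaler=x_scaler,
        y_mean=y_mean,
        y_sd=y_sd,
        columns=columns,
        model=model,
        n_lv=n_lv,
        training_spectra_masked=raw_masked,
    )


def importance_rank(model: CalibrationModel) -> pd.DataFrame:
    """Rank predictors of a fitted PLS model by |standardized coefficient|.

    Returns a DataFrame (predictor, score) sorted by descending score; ties
    keep design-matrix column order (stable sort).
    """
    if not isinstance(model.model, PLSModel):
        raise TypeError("variable importance is defined for PLS models only")
    score = np.abs(model.model.coef)
    df = pd.DataFrame({"predictor": model.columns, "score": score})
    return df.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
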