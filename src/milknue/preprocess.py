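"""Spectral pre-treatments and applicability-domain diagnostics.

Covers the standard chemometric toolkit used before calibration on milk MIR
absorbance spectra: masking of water/noise wavenumber regions, multiplicative
scatter correction (MSC), standard normal variate (SNV), column z-scaling, and
PCA-space Mahalanobis distances (outlier screening and the GH "global
distance" used to judge whether new samples sit inside the calibration
domain).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .data import SpectrumGrid

__all__ = [
    "DEFAULT_REGIONS",
    "RegionMask",
    "mask_regions",
    "snv",
    "msc_fit",
    "msc_apply",
    "ScalerState",
    "zscore_fit",
    "zscore_apply",
    "DistanceReport",
    "pca_mahalanobis_outliers",
    "gh_distance",
]

#: retained wavenumber intervals (cm^-1, closed); everything else is water or
#: detector-noise dominated and excluded from calibration
DEFAULT_REGIONS: tuple[tuple[float, float], ...] = (
    (968.1, 1577.5),
    (1731.8, 1762.6),
    (1781.9, 1808.9),
    (2831.0, 2966.0),
)


@dataclasses.dataclass(frozen=True)
class RegionMask:
    """Closed, sorted, non-overlapping [low, high] wavenumber intervals."""

    intervals: tuple[tuple[float, float], ...] = DEFAULT_REGIONS

    def __post_init__(self) -> None:
        prev_high = -np.inf
        for lo, hi in self.intervals:
            if lo > hi:
                raise ValueError(f"interval [{lo}, {hi}] has low > high")
            if lo <= prev_high:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_high = hi

    def contains(self, wavenumbers: np.ndarray) -> np.ndarray:
        wn = np.asarray(wavenumbers, dtype=float)
        keep = np.zeros(wn.shape, dtype=bool)
        for lo, hi in self.intervals:
            keep |= (wn >= lo) & (wn <= hi)
        return keep


def mask_regions(
    spectra: np.ndarray, grid: SpectrumGrid, mask: RegionMask = RegionMask()
) -> tuple[np.ndarray, SpectrumGrid]:
    """Keep only channels whose wavenumber falls in a retained interval.

    Channel order is preserved; the operation is idempotent.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    if X.shape[1] != len(grid):
        raise ValueError(f"spectra have {X.shape[1]} channels, grid has {len(grid)}")
    keep = mask.contains(grid.wavenumbers)
    if not keep.any():
        raise ValueError("region mask removes every channel")
    return X[:, keep], SpectrumGrid(grid.wavenumbers[keep])


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: center and scale each spectrum to unit SD.

    Uses the sample SD (divisor n-1).  Affine-invariant: snv(a + b*x) ==
    snv(x) for b > 0, and snv is idempotent.
    """
    X = np.asarray(spectra, dtype=float)
    one_d = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] < 2:
        raise ValueError("SNV needs at least 2 channels")
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant spectrum: SNV undefined")
    out = (X - X.mean(axis=1, keepdims=True)) / sd
    return out[0] if one_d else out


def msc_fit(training_spectra: np.ndarray) -> np.ndarray:
    """MSC reference spectrum: the channel-wise mean of the training set."""
    X = np.atleast_2d(np.asarray(training_spectra, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("MSC needs at least one training spectrum")
    return X.mean(axis=0)


def msc_apply(spectra: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed channel-wise on the reference, x = a + b*r,
    and the fitted offset and slope are removed: (x - a) / b.  Exactly inverts
    the scatter model for any a and b > 0.
    """
    r = np.asarray(reference, dtype=float)
    X = np.asarray(spectra, dtype=float)
    one_d = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != r.size:
        raise ValueError("spectrum and reference grids differ")
    r_c = r - r.mean()
    denom = float(r_c @ r_c)
    if denom == 0:
        raise ValueError("constant reference: MSC regression ill-posed")
    b = (X - X.mean(axis=1, keepdims=True)) @ r_c / denom
    if np.any(np.abs(b) < 1e-12):
        raise ValueError("fitted scatter slope numerically zero")
    a = X.mean(axis=1) - b * r.mean()
    out = (X - a[:, None]) / b[:, None]
    return out[0] if one_d else out


@dataclasses.dataclass(frozen=True)
class ScalerState:
    """Per-column mean/SD (divisor n-1) learned on training data only."""

    mean: np.ndarray
    sd: np.ndarray
    columns: tuple[str, ...] | None = None


def zscore_fit(X: np.ndarray, columns: list[str] | None = None) -> ScalerState:
    """Learn column means and sample SDs; zero-variance columns are rejected."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("z-scaling needs at least 2 training rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        name = columns[j] if columns else f"column {j}"
        raise ValueError(f"zero-variance predictor: {name}")
    return ScalerState(mean, sd, tuple(columns) if columns else None)


def zscore_apply(X: np.ndarray, state: ScalerState) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return (X - state.mean) / state.sd


@dataclasses.dataclass
class DistanceReport:
    """PCA-space squared Mahalanobis distances with an outlier threshold."""

    distance: np.ndarray
    gh: np.ndarray
    threshold: float
    flags: np.ndarray
    n_pcs: int


class _PCABasis:
    """Centroid + leading principal directions and PC variances (divisor n)."""

    def __init__(self, X: np.ndarray, n_pcs: int):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n <= n_pcs:
            raise ValueError(f"need more than {n_pcs} rows, got {n}")
        self.center = X.mean(axis=0)
        Xc = X - self.center
        # SVD of the centered matrix; PC variance uses divisor n so the
        # calibration-set mean GH identity is exact
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        if len(s) < n_pcs or s[n_pcs - 1] ** 2 / n < 1e-12 * max(s[0] ** 2 / n, 1.0):
            raise np.linalg.LinAlgError(
                f"PC covariance singular: rank < {n_pcs} requested components"
            )
        self.components = vt[:n_pcs]
        self.pc_var = (s[:n_pcs] ** 2) / n
        self.n_pcs = n_pcs

    def sq_mahalanobis(self, X: np.ndarray) -> np.ndarray:
        scores = (np.atleast_2d(np.asarray(X, dtype=float)) - self.center) @ self.components.T
        return np.sum(scores**2 / self.pc_var, axis=1)


def pca_mahalanobis_outliers(
    X: np.ndarray,
    n_pcs: int = 3,
    percentile: float = 0.999,
    df: int | None = None,
) -> DistanceReport:
    """Screen spectra by squared Mahalanobis distance in PC space.

    Projects onto the first ``n_pcs`` principal components and flags samples
    whose squared distance from the centroid (PC variances as metric) exceeds
    the chi-squared quantile at ``percentile`` with ``df`` degrees of freedom
    (default: df = n_pcs, matching the distance's dimensionality).
    """
    basis = _PCABasis(X, n_pcs)
    d = basis.sq_mahalanobis(X)
    threshold = float(stats.chi2.ppf(percentile, df if df is not None else n_pcs))
    return DistanceReport(
        distance=d, gh=d / n_pcs, threshold=threshold, flags=d > threshold, n_pcs=n_pcs
    )


def gh_distance(query: np.ndarray, calibration: np.ndarray, n_pcs: int = 3) -> np.ndarray:
    """GH (global distance) of query spectra from a calibration set.

    PC basis, centroid and PC variances (covariance divisor n) come from the
    calibration set only; GH = squared Mahalanobis distance / n_pcs.  Under
    this convention the calibration set's own mean GH is exactly 1, so GH is
    read as "how many calibration-typical distances away" a new sample sits.
    """
    basis = _PCABasis(calibration, n_pcs)
    return basis.sq_mahalanobis(query) / n_pcs
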