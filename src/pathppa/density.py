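"""Savitzky-Golay density estimation from weighted, labelled samples.

Instead of histogramming the reactive/unreactive CV samples directly, the
*integrated* (cumulative) distributions R and U are built from the weighted
empirical CDF, interpolated onto a dense regular grid, extended with
horizontal plateaus to suppress boundary artefacts, and smoothed with a
Savitzky-Golay (local least-squares polynomial) filter.  The filter's first
derivative then yields the densities r, u (and t = r + u) without any binning
— the step that makes the downstream overlap integral robust to sparse data.

Defaults: 2000 grid points, window covering ~1/16 of the CV range (rounded to
the nearest odd integer, e.g. 125 for 2000 points), second-order polynomial,
plateaus of one quarter of the range (500 points) on each side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator

from .crossings import SampleSet

__all__ = [
    "SGSettings",
    "IntegratedDistributions",
    "DensityEstimate",
    "DegenerateSupportError",
    "weighted_cdfs",
    "regrid",
    "pad_plateaus",
    "sg_window",
    "sg_derivative",
    "estimate_densities",
    "binned_densities",
    "SavitzkyGolayDensity",
]


class DegenerateSupportError(ValueError):
    """All CV values identical: no support to estimate a density on."""


@dataclass(frozen=True)
class SGSettings:
    """Savitzky-Golay estimator settings.

    Polynomial orders above 2 can produce negative density amplitudes and are
    refused unless ``allow_higher_order`` is set explicitly.
    """

    n_gp: int = 2000
    window_fraction: float = 1.0 / 16.0
    polyorder: int = 2
    pad_fraction: float = 0.25
    allow_higher_order: bool = False

    def __post_init__(self) -> None:
        if self.n_gp < 16:
            raise ValueError(f"n_gp must be >= 16, got {self.n_gp}")
        if not 0 < self.window_fraction < 1:
            raise ValueError("window_fraction must be in (0, 1)")
        if self.polyorder < 0:
            raise ValueError("polyorder must be >= 0")
        if self.polyorder > 2 and not self.allow_higher_order:
            raise ValueError(
                "polyorder > 2 can yield negative densities; "
                "set allow_higher_order=True to override"
            )
        if self.pad_fraction < 0:
            raise ValueError("pad_fraction must be >= 0")


@dataclass
class IntegratedDistributions:
    """Integrated (cumulative) reactive/unreactive distributions on a grid.

    R and U are nondecreasing; R[-1] + U[-1] = 1 on the unpadded part.
    ``n_pad`` records how many plateau points were prepended/appended.
    """

    grid: np.ndarray
    R: np.ndarray
    U: np.ndarray
    n_pad: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        if not (self.grid.shape == self.R.shape == self.U.shape):
            raise ValueError("grid/R/U length mismatch")
        for name, arr in (("R", self.R), ("U", self.U)):
            if np.any(np.diff(arr) < -1e-12):
                raise ValueError(f"{name} must be nondecreasing")

    @property
    def p_bar(self) -> float:
        return float(self.R[-1])


@dataclass
class DensityEstimate:
    """Densities r, u and t = r + u on a regular CV grid.

    ``bin_width`` is set for piecewise-constant (histogram) estimates, in
    which case integrals downstream use the rectangle rule instead of the
    trapezoidal rule.
    """

    grid: np.ndarray
    r: np.ndarray
    u: np.ndarray
    t: np.ndarray = None  # type: ignore[assignment]
    bin_width: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.t is None:
            self.t = self.r + self.u
        else:
            self.t = np.asarray(self.t, dtype=float)
        if not (self.grid.shape == self.r.shape == self.u.shape == self.t.shape):
            raise ValueError("grid/r/u/t length mismatch")

    def integrate(self, values: np.ndarray) -> float:
        """Integrate ``values`` over the grid with the estimate's native rule."""
        if self.bin_width is not None:
            return float(np.sum(values) * self.bin_width)
        return float(np.trapezoid(values, self.grid))


# ---------------------------------------------------------------------------
# pipeline stages


def weighted_cdfs(s: SampleSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stepwise integrated distributions at the sorted distinct CV values.

    Returns ``(cv, R, U)`` where ``R[i]`` is the total weight of reactive
    samples with CV <= cv[i], divided by the total weight W (U analogous).
    Duplicate CV values merge into a single step of summed weight.
    """
    x = s.cv_array()
    if np.all(x == x[0]):
        raise DegenerateSupportError("all CV values identical")
    order = np.argsort(x, kind="stable")
    x_sorted = x[order]
    wr = np.where(s.reactive[order], s.weights[order], 0.0)
    wu = np.where(s.reactive[order], 0.0, s.weights[order])
    uniq, start = np.unique(x_sorted, return_index=True)
    W = s.total_weight
    R = np.add.reduceat(wr, start).cumsum() / W
    U = np.add.reduceat(wu, start).cumsum() / W
    return uniq, R, U


def regrid(
    cv: np.ndarray, R: np.ndarray, U: np.ndarray, n_gp: int = 2000
) -> IntegratedDistributions:
    """Linearly interpolate the step curves onto a regular grid.

    The grid has ``n_gp`` equally spaced points spanning exactly
    [min(cv), max(cv)]; monotonicity is preserved by linear interpolation.
    """
    if n_gp < 16:
        raise ValueError(f"n_gp must be >= 16, got {n_gp}")
    grid = np.linspace(cv[0], cv[-1], n_gp)
    return IntegratedDistributions(
        grid=grid, R=np.interp(grid, cv, R), U=np.interp(grid, cv, U)
    )


def pad_plateaus(
    d: IntegratedDistributions, pad_fraction: float = 0.25
) -> IntegratedDistributions:
    """Extend the integrated curves with horizontal plateaus on both sides.

    ``round(pad_fraction * n_gp)`` points are prepended at height 0 and
    appended at the final height, with the grid continued at the same spacing
    (500 points per side for the 2000-point default).
    """
    n_pad = int(round(pad_fraction * d.grid.size))
    if n_pad == 0:
        return IntegratedDistributions(d.grid, d.R, d.U, n_pad=0)
    dx = d.grid[1] - d.grid[0]
    left = d.grid[0] - dx * np.arange(n_pad, 0, -1)
    right = d.grid[-1] + dx * np.arange(1, n_pad + 1)
    grid = np.concatenate([left, d.grid, right])
    R = np.concatenate([np.zeros(n_pad), d.R, np.full(n_pad, d.R[-1])])
    U = np.concatenate([np.zeros(n_pad), d.U, np.full(n_pad, d.U[-1])])
    return IntegratedDistributions(grid, R, U, n_pad=n_pad)


def sg_window(n_gp: int, window_fraction: float = 1.0 / 16.0) -> int:
    """Savitzky-Golay window length: nearest odd integer to
    ``n_gp * window_fraction``, clamped to a minimum of 5.

    (2000, 1/16) -> 125, the canonical default.
    """
    if n_gp < 16:
        raise ValueError(f"n_gp must be >= 16, got {n_gp}")
    x = n_gp * window_fraction
    w = 2 * int(round((x - 1) / 2)) + 1
    return max(w, 5)


def sg_derivative(
    padded: IntegratedDistributions, settings: SGSettings | None = None
) -> DensityEstimate:
    """Differentiate the padded integrated curves with the SG filter.

    Returns densities on the original (unpadded) grid; t = r + u.  The window
    is clamped to the padded length if it would exceed it.
    """
    settings = settings or SGSettings()
    n_total = padded.grid.size
    if n_total < 5:
        raise ValueError("padded curve too short for SG filtering (< 5 points)")
    window = sg_window(settings.n_gp, settings.window_fraction)
    if window > n_total:
        window = n_total if n_total % 2 == 1 else n_total - 1
    dx = padded.grid[1] - padded.grid[0]
    r = savgol_filter(padded.R, window, settings.polyorder, deriv=1, delta=dx)
    u = savgol_filter(padded.U, window, settings.polyorder, deriv=1, delta=dx)
    n_pad = padded.n_pad
    sl = slice(n_pad, n_total - n_pad if n_pad else n_total)
    return DensityEstimate(grid=padded.grid[sl], r=r[sl], u=u[sl])


def estimate_densities(
    s: SampleSet, settings: SGSettings | None = None
) -> DensityEstimate:
    """Full pipeline: weighted CDFs -> regrid -> pad -> SG derivative."""
    settings = settings or SGSettings()
    cv, R, U = weighted_cdfs(s)
    d = regrid(cv, R, U, settings.n_gp)
    padded = pad_plateaus(d, settings.pad_fraction)
    return sg_derivative(padded, settings)


def binned_densities(s: SampleSet, n_bins: int) -> DensityEstimate:
    """Naive weighted-histogram estimate (fallback and failure-mode oracle).

    Piecewise-constant densities on equal-width bins over the sampled range,
    normalized by the total weight so that the rectangle-rule integral of t
    is 1.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    x = s.cv_array()
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise DegenerateSupportError("all CV values identical")
    edges = np.linspace(lo, hi, n_bins + 1)
    width = edges[1] - edges[0]
    W = s.total_weight
    hr, _ = np.histogram(x[s.reactive], bins=edges, weights=s.weights[s.reactive])
    hu, _ = np.histogram(x[~s.reactive], bins=edges, weights=s.weights[~s.reactive])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityEstimate(
        grid=centers, r=hr / (W * width), u=hu / (W * width), bin_width=float(width)
    )


# ---------------------------------------------------------------------------
# sklearn-style estimator


class SavitzkyGolayDensity(BaseEstimator):
    """Weighted reactive/unreactive density estimator (sklearn API).

    Fit on a 1-D CV sample ``X`` with binary labels ``y`` (1 = reactive) and
    optional ``sample_weight``; exposes the estimated densities as fitted
    attributes and evaluates the local success probability r/t via
    :meth:`predict_proba`.

    Parameters
    ----------
    n_grid : int
        Number of regular grid points spanning the sampled CV range.
    window_fraction : float
        SG window length as a fraction of the grid (rounded to odd).
    polyorder : int
        SG polynomial order (<= 2 unless ``allow_higher_order``).
    pad_fraction : float
        Plateau extension on each side, as a fraction of the grid.

    Attributes
    ----------
    grid_ : ndarray of shape (n_grid,)
    r_, u_, t_ : ndarray
        Reactive, unreactive and total densities (units 1/CV-unit).
    p_bar_ : float
        Sample-level average transition probability (reactive weight / W).
    """

    def __init__(
        self,
        n_grid: int = 2000,
        window_fraction: float = 1.0 / 16.0,
        polyorder: int = 2,
        pad_fraction: float = 0.25,
        allow_higher_order: bool = False,
    ):
        self.n_grid = n_grid
        self.window_fraction = window_fraction
        self.polyorder = polyorder
        self.pad_fraction = pad_fraction
        self.allow_higher_order = allow_higher_order

    def _settings(self) -> SGSettings:
        return SGSettings(
            n_gp=self.n_grid,
            window_fraction=self.window_fraction,
            polyorder=self.polyorder,
            pad_fraction=self.pad_fraction,
            allow_higher_order=self.allow_higher_order,
        )

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError(
                    f"SG density estimation is one-dimensional; got {X.shape[1]} columns"
                )
            X = X[:, 0]
        y = np.asarray(y).ravel().astype(bool)
        if sample_weight is None:
            sample_weight = np.ones_like(X)
        s = SampleSet(values=X, weights=np.asarray(sample_weight, float), reactive=y)
        est = estimate_densities(s, self._settings())
        self.grid_ = est.grid
        self.r_ = est.r
        self.u_ = est.u
        self.t_ = est.t
        self.p_bar_ = s.reactive_weight / s.total_weight
        self.n_samples_ = len(s)
        return self

    @property
    def density_(self) -> DensityEstimate:
        return DensityEstimate(grid=self.grid_, r=self.r_, u=self.u_, t=self.t_)

    def predict_proba(self, X):
        """Estimated P(reactive | CV) = r/t, interpolated on the fitted grid.

        Outside the sampled range the total density is 0; the marginal
        probability p_bar_ is returned there.
        """
        X = np.asarray(X, dtype=float)
        flat = X.ravel()
        r = np.interp(flat, self.grid_, self.r_, left=0.0, right=0.0)
        t = np.interp(flat, self.grid_, self.t_, left=0.0, right=0.0)
        eps = 1e-8 * max(self.t_.max(), 1e-300)
        p = np.where(t > eps, np.clip(r / np.where(t > eps, t, 1.0), 0.0, 1.0), self.p_bar_)
        return np.column_stack([1.0 - p, p])
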