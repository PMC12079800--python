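"""Overlap integral and predictive capacity of a collective variable.

With reactive/unreactive densities r(psi), u(psi) and t = r + u at a crossing
interface, the predictive capacity is the reactive-weighted average of the
local success probability r/t:

    P = (1/p_bar) * int r(psi)^2 / t(psi) dpsi = 1 - O / p_bar

where p_bar = int r is the average transition probability and
O = int r*u/t is the overlap integral.  P ranges from p_bar (CV carries no
information about success) to 1 (r and u have disjoint supports; the CV fully
determines success).  Both algebraic forms are computed and cross-checked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .crossings import SampleSet, build_sample_set, mean_crossing_prob
from .density import DensityEstimate, SGSettings, SavitzkyGolayDensity, estimate_densities
from .paths import PathRecord, PPAQuery

__all__ = [
    "PredictiveResult",
    "PPAMap",
    "overlap_integral",
    "predictive_capacity",
    "capacity_from_samples",
    "ppa_scan",
    "PredictiveCapacityEstimator",
]

#: relative guard on t for the 0/0 tails of the overlap integrand.
EPS_T = 1e-8
#: agreement required between the two algebraic forms of the capacity.
FORM_AGREEMENT = 1e-9


@dataclass(frozen=True)
class PredictiveResult:
    """Capacity of one CV at one (lambda_c, lambda_r) query."""

    p_bar: float
    overlap: float
    capacity: float
    n_samples: int = 0
    query: PPAQuery | None = None

    def to_dict(self) -> dict:
        return {
            "p_bar": self.p_bar,
            "overlap": self.overlap,
            "capacity": self.capacity,
            "n_samples": self.n_samples,
        }


@dataclass
class PPAMap:
    """Crossing probability, capacity and their ratio over a (lc, lr) grid.

    Cells with lc > lr, or with fewer than the minimum sample count, are
    undefined (NaN, ``defined`` False).  Index order: [i_lc, i_lr].
    """

    lc_grid: np.ndarray
    lr_grid: np.ndarray
    P: np.ndarray
    capacity: np.ndarray
    ratio: np.ndarray
    defined: np.ndarray

    def to_long_frame(self):
        import pandas as pd

        lc, lr = np.meshgrid(self.lc_grid, self.lr_grid, indexing="ij")
        return pd.DataFrame(
            {
                "lc": lc.ravel(),
                "lr": lr.ravel(),
                "P": self.P.ravel(),
                "capacity": self.capacity.ravel(),
                "ratio": self.ratio.ravel(),
                "defined": self.defined.ravel(),
            }
        )


def _guarded_ratio(num: np.ndarray, t: np.ndarray) -> np.ndarray:
    eps = EPS_T * max(float(t.max()), 1e-300)
    safe = t > eps
    return np.where(safe, num / np.where(safe, t, 1.0), 0.0)


def overlap_integral(d: DensityEstimate) -> float:
    """O = int r*u/t over the grid, with the integrand set to 0 where the
    total density is below EPS_T * max(t)."""
    return d.integrate(_guarded_ratio(d.r * d.u, d.t))


def predictive_capacity(
    d: DensityEstimate, n_samples: int = 0, query: PPAQuery | None = None
) -> PredictiveResult:
    """Capacity from a density estimate, with p_bar taken as int r.

    The direct form (1/p_bar) int r^2/t and the identity 1 - O/p_bar must
    agree to 1e-9; disagreement indicates a corrupted estimate.
    """
    p_bar = d.integrate(d.r)
    if p_bar <= 0:
        raise ValueError("p_bar = int r is zero: no reactive density")
    overlap = overlap_integral(d)
    direct = d.integrate(_guarded_ratio(d.r * d.r, d.t))
    # identity r^2/t = r - r*u/t, checked on the guarded domain (the eps_t
    # guard drops the same tail from both integrals but not from int r)
    eps = EPS_T * max(float(d.t.max()), 1e-300)
    r_guarded = d.integrate(np.where(d.t > eps, d.r, 0.0))
    if abs(direct + overlap - r_guarded) > FORM_AGREEMENT:
        raise AssertionError(
            f"capacity forms disagree: {direct + overlap!r} vs {r_guarded!r}"
        )
    via_overlap = 1.0 - overlap / p_bar
    return PredictiveResult(
        p_bar=float(p_bar),
        overlap=float(overlap),
        capacity=float(via_overlap),
        n_samples=n_samples,
        query=query,
    )


def capacity_from_samples(
    s: SampleSet, settings: SGSettings | None = None
) -> PredictiveResult:
    """End-to-end capacity: SG density estimation then the overlap forms.

    The density-level p_bar (int r) is cross-checked against the sample-level
    reactive weight fraction; a discrepancy beyond 1e-3 emits a diagnostics
    warning (never an error — small-n curvature of the integrated curves can
    shift the integral slightly).
    """
    settings = settings or SGSettings()
    d = estimate_densities(s, settings)
    res = predictive_capacity(d, n_samples=len(s), query=s.query)
    p_bar_sample = mean_crossing_prob(s)
    if abs(res.p_bar - p_bar_sample) > 1e-3:
        warnings.warn(
            f"density-level p_bar {res.p_bar:.6f} deviates from sample-level "
            f"{p_bar_sample:.6f} by more than 1e-3",
            stacklevel=2,
        )
    return res


def ppa_scan(
    paths,
    cv_name: str,
    lc_grid,
    lr_grid,
    settings: SGSettings | None = None,
    n_min: int = 200,
) -> PPAMap:
    """Scan capacity and crossing probability over a (lambda_c, lambda_r) grid.

    For each pair with lc <= lr: P = (weighted fraction with lambda_max >= lr)
    / (fraction >= lc), and the capacity is estimated from the first-crossing
    samples at lc labelled by lr.  First crossings are extracted once per lc
    (they do not depend on lr); labels are recomputed per lr.  Cells with
    fewer than ``n_min`` samples are reported undefined rather than thrown.
    """
    from .paths import ensemble_interface_index

    settings = settings or SGSettings()
    lc_grid = np.asarray(lc_grid, dtype=float)
    lr_grid = np.asarray(lr_grid, dtype=float)
    plus = [p for p in paths if ensemble_interface_index(p.ensemble) is not None]
    if not plus:
        raise ValueError("no [i+] paths to scan")
    maxima = np.array([p.lambda_max() for p in plus])
    weights = np.array([p.weight for p in plus])
    Wtot = weights.sum()

    shape = (lc_grid.size, lr_grid.size)
    P = np.full(shape, np.nan)
    cap = np.full(shape, np.nan)
    defined = np.zeros(shape, dtype=bool)

    for i, lc in enumerate(lc_grid):
        sel = maxima >= lc
        n_sel = int(sel.sum())
        if n_sel == 0:
            continue
        cv_at = np.empty(n_sel)
        k = 0
        for p, hit in zip(plus, sel):
            if hit:
                idx = int(np.argmax(p.lam >= lc))
                cv_at[k] = p.cvs[cv_name][idx]
                k += 1
        m_sel = maxima[sel]
        w_sel = weights[sel]
        W_lc = w_sel.sum()
        for j, lr in enumerate(lr_grid):
            if lr < lc:
                continue
            reactive = m_sel >= lr
            P[i, j] = w_sel[reactive].sum() / W_lc
            if n_sel < n_min or not reactive.any():
                continue
            if not reactive.all() and np.unique(cv_at).size < 2:
                continue
            if reactive.all():
                # degenerate query: every sample reactive, u == 0 identically
                cap[i, j] = 1.0
                defined[i, j] = True
                continue
            s = SampleSet(
                values=cv_at.copy(),
                weights=w_sel,
                reactive=reactive,
                query=PPAQuery(lam_c=float(lc), lam_r=float(lr)),
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cap[i, j] = capacity_from_samples(s, settings).capacity
                defined[i, j] = True
            except (ValueError, AssertionError):
                continue

    ratio = cap / P
    return PPAMap(
        lc_grid=lc_grid, lr_grid=lr_grid, P=P, capacity=cap, ratio=ratio,
        defined=defined,
    )


class PredictiveCapacityEstimator(BaseEstimator):
    """Predictive capacity of a 1-D CV (sklearn API).

    Fit on CV values ``X`` with binary success labels ``y`` and optional
    ``sample_weight``; the fitted attributes expose p_bar_, overlap_ and
    capacity_.  ``score`` returns the capacity, so the estimator plugs into
    sklearn model selection directly.
    """

    def __init__(
        self,
        n_grid: int = 2000,
        window_fraction: float = 1.0 / 16.0,
        polyorder: int = 2,
        pad_fraction: float = 0.25,
    ):
        self.n_grid = n_grid
        self.window_fraction = window_fraction
        self.polyorder = polyorder
        self.pad_fraction = pad_fraction

    def fit(self, X, y, sample_weight=None):
        dens = SavitzkyGolayDensity(
            n_grid=self.n_grid,
            window_fraction=self.window_fraction,
            polyorder=self.polyorder,
            pad_fraction=self.pad_fraction,
        ).fit(X, y, sample_weight=sample_weight)
        res = predictive_capacity(dens.density_, n_samples=dens.n_samples_)
        self.density_estimator_ = dens
        self.p_bar_ = res.p_bar
        self.overlap_ = res.overlap
        self.capacity_ = res.capacity
        self.n_samples_ = dens.n_samples_
        return self

    def predict_proba(self, X):
        return self.density_estimator_.predict_proba(X)

    def score(self, X=None, y=None, sample_weight=None):
        """The fitted predictive capacity (ignores arguments)."""
        return self.capacity_

    def result_(self) -> PredictiveResult:
        return PredictiveResult(
            p_bar=self.p_bar_,
            overlap=self.overlap_,
            capacity=self.capacity_,
            n_samples=self.n_samples_,
        )
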