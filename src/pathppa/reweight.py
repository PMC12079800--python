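"""Path reweighting across nested interface ensembles (WHAM), crossing
probabilities, flux and rate assembly.

The nested ensembles ``[0+], [1+], ...`` oversample paths that progress far
along the order parameter.  Because the ensemble biases are step functions of
the path maximum (a path belongs to ``[j+]`` iff lambda_max >= lambda_j), the
weighted-histogram equations admit a non-iterative left-to-right solution: a
path with maximum m receives weight

    w(m) = 1 / sum_{k : lambda_k <= m} n_k / Phat(lambda_k)

where n_k is the path count of ensemble ``[k+]`` and Phat the crossing
probability built recursively from interfaces already processed.  With these
weights the weighted distribution of lambda_max equals the distribution of
first-crossing segments of an (effectively infinite) unbiased trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .paths import InterfaceSet, PathRecord, ensemble_interface_index

__all__ = [
    "CrossingCurve",
    "RateResult",
    "DegenerateEnsembleError",
    "lambda_max",
    "wham_weights",
    "crossing_curve",
    "flux_estimate",
    "rate",
]

#: fs -> ns conversion applied at the reporting layer only.
FS_PER_NS = 1.0e6


class DegenerateEnsembleError(ValueError):
    """An ensemble contains no path crossing its own interface (or a path
    that fails its ensemble's crossing requirement)."""


@dataclass
class CrossingCurve:
    """P_A(lambda | lambda_A) evaluated on a lambda grid.

    The curve is reported only up to the largest lambda reached by at least
    one path; beyond that it is undefined rather than zero.
    """

    lam_grid: np.ndarray
    prob: np.ndarray

    def __post_init__(self) -> None:
        self.lam_grid = np.asarray(self.lam_grid, dtype=float)
        self.prob = np.asarray(self.prob, dtype=float)
        if self.lam_grid.shape != self.prob.shape:
            raise ValueError("grid/prob length mismatch")
        if np.any(np.diff(self.prob) > 1e-12):
            raise ValueError("crossing probability must be non-increasing")

    @property
    def total(self) -> float:
        """Value at the last reported grid point."""
        return float(self.prob[-1])

    def __call__(self, lam: float) -> float:
        """Step-interpolate the curve at ``lam`` (exact for grid values)."""
        if lam < self.lam_grid[0] - 1e-12 or lam > self.lam_grid[-1] + 1e-12:
            raise ValueError(f"lambda {lam} outside reported curve range")
        idx = np.searchsorted(self.lam_grid, lam + 1e-12) - 1
        return float(self.prob[max(idx, 0)])


@dataclass(frozen=True)
class RateResult:
    """Flux, total crossing probability, and their product, the rate k_AB.

    ``rate == flux * total_crossing_prob`` exactly by construction.
    """

    flux: float
    total_crossing_prob: float
    rate: float

    @classmethod
    def assemble(cls, flux: float, total_crossing_prob: float) -> "RateResult":
        return cls(flux, total_crossing_prob, flux * total_crossing_prob)


def lambda_max(path: PathRecord) -> float:
    """Maximum order-parameter value over the stored frames of a path."""
    return path.lambda_max()


def _plus_paths(paths: Sequence[PathRecord]) -> list[PathRecord]:
    return [p for p in paths if ensemble_interface_index(p.ensemble) is not None]


def wham_weights(
    paths: Sequence[PathRecord], interfaces: InterfaceSet
) -> list[PathRecord]:
    """Assign WHAM weights to ``[i+]`` paths; ``[0-]`` paths pass unchanged.

    Weights are normalized so their mean over the ``[i+]`` paths is 1.
    Raises :class:`DegenerateEnsembleError` if an ensemble has no path
    crossing its own interface, or a member path fails the requirement.
    """
    lam = np.asarray(interfaces.lambdas)
    plus = _plus_paths(paths)
    if not plus:
        raise ValueError("no [i+] paths to reweight")
    ens_idx = np.array([ensemble_interface_index(p.ensemble) for p in plus])
    if ens_idx.max() >= len(lam) - 1:
        raise ValueError(
            f"ensemble [{ens_idx.max()}+] has no interface in {interfaces.lambdas}"
        )
    maxima = np.array([p.lambda_max() for p in plus])

    bad = maxima < lam[ens_idx]
    if np.any(bad):
        p = plus[int(np.argmax(bad))]
        raise DegenerateEnsembleError(
            f"path {p.path_id!r} of ensemble {p.ensemble!r} has lambda_max "
            f"{p.lambda_max():.6g} below its interface"
        )

    present = np.unique(ens_idx)
    counts = {int(j): int(np.sum(ens_idx == j)) for j in present}

    # Recursive crossing-probability estimate at each interface.  The pool for
    # the ratio across [lam_k, lam_{k+1}] is every path from ensembles with
    # interface <= k; conditioned on lambda_max >= lam_k those paths are
    # equally weighted draws from the same conditional law, so the weighted
    # ratio reduces to a count ratio.
    n_int = len(lam)
    phat = np.ones(n_int)
    for k in range(1, n_int):
        pool = ens_idx <= k - 1
        den = int(np.sum(pool & (maxima >= lam[k - 1])))
        num = int(np.sum(pool & (maxima >= lam[k])))
        if den == 0:
            raise DegenerateEnsembleError(
                f"no paths available to bridge interfaces {lam[k-1]} -> {lam[k]}"
            )
        phat[k] = phat[k - 1] * num / den
        if phat[k] == 0.0:
            phat[k:] = 0.0
            break

    # Closed-form weights: w(m) = 1 / sum_{k present, lam_k <= m} n_k / phat_k
    inv = np.zeros(len(plus))
    for j in present:
        sel = maxima >= lam[j]
        if phat[j] <= 0:
            raise DegenerateEnsembleError(
                f"ensemble [{j}+] lies beyond the last reached interface"
            )
        inv[sel] += counts[int(j)] / phat[j]
    w = 1.0 / inv
    w *= len(w) / w.sum()

    out: list[PathRecord] = []
    i = 0
    for p in paths:
        if ensemble_interface_index(p.ensemble) is None:
            out.append(p)
        else:
            out.append(p.with_weight(float(w[i])))
            i += 1
    return out


def crossing_curve(
    paths: Sequence[PathRecord], lam_grid: Sequence[float]
) -> CrossingCurve:
    """Weighted crossing-probability curve P_A(lambda | lambda_A).

    ``prob(lam) = sum{w : lambda_max >= lam} / sum{w over all [i+] paths}``.
    The grid is truncated at the largest lambda_max reached, so every reported
    value is positive.
    """
    plus = _plus_paths(paths)
    if not plus:
        raise ValueError("crossing_curve needs at least one [i+] path")
    grid = np.asarray(lam_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("lam_grid must be a nonempty increasing sequence")
    maxima = np.array([p.lambda_max() for p in plus])
    w = np.array([p.weight for p in plus])
    reach = maxima.max()
    grid = grid[grid <= reach + 1e-12]
    if grid.size == 0:
        raise ValueError("no grid point is reached by any path")
    order = np.argsort(maxima)
    m_sorted, w_sorted = maxima[order], w[order]
    tail = np.concatenate([np.cumsum(w_sorted[::-1])[::-1], [0.0]])
    idx = np.searchsorted(m_sorted, grid, side="left")
    prob = tail[idx] / w.sum()
    prob = np.minimum.accumulate(prob)
    return CrossingCurve(lam_grid=grid, prob=prob)


def flux_estimate(
    paths_0minus: Sequence[PathRecord], paths_0plus: Sequence[PathRecord]
) -> float:
    """Initial flux f_A in ns^-1 from mean path durations.

    f_A = 1 / (<tau>_{0-} + <tau>_{0+}) with tau = times[-1] - times[0] (fs).
    """
    if not paths_0minus:
        raise ValueError("empty [0-] ensemble")
    if not paths_0plus:
        raise ValueError("empty [0+] ensemble")
    tau_m = np.array([p.duration for p in paths_0minus])
    tau_p = np.array([p.duration for p in paths_0plus])
    # single-frame [0-] paths (touch-and-go A visits) carry zero duration by
    # the shared-endpoint convention and enter the mean; a whole ensemble of
    # zero-duration paths is degenerate
    if np.any(tau_m < 0) or np.any(tau_p < 0):
        raise ValueError("negative path duration encountered")
    if tau_m.mean() == 0 or tau_p.mean() == 0:
        raise ValueError("zero-duration path ensemble")
    return FS_PER_NS / (tau_m.mean() + tau_p.mean())


def rate(flux: float, curve: CrossingCurve) -> RateResult:
    """Rate constant k_AB = f_A * P_A(lambda_B | lambda_A) (ns^-1)."""
    return RateResult.assemble(flux, curve.total)
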