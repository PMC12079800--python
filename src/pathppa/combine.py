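"""Linear CV combinations optimized for predictive capacity.

Candidate CVs are first made dimensionless and screened individually; subsets
of 2-3 CVs are then optimized by generalized simulated annealing over the
coefficient cube [-1, 1]^n, re-normalized to the L1 constraint
|alpha| + |beta| + |gamma| = 1 before every evaluation.  The loss is the
overlap integral — minimizing it maximizes the capacity, since the average
transition probability p_bar does not depend on the CV.  The best subset gets
a final local refinement.  Overall scale and sign of a combination do not
change its capacity; reported coefficients canonicalize the largest-magnitude
coefficient to be positive.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import dual_annealing, minimize
from sklearn.base import BaseEstimator

from .capacity import PredictiveResult, capacity_from_samples
from .crossings import SampleSet
from .density import SGSettings

__all__ = [
    "LinearCombo",
    "AnnealSettings",
    "UNIT_QUANTA",
    "nondimensionalize",
    "normalize_l1",
    "combo_project",
    "screen_singles",
    "anneal_combo",
    "LinearCombinationAnnealer",
]

#: unit quanta dividing each CV class to make it dimensionless.
UNIT_QUANTA = {
    "angstrom": 1.0,  # distance-based CVs divided by 1 Angstrom
    "nm^-3": 1.0,  # density-based CVs divided by 1 nm^-3
    "unitless": None,  # left unchanged
}


@dataclass(frozen=True)
class LinearCombo:
    """A 1-3 term linear combination with sum(|coef|) = 1."""

    terms: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.terms) <= 3:
            raise ValueError("a combination has 1 to 3 terms")
        total = sum(abs(c) for _, c in self.terms)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"coefficients must satisfy sum|c| = 1, got {total}")
        for _, c in self.terms:
            if not -1.0 - 1e-12 <= c <= 1.0 + 1e-12:
                raise ValueError(f"coefficient {c} outside [-1, 1]")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.terms)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for _, c in self.terms])

    @property
    def normalized_by_max(self) -> tuple[tuple[str, float], ...]:
        """Coefficients rescaled by the largest absolute prefactor."""
        scale = max(abs(c) for _, c in self.terms)
        return tuple((n, c / scale) for n, c in self.terms)

    @classmethod
    def from_coefficients(
        cls, names: Sequence[str], coefs: Sequence[float]
    ) -> "LinearCombo":
        c = normalize_l1(np.asarray(coefs, dtype=float))
        lead = int(np.argmax(np.abs(c)))
        if c[lead] < 0:
            c = -c
        return cls(terms=tuple(zip(names, (float(x) for x in c))))


@dataclass(frozen=True)
class AnnealSettings:
    """Simulated-annealing search settings.

    ``max_iterations`` defaults by term count: 200 for 2-CV combinations,
    1000 for 3-CV.  The initial temperature is an opaque scale of the
    underlying generalized-annealing scheme.  Restart seeds derive from
    ``seed`` so the whole search is deterministic.
    """

    initial_temperature: float = 26150.0
    max_iterations: int | None = None
    seed: int = 0
    local_search: bool = True
    n_restarts: int = 3
    top_k: int = 10
    max_evaluations: int = 2000
    sg: SGSettings = field(default_factory=SGSettings)

    def __post_init__(self) -> None:
        if self.initial_temperature <= 0:
            raise ValueError("initial_temperature must be positive")
        if self.max_iterations is not None and self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")

    def iterations_for(self, n_terms: int) -> int:
        if self.max_iterations is not None:
            return self.max_iterations
        return 1000 if n_terms >= 3 else 200


def nondimensionalize(
    samples: SampleSet, units: dict[str, str]
) -> SampleSet:
    """Divide each CV by its unit quantum (1 A, 1 nm^-3, ...).

    ``units`` maps CV name to one of the keys of :data:`UNIT_QUANTA`.
    Unitless CVs pass through unchanged; unknown units raise.
    """
    if not isinstance(samples.values, pd.DataFrame):
        names = samples.cv_names
    else:
        names = list(samples.values.columns)
    for name in names:
        unit = units.get(name, "unitless")
        if unit not in UNIT_QUANTA:
            raise ValueError(
                f"unknown unit {unit!r} for CV {name!r}; "
                f"known: {sorted(UNIT_QUANTA)}"
            )
    if isinstance(samples.values, pd.DataFrame):
        values = samples.values.copy()
        for name in names:
            quantum = UNIT_QUANTA[units.get(name, "unitless")]
            if quantum is not None:
                values[name] = values[name] / quantum
    else:
        quantum = UNIT_QUANTA[units.get(names[0], "unitless")]
        values = samples.values if quantum is None else samples.values / quantum
    return SampleSet(
        values=values,
        weights=samples.weights,
        reactive=samples.reactive,
        path_ids=samples.path_ids,
        query=samples.query,
    )


def normalize_l1(coefs: Sequence[float]) -> np.ndarray:
    """Rescale coefficients so that sum(|coef|) = 1."""
    c = np.asarray(coefs, dtype=float)
    total = np.abs(c).sum()
    if total == 0:
        raise ValueError("all coefficients are zero")
    return c / total


def combo_project(samples: SampleSet, combo: LinearCombo) -> SampleSet:
    """Project multi-CV samples onto the 1-D combination Psi = sum c_i CV_i."""
    if not isinstance(samples.values, pd.DataFrame):
        if len(combo.terms) != 1 or combo.names[0] not in samples.cv_names:
            raise ValueError(
                f"missing CV(s) {combo.names}; available: {samples.cv_names}"
            )
        psi = samples.values * combo.coefficients[0]
    else:
        missing = [n for n in combo.names if n not in samples.values.columns]
        if missing:
            raise ValueError(
                f"missing CV(s) {missing}; available: {list(samples.values.columns)}"
            )
        psi = np.zeros(len(samples))
        for name, coef in combo.terms:
            psi = psi + coef * samples.values[name].to_numpy()
    return SampleSet(
        values=np.asarray(psi, dtype=float),
        weights=samples.weights,
        reactive=samples.reactive,
        path_ids=samples.path_ids,
        query=samples.query,
    )


def screen_singles(
    samples: SampleSet,
    cv_names: Sequence[str] | None = None,
    settings: AnnealSettings | None = None,
) -> list[tuple[str, float]]:
    """Rank CVs by their individual predictive capacity (descending).

    Ties break lexicographically on the CV name.
    """
    settings = settings or AnnealSettings()
    names = list(cv_names) if cv_names is not None else samples.cv_names
    if not names:
        raise ValueError("no CVs to screen")
    scored = []
    for name in sorted(names):
        single = combo_project(samples, LinearCombo(terms=((name, 1.0),)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = capacity_from_samples(single, settings.sg)
        scored.append((name, res.capacity))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def anneal_combo(
    samples: SampleSet,
    candidate_cvs: Sequence[str],
    n_terms: int = 2,
    settings: AnnealSettings | None = None,
) -> tuple[LinearCombo, PredictiveResult]:
    """Search linear combinations of ``n_terms`` CVs for maximal capacity.

    Every ``n_terms``-subset of the candidates is screened with generalized
    simulated annealing (several restarts, deterministic seeds derived from
    ``settings.seed``); the best subset is refined with a local simplex
    search.  Returns the canonicalized combination and its capacity.
    """
    settings = settings or AnnealSettings()
    candidates = list(candidate_cvs)
    if len(candidates) < n_terms:
        raise ValueError(
            f"need at least {n_terms} candidate CVs, got {len(candidates)}"
        )
    if not isinstance(samples.values, pd.DataFrame):
        raise ValueError("anneal_combo needs multi-CV samples (DataFrame values)")

    rng_root = np.random.SeedSequence(settings.seed)
    maxiter = settings.iterations_for(n_terms)
    weights = samples.weights
    reactive = samples.reactive

    def make_loss(names: list[str]):
        cols = [samples.values[n].to_numpy() for n in names]

        def loss(theta: np.ndarray) -> float:
            if np.abs(theta).sum() < 1e-12:
                return 1.0
            c = normalize_l1(theta)
            psi = c @ np.asarray(cols)
            if np.ptp(psi) == 0:
                return 1.0
            s = SampleSet(values=psi, weights=weights, reactive=reactive)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    return capacity_from_samples(s, settings.sg).overlap
            except (ValueError, AssertionError):
                return 1.0

        return loss

    best: tuple[float, list[str], np.ndarray] | None = None
    subsets = list(itertools.combinations(candidates, n_terms))
    seeds = rng_root.generate_state(len(subsets) * settings.n_restarts) % (2**31 - 1)
    bounds = [(-1.0, 1.0)] * n_terms
    k = 0
    for names in subsets:
        loss = make_loss(list(names))
        for _ in range(settings.n_restarts):
            res = dual_annealing(
                loss,
                bounds=bounds,
                maxiter=maxiter,
                initial_temp=settings.initial_temperature,
                maxfun=settings.max_evaluations,
                seed=int(seeds[k]),
                no_local_search=True,
            )
            k += 1
            if best is None or res.fun < best[0]:
                best = (float(res.fun), list(names), np.asarray(res.x))

    assert best is not None
    fun, names, theta = best
    if settings.local_search:
        loss = make_loss(names)
        refined = minimize(
            loss,
            theta,
            method="Nelder-Mead",
            options={"maxiter": 200 * n_terms, "xatol": 1e-4, "fatol": 1e-6},
        )
        if refined.fun <= fun:
            theta = np.clip(refined.x, -1.0, 1.0)

    combo = LinearCombo.from_coefficients(names, theta)
    projected = combo_project(samples, combo)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = capacity_from_samples(projected, settings.sg)
    return combo, result


class LinearCombinationAnnealer(BaseEstimator):
    """Simulated-annealing search over linear CV combinations (sklearn API).

    Fit on a feature matrix ``X`` (DataFrame or array with
    ``feature_names``), binary labels ``y`` and optional ``sample_weight``.

    Attributes
    ----------
    combo_ : LinearCombo
    coef_ : ndarray — L1-normalized coefficients of the selected terms
    terms_ : tuple of (name, coefficient)
    capacity_, overlap_, p_bar_ : float
    """

    def __init__(
        self,
        n_terms: int = 2,
        initial_temperature: float = 26150.0,
        max_iterations: int | None = None,
        n_restarts: int = 3,
        top_k: int = 10,
        local_search: bool = True,
        max_evaluations: int = 2000,
        random_state: int = 0,
        feature_names: Sequence[str] | None = None,
        sg_settings: SGSettings | None = None,
    ):
        self.n_terms = n_terms
        self.initial_temperature = initial_temperature
        self.max_iterations = max_iterations
        self.n_restarts = n_restarts
        self.top_k = top_k
        self.local_search = local_search
        self.max_evaluations = max_evaluations
        self.random_state = random_state
        self.feature_names = feature_names
        self.sg_settings = sg_settings

    def fit(self, X, y, sample_weight=None):
        if isinstance(X, pd.DataFrame):
            df = X.copy()
        else:
            X = np.asarray(X, dtype=float)
            names = (
                list(self.feature_names)
                if self.feature_names is not None
                else [f"cv{i}" for i in range(X.shape[1])]
            )
            df = pd.DataFrame(X, columns=names)
        y = np.asarray(y).ravel().astype(bool)
        if sample_weight is None:
            sample_weight = np.ones(len(df))
        samples = SampleSet(values=df, weights=np.asarray(sample_weight, float), reactive=y)
        settings = AnnealSettings(
            initial_temperature=self.initial_temperature,
            max_iterations=self.max_iterations,
            seed=self.random_state,
            local_search=self.local_search,
            n_restarts=self.n_restarts,
            top_k=self.top_k,
            max_evaluations=self.max_evaluations,
            sg=self.sg_settings or SGSettings(),
        )
        ranked = screen_singles(samples, settings=settings)
        self.screening_ = ranked
        shortlist = [name for name, _ in ranked[: self.top_k]]
        combo, result = anneal_combo(samples, shortlist, self.n_terms, settings)
        self.combo_ = combo
        self.terms_ = combo.terms
        self.coef_ = combo.coefficients
        self.capacity_ = result.capacity
        self.overlap_ = result.overlap
        self.p_bar_ = result.p_bar
        return self

    def transform(self, X):
        """Project a feature matrix onto the fitted combination."""
        if isinstance(X, pd.DataFrame):
            cols = [X[n].to_numpy() for n in self.combo_.names]
        else:
            X = np.asarray(X, dtype=float)
            names = (
                list(self.feature_names)
                if self.feature_names is not None
                else [f"cv{i}" for i in range(X.shape[1])]
            )
            idx = [names.index(n) for n in self.combo_.names]
            cols = [X[:, i] for i in idx]
        psi = sum(c * col for c, col in zip(self.coef_, cols))
        return np.asarray(psi)[:, None]

    def score(self, X=None, y=None, sample_weight=None):
        return self.capacity_
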