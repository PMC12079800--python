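"""First-crossing extraction and reactive/unreactive labelling.

For a query (lambda_c, lambda_r) with lambda_A <= lambda_c <= lambda_r, every
path whose maximum reaches lambda_c contributes exactly one sample: its CV
values at the first stored frame with lambda >= lambda_c, carrying the path's
statistical weight.  The sample is *reactive* iff the path also reaches
lambda_r (lambda_max >= lambda_r, with >= as the tie rule); otherwise it is
*unreactive*.  No interpolation between stored frames is performed — the
crossing convention is resolution-honest at the stored time step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .paths import PathRecord, PPAQuery

__all__ = [
    "FirstCrossingSample",
    "SampleSet",
    "first_crossing_index",
    "label_path",
    "build_sample_set",
    "mean_crossing_prob",
]

REACTIVE = "reactive"
UNREACTIVE = "unreactive"


@dataclass(frozen=True)
class FirstCrossingSample:
    """One first-crossing data point: CV value(s), weight and label."""

    path_id: str
    cv: float | dict[str, float]
    weight: float
    label: str
    lam_c: float
    lam_r: float


@dataclass
class SampleSet:
    """Weighted, labelled first-crossing CV samples (columnar storage).

    ``values`` is (n,) for a single CV or a DataFrame column per CV name for
    the multi-CV case; ``reactive`` is a boolean mask, ``weights`` positive.
    """

    values: np.ndarray | pd.DataFrame
    weights: np.ndarray
    reactive: np.ndarray
    path_ids: np.ndarray | None = None
    query: PPAQuery | None = None

    def __post_init__(self) -> None:
        if isinstance(self.values, pd.DataFrame):
            n = len(self.values)
        else:
            self.values = np.asarray(self.values, dtype=float).ravel()
            n = self.values.size
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.reactive = np.asarray(self.reactive, dtype=bool).ravel()
        if self.weights.size != n or self.reactive.size != n:
            raise ValueError("values/weights/reactive length mismatch")
        if n == 0:
            raise ValueError("empty sample set")
        if np.any(self.weights <= 0):
            raise ValueError("sample weights must be > 0")

    def __len__(self) -> int:
        return self.weights.size

    @property
    def n_cvs(self) -> int:
        return self.values.shape[1] if isinstance(self.values, pd.DataFrame) else 1

    @property
    def cv_names(self) -> list[str]:
        if isinstance(self.values, pd.DataFrame):
            return list(self.values.columns)
        return ["cv"]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    @property
    def reactive_weight(self) -> float:
        return float(self.weights[self.reactive].sum())

    def cv_array(self, name: str | None = None) -> np.ndarray:
        """The 1-D CV column (the only one, or the named one)."""
        if isinstance(self.values, pd.DataFrame):
            if name is None:
                if self.values.shape[1] != 1:
                    raise ValueError(
                        f"multi-CV sample set; pick one of {self.cv_names}"
                    )
                name = self.values.columns[0]
            if name not in self.values.columns:
                raise ValueError(
                    f"unknown CV {name!r}; available: {self.cv_names}"
                )
            return self.values[name].to_numpy()
        return self.values

    @property
    def samples(self) -> Iterator[FirstCrossingSample]:
        q = self.query or PPAQuery(-np.inf, np.inf, -np.inf)
        for i in range(len(self)):
            if isinstance(self.values, pd.DataFrame):
                cv = {c: float(self.values[c].iloc[i]) for c in self.values.columns}
            else:
                cv = float(self.values[i])
            yield FirstCrossingSample(
                path_id=str(self.path_ids[i]) if self.path_ids is not None else str(i),
                cv=cv,
                weight=float(self.weights[i]),
                label=REACTIVE if self.reactive[i] else UNREACTIVE,
                lam_c=q.lam_c,
                lam_r=q.lam_r,
            )

    def to_frame(self) -> pd.DataFrame:
        df = (
            self.values.copy()
            if isinstance(self.values, pd.DataFrame)
            else pd.DataFrame({"cv": self.values})
        )
        df.insert(0, "path_id", self.path_ids if self.path_ids is not None else np.arange(len(self)))
        df["weight"] = self.weights
        df["label"] = np.where(self.reactive, REACTIVE, UNREACTIVE)
        return df


def first_crossing_index(path: PathRecord, lam_c: float) -> int | None:
    """Index of the first stored frame with lambda >= lam_c, or None.

    A path already starting at lambda >= lam_c crosses at frame 0.
    """
    hit = path.lam >= lam_c
    if not hit.any():
        return None
    return int(np.argmax(hit))


def label_path(path: PathRecord, lam_r: float) -> str:
    """'reactive' iff the path's lambda_max reaches lam_r (>= tie rule)."""
    return REACTIVE if path.lambda_max() >= lam_r else UNREACTIVE


def build_sample_set(
    paths: Sequence[PathRecord],
    query: PPAQuery,
    cv_names: str | Sequence[str],
) -> SampleSet:
    """Assemble the weighted first-crossing sample set for a query.

    One sample per path with lambda_max >= lam_c, carrying the CV value(s) at
    the first-crossing frame, the path weight and the reactive label.
    """
    if not paths:
        raise ValueError("empty path sequence")
    single = isinstance(cv_names, str)
    names = [cv_names] if single else list(cv_names)
    available = paths[0].cv_names
    unknown = [n for n in names if n not in available]
    if unknown:
        raise ValueError(
            f"unknown CV name(s) {unknown}; available: {available}"
        )
    ids, w, lab = [], [], []
    cols: dict[str, list[float]] = {n: [] for n in names}
    for p in paths:
        idx = first_crossing_index(p, query.lam_c)
        if idx is None:
            continue
        ids.append(p.path_id)
        w.append(p.weight)
        lab.append(p.lambda_max() >= query.lam_r)
        for n in names:
            cols[n].append(float(p.cvs[n][idx]))
    if not ids:
        raise ValueError(f"no path reaches lambda_c = {query.lam_c}")
    values: np.ndarray | pd.DataFrame
    if single:
        values = np.array(cols[names[0]])
    else:
        values = pd.DataFrame(cols)
    return SampleSet(
        values=values,
        weights=np.array(w),
        reactive=np.array(lab),
        path_ids=np.array(ids, dtype=object),
        query=query,
    )


def mean_crossing_prob(s: SampleSet) -> float:
    """Average transition probability p_bar = reactive weight / total weight."""
    if s.total_weight <= 0:
        raise ValueError("total weight is zero")
    return s.reactive_weight / s.total_weight
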