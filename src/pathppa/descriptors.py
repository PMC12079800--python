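"""Collective variables from atomic configurations.

The central descriptor is the index-invariant distance matrix (IIDM): from a
full interatomic distance matrix, rows are sorted by species and then by
distance to an anchor atom, columns within each row by species and distance
to the row atom, and the matrix is truncated.  Sorting makes every entry
independent of the input atom ordering, so entries can be named positionally:
``XYi`` is the distance from anchor X to its i-th closest atom of species Y,
and ``XYiZj`` the distance from that atom to *its* j-th closest neighbor of
species Z within the truncated pool.

Also provided: a smooth switching-function "bridging" coordination count, the
largest-cosine angle CVs, and axis-relative cylindrical density maps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .paths import Configuration

__all__ = [
    "IIDMSpec",
    "IIDMatrix",
    "min_image_distance",
    "build_iidm",
    "iidm_feature",
    "switching_count",
    "largest_cosine",
    "axial_density_map",
    "IIDMFeaturizer",
]

#: O-H bond cutoff (Angstrom) used to assign intramolecular hydrogens.
OH_BOND_CUTOFF = 1.2


@dataclass(frozen=True)
class IIDMSpec:
    """Which neighbors enter the truncated matrix.

    ``counts`` maps species to the number of closest atoms kept as rows
    (e.g. ``{"Cl": 1, "O": 15, "H": 30}`` for an Na anchor); its key order is
    the canonical species order used by all sorts.  ``column_counts``
    (defaulting to ``counts``) truncates the per-row columns.  Hydrogens
    bonded to a row oxygen are excluded from that row's H columns unless
    ``exclude_intramolecular_h`` is switched off.
    """

    anchor: str
    counts: dict[str, int] = field(
        default_factory=lambda: {"Cl": 1, "O": 15, "H": 30}
    )
    column_counts: dict[str, int] | None = None
    exclude_intramolecular_h: bool = True

    def __post_init__(self) -> None:
        for sp, c in self.counts.items():
            if c < 1:
                raise ValueError(f"count for species {sp!r} must be positive")
        if self.column_counts is not None:
            for sp, c in self.column_counts.items():
                if c < 1:
                    raise ValueError(f"column count for {sp!r} must be positive")

    @property
    def effective_column_counts(self) -> dict[str, int]:
        return self.column_counts if self.column_counts is not None else self.counts


@dataclass
class IIDMatrix:
    """Truncated, species/distance-sorted distance matrix with named entries."""

    anchor: str
    row_labels: list[str]
    entries: dict[str, float]

    def __getitem__(self, name: str) -> float:
        if name not in self.entries:
            raise ValueError(
                f"feature {name!r} not in matrix (rank beyond truncation?)"
            )
        return self.entries[name]


def min_image_distance(a, b, box=None) -> float:
    """Euclidean distance under the per-axis minimum-image convention."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if box is not None:
        box = np.asarray(box, dtype=float)
        d -= box * np.round(d / box)
    return float(np.linalg.norm(d))


def _pair_displacements(coords: np.ndarray, ref: np.ndarray, box) -> np.ndarray:
    d = coords - ref
    if box is not None:
        d -= box * np.round(d / box)
    return d


def _distances_to(cfg: Configuration, idx: int) -> np.ndarray:
    d = _pair_displacements(cfg.coords, cfg.coords[idx], cfg.box)
    return np.linalg.norm(d, axis=1)


def _resolve_anchor(cfg: Configuration, anchor: str) -> int:
    hits = [i for i, s in enumerate(cfg.species) if s == anchor]
    if not hits:
        raise ValueError(f"anchor species {anchor!r} not found in configuration")
    return hits[0]


def build_iidm(cfg: Configuration, spec: IIDMSpec) -> IIDMatrix:
    """Build the truncated index-invariant distance matrix around the anchor.

    Rows: for each species (in ``spec.counts`` order) the requested number of
    closest atoms to the anchor.  Columns of row atom Yi: the anchor plus all
    row atoms, re-sorted by species and by distance to Yi, truncated per
    species.  Ties in distance are broken by coordinates (lexicographic), so
    the result is invariant under any permutation of the input atom order.
    """
    species = np.array(cfg.species)
    anchor_idx = _resolve_anchor(cfg, spec.anchor)
    d_anchor = _distances_to(cfg, anchor_idx)

    def sort_by_distance(indices: np.ndarray, dist: np.ndarray) -> np.ndarray:
        # lexicographic tie-break on coordinates for bit-exact index invariance
        keys = np.lexsort(
            (
                cfg.coords[indices, 2],
                cfg.coords[indices, 1],
                cfg.coords[indices, 0],
                np.round(dist[indices], 12),
            )
        )
        return indices[keys]

    row_atoms: list[tuple[str, int, int]] = []  # (species, rank 1-based, atom idx)
    for sp, count in spec.counts.items():
        cand = np.where((species == sp) & (np.arange(len(species)) != anchor_idx))[0]
        if cand.size < count:
            raise ValueError(
                f"need {count} atoms of species {sp!r}, configuration has {cand.size}"
            )
        cand = sort_by_distance(cand, d_anchor)[:count]
        for rank, ai in enumerate(cand, start=1):
            row_atoms.append((sp, rank, int(ai)))

    entries: dict[str, float] = {}
    row_labels: list[str] = []
    X = spec.anchor
    for sp, rank, ai in row_atoms:
        row_labels.append(f"{sp}{rank}")
        entries[f"{X}{sp}{rank}"] = float(d_anchor[ai])

    # intramolecular H assignment: each row O owns the (up to 2) H atoms
    # within the O-H bond cutoff
    intramolecular: dict[int, set[int]] = {}
    if spec.exclude_intramolecular_h:
        h_rows = [ai for sp, _, ai in row_atoms if sp == "H"]
        for sp, _, ai in row_atoms:
            if sp != "O":
                continue
            d_row = _distances_to(cfg, ai)
            bonded = [h for h in h_rows if d_row[h] <= OH_BOND_CUTOFF]
            bonded.sort(key=lambda h: d_row[h])
            intramolecular[ai] = set(bonded[:2])

    # column pool: anchor + all row atoms
    pool = [(spec.anchor, anchor_idx)] + [(sp, ai) for sp, _, ai in row_atoms]
    col_counts = spec.effective_column_counts
    col_species_order = list(dict.fromkeys([spec.anchor] + list(spec.counts)))
    for sp_row, rank_row, ai in row_atoms:
        d_row = _distances_to(cfg, ai)
        excluded = intramolecular.get(ai, set())
        for sp_col in col_species_order:
            cand = np.array(
                [
                    j
                    for s, j in pool
                    if s == sp_col and j != ai and j not in (excluded if sp_col == "H" else ())
                ],
                dtype=int,
            )
            if cand.size == 0:
                continue
            cand = sort_by_distance(cand, d_row)
            limit = col_counts.get(sp_col, cand.size)
            for rank_col, aj in enumerate(cand[:limit], start=1):
                entries[f"{X}{sp_row}{rank_row}{sp_col}{rank_col}"] = float(d_row[aj])

    return IIDMatrix(anchor=spec.anchor, row_labels=row_labels, entries=entries)


def _feature_regex(spec: IIDMSpec) -> re.Pattern:
    symbols = sorted(
        set([spec.anchor] + list(spec.counts)), key=len, reverse=True
    )
    sym = "|".join(re.escape(s) for s in symbols)
    return re.compile(
        rf"^(?P<X>{re.escape(spec.anchor)})(?P<Y>{sym})(?P<i>\d+)"
        rf"(?:(?P<Z>{sym})(?P<j>\d+))?$"
    )


def iidm_feature(cfg: Configuration, spec: IIDMSpec, name: str) -> float:
    """Evaluate one named IIDM entry (``XYi`` or ``XYiZj``)."""
    if _feature_regex(spec).match(name) is None:
        raise ValueError(f"malformed IIDM feature name {name!r}")
    return build_iidm(cfg, spec)[name]


def switching_function(d: np.ndarray, r0: float, steepness: float) -> np.ndarray:
    """Smooth indicator: 1 at short distance, 1/2 at r0, -> 0 beyond.

    Logistic form f(d) = 1 / (1 + exp(steepness * (d - r0))).
    """
    return 1.0 / (1.0 + np.exp(np.clip(steepness * (d - r0), -500, 500)))


def _resolve_atom(cfg: Configuration, sel) -> int:
    if isinstance(sel, (int, np.integer)):
        return int(sel)
    return _resolve_anchor(cfg, sel)


def switching_count(
    cfg: Configuration,
    center_a,
    center_b,
    r0: float,
    steepness: float,
    candidate_species: str = "O",
) -> float:
    """Smooth count of atoms simultaneously in both centers' shells.

    Sum over candidate atoms of f(d_a) * f(d_b); fractional by construction
    (a water exactly at r0 from both ions contributes 1/4).
    """
    if r0 <= 0 or steepness <= 0:
        raise ValueError("r0 and steepness must be positive")
    ia, ib = _resolve_atom(cfg, center_a), _resolve_atom(cfg, center_b)
    cand = [
        i
        for i, s in enumerate(cfg.species)
        if s == candidate_species and i not in (ia, ib)
    ]
    if not cand:
        return 0.0
    da = _distances_to(cfg, ia)[cand]
    db = _distances_to(cfg, ib)[cand]
    return float(
        np.sum(switching_function(da, r0, steepness) * switching_function(db, r0, steepness))
    )


def largest_cosine(
    cfg: Configuration,
    apex,
    arm1,
    candidate_species: str,
    shell_radius: float,
    shell_center=None,
) -> float:
    """Maximum cosine of the apex angle over shell candidates.

    The angle is formed at ``apex`` between the directions to ``arm1`` and to
    each candidate atom of ``candidate_species`` within ``shell_radius`` of
    ``shell_center`` (the apex atom by default).
    """
    i_apex, i_arm = _resolve_atom(cfg, apex), _resolve_atom(cfg, arm1)
    i_shell = i_apex if shell_center is None else _resolve_atom(cfg, shell_center)
    d_shell = _distances_to(cfg, i_shell)
    cand = [
        i
        for i, s in enumerate(cfg.species)
        if s == candidate_species
        and i not in (i_apex, i_arm)
        and d_shell[i] <= shell_radius
    ]
    if not cand:
        raise ValueError(
            f"no {candidate_species!r} atoms within {shell_radius} of the shell center"
        )
    v1 = _pair_displacements(
        cfg.coords[i_arm][None, :], cfg.coords[i_apex], cfg.box
    )[0]
    vc = _pair_displacements(cfg.coords[cand], cfg.coords[i_apex], cfg.box)
    cosines = (vc @ v1) / (np.linalg.norm(vc, axis=1) * np.linalg.norm(v1))
    return float(cosines.max())


def axial_density_map(
    cfgs: Sequence[Configuration],
    anchor_pair: tuple,
    selector: tuple[str, int],
    bins: tuple[int, int] = (50, 25),
    extent: tuple[tuple[float, float], tuple[float, float]] | None = None,
):
    """Cylindrical density of selected atoms around the anchor-pair axis.

    ``selector = (species, k)`` picks, per frame, the k closest atoms of that
    species to the first anchor.  Axial coordinate z runs along the
    first-to-second anchor axis with origin at the first anchor; radial
    coordinate rho is the distance from the axis.  The returned density is
    normalized per configuration: sum(density * cell_area) = k.

    Returns ``(z_edges, rho_edges, density)``.
    """
    if not cfgs:
        raise ValueError("no configurations")
    species_sel, k = selector
    pts_z, pts_r = [], []
    for cfg in cfgs:
        ia = _resolve_atom(cfg, anchor_pair[0])
        ib = _resolve_atom(cfg, anchor_pair[1])
        axis = _pair_displacements(
            cfg.coords[ib][None, :], cfg.coords[ia], cfg.box
        )[0]
        norm = np.linalg.norm(axis)
        if norm < 1e-10:
            raise ValueError("degenerate axis: anchor atoms coincide")
        e = axis / norm
        cand = [
            i for i, s in enumerate(cfg.species) if s == species_sel and i not in (ia, ib)
        ]
        if len(cand) < k:
            raise ValueError(
                f"need {k} atoms of {species_sel!r}, frame has {len(cand)}"
            )
        disp = _pair_displacements(cfg.coords[cand], cfg.coords[ia], cfg.box)
        dist = np.linalg.norm(disp, axis=1)
        sel = np.argsort(dist, kind="stable")[:k]
        z = disp[sel] @ e
        rho = np.linalg.norm(disp[sel] - np.outer(z, e), axis=1)
        pts_z.append(z)
        pts_r.append(rho)
    z_all = np.concatenate(pts_z)
    r_all = np.concatenate(pts_r)
    if extent is None:
        extent = ((z_all.min(), z_all.max()), (0.0, r_all.max()))
    counts, z_edges, rho_edges = np.histogram2d(
        z_all, r_all, bins=bins, range=extent
    )
    cell = (z_edges[1] - z_edges[0]) * (rho_edges[1] - rho_edges[0])
    density = counts / (len(cfgs) * cell)
    return z_edges, rho_edges, density


class IIDMFeaturizer(TransformerMixin, BaseEstimator):
    """Transform configurations into IIDM feature vectors (sklearn API).

    Parameters mirror :class:`IIDMSpec`; ``features`` selects named entries
    (default: every entry of the truncated matrix, in matrix order).
    """

    def __init__(
        self,
        anchor: str = "Na",
        counts: dict[str, int] | None = None,
        column_counts: dict[str, int] | None = None,
        features: Sequence[str] | None = None,
        exclude_intramolecular_h: bool = True,
    ):
        self.anchor = anchor
        self.counts = counts
        self.column_counts = column_counts
        self.features = features
        self.exclude_intramolecular_h = exclude_intramolecular_h

    def _spec(self) -> IIDMSpec:
        kwargs = {}
        if self.counts is not None:
            kwargs["counts"] = self.counts
        return IIDMSpec(
            anchor=self.anchor,
            column_counts=self.column_counts,
            exclude_intramolecular_h=self.exclude_intramolecular_h,
            **kwargs,
        )

    def fit(self, X, y=None):
        spec = self._spec()
        if self.features is not None:
            self.feature_names_ = list(self.features)
        else:
            first = X[0] if not isinstance(X, Configuration) else X
            self.feature_names_ = list(build_iidm(first, spec).entries)
        return self

    def transform(self, X) -> np.ndarray:
        if isinstance(X, Configuration):
            X = [X]
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        spec = self._spec()
        out = np.empty((len(X), len(self.feature_names_)))
        for i, cfg in enumerate(X):
            matrix = build_iidm(cfg, spec)
            out[i] = [matrix[name] for name in self.feature_names_]
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
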