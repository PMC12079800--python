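"""Domain types and plain-text I/O for path ensembles and configurations.

A *path* is one short trajectory sampled by a transition-interface scheme:
a time series of the order parameter lambda (here, typically an interionic
distance in Angstrom) plus any number of collective-variable (CV) columns,
together with ensemble metadata.  Paths live in nested ensembles labelled
``"0-"`` (the reactant-interior ensemble) and ``"0+", "1+", ...`` (paths
required to cross interface lambda_i).

Units are fixed throughout the package: lengths in Angstrom, times in
femtoseconds.  Rates are converted to ns^-1 only at the reporting layer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Frame",
    "PathRecord",
    "InterfaceSet",
    "Configuration",
    "PPAQuery",
    "PathFormatError",
    "read_path_table",
    "write_path_table",
    "read_xyz",
    "write_xyz",
    "subsample_chain",
    "ensemble_sort_key",
]

#: significant digits used by all text writers; round-trips are bit-stable
#: at analysis tolerance.
WRITER_PRECISION = 10

_META_COLUMNS = ["path_id", "ensemble", "mc_cycle", "weight", "start_side", "end_side"]
_FRAME_FIXED = ["path_id", "frame", "time_fs", "lambda"]


class PathFormatError(ValueError):
    """Raised when a path table or XYZ file violates the format contract."""


@dataclass(frozen=True)
class Frame:
    """A single stored time slice of a path."""

    time: float
    lam: float
    cvs: Mapping[str, float]


@dataclass
class PathRecord:
    """One sampled path with its ensemble metadata.

    Frames are stored columnar (``times``, ``lam``, ``cvs``) for speed; the
    ``frames`` property yields :class:`Frame` views.
    """

    path_id: str
    ensemble: str
    mc_cycle: int
    weight: float
    times: np.ndarray
    lam: np.ndarray
    cvs: dict[str, np.ndarray]
    start_side: str = "A"
    end_side: str = "A"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.cvs = {k: np.asarray(v, dtype=float) for k, v in self.cvs.items()}
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.times.size == 0:
            raise PathFormatError(f"path {self.path_id!r}: no frames")
        if self.lam.shape != self.times.shape:
            raise PathFormatError(f"path {self.path_id!r}: lambda/time length mismatch")
        for name, col in self.cvs.items():
            if col.shape != self.times.shape:
                raise PathFormatError(
                    f"path {self.path_id!r}: CV {name!r} has {col.size} values "
                    f"for {self.times.size} frames"
                )
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            idx = int(np.argmax(dt <= 0)) + 1
            raise PathFormatError(
                f"path {self.path_id!r}: time not strictly increasing at frame {idx}"
            )
        if not self.weight > 0:
            raise PathFormatError(f"path {self.path_id!r}: weight must be > 0")
        if self.mc_cycle < 0:
            raise PathFormatError(f"path {self.path_id!r}: mc_cycle must be >= 0")
        for side in (self.start_side, self.end_side):
            if side not in ("A", "B"):
                raise PathFormatError(
                    f"path {self.path_id!r}: side {side!r} must be 'A' or 'B'"
                )

    # -- convenience -----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def cv_names(self) -> list[str]:
        return list(self.cvs)

    @property
    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield Frame(
                time=float(self.times[i]),
                lam=float(self.lam[i]),
                cvs={k: float(v[i]) for k, v in self.cvs.items()},
            )

    @property
    def duration(self) -> float:
        """Path duration in fs, excluding one shared endpoint per junction.

        Defined as ``times[-1] - times[0]`` so that durations of consecutive
        segments of a chopped long trajectory sum to the trajectory duration.
        """
        return float(self.times[-1] - self.times[0])

    def lambda_max(self) -> float:
        return float(self.lam.max())

    def with_weight(self, weight: float) -> "PathRecord":
        return replace(self, weight=weight)

    @classmethod
    def from_frames(
        cls,
        path_id: str,
        ensemble: str,
        mc_cycle: int,
        weight: float,
        frames: Sequence[Frame],
        start_side: str = "A",
        end_side: str = "A",
    ) -> "PathRecord":
        if not frames:
            raise PathFormatError(f"path {path_id!r}: no frames")
        names = list(frames[0].cvs)
        for i, f in enumerate(frames):
            if list(f.cvs) != names:
                raise PathFormatError(
                    f"path {path_id!r}: frame {i} has CV keys {list(f.cvs)!r}, "
                    f"expected {names!r}"
                )
        return cls(
            path_id=path_id,
            ensemble=ensemble,
            mc_cycle=mc_cycle,
            weight=weight,
            times=np.array([f.time for f in frames]),
            lam=np.array([f.lam for f in frames]),
            cvs={n: np.array([f.cvs[n] for f in frames]) for n in names},
            start_side=start_side,
            end_side=end_side,
        )


@dataclass(frozen=True)
class InterfaceSet:
    """Strictly increasing interface positions lambda_0 ... lambda_n (Angstrom).

    lambda_0 = lambda_A bounds the reactant state A, lambda_n = lambda_B the
    product state B.
    """

    lambdas: tuple[float, ...]

    def __init__(self, lambdas: Sequence[float]):
        object.__setattr__(self, "lambdas", tuple(float(x) for x in lambdas))
        if len(self.lambdas) < 2:
            raise ValueError("InterfaceSet needs at least 2 interfaces")
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValueError(f"interfaces must be strictly increasing: {self.lambdas}")

    @property
    def lam_A(self) -> float:
        return self.lambdas[0]

    @property
    def lam_B(self) -> float:
        return self.lambdas[-1]

    def __len__(self) -> int:
        return len(self.lambdas)


@dataclass
class Configuration:
    """An atomic configuration: species symbols, coordinates (Angstrom) and an
    optional orthorhombic box (edge lengths, Angstrom)."""

    species: list[str]
    coords: np.ndarray
    box: np.ndarray | None = None
    comment: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.species) != self.coords.shape[0]:
            raise ValueError(
                f"{len(self.species)} species for {self.coords.shape[0]} coordinates"
            )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise ValueError(f"box edges must be positive: {self.box}")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class PPAQuery:
    """A (lambda_c, lambda_r) query: CVs are sampled at the first crossing of
    lambda_c and labelled by whether the path also reaches lambda_r."""

    lam_c: float
    lam_r: float
    lam_A: float = -np.inf

    def __post_init__(self) -> None:
        if not (self.lam_A <= self.lam_c <= self.lam_r):
            raise ValueError(
                f"require lam_A <= lam_c <= lam_r, got "
                f"({self.lam_A}, {self.lam_c}, {self.lam_r})"
            )


# ---------------------------------------------------------------------------
# ensemble ordering


def ensemble_sort_key(label: str) -> tuple[int, int]:
    """Sort key placing '0-' first, then '0+', '1+', ... numerically."""
    m = re.fullmatch(r"(\d+)([+-])", label)
    if m is None:
        raise PathFormatError(f"unrecognized ensemble label {label!r}")
    idx, sign = int(m.group(1)), m.group(2)
    return (-1, 0) if sign == "-" else (idx, 1)


def ensemble_interface_index(label: str) -> int | None:
    """Interface index j for ensemble '[j+]'; None for '0-'."""
    m = re.fullmatch(r"(\d+)\+", label)
    return int(m.group(1)) if m else None


# ---------------------------------------------------------------------------
# path tables


def read_path_table(path_file, meta_file) -> list[PathRecord]:
    """Read a frame table + metadata table into validated PathRecords.

    Frame table columns: ``path_id,frame,time_fs,lambda,<cv...>``; metadata
    columns: ``path_id,ensemble,mc_cycle,weight,start_side,end_side``.
    Returned paths are ordered by (ensemble, mc_cycle).
    """
    frames = pd.read_csv(path_file, dtype={"path_id": str})
    meta = pd.read_csv(meta_file, dtype={"path_id": str})
    for col in _FRAME_FIXED:
        if col not in frames.columns:
            raise PathFormatError(f"frame table missing column {col!r}")
    for col in _META_COLUMNS:
        if col not in meta.columns:
            raise PathFormatError(f"metadata table missing column {col!r}")
    if meta["path_id"].duplicated().any():
        dup = meta.loc[meta["path_id"].duplicated(), "path_id"].iloc[0]
        raise PathFormatError(f"duplicate path_id {dup!r} in metadata table")
    known = set(meta["path_id"])
    unknown = set(frames["path_id"]) - known
    if unknown:
        raise PathFormatError(
            f"frame table references unknown path_id {sorted(unknown)[0]!r}"
        )
    missing = known - set(frames["path_id"])
    if missing:
        raise PathFormatError(f"no frames for path_id {sorted(missing)[0]!r}")

    cv_names = [c for c in frames.columns if c not in _FRAME_FIXED]
    records = []
    meta = meta.set_index("path_id")
    for pid, grp in frames.groupby("path_id", sort=False):
        grp = grp.sort_values("frame")
        row = meta.loc[pid]
        records.append(
            PathRecord(
                path_id=str(pid),
                ensemble=str(row["ensemble"]),
                mc_cycle=int(row["mc_cycle"]),
                weight=float(row["weight"]),
                times=grp["time_fs"].to_numpy(),
                lam=grp["lambda"].to_numpy(),
                cvs={n: grp[n].to_numpy() for n in cv_names},
                start_side=str(row["start_side"]),
                end_side=str(row["end_side"]),
            )
        )
    records.sort(key=lambda p: (ensemble_sort_key(p.ensemble), p.mc_cycle))
    return records


def write_path_table(paths: Sequence[PathRecord], path_file, meta_file) -> None:
    """Write paths as frame + metadata CSVs readable by :func:`read_path_table`.

    Numeric text uses 10 significant digits so read(write(x)) is bit-stable at
    analysis tolerance.
    """
    if not paths:
        raise ValueError("no paths to write")
    fmt = f"%.{WRITER_PRECISION}g"
    cv_names = paths[0].cv_names
    frame_parts = []
    meta_rows = []
    for p in paths:
        if p.cv_names != cv_names:
            raise ValueError(
                f"path {p.path_id!r} has CV columns {p.cv_names}, expected {cv_names}"
            )
        part = pd.DataFrame(
            {
                "path_id": p.path_id,
                "frame": np.arange(p.n_frames),
                "time_fs": p.times,
                "lambda": p.lam,
                **{n: p.cvs[n] for n in cv_names},
            }
        )
        frame_parts.append(part)
        meta_rows.append(
            {
                "path_id": p.path_id,
                "ensemble": p.ensemble,
                "mc_cycle": p.mc_cycle,
                "weight": p.weight,
                "start_side": p.start_side,
                "end_side": p.end_side,
            }
        )
    pd.concat(frame_parts).to_csv(path_file, index=False, float_format=fmt)
    pd.DataFrame(meta_rows).to_csv(meta_file, index=False, float_format=fmt)


def subsample_chain(paths: Sequence[PathRecord], stride: int) -> list[PathRecord]:
    """Keep every ``stride``-th path in MC-cycle order within each ensemble.

    Rank 0 (the first path of each ensemble) is always kept, giving
    ceil(N / stride) survivors per ensemble.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    by_ens: dict[str, list[PathRecord]] = {}
    for p in paths:
        by_ens.setdefault(p.ensemble, []).append(p)
    out: list[PathRecord] = []
    for ens in sorted(by_ens, key=ensemble_sort_key):
        chain = sorted(by_ens[ens], key=lambda p: p.mc_cycle)
        out.extend(chain[::stride])
    return out


# ---------------------------------------------------------------------------
# XYZ configurations

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_BOX_RE = re.compile(r"box=([0-9eE+.,\-]+)")


def _parse_box(comment: str) -> np.ndarray | None:
    m = _LATTICE_RE.search(comment)
    if m:
        vals = np.array([float(x) for x in m.group(1).split()])
        if vals.size != 9:
            raise PathFormatError(f"Lattice needs 9 numbers, got {vals.size}")
        cell = vals.reshape(3, 3)
        off = cell - np.diag(np.diag(cell))
        if np.any(np.abs(off) > 1e-10):
            raise PathFormatError("only orthorhombic (diagonal) lattices supported")
        return np.diag(cell).copy()
    m = _BOX_RE.search(comment)
    if m:
        vals = np.array([float(x) for x in m.group(1).split(",")])
        if vals.size != 3:
            raise PathFormatError(f"box= needs 3 numbers, got {vals.size}")
        return vals
    return None


def read_xyz(file) -> list[Configuration]:
    """Read a (multi-frame, possibly extended) XYZ file.

    The orthorhombic box is taken from the comment line when present, either
    as ``Lattice="Lx 0 0 0 Ly 0 0 0 Lz"`` or ``box=Lx,Ly,Lz``.
    """
    if hasattr(file, "read"):
        lines = file.read().splitlines()
    else:
        with open(file) as fh:
            lines = fh.read().splitlines()
    configs: list[Configuration] = []
    i, frame = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise PathFormatError(
                f"frame {frame}: expected atom count, got {lines[i]!r}"
            ) from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        atom_lines = lines[i + 2 : i + 2 + n]
        if len(atom_lines) < n or any(len(l.split()) < 4 for l in atom_lines):
            raise PathFormatError(f"frame {frame}: declared {n} atoms but fewer listed")
        species, coords = [], []
        for l in atom_lines:
            parts = l.split()
            species.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        configs.append(
            Configuration(
                species=species,
                coords=np.array(coords),
                box=_parse_box(comment),
                comment=comment,
            )
        )
        i += 2 + n
        frame += 1
    return configs


def write_xyz(configs: Sequence[Configuration], file) -> None:
    """Write configurations as extended XYZ (box on the comment line)."""
    fmt = f"%.{WRITER_PRECISION}g"

    def emit(fh):
        for cfg in configs:
            fh.write(f"{cfg.n_atoms}\n")
            if cfg.box is not None:
                bx, by, bz = (fmt % v for v in cfg.box)
                fh.write(f'Lattice="{bx} 0 0 0 {by} 0 0 0 {bz}"\n')
            else:
                fh.write(f"{cfg.comment}\n")
            for s, (x, y, z) in zip(cfg.species, cfg.coords):
                fh.write(f"{s} {fmt % x} {fmt % y} {fmt % z}\n")

    if hasattr(file, "write"):
        emit(file)
    else:
        with open(file, "w") as fh:
            emit(fh)
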