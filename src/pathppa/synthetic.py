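"""Synthetic path ensembles and labelled CV samples with known ground truth.

Every analysis stage in this package has a statistical contract; this module
provides the oracles.  A long overdamped Langevin trajectory on a 2-D double
well stands in for the "effectively infinite MD run": chopping it into
A-to-A / A-to-B segments gives an unbiased path ensemble whose crossing
probabilities, flux and rate can be counted directly.  Filtering those
segments per interface (with recorded subsampling rates) emulates nested
interface ensembles for the WHAM oracle, and parametric reactive/unreactive
mixtures give samples whose true predictive capacity is computable by
quadrature.

Toy units: kT = 1, dimensionless coordinates; the time step plays the role
of the femtosecond in the I/O layer, which is irrelevant for analysis
correctness (the analysis is unit-agnostic).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit
from scipy.integrate import quad

from .crossings import SampleSet
from .paths import Configuration, InterfaceSet, PathRecord, PPAQuery

__all__ = [
    "DoubleWellParams",
    "MixtureSpec",
    "Trajectory",
    "DirectCounts",
    "IntegrationError",
    "langevin_doublewell",
    "chop_trajectory",
    "tis_like_subsets",
    "sample_mixture",
    "mixture_true_capacity",
    "gaussian_reference_specs",
    "random_mixture_spec",
    "toy_solvated_pair",
]


class IntegrationError(RuntimeError):
    """The integrator diverged; use a smaller time step."""


@dataclass(frozen=True)
class DoubleWellParams:
    """Overdamped dynamics on V(x, y) = h (x^2 - 1)^2 + y^2/2 + g x y.

    ``x`` is the order parameter; ``y`` is a coupled hidden coordinate that
    is genuinely predictive of barrier crossing when g != 0.  A third,
    independent standard-normal noise channel is recorded as an intentionally
    uninformative CV.  kT = 1.
    """

    barrier_height: float = 3.0
    coupling: float = 1.0
    friction: float = 1.0
    temperature: float = 1.0
    dt: float = 1e-3
    lam_A: float = -0.7
    lam_B: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.barrier_height <= 0:
            raise ValueError("barrier_height must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.lam_A < self.lam_B:
            raise ValueError("lam_A must be below lam_B")


@dataclass
class Trajectory:
    """A long, uniformly sampled (x, y) trajectory plus a noise CV channel."""

    x: np.ndarray
    y: np.ndarray
    noise: np.ndarray
    dt: float
    params: DoubleWellParams

    @property
    def n_steps(self) -> int:
        return self.x.size

    @property
    def total_time(self) -> float:
        return (self.n_steps - 1) * self.dt


@dataclass
class DirectCounts:
    """Brute-force statistics counted on the uncut trajectory.

    These are the oracles for the reweighting stack: ``crossing_probability``
    is the fraction of A-exit segments whose maximum reaches lambda, ``flux``
    the number of segments per unit time spent in the A cycle, and ``rate``
    the number of A-to-B transitions per unit A-cycle time.  Times in the
    same units as the trajectory (dt plays the fs).
    """

    lam_max: np.ndarray
    durations_0plus: np.ndarray
    durations_0minus: np.ndarray
    n_transitions: int

    @property
    def n_segments(self) -> int:
        return self.lam_max.size

    @property
    def cycle_time(self) -> float:
        return float(self.durations_0plus.sum() + self.durations_0minus.sum())

    def crossing_probability(self, lam: float) -> float:
        return float(np.mean(self.lam_max >= lam))

    @property
    def flux(self) -> float:
        return self.n_segments / self.cycle_time

    @property
    def rate(self) -> float:
        return self.n_transitions / self.cycle_time


@njit(cache=True)
def _integrate(n_steps, h, g, gamma, kT, dt, x0, y0, seed):  # pragma: no cover
    np.random.seed(seed)
    x = np.empty(n_steps)
    y = np.empty(n_steps)
    x[0], y[0] = x0, y0
    amp = np.sqrt(2.0 * kT * dt / gamma)
    ok = True
    for i in range(1, n_steps):
        xi, yi = x[i - 1], y[i - 1]
        fx = -(4.0 * h * xi * (xi * xi - 1.0) + g * yi)
        fy = -(yi + g * xi)
        x[i] = xi + fx * dt / gamma + amp * np.random.normal()
        y[i] = yi + fy * dt / gamma + amp * np.random.normal()
        if abs(x[i]) > 10.0:
            ok = False
            break
    return x, y, ok


def langevin_doublewell(
    params: DoubleWellParams, n_steps: int, store_noise: bool = True
) -> Trajectory:
    """Integrate the double well with Euler-Maruyama; seeded, reproducible."""
    x, y, ok = _integrate(
        int(n_steps),
        params.barrier_height,
        params.coupling,
        params.friction,
        params.temperature,
        params.dt,
        -1.0,
        0.0,
        params.seed % (2**31 - 1),
    )
    if not ok:
        raise IntegrationError(
            "trajectory diverged (|x| > 10); use a smaller dt"
        )
    rng = np.random.default_rng(params.seed + 1)
    noise = rng.standard_normal(int(n_steps)) if store_noise else np.zeros(int(n_steps))
    return Trajectory(x=x, y=y, noise=noise, dt=params.dt, params=params)


def chop_trajectory(
    traj: Trajectory, lam_A: float | None = None, lam_B: float | None = None
) -> tuple[list[PathRecord], DirectCounts]:
    """Cut the long trajectory into [0+] and [0-] segments.

    A [0+] segment runs from the last frame inside A (x < lam_A) through the
    excursion to the first frame back inside A or inside B (x >= lam_B);
    consecutive segments share their junction frame, so durations add up to
    the covered trajectory time.  [0-] segments are the interior-of-A pieces
    between them.  After a B entry, chopping resumes at the next A visit.

    Returns the segments (unit weights, CVs ``y`` and ``noise``) and the
    direct-count oracle summaries.
    """
    lam_A = traj.params.lam_A if lam_A is None else lam_A
    lam_B = traj.params.lam_B if lam_B is None else lam_B
    x = traj.x
    n = x.size
    in_A = x < lam_A
    in_B = x >= lam_B
    if not in_A.any():
        raise ValueError("trajectory never visits state A")

    # A-exit junctions: last in-A frame before leaving A
    exits = np.where(in_A[:-1] & ~in_A[1:])[0]
    # frames where an excursion can terminate (back in A, or in B)
    stop_idx = np.where(in_A | in_B)[0]

    dt = traj.dt
    times_full = np.arange(n) * dt
    paths: list[PathRecord] = []
    seg_max: list[float] = []
    dur_plus: list[float] = []
    dur_minus: list[float] = []
    n_trans = 0
    mc_plus = mc_minus = 0

    def make_record(i0: int, i1: int, ensemble: str, mc: int, end: str):
        sl = slice(i0, i1 + 1)  # views into the full trajectory, no copies
        return PathRecord(
            path_id=f"{ensemble}_{mc}",
            ensemble=ensemble,
            mc_cycle=mc,
            weight=1.0,
            times=times_full[sl],
            lam=x[sl],
            cvs={"y": traj.y[sl], "noise": traj.noise[sl]},
            start_side="A",
            end_side=end,
        )

    i = int(np.argmax(in_A))  # first A visit: start of the first [0-] stretch
    for j in exits:
        if j < i:
            continue  # exit during a skipped B sojourn
        pos = np.searchsorted(stop_idx, j + 1)
        if pos >= stop_idx.size:
            break  # excursion never terminates; drop incomplete tail
        k = int(stop_idx[pos])
        end_side = "B" if in_B[k] else "A"
        # the [0-] stretch [i, j] shares frame j with the [0+] path [j, k];
        # a touch-and-go A visit gives a legitimate single-frame [0-] path
        paths.append(make_record(i, int(j), "0-", mc_minus, "A"))
        dur_minus.append((int(j) - i) * dt)
        mc_minus += 1
        paths.append(make_record(int(j), k, "0+", mc_plus, end_side))
        seg_max.append(float(x[j : k + 1].max()))
        dur_plus.append((k - int(j)) * dt)
        mc_plus += 1
        if end_side == "B":
            n_trans += 1
            rest = in_A[k:]
            if not rest.any():
                break
            i = k + int(np.argmax(rest))  # resume at the next A visit
        else:
            i = k
    if not seg_max:
        raise ValueError("no complete A-exit segments found")
    counts = DirectCounts(
        lam_max=np.array(seg_max),
        durations_0plus=np.array(dur_plus),
        durations_0minus=np.array(dur_minus),
        n_transitions=n_trans,
    )
    return paths, counts


def tis_like_subsets(
    paths: Sequence[PathRecord],
    interfaces: InterfaceSet,
    rates: Sequence[float] | None = None,
    seed: int = 0,
    disjoint: bool = False,
) -> tuple[list[PathRecord], list[float]]:
    """Emulate nested interface ensembles by filtered subsampling.

    For each interface lambda_i (all but the last), the paths with
    lambda_max >= lambda_i are subsampled at ``rates[i]`` (default: aim for
    roughly the population of the deepest ensemble, capped at 1) and
    relabelled ensemble ``"i+"``.  The recorded rates make the ground-truth
    weights known for oracle comparisons.  Deterministic given ``seed``.

    With ``disjoint=True`` the segments are first partitioned round-robin
    into one group per ensemble, so no segment appears in two ensembles —
    this emulates statistically independent per-ensemble simulations, which
    keeps chi-square comparisons against direct counting honest.
    """
    if len(interfaces) < 2:
        raise ValueError("need at least 2 interfaces")
    plus = [p for p in paths if p.ensemble.endswith("+")]
    if not plus:
        raise ValueError("no [0+]-style segments to subset")
    maxima = np.array([p.lambda_max() for p in plus])
    n_int = len(interfaces) - 1
    if disjoint:
        group = np.random.default_rng(seed + 1).integers(0, n_int, size=len(plus))
        members = [
            np.where((maxima >= interfaces.lambdas[i]) & (group == i))[0]
            for i in range(n_int)
        ]
    else:
        members = [
            np.where(maxima >= interfaces.lambdas[i])[0] for i in range(n_int)
        ]
    if any(m.size == 0 for m in members):
        empty = next(i for i, m in enumerate(members) if m.size == 0)
        raise ValueError(
            f"no segment reaches interface {interfaces.lambdas[empty]} "
            f"(ensemble [{empty}+] would be empty)"
        )
    if rates is None:
        if disjoint:
            rates = [1.0] * n_int
        else:
            target = max(members[-1].size, 200)
            rates = [min(1.0, target / m.size) for m in members]
    if len(rates) != n_int:
        raise ValueError(f"need {n_int} rates, got {len(rates)}")
    rng = np.random.default_rng(seed)
    out: list[PathRecord] = []
    for i, (m, rate) in enumerate(zip(members, rates)):
        keep = m[rng.random(m.size) < rate] if rate < 1.0 else m
        if keep.size == 0:
            raise ValueError(f"ensemble [{i}+] empty after subsampling")
        for idx in keep:
            p = plus[idx]
            out.append(
                replace(
                    p,
                    path_id=f"{p.path_id}_e{i}",
                    ensemble=f"{i}+",
                    weight=1.0,
                )
            )
    return out, list(rates)


# ---------------------------------------------------------------------------
# parametric mixtures with quadrature ground truth


@dataclass(frozen=True)
class MixtureSpec:
    """Gaussian mixtures for the reactive and unreactive CV densities.

    ``components_r`` / ``components_u`` are (mean, sd, mass) triples; the r
    masses sum to p_bar and the u masses to 1 - p_bar (total mass 1).
    ``weight_law`` is "uniform" or ("lognormal", sigma) for skewed path
    weights with unit mean.
    """

    components_r: tuple[tuple[float, float, float], ...]
    components_u: tuple[tuple[float, float, float], ...]
    n: int = 10000
    weight_law: str | tuple[str, float] = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        for mean, sd, mass in self.components_r + self.components_u:
            if sd <= 0:
                raise ValueError("component sd must be positive")
            if mass <= 0:
                raise ValueError("component mass must be positive")
        total = self.mass_r + self.mass_u
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component masses must sum to 1, got {total}")
        if not 0 < self.mass_r < 1:
            raise ValueError("p_bar must be in (0, 1)")

    @property
    def mass_r(self) -> float:
        return sum(m for _, _, m in self.components_r)

    @property
    def mass_u(self) -> float:
        return sum(m for _, _, m in self.components_u)

    @property
    def p_bar(self) -> float:
        return self.mass_r

    def r_density(self, x: np.ndarray) -> np.ndarray:
        return _mix_pdf(x, self.components_r)

    def u_density(self, x: np.ndarray) -> np.ndarray:
        return _mix_pdf(x, self.components_u)

    def t_density(self, x: np.ndarray) -> np.ndarray:
        return self.r_density(x) + self.u_density(x)


def _mix_pdf(x, components) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for mean, sd, mass in components:
        z = (x - mean) / sd
        out += mass * np.exp(-0.5 * z * z) / (sd * np.sqrt(2.0 * np.pi))
    return out


def sample_mixture(spec: MixtureSpec) -> SampleSet:
    """Draw weighted first-crossing samples from a mixture specification.

    CV values are drawn from t = r + u; each sample is labelled reactive with
    probability r(psi)/t(psi), so the true capacity is computable by
    quadrature (:func:`mixture_true_capacity`).
    """
    rng = np.random.default_rng(spec.seed)
    comps = spec.components_r + spec.components_u
    masses = np.array([m for _, _, m in comps])
    choice = rng.choice(len(comps), size=spec.n, p=masses / masses.sum())
    means = np.array([c[0] for c in comps])[choice]
    sds = np.array([c[1] for c in comps])[choice]
    psi = rng.normal(means, sds)
    p_reactive = spec.r_density(psi) / spec.t_density(psi)
    reactive = rng.random(spec.n) < p_reactive
    if spec.weight_law == "uniform":
        w = np.ones(spec.n)
    else:
        law, sigma = spec.weight_law
        if law != "lognormal":
            raise ValueError(f"unknown weight law {spec.weight_law!r}")
        w = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=spec.n)
    return SampleSet(
        values=psi,
        weights=w,
        reactive=reactive,
        query=PPAQuery(lam_c=0.0, lam_r=0.0),
    )


def gaussian_reference_specs(n: int = 50_000, seed: int = 0) -> list[MixtureSpec]:
    """Canonical corpus of half-weighted unit-Gaussian pairs.

    Ten separations from fully overlapping (capacity = p_bar) to essentially
    disjoint; the widest pair (separation 6.5) doubles as the sparse-binning
    failure-mode fixture: at n = 50,000 and 10,000 equal-width bins the
    expected per-bin count near the density crossing is ~0.07, so nearly
    every bin there holds zero or one point of each label.
    """
    seps = [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.5]
    return [
        MixtureSpec(
            components_r=((0.0, 1.0, 0.5),),
            components_u=((d, 1.0, 0.5),),
            n=n,
            seed=seed + i,
        )
        for i, d in enumerate(seps)
    ]


def random_mixture_spec(rng: np.random.Generator, n: int = 10_000) -> MixtureSpec:
    """One random mixture spec for bounds-property corpora.

    1-3 Gaussian components per class, means in [-3, 3], sds in [0.3, 2],
    p_bar in [0.1, 0.9], weights uniform or lognormal.
    """
    p_bar = rng.uniform(0.1, 0.9)

    def comps(total: float):
        k = int(rng.integers(1, 4))
        masses = rng.dirichlet(np.ones(k)) * total
        return tuple(
            (float(rng.uniform(-3, 3)), float(rng.uniform(0.3, 2.0)), float(m))
            for m in masses
        )

    law: str | tuple[str, float]
    if rng.random() < 0.5:
        law = "uniform"
    else:
        law = ("lognormal", float(rng.uniform(0.3, 1.0)))
    return MixtureSpec(
        components_r=comps(p_bar),
        components_u=comps(1.0 - p_bar),
        n=n,
        weight_law=law,
        seed=int(rng.integers(2**31 - 1)),
    )


def mixture_true_capacity(spec: MixtureSpec) -> float:
    """Ground-truth capacity P = 1 - O/p_bar by adaptive quadrature."""
    means = [c[0] for c in spec.components_r + spec.components_u]
    sds = [c[1] for c in spec.components_r + spec.components_u]
    lo = min(m - 10 * s for m, s in zip(means, sds))
    hi = max(m + 10 * s for m, s in zip(means, sds))

    def integrand(x):
        r = spec.r_density(np.array([x]))[0]
        u = spec.u_density(np.array([x]))[0]
        t = r + u
        return r * u / t if t > 1e-300 else 0.0

    overlap, _ = quad(integrand, lo, hi, limit=400)
    return 1.0 - overlap / spec.p_bar


# ---------------------------------------------------------------------------
# descriptor fixture generator


def toy_solvated_pair(
    n_waters: int,
    ion_distance: float = 3.2,
    box: Sequence[float] = (30.0, 30.0, 30.0),
    seed: int = 0,
    min_oo: float = 2.6,
    min_ion: float = 2.2,
    max_tries: int = 20000,
) -> Configuration:
    """A seeded Na/Cl pair with rigid waters packed by rejection sampling.

    Ions sit on the x axis at the stated separation, centered in the box;
    water oxygens keep at least ``min_oo`` from each other and ``min_ion``
    from the ions, with two hydrogens at fixed bond geometry (0.9572 A,
    104.52 deg) in a random orientation.
    """
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    center = box / 2.0
    na = center + np.array([-ion_distance / 2.0, 0.0, 0.0])
    cl = center + np.array([+ion_distance / 2.0, 0.0, 0.0])
    species = ["Na", "Cl"]
    coords = [na, cl]
    oxygens: list[np.ndarray] = []
    tries = 0
    while len(oxygens) < n_waters:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not pack {n_waters} waters after {max_tries} tries; "
                "use a larger box"
            )
        o = rng.random(3) * box
        d_na = min_image_dist(o, na, box)
        d_cl = min_image_dist(o, cl, box)
        if d_na < min_ion or d_cl < min_ion:
            continue
        if any(min_image_dist(o, q, box) < min_oo for q in oxygens):
            continue
        oxygens.append(o)
    bond, half_angle = 0.9572, np.deg2rad(104.52) / 2.0
    for o in oxygens:
        # random orthonormal frame for the HOH plane
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        v = rng.standard_normal(3)
        v -= (v @ u) * u
        v /= np.linalg.norm(v)
        h1 = o + bond * (np.cos(half_angle) * u + np.sin(half_angle) * v)
        h2 = o + bond * (np.cos(half_angle) * u - np.sin(half_angle) * v)
        species.extend(["O", "H", "H"])
        coords.extend([o, h1, h2])
    return Configuration(species=species, coords=np.array(coords), box=box)


def min_image_dist(a, b, box) -> float:
    d = np.asarray(a) - np.asarray(b)
    d -= box * np.round(d / box)
    return float(np.linalg.norm(d))
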