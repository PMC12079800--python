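"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import pathppa as pp


@pytest.fixture(scope="session")
def doublewell_trajectory() -> pp.Trajectory:
    """A medium-length double-well trajectory shared across test modules."""
    params = pp.DoubleWellParams(barrier_height=3.0, coupling=1.0, seed=11)
    return pp.langevin_doublewell(params, 8_000_000)


@pytest.fixture(scope="session")
def chopped(doublewell_trajectory):
    """Segments plus direct-count oracle summaries."""
    return pp.chop_trajectory(doublewell_trajectory)


@pytest.fixture(scope="session")
def toy_paths(chopped):
    return chopped[0]


@pytest.fixture(scope="session")
def direct_counts(chopped):
    return chopped[1]


@pytest.fixture(scope="session")
def toy_interfaces() -> pp.InterfaceSet:
    return pp.InterfaceSet([-0.7, -0.5, 0.7])


@pytest.fixture(scope="session")
def weighted_toy(toy_paths, toy_interfaces):
    ens, _ = pp.tis_like_subsets(toy_paths, toy_interfaces, seed=3, disjoint=True)
    return pp.wham_weights(ens, toy_interfaces)


@pytest.fixture
def gaussian_sampleset():
    """Half-weighted unit Gaussians at 0 and 4: a well-predicted CV."""
    spec = pp.MixtureSpec(
        components_r=((0.0, 1.0, 0.5),),
        components_u=((4.0, 1.0, 0.5),),
        n=20_000,
        seed=21,
    )
    return pp.sample_mixture(spec), spec


@pytest.fixture
def tiny_paths():
    """Four hand-built equal-weight paths with known maxima."""

    def mk(pid, lams, ens="0+", mc=0, w=1.0):
        lams = np.asarray(lams, dtype=float)
        return pp.PathRecord(
            path_id=pid,
            ensemble=ens,
            mc_cycle=mc,
            weight=w,
            times=np.arange(lams.size) * 10.0,
            lam=lams,
            cvs={"cv": lams * 2.0, "other": np.ones_like(lams)},
        )

    return [
        mk("p0", [3.0, 3.3, 3.1], mc=0),
        mk("p1", [3.0, 3.5, 3.2], mc=1),
        mk("p2", [3.1, 3.5, 3.0], mc=2),
        mk("p3", [3.0, 3.6, 4.0], mc=3),
    ]
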