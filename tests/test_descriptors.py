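"""IIDM construction, switching counts, angle CVs, and density maps."""

import numpy as np
import pytest

import pathppa as pp
from pathppa.descriptors import switching_function


@pytest.fixture
def line_config():
    """1 Na, 1 Cl, 1 O, 2 H on a line: every distance hand-computable."""
    return pp.Configuration(
        species=["Na", "Cl", "O", "H", "H"],
        coords=np.array(
            [
                [0.0, 0.0, 0.0],  # Na
                [3.0, 0.0, 0.0],  # Cl
                [1.0, 0.0, 0.0],  # O
                [1.5, 0.0, 0.0],  # H (0.5 from O)
                [5.0, 0.0, 0.0],  # H (4.0 from O)
            ]
        ),
    )


@pytest.fixture
def solvated():
    return pp.toy_solvated_pair(n_waters=20, ion_distance=3.2, seed=42)


class TestMinImage:
    def test_wrap(self):
        assert pp.min_image_distance((0, 0, 0), (29, 0, 0), (30, 30, 30)) == pytest.approx(1.0)

    def test_coincident(self):
        assert pp.min_image_distance((1, 2, 3), (1, 2, 3), (10, 10, 10)) == 0.0

    def test_against_27_image_bruteforce(self):
        rng = np.random.default_rng(7)
        box = np.array([8.0, 11.0, 5.0])
        shifts = np.array(
            [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        )
        for _ in range(200):
            a, b = rng.uniform(0, 1, 3) * box, rng.uniform(0, 1, 3) * box
            brute = min(
                np.linalg.norm(a - (b + s * box)) for s in shifts
            )
            assert pp.min_image_distance(a, b, box) == pytest.approx(brute, abs=1e-12)


class TestIIDM:
    def test_hand_enumeration(self, line_config):
        spec = pp.IIDMSpec(
            anchor="Na", counts={"Cl": 1, "O": 1, "H": 2},
            exclude_intramolecular_h=False,
        )
        m = pp.build_iidm(line_config, spec)
        assert m["NaCl1"] == pytest.approx(3.0)
        assert m["NaO1"] == pytest.approx(1.0)
        assert m["NaH1"] == pytest.approx(1.5)
        assert m["NaH2"] == pytest.approx(5.0)
        # columns of the O1 row: distances from O to pool atoms
        assert m["NaO1Na1"] == pytest.approx(1.0)
        assert m["NaO1Cl1"] == pytest.approx(2.0)
        assert m["NaO1H1"] == pytest.approx(0.5)
        assert m["NaO1H2"] == pytest.approx(4.0)

    def test_intramolecular_h_excluded_from_o_rows(self, line_config):
        spec = pp.IIDMSpec(anchor="Na", counts={"Cl": 1, "O": 1, "H": 2})
        m = pp.build_iidm(line_config, spec)
        # the bonded H at 0.5 A is excluded: H1 of the O row is the far H
        assert m["NaO1H1"] == pytest.approx(4.0)

    def test_index_permutation_invariance(self, solvated):
        spec = pp.IIDMSpec(anchor="Na", counts={"Cl": 1, "O": 6, "H": 8})
        ref = pp.build_iidm(solvated, spec)
        rng = np.random.default_rng(0)
        perm = rng.permutation(solvated.n_atoms)
        shuffled = pp.Configuration(
            species=[solvated.species[i] for i in perm],
            coords=solvated.coords[perm],
            box=solvated.box,
        )
        out = pp.build_iidm(shuffled, spec)
        assert out.entries == ref.entries  # bit-exact

    def test_isometry_invariance(self, solvated):
        spec = pp.IIDMSpec(anchor="Na", counts={"Cl": 1, "O": 6, "H": 8})
        cluster = pp.Configuration(
            species=solvated.species, coords=solvated.coords, box=None
        )
        ref = pp.build_iidm(cluster, spec)
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = pp.Configuration(
            species=cluster.species,
            coords=cluster.coords @ rot.T + np.array([1.0, -2.0, 0.5]),
            box=None,
        )
        out = pp.build_iidm(moved, spec)
        for k, v in ref.entries.items():
            assert abs(out[k] - v) < 1e-10

    def test_sorted_row_monotonicity(self, solvated):
        spec = pp.IIDMSpec(anchor="Na", counts={"Cl": 1, "O": 10, "H": 10})
        m = pp.build_iidm(solvated, spec)
        for sp in ("O", "H"):
            dists = [m[f"Na{sp}{i}"] for i in range(1, 11)]
            assert np.all(np.diff(dists) >= 0)

    def test_feature_against_sort_oracle(self, solvated):
        spec = pp.IIDMSpec(anchor="Na", counts={"Cl": 1, "O": 10, "H": 10})
        na = solvated.coords[0]
        d_o = sorted(
            pp.min_image_distance(na, c, solvated.box)
            for c, s in zip(solvated.coords, solvated.species)
            if s == "O"
        )
        assert pp.iidm_feature(solvated, spec, "NaO6") == pytest.approx(d_o[5])

    def test_insufficient_species_named(self, line_config):
        spec = pp.IIDMSpec(anchor="Na", counts={"O": 5})
        with pytest.raises(ValueError, match="O"):
            pp.build_iidm(line_config, spec)

    def test_malformed_name_rejected(self, solvated):
        spec = pp.IIDMSpec(anchor="Na", counts={"Cl": 1, "O": 5, "H": 5})
        with pytest.raises(ValueError):
            pp.iidm_feature(solvated, spec, "Xx9")
        with pytest.raises(ValueError, match="truncation"):
            pp.iidm_feature(solvated, spec, "NaO99")

    def test_featurizer_transform(self, solvated):
        feat = pp.IIDMFeaturizer(
            anchor="Na", counts={"Cl": 1, "O": 6, "H": 8},
            features=["NaO6", "NaCl1"],
        )
        X = feat.fit_transform([solvated, solvated])
        assert X.shape == (2, 2)
        assert list(feat.get_feature_names_out()) == ["NaO6", "NaCl1"]
        np.testing.assert_allclose(X[0], X[1])


class TestSwitchingCount:
    def test_single_water_at_r0(self):
        cfg = pp.Configuration(
            species=["Na", "Cl", "O"],
            coords=np.array([[0, 0, 0], [4, 0, 0], [2, np.sqrt(3.0**2 - 2**2), 0]]),
        )
        # the O sits exactly 3.0 from both ions
        nb = pp.switching_count(cfg, "Na", "Cl", r0=3.0, steepness=8.0)
        assert nb == pytest.approx(0.25, abs=1e-9)

    def test_distant_waters_negligible(self):
        cfg = pp.Configuration(
            species=["Na", "Cl", "O"],
            coords=np.array([[0, 0, 0], [4, 0, 0], [50, 0, 0]]),
        )
        assert pp.switching_count(cfg, "Na", "Cl", r0=3.0, steepness=5.0) < 1e-3

    def test_steepness_limit_matches_hard_count(self, solvated):
        r0 = 3.5
        soft = pp.switching_count(solvated, "Na", "Cl", r0=r0, steepness=500.0)
        na, cl = solvated.coords[0], solvated.coords[1]
        hard = sum(
            1
            for c, s in zip(solvated.coords, solvated.species)
            if s == "O"
            and pp.min_image_distance(c, na, solvated.box) < r0
            and pp.min_image_distance(c, cl, solvated.box) < r0
        )
        assert soft == pytest.approx(hard, abs=0.05)

    def test_monotone_in_distance(self):
        f = switching_function(np.linspace(0, 10, 50), r0=3.0, steepness=4.0)
        assert np.all(np.diff(f) <= 0)
        assert switching_function(np.array([3.0]), 3.0, 4.0)[0] == pytest.approx(0.5)


class TestLargestCosine:
    def test_collinear_candidate(self):
        cfg = pp.Configuration(
            species=["Cl", "Na", "H"],
            coords=np.array([[0, 0, 0], [-3, 0, 0], [2, 0, 0]]),
        )
        c = pp.largest_cosine(cfg, apex="Cl", arm1="Na", candidate_species="H",
                              shell_radius=5.0)
        assert c == pytest.approx(-1.0)  # H opposite to Na across the apex

    def test_perpendicular_candidate(self):
        cfg = pp.Configuration(
            species=["Cl", "Na", "H"],
            coords=np.array([[0, 0, 0], [-3, 0, 0], [0, 2, 0]]),
        )
        c = pp.largest_cosine(cfg, apex="Cl", arm1="Na", candidate_species="H",
                              shell_radius=5.0)
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_max_over_candidates_oracle(self, solvated):
        out = pp.largest_cosine(
            solvated, apex="Cl", arm1="Na", candidate_species="H", shell_radius=6.0
        )
        cl, na = solvated.coords[1], solvated.coords[0]
        best = -2.0
        for c, s in zip(solvated.coords, solvated.species):
            if s != "H" or pp.min_image_distance(c, cl, solvated.box) > 6.0:
                continue
            v1, v2 = na - cl, c - cl
            best = max(best, v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2))
        assert out == pytest.approx(best)

    def test_empty_shell_rejected(self):
        cfg = pp.Configuration(
            species=["Cl", "Na"], coords=np.array([[0, 0, 0], [-3, 0, 0]])
        )
        with pytest.raises(ValueError):
            pp.largest_cosine(cfg, "Cl", "Na", "H", shell_radius=4.0)


class TestAxialDensityMap:
    def test_single_atom_on_axis(self):
        cfg = pp.Configuration(
            species=["Na", "Cl", "O"],
            coords=np.array([[0, 0, 0], [4, 0, 0], [2, 0, 0]]),
        )
        z, r, dens = pp.axial_density_map([cfg], ("Na", "Cl"), ("O", 1), bins=(4, 2))
        cell = (z[1] - z[0]) * (r[1] - r[0])
        assert np.count_nonzero(dens) == 1
        assert dens.sum() * cell == pytest.approx(1.0)

    def test_mass_conservation(self, solvated):
        k = 6
        z, r, dens = pp.axial_density_map(
            [solvated, solvated], ("Na", "Cl"), ("O", k), bins=(10, 8)
        )
        cell = (z[1] - z[0]) * (r[1] - r[0])
        assert dens.sum() * cell == pytest.approx(k, rel=1e-9)

    def test_isotropic_shell_peaks_at_radius(self):
        rng = np.random.default_rng(5)
        shell_r = 3.0
        cfgs = []
        for _ in range(200):
            v = rng.standard_normal(3)
            v *= shell_r / np.linalg.norm(v)
            cfgs.append(
                pp.Configuration(
                    species=["Na", "Cl", "O"],
                    coords=np.array([[0.0, 0, 0], [0.1, 0, 0], v + [0, 0, 0]]),
                )
            )
        z, r, dens = pp.axial_density_map(
            cfgs, ("Na", "Cl"), ("O", 1), bins=(1, 12),
            extent=((-4.0, 4.0), (0.0, 4.0)),
        )
        radial = dens[0]
        centers = 0.5 * (r[:-1] + r[1:])
        # distance from the axis peaks near the shell radius
        assert abs(centers[np.argmax(radial)] - shell_r) < 0.8

    def test_degenerate_axis_rejected(self):
        cfg = pp.Configuration(
            species=["Na", "Cl", "O"],
            coords=np.array([[0, 0, 0], [0, 0, 0], [2, 0, 0]]),
        )
        with pytest.raises(ValueError, match="axis"):
            pp.axial_density_map([cfg], ("Na", "Cl"), ("O", 1))
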