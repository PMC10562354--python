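"""Synthetic landscape generator: share control, point patterns, allometry, DDW."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial import cKDTree

import forestprio as fp


class TestSiteClasses:
    def test_achieved_shares_match_study_defaults_within_one_cell(self):
        grid = fp.generate_site_classes(960, 960, 16, seed=3)
        target = np.array([0.324, 0.511, 0.156, 0.009])
        assert grid.n_cells == 3600
        assert np.all(np.abs(grid.shares() - target) <= 1.0 / grid.n_cells + 1e-12)

    def test_degenerate_shares_fill_single_class(self):
        grid = fp.generate_site_classes(160, 160, 16, shares=(1, 0, 0, 0), seed=0)
        assert (grid.classes == 1).all()

    def test_seed_determinism_and_variation(self):
        a = fp.generate_site_classes(320, 320, 16, seed=5)
        b = fp.generate_site_classes(320, 320, 16, seed=5)
        c = fp.generate_site_classes(320, 320, 16, seed=6)
        np.testing.assert_array_equal(a.classes, b.classes)
        assert (a.classes != c.classes).any()
        # different seeds still hit the same quantile quotas
        np.testing.assert_array_equal(np.sort(a.shares()), np.sort(c.shares()))

    def test_non_divisible_extent_names_dimension(self):
        with pytest.raises(ValueError, match="extent_x"):
            fp.generate_site_classes(100, 320, 16, seed=0)
        with pytest.raises(ValueError, match="extent_y"):
            fp.generate_site_classes(320, 100, 16, seed=0)

    def test_rare_class_forms_contiguous_patches(self):
        """Class f4 cells should clump, not scatter: mean neighbours well above random."""
        grid = fp.generate_site_classes(960, 960, 16, smoothness=80, seed=9)
        mask = grid.classes == 4
        padded = np.pad(mask, 1)
        neigh = sum(
            padded[1 + dr : 61 + dr, 1 + dc : 61 + dc]
            for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]
        )
        # under random scatter at share 0.9% the expected same-class neighbour
        # count is ~0.036; smoothing should give patches with interior cells
        assert neigh[mask].mean() > 1.0


class TestTrees:
    def test_aspen_is_a_minor_sporadic_component(self, small_site):
        """Aspen stems stay under 10% of spruce stems across seeds."""
        for seed in range(5):
            trees = fp.generate_trees(small_site, seed=seed)
            counts = trees.groupby("species").size()
            assert counts.get("aspen", 0) < 0.10 * counts["spruce"]

    def test_zero_intensity_gives_empty_landscape(self, small_site):
        params = {
            sp: p.replace(intensity_per_ha=(0, 0, 0, 0))
            for sp, p in fp.DEFAULT_SPECIES_PARAMS.items()
        }
        trees = fp.generate_trees(small_site, params=params, seed=0)
        assert len(trees) == 0
        assert list(trees.columns) == ["x", "y", "species", "height_m", "dbh_cm", "vol_m3"]

    def test_records_satisfy_domain_invariants(self, small_landscape):
        site, trees, _ = small_landscape
        assert trees["x"].between(0, site.extent_x).all()
        assert trees["y"].between(0, site.extent_y).all()
        assert (trees["height_m"] > 0).all()
        assert (trees["dbh_cm"] > 0).all()
        assert (trees["vol_m3"] > 0).all()
        for sp, g in trees.groupby("species"):
            g = g.sort_values("height_m")
            assert g["dbh_cm"].is_monotonic_increasing

    def test_sporadic_pattern_is_more_dispersed_than_clustered(self):
        """At equal intensity, sporadic nearest-neighbour distances exceed clustered ones."""
        site = fp.generate_site_classes(480, 480, 16, shares=(1, 0, 0, 0), seed=1)
        lam = (60.0, 0, 0, 0)
        clustered = fp.DEFAULT_SPECIES_PARAMS["spruce"].replace(intensity_per_ha=lam)
        sporadic = fp.DEFAULT_SPECIES_PARAMS["aspen"].replace(intensity_per_ha=lam)
        diffs = []
        for seed in range(5):
            tc = fp.generate_trees(site, {"spruce": clustered}, seed=seed)
            ts = fp.generate_trees(site, {"aspen": sporadic}, seed=seed + 100)

            def mean_nn(df):
                pts = df[["x", "y"]].to_numpy()
                d, _ = cKDTree(pts).query(pts, k=2)
                return d[:, 1].mean()

            diffs.append(mean_nn(ts) - mean_nn(tc))
        assert np.mean(diffs) > 0

    def test_default_volume_composition_matches_study_area(self, small_site):
        """Species volume shares average within 10 points of 40/35/17/5 %."""
        shares = []
        for seed in range(5):
            trees = fp.generate_trees(small_site, seed=seed)
            vol = trees.groupby("species")["vol_m3"].sum()
            shares.append(vol / vol.sum())
        mean = sum(shares) / len(shares)
        target = {"spruce": 0.40, "pine": 0.35, "birch": 0.17, "aspen": 0.05}
        for sp, t in target.items():
            assert abs(mean[sp] - t) < 0.10, (sp, mean[sp])

    def test_determinism(self, small_site):
        a = fp.generate_trees(small_site, seed=4)
        b = fp.generate_trees(small_site, seed=4)
        assert a.equals(b)


class TestAllometry:
    def test_identity_coefficients(self):
        p = fp.SpeciesParams(intensity_per_ha=(1, 1, 1, 1), dbh_a=1.0, dbh_b=1.0)
        assert fp.allometry_dbh("spruce", 20.0, p) == pytest.approx(20.0)

    def test_power_law_scaling(self):
        p = fp.SpeciesParams(intensity_per_ha=(1, 1, 1, 1), dbh_a=0.8, dbh_b=1.3)
        d1 = fp.allometry_dbh("pine", 10.0, p)
        d2 = fp.allometry_dbh("pine", 20.0, p)
        assert d2 / d1 == pytest.approx(2**1.3)

    def test_default_spruce_closed_form(self):
        p = fp.DEFAULT_SPECIES_PARAMS["spruce"]
        assert fp.allometry_dbh("spruce", 25.0) == pytest.approx(p.dbh_a * 25.0**p.dbh_b)

    def test_volume_closed_form_and_monotonicity(self):
        p = fp.SpeciesParams(intensity_per_ha=(1, 1, 1, 1), form_factor=0.5)
        assert fp.allometry_volume("birch", 30.0, 20.0, p) == pytest.approx(0.9)
        assert fp.allometry_volume("birch", 10.0, 20.0, p) < fp.allometry_volume(
            "birch", 11.0, 20.0, p
        )
        assert fp.allometry_volume("birch", 1e-6, 20.0, p) < 1e-9  # vanishes with dbh

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            fp.allometry_dbh("spruce", 0.0)
        with pytest.raises(ValueError):
            fp.allometry_volume("spruce", -1.0, 20.0)


class TestDDW:
    def test_zero_intensity_empty(self, small_site):
        ddw = fp.generate_ddw(small_site, fp.DDWParams(intensity_per_ha=0.0), seed=0)
        assert len(ddw) == 0

    def test_length_equals_endpoint_distance(self, small_landscape):
        _, _, ddw = small_landscape
        d = np.hypot(ddw.x2 - ddw.x1, ddw.y2 - ddw.y1)
        np.testing.assert_allclose(d, ddw.length_m, atol=1e-9)
        assert (ddw.vol_m3 > 0).all()

    def test_mean_volume_matches_cylinder_closed_form(self):
        """Monte-Carlo mean record volume vs pi/4 E[d^2] E[L] from truncnorm moments."""
        site = fp.generate_site_classes(960, 960, 16, seed=2)
        p = fp.DDWParams(intensity_per_ha=30.0, length_mean=6.0, length_max=12.0)
        ddw = fp.generate_ddw(site, p, seed=5)
        assert len(ddw) > 1000

        def tn(mean, sd, lo, hi):
            return stats.truncnorm((lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd)

        dl = tn(p.diameter_mean, p.diameter_sd, p.diameter_min, p.diameter_max)
        ll = tn(p.length_mean, p.length_sd, p.length_min, p.length_max)
        e_d2 = dl.moment(2)
        expected = np.pi / 4 * e_d2 / 1e4 * ll.mean()
        assert ddw.vol_m3.mean() == pytest.approx(expected, rel=0.05)

    def test_endpoints_clipped_into_extent(self, small_landscape):
        site, _, ddw = small_landscape
        for col, hi in (("x1", site.extent_x), ("x2", site.extent_x),
                        ("y1", site.extent_y), ("y2", site.extent_y)):
            assert ddw[col].between(0, hi).all()
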