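"""Unit and property tests for FON geometry, growth, allometry, summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mangal import SpeciesParams, Stand, Tree
from mangal.stand import (BREAST_HEIGHT_CM, annual_growth, competition_index,
                          competition_indices, diameter_increment,
                          fon_intensity, fon_radius, height_from_dbh,
                          stand_summary, tree_biomass)


# ---------------------------------------------------------------------------
# FON radius and intensity
# ---------------------------------------------------------------------------

class TestFonRadius:
    def test_canonical_scaling(self):
        p = SpeciesParams(fon_a=10.0, fon_b=0.5)
        # 18 cm dbh -> 0.09 m stem radius -> 10 * 0.3 = 3.0 m
        assert fon_radius(18.0, p) == pytest.approx(3.0, rel=1e-12)

    def test_zero_stem_has_no_fon(self):
        assert fon_radius(0.0, SpeciesParams()) == 0.0

    def test_degenerate_exponent_gives_constant_radius(self):
        p = SpeciesParams(fon_a=4.0, fon_b=0.0)
        for dbh in (1.0, 10.0, 40.0):
            assert fon_radius(dbh, p) == pytest.approx(4.0)

    def test_negative_dbh_rejected(self):
        with pytest.raises(ValueError):
            fon_radius(-1.0, SpeciesParams())

    @given(st.floats(0.1, 45.0), st.floats(0.1, 45.0))
    def test_monotone_in_dbh(self, a, b):
        p = SpeciesParams()
        lo, hi = sorted((a, b))
        assert fon_radius(lo, p) <= fon_radius(hi, p) + 1e-12


class TestFonIntensity:
    def test_plateau_inside_stem(self, params):
        t = Tree(50.0, 50.0, 20.0)
        assert fon_intensity(t, 50.0, 50.0, params) == 1.0

    def test_boundary_value_is_fon_min(self, params):
        t = Tree(0.0, 0.0, 20.0)
        R = float(fon_radius(20.0, params))
        val = fon_intensity(t, R, 0.0, params)
        assert val == pytest.approx(params.fon_min, rel=1e-9)

    def test_zero_outside_support(self, params):
        t = Tree(50.0, 50.0, 20.0)
        R = float(fon_radius(20.0, params))
        assert fon_intensity(t, 50.0 + 10 * R, 50.0, params) == 0.0

    @given(st.floats(0.5, 45.0), st.floats(0.0, 50.0))
    def test_bounded_unit_interval(self, dbh, dist):
        p = SpeciesParams()
        t = Tree(60.0, 60.0, dbh)
        v = float(fon_intensity(t, 60.0 + dist, 60.0, p))
        assert 0.0 <= v <= 1.0


# ---------------------------------------------------------------------------
# Competition index vs brute-force quadrature oracle
# ---------------------------------------------------------------------------

def brute_force_F(focal: Tree, neighbours, params, h=0.02):
    """Independent fine-grid integral of neighbour intensity over the disc."""
    R = float(fon_radius(focal.dbh, params))
    n = int(np.ceil(2 * R / h))
    off = (np.arange(n) + 0.5) * h - R
    X, Y = np.meshgrid(focal.x + off, focal.y + off)
    mask = (X - focal.x) ** 2 + (Y - focal.y) ** 2 <= R * R
    tot = np.zeros_like(X)
    for t in neighbours:
        tot += fon_intensity(t, X, Y, params)
    return tot[mask].sum() / mask.sum()


class TestCompetitionIndex:
    def test_lone_tree_feels_nothing(self, params):
        st_ = Stand.from_trees([Tree(60.0, 60.0, 20.0)])
        assert competition_indices(st_, params)[0] == 0.0

    def test_disjoint_fons_do_not_interact(self, params):
        R = float(fon_radius(10.0, params))
        trees = [Tree(30.0, 60.0, 10.0), Tree(30.0 + 3 * R, 60.0, 10.0)]
        F = competition_indices(Stand.from_trees(trees), params)
        assert np.all(F == 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_grid_refinement_oracle(self, params, seed):
        """Quadrature F agrees with a 0.02 m brute-force integral within 1%."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        trees = [Tree(60.0 + rng.uniform(-2, 2), 60.0 + rng.uniform(-2, 2),
                      float(rng.uniform(5, 35))) for _ in range(k)]
        focal = trees[0]
        ref = brute_force_F(focal, trees[1:], params)
        assert ref > 0
        got = competition_index(focal, Stand.from_trees(trees), params,
                                resolution=0.125)
        assert got == pytest.approx(ref, rel=0.01)

    def test_refinement_converges(self, params):
        trees = [Tree(60.0, 60.0, 20.0), Tree(61.5, 60.0, 20.0)]
        focal = trees[0]
        ref = brute_force_F(focal, trees[1:], params)
        errs = [abs(competition_index(focal, Stand.from_trees(trees), params,
                                      resolution=r) - ref) / ref
                for r in (0.5, 0.25, 0.125)]
        assert errs[2] < errs[0]
        assert errs[2] <= 0.01

    def test_symmetric_for_identical_pair(self, params):
        # positions mirror-symmetric about the grid line x=60
        trees = [Tree(59.0, 60.0, 20.0), Tree(61.0, 60.0, 20.0)]
        F = competition_indices(Stand.from_trees(trees), params)
        assert F[0] == pytest.approx(F[1], rel=1e-9)
        assert F[0] > 0

    def test_probe_tree_outside_stand(self, params):
        st_ = Stand.from_trees([Tree(60.0, 60.0, 30.0)])
        probe = Tree(61.0, 60.0, 10.0)
        assert competition_index(probe, st_, params) > 0


# ---------------------------------------------------------------------------
# Allometry and growth
# ---------------------------------------------------------------------------

class TestHeight:
    def test_seedling_intercept(self, params):
        assert height_from_dbh(0.0, params) == BREAST_HEIGHT_CM

    def test_maximum_height_at_d_max(self, params):
        assert height_from_dbh(params.d_max, params) == pytest.approx(
            params.h_max)

    def test_midpoint_closed_form(self, params):
        expected = 137.0 + 0.75 * (params.h_max - 137.0)
        assert height_from_dbh(params.d_max / 2, params) == pytest.approx(
            expected)

    def test_monotone_and_domain_checked(self, params):
        d = np.linspace(0, params.d_max, 200)
        h = height_from_dbh(d, params)
        assert np.all(np.diff(h) > 0)
        with pytest.raises(ValueError):
            height_from_dbh(params.d_max + 1.0, params)


class TestGrowth:
    def test_full_suppression_stops_growth(self, params):
        F = 1.0 / params.comp_slope + 0.01
        assert annual_growth(Tree(0, 0, 10.0), F, 1.0, params) == 0.0

    def test_no_growth_at_d_max(self, params):
        assert annual_growth(Tree(0, 0, params.d_max), 0.0, 1.0, params) == \
            pytest.approx(0.0, abs=1e-12)

    def test_total_impact_zone_factor_silences_growth(self, params):
        # I=1, S=0 in the scenario formula gives factor 0
        assert annual_growth(Tree(0, 0, 10.0), 0.0, 0.0, params) == 0.0

    def test_open_grown_increment_positive(self, params):
        assert annual_growth(Tree(0, 0, 10.0), 0.0, 1.0, params) > 0

    def test_iteration_converges_to_d_max(self, params):
        """Competition-free growth approaches the d_max asymptote monotonically."""
        d = 1.0
        prev = 0.0
        for _ in range(600):
            assert d > prev
            prev = d
            d = min(d + float(diameter_increment(d, 0.0, 1.0, params)),
                    params.d_max)
        assert d == pytest.approx(params.d_max, rel=0.01)
        assert d <= params.d_max


class TestBiomass:
    def test_zero_at_zero(self, params):
        assert tree_biomass(0.0, params) == 0.0

    def test_reference_tree_mass(self, params):
        # 300 t/ha over 1344 stems -> ~223 kg at the mean diameter 17.38 cm
        assert tree_biomass(17.38, params) == pytest.approx(223.2, rel=0.01)

    def test_linear_in_allom_s(self, params):
        import dataclasses
        doubled = dataclasses.replace(params, allom_s=2 * params.allom_s)
        assert tree_biomass(20.0, doubled) == pytest.approx(
            2 * tree_biomass(20.0, params))


# ---------------------------------------------------------------------------
# Stand summaries
# ---------------------------------------------------------------------------

class TestStandSummary:
    def test_empty_stand(self, params):
        sm = stand_summary(Stand(), params)
        assert (sm.density, sm.basal_area, sm.biomass) == (0.0, 0.0, 0.0)

    def test_reference_basal_area(self, params):
        rng = np.random.default_rng(0)
        n = 1344
        st_ = Stand(x=rng.uniform(10, 110, n), y=rng.uniform(10, 110, n),
                    dbh=np.full(n, 17.38))
        sm = stand_summary(st_, params)
        assert sm.density == 1344.0
        assert sm.basal_area == pytest.approx(31.89, rel=5e-3)

    def test_edge_band_tree_excluded(self, params):
        st_ = Stand(x=[5.0], y=[60.0], dbh=[30.0])
        sm = stand_summary(st_, params)
        assert (sm.density, sm.basal_area, sm.biomass) == (0.0, 0.0, 0.0)

    def test_additive_over_disjoint_subsets(self, params):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 120, 60)
        y = rng.uniform(0, 120, 60)
        d = rng.uniform(2, 40, 60)
        whole = stand_summary(Stand(x=x, y=y, dbh=d), params)
        a = stand_summary(Stand(x=x[:30], y=y[:30], dbh=d[:30]), params)
        b = stand_summary(Stand(x=x[30:], y=y[30:], dbh=d[30:]), params)
        assert whole.density == a.density + b.density
        assert whole.basal_area == pytest.approx(a.basal_area + b.basal_area)
        assert whole.biomass == pytest.approx(a.biomass + b.biomass)

    def test_sampling_never_inflates_density(self, params):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 120, 500)
        y = rng.uniform(0, 120, 500)
        st_ = Stand(x=x, y=y, dbh=np.full(500, 10.0))
        assert stand_summary(st_, params).density * 1.0 <= 500


class TestStandContainer:
    def test_tree_roundtrip_preserves_memory(self):
        trees = [Tree(10.0, 20.0, 5.0, 3, (0.1, 0.05)),
                 Tree(30.0, 40.0, 15.0, 30, (0.01,) * 5)]
        st_ = Stand.from_trees(trees)
        assert st_.trees() == trees

    def test_csv_roundtrip(self, tmp_path):
        st_ = Stand(x=[10.0, 50.0], y=[20.0, 60.0], dbh=[5.0, 25.0],
                    age=[2, 80])
        path = tmp_path / "stand.csv"
        st_.to_csv(path)
        back = Stand.from_csv(path)
        assert np.allclose(back.x, st_.x)
        assert np.allclose(back.dbh, st_.dbh)
        assert list(back.age) == [2, 80]

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            Stand(domain_side=50.0, sample_origin=10.0, sample_side=100.0)

    def test_validate_flags_escaped_tree(self, params):
        st_ = Stand(x=[150.0], y=[60.0], dbh=[10.0])
        with pytest.raises(ValueError):
            st_.validate(params)
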