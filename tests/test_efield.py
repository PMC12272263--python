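import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmsnet import (
    CoilModel,
    CoilPlacement,
    EFieldMap,
    build_grid,
    efsi,
    human_profile,
    macaque_profile,
    per_map_suprathreshold_fraction,
    planted_field,
    primary_efield,
)
from tmsnet.efield import ORIENTATIONS_DEG, loop_vector_potential
from tmsnet.errors import (
    DegenerateInputError,
    GeometryError,
    InputError,
    ParameterError,
)

from .conftest import lattice_mesh
from .helpers import loop_a_phi_exact


class TestBuildGrid:
    def test_human_grid_enumerates_432_placements(self, human_mesh):
        placements = build_grid(human_profile(), human_mesh)
        assert len(placements) == 432

    def test_grid_counts(self, human_mesh):
        placements = build_grid(human_profile(), human_mesh)
        locations = {(p.row, p.col) for p in placements}
        assert len(locations) == 36
        for row, col in locations:
            thetas = {p.theta_deg for p in placements
                      if (p.row, p.col) == (row, col)}
            assert thetas == set(ORIENTATIONS_DEG)

    @pytest.mark.parametrize("profile_fn", [human_profile, macaque_profile])
    def test_same_row_spacing(self, profile_fn, human_mesh, macaque_mesh):
        profile = profile_fn()
        mesh = human_mesh if profile.name.startswith("human") else macaque_mesh
        placements = {(p.row, p.col): p.center
                      for p in build_grid(profile, mesh)}
        for row in range(6):
            for col in range(5):
                dx = placements[(row, col + 1)][0] - placements[(row, col)][0]
                assert dx == pytest.approx(profile.spacing)

    def test_rows_advance_posteriorly_cols_laterally(self, human_mesh):
        centers = {(p.row, p.col): p.center
                   for p in build_grid(human_profile(), human_mesh)}
        assert centers[(1, 0)][1] < centers[(0, 0)][1]  # posterior = -y
        assert centers[(0, 1)][0] > centers[(0, 0)][0]  # lateral = +x

    def test_grid_above_surface(self, human_mesh):
        zmax = human_mesh.vertices[:, 2].max()
        for p in build_grid(human_profile(), human_mesh):
            assert p.center[2] == pytest.approx(zmax + human_profile().standoff)

    def test_footprint_exceeding_patch_rejected(self):
        small = lattice_mesh(25, 25, spacing=1.0)  # 24 mm span < 50 mm grid
        with pytest.raises(GeometryError):
            build_grid(human_profile(), small)

    def test_handle_perpendicular_to_normal(self, human_mesh):
        for p in build_grid(human_profile(), human_mesh)[:24]:
            assert abs(float(p.handle @ p.normal)) < 1e-6

    def test_theta_outside_simulated_set_rejected(self):
        with pytest.raises(ParameterError):
            CoilPlacement(0, 0, 17, np.zeros(3), np.array([0.0, 1.0, 0.0]),
                          np.array([0.0, 0.0, -1.0]))


class TestLoopOracle:
    def test_discretized_loop_matches_elliptic_closed_form(self):
        radius = 35.0
        u, v = np.array([1.0, 0, 0]), np.array([0.0, 1, 0])
        for rho, z in [(10.0, 10.0), (20.0, 15.0), (35.0, 20.0),
                       (50.0, 12.0), (5.0, 40.0)]:
            a = loop_vector_potential(np.array([[rho, 0.0, z]]), np.zeros(3),
                                      u, v, radius, 64)[0]
            # At (rho, 0, z) the azimuthal direction is +y.
            assert a[1] == pytest.approx(loop_a_phi_exact(radius, rho, z),
                                         rel=0.01)
            assert abs(a[0]) < 1e-12 and abs(a[2]) < 1e-12

    def test_on_axis_potential_vanishes(self):
        u, v = np.array([1.0, 0, 0]), np.array([0.0, 1, 0])
        a = loop_vector_potential(np.array([[0.0, 0.0, 20.0]]), np.zeros(3),
                                  u, v, 35.0, 64)[0]
        assert np.linalg.norm(a) < 1e-15

    def test_point_on_winding_rejected(self):
        u, v = np.array([1.0, 0, 0]), np.array([0.0, 1, 0])
        mid, _ = u, v
        from tmsnet.efield import _loop_segments

        mids, _ = _loop_segments(np.zeros(3), u, v, 35.0, 64, 1)
        with pytest.raises(GeometryError):
            loop_vector_potential(mids[:1], np.zeros(3), u, v, 35.0, 64)


@pytest.fixture(scope="module")
def flat_mesh():
    return lattice_mesh(31, 31, spacing=2.0)  # 60x60 mm flat sheet


@pytest.fixture(scope="module")
def centered_placement():
    return CoilPlacement(2, 2, 0, np.array([30.0, 30.0, 12.0]),
                         np.array([0.0, 1.0, 0.0]),
                         np.array([0.0, 0.0, -1.0]))


class TestPrimaryField:
    def test_linearity_in_di_dt(self, flat_mesh, centered_placement):
        e1 = primary_efield(CoilModel(di_dt=1e8), centered_placement, flat_mesh)
        e2 = primary_efield(CoilModel(di_dt=2e8), centered_placement, flat_mesh)
        np.testing.assert_allclose(e2.values, 2.0 * e1.values, rtol=1e-12)

    def test_determinism(self, flat_mesh, centered_placement):
        coil = CoilModel()
        a = primary_efield(coil, centered_placement, flat_mesh)
        b = primary_efield(coil, centered_placement, flat_mesh)
        np.testing.assert_array_equal(a.values, b.values)

    def test_maximum_under_coil_intersection(self, flat_mesh,
                                             centered_placement):
        e = primary_efield(CoilModel(), centered_placement, flat_mesh)
        peak = flat_mesh.vertices[int(np.argmax(e.values))]
        # Brute force over all vertices: the peak must sit near the point
        # directly beneath the figure-8 intersection (within ~1 lattice cell
        # of the centre in-plane).
        assert np.linalg.norm(peak[:2] - np.array([30.0, 30.0])) <= 4.0

    def test_all_magnitudes_positive_somewhere(self, flat_mesh,
                                               centered_placement):
        e = primary_efield(CoilModel(), centered_placement, flat_mesh)
        assert np.all(e.values >= 0)
        assert e.values.max() > 0

    def test_crown_stronger_than_sulci(self, macaque_mesh):
        profile = macaque_profile()
        placements = build_grid(profile, macaque_mesh)
        center = next(p for p in placements
                      if (p.row, p.col, p.theta_deg) == (2, 2, 0))
        e = primary_efield(CoilModel(), center, macaque_mesh)
        z = macaque_mesh.vertices[:, 2]
        crown = z > 0.6 * z.max()
        sulci = z < 0.6 * z.min()
        assert e.values[crown].mean() > e.values[sulci].mean()

    def test_coil_parameter_validation(self):
        with pytest.raises(ParameterError):
            CoilModel(radius_mm=-1)
        with pytest.raises(ParameterError):
            CoilModel(segments_per_loop=4)
        with pytest.raises(ParameterError):
            CoilModel(di_dt=0)


class TestPlantedField:
    def test_center_value_is_one(self, small_flat_mesh):
        f = planted_field(small_flat_mesh, 37, spread_mm=2.0)
        assert f.values[37] == 1.0
        assert f.values.max() == 1.0

    def test_infinite_spread_limit(self, small_flat_mesh):
        f = planted_field(small_flat_mesh, 0, spread_mm=1e9)
        np.testing.assert_allclose(f.values, 1.0, atol=1e-12)

    def test_monotone_decay(self, small_flat_mesh):
        center = 44
        f = planted_field(small_flat_mesh, center, spread_mm=3.0)
        d = np.linalg.norm(
            small_flat_mesh.vertices - small_flat_mesh.vertices[center], axis=1
        )
        nn = np.sort(d[d > 0])[0]
        farther = d > nn + 1e-12
        assert np.all(f.values[farther] < np.exp(-nn**2 / (2 * 9.0)) + 1e-15)

    def test_invalid_vertex_rejected(self, small_flat_mesh):
        with pytest.raises(InputError):
            planted_field(small_flat_mesh, 10_000, spread_mm=1.0)
        with pytest.raises(ParameterError):
            planted_field(small_flat_mesh, 0, spread_mm=0.0)


class TestEfsi:
    def test_single_map_is_binary(self):
        f = EFieldMap(np.array([1.0, 0.6, 0.4]))
        out = efsi([f])
        np.testing.assert_array_equal(out.values, [100.0, 100.0, 0.0])

    def test_two_of_three_maps(self):
        maps = [
            EFieldMap(np.array([1.0, 0.9])),
            EFieldMap(np.array([1.0, 0.8])),
            EFieldMap(np.array([1.0, 0.2])),
        ]
        out = efsi(maps)
        assert out.values[1] == pytest.approx(66.67, abs=0.01)

    def test_vertex_at_maximum_everywhere_scores_100(self):
        maps = [EFieldMap(np.array([0.2, 1.0])),
                EFieldMap(np.array([0.1, 2.0]))]
        assert efsi(maps).values[1] == 100.0

    def test_scale_invariance_of_threshold(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.01, 1.0, size=50)
        a = efsi([EFieldMap(vals)])
        b = efsi([EFieldMap(vals * 37.5)])
        np.testing.assert_array_equal(a.values, b.values)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 6))
    def test_bounds_property(self, seed, n_maps):
        rng = np.random.default_rng(seed)
        maps = [EFieldMap(rng.uniform(0.01, 1.0, size=20))
                for _ in range(n_maps)]
        out = efsi(maps)
        assert np.all(out.values >= 0) and np.all(out.values <= 100)

    def test_monotone_in_vertex_value(self):
        base = np.array([1.0, 0.45, 0.3])
        boosted = np.array([1.0, 0.55, 0.3])
        lo = efsi([EFieldMap(base)]).values
        hi = efsi([EFieldMap(boosted)]).values
        assert np.all(hi >= lo)

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            efsi([])

    def test_all_zero_map_rejected(self):
        with pytest.raises(DegenerateInputError):
            efsi([EFieldMap(np.zeros(5))])

    def test_per_map_summary(self):
        maps = [EFieldMap(np.array([1.0, 0.6, 0.4, 0.1]))]
        np.testing.assert_allclose(per_map_suprathreshold_fraction(maps),
                                   [50.0])
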