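"""Plane-marching profiler: analytic pores, brute-force oracle, invariants."""

import numpy as np
import pytest

from conftest import brute_force_plane_radius, structure_from_arrays

from porescan import (
    ProfilerParams,
    inscribed_radius,
    profile_channel,
    profile_stats,
    seed_point,
)
from porescan.synthetic_data import PoreSpec, make_pore, make_lysine


class TestSeedPoint:
    def test_midpoint(self):
        lys = make_lysine()
        ca = lys.coords[list(lys.name).index("CA")]
        nz = lys.coords[list(lys.name).index("NZ")]
        np.testing.assert_allclose(seed_point(lys), 0.5 * (ca + nz))

    def test_missing_atom_named(self, methyl_lysine):
        no_nz = methyl_lysine.subset(methyl_lysine.name != "NZ")
        with pytest.raises(ValueError, match="NZ"):
            seed_point(no_nz)


class TestInscribedRadius:
    def test_single_far_atom_caps_at_end_radius(self):
        s = structure_from_arrays(np.array([[0.0, 5.0, 0.0]]), np.array([1.5]))
        params = ProfilerParams(in_plane_search_bound=0.05, grid_step=0.2)
        st = inscribed_radius(s, plane=0.0, start=np.zeros(3), params=params)
        assert st.radius == pytest.approx(3.5, abs=1e-6)

    def test_hexagon_symmetry(self):
        # regular hexagon of atoms (VDW r_a) of circumradius R, seed at centroid
        R, r_a = 4.0, 1.5
        angles = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        coords = np.column_stack(
            [np.zeros(6), R * np.cos(angles), R * np.sin(angles)]
        )
        s = structure_from_arrays(coords, np.full(6, r_a))
        st = inscribed_radius(
            s, plane=0.0, start=np.zeros(3),
            params=ProfilerParams(in_plane_search_bound=2.0),
        )
        assert st.radius == pytest.approx(R - r_a, abs=1e-3)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        bound = 3.0
        for _ in range(25):
            n = rng.integers(5, 50)
            coords = rng.uniform(-5, 5, size=(n, 3))
            vdw = rng.uniform(1.0, 2.0, size=n)
            oracle = brute_force_plane_radius(coords, vdw, 0.0, bound)
            st = inscribed_radius(
                structure_from_arrays(coords, vdw),
                plane=0.0,
                start=np.zeros(3),
                params=ProfilerParams(in_plane_search_bound=bound),
            )
            assert st.radius == pytest.approx(max(oracle, 0.0), abs=0.02)

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(-5, 5, size=(30, 3))
        vdw = rng.uniform(1.0, 2.0, size=30)
        s = structure_from_arrays(coords, vdw)
        params = ProfilerParams(in_plane_search_bound=3.0)
        a = inscribed_radius(s, 0.0, np.zeros(3), params)
        b = inscribed_radius(s, 0.0, np.zeros(3), params)
        assert a.radius == b.radius
        np.testing.assert_array_equal(a.center, b.center)


class TestProfileChannel:
    def test_cylinder_recovery(self, cylinder_pore, cylinder_profile):
        spec, _, analytic = cylinder_pore
        inside = [
            s for s in cylinder_profile.interior()
            if 0.0 <= s.axial_coordinate <= spec.length
        ]
        assert len(inside) >= 35
        for st in inside:
            assert st.radius == pytest.approx(analytic(st.axial_coordinate), abs=0.02)
            assert st.radius == pytest.approx(spec.inner_radius, abs=0.02)

    def test_cone_linear_increase(self):
        spec = PoreSpec(shape="cone", r_start=1.5, r_end=3.4, length=10.0)
        structure, analytic = make_pore(spec)
        prof = profile_channel(
            structure, params=ProfilerParams(seed=tuple(spec.seed_hint()))
        )
        inside = [s for s in prof.interior() if 1.0 <= s.axial_coordinate <= 9.0]
        z = np.array([s.axial_coordinate for s in inside])
        r = np.array([s.radius for s in inside])
        for st in inside:
            assert st.radius == pytest.approx(analytic(st.axial_coordinate), abs=0.02)
        slope = np.polyfit(z, r, 1)[0]
        # wall slope s appears as the perpendicular clearance slope s/sqrt(1+s^2)
        s_nominal = (spec.r_end - spec.r_start) / spec.length
        assert slope == pytest.approx(s_nominal / np.hypot(1, s_nominal), abs=0.01)
        assert np.all(np.diff(r) > -0.02)

    def test_constriction_minimum_located(self):
        spec = PoreSpec(shape="constricted", neck_radius=1.45, length=10.0)
        structure, analytic = make_pore(spec)
        prof = profile_channel(
            structure, params=ProfilerParams(seed=tuple(spec.seed_hint()))
        )
        mn, _ = profile_stats(prof, (0.0, spec.length))
        assert mn == pytest.approx(1.45, abs=0.02)
        inside = [s for s in prof.interior() if 0 <= s.axial_coordinate <= spec.length]
        limiting = min(inside, key=lambda s: s.radius)
        assert limiting.axial_coordinate == pytest.approx(0.5 * spec.length, abs=0.26)

    def test_seed_outside_pore_errors(self, cylinder_pore):
        spec, structure, _ = cylinder_pore
        with pytest.raises(ValueError, match="seed not inside a pore"):
            profile_channel(
                structure,
                params=ProfilerParams(seed=(spec.length / 2, 40.0, 0.0)),
            )

    def test_anti_monotonicity_added_atom(self, cylinder_pore, cylinder_profile):
        spec, structure, _ = cylinder_pore
        extra = structure_from_arrays(
            np.array([[spec.length / 2, 0.8, 0.0]]), np.array([1.2])
        )
        merged = structure_from_arrays(
            np.vstack([structure.coords, extra.coords]),
            np.concatenate([structure.vdw, extra.vdw]),
        )
        prof2 = profile_channel(
            merged, params=ProfilerParams(seed=tuple(spec.seed_hint()))
        )
        base = {s.axial_coordinate: s.radius for s in cylinder_profile.stations}
        for st in prof2.stations:
            if st.axial_coordinate in base:
                assert st.radius <= base[st.axial_coordinate] + 1e-6

    def test_vdw_inflation_shifts_radii(self, cylinder_pore, cylinder_profile):
        spec, structure, _ = cylinder_pore
        delta = 0.2
        inflated = structure_from_arrays(structure.coords, structure.vdw + delta)
        prof2 = profile_channel(
            inflated, params=ProfilerParams(seed=tuple(spec.seed_hint()))
        )
        base = {
            s.axial_coordinate: s.radius
            for s in cylinder_profile.interior()
            if 0 <= s.axial_coordinate <= spec.length
        }
        for st in prof2.interior():
            if st.axial_coordinate in base:
                assert st.radius == pytest.approx(
                    base[st.axial_coordinate] - delta, abs=1e-3
                )

    def test_determinism_bit_identical(self, cylinder_pore, cylinder_profile):
        spec, structure, _ = cylinder_pore
        prof2 = profile_channel(
            structure, params=ProfilerParams(seed=tuple(spec.seed_hint()))
        )
        assert [s.radius for s in prof2.stations] == [
            s.radius for s in cylinder_profile.stations
        ]
        assert [tuple(s.center) for s in prof2.stations] == [
            tuple(s.center) for s in cylinder_profile.stations
        ]


class TestProfileStats:
    def test_constant_profile(self, cylinder_pore, cylinder_profile):
        spec, _, _ = cylinder_pore
        mn, avg = profile_stats(cylinder_profile, (0.0, spec.length))
        assert mn == pytest.approx(spec.inner_radius, abs=0.02)
        assert avg == pytest.approx(spec.inner_radius, abs=0.02)

    def test_simple_arithmetic(self, cylinder_profile):
        from porescan.channel_profiler import RadiusProfile, Station

        stations = [
            Station(axial_coordinate=float(i), center=np.zeros(3), radius=float(r))
            for i, r in enumerate([1.0, 2.0, 3.0])
        ]
        prof = RadiusProfile(stations=stations, params=ProfilerParams())
        mn, avg = profile_stats(prof, "all")
        assert (mn, avg) == (1.0, 2.0)

    def test_empty_window_errors(self, cylinder_profile):
        with pytest.raises(ValueError, match="window"):
            profile_stats(cylinder_profile, (500.0, 600.0))
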