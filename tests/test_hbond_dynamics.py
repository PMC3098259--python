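"""Hydrogen-bond detection oracle checks and water-state tracking."""

import numpy as np
import pytest

from conftest import brute_force_hbonds

from porescan import (
    HBondCriteria,
    StateRules,
    find_hbonds,
    vacancy_intervals,
    water_site_series,
)
from porescan.hbond_dynamics import (
    STATE_EXIT_CAPTURED,
    STATE_TRANSIT,
    STATE_TRIAD_BOUND,
    STATE_VACANT,
)
from porescan.structure_io import Atom, Structure, Ensemble
from porescan.synthetic_data import (
    A295_ONLY,
    MIXED_A295_Y335,
    OccupancyScript,
    Segment,
    TRIAD,
    UNBONDED,
    Y335_ONLY,
    make_site_ensemble,
    site_template,
)


def _frame(atom_rows):
    """Rows: (name, element, x, y, z)."""
    return Structure.from_atoms(
        [
            Atom(
                serial=i + 1, name=n, residue_name="DUM", chain="A",
                residue_number=i + 1, element=e, position=np.array([x, y, z]),
            )
            for i, (n, e, x, y, z) in enumerate(atom_rows)
        ]
    )


def _random_frame(rng, n=30):
    rows = []
    for i in range(n):
        element = rng.choice(["N", "O", "H", "C"], p=[0.25, 0.25, 0.4, 0.1])
        x, y, z = rng.uniform(-4, 4, 3)
        rows.append((f"A{i}", element, x, y, z))
    return _frame(rows)


class TestFindHbonds:
    def test_ideal_linear_geometry(self):
        frame = _frame(
            [("O1", "O", 0, 0, 0), ("H1", "H", 0.96, 0, 0), ("O2", "O", 2.8, 0, 0)]
        )
        bonds = find_hbonds(frame)
        assert len(bonds) == 1
        b = bonds[0]
        assert (b.donor_index, b.hydrogen_index, b.acceptor_index) == (0, 1, 2)
        assert b.distance == pytest.approx(2.8)
        assert b.angle == pytest.approx(0.0, abs=1e-6)

    def test_distance_cutoff_excludes(self):
        frame = _frame(
            [("O1", "O", 0, 0, 0), ("H1", "H", 0.96, 0, 0), ("O2", "O", 3.6, 0, 0)]
        )
        assert find_hbonds(frame) == []

    def test_angle_cutoff_excludes(self):
        # hydrogen 40° off the donor-acceptor axis
        theta = np.deg2rad(40)
        frame = _frame(
            [
                ("O1", "O", 0, 0, 0),
                ("H1", "H", 0.96 * np.cos(theta), 0.96 * np.sin(theta), 0),
                ("O2", "O", 2.8, 0, 0),
            ]
        )
        assert find_hbonds(frame) == []

    def test_matches_brute_force_on_random_frames(self):
        rng = np.random.default_rng(11)
        criteria = HBondCriteria()
        for _ in range(40):
            frame = _random_frame(rng)
            elements = np.char.upper(frame.element.astype(str))
            heavy = np.flatnonzero(np.isin(elements, ["N", "O"]))
            got = {
                (b.donor_index, b.hydrogen_index, b.acceptor_index)
                for b in find_hbonds(
                    frame, heavy, heavy, criteria, require_hydrogens=False
                )
            }
            expected = brute_force_hbonds(frame, heavy, heavy, criteria)
            assert got == expected

    def test_monotone_under_tightening(self):
        rng = np.random.default_rng(5)
        loose = HBondCriteria(max_donor_acceptor_distance=3.5, max_angle=35)
        for _ in range(10):
            frame = _random_frame(rng)
            n_loose = len(find_hbonds(frame, criteria=loose, require_hydrogens=False))
            for tight in (
                HBondCriteria(max_donor_acceptor_distance=3.0, max_angle=35),
                HBondCriteria(max_donor_acceptor_distance=3.5, max_angle=20),
                HBondCriteria(max_donor_acceptor_distance=2.8, max_angle=15),
            ):
                n_tight = len(
                    find_hbonds(frame, criteria=tight, require_hydrogens=False)
                )
                assert n_tight <= n_loose

    def test_rigid_transformation_invariance(self):
        rng = np.random.default_rng(3)
        frame = _random_frame(rng)
        theta = 1.1
        rot = np.array(
            [
                [1, 0, 0],
                [0, np.cos(theta), -np.sin(theta)],
                [0, np.sin(theta), np.cos(theta)],
            ]
        )
        moved = frame.copy()
        moved.coords = frame.coords @ rot.T + np.array([5.0, -3.0, 2.0])
        key = lambda bonds: sorted(
            (b.donor_index, b.hydrogen_index, b.acceptor_index) for b in bonds
        )
        assert key(find_hbonds(frame, require_hydrogens=False)) == key(
            find_hbonds(moved, require_hydrogens=False)
        )

    def test_no_hydrogens_raises_when_required(self):
        frame = _frame([("O1", "O", 0, 0, 0), ("O2", "O", 2.8, 0, 0)])
        with pytest.raises(ValueError, match="hydrogen"):
            find_hbonds(frame)


class TestWaterSiteSeries:
    def test_triad_bound_throughout(self):
        script = OccupancyScript([Segment(10, TRIAD)])
        series = water_site_series(make_site_ensemble(script))
        assert series.states == [STATE_TRIAD_BOUND] * 10
        np.testing.assert_array_equal(
            series.counts, np.tile([1, 1, 1, 0], (10, 1))
        )
        np.testing.assert_array_equal(series.total, np.full(10, 3))

    def test_exit_sequence(self):
        # triad bonds → A295-only → Y335-only → vacancy
        script = OccupancyScript(
            [
                Segment(2, TRIAD),
                Segment(2, A295_ONLY),
                Segment(2, Y335_ONLY),
                Segment(2, None),
            ]
        )
        series = water_site_series(make_site_ensemble(script))
        assert series.states == (
            [STATE_TRIAD_BOUND] * 2
            + [STATE_TRANSIT] * 2
            + [STATE_EXIT_CAPTURED] * 2
            + [STATE_VACANT] * 2
        )

    def test_mixed_and_unbonded_states(self):
        script = OccupancyScript(
            [Segment(1, MIXED_A295_Y335), Segment(1, UNBONDED)]
        )
        series = water_site_series(make_site_ensemble(script))
        assert series.states == [STATE_TRANSIT, STATE_TRANSIT]
        np.testing.assert_array_equal(series.counts[0], [0, 1, 0, 1])
        np.testing.assert_array_equal(series.counts[1], [0, 0, 0, 0])

    def test_no_waters_all_vacant_with_warning(self):
        template = site_template()
        frames = [template.copy() for _ in range(3)]
        ens = Ensemble(frames=frames, frame_times=np.array([0.0, 10.0, 20.0]))
        with pytest.warns(UserWarning, match="no waters"):
            series = water_site_series(ens)
        assert series.states == [STATE_VACANT] * 3
        assert series.total.sum() == 0

    def test_identity_change_flagged_once(self):
        script = OccupancyScript(
            [Segment(3, TRIAD, 9001), Segment(3, TRIAD, 9101)]
        )
        series = water_site_series(make_site_ensemble(script))
        assert list(np.flatnonzero(series.identity_change)) == [3]

    def test_state_rules_total(self):
        rules = StateRules()
        labels = ["G292", "A295", "Y305", "Y335"]
        for pattern in range(16):
            counts = {lbl: (pattern >> i) & 1 for i, lbl in enumerate(labels)}
            assert rules.classify(counts, True) in (
                STATE_TRIAD_BOUND, STATE_EXIT_CAPTURED, STATE_TRANSIT,
            )
        assert rules.classify({}, False) == STATE_VACANT


class TestVacancyIntervals:
    def test_no_vacancy_empty(self):
        series = water_site_series(make_site_ensemble(OccupancyScript([Segment(5, TRIAD)])))
        assert vacancy_intervals(series) == []

    def test_single_run_duration(self):
        script = OccupancyScript(
            [Segment(3, TRIAD), Segment(744, None), Segment(3, TRIAD)],
            stride_ps=10.0,
        )
        series = water_site_series(make_site_ensemble(script))
        intervals = vacancy_intervals(series)
        assert len(intervals) == 1
        start, end, duration = intervals[0]
        assert duration == pytest.approx(7440.0)
        assert start == pytest.approx(30.0)

    def test_alternating_single_frames(self):
        segments = []
        for _ in range(3):
            segments += [Segment(1, None), Segment(1, TRIAD)]
        series = water_site_series(
            make_site_ensemble(OccupancyScript(segments, stride_ps=10.0))
        )
        intervals = vacancy_intervals(series)
        assert len(intervals) == 3
        assert all(d == pytest.approx(10.0) for _, _, d in intervals)

    def test_total_vacancy_bounded_by_duration(self):
        script = OccupancyScript(
            [Segment(4, None), Segment(3, TRIAD), Segment(5, None)], stride_ps=10.0
        )
        series = water_site_series(make_site_ensemble(script))
        total = sum(d for _, _, d in vacancy_intervals(series))
        assert total <= script.n_frames * script.stride_ps
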