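import numpy as np
import pytest

from gelscan import Trajectory, build_grid_system
from gelscan.core_model import SystemFrame
from gelscan.geometry import random_rotation, rotation_about_axis
from gelscan.interactions import (
    InteractionEvent,
    classify_stacking,
    default_taxonomy,
    detect_hbond,
    enumerate_interactions,
    min_heavy_atom_distance,
    percent_frequency,
)


def _hexagon(center, z, r=1.39):
    ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    return np.column_stack(
        [center[0] + r * np.cos(ang), center[1] + r * np.sin(ang), np.full(6, z)]
    )


class TestMinDistance:
    def test_minimum_image_across_boundary(self, f34):
        coords = np.zeros((2, f34.n_atoms, 3))
        coords[0, :, 0] = 1.0
        coords[1, :, 0] = 89.0
        frame = SystemFrame(0, 0.2, (90, 90, 90), coords)
        sel = np.array([0])
        assert min_heavy_atom_distance(frame, 0, 1, sel, sel) == pytest.approx(2.0)

    def test_superposed_copies_are_at_zero(self, f34):
        coords = np.stack([f34.coords, f34.coords]) + 20.0
        frame = SystemFrame(0, 0.2, (90, 90, 90), coords)
        h = f34.heavy_indices
        assert min_heavy_atom_distance(frame, 0, 1, h, h) == 0.0

    def test_matches_exhaustive_double_loop(self, f34, rng):
        box = np.array([30.0, 30.0, 30.0])
        for _ in range(20):
            a = rng.uniform(0, 30, (10, 3))
            b = rng.uniform(0, 30, (10, 3))
            coords = np.zeros((2, f34.n_atoms, 3))
            coords[0, :10] = a
            coords[1, :10] = b
            frame = SystemFrame(0, 0.2, box, coords)
            sel = np.arange(10)
            got = min_heavy_atom_distance(frame, 0, 1, sel, sel)
            best = np.inf
            for p in a:
                for q in b:
                    d = q - p
                    d -= box * np.round(d / box)
                    best = min(best, float(np.linalg.norm(d)))
            assert got == pytest.approx(best, abs=1e-12)

    def test_empty_selection_raises(self, f34):
        frame = SystemFrame(0, 0.2, (90, 90, 90), np.zeros((2, f34.n_atoms, 3)))
        with pytest.raises(ValueError, match="empty"):
            min_heavy_atom_distance(frame, 0, 1, np.array([], dtype=int), np.array([0]))


class TestStacking:
    def test_parallel_rings_face_to_face(self):
        a = _hexagon((0, 0), 0.0)
        b = _hexagon((0, 0), 4.0)
        cls, geom = classify_stacking(a, b)
        assert cls == "face_to_face"
        assert geom["centroid_distance"] == pytest.approx(4.0)
        assert geom["interplanar_angle"] == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_rings_offset_or_edge(self):
        a = _hexagon((0, 0), 0.0)
        b = _hexagon((0, 0), 0.0)
        rot = rotation_about_axis([1, 0, 0], 90.0)
        b = b @ rot.T + np.array([0.0, 0.0, 5.0])
        cls, geom = classify_stacking(a, b)
        assert cls == "offset_or_edge"
        assert geom["interplanar_angle"] == pytest.approx(90.0)

    def test_distant_rings_none(self):
        cls, _ = classify_stacking(_hexagon((0, 0), 0.0), _hexagon((0, 0), 9.0))
        assert cls == "none"

    def test_degenerate_ring_raises(self):
        line = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
        with pytest.raises(ValueError, match="collinear"):
            classify_stacking(line, _hexagon((0, 0), 4.0))


class TestHbond:
    def test_canonical_bond_detected(self):
        d = np.array([0.0, 0, 0])
        h = np.array([1.01, 0, 0])
        a = np.array([2.9, 0.35, 0])  # ~173 deg
        ok, geom = detect_hbond(d, h, a)
        assert ok
        assert geom["da_distance"] < 3.0

    def test_long_contact_rejected(self):
        ok, _ = detect_hbond(
            np.zeros(3), np.array([1.01, 0, 0]), np.array([4.2, 0, 0])
        )
        assert not ok

    def test_threshold_grid_matches_direct_evaluation(self):
        """Acceptors placed on an exact (distance, angle) grid must be
        accepted iff the planted distance and angle pass the thresholds."""
        d = np.zeros(3)
        h = np.array([1.0, 0.0, 0.0])
        for dist in (2.6, 3.0, 3.45, 3.55, 4.0):
            for ang in (100.0, 115.0, 125.0, 150.0, 180.0):
                theta = np.radians(180.0 - ang)
                direction = np.array([np.cos(theta), np.sin(theta), 0.0])
                # solve for the ray length from H giving D...A == dist
                lo, hi = 0.0, 8.0
                for _ in range(80):
                    mid = 0.5 * (lo + hi)
                    if np.linalg.norm(h + mid * direction - d) < dist:
                        lo = mid
                    else:
                        hi = mid
                a = h + lo * direction
                ok, geom = detect_hbond(d, h, a)
                assert geom["da_distance"] == pytest.approx(dist, abs=1e-6)
                assert geom["dha_angle"] == pytest.approx(ang, abs=1e-6)
                assert ok == (dist <= 3.5 and ang >= 120.0)

    def test_missing_hydrogen_instructs_placement(self):
        with pytest.raises(ValueError, match="place hydrogens"):
            detect_hbond(np.zeros(3), None, np.ones(3))


class TestEnumerate:
    def test_initial_grid_has_zero_events(self, f34):
        frame = build_grid_system(f34, 8, (40, 40, 40), (90, 90, 90), seed=2)
        traj = Trajectory(0, f34, [frame])
        assert enumerate_interactions(traj) == []

    def test_planted_fmoc_stack_gives_exactly_one_event(self, f34):
        # translate a copy along the fluorene normal: a tight face-to-face
        # stack within the heavy-atom contact cutoff
        xyz = f34.coords
        m2 = xyz + np.array([0.0, 0.0, 3.7])
        coords = np.stack([xyz, m2]) + 40.0
        frame = SystemFrame(0, 0.2, (200, 200, 200), coords)
        traj = Trajectory(0, f34, [frame])
        events = enumerate_interactions(traj)
        stacks = [e for e in events if e.label == "FMOC_FMOC_STACK"]
        assert len(stacks) == 1
        assert stacks[0].geometry["classification"] == "face_to_face"

    def test_events_invariant_under_global_rigid_motion(self, f34, rng):
        from gelscan.synthetic import plant_contact_chain

        chain = plant_contact_chain(f34, ["F_F"], np.random.default_rng(4))
        coords = chain + 60.0
        frame = SystemFrame(0, 0.2, (500, 500, 500), coords)
        base = enumerate_interactions(Trajectory(0, f34, [frame]))
        rot = random_rotation(rng)
        center = np.array([250.0] * 3)
        moved = (coords - center) @ rot.T + center
        frame2 = SystemFrame(0, 0.2, (500, 500, 500), moved)
        after = enumerate_interactions(Trajectory(0, f34, [frame2]))
        assert {(e.label, e.i, e.j) for e in base} == {
            (e.label, e.i, e.j) for e in after
        }

    def test_event_pair_ordering_normalized(self):
        e = InteractionEvent(0, 3, 1, "F_F", 2.5)
        assert (e.i, e.j) == (1, 3)
        with pytest.raises(ValueError):
            InteractionEvent(0, 2, 2, "F_F", 1.0)

    def test_brute_force_oracle_on_small_systems(self, f34, rng):
        """Pair-level contact events must match an exhaustive atom-loop
        reimplementation of the cutoff rule on small random systems."""
        h = f34.heavy_indices
        fl = np.array(f34.fluorine_indices)
        box = np.array([60.0, 60.0, 60.0])
        local = f34.coords - f34.coords.mean(axis=0)
        for trial in range(10):
            n = int(rng.integers(2, 6))
            coords = np.stack(
                [
                    local @ random_rotation(rng).T + rng.uniform(10, 50, 3)
                    for _ in range(n)
                ]
            )
            frame = SystemFrame(0, 0.2, box, coords)
            events = enumerate_interactions(Trajectory(0, f34, [frame]))
            got_ff = {(e.i, e.j) for e in events if e.label == "F_F"}
            want_ff = set()
            for i in range(n):
                for j in range(i + 1, n):
                    best = np.inf
                    for p in coords[i, fl]:
                        for q in coords[j, fl]:
                            d = q - p
                            d -= box * np.round(d / box)
                            best = min(best, np.linalg.norm(d))
                    if best <= 4.0:
                        want_ff.add((i, j))
            assert got_ff == want_ff


class TestPercentFrequency:
    def _events(self, spec):
        out = []
        for rep, counts in spec.items():
            k = 0
            for label, n in counts.items():
                for _ in range(n):
                    out.append(InteractionEvent(0, 2 * k, 2 * k + 1, label, 1.0, rep))
                    k += 1
        return out

    def test_counts_to_percents(self):
        table = percent_frequency(
            self._events({0: {"FMOC_FMOC_STACK": 75, "F_F": 25}})
        )
        by = {
            (r["label"], r["replicate"]): r["percent"] for _, r in table.iterrows()
        }
        assert by[("FMOC_FMOC_STACK", 0)] == pytest.approx(75.0)
        assert by[("F_F", 0)] == pytest.approx(25.0)

    def test_single_label_is_100(self):
        table = percent_frequency(self._events({0: {"F_F": 7}}))
        row = table[(table.label == "F_F") & (table.replicate == 0)]
        assert float(row.percent.iloc[0]) == pytest.approx(100.0)

    def test_percents_sum_to_100_machine_precision(self, rng):
        labels = [s.label for s in default_taxonomy()]
        events = []
        for rep in range(4):
            for _ in range(500):
                lab = labels[int(rng.integers(len(labels)))]
                events.append(InteractionEvent(0, 0, 1, lab, 1.0, rep))
        table = percent_frequency(events, labels)
        for rep in range(4):
            s = table[table.replicate == rep].percent.sum()
            assert s == pytest.approx(100.0, abs=1e-9)

    def test_multinomial_generator_recovered(self, rng):
        """Sampling labels with known probabilities, the percent table
        must recover them (multinomial oracle, n = 10000)."""
        probs = {"A": 0.5, "B": 0.3, "C": 0.2}
        labels = list(probs)
        draws = rng.choice(labels, size=10000, p=list(probs.values()))
        events = [InteractionEvent(0, 0, 1, lab, 1.0, 0) for lab in draws]
        table = percent_frequency(events, labels)
        for lab, p in probs.items():
            row = table[(table.label == lab) & (table.replicate == 0)]
            assert float(row.percent.iloc[0]) == pytest.approx(100 * p, abs=1.5)

    def test_zero_event_replicate_excluded_with_warning(self, caplog):
        events = self._events({0: {"F_F": 5}})
        import logging

        with caplog.at_level(logging.WARNING):
            table = percent_frequency(events + [], labels=["F_F"])
        assert not table.empty
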