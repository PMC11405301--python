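import numpy as np
import pytest

from seegviz.electrodes import (
    BuildParams,
    assign_labels,
    brain_center,
    build_electrodes,
    electrodes_table,
    number_contacts,
)
from seegviz.volumes import VoxelGrid


def _mask_grid(mask):
    return VoxelGrid(np.asarray(mask, dtype=np.uint8), np.eye(4))


def _line(start, direction, n, step=3.5):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return np.array([np.asarray(start, float) + i * step * d for i in range(n)])


class TestBrainCenter:
    def test_centered_cube(self):
        m = np.zeros((21, 21, 21))
        m[5:15, 5:15, 5:15] = 1
        np.testing.assert_allclose(brain_center(_mask_grid(m)), (9.5, 9.5, 9.5))

    def test_two_equal_cubes_average(self):
        m = np.zeros((30, 10, 10))
        m[2:6, 3:7, 3:7] = 1
        m[22:26, 3:7, 3:7] = 1
        c = brain_center(_mask_grid(m))
        np.testing.assert_allclose(c, (13.5, 4.5, 4.5))

    def test_ellipsoid_centroid_near_analytic_center(self, phantom_default):
        _, _, brain, _ = phantom_default
        c = brain_center(brain)
        np.testing.assert_allclose(c, (0.0, 0.0, 0.0), atol=1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            brain_center(_mask_grid(np.zeros((5, 5, 5))))


class TestBuildElectrodes:
    def test_collinear_chain_single_electrode_in_order(self):
        pts = _line((50, 0, 0), (-1, 0, 0), 6)
        elecs = build_electrodes(pts, np.zeros(3))
        assert len(elecs) == 1
        # spatial order along the line, starting at the outermost point
        got_x = elecs[0].points_mm[:, 0]
        assert np.all(np.diff(got_x) < 0)

    def test_parallel_trajectories_never_merge(self):
        a = _line((50, 0, 0), (-1, 0, 0), 6)
        b = _line((50, 10, 0), (-1, 0, 0), 6)
        pts = np.vstack([a, b])
        elecs = build_electrodes(pts, np.zeros(3))
        assert len(elecs) == 2
        sets = [frozenset(e.contact_ids) for e in elecs]
        assert frozenset(range(6)) in sets and frozenset(range(6, 12)) in sets
        # brute-force confirmation: any cross-line hop violates the rules
        params = BuildParams()
        for i in range(6):
            for j in range(6, 12):
                for k in range(6):
                    if k == i:
                        continue
                    u = pts[i] - pts[k]
                    v = pts[j] - pts[i]
                    cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    hop = np.linalg.norm(v)
                    assert ang > params.max_deviation_deg or hop > 4.0

    def test_bent_trajectory_stays_one_electrode(self):
        # 15 degree bend at mid-shaft is absorbed by the 20 degree limit
        first = _line((60, 0, 0), (-1, 0, 0), 3)
        bend = np.deg2rad(15)
        d2 = np.array([-np.cos(bend), np.sin(bend), 0.0])
        second = _line(first[-1] + 3.5 * d2, d2, 3)
        pts = np.vstack([first, second])
        elecs = build_electrodes(pts, np.zeros(3))
        assert len(elecs) == 1
        assert elecs[0].n_contacts == 6

    def test_orphan_contact_becomes_singleton(self):
        pts = np.vstack([_line((40, 0, 0), (-1, 0, 0), 4), [[0, 60, 0]]])
        elecs = build_electrodes(pts, np.zeros(3))
        sizes = sorted(e.n_contacts for e in elecs)
        assert sizes == [1, 4]

    def test_partition_and_permutation_invariance(self, rng):
        pts = np.vstack(
            [
                _line((50, 5, 0), (-1, 0.1, 0.05), 8),
                _line((0, 55, 5), (0.05, -1, 0.1), 10),
                _line((-45, -10, 5), (1, 0.15, -0.1), 6),
            ]
        )
        elecs = build_electrodes(pts, np.zeros(3))
        ids = sorted(i for e in elecs for i in e.contact_ids)
        assert ids == list(range(len(pts)))  # exact partition
        ref_sets = sorted(sorted(e.contact_ids) for e in elecs)
        for _ in range(3):
            perm = rng.permutation(len(pts))
            elecs_p = build_electrodes(pts[perm], np.zeros(3))
            got = sorted(sorted(perm[e.contact_ids].tolist()) for e in elecs_p)
            assert got == ref_sets


class TestNumbering:
    def test_deep_end_gets_number_one(self):
        pts = _line((50, 0, 0), (-1, 0, 0), 6)  # builds outermost-first
        e = build_electrodes(pts, np.zeros(3))[0]
        e = number_contacts(e, np.zeros(3))
        deep = e.points_mm[np.argmin(e.numbers)]
        assert np.linalg.norm(deep) == min(np.linalg.norm(p) for p in e.points_mm)
        assert sorted(e.numbers) == list(range(1, 7))

    def test_symmetric_tie_broken_lexicographically(self):
        pts = np.array([[-5.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        e = build_electrodes(pts, np.zeros(3))[0]
        e = number_contacts(e, np.zeros(3))
        by_num = {n: tuple(p) for n, p in zip(e.numbers, e.points_mm)}
        assert by_num[1] == (-5.0, 0.0, 0.0)

    def test_phantom_deepest_contact_is_number_one(self, phantom_default):
        spec, _, brain, truth = phantom_default
        center = brain_center(brain)
        pts = truth.centers_mm()
        elecs = [
            number_contacts(e, center)
            for e in build_electrodes(pts, center)
        ]
        for e in elecs:
            # ground-truth contact number of the point numbered 1
            deep_id = e.contact_ids[int(np.argmin(e.numbers))]
            assert truth.contacts.iloc[deep_id]["number"] == 1


class TestAssignLabels:
    def _two(self):
        pts = np.vstack(
            [_line((50, 0, 0), (-1, 0, 0), 6), _line((0, 50, 0), (0, -1, 0), 6)]
        )
        elecs = build_electrodes(pts, np.zeros(3))
        return [number_contacts(e, np.zeros(3)) for e in elecs]

    def test_anchor_maps_to_nearest_tail(self):
        elecs = assign_labels(self._two(), {"A": [52.0, 1.0, 0.0]})
        labels = {e.label for e in elecs}
        assert "A" in labels
        a = next(e for e in elecs if e.label == "A")
        assert a.contact_names()[0].startswith("A")
        assert np.allclose(a.outer_point(), (50, 0, 0))

    def test_empty_map_autonames(self):
        elecs = assign_labels(self._two(), {})
        assert {e.label for e in elecs} == {"E1", "E2"}

    def test_far_anchor_rejected(self):
        with pytest.raises(ValueError, match="no electrode tail"):
            assign_labels(self._two(), {"A": [200.0, 0.0, 0.0]})

    def test_ambiguous_anchor_lists_candidates(self):
        pts = np.vstack(
            [_line((50, 5, 0), (-1, 0, 0), 4), _line((50, -5, 0), (-1, 0, 0), 4)]
        )
        elecs = [
            number_contacts(e, np.zeros(3))
            for e in build_electrodes(pts, np.zeros(3))
        ]
        with pytest.raises(ValueError, match="ambiguous"):
            assign_labels(elecs, {"A": [50.0, 0.0, 0.0]})

    def test_table_output_sorted(self):
        elecs = assign_labels(self._two(), {"A": [52.0, 1.0, 0.0]})
        df = electrodes_table(elecs)
        assert list(df.columns[:3]) == ["electrode", "contact_number", "contact_name"]
        assert len(df) == 12
        a = df[df.electrode == "A"]
        assert list(a.contact_number) == sorted(a.contact_number)


class TestPlantedTrajectoryRecovery:
    """Electrode-partition recovery on phantoms with known geometry."""

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_exact_membership_and_numbering(self, seed):
        from seegviz.phantom import random_study_spec

        spec = random_study_spec(seed)
        truth_rows = []
        pts = []
        for t in spec.electrodes:
            centers = t.contact_centers(spec.contact_spacing_mm)
            for num, c in enumerate(centers, start=1):
                truth_rows.append((t.label, num))
                pts.append(c)
        pts = np.array(pts)
        elecs = build_electrodes(pts, np.zeros(3))
        assert len(elecs) == len(spec.electrodes)
        elecs = [number_contacts(e, np.zeros(3)) for e in elecs]
        for e in elecs:
            labels = {truth_rows[i][0] for i in e.contact_ids}
            assert len(labels) == 1  # no cross-electrode mixing
            got = [truth_rows[i][1] for i in e.contact_ids]
            nums = list(e.numbers)
            assert got == nums  # inner-to-outer numbering matches the plant
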