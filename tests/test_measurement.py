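"""Measurement creation, scale-invariant distance, editing, display."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caliper3d import (
    GrabStateError,
    SceneNode,
    Transform,
    connector_layout,
    create_measurement,
    format_label,
    grab,
    load_sidecar,
    marker_render_scale,
    measured_distance,
    release,
    save_sidecar,
    set_uniform_scale,
    volume_space_distance,
)
from caliper3d.measurement import measurement_from_entry

from conftest import random_quaternion, random_rigid


def _mm_measurement(vol, p1_mm, p2_mm, mid="m"):
    return create_measurement(vol, vol.mm_to_world(p1_mm),
                              vol.mm_to_world(p2_mm), id=mid)


class TestCreateMeasurement:
    def test_world_anchors_reproduced(self, scene_with_volume, rng):
        _, vol = scene_with_volume
        set_uniform_scale(vol, 1.7)
        vol.local = Transform(translation=(0.3, -0.2, 0.5),
                              rotation=random_quaternion(rng), scale=1.7)
        start_w = vol.mm_to_world((1.0, 2.0, 3.0))
        end_w = vol.mm_to_world((4.0, 2.0, 3.0))
        m = create_measurement(vol, start_w, end_w, id="a")
        np.testing.assert_allclose(m.start_world(), start_w, atol=1e-9)
        np.testing.assert_allclose(m.end_world(), end_w, atol=1e-9)

    def test_identity_pose_locals_equal_world(self):
        root = SceneNode("root")
        from caliper3d import VolumeImage, attach_volume
        vol = attach_volume(root, VolumeImage(np.zeros((4, 4, 4))),
                            mm_per_world_unit=1.0)
        m = create_measurement(vol, (0.0, 0.0, 0.0), (0.01, 0.0, 0.0), id="a")
        np.testing.assert_allclose(m.start.local.translation, 0.0, atol=1e-12)
        np.testing.assert_allclose(m.end.local.translation, (0.01, 0, 0),
                                   atol=1e-12)

    def test_translated_volume_shifts_locals(self):
        root = SceneNode("root")
        from caliper3d import VolumeImage, attach_volume
        vol = attach_volume(root, VolumeImage(np.zeros((4, 4, 4))),
                            mm_per_world_unit=1.0)
        vol.local = Transform.from_translation((1.0, 0.0, 0.0))
        m = create_measurement(vol, (1.0, 2.0, 3.0), (1.5, 2.0, 3.0), id="a")
        np.testing.assert_allclose(m.start.local.translation, (0, 2, 3),
                                   atol=1e-12)

    def test_zero_length_measurement_allowed(self, scene_with_volume):
        _, vol = scene_with_volume
        p = vol.mm_to_world((2.0, 2.0, 2.0))
        m = create_measurement(vol, p, p, id="zero")
        assert measured_distance(m) == 0.0

    def test_five_children(self, scene_with_volume):
        _, vol = scene_with_volume
        m = _mm_measurement(vol, (0, 0, 0), (3, 0, 0))
        assert sorted(c.name for c in m.measurement_node.children) == [
            "connector", "end", "label", "label_link", "start"]


class TestMeasuredDistance:
    def test_reference_scale_one_reports_world_mm(self):
        root = SceneNode("root")
        from caliper3d import VolumeImage, attach_volume
        vol = attach_volume(root, VolumeImage(np.zeros((4, 4, 4))))
        m = create_measurement(vol, (0.0, 0.0, 0.0), (0.03, 0.0, 0.0), id="a")
        assert np.isclose(measured_distance(m), 30.0, atol=1e-9)

    def test_zoom_invariance(self):
        root = SceneNode("root")
        from caliper3d import VolumeImage, attach_volume
        vol = attach_volume(root, VolumeImage(np.zeros((4, 4, 4))))
        m = create_measurement(vol, (0.0, 0.0, 0.0), (0.03, 0.0, 0.0), id="a")
        set_uniform_scale(vol, 2.0)
        sep = np.linalg.norm(m.end_world() - m.start_world())
        assert np.isclose(sep, 0.06, atol=1e-12)  # world separation doubled
        assert np.isclose(measured_distance(m), 30.0, rtol=1e-9)

    def test_equals_mm_space_euclidean_under_random_pose(self,
                                                         scene_with_volume, rng):
        _, vol = scene_with_volume
        for _ in range(20):
            p1, p2 = rng.uniform(0, 8, size=(2, 3))
            vol.local = Transform(translation=rng.normal(size=3),
                                  rotation=random_quaternion(rng),
                                  scale=np.exp(rng.uniform(-1.2, 1.2)))
            m = _mm_measurement(vol, p1, p2)
            expected = np.linalg.norm(p2 - p1)
            assert np.isclose(measured_distance(m), expected, rtol=1e-9)
            assert np.isclose(volume_space_distance(m), expected, rtol=1e-9)
            m.measurement_node.detach()

    def test_rigid_and_zoom_invariance_suite(self, scene_with_volume, rng):
        """100 random rigid motions and zooms leave the distance fixed."""
        _, vol = scene_with_volume
        m = _mm_measurement(vol, (1.0, 1.0, 1.0), (5.0, 3.0, 2.0))
        baseline = measured_distance(m)
        assert np.isclose(baseline, np.linalg.norm((4.0, 2.0, 1.0)), rtol=1e-9)
        for _ in range(100):
            t = random_rigid(rng)
            vol.local = Transform(translation=t.translation,
                                  rotation=t.rotation,
                                  scale=np.exp(rng.uniform(-1.6, 1.6)))
            assert np.isclose(measured_distance(m), baseline, rtol=1e-9)

    def test_independent_of_mm_per_world_unit(self, small_volume, rng):
        from caliper3d import attach_volume
        for mmpw in (1.0, 254.0, 1000.0, 3000.0):
            root = SceneNode("root")
            vol = attach_volume(root, small_volume, mm_per_world_unit=mmpw)
            m = _mm_measurement(vol, (0.0, 1.0, 0.0), (0.0, 1.0, 6.5))
            assert np.isclose(measured_distance(m), 6.5, rtol=1e-9)


class TestEditing:
    def test_grab_move_release_changes_distance(self, scene_with_volume):
        root, vol = scene_with_volume
        ctrl = SceneNode("controller", parent=root)
        m = _mm_measurement(vol, (0, 0, 0), (3, 0, 0))
        grab(m.end, ctrl)
        ctrl.local = Transform.from_translation((0.002, 0.0, 0.0))
        moved = measured_distance(m)
        release(m.end)
        # oracle: recompute from the mm-space coordinates after the edit
        expected = np.linalg.norm(m.end_mm() - m.start_mm())
        assert np.isclose(moved, expected, rtol=1e-9)
        assert np.isclose(measured_distance(m), expected, rtol=1e-9)

    def test_grab_release_without_motion_is_identity(self, scene_with_volume,
                                                     rng):
        root, vol = scene_with_volume
        vol.local = Transform(translation=(0.1, 0.2, 0.3),
                              rotation=random_quaternion(rng), scale=1.4)
        ctrl = SceneNode("controller", parent=root,
                         local=Transform.from_translation((1, 1, 1)))
        m = _mm_measurement(vol, (1, 2, 3), (4, 5, 6))
        before = measured_distance(m)
        start_before = m.start_world()
        grab(m.start, ctrl)
        release(m.start)
        assert m.start.parent is m.measurement_node
        np.testing.assert_allclose(m.start_world(), start_before, atol=1e-9)
        assert np.isclose(measured_distance(m), before, rtol=1e-9)

    def test_grab_connector_moves_whole_measurement_rigidly(
            self, scene_with_volume):
        root, vol = scene_with_volume
        ctrl = SceneNode("controller", parent=root)
        m = _mm_measurement(vol, (0, 0, 0), (3, 0, 0))
        d0 = measured_distance(m)
        s0, e0 = m.start_world(), m.end_world()
        grab(m.connector, ctrl)
        assert m.measurement_node.parent is ctrl
        ctrl.local = Transform.from_translation((0.004, 0.001, 0.0))
        shift_s = m.start_world() - s0
        shift_e = m.end_world() - e0
        np.testing.assert_allclose(shift_s, shift_e, atol=1e-9)
        assert np.isclose(measured_distance(m), d0, rtol=1e-9)
        release(m.connector)
        assert m.measurement_node.parent is vol.image_node

    def test_double_grab_rejected_and_bare_release_warns(self,
                                                         scene_with_volume):
        root, vol = scene_with_volume
        ctrl = SceneNode("controller", parent=root)
        m = _mm_measurement(vol, (0, 0, 0), (3, 0, 0))
        grab(m.end, ctrl)
        with pytest.raises(GrabStateError):
            grab(m.end, ctrl)
        release(m.end)
        with pytest.warns(UserWarning):
            release(m.end)

    def test_editing_closure_structure_intact(self, scene_with_volume, rng):
        """Random grab/move/release sequences keep the five-child subtree."""
        root, vol = scene_with_volume
        ctrl = SceneNode("controller", parent=root)
        m = _mm_measurement(vol, (0, 0, 0), (3, 0, 0))
        elements = [m.start, m.end, m.label, m.connector]
        for _ in range(30):
            el = elements[rng.integers(len(elements))]
            grab(el, ctrl)
            ctrl.local = Transform.from_translation(rng.normal(scale=0.01,
                                                               size=3))
            release(el)
        names = sorted(c.name for c in m.measurement_node.children)
        assert names == ["connector", "end", "label", "label_link", "start"]
        assert m.measurement_node.parent is vol.image_node
        # still a valid forest: walking the root terminates without cycles
        assert sum(1 for _ in root.walk()) >= 8


class TestConnectorLayout:
    def test_counts(self):
        lay = connector_layout((0, 0, 0), (10, 0, 0), segment_length=1, gap=1)
        assert len(lay) == 5
        assert len(connector_layout((0, 0, 0), (0, 0, 0), 1, 1)) == 0

    def test_segments_regular_and_symmetric(self):
        lay = connector_layout((0, 0, 0), (10, 0, 0), segment_length=1, gap=1)
        centres = np.array([c for c, _, _ in lay.segment_poses])
        gaps = np.diff(centres[:, 0])
        np.testing.assert_allclose(gaps, gaps[0], atol=1e-9)
        np.testing.assert_allclose(centres[0, 0] + centres[-1, 0], 10.0,
                                   atol=1e-9)  # symmetric about the midpoint
        for _, direction, length in lay.segment_poses:
            np.testing.assert_allclose(direction, (1, 0, 0), atol=1e-12)
            assert length == 1

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(d=st.floats(0.01, 50.0), d2=st.floats(0.0, 10.0))
    def test_count_nondecreasing_in_distance(self, d, d2):
        n1 = len(connector_layout((0, 0, 0), (d, 0, 0), 1.0, 0.5))
        n2 = len(connector_layout((0, 0, 0), (d + d2, 0, 0), 1.0, 0.5))
        assert n2 >= n1


class TestDisplay:
    @pytest.mark.parametrize("scale", [1.0, 2.0, 0.25, 3.7])
    def test_marker_render_scale_cancels_zoom(self, scale):
        assert marker_render_scale(scale) * scale == pytest.approx(1.0,
                                                                   abs=1e-15)
        assert marker_render_scale(2.0) == 0.5
        assert marker_render_scale(0.25) == 4.0

    @pytest.mark.parametrize("distance,precision,expected", [
        (30.04, 0.1, "30.0 mm"),
        (10.4, 1.0, "10 mm"),
        (3.45, 0.1, "3.5 mm"),   # ties away from zero
        (10.5, 1.0, "11 mm"),
        (0.0, 0.1, "0.0 mm"),
        (2.5, 0.25, "2.50 mm"),
    ])
    def test_format_label(self, distance, precision, expected):
        assert format_label(distance, precision) == expected

    def test_label_refreshes_on_edit(self, scene_with_volume):
        root, vol = scene_with_volume
        ctrl = SceneNode("controller", parent=root)
        m = _mm_measurement(vol, (0, 0, 0), (3, 0, 0))
        assert m.label_text == "3.0 mm"
        grab(m.end, ctrl)
        ctrl.local = Transform.from_translation(
            (1.0 / vol.mm_per_world_unit, 0, 0))
        release(m.end)
        assert m.refresh_label() == "4.0 mm"

    def test_connector_layout_world_scales_with_zoom(self, scene_with_volume):
        _, vol = scene_with_volume
        # 9.5 mm: not an exact multiple of the dash pitch, so the count is
        # insensitive to floating-point jitter under zoom
        m = _mm_measurement(vol, (0, 0, 0), (9.5, 0, 0))
        n1 = len(m.connector_layout_world())
        set_uniform_scale(vol, 3.0)
        # dash count depends on the anatomical length only, not the zoom
        assert len(m.connector_layout_world()) == n1


class TestSidecar:
    def test_roundtrip_bit_exact(self, scene_with_volume, tmp_path):
        _, vol = scene_with_volume
        m1 = _mm_measurement(vol, (0.1, 0.2, 0.3), (3.7, 0.2, 0.3), "m1")
        m2 = _mm_measurement(vol, (1, 1, 1), (2, 2, 2), "m2")
        path = tmp_path / "measurements.json"
        save_sidecar([m1, m2], path)
        entries = load_sidecar(path)
        assert [e["id"] for e in entries] == ["m1", "m2"]
        # save what we loaded: the file must be byte-identical
        path2 = tmp_path / "again.json"
        save_sidecar(entries, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_entries_are_mm_space_and_reanchorable(self, scene_with_volume,
                                                   tmp_path, rng):
        _, vol = scene_with_volume
        set_uniform_scale(vol, 2.5)
        m = _mm_measurement(vol, (0.5, 1.5, 2.5), (4.5, 1.5, 2.5), "m1")
        path = tmp_path / "m.json"
        save_sidecar([m], path)
        entry = load_sidecar(path)[0]
        np.testing.assert_allclose(entry["start_mm"], (0.5, 1.5, 2.5),
                                   atol=1e-9)
        assert entry["distance_mm"] == pytest.approx(4.0, rel=1e-9)
        restored = measurement_from_entry(vol, entry)
        assert measured_distance(restored) == pytest.approx(4.0, rel=1e-9)
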