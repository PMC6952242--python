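"""Linear measurements anchored to a volume in the scene graph.

A measurement is a small subtree parented under the volume it annotates, so
it translates, rotates and zooms with the anatomy.  It has five children:
the start point, the end point, the dashed connector between them, the text
label, and the line linking the label to the end point.

The distance is computed in *world* space and divided by the accumulated
uniform scale of the scene's reference-scale node (the volume).  This keeps
the reported value in true anatomical millimetres no matter how the volume
is posed or zoomed, and — unlike computing in volume-local coordinates —
keeps working while an endpoint is temporarily re-parented to a controller
during editing.

Editing follows the grab/release idiom: grabbing re-parents the element
under the controller node without moving it in world space, so it then
tracks the controller; releasing restores the original parent, again
preserving world pose.  Grabbing the connector redirects to the whole
measurement, so all five children move rigidly together.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._rounding import precision_decimals, round_to_multiple
from .exceptions import ConfigurationError, GrabStateError
from .scene_graph import (
    SceneNode,
    Transform,
    accumulated_uniform_scale,
    find_reference_node,
    reparent_keep_world,
)
from .volume_io import VolumeNode

__all__ = [
    "Measurement",
    "ConnectorLayout",
    "create_measurement",
    "measured_distance",
    "volume_space_distance",
    "grab",
    "release",
    "connector_layout",
    "marker_render_scale",
    "format_label",
    "save_sidecar",
    "load_sidecar",
    "measurement_from_entry",
]

#: Default display precision of the measurement label, mm.
DEFAULT_DISPLAY_PRECISION_MM = 0.1

# Display geometry at reference scale 1 (the render meshes are inversely
# scaled with zoom, so these stay this size on screen).  Arbitrary defaults.
DEFAULT_MARKER_SPHERE_RADIUS_MM = 1.0
DEFAULT_MARKER_SPOKE_LENGTH_MM = 4.0
DEFAULT_CONNECTOR_SEGMENT_MM = 2.0
DEFAULT_CONNECTOR_GAP_MM = 2.0

_CHILD_NAMES = ("start", "end", "connector", "label", "label_link")


@dataclass
class ConnectorLayout:
    """Poses of the dashed-connector segments along the measurement chord."""

    segment_poses: list[tuple[np.ndarray, np.ndarray, float]]
    gap: float
    segment_length: float

    def __len__(self) -> int:
        return len(self.segment_poses)


@dataclass
class Measurement:
    """A single linear measurement attached to a volume.

    ``measurement_node`` is a child of the volume's image-space node, so its
    local coordinates (and those of its start/end children, when not
    grabbed) are physical millimetres.
    """

    id: str
    volume: VolumeNode
    measurement_node: SceneNode
    display_precision: float = DEFAULT_DISPLAY_PRECISION_MM
    frame_index: int = 0
    label_text: str = ""
    marker_sphere_radius_mm: float = DEFAULT_MARKER_SPHERE_RADIUS_MM
    marker_spoke_length_mm: float = DEFAULT_MARKER_SPOKE_LENGTH_MM
    connector_segment_mm: float = DEFAULT_CONNECTOR_SEGMENT_MM
    connector_gap_mm: float = DEFAULT_CONNECTOR_GAP_MM
    # direct references: elements stay reachable while transiently re-parented
    # to a controller during editing
    _nodes: dict = field(default_factory=dict, repr=False)

    @property
    def start(self) -> SceneNode:
        return self._element("start")

    @property
    def end(self) -> SceneNode:
        return self._element("end")

    @property
    def connector(self) -> SceneNode:
        return self._element("connector")

    @property
    def label(self) -> SceneNode:
        return self._element("label")

    @property
    def label_link(self) -> SceneNode:
        return self._element("label_link")

    def _element(self, name: str) -> SceneNode:
        try:
            return self._nodes[name]
        except KeyError:
            raise ConfigurationError(
                f"measurement {self.id!r} has no element {name!r}") from None

    def start_world(self) -> np.ndarray:
        return self.start.to_world((0.0, 0.0, 0.0))

    def end_world(self) -> np.ndarray:
        return self.end.to_world((0.0, 0.0, 0.0))

    def start_mm(self) -> np.ndarray:
        """Start point in the volume's physical mm space."""
        return self.volume.world_to_mm(self.start_world())

    def end_mm(self) -> np.ndarray:
        return self.volume.world_to_mm(self.end_world())

    def distance_mm(self) -> float:
        return measured_distance(self)

    def refresh_label(self) -> str:
        """Re-format the label from the current distance (call on mutation)."""
        self.label_text = format_label(self.distance_mm(), self.display_precision)
        return self.label_text

    def connector_layout_world(self) -> ConnectorLayout:
        """Dashed-connector layout in world units at the current zoom.

        Dash length and gap are fixed sizes at reference scale 1 and scale
        with the volume, so the dash count depends only on the anatomical
        distance, not the zoom.
        """
        scale = accumulated_uniform_scale(_reference_node(self))
        to_world_units = scale / self.volume.mm_per_world_unit
        return connector_layout(
            self.start_world(), self.end_world(),
            segment_length=self.connector_segment_mm * to_world_units,
            gap=self.connector_gap_mm * to_world_units,
        )


def create_measurement(volume_node: VolumeNode, start_world, end_world,
                       id: str,
                       display_precision: float = DEFAULT_DISPLAY_PRECISION_MM,
                       frame_index: int = 0) -> Measurement:
    """Create a measurement between two world-space points.

    The measurement subtree is parented under the volume so it tracks the
    volume's pose and zoom; start/end local positions are set so that their
    world positions equal the given points.  Coincident endpoints are
    allowed (a zero-length measurement).
    """
    parent = volume_node.image_node
    mnode = SceneNode(f"measurement:{id}", parent=parent)
    start_local = mnode.to_local(np.asarray(start_world, dtype=float))
    end_local = mnode.to_local(np.asarray(end_world, dtype=float))
    nodes = {
        "start": SceneNode("start", local=Transform.from_translation(start_local),
                           parent=mnode),
        "end": SceneNode("end", local=Transform.from_translation(end_local),
                         parent=mnode),
        "connector": SceneNode("connector", parent=mnode),
        "label": SceneNode(
            "label",
            local=Transform.from_translation(
                0.5 * (start_local + end_local) + (0.0, 5.0, 0.0)),
            parent=mnode),
        "label_link": SceneNode("label_link", parent=mnode),
    }
    m = Measurement(id=str(id), volume=volume_node, measurement_node=mnode,
                    display_precision=float(display_precision),
                    frame_index=int(frame_index), _nodes=nodes)
    m.refresh_label()
    return m


def _reference_node(m: Measurement) -> SceneNode:
    """The reference-scale node governing this measurement's zoom correction.

    Preferentially found on the measurement node's ancestor path; while the
    whole measurement is grabbed the path runs through the controller, so we
    fall back to the unique reference node of the scene.
    """
    for node in [m.measurement_node] + list(m.measurement_node.ancestors()):
        if node.is_reference_scale:
            return node
    ref = find_reference_node(m.measurement_node.root())
    if ref is None:
        ref = find_reference_node(m.volume.root())
    if ref is None:
        raise ConfigurationError(
            f"no reference-scale node found for measurement {m.id!r}")
    return ref


def measured_distance(m: Measurement,
                      mm_per_world_unit: float | None = None) -> float:
    """Distance between the endpoints in anatomical millimetres.

    ``mm_per_world_unit * ||world(end) - world(start)|| / reference_scale``,
    where ``reference_scale`` is the accumulated uniform scale of the
    scene's reference-scale node.  Invariant to any rigid motion or uniform
    zoom of the volume, and valid while elements are grabbed.
    """
    if mm_per_world_unit is None:
        mm_per_world_unit = m.volume.mm_per_world_unit
    if mm_per_world_unit <= 0:
        raise ValueError("mm_per_world_unit must be positive")
    ref = _reference_node(m)
    d_world = float(np.linalg.norm(m.end_world() - m.start_world()))
    return mm_per_world_unit * d_world / accumulated_uniform_scale(ref)


def volume_space_distance(m: Measurement) -> float:
    """Distance computed from volume-local (mm) endpoint coordinates.

    An independent route to the same value, valid whenever no element is
    grabbed (a grabbed endpoint's local position is controller-relative, not
    volume-relative, which is why the world-space route is primary).
    """
    return float(np.linalg.norm(m.end_mm() - m.start_mm()))


# ---------------------------------------------------------------------------
# Editing (grab / release)
# ---------------------------------------------------------------------------

def _grab_target(element: SceneNode) -> SceneNode:
    # the connector acts as a handle for the whole measurement
    if element.name == "connector":
        parent = element.parent
        if parent is None or not parent.name.startswith("measurement:"):
            raise GrabStateError("connector is not attached to a measurement")
        return parent
    return element


def grab(element: SceneNode, controller: SceneNode) -> None:
    """Pick up an element: re-parent it under the controller, keeping world pose.

    ``element`` may be the start point, end point, label, or the connector
    (which redirects to the whole measurement node so all five children move
    together).  The original parent is recorded for :func:`release`.
    """
    target = _grab_target(element)
    if getattr(target, "_grab_original_parent", None) is not None:
        raise GrabStateError(f"{target.name!r} is already grabbed")
    original = target.parent
    if original is None:
        raise GrabStateError(f"{target.name!r} has no parent to restore")
    reparent_keep_world(target, controller)
    target._grab_original_parent = original


def release(element: SceneNode) -> None:
    """Let go of an element: restore its original parent, keeping world pose.

    Releasing something that is not grabbed is a warning no-op.
    """
    target = _grab_target(element)
    original = getattr(target, "_grab_original_parent", None)
    if original is None:
        warnings.warn(f"release of {target.name!r} without grab; ignored",
                      stacklevel=2)
        return
    reparent_keep_world(target, original)
    target._grab_original_parent = None


# ---------------------------------------------------------------------------
# Display helpers
# ---------------------------------------------------------------------------

def connector_layout(start_world, end_world, segment_length: float,
                     gap: float) -> ConnectorLayout:
    """Dash poses for the connector between two points.

    ``n = max(1, floor((d + gap) / (segment_length + gap)))`` dashes, centred
    symmetrically on the chord with equal gaps; the degenerate zero-length
    chord yields an empty layout.
    """
    if segment_length <= 0:
        raise ValueError("segment_length must be positive")
    if gap < 0:
        raise ValueError("gap must be non-negative")
    s = np.asarray(start_world, dtype=float)
    e = np.asarray(end_world, dtype=float)
    d = float(np.linalg.norm(e - s))
    if d == 0.0:
        return ConnectorLayout([], gap=gap, segment_length=segment_length)
    u = (e - s) / d
    n = max(1, math.floor((d + gap) / (segment_length + gap)))
    span = n * segment_length + (n - 1) * gap
    first_centre = 0.5 * (d - span) + 0.5 * segment_length
    pitch = segment_length + gap
    poses = [(s + u * (first_centre + i * pitch), u.copy(), segment_length)
             for i in range(n)]
    return ConnectorLayout(poses, gap=gap, segment_length=segment_length)


def marker_render_scale(reference_scale: float) -> float:
    """Inverse-scale factor for marker/label render meshes.

    Multiplying the mesh scale by ``1 / reference_scale`` cancels the zoom,
    so markers keep a constant world (on-screen) size.
    """
    if reference_scale <= 0:
        raise ValueError("reference_scale must be positive")
    return 1.0 / reference_scale


def format_label(distance_mm: float, display_precision: float,
                 unit: str = "mm") -> str:
    """Render a distance at the tool's display precision.

    Rounds to the nearest multiple of the precision with ties away from
    zero and shows exactly the decimals the precision implies
    (e.g. ``format_label(3.45, 0.1) == "3.5 mm"``).
    """
    q = round_to_multiple(distance_mm, display_precision)
    decimals = precision_decimals(display_precision)
    return f"{q:.{decimals}f} {unit}"


# ---------------------------------------------------------------------------
# Sidecar JSON
# ---------------------------------------------------------------------------

def _entry_from_measurement(m: Measurement) -> dict:
    return {
        "id": m.id,
        "label": m.label_text,
        "start_mm": [float(x) for x in m.start_mm()],
        "end_mm": [float(x) for x in m.end_mm()],
        "distance_mm": m.distance_mm(),
        "display_precision_mm": m.display_precision,
        "frame_index": m.frame_index,
    }


def save_sidecar(measurements, path) -> None:
    """Write measurements as a JSON sidecar.

    Coordinates are stored in the volume's physical mm space, so the file is
    portable to any viewer that understands the image geometry.  Stored
    decimals survive a load/save round trip bit-exactly (floats are
    serialised with shortest round-trip repr).
    """
    entries = [
        e if isinstance(e, dict) else _entry_from_measurement(e)
        for e in measurements
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(entries, fh, indent=2)
        fh.write("\n")


def load_sidecar(path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        entries = json.load(fh)
    if not isinstance(entries, list):
        raise ValueError(f"sidecar {path!r} must contain a JSON array")
    return entries


def measurement_from_entry(volume_node: VolumeNode, entry: dict) -> Measurement:
    """Re-anchor a sidecar entry to a volume in a scene."""
    m = create_measurement(
        volume_node,
        volume_node.mm_to_world(entry["start_mm"]),
        volume_node.mm_to_world(entry["end_mm"]),
        id=entry["id"],
        display_precision=entry.get("display_precision_mm",
                                    DEFAULT_DISPLAY_PRECISION_MM),
        frame_index=entry.get("frame_index", 0),
    )
    return m
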