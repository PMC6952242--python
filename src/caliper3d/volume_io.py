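"""Volumetric image I/O and voxel/physical/world coordinate mapping.

Images are read and written with SimpleITK, so NIfTI-1 (``.nii``,
``.nii.gz``) and MetaImage (``.mha``, ``.mhd``) come for free and physical
space is LPS millimetres, the DICOM convention (SimpleITK converts NIfTI's
RAS on read).  Continuous voxel indices are 0-based and voxel-centred.

A volume enters the scene through :func:`attach_volume`, which creates a
:class:`VolumeNode` holding the image.  The node itself carries the user's
pose and zoom and is flagged as the scene's reference scale; an internal
``image_space`` child maps physical millimetres to world units (1 world unit
= ``mm_per_world_unit`` mm of anatomy, 1000 by default so anatomy lives at
metre scale).  A point ``p`` mm from the volume origin therefore sits
``p / 1000`` world units from the node origin at zoom 1.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .exceptions import ConfigurationError, VolumeFormatError
from .scene_graph import SceneNode, Transform, find_reference_node

__all__ = [
    "VolumeImage",
    "VolumeNode",
    "read_volume",
    "write_volume",
    "index_to_physical",
    "physical_to_index",
    "attach_volume",
    "set_uniform_scale",
    "DEFAULT_MM_PER_WORLD_UNIT",
]

#: 1 world unit = 1 m; image headers are in mm.
DEFAULT_MM_PER_WORLD_UNIT = 1000.0

_SUPPORTED_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


@dataclass
class VolumeImage:
    """A voxel grid with physical-space (mm) geometry.

    ``voxels`` is indexed ``[i, j, k]`` (x-fastest convention);
    ``direction`` is the orthonormal matrix whose columns are the physical
    directions of the voxel axes.
    """

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got ndim={self.voxels.ndim}")
        if np.isscalar(self.spacing):
            self.spacing = np.full(3, float(self.spacing))
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.allclose(self.direction.T @ self.direction, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def size_mm(self) -> np.ndarray:
        """Physical extent of the grid along each voxel axis."""
        return self.spacing * np.asarray(self.voxels.shape)


def _check_extension(path: str) -> None:
    low = str(path).lower()
    if not low.endswith(_SUPPORTED_EXTENSIONS):
        raise VolumeFormatError(
            f"unsupported volume format for {path!r} "
            f"(expected one of {', '.join(_SUPPORTED_EXTENSIONS)})")


def read_volume(path) -> VolumeImage:
    """Read a NIfTI or MetaImage volume; geometry metadata is preserved."""
    path = os.fspath(path)
    _check_extension(path)
    if not os.path.exists(path):
        raise VolumeFormatError(f"volume file not found: {path!r}")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:
        raise VolumeFormatError(f"could not read volume {path!r}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeFormatError(
            f"{path!r} is {img.GetDimension()}-D; only 3-D volumes are supported")
    # sitk arrays are (z, y, x); transpose to our (x, y, z) indexing
    voxels = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return VolumeImage(
        voxels=voxels,
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
        direction=np.array(img.GetDirection()).reshape(3, 3),
    )


def write_volume(image: VolumeImage, path) -> None:
    """Write a volume; ``write_volume`` then :func:`read_volume` is lossless."""
    path = os.fspath(path)
    _check_extension(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        np.transpose(image.voxels, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in image.spacing))
    img.SetOrigin(tuple(float(o) for o in image.origin))
    img.SetDirection(tuple(float(d) for d in image.direction.flatten()))
    try:
        sitk.WriteImage(img, path)
    except RuntimeError as exc:
        raise VolumeFormatError(f"could not write volume {path!r}: {exc}") from exc


def index_to_physical(image: VolumeImage, ijk) -> np.ndarray:
    """Continuous voxel index -> physical mm: origin + direction @ (spacing ∘ ijk)."""
    idx = np.asarray(ijk, dtype=float)
    return (idx * image.spacing) @ image.direction.T + image.origin


def physical_to_index(image: VolumeImage, point_mm) -> np.ndarray:
    """Physical mm -> continuous voxel index (inverse of index_to_physical).

    Out-of-grid indices are allowed (the caller decides what to do with them).
    """
    p = np.asarray(point_mm, dtype=float)
    return ((p - image.origin) @ image.direction) / image.spacing


class VolumeNode(SceneNode):
    """Scene node anchoring a volume; the scene's reference-scale object.

    The node's own transform holds the user's pose and zoom (and is what
    :func:`~caliper3d.scene_graph.accumulated_uniform_scale` measures); its
    ``image_space`` child applies the fixed mm -> world-unit factor so that
    children of ``image_node`` use physical millimetres as local coordinates.
    """

    def __init__(self, name: str, image: VolumeImage,
                 mm_per_world_unit: float = DEFAULT_MM_PER_WORLD_UNIT,
                 parent: SceneNode | None = None):
        if mm_per_world_unit <= 0:
            raise ValueError("mm_per_world_unit must be positive")
        super().__init__(name, parent=parent, is_reference_scale=True)
        self.image = image
        self.mm_per_world_unit = float(mm_per_world_unit)
        self._image_node = SceneNode(
            "image_space",
            local=Transform.from_scale(1.0 / self.mm_per_world_unit),
            parent=self,
        )

    @property
    def image_node(self) -> SceneNode:
        """The node whose local coordinates are physical millimetres."""
        return self._image_node

    def mm_to_world(self, point_mm) -> np.ndarray:
        return self._image_node.to_world(point_mm)

    def world_to_mm(self, world_point) -> np.ndarray:
        return self._image_node.to_local(world_point)


def attach_volume(scene_root: SceneNode, image: VolumeImage,
                  mm_per_world_unit: float = DEFAULT_MM_PER_WORLD_UNIT,
                  name: str = "volume") -> VolumeNode:
    """Attach a volume under ``scene_root`` at anatomical metre scale.

    The new node is flagged as the reference scale; attaching a second
    volume to a scene that already has one raises ConfigurationError.
    """
    if find_reference_node(scene_root.root()) is not None:
        raise ConfigurationError(
            "scene already has a reference-scale node; only one is allowed")
    return VolumeNode(name, image, mm_per_world_unit, parent=scene_root)


def set_uniform_scale(node: SceneNode, scale: float) -> None:
    """Set a node's local scale to a uniform factor, keeping pose (zoom)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    node.local = Transform(translation=node.local.translation,
                           rotation=node.local.rotation,
                           scale=(scale, scale, scale))
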