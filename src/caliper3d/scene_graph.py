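"""Parent-child transform hierarchy with local/world conversion.

The scene graph is a forest of :class:`SceneNode` objects.  Each node owns a
local :class:`Transform` (translation, rotation, per-axis scale, composed in
scale-rotation-translation order) relative to its parent; the world transform
of a node is the fold of local transforms from its root down to the node.

Conventions
-----------
* World coordinates are right-handed; one world unit corresponds to one
  metre by convention (volumes are attached so anatomy is at metre scale).
* Quaternions are stored ``(x, y, z, w)`` (scalar last) and normalised on
  construction.
* Transforms compose as ``T * R * S`` (scale first).  Composition and
  reparenting are carried out on 4x4 homogeneous matrices, so composites of
  anisotropic scales and rotations (which are not expressible as TRS) remain
  exact; the TRS accessors decompose on demand and raise
  :class:`~caliper3d.exceptions.TransformError` if the linear part carries
  shear.

A node may be flagged ``is_reference_scale``: distances measured in world
space are divided by the accumulated uniform scale of that node, so that
zooming the displayed volume never changes a reported measurement.  At most
one node per scene may carry the flag.
"""

from __future__ import annotations

import json
from typing import Callable, Iterator, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import (
    AnisotropicScaleError,
    SceneStructureError,
    TransformError,
)

__all__ = [
    "Transform",
    "SceneNode",
    "compose",
    "world_transform",
    "to_world",
    "to_local",
    "reparent_keep_world",
    "accumulated_uniform_scale",
    "find_reference_node",
    "scene_to_dict",
    "scene_from_dict",
    "save_scene",
    "load_scene",
]

_QUAT_NORM_TOL = 1e-9
_ORTHO_TOL = 1e-6
_ANISO_TOL = 1e-6


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    return v


class Transform:
    """A rigid-plus-scale spatial transform.

    Parameters
    ----------
    translation
        3-vector, world units.
    rotation
        Unit quaternion ``(x, y, z, w)``.  Normalised on construction;
        a zero quaternion is rejected.
    scale
        3-vector of strictly positive per-axis scale factors.
    """

    __slots__ = ("_matrix", "_trs")

    def __init__(self, translation=(0.0, 0.0, 0.0), rotation=(0.0, 0.0, 0.0, 1.0),
                 scale=(1.0, 1.0, 1.0)):
        t = _as_vec3(translation, "translation")
        q = np.asarray(rotation, dtype=float)
        if q.shape != (4,):
            raise ValueError("rotation must be a quaternion (x, y, z, w)")
        norm = np.linalg.norm(q)
        if norm < _QUAT_NORM_TOL:
            raise TransformError("zero-norm quaternion")
        q = q / norm
        if np.isscalar(scale):
            s = np.full(3, float(scale))
        else:
            s = _as_vec3(scale, "scale")
        if np.any(s <= 0):
            raise TransformError(f"scale components must be positive, got {s}")
        m = np.eye(4)
        m[:3, :3] = Rotation.from_quat(q).as_matrix() * s[np.newaxis, :]
        m[:3, 3] = t
        self._matrix = m
        # authored TRS kept verbatim so serialisation round-trips bit-exactly
        self._trs = (t.copy(), q.copy(), s.copy())

    # -- constructors -----------------------------------------------------

    @classmethod
    def identity(cls) -> "Transform":
        return cls()

    @classmethod
    def from_translation(cls, t) -> "Transform":
        return cls(translation=t)

    @classmethod
    def from_scale(cls, s) -> "Transform":
        return cls(scale=np.full(3, float(s)) if np.isscalar(s) else s)

    @classmethod
    def from_matrix(cls, matrix) -> "Transform":
        """Wrap a 4x4 homogeneous affine matrix without decomposing it."""
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise TransformError(f"expected a 4x4 matrix, got shape {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise TransformError("bottom row of an affine matrix must be (0,0,0,1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-15:
            raise TransformError("singular linear part")
        obj = cls.__new__(cls)
        obj._matrix = m.copy()
        obj._matrix[3] = (0.0, 0.0, 0.0, 1.0)
        obj._trs = None
        return obj

    # -- accessors --------------------------------------------------------

    @property
    def matrix(self) -> np.ndarray:
        """The 4x4 homogeneous matrix (a copy)."""
        return self._matrix.copy()

    @property
    def translation(self) -> np.ndarray:
        if self._trs is not None:
            return self._trs[0].copy()
        return self._matrix[:3, 3].copy()

    def _decompose(self) -> tuple[np.ndarray, np.ndarray]:
        """Split the linear part into (rotation matrix, scale vector).

        Valid only for shear-free transforms; raises TransformError otherwise.
        """
        a = self._matrix[:3, :3]
        s = np.linalg.norm(a, axis=0)
        if np.any(s <= 0):
            raise TransformError("degenerate scale")
        r = a / s[np.newaxis, :]
        if not np.allclose(r.T @ r, np.eye(3), atol=_ORTHO_TOL):
            raise TransformError("transform carries shear; no TRS decomposition")
        if np.linalg.det(r) < 0:
            raise TransformError("transform carries a reflection; scales must be positive")
        return r, s

    @property
    def rotation(self) -> np.ndarray:
        """Unit quaternion ``(x, y, z, w)`` of the rotation part."""
        if self._trs is not None:
            return self._trs[1].copy()
        r, _ = self._decompose()
        return Rotation.from_matrix(r).as_quat()

    @property
    def scale(self) -> np.ndarray:
        if self._trs is not None:
            return self._trs[2].copy()
        _, s = self._decompose()
        return s

    # -- algebra ----------------------------------------------------------

    def compose(self, other: "Transform") -> "Transform":
        """Return ``self ∘ other`` (apply ``other`` first, then ``self``)."""
        return Transform.from_matrix(self._matrix @ other._matrix)

    def __matmul__(self, other: "Transform") -> "Transform":
        return self.compose(other)

    def inverse(self) -> "Transform":
        return Transform.from_matrix(np.linalg.inv(self._matrix))

    def apply(self, points) -> np.ndarray:
        """Map one point (3,) or many points (N, 3) through the transform."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        if p.shape[1] != 3:
            raise ValueError("points must have shape (3,) or (N, 3)")
        out = p @ self._matrix[:3, :3].T + self._matrix[:3, 3]
        return out[0] if single else out

    def is_close(self, other: "Transform", atol: float = 1e-9) -> bool:
        return np.allclose(self._matrix, other._matrix, atol=atol)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        try:
            r, s = self._decompose()
            q = Rotation.from_matrix(r).as_quat()
            return (f"Transform(translation={self.translation.tolist()}, "
                    f"rotation={q.tolist()}, scale={s.tolist()})")
        except TransformError:
            return f"Transform(matrix={self._matrix.tolist()})"


class SceneNode:
    """A named node in the transform hierarchy.

    Children are ordered; a node belongs to at most one parent.  Structural
    edits go through :meth:`add_child` / :meth:`detach` /
    :func:`reparent_keep_world`, which maintain the forest invariant.
    """

    def __init__(self, name: str, local: Transform | None = None,
                 parent: "SceneNode | None" = None,
                 is_reference_scale: bool = False):
        self.name = str(name)
        self.local = local if local is not None else Transform.identity()
        self._parent: SceneNode | None = None
        self.children: list[SceneNode] = []
        self.is_reference_scale = bool(is_reference_scale)
        if parent is not None:
            parent.add_child(self)

    # -- structure --------------------------------------------------------

    @property
    def parent(self) -> "SceneNode | None":
        return self._parent

    def add_child(self, node: "SceneNode") -> None:
        if node is self or node.is_ancestor_of(self):
            raise SceneStructureError(
                f"adding {node.name!r} under {self.name!r} would create a cycle")
        if node._parent is not None:
            node._parent.children.remove(node)
        node._parent = self
        self.children.append(node)

    def detach(self) -> None:
        """Remove this node (and its subtree) from its parent, making it a root."""
        if self._parent is not None:
            self._parent.children.remove(self)
            self._parent = None

    def is_ancestor_of(self, node: "SceneNode") -> bool:
        for anc in node.ancestors():
            if anc is self:
                return True
        return False

    def ancestors(self) -> Iterator["SceneNode"]:
        """Yield parent, grandparent, ... up to the root (cycle-checked)."""
        seen = {id(self)}
        cur = self._parent
        while cur is not None:
            if id(cur) in seen:
                raise SceneStructureError(f"cycle detected above node {self.name!r}")
            seen.add(id(cur))
            yield cur
            cur = cur._parent

    def root(self) -> "SceneNode":
        node = self
        for anc in self.ancestors():
            node = anc
        return node

    def walk(self) -> Iterator["SceneNode"]:
        """Depth-first iteration over this node's subtree, self first."""
        stack = [self]
        seen = set()
        while stack:
            node = stack.pop()
            if id(node) in seen:
                raise SceneStructureError(f"cycle detected at node {node.name!r}")
            seen.add(id(node))
            yield node
            stack.extend(reversed(node.children))

    def find(self, predicate: Callable[["SceneNode"], bool]) -> "SceneNode | None":
        for node in self.walk():
            if predicate(node):
                return node
        return None

    def child(self, name: str) -> "SceneNode":
        for c in self.children:
            if c.name == name:
                return c
        raise KeyError(f"node {self.name!r} has no child named {name!r}")

    # -- geometry ---------------------------------------------------------

    def world_transform(self) -> Transform:
        return world_transform(self)

    def to_world(self, local_point) -> np.ndarray:
        return to_world(self, local_point)

    def to_local(self, world_point) -> np.ndarray:
        return to_local(self, world_point)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        flag = ", reference_scale" if self.is_reference_scale else ""
        return f"SceneNode({self.name!r}, {len(self.children)} children{flag})"


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def compose(parent_world: Transform, local: Transform) -> Transform:
    """Transform mapping the child's local coordinates to world coordinates."""
    return parent_world.compose(local)


def world_transform(node: SceneNode) -> Transform:
    """Fold of local transforms from the node's root down to the node."""
    chain = [node] + list(node.ancestors())
    world = chain[-1].local
    for n in reversed(chain[:-1]):
        world = compose(world, n.local)
    return world


def to_world(node: SceneNode, local_point) -> np.ndarray:
    return world_transform(node).apply(local_point)


def to_local(node: SceneNode, world_point) -> np.ndarray:
    return world_transform(node).inverse().apply(world_point)


def reparent_keep_world(node: SceneNode, new_parent: SceneNode) -> None:
    """Move ``node`` under ``new_parent`` without changing its world pose.

    The node's local transform is rewritten to ``inv(world(new_parent)) ∘
    world(node)``, so every point of the node's subtree keeps its world
    position.  Reparenting under the node itself or one of its descendants
    is rejected (it would create a cycle).
    """
    if new_parent is node or node.is_ancestor_of(new_parent):
        raise SceneStructureError(
            f"cannot reparent {node.name!r} under its own subtree")
    world = world_transform(node)
    parent_world = world_transform(new_parent)
    node.local = parent_world.inverse().compose(world)
    new_parent.add_child(node)


def accumulated_uniform_scale(node: SceneNode) -> float:
    """Product of uniform local scales from the root down to ``node``.

    Every node on the path must carry an isotropic scale (within a relative
    tolerance of 1e-6, in which case the geometric mean is used); anisotropic
    scale raises :class:`AnisotropicScaleError`, because the zoom correction
    of measured distances is only defined for uniform zoom.
    """
    total = 1.0
    for n in [node] + list(node.ancestors()):
        s = n.local.scale
        mean = float(np.cbrt(s[0] * s[1] * s[2]))
        if np.max(np.abs(s - mean)) > _ANISO_TOL * mean:
            raise AnisotropicScaleError(
                f"anisotropic reference scale {s.tolist()} on node {n.name!r}")
        total *= mean
    return total


def find_reference_node(root: SceneNode) -> SceneNode | None:
    """The unique reference-scale node of a scene, or None.

    Raises SceneStructureError if the flag is set on more than one node.
    """
    hits = [n for n in root.walk() if n.is_reference_scale]
    if len(hits) > 1:
        names = [n.name for n in hits]
        raise SceneStructureError(f"multiple reference-scale nodes: {names}")
    return hits[0] if hits else None


# ---------------------------------------------------------------------------
# JSON (de)serialisation
# ---------------------------------------------------------------------------

def _node_to_dict(node: SceneNode) -> dict:
    return {
        "name": node.name,
        "translation": node.local.translation.tolist(),
        "rotation": node.local.rotation.tolist(),
        "scale": node.local.scale.tolist(),
        "is_reference_scale": node.is_reference_scale,
        "children": [_node_to_dict(c) for c in node.children],
    }


def scene_to_dict(root: SceneNode) -> dict:
    """Serialise a scene tree to a plain dict (JSON-compatible)."""
    return _node_to_dict(root)


def scene_from_dict(data: dict, parent: SceneNode | None = None) -> SceneNode:
    node = SceneNode(
        data["name"],
        local=Transform(translation=data["translation"],
                        rotation=data["rotation"],
                        scale=data["scale"]),
        parent=parent,
        is_reference_scale=bool(data.get("is_reference_scale", False)),
    )
    for child in data.get("children", ()):
        scene_from_dict(child, parent=node)
    return node


def save_scene(root: SceneNode, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(scene_to_dict(root), fh, indent=2)
        fh.write("\n")


def load_scene(path) -> SceneNode:
    with open(path, encoding="utf-8") as fh:
        return scene_from_dict(json.load(fh))
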