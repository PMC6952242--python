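"""Synthetic ultrasound calibration phantom and automated caliper.

The phantom emulates the appearance of a scanned grey-scale calibration
phantom containing cylindrical low-scatter ("cyst") inserts of known
diameter — by default three cylinders of 4, 6 and 10 mm — embedded in a
brighter speckled background.  Generation is appearance-level, not acoustic
simulation: voxels inside a cylinder get the insert intensity, the rest the
background intensity; optional multiplicative unit-mean Rayleigh speckle is
applied, then an isotropic Gaussian blur standing in for the point-spread
function.  Everything is deterministic given the spec's seed.

The caliper measures an insert the way a reader would place calipers on a
cyst: it samples the intensity profile along a line through the insert
centre and finds, on each side, where the profile crosses half-way between
the insert plateau and the background plateau (full width at half
contrast).  Crossings are localised by linear interpolation between
samples, so resolution is limited by the image blur and voxel size, not by
the sampling step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .exceptions import EdgeNotFoundError, PhantomSpecError
from .volume_io import VolumeImage, physical_to_index

__all__ = [
    "CylinderInsert",
    "PhantomSpec",
    "CaliperResult",
    "default_phantom_spec",
    "generate_phantom",
    "measure_insert_diameter",
    "insert_profile_axes",
    "caliper_table",
]

#: True diameters (mm) of the default inserts.
DEFAULT_INSERT_DIAMETERS_MM = (4.0, 6.0, 10.0)


@dataclass
class CylinderInsert:
    """A cylindrical low-scatter insert: centre, axis, diameter, length (mm)."""

    centre_mm: np.ndarray
    axis: np.ndarray
    diameter_mm: float
    length_mm: float

    def __post_init__(self):
        self.centre_mm = np.asarray(self.centre_mm, dtype=float).reshape(3)
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise PhantomSpecError("insert axis must be a non-zero vector")
        self.axis = self.axis / n
        if self.diameter_mm <= 0 or self.length_mm <= 0:
            raise PhantomSpecError("insert diameter and length must be positive")

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.diameter_mm

    def half_extent_mm(self) -> np.ndarray:
        """Conservative half-extent of the cylinder along each coordinate axis."""
        a = np.abs(self.axis)
        return 0.5 * self.length_mm * a + self.radius_mm * np.sqrt(
            np.clip(1.0 - a ** 2, 0.0, None))


@dataclass
class PhantomSpec:
    """Geometry and appearance of a synthetic calibration phantom."""

    size_mm: np.ndarray
    spacing_mm: np.ndarray
    inserts: list[CylinderInsert]
    background_intensity: float = 180.0
    insert_intensity: float = 30.0
    blur_sigma_mm: float = 0.3
    speckle: bool = True
    seed: int = 0

    def __post_init__(self):
        self.size_mm = np.asarray(self.size_mm, dtype=float).reshape(3)
        if np.isscalar(self.spacing_mm):
            self.spacing_mm = np.full(3, float(self.spacing_mm))
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        if np.any(self.size_mm <= 0) or np.any(self.spacing_mm <= 0):
            raise PhantomSpecError("volume size and spacing must be positive")
        if self.insert_intensity >= self.background_intensity:
            raise PhantomSpecError(
                "inserts are low-scatter: insert intensity must be below background")
        if self.blur_sigma_mm < 0:
            raise PhantomSpecError("blur sigma must be non-negative")
        self._validate_geometry()

    def _validate_geometry(self) -> None:
        for ins in self.inserts:
            half = ins.half_extent_mm()
            if np.any(ins.centre_mm - half < 0) or np.any(
                    ins.centre_mm + half > self.size_mm):
                raise PhantomSpecError(
                    f"insert of diameter {ins.diameter_mm} mm at "
                    f"{ins.centre_mm.tolist()} does not fit inside the volume")
        # conservative overlap test on axis segments (treats cylinders as
        # capsules; may reject some touching-but-disjoint configurations)
        for i in range(len(self.inserts)):
            for j in range(i + 1, len(self.inserts)):
                a, b = self.inserts[i], self.inserts[j]
                if _segment_distance(a, b) < a.radius_mm + b.radius_mm:
                    raise PhantomSpecError(
                        f"inserts {i} and {j} overlap "
                        f"({a.diameter_mm} mm and {b.diameter_mm} mm)")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(int(round(s)) for s in self.size_mm / self.spacing_mm)


def _segment_distance(a: CylinderInsert, b: CylinderInsert) -> float:
    """Minimum distance between the two cylinders' axis segments."""
    p1 = a.centre_mm - 0.5 * a.length_mm * a.axis
    d1 = a.length_mm * a.axis
    p2 = b.centre_mm - 0.5 * b.length_mm * b.axis
    d2 = b.length_mm * b.axis
    # standard segment-segment closest-approach (Ericson)
    r = p1 - p2
    a11 = d1 @ d1
    a22 = d2 @ d2
    a12 = d1 @ d2
    b1 = d1 @ r
    b2 = d2 @ r
    denom = a11 * a22 - a12 * a12
    s = np.clip((a12 * b2 - a22 * b1) / denom, 0, 1) if denom > 1e-12 else 0.0
    t = (a12 * s + b2) / a22
    t = np.clip(t, 0, 1)
    s = np.clip((a12 * t - b1) / a11, 0, 1)
    return float(np.linalg.norm((p1 + s * d1) - (p2 + t * d2)))


def default_phantom_spec(spacing_mm: float = 0.2, *,
                         speckle: bool = True,
                         blur_sigma_mm: float = 0.3,
                         seed: int = 0) -> PhantomSpec:
    """The standard three-insert phantom (4, 6 and 10 mm cylinders).

    Inserts run parallel (axis along z) and are spaced widely enough along x
    that a horizontal or vertical caliper profile through any insert centre
    reaches a clean background plateau before meeting a neighbour or the
    volume boundary.
    """
    size = (60.0, 24.0, 20.0)
    centres_x = {4.0: 10.0, 6.0: 28.0, 10.0: 48.0}
    inserts = [
        CylinderInsert(centre_mm=(centres_x[d], 12.0, 10.0),
                       axis=(0.0, 0.0, 1.0),
                       diameter_mm=d, length_mm=14.0)
        for d in DEFAULT_INSERT_DIAMETERS_MM
    ]
    return PhantomSpec(size_mm=size, spacing_mm=spacing_mm, inserts=inserts,
                       blur_sigma_mm=blur_sigma_mm, speckle=speckle, seed=seed)


def generate_phantom(spec: PhantomSpec) -> VolumeImage:
    """Render a phantom spec to a volume.

    Voxel centres sit at ``origin + index * spacing`` with
    ``origin = spacing / 2``, so the physical domain is ``[0, size_mm]``.
    """
    shape = spec.grid_shape
    vox = np.full(shape, spec.background_intensity, dtype=np.float32)
    origin = spec.spacing_mm / 2.0

    for ins in spec.inserts:
        half = ins.half_extent_mm() + spec.spacing_mm  # one-voxel margin
        lo = np.maximum(
            np.floor((ins.centre_mm - half - origin) / spec.spacing_mm), 0
        ).astype(int)
        hi = np.minimum(
            np.ceil((ins.centre_mm + half - origin) / spec.spacing_mm) + 1,
            shape,
        ).astype(int)
        ii, jj, kk = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        dx = (origin[0] + ii * spec.spacing_mm[0]) - ins.centre_mm[0]
        dy = (origin[1] + jj * spec.spacing_mm[1]) - ins.centre_mm[1]
        dz = (origin[2] + kk * spec.spacing_mm[2]) - ins.centre_mm[2]
        axial = dx * ins.axis[0] + dy * ins.axis[1] + dz * ins.axis[2]
        radial2 = (dx * dx + dy * dy + dz * dz) - axial * axial
        mask = (radial2 <= ins.radius_mm ** 2) & (
            np.abs(axial) <= 0.5 * ins.length_mm)
        sub = vox[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[mask] = spec.insert_intensity

    if spec.speckle:
        rng = np.random.default_rng(spec.seed)
        # unit-mean Rayleigh: scale sigma = sqrt(2/pi)
        field = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=shape)
        vox *= field.astype(np.float32)

    if spec.blur_sigma_mm > 0:
        sigma_vox = spec.blur_sigma_mm / spec.spacing_mm
        vox = gaussian_filter(vox, sigma=sigma_vox)

    return VolumeImage(voxels=vox, spacing=spec.spacing_mm, origin=origin)


@dataclass
class CaliperResult:
    """An automated diameter read-out: the two edge points and their distance."""

    diameter_mm: float
    edge_points_mm: np.ndarray  # (2, 3), low-t edge first
    axis_label: str = ""

    def __post_init__(self):
        self.edge_points_mm = np.asarray(self.edge_points_mm,
                                         dtype=float).reshape(2, 3)


def _sample_profile(image: VolumeImage, points_mm: np.ndarray) -> np.ndarray:
    idx = physical_to_index(image, points_mm)  # (N, 3)
    return map_coordinates(image.voxels.astype(np.float64), idx.T,
                           order=1, mode="nearest")


def _first_crossing(ts: np.ndarray, vs: np.ndarray, threshold: float,
                    rising: bool) -> float:
    """Position of the first threshold crossing moving outward along ts >= 0."""
    above = vs >= threshold if rising else vs <= threshold
    hits = np.nonzero(above[1:] & ~above[:-1])[0]
    if hits.size == 0:
        raise EdgeNotFoundError("no edge crossing found within the profile")
    k = hits[0] + 1
    v0, v1 = vs[k - 1], vs[k]
    frac = 0.0 if v1 == v0 else (threshold - v0) / (v1 - v0)
    return float(ts[k - 1] + frac * (ts[k] - ts[k - 1]))


def measure_insert_diameter(image: VolumeImage, centre_mm, direction,
                            step_mm: float | None = None, *,
                            max_radius_mm: float = 8.0,
                            core_radius_mm: float = 1.0,
                            tail_fraction: float = 0.2,
                            threshold_fraction: float = 0.5,
                            axis_label: str = "") -> CaliperResult:
    """Full-width-at-half-contrast diameter along a line through ``centre_mm``.

    The profile is sampled at ``step_mm`` (default half the smallest voxel
    spacing) out to ``max_radius_mm`` on both sides.  The insert plateau is
    the mean within ``core_radius_mm`` of the centre; the background plateau
    is the mean over the outermost ``tail_fraction`` of each side.  The edge
    is where the profile crosses
    ``insert + threshold_fraction * (background - insert)``, localised by
    linear interpolation; both edges give the diameter.  The criterion uses
    only intensity ratios between the two plateaus, so the result is
    invariant to affine rescaling of the image intensities.
    """
    centre = np.asarray(centre_mm, dtype=float).reshape(3)
    u = np.asarray(direction, dtype=float).reshape(3)
    n = np.linalg.norm(u)
    if n == 0:
        raise ValueError("direction must be a non-zero vector")
    u = u / n
    if step_mm is None:
        step_mm = float(np.min(image.spacing)) / 2.0
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")

    ts = np.arange(0.0, max_radius_mm + step_mm / 2, step_mm)
    if ts.size < 4:
        raise ValueError("max_radius_mm too small for the sampling step")
    pos = _sample_profile(image, centre + np.outer(ts, u))
    neg = _sample_profile(image, centre - np.outer(ts, u))

    core = ts <= core_radius_mm
    insert_mean = float(np.mean(np.concatenate([pos[core], neg[core]])))
    n_tail = max(1, int(round(tail_fraction * ts.size)))
    background_mean = float(np.mean(np.concatenate([pos[-n_tail:],
                                                    neg[-n_tail:]])))
    if background_mean == insert_mean:
        raise EdgeNotFoundError("no contrast between insert and background")
    threshold = insert_mean + threshold_fraction * (background_mean - insert_mean)
    rising = background_mean > insert_mean

    t_pos = _first_crossing(ts, pos, threshold, rising)
    t_neg = _first_crossing(ts, neg, threshold, rising)
    edges = np.stack([centre - t_neg * u, centre + t_pos * u])
    return CaliperResult(diameter_mm=t_pos + t_neg, edge_points_mm=edges,
                         axis_label=axis_label)


def insert_profile_axes(insert: CylinderInsert) -> dict[str, np.ndarray]:
    """Horizontal and vertical profile directions perpendicular to the axis."""
    ref = np.array([0.0, 1.0, 0.0])
    if abs(insert.axis @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    h = np.cross(ref, insert.axis)
    h = h / np.linalg.norm(h)
    v = np.cross(insert.axis, h)
    return {"H": h, "V": v}


def caliper_table(image: VolumeImage, spec: PhantomSpec,
                  step_mm: float | None = None, **caliper_kwargs):
    """Measure every insert of ``spec`` along H and V.

    Returns a pandas DataFrame with one row per insert x axis:
    true diameter, axis label, measured diameter and signed error.
    """
    import pandas as pd

    rows = []
    for ins in spec.inserts:
        for label, direction in insert_profile_axes(ins).items():
            res = measure_insert_diameter(image, ins.centre_mm, direction,
                                          step_mm, axis_label=label,
                                          **caliper_kwargs)
            rows.append({
                "true_diameter_mm": ins.diameter_mm,
                "axis": label,
                "measured_mm": res.diameter_mm,
                "error_mm": res.diameter_mm - ins.diameter_mm,
            })
    return pd.DataFrame(rows)
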