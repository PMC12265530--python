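"""Physical constants, thin-lens magnification and pixel<->world mapping.

Coordinate conventions
----------------------
World frame (right-handed, millimetres):

* ``x`` — the horizontal axis shared by both views (along the well row
  containing the mirror pair), zero at the well centre.
* ``y`` — the horizontal axis seen only in the top view, zero at the well
  centre; the side-view camera (via the 45-degree mirror) looks along ``-y``.
* ``z`` — height above the well bottom, positive up.

Image frame: 0-based pixel indices ``(u, v)`` = (column, row); pixel centres
sit at integer coordinates; the row index increases downward, so the side
view negates it to make ``z`` increase upward.

Each view images the well through a thin lens of focal length ``f`` at an
object distance ``d``; the magnification is ``m(d) = f / (d - f)``.  The
mirror adds extra optical path to the side view, and the object distance of
an individual point additionally varies with its height (top view) or its
``y`` position (side view), which is what makes the per-point magnification
height-dependent.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from .errors import GeometryError

ViewLabel = Literal["top", "side"]

__all__ = [
    "WellGeometry",
    "ViewGeometry",
    "WorldPoint",
    "ViewLabel",
    "thin_lens_magnification",
    "pixel_to_world",
    "world_to_pixel",
    "fuse_point",
    "load_geometry",
    "save_geometry",
]


@dataclass(frozen=True)
class WellGeometry:
    """Dimensions of a single specimen well and its mirror partner.

    All lengths in mm.  ``pitch`` is the centre-to-centre spacing between
    adjacent wells; ``mirror_angle`` is the tilt of the mirror well.
    """

    footprint_x: float = 8.0
    footprint_y: float = 8.0
    depth: float = 12.0
    pitch: float = 9.0
    mirror_angle: float = 45.0
    water_fill: float | None = None

    def __post_init__(self) -> None:
        fill = self.depth if self.water_fill is None else self.water_fill
        object.__setattr__(self, "water_fill", float(fill))
        for name in ("footprint_x", "footprint_y", "depth", "pitch"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0")
        if not 0.0 < self.mirror_angle < 90.0:
            raise GeometryError("mirror_angle must lie in (0, 90) degrees")
        if self.water_fill > self.depth:
            raise GeometryError("water_fill cannot exceed well depth")

    @property
    def half_extent_x(self) -> float:
        return self.footprint_x / 2.0

    @property
    def half_extent_y(self) -> float:
        return self.footprint_y / 2.0


@dataclass(frozen=True)
class ViewGeometry:
    """Per-camera imaging model shared by the top and side views.

    ``axial_offset_side`` is the extra optical path introduced by the
    mirror; its default (pitch + depth/2 = 15 mm) places the side-view
    nominal object plane at the well centre of the mirrored path.
    ``pixel_pitch`` is the physical sensor pixel size in mm; the default is
    derived so that the stated field of view spans the long sensor axis at
    the nominal object distance.  ``focal_plane_z`` is the height (mm above
    the well bottom) whose image is in nominal focus in the top view and is
    used as the reference height for magnification corrections.
    """

    focal_length: float = 25.05
    nominal_object_distance: float = 240.0
    sensor_pixels: tuple[int, int] = (3120, 4208)
    fov: float = 28.5
    axial_offset_top: float = 0.0
    axial_offset_side: float = 15.0
    frame_rate: float = 20.0
    pixel_pitch: float | None = None
    focal_plane_z: float = 6.0
    focal_plane_y: float = 0.0

    def __post_init__(self) -> None:
        if self.focal_length >= self.nominal_object_distance:
            raise GeometryError("focal_length must be < nominal_object_distance")
        if self.fov <= 0 or self.frame_rate <= 0:
            raise GeometryError("fov and frame_rate must be > 0")
        if self.pixel_pitch is None:
            m0 = thin_lens_magnification(self.focal_length, self.nominal_object_distance)
            pitch = self.fov / max(self.sensor_pixels) * m0
            object.__setattr__(self, "pixel_pitch", float(pitch))
        if self.pixel_pitch <= 0:
            raise GeometryError("pixel_pitch must be > 0")

    def axial_offset(self, view: ViewLabel) -> float:
        if view == "top":
            return self.axial_offset_top
        if view == "side":
            return self.axial_offset_side
        raise GeometryError(f"unknown view label {view!r}")

    def object_distance(self, view: ViewLabel, *, z: float = None, y: float = None) -> float:
        """Object distance of a point in the given view.

        The top camera looks down: points below the focal plane are farther
        away.  The side camera (via the mirror) looks along ``-y``: points
        at smaller ``y`` are farther away.
        """
        d = self.nominal_object_distance + self.axial_offset(view)
        if view == "top" and z is not None:
            d += self.focal_plane_z - z
        if view == "side" and y is not None:
            d += self.focal_plane_y - y
        return d

    def magnification(self, view: ViewLabel, *, z: float = None, y: float = None) -> float:
        return thin_lens_magnification(
            self.focal_length, self.object_distance(view, z=z, y=y)
        )

    @property
    def principal_point(self) -> tuple[float, float]:
        """(u, v) image coordinates of the optical axis (sensor centre)."""
        rows, cols = self.sensor_pixels
        return (cols - 1) / 2.0, (rows - 1) / 2.0


@dataclass(frozen=True)
class WorldPoint:
    """3D point in the well frame (mm); see module docstring for axes."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def is_confined(self, well: WellGeometry) -> bool:
        return (
            abs(self.x) <= well.half_extent_x
            and abs(self.y) <= well.half_extent_y
            and 0.0 <= self.z <= well.depth
        )


def thin_lens_magnification(focal_length: float, object_distance: float) -> float:
    """Transverse magnification ``m = f / (d - f)`` of a thin lens.

    Strictly decreasing in the object distance ``d``; raises
    :class:`GeometryError` when the object sits at or inside the focal
    point (no real image).
    """
    if object_distance <= focal_length:
        raise GeometryError(
            f"object distance {object_distance} mm must exceed focal length "
            f"{focal_length} mm"
        )
    return focal_length / (object_distance - focal_length)


def _check_pixel_bounds(uv: tuple[float, float], geom: ViewGeometry) -> None:
    rows, cols = geom.sensor_pixels
    u, v = uv
    if not (np.isfinite(u) and np.isfinite(v)):
        raise GeometryError(f"non-finite pixel coordinates {uv}")
    if not (-0.5 <= u <= cols - 0.5 and -0.5 <= v <= rows - 0.5):
        raise GeometryError(f"pixel {uv} outside sensor {geom.sensor_pixels}")


def pixel_to_world(
    view: ViewLabel,
    pixel_uv: tuple[float, float],
    object_distance: float,
    geom: ViewGeometry,
) -> tuple[float, float]:
    """Map an image pixel to object-plane mm at the given object distance.

    Top view returns ``(x, y)``; side view returns ``(x, z)`` relative to
    the side-view reference height ``focal_plane_z``.  The image row index
    increases downward and is negated in both views so that y and z
    increase in the right-handed world directions.
    """
    _check_pixel_bounds(pixel_uv, geom)
    m = thin_lens_magnification(geom.focal_length, object_distance)
    cu, cv = geom.principal_point
    du = (pixel_uv[0] - cu) * geom.pixel_pitch / m
    dv = (pixel_uv[1] - cv) * geom.pixel_pitch / m
    if view == "top":
        return du, -dv
    if view == "side":
        return du, geom.focal_plane_z - dv
    raise GeometryError(f"unknown view label {view!r}")


def world_to_pixel(
    view: ViewLabel,
    world_2d: tuple[float, float],
    object_distance: float,
    geom: ViewGeometry,
) -> tuple[float, float]:
    """Exact inverse of :func:`pixel_to_world` for in-bounds points."""
    m = thin_lens_magnification(geom.focal_length, object_distance)
    cu, cv = geom.principal_point
    a, b = world_2d
    if view == "top":
        du, dv = a, -b
    elif view == "side":
        du, dv = a, geom.focal_plane_z - b
    else:
        raise GeometryError(f"unknown view label {view!r}")
    uv = (cu + du * m / geom.pixel_pitch, cv + dv * m / geom.pixel_pitch)
    _check_pixel_bounds(uv, geom)
    return uv


def default_fuse_tolerance(geom: ViewGeometry) -> float:
    """5 object-pixels at the nominal top-view distance, in mm."""
    m = geom.magnification("top")
    return 5.0 * geom.pixel_pitch / m


def fuse_point(
    top_xy: tuple[float, float],
    side_xz: tuple[float, float],
    tolerance: float,
) -> tuple[WorldPoint, bool]:
    """Combine a top-view (x, y) and side-view (x, z) estimate into 3D.

    The shared ``x`` axis is reconciled by the arithmetic mean of the two
    estimates; the returned flag is True when the two estimates disagree by
    more than ``tolerance`` mm.
    """
    vals = (*top_xy, *side_xz)
    if not all(math.isfinite(v) for v in vals):
        raise GeometryError(f"non-finite input to fuse_point: {vals}")
    x = 0.5 * (top_xy[0] + side_xz[0])
    mismatch = abs(top_xy[0] - side_xz[0]) > tolerance
    return WorldPoint(x=x, y=top_xy[1], z=side_xz[1]), mismatch


def save_geometry(path: str | Path, well: WellGeometry, view: ViewGeometry) -> None:
    doc = {"well": asdict(well), "view": asdict(view)}
    doc["view"]["sensor_pixels"] = list(view.sensor_pixels)
    Path(path).write_text(yaml.safe_dump(doc))


def load_geometry(path: str | Path) -> tuple[WellGeometry, ViewGeometry]:
    """Read a flat YAML geometry/config file written by :func:`save_geometry`."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "well" not in doc or "view" not in doc:
        raise GeometryError(f"{path}: expected 'well' and 'view' sections")
    view_kwargs = dict(doc["view"])
    if "sensor_pixels" in view_kwargs:
        view_kwargs["sensor_pixels"] = tuple(view_kwargs["sensor_pixels"])
    return WellGeometry(**doc["well"]), ViewGeometry(**view_kwargs)
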