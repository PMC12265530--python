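"""Per-larva kinematic metrics in 2D (top view only) and 3D.

The 3D reference point is the midpoint of the line connecting the two
eyes (the head being the only rigid body part).  Per-frame displacement is
the Euclidean distance between consecutive reference points; speed and
acceleration follow by forward differencing with the frame rate; the total
travel distance is the sum of inter-frame displacements.  The tail angle
is measured between the nostril-to-reference "forward" vector and the
nostril-to-tail vector.

2D mode drops the z coordinate before taking norms, which is exactly what
a top-view-only tracker would measure; by the projection inequality every
2D displacement is <= its 3D counterpart, so single-view tracking
systematically underestimates movement.

QC-dropped frames break the displacement chain (the gap is not bridged:
bridging would divide a multi-frame excursion by one frame interval and
inflate speed); the first frame after a gap carries NaN displacement and
is excluded from the summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, GeometryError
from .geometry import WellGeometry, WorldPoint
from .skeleton3d import Skeleton3D

Mode = Literal["2D", "3D"]

__all__ = [
    "KinematicsTable",
    "reference_point",
    "kinematics_from_track",
    "tail_angle",
    "compare_2d_3d",
    "axial_summary",
    "AxialSummary",
]


@dataclass(frozen=True)
class KinematicsTable:
    """Per-frame kinematics plus per-larva scalars.

    ``frames`` columns: frame, displacement_mm, speed_mm_s,
    acceleration_mm_s2 (NaN where undefined: the first frame of each
    unbroken run has no displacement, the first two no acceleration).
    """

    frames: pd.DataFrame
    total_distance: float
    move_count: int
    mode: Mode
    frame_rate: float

    @property
    def mean_speed(self) -> float:
        return float(np.nanmean(self.frames["speed_mm_s"]))

    @property
    def mean_abs_acceleration(self) -> float:
        return float(np.nanmean(np.abs(self.frames["acceleration_mm_s2"])))


def reference_point(skel: Skeleton3D) -> WorldPoint:
    """Midpoint of the two eye landmarks."""
    for eye in ("eye_left", "eye_right"):
        if eye not in skel.landmarks:
            raise FormatError(f"frame {skel.frame_index}: missing landmark {eye}")
    return skel.eye_midpoint


def _refs_to_array(refs: Sequence[WorldPoint] | np.ndarray) -> np.ndarray:
    if isinstance(refs, np.ndarray):
        arr = np.asarray(refs, dtype=float)
    else:
        arr = np.array([p.as_array() for p in refs])
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise FormatError("reference track must be (n, 3)")
    return arr


def kinematics_from_track(
    refs: Sequence[WorldPoint] | np.ndarray,
    frame_rate: float,
    mode: Mode = "3D",
    move_threshold: float = 2.0,
    min_move_frames: int = 2,
    frame_index: np.ndarray | None = None,
) -> KinematicsTable:
    """Displacement / speed / acceleration series from a reference track.

    ``move_threshold`` (mm/s) and ``min_move_frames`` define a movement
    bout: a maximal run of at least ``min_move_frames`` consecutive frames
    with speed strictly above the threshold.  ``frame_index`` (optional)
    marks gaps from QC-dropped frames; displacement is undefined across a
    gap.
    """
    arr = _refs_to_array(refs)
    n = len(arr)
    if n < 3:
        raise FormatError("kinematics needs at least 3 frames")
    if frame_rate <= 0:
        raise GeometryError("frame_rate must be > 0")
    if mode == "2D":
        arr = arr[:, :2]
    elif mode != "3D":
        raise ValueError(f"mode must be '2D' or '3D', got {mode!r}")
    idx = (
        np.arange(n) if frame_index is None else np.asarray(frame_index, dtype=int)
    )
    if len(idx) != n:
        raise FormatError("frame_index length mismatch")

    displacement = np.full(n, np.nan)
    steps = np.linalg.norm(np.diff(arr, axis=0), axis=1)
    contiguous = np.diff(idx) == 1
    displacement[1:][contiguous] = steps[contiguous]

    speed = displacement * frame_rate
    acceleration = np.full(n, np.nan)
    dspeed = speed[1:] - speed[:-1]
    acceleration[1:][contiguous] = (dspeed * frame_rate)[contiguous]

    total_distance = float(np.nansum(displacement))
    moving = speed > move_threshold
    move_count = _count_bouts(moving, min_move_frames)
    frames = pd.DataFrame(
        {
            "frame": idx,
            "displacement_mm": displacement,
            "speed_mm_s": speed,
            "acceleration_mm_s2": acceleration,
        }
    )
    return KinematicsTable(
        frames=frames,
        total_distance=total_distance,
        move_count=move_count,
        mode=mode,
        frame_rate=float(frame_rate),
    )


def _count_bouts(moving: np.ndarray, min_frames: int) -> int:
    """Number of maximal runs of True of length >= min_frames (NaN = False)."""
    m = np.asarray(moving, dtype=bool)
    count = 0
    run = 0
    for flag in m:
        if flag:
            run += 1
        else:
            if run >= min_frames:
                count += 1
            run = 0
    if run >= min_frames:
        count += 1
    return count


def tail_angle(
    skel: Skeleton3D, mode: Mode = "3D", tail_landmark: str = "tail_4"
) -> float:
    """Angle (degrees, [0, 180]) between the forward vector and the tail.

    Forward vector: nostril -> eye midpoint reference; tail vector:
    nostril -> ``tail_landmark`` (most distal tail point by default).  A
    straight body gives 0 degrees.  2D mode projects both vectors onto the
    x-y plane first, discarding the vertical bending component.
    """
    nostril = skel.landmarks["nostril"].as_array()
    ref = reference_point(skel).as_array()
    tail = skel.landmarks[tail_landmark].as_array()
    v1 = ref - nostril
    v2 = tail - nostril
    if mode == "2D":
        v1, v2 = v1[:2], v2[:2]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise GeometryError(
            f"frame {skel.frame_index}: zero-length vector in tail angle"
        )
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def compare_2d_3d(
    table2d: KinematicsTable, table3d: KinematicsTable
) -> dict[str, object]:
    """Paired per-frame and per-larva comparison of 2D vs 3D kinematics.

    Returns per-frame difference series (3D minus 2D) and scalar summaries
    for total distance, mean |acceleration| and move count — the panel of
    metrics on which top-view-only tracking underestimates movement.
    """
    f2, f3 = table2d.frames, table3d.frames
    if len(f2) != len(f3) or np.any(f2["frame"].to_numpy() != f3["frame"].to_numpy()):
        raise FormatError("2D and 3D tables cover different frames")
    per_frame = pd.DataFrame(
        {
            "frame": f3["frame"],
            "displacement_diff_mm": f3["displacement_mm"] - f2["displacement_mm"],
            "speed_diff_mm_s": f3["speed_mm_s"] - f2["speed_mm_s"],
        }
    )
    return {
        "per_frame": per_frame,
        "total_distance_2d": table2d.total_distance,
        "total_distance_3d": table3d.total_distance,
        "total_distance_gap": table3d.total_distance - table2d.total_distance,
        "mean_abs_acceleration_2d": table2d.mean_abs_acceleration,
        "mean_abs_acceleration_3d": table3d.mean_abs_acceleration,
        "move_count_2d": table2d.move_count,
        "move_count_3d": table3d.move_count,
    }


@dataclass(frozen=True)
class AxialSummary:
    """Depth-over-time series and 3D occupancy histogram."""

    time_bin_centers_s: np.ndarray
    depth_mean_mm: np.ndarray
    depth_sd_mm: np.ndarray
    occupancy: np.ndarray
    voxel_edges: tuple[np.ndarray, np.ndarray, np.ndarray]


def axial_summary(
    refs: Sequence[WorldPoint] | np.ndarray,
    frame_rate: float,
    well: WellGeometry,
    bin_size: float = 1.0,
    time_bin_s: float = 1.0,
) -> AxialSummary:
    """Swimming-depth profile and 3D occupancy heatmap.

    ``bin_size`` (mm) sets the voxel edge length of the occupancy
    histogram over the full well volume; the voxel counts sum to the
    number of frames.  ``time_bin_s`` sets the window for the mean/SD
    depth series.
    """
    arr = _refs_to_array(refs)
    if len(arr) == 0:
        raise FormatError("empty track")
    if bin_size <= 0 or time_bin_s <= 0:
        raise ValueError("bin_size and time_bin_s must be > 0")
    t = np.arange(len(arr)) / frame_rate
    n_tbins = max(1, int(np.ceil((t[-1] + 1e-12) / time_bin_s)))
    which = np.minimum((t / time_bin_s).astype(int), n_tbins - 1)
    means = np.full(n_tbins, np.nan)
    sds = np.full(n_tbins, np.nan)
    for b in range(n_tbins):
        zs = arr[which == b, 2]
        if len(zs):
            means[b] = zs.mean()
            sds[b] = zs.std()
    edges = (
        np.arange(-well.half_extent_x, well.half_extent_x + bin_size / 2, bin_size),
        np.arange(-well.half_extent_y, well.half_extent_y + bin_size / 2, bin_size),
        np.arange(0.0, well.depth + bin_size / 2, bin_size),
    )
    # clip to the well volume so boundary-touching frames are counted
    clipped = np.column_stack(
        [
            np.clip(arr[:, 0], edges[0][0], np.nextafter(edges[0][-1], -np.inf)),
            np.clip(arr[:, 1], edges[1][0], np.nextafter(edges[1][-1], -np.inf)),
            np.clip(arr[:, 2], edges[2][0], np.nextafter(edges[2][-1], -np.inf)),
        ]
    )
    occupancy, _ = np.histogramdd(clipped, bins=edges)
    return AxialSummary(
        time_bin_centers_s=(np.arange(n_tbins) + 0.5) * time_bin_s,
        depth_mean_mm=means,
        depth_sd_mm=sds,
        occupancy=occupancy,
        voxel_edges=edges,
    )
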