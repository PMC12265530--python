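"""Ground-truthed phantoms: swimming larvae, silhouette masks, edge targets.

The simulator produces the full data regime the pipeline consumes, with
known ground truth, so every stage is testable without recorded data:

* an articulated larva — a rigid head block (nostril, eyes, swim bladder)
  plus a four-point tail bending sinusoidally in a slowly rolling body
  plane — swimming at constant speed with a smoothly wandering heading
  inside the well, reflecting off the walls;
* dual-view keypoint tracks rendered through the same height-dependent
  magnification model the reconstruction inverts, with Gaussian pixel
  noise and a likelihood/dropout model (only the 0.7 threshold matters
  downstream: passing frames draw likelihoods from U(0.85, 1), dropout
  frames from U(0, 0.7));
* exact ellipsoid-silhouette bladder masks via the Schur-complement
  projection, rasterized as filled ellipses;
* slanted, Gaussian-blurred step-edge targets for the MTF pipeline.

Body-chain segment lengths are constant over time (rigid-length
articulated model) and all landmarks stay inside the well volume.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.special import erf

from .bladder import (
    Ellipsoid3D,
    _ellipse_from_form,
    _euler_xzy_from_rotation,
    ellipsoid_form,
    project_form,
)
from .errors import GeometryError
from .geometry import ViewGeometry, WellGeometry, WorldPoint, world_to_pixel
from .tracking_io import LANDMARKS, TrackSet

__all__ = [
    "LarvaParams",
    "RenderNoise",
    "PhantomTruth",
    "simulate_larva",
    "render_views",
    "render_bladder_mask",
    "make_edge_target",
]


@dataclass(frozen=True)
class LarvaParams:
    """Kinematic and body-shape parameters of the simulated larva.

    Defaults describe a 7 dpf larva: ~4 mm body, cruising at 5 mm/s,
    imaged at 20 fps.  Segment lengths (mm): nostril-eye midpoint 0.5,
    eye midpoint-bladder 1.0, four tail segments of 0.625.
    """

    n_frames: int = 600
    frame_rate: float = 20.0
    mean_speed: float = 5.0  # mm/s
    turn_rate: float = 0.05  # SD of per-frame azimuth perturbation, rad
    pitch_sd: float = 0.12  # stationary SD of heading elevation, rad
    roll_sd: float = 0.08  # stationary SD of body roll, rad
    righting_rate: float = 0.05  # mean-reversion per frame of pitch/roll
    max_pitch: float = 0.6  # hard cap on heading elevation, rad
    vertical_drift: float = 0.0  # mm/s bias toward the surface (+) or bottom (-)
    body_turn_cap: float = 0.2  # max body re-orientation per frame, rad
    snout_to_eyes: float = 0.5
    eyes_to_bladder: float = 1.0
    tail_segment: float = 0.625
    eye_halfspan: float = 0.25
    tail_beat_hz: float = 2.0
    tail_amplitude: float = 0.35  # rad per segment at the beat peak
    bladder_axes: tuple[float, float, float] = (0.30, 0.18, 0.15)

    @property
    def body_length(self) -> float:
        return self.snout_to_eyes + self.eyes_to_bladder + 4 * self.tail_segment

    @property
    def max_reach(self) -> float:
        """Largest distance of any landmark from the bladder anchor."""
        head = self.snout_to_eyes + self.eyes_to_bladder
        eye = math.hypot(self.eyes_to_bladder, self.eye_halfspan)
        return max(head, eye, 4 * self.tail_segment)


@dataclass(frozen=True)
class RenderNoise:
    keypoint_sigma_px: float = 0.5
    dropout_prob: float = 0.0


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth landmarks (n, 8, 3) and per-frame bladder ellipsoids."""

    landmarks: np.ndarray
    bladders: tuple[Ellipsoid3D, ...]
    params: LarvaParams
    well: WellGeometry
    seed: int

    def landmark_points(self, frame: int) -> dict[str, WorldPoint]:
        return {
            name: WorldPoint(*self.landmarks[frame, j])
            for j, name in enumerate(LANDMARKS)
        }

    def reference_track(self) -> np.ndarray:
        """(n, 3) eye-midpoint track, the kinematics reference point."""
        il, ir = LANDMARKS.index("eye_left"), LANDMARKS.index("eye_right")
        return 0.5 * (self.landmarks[:, il] + self.landmarks[:, ir])

    def save_truth_json(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "params": asdict(self.params),
            "well": asdict(self.well),
            "landmark_names": list(LANDMARKS),
            "landmarks_mm": self.landmarks.tolist(),
            "bladder_axes_mm": [[b.a, b.b, b.c] for b in self.bladders],
            "bladder_centers_mm": [
                [b.center.x, b.center.y, b.center.z] for b in self.bladders
            ],
        }
        Path(path).write_text(json.dumps(doc))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero vector")
    return v / n


def _perp_frame(heading: np.ndarray, roll: float) -> tuple[np.ndarray, np.ndarray]:
    """Side and bend-normal unit vectors for a given heading and roll angle."""
    up = np.array([0.0, 0.0, 1.0])
    side = np.cross(up, heading)
    if np.linalg.norm(side) < 1e-9:  # heading vertical: pick x as side
        side = np.array([1.0, 0.0, 0.0])
    side = _unit(side)
    normal = _unit(np.cross(heading, side))
    # roll rotates the bend plane about the heading axis
    s = math.cos(roll) * side + math.sin(roll) * normal
    n = -math.sin(roll) * side + math.cos(roll) * normal
    return s, n


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(axis)
    return (
        v * math.cos(angle)
        + np.cross(axis, v) * math.sin(angle)
        + axis * np.dot(axis, v) * (1.0 - math.cos(angle))
    )


def _rotate_toward(v: np.ndarray, target: np.ndarray, max_angle: float) -> np.ndarray:
    """Rotate unit vector ``v`` toward ``target`` by at most ``max_angle``."""
    cosang = float(np.clip(np.dot(v, target), -1.0, 1.0))
    ang = math.acos(cosang)
    if ang <= max_angle:
        return target.copy()
    axis = np.cross(v, target)
    if np.linalg.norm(axis) < 1e-12:  # antiparallel: pick any perpendicular
        axis = np.cross(v, [0.0, 0.0, 1.0])
        if np.linalg.norm(axis) < 1e-12:
            axis = np.cross(v, [1.0, 0.0, 0.0])
    return _rotate_about(v, axis, max_angle)


def simulate_larva(
    params: LarvaParams = LarvaParams(),
    seed: int = 0,
    well: WellGeometry = WellGeometry(),
) -> PhantomTruth:
    """Simulate a confined 3D swim with an articulated, rigid-length body.

    The bladder anchor moves at constant speed ``mean_speed`` with a
    movement direction that random-walks on the unit sphere
    (pitch-limited) and reflects off an inner box inset by the body reach,
    so no landmark ever leaves the well.  The body axis follows the
    movement direction with a bounded per-frame turn rate
    (``body_turn_cap``), so the rigid head turns smoothly through wall
    reflections instead of jumping — the head reference point therefore
    travels at very nearly the commanded speed.  Deterministic given
    ``seed``.
    """
    margin = params.max_reach + 0.1
    lox = -well.half_extent_x + margin
    hix = well.half_extent_x - margin
    loy = -well.half_extent_y + margin
    hiy = well.half_extent_y - margin
    loz, hiz = margin, well.depth - margin
    if lox >= hix or loy >= hiy or loz >= hiz:
        raise GeometryError(
            f"body (reach {params.max_reach:.2f} mm) too long for the well"
        )
    rng = np.random.default_rng(seed)
    n = params.n_frames
    dt = 1.0 / params.frame_rate
    step = params.mean_speed * dt

    anchor = np.array(
        [
            rng.uniform(lox, hix),
            rng.uniform(loy, hiy),
            rng.uniform(loz, hiz),
        ]
    )
    azim = rng.uniform(0, 2 * math.pi)
    elev = 0.0
    roll = 0.0
    lo = np.array([lox, loy, loz])
    hi = np.array([hix, hiy, hiz])

    landmarks = np.empty((n, len(LANDMARKS), 3))
    bladders = []
    i_n = LANDMARKS.index("nostril")
    i_el = LANDMARKS.index("eye_left")
    i_er = LANDMARKS.index("eye_right")
    i_b = LANDMARKS.index("swim_bladder")
    i_tail = [LANDMARKS.index(f"tail_{k}") for k in (1, 2, 3, 4)]

    lam = params.righting_rate
    ou_sd = math.sqrt(max(2 * lam - lam * lam, 1e-12))
    drift = params.vertical_drift * dt
    for t in range(n):
        # azimuth wanders freely; pitch and roll are mean-reverting
        # (righting reflex) with the stationary SDs set in the params
        azim += rng.normal(0.0, params.turn_rate)
        elev = float(
            np.clip(
                (1 - lam) * elev + rng.normal(0.0, params.pitch_sd * ou_sd),
                -params.max_pitch,
                params.max_pitch,
            )
        )
        roll = (1 - lam) * roll + rng.normal(0.0, params.roll_sd * ou_sd)
        heading = np.array(
            [
                math.cos(elev) * math.cos(azim),
                math.cos(elev) * math.sin(azim),
                math.sin(elev),
            ]
        )
        if t == 0:
            body = heading.copy()
            stride = step
        else:
            body_new = _rotate_toward(body, heading, params.body_turn_cap)
            # choose the anchor stride so that the eye-midpoint (the
            # kinematics reference on the rigid head) advances by exactly
            # the commanded step despite the head's own rotation:
            # |stride*h + L*(body_new - body)| = step
            b = params.eyes_to_bladder * (body_new - body)
            hb = float(np.dot(heading, b))
            disc = hb * hb + step * step - float(np.dot(b, b))
            stride = -hb + math.sqrt(disc) if disc > 0 else step
            body = body_new
        anchor = anchor + stride * heading + np.array([0.0, 0.0, drift])
        # reflective walls: fold position back into the box, flip heading
        for ax in range(3):
            if anchor[ax] < lo[ax]:
                anchor[ax] = 2 * lo[ax] - anchor[ax]
                heading[ax] = -heading[ax]
            elif anchor[ax] > hi[ax]:
                anchor[ax] = 2 * hi[ax] - anchor[ax]
                heading[ax] = -heading[ax]
        azim = math.atan2(heading[1], heading[0])
        elev = math.asin(np.clip(heading[2], -1.0, 1.0))

        side, normal = _perp_frame(body, roll)
        eye_mid = anchor + params.eyes_to_bladder * body
        landmarks[t, i_n] = anchor + (params.eyes_to_bladder + params.snout_to_eyes) * body
        landmarks[t, i_el] = eye_mid + params.eye_halfspan * side
        landmarks[t, i_er] = eye_mid - params.eye_halfspan * side
        landmarks[t, i_b] = anchor

        # articulated tail: fixed-length segments, sinusoidal bend angles
        phase = 2 * math.pi * params.tail_beat_hz * t * dt
        direction = -body
        point = anchor.copy()
        for s_i, idx in enumerate(i_tail):
            bend = params.tail_amplitude * math.sin(phase - 0.9 * s_i) * (
                0.4 + 0.2 * s_i
            )
            direction = _unit(_rotate_about(direction, normal, bend))
            point = point + params.tail_segment * direction
            landmarks[t, idx] = point

        # bladder principal axis along the body axis, second axis along side
        R = np.vstack([body, side, np.cross(body, side)])
        phi, psi, theta = _euler_xzy_from_rotation(R)
        a, b, c = params.bladder_axes
        bladders.append(
            Ellipsoid3D(
                center=WorldPoint(*anchor), a=a, b=b, c=c, phi=phi, psi=psi, theta=theta
            )
        )

    truth = PhantomTruth(
        landmarks=landmarks,
        bladders=tuple(bladders),
        params=params,
        well=well,
        seed=seed,
    )
    inside = (
        np.all(landmarks[:, :, 0] >= -well.half_extent_x)
        and np.all(landmarks[:, :, 0] <= well.half_extent_x)
        and np.all(landmarks[:, :, 1] >= -well.half_extent_y)
        and np.all(landmarks[:, :, 1] <= well.half_extent_y)
        and np.all(landmarks[:, :, 2] >= 0)
        and np.all(landmarks[:, :, 2] <= well.depth)
    )
    if not inside:
        raise GeometryError("simulated landmark escaped the well volume")
    return truth


def _project_landmark(
    view: str, p: np.ndarray, geom: ViewGeometry
) -> tuple[float, float]:
    if view == "top":
        d = geom.object_distance("top", z=p[2])
        return world_to_pixel("top", (p[0], p[1]), d, geom)
    d = geom.object_distance("side", y=p[1])
    return world_to_pixel("side", (p[0], p[2]), d, geom)


def render_views(
    truth: PhantomTruth,
    geom: ViewGeometry = ViewGeometry(),
    noise: RenderNoise = RenderNoise(),
    seed: int = 0,
) -> tuple[TrackSet, TrackSet]:
    """Project the phantom into dual-view keypoint tracks with likelihoods.

    Dropout frames (probability ``dropout_prob``, per view) draw all
    landmark likelihoods from U(0, 0.7) and therefore fail the frame-level
    QC test; other frames draw from U(0.85, 1).
    """
    rng = np.random.default_rng(seed)
    n = len(truth.landmarks)
    tracks = {}
    for view in ("top", "side"):
        coords = np.empty((n, len(LANDMARKS), 2))
        for t in range(n):
            for j in range(len(LANDMARKS)):
                coords[t, j] = _project_landmark(view, truth.landmarks[t, j], geom)
        coords += rng.normal(0.0, noise.keypoint_sigma_px, size=coords.shape)
        dropout = rng.random(n) < noise.dropout_prob
        lik = rng.uniform(0.85, 1.0, size=(n, len(LANDMARKS)))
        lik[dropout] = rng.uniform(0.0, 0.7, size=(int(dropout.sum()), len(LANDMARKS)))
        tracks[view] = TrackSet(
            view_label=view,
            frame_index=np.arange(n),
            coords=coords,
            likelihood=lik,
            source_id=f"phantom{truth.seed:03d}",
        )
    return tracks["top"], tracks["side"]


def render_bladder_mask(
    ellipsoid: Ellipsoid3D,
    view: str,
    geom: ViewGeometry = ViewGeometry(),
    downsample: int = 4,
) -> np.ndarray:
    """Rasterize the exact silhouette of the bladder ellipsoid as a mask.

    The silhouette ellipse comes from the Schur-complement projection of
    the ellipsoid's quadratic form; it is drawn filled on the view's pixel
    grid, optionally ``downsample``-times coarser than the full sensor.
    """
    from skimage.draw import ellipse as draw_ellipse

    M = ellipsoid_form(ellipsoid)
    drop = "z" if view == "top" else "y"
    M2 = project_form(M, drop)
    c = ellipsoid.center
    center2 = (c.x, c.y) if view == "top" else (c.x, c.z)
    sil = _ellipse_from_form(M2, center2)
    if view == "top":
        d = geom.object_distance("top", z=c.z)
    else:
        d = geom.object_distance("side", y=c.y)
    cu, cv = world_to_pixel(view, center2, d, geom)
    m = geom.magnification(view, z=c.z) if view == "top" else geom.magnification(view, y=c.y)
    px = geom.pixel_pitch / m  # object mm per pixel
    rows, cols = geom.sensor_pixels
    rows //= downsample
    cols //= downsample
    mask = np.zeros((rows, cols), dtype=np.uint8)
    # pixel-grid rotation: +phi in world (y up) is -phi in row coords
    # coarse pixel i spans fine pixels [i*ds, (i+1)*ds): centre alignment
    rr, cc = draw_ellipse(
        (cv - (downsample - 1) / 2.0) / downsample,
        (cu - (downsample - 1) / 2.0) / downsample,
        sil.k / (px * downsample),
        sil.j / (px * downsample),
        shape=mask.shape,
        # draw.ellipse's rotation maps to -phi in image coords, and the
        # image v-axis flip maps world +phi to image -phi: net +phi here
        rotation=sil.phi,
    )
    mask[rr, cc] = 255
    return mask


def make_edge_target(
    sigma_um: float = 10.0,
    noise_sd: float = 0.0,
    pixel_size_um: float = 6.77,
    shape: tuple[int, int] = (256, 256),
    slant_deg: float = 5.0,
    contrast: tuple[float, float] = (0.1, 0.9),
    seed: int = 0,
) -> np.ndarray:
    """Slanted step edge convolved with a Gaussian PSF plus i.i.d. noise.

    ``sigma_um`` is the Gaussian blur in object micrometres; the analytic
    MTF of such an edge is exp(-2 pi^2 sigma^2 f^2).  Deterministic given
    ``seed``.
    """
    if sigma_um < 0:
        raise ValueError("sigma must be >= 0")
    rows, cols = shape
    rng = np.random.default_rng(seed)
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    edge_col = (cols - 1) / 2.0 + math.tan(math.radians(slant_deg)) * (
        r - (rows - 1) / 2.0
    )
    dist_um = (c - edge_col) * pixel_size_um * math.cos(math.radians(slant_deg))
    lo, hi = contrast
    if sigma_um == 0:
        profile = (dist_um >= 0).astype(float)
    else:
        profile = 0.5 * (1.0 + erf(dist_um / (sigma_um * math.sqrt(2.0))))
    img = lo + (hi - lo) * profile
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img
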