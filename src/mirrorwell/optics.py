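"""System optics characterization: refraction ray tracing and MTF resolution.

Ray tracing uses the four-well equivalent model (two real wells and their
two mirror-image virtual counterparts): the camera axis is centered on the
2x2 well block, and chief rays are scanned laterally in 0.1 mm steps out
to the farthest in-well point.  Refraction at the air-water (n = 1.33) and
air-plastic (n = 1.5) interfaces follows Snell's law; the apparent lateral
shift of a submerged point relative to refraction-free imaging through a
flat layer of thickness t is t (tan th - tan th'), summed over layers.

Lateral resolution is estimated from a high-contrast edge image with a
slanted-edge spatial frequency response procedure: project pixels onto the
edge-normal axis, build a 4x-oversampled edge-spread function, finite-
difference it into a line-spread function, and take the normalized DFT
magnitude as the MTF on 0-50 cycles/mm.  The MTF's exponential decay
region is fitted with A exp(-B f); the cutoff frequency is where this fit
meets the mean noise floor, and its reciprocal is reported as the lateral
resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import FitError, GeometryError, TotalInternalReflectionError
from .geometry import ViewGeometry, WellGeometry, thin_lens_magnification

N_WATER = 1.33
N_PLASTIC = 1.5

__all__ = [
    "N_WATER",
    "N_PLASTIC",
    "RayTraceResult",
    "MTFCurve",
    "snell",
    "flat_slab_shift",
    "trace_view",
    "distortion_summary",
    "mtf_from_edge",
    "resolution_from_mtf",
    "default_aperture_radius",
]


def snell(theta_in_deg: float, n1: float, n2: float) -> float:
    """Refracted angle (degrees) for incidence ``theta_in_deg`` at n1 -> n2."""
    if n1 <= 0 or n2 <= 0:
        raise GeometryError("refractive indices must be positive")
    if not abs(theta_in_deg) < 90:
        raise GeometryError("incidence angle must satisfy |theta| < 90 degrees")
    s = n1 * math.sin(math.radians(theta_in_deg)) / n2
    if abs(s) > 1.0:
        raise TotalInternalReflectionError(
            f"total internal reflection: n1 sin(theta)/n2 = {s:.4f}"
        )
    return math.degrees(math.asin(s))


def flat_slab_shift(theta_in_deg: float, thickness: float, n1: float, n2: float) -> float:
    """Apparent lateral shift through a flat slab: t (tan th - tan th')."""
    theta_out = snell(theta_in_deg, n1, n2)
    return thickness * (
        math.tan(math.radians(theta_in_deg)) - math.tan(math.radians(theta_out))
    )


@dataclass(frozen=True)
class RayTraceResult:
    """Per-lateral-position refraction angles and apparent shifts."""

    view: str
    lateral_position: np.ndarray  # mm from the optical axis
    incidence_angle: np.ndarray  # degrees in air (theta_1 top / theta_4 side)
    refracted_angle: np.ndarray  # degrees in water
    apparent_shift: np.ndarray  # mm, relative to refraction-free imaging
    relative_distortion: np.ndarray  # fraction of the per-camera FOV


def max_chief_lateral(well: WellGeometry) -> float:
    """Distance from the 2x2-block axis to the farthest in-well point (mm).

    Well centers sit at (+-pitch/2, +-pitch/2); the farthest corner of the
    farthest well is sqrt(2) (pitch/2 + footprint/2) from the axis.
    """
    return math.sqrt(2.0) * (well.pitch / 2.0 + well.footprint_x / 2.0)


def default_aperture_radius(
    well: WellGeometry, geom: ViewGeometry, worst_incidence_deg: float = 5.0
) -> float:
    """Aperture radius (mm) calibrated so the marginal ray at the FOV
    corner reaches the stated worst-case incidence angle."""
    d = geom.object_distance("top")
    r = d * math.tan(math.radians(worst_incidence_deg)) - max_chief_lateral(well)
    if r <= 0:
        raise GeometryError("worst-case incidence below the chief-ray maximum")
    return r


def trace_view(
    well: WellGeometry,
    geom: ViewGeometry,
    view: str = "top",
    step: float = 0.1,
    wall_thickness: float = 1.0,
    target_depth: float | None = None,
    aperture_radius: float = 0.0,
) -> RayTraceResult:
    """Scan chief rays laterally and compute refraction shifts.

    Top view: rays enter the water surface directly (air -> water) and
    traverse the water column down to the target (default: the well
    bottom, the worst case).  Side view: rays pass through the virtual
    well's plastic wall and then the water (air -> plastic -> water); the
    horizontal water path is the well footprint.  ``aperture_radius`` > 0
    shifts each incidence angle to the marginal ray through the aperture
    edge.  Rays whose angle would leave the well volume are terminated
    (the scan itself stops at the farthest in-well point).
    """
    if step <= 0:
        raise GeometryError("step must be > 0")
    if view not in ("top", "side"):
        raise GeometryError(f"unknown view {view!r}")
    d = geom.object_distance(view)
    lmax = max_chief_lateral(well)
    lateral = np.arange(0.0, lmax + step / 2, step)
    if view == "top":
        t_water = well.water_fill if target_depth is None else target_depth
        layers = [(t_water, N_WATER)]
    else:
        t_water = well.footprint_y if target_depth is None else target_depth
        layers = [(wall_thickness, N_PLASTIC), (t_water, N_WATER)]

    incidence = np.degrees(
        np.arctan((lateral + aperture_radius) / d)
    )
    refracted = np.empty_like(incidence)
    shift = np.empty_like(incidence)
    for i, th in enumerate(incidence):
        # flat parallel layers: the in-water angle obeys n sin(th_w) =
        # sin(th) regardless of the plastic in between; shifts add per layer
        total = 0.0
        for thickness, n in layers:
            total += flat_slab_shift(th, thickness, 1.0, n)
        refracted[i] = snell(th, 1.0, N_WATER)
        shift[i] = total
    return RayTraceResult(
        view=view,
        lateral_position=lateral,
        incidence_angle=incidence,
        refracted_angle=refracted,
        apparent_shift=shift,
        relative_distortion=shift / geom.fov,
    )


def distortion_summary(
    result: RayTraceResult, geom: ViewGeometry
) -> dict[str, float]:
    """Worst-case shift over the profile, in mm, object pixels and FOV %."""
    m = geom.magnification(result.view)
    object_pixel = geom.pixel_pitch / m
    max_shift = float(np.max(np.abs(result.apparent_shift)))
    return {
        "max_incidence_deg": float(np.max(np.abs(result.incidence_angle))),
        "max_shift_mm": max_shift,
        "max_shift_px": max_shift / object_pixel,
        "max_relative_distortion": max_shift / geom.fov,
    }


@dataclass(frozen=True)
class MTFCurve:
    """MTF samples on 0-50 cycles/mm, plus cutoff fields once fitted."""

    spatial_frequency: np.ndarray
    mtf: np.ndarray
    noise_floor: float | None = None
    cutoff_frequency: float | None = None
    resolution_um: float | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"spatial_frequency_cyc_mm": self.spatial_frequency, "mtf": self.mtf}
        )


def mtf_from_edge(
    image: np.ndarray,
    pixel_size: float,
    edge_orientation: str = "vertical",
    oversample: int = 4,
    max_frequency: float = 50.0,
) -> MTFCurve:
    """Slanted-edge spatial frequency response.

    ``pixel_size`` is the object-plane pixel size in mm.  The edge must be
    near-vertical (or near-horizontal with ``edge_orientation``); a small
    slant lets the row-wise sub-pixel edge positions populate the
    ``oversample``-times finer edge-spread grid.
    """
    img = np.asarray(image, dtype=float)
    if edge_orientation == "horizontal":
        img = img.T
    elif edge_orientation != "vertical":
        raise ValueError("edge_orientation must be 'vertical' or 'horizontal'")
    if img.ndim != 2 or min(img.shape) < 8:
        raise FitError("edge image too small")
    rows, cols = img.shape
    r = np.arange(rows)
    grad = np.abs(np.diff(img, axis=1))
    pos = np.arange(cols - 1) + 0.5
    if grad.sum() == 0:
        raise FitError("no detectable edge")
    # pass 1: coarse per-row edge = peak of the smoothed gradient (robust
    # to pixel noise, which would bias a full-row centroid); pass 2:
    # sub-pixel squared-gradient centroid in a narrow window around the
    # straight-edge line fitted to pass 1
    kernel = np.ones(5) / 5.0
    smooth = np.apply_along_axis(lambda x: np.convolve(x, kernel, mode="same"), 1, grad)
    coarse = pos[np.argmax(smooth, axis=1)]
    slope, intercept = np.polyfit(r, coarse, 1)
    fitted = slope * r + intercept
    half_width = 8.0
    w = grad**2 * (np.abs(pos[None, :] - fitted[:, None]) <= half_width)
    wsum = w.sum(axis=1)
    if np.any(wsum <= 0):
        raise FitError("no detectable edge in some rows")
    edge_cols = (w * pos).sum(axis=1) / wsum
    slope, intercept = np.polyfit(r, edge_cols, 1)
    fitted = slope * r + intercept
    if np.ptp(fitted) > cols / 2:
        raise FitError("edge not straight or not near-vertical")
    cos_slant = 1.0 / math.sqrt(1.0 + slope**2)
    # project every pixel onto the edge-normal axis (units: pixels)
    cc, rr = np.meshgrid(np.arange(cols), r)
    dist = (cc - fitted[:, None]) * cos_slant
    binw = 1.0 / oversample
    bins = np.round(dist / binw).astype(int)
    bmin, bmax = bins.min(), bins.max()
    counts = np.bincount((bins - bmin).ravel())
    sums = np.bincount((bins - bmin).ravel(), weights=img.ravel())
    valid = counts > 0
    esf = sums[valid] / counts[valid]
    lsf = np.diff(esf) / binw
    window = np.hamming(len(lsf))
    spectrum = np.abs(np.fft.rfft(lsf * window))
    if spectrum[0] == 0:
        raise FitError("degenerate edge spectrum")
    mtf = spectrum / spectrum[0]
    sample_mm = binw * pixel_size
    freqs = np.fft.rfftfreq(len(lsf), d=sample_mm)
    keep = freqs <= max_frequency
    return MTFCurve(spatial_frequency=freqs[keep], mtf=mtf[keep])


def resolution_from_mtf(
    curve: MTFCurve, noise_band_fraction: float = 0.2
) -> MTFCurve:
    """Cutoff frequency and lateral resolution from an MTF curve.

    Noise floor: mean MTF over the top ``noise_band_fraction`` of the
    frequency range.  Decay region: from the first nonzero frequency down
    to the first sample below twice the floor; fitted with A exp(-B f) by
    log-linear least squares.  The cutoff solves A exp(-B f) = floor and
    the resolution is its reciprocal in micrometres.
    """
    f = np.asarray(curve.spatial_frequency, dtype=float)
    m = np.asarray(curve.mtf, dtype=float)
    if len(f) < 8:
        raise FitError("MTF curve too short")
    fmax = f[-1]
    floor = float(np.mean(m[f >= (1.0 - noise_band_fraction) * fmax]))
    if floor >= 1.0:
        raise FitError("noise floor >= MTF(0): no resolvable decay region")
    in_decay = m > 2.0 * floor
    stop = len(f)
    for i in range(1, len(f)):
        if not in_decay[i]:
            stop = i
            break
    sel = slice(1, stop)
    fd, md = f[sel], m[sel]
    pos = md > 0
    fd, md = fd[pos], md[pos]
    if len(fd) < 3:
        raise FitError("decay region too short to fit")
    B, logA = np.polyfit(fd, np.log(md), 1)
    B = -B
    A = math.exp(logA)
    if B <= 0 or A <= floor:
        raise FitError("MTF does not decay toward the noise floor")
    cutoff = math.log(A / floor) / B
    if cutoff <= 0:
        raise FitError("degenerate cutoff frequency")
    return replace(
        curve,
        noise_floor=floor,
        cutoff_frequency=float(cutoff),
        resolution_um=float(1000.0 / cutoff),
    )
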