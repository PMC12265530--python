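"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from mirrorwell.geometry import ViewGeometry, WellGeometry


@pytest.fixture(scope="session")
def well_geom() -> WellGeometry:
    return WellGeometry()


@pytest.fixture(scope="session")
def view_geom() -> ViewGeometry:
    return ViewGeometry()


def silhouette_extent_oracle(M: np.ndarray, drop_axis: str, angles_deg: np.ndarray):
    """Brute-force silhouette of the quadric {v: v^T M v = 1}.

    For each in-plane ray direction, finds the largest radius r such that
    some value of the dropped coordinate w puts the point on the quadric:
    expanding Q(r d + w e) = 1 gives a quadratic in r whose larger root,
    maximized numerically over w, is the silhouette extent along d.  This
    never forms the Schur complement, so it is an independent check of the
    analytic projection.

    Returns (extents, directions): radii and (n, 2) unit vectors.
    """
    k = {"x": 0, "y": 1, "z": 2}[drop_axis]
    r_axes = [i for i in range(3) if i != k]
    e = np.zeros(3)
    e[k] = 1.0
    mee = float(e @ M @ e)
    # safe bound on the dropped coordinate: the longest semi-axis
    w_lim = 1.0 / math.sqrt(float(np.min(np.linalg.eigvalsh(M))))
    extents = []
    dirs = []
    for ang in np.radians(angles_deg):
        d = np.zeros(3)
        d[r_axes[0]] = math.cos(ang)
        d[r_axes[1]] = math.sin(ang)
        mdd = float(d @ M @ d)
        mde = float(d @ M @ e)

        def neg_rmax(w: float) -> float:
            disc = (w * mde) ** 2 + mdd * (1.0 - w * w * mee)
            if disc < 0:
                return 0.0
            return -((-w * mde + math.sqrt(disc)) / mdd)

        # the feasible w band can be a narrow sub-interval: bracket the
        # optimum on a coarse grid first, then refine locally
        grid = np.linspace(-w_lim, w_lim, 201)
        vals = np.array([neg_rmax(w) for w in grid])
        j = int(np.argmin(vals))
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, len(grid) - 1)]
        res = minimize_scalar(
            neg_rmax, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        extents.append(max(-res.fun, -vals[j]))
        dirs.append([math.cos(ang), math.sin(ang)])
    return np.array(extents), np.array(dirs)


def random_spd_quadric(rng: np.random.Generator, lo: float = 0.05, hi: float = 0.5):
    """Random ellipsoid quadratic form with semi-axes in [lo, hi] mm."""
    from scipy.stats import special_ortho_group

    axes = rng.uniform(lo, hi, 3)
    R = special_ortho_group.rvs(3, random_state=rng)
    return R.T @ np.diag(1.0 / axes**2) @ R, np.sort(axes)[::-1]
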