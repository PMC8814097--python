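"""Short-axis vessel tracking: polar edge detection of the cross-section.

For every frame, rays are cast from a center point at M equally spaced
angles; along each ray the lumen→wall transition is found as the strongest
dark-to-bright intensity gradient within a window around the previous
frame's radius, refined to sub-pixel.  Failed rays are interpolated
circularly from their angular neighbors and the radius-versus-angle
function is smoothed by truncating its Fourier series.  The center used for
the next frame is the area centroid of the current contour, so the tracker
self-centers even from an imperfect seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates

from .errors import InputError, TrackingLostError
from .video_io import VideoSequence

__all__ = [
    "ShortAxisConfig",
    "ContourTrace",
    "detect_contour_polar",
    "polygon_area",
    "polygon_centroid",
    "update_centroid",
    "shape_indices",
    "run_short_axis",
]


@dataclass(frozen=True)
class ShortAxisConfig:
    """Tunable parameters of the short-axis tracker (lengths in px)."""

    n_rays: int = 36               # M, angular sampling (10 degrees apart)
    search_halfwidth: float = 10.0  # w_r around the previous radius
    radial_step: float = 0.5       # ray sampling step
    edge_sigma: float = 2.0        # smoothing along the ray, in samples
    gradient_min: float = 3.0      # gray/px; weaker rays flagged
    n_harmonics: int = 8           # H, Fourier harmonics kept
    r_min: float = 2.0             # closest radius searched


@dataclass
class ContourTrace:
    """Per-frame contour, centroid and shape measures of a short-axis cine."""

    vertices: np.ndarray           # (n_frames, M, 2) (row, col), angle-ordered
    radii: np.ndarray              # (n_frames, M)
    centroid: np.ndarray           # (n_frames, 2) area centroid
    area: np.ndarray               # (n_frames,) px^2 (mm^2 when spacing known)
    perimeter: np.ndarray
    circularity: np.ndarray        # 4πA/P² ∈ (0, 1]
    flattening: np.ndarray         # 1 - minor/major of the moment ellipse
    ray_ok: np.ndarray             # (n_frames, M)
    fps: float
    pixel_spacing: Optional[tuple[float, float]] = None

    @property
    def frame_ok(self) -> np.ndarray:
        return self.ray_ok.mean(axis=1) >= 0.5


# ---------------------------------------------------------------------------
# polygon geometry (shoelace)
# ---------------------------------------------------------------------------

def _shoelace_cross(v: np.ndarray) -> np.ndarray:
    x, y = v[:, 1], v[:, 0]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return x * yn - xn * y


def polygon_area(vertices: np.ndarray) -> float:
    """Unsigned area of a simple closed polygon (shoelace formula)."""
    return abs(0.5 * _shoelace_cross(np.asarray(vertices, float)).sum())


def polygon_centroid(vertices: np.ndarray) -> tuple[float, float]:
    """Area centroid (row, col) of a simple closed polygon."""
    v = np.asarray(vertices, dtype=float)
    cross = _shoelace_cross(v)
    a = 0.5 * cross.sum()
    if abs(a) < 1e-12:
        raise InputError("degenerate (zero-area) polygon")
    x, y = v[:, 1], v[:, 0]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return (cy, cx)


def update_centroid(contour: np.ndarray) -> tuple[float, float]:
    """Ray origin for the next frame: the contour's area centroid."""
    return polygon_centroid(contour)


def _polygon_second_moments(v: np.ndarray):
    """Central second area moments (μ_xx, μ_yy, μ_xy) of a polygon."""
    x, y = v[:, 1], v[:, 0]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    ixx = ((x ** 2 + x * xn + xn ** 2) * cross).sum() / 12.0
    iyy = ((y ** 2 + y * yn + yn ** 2) * cross).sum() / 12.0
    ixy = ((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross).sum() / 24.0
    mu_xx = ixx / a - cx ** 2
    mu_yy = iyy / a - cy ** 2
    mu_xy = ixy / a - cx * cy
    return mu_xx, mu_yy, mu_xy


def shape_indices(contour: np.ndarray) -> tuple[float, float]:
    """Circularity ``4πA/P²`` and flattening ``1 − minor/major``.

    The axis ratio comes from the eigenvalues of the polygon's central
    second-moment matrix (a perfect ellipse with semi-axes a ≥ b has
    eigenvalues a²/4 and b²/4, so flattening = 1 − b/a).
    """
    v = np.asarray(contour, dtype=float)
    area = polygon_area(v)
    seg = np.roll(v, -1, axis=0) - v
    perimeter = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    circ = 4.0 * math.pi * area / perimeter ** 2 if perimeter > 0 else 0.0
    mu_xx, mu_yy, mu_xy = _polygon_second_moments(v)
    tr, det = mu_xx + mu_yy, mu_xx * mu_yy - mu_xy ** 2
    disc = max(tr * tr / 4.0 - det, 0.0)
    lam1 = tr / 2.0 + math.sqrt(disc)
    lam2 = max(tr / 2.0 - math.sqrt(disc), 0.0)
    flattening = 1.0 - math.sqrt(lam2 / lam1) if lam1 > 0 else 0.0
    return float(circ), float(flattening)


# ---------------------------------------------------------------------------
# polar edge detection
# ---------------------------------------------------------------------------

def _fourier_smooth(radii: np.ndarray, n_harmonics: int) -> np.ndarray:
    spec = np.fft.rfft(radii)
    spec[n_harmonics + 1:] = 0.0
    return np.fft.irfft(spec, n=len(radii))


def detect_contour_polar(
    frame: np.ndarray,
    center: tuple[float, float],
    prev_radii: np.ndarray | float,
    config: ShortAxisConfig = ShortAxisConfig(),
    frame_index: int = 0,
    full_search: bool = False,
):
    """Find the lumen contour along M rays from ``center``.

    Per ray the edge is the sub-pixel radius of the strongest positive
    (dark lumen → bright wall) intensity gradient within
    ``prev_radii ± search_halfwidth`` (the whole ray when ``full_search``).
    Rays whose peak gradient falls below ``gradient_min`` are flagged and
    replaced by circular interpolation from valid neighbors; the final
    radius profile keeps only the first ``n_harmonics`` Fourier harmonics.

    Returns ``(vertices, radii, ray_ok)``; raises
    :class:`TrackingLostError` when more than half the rays fail.
    """
    M = config.n_rays
    if M < 8:
        raise InputError("need at least 8 rays")
    rows, cols = frame.shape
    cr, cc = float(center[0]), float(center[1])
    if not (0 <= cr < rows and 0 <= cc < cols):
        raise InputError(f"center {center} outside the frame")

    theta = 2.0 * np.pi * np.arange(M) / M
    prev = np.broadcast_to(np.asarray(prev_radii, dtype=float), (M,)).copy()

    r_edge = np.full(M, np.nan)
    ok = np.zeros(M, dtype=bool)
    step = config.radial_step
    img = frame.astype(np.float64)

    # radial sampling window per ray
    if full_search:
        r_lo = np.full(M, config.r_min)
        r_hi = np.full(M, _max_radius(rows, cols, cr, cc, theta))
    else:
        r_lo = np.maximum(prev - config.search_halfwidth, config.r_min)
        r_hi = prev + config.search_halfwidth
    n_samp = int(np.ceil((r_hi - r_lo).max() / step)) + 1
    if n_samp < 5:
        raise InputError("radial search window too small")
    rs = r_lo[:, None] + step * np.arange(n_samp)[None, :]
    valid_r = rs <= r_hi[:, None]
    rr = cr + rs * np.sin(theta)[:, None]
    cc_ = cc + rs * np.cos(theta)[:, None]
    prof = map_coordinates(img, [rr, cc_], order=1, mode="nearest")
    prof = gaussian_filter1d(prof, config.edge_sigma, axis=1, mode="nearest")
    grad = np.gradient(prof, step, axis=1)
    grad = np.where(valid_r, grad, -np.inf)

    best = np.argmax(grad, axis=1)
    rays = np.arange(M)
    peak = grad[rays, best]
    ok = peak >= config.gradient_min
    b0 = np.clip(best, 1, n_samp - 2)
    a = grad[rays, b0 - 1]
    b = grad[rays, b0]
    c = grad[rays, b0 + 1]
    a = np.where(np.isfinite(a), a, b)
    c = np.where(np.isfinite(c), c, b)
    den = a - 2 * b + c
    delta = np.where(den < 0, 0.5 * (a - c) / np.where(den == 0, 1, den), 0.0)
    r_edge = r_lo + step * (b0 + np.clip(delta, -0.5, 0.5))

    if ok.sum() <= M // 2:
        raise TrackingLostError(frame_index,
                                f"frame {frame_index}: {M - ok.sum()}/{M} rays failed")

    if not ok.all():  # circular interpolation of failed rays
        good = np.flatnonzero(ok)
        bad = np.flatnonzero(~ok)
        gx = np.concatenate([good - M, good, good + M])
        gy = np.tile(r_edge[good], 3)
        r_edge[bad] = np.interp(bad, gx, gy)

    r_edge = _fourier_smooth(r_edge, config.n_harmonics)
    vertices = np.stack([cr + r_edge * np.sin(theta),
                         cc + r_edge * np.cos(theta)], axis=1)
    return vertices, r_edge, ok


def _max_radius(rows, cols, cr, cc, theta) -> float:
    return float(min(cr, rows - 1 - cr, cc, cols - 1 - cc) - 1.0)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_short_axis(
    video: VideoSequence,
    seed_center: tuple[float, float],
    config: ShortAxisConfig = ShortAxisConfig(),
) -> ContourTrace:
    """Run the complete short-axis pipeline on a cine loop.

    Frame 0 searches every ray over its full length from the seed point
    (which must lie inside the lumen); each subsequent frame reuses the
    previous radii as the search band and the previous contour's area
    centroid as the ray origin.
    """
    n, M = video.n_frames, config.n_rays
    vertices = np.empty((n, M, 2))
    radii = np.empty((n, M))
    cents = np.empty((n, 2))
    areas = np.empty(n)
    perims = np.empty(n)
    circs = np.empty(n)
    flats = np.empty(n)
    ray_ok = np.empty((n, M), dtype=bool)

    spacing = video.pixel_spacing
    scale = np.array(spacing) if spacing is not None else np.array([1.0, 1.0])

    center = seed_center
    prev_r: np.ndarray | float = 0.0
    for i in range(n):
        v, r, okr = detect_contour_polar(
            video.frames[i], center, prev_r, config, i, full_search=(i == 0))
        vertices[i], radii[i], ray_ok[i] = v, r, okr
        v_mm = v * scale[None, :]
        cents[i] = polygon_centroid(v)
        areas[i] = polygon_area(v_mm)
        circs[i], flats[i] = shape_indices(v_mm)
        seg = np.roll(v_mm, -1, axis=0) - v_mm
        perims[i] = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
        center = cents[i]
        prev_r = radii[i]

    return ContourTrace(
        vertices=vertices, radii=radii, centroid=cents, area=areas,
        perimeter=perims, circularity=circs, flattening=flats,
        ray_ok=ray_ok, fps=video.fps, pixel_spacing=spacing,
    )
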