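"""Long-axis vessel tracking: reference points, motion compensation,
wall-edge delineation, midline fit, and diameters orthogonal to the midline.

Pipeline per frame: the two user-selected reference points are followed by
normalized cross-correlation of their frame-0 templates; the two point
pairs define a rigid (rotation + translation, scale 1) transform that
stabilizes each frame into frame-0 coordinates; both wall edges are then
detected column-wise inside a band around the previous frame's edges as
sub-pixel extrema of the depth gradient; a low-order polynomial midline is
fitted to the edge midpoints; finally diameters are measured along midline
normals at equally spaced stations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates
from skimage.feature import match_template

from .errors import InputError, TrackingLostError
from .video_io import VideoSequence

__all__ = [
    "LongAxisConfig",
    "ReferencePoints",
    "LongAxisTrace",
    "track_reference_points",
    "compensate_motion",
    "detect_edges_long",
    "estimate_midline",
    "compute_diameters",
    "run_long_axis",
]


@dataclass(frozen=True)
class LongAxisConfig:
    """Tunable parameters of the long-axis tracker (all lengths in px)."""

    template_size: int = 21        # K, odd; NCC template side
    search_radius: int = 12        # S, max per-frame displacement
    corr_threshold: float = 0.6    # below this the point is carried forward
    edge_band: int = 12            # w, half-width of the edge search band
    edge_sigma: float = 2.0        # Gaussian smoothing along depth
    gradient_min: float = 3.0      # gray/px; weaker columns flagged missing
    max_gap: int = 5               # longest interpolated run of missing columns
    midline_degree: int = 2        # d
    n_stations: int = 21           # N, diameter measurement stations
    D0_guess: float = 40.0         # initial diameter guess for frame-0 band


@dataclass
class ReferencePoints:
    """Per-frame sub-pixel positions of the two tracked reference points."""

    p1: np.ndarray                 # (n_frames, 2) (row, col)
    p2: np.ndarray
    ok: np.ndarray                 # (n_frames,) correlation above threshold


@dataclass
class LongAxisTrace:
    """Edges, midline and diameters of a long-axis cine, frame-0 coordinates."""

    cols: np.ndarray               # (n_cols,) axial sample columns
    upper: np.ndarray              # (n_frames, n_cols) sub-pixel edge rows
    lower: np.ndarray
    col_ok: np.ndarray             # (n_frames, n_cols) edge quality
    midline_coeffs: np.ndarray     # (n_frames, degree+1), np.polyval order
    station_cols: np.ndarray       # (n_stations,)
    diameters: np.ndarray          # (n_frames, n_stations)
    station_ok: np.ndarray         # (n_frames, n_stations)
    refs: ReferencePoints
    transforms: np.ndarray         # (n_frames, 3): rot_deg, trow, tcol
    fps: float
    pixel_spacing: Optional[tuple[float, float]] = None

    @property
    def mean_diameter(self) -> np.ndarray:
        """Station-mean diameter per frame, ignoring flagged stations."""
        d = np.where(self.station_ok, self.diameters, np.nan)
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=1)

    @property
    def frame_ok(self) -> np.ndarray:
        return self.station_ok.any(axis=1)


# ---------------------------------------------------------------------------
# reference-point tracking
# ---------------------------------------------------------------------------

def _parabolic_peak_2d(surface: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Refine an argmax to sub-pixel by separable parabola fits."""
    dr = dc = 0.0
    if 0 < r < surface.shape[0] - 1:
        a, b, cc = surface[r - 1, c], surface[r, c], surface[r + 1, c]
        den = a - 2 * b + cc
        if den < 0:
            dr = float(np.clip(0.5 * (a - cc) / den, -0.5, 0.5))
    if 0 < c < surface.shape[1] - 1:
        a, b, cc = surface[r, c - 1], surface[r, c], surface[r, c + 1]
        den = a - 2 * b + cc
        if den < 0:
            dc = float(np.clip(0.5 * (a - cc) / den, -0.5, 0.5))
    return dr, dc


def track_reference_points(
    video: VideoSequence,
    p1_0: tuple[float, float],
    p2_0: tuple[float, float],
    config: LongAxisConfig = LongAxisConfig(),
) -> ReferencePoints:
    """Track both seed points through the cine by template matching.

    The templates are cut from frame 0 (side ``template_size``) and never
    updated, which avoids drift accumulation; each frame is searched within
    ``search_radius`` px of the previous position.  Frames whose best
    normalized correlation falls below ``corr_threshold`` inherit the
    previous position and are flagged.
    """
    K, S = config.template_size, config.search_radius
    half = K // 2
    rows, cols = video.shape
    seeds = [np.asarray(p1_0, dtype=float), np.asarray(p2_0, dtype=float)]
    if np.allclose(seeds[0], seeds[1]):
        raise InputError("the two reference points must be distinct")
    for p in seeds:
        if not (half <= p[0] < rows - half and half <= p[1] < cols - half):
            raise InputError(
                f"seed point {tuple(p)} closer than {half} px to the border"
            )

    frame0 = video.frames[0].astype(np.float64)
    tracks = [np.empty((video.n_frames, 2)) for _ in seeds]
    ok = np.ones(video.n_frames, dtype=bool)

    for j, seed in enumerate(seeds):
        ri, ci = int(round(seed[0])), int(round(seed[1]))
        frac = seed - (ri, ci)
        template = frame0[ri - half:ri + half + 1, ci - half:ci + half + 1]
        t_std = template.std()
        pos = np.array([float(ri), float(ci)])
        tracks[j][0] = seed
        for i in range(1, video.n_frames):
            pr, pc = int(round(pos[0])), int(round(pos[1]))
            r0 = max(pr - S - half, 0)
            r1 = min(pr + S + half + 1, rows)
            c0 = max(pc - S - half, 0)
            c1 = min(pc + S + half + 1, cols)
            window = video.frames[i][r0:r1, c0:c1].astype(np.float64)
            if window.shape[0] < K or window.shape[1] < K:
                ok[i] = False
                tracks[j][i] = pos + frac
                continue
            if t_std < 1e-9 or window.std() < 1e-9:
                ok[i] = ok[i] and False
                tracks[j][i] = pos + frac
                continue
            corr = match_template(window, template)
            # featureless templates (e.g. a uniform wall band) produce flat
            # correlation ridges; a tiny centring penalty anchors ties at
            # the previous position without disturbing real matches
            rr, cc = np.meshgrid(np.arange(corr.shape[0], dtype=float),
                                 np.arange(corr.shape[1], dtype=float),
                                 indexing="ij")
            pr_rel = pos[0] - r0 - half
            pc_rel = pos[1] - c0 - half
            penalty = 1e-6 * np.hypot(rr - pr_rel, cc - pc_rel)
            r, c = np.unravel_index(np.argmax(corr - penalty), corr.shape)
            if corr[r, c] < config.corr_threshold:
                ok[i] = False
                tracks[j][i] = pos + frac
                continue
            dr, dc = _parabolic_peak_2d(corr, r, c)
            pos = np.array([r0 + half + r + dr, c0 + half + c + dc])
            tracks[j][i] = pos + frac
    return ReferencePoints(p1=tracks[0], p2=tracks[1], ok=ok)


def compensate_motion(refs: ReferencePoints) -> np.ndarray:
    """Per-frame rigid transform mapping frame-t into frame-0 coordinates.

    Returns an ``(n_frames, 3)`` array of (rotation_deg, t_row, t_col) such
    that ``p0 = R(rotation) @ p_t + t``; the rotation angle comes from the
    p1→p2 segment orientation and the translation from the segment
    midpoints (scale is fixed to 1).  Flagged frames inherit the previous
    transform.
    """
    n = refs.p1.shape[0]
    out = np.zeros((n, 3))
    v0 = refs.p2[0] - refs.p1[0]
    ang0 = math.atan2(v0[0], v0[1])
    m0 = 0.5 * (refs.p1[0] + refs.p2[0])
    for i in range(n):
        if i > 0 and not refs.ok[i]:
            out[i] = out[i - 1]
            continue
        v = refs.p2[i] - refs.p1[i]
        phi = ang0 - math.atan2(v[0], v[1])
        mi = 0.5 * (refs.p1[i] + refs.p2[i])
        ct, st = math.cos(phi), math.sin(phi)
        # rotation acts on (row, col) vectors
        tr = m0[0] - (ct * mi[0] - st * mi[1])
        tc = m0[1] - (st * mi[0] + ct * mi[1])
        out[i] = (math.degrees(phi), tr, tc)
    return out


def apply_transform(points: np.ndarray, transform: np.ndarray) -> np.ndarray:
    """Map (row, col) points with a (rot_deg, t_row, t_col) rigid transform."""
    phi = math.radians(transform[0])
    ct, st = math.cos(phi), math.sin(phi)
    pts = np.atleast_2d(points)
    return np.stack([ct * pts[:, 0] - st * pts[:, 1] + transform[1],
                     st * pts[:, 0] + ct * pts[:, 1] + transform[2]], axis=1)


def stabilize_frame(frame: np.ndarray, transform: np.ndarray) -> np.ndarray:
    """Resample a frame into frame-0 coordinates (bilinear)."""
    phi = math.radians(transform[0])
    ct, st = math.cos(phi), math.sin(phi)
    rows, cols = frame.shape
    rr, cc = np.meshgrid(np.arange(rows, dtype=float),
                         np.arange(cols, dtype=float), indexing="ij")
    # invert p0 = R p + t  ->  p = R^T (p0 - t)
    r0, c0 = rr - transform[1], cc - transform[2]
    src_r = ct * r0 + st * c0
    src_c = -st * r0 + ct * c0
    return map_coordinates(frame.astype(np.float64), [src_r, src_c],
                           order=3, mode="nearest")


# ---------------------------------------------------------------------------
# edge detection
# ---------------------------------------------------------------------------

def _band_extrema(grad: np.ndarray, prev: np.ndarray, w: int, sign: float,
                  g_min: float) -> tuple[np.ndarray, np.ndarray]:
    """Sub-pixel extremum of ``sign*grad`` within ``prev ± w`` per column.

    Ties in gradient magnitude are broken toward the previous edge (a tiny
    distance penalty, far below the gradient scale).
    """
    rows, ncols = grad.shape
    centers = np.clip(np.round(prev).astype(int), w, rows - 1 - w)
    offs = np.arange(-w, w + 1)
    idx = centers[None, :] + offs[:, None]               # (2w+1, ncols)
    vals = sign * grad[idx, np.arange(ncols)[None, :]]
    score = vals - 1e-6 * np.abs(idx - prev[None, :])
    best = np.argmax(score, axis=0)
    colr = np.arange(ncols)
    peak = vals[best, colr]
    okcol = peak >= g_min
    # parabolic refinement inside the band
    b0 = np.clip(best, 1, 2 * w - 1)
    a = vals[b0 - 1, colr]
    b = vals[b0, colr]
    c = vals[b0 + 1, colr]
    den = a - 2 * b + c
    delta = np.where(den < 0, 0.5 * (a - c) / np.where(den == 0, 1, den), 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    edge = idx[b0, colr] + delta
    return edge, okcol


def _fill_gaps(values: np.ndarray, ok: np.ndarray, max_gap: int):
    """Linearly interpolate runs of missing columns no longer than max_gap."""
    vals = values.copy()
    good = np.flatnonzero(ok)
    if good.size == 0:
        return vals, ok.copy()
    filled = ok.copy()
    bad = np.flatnonzero(~ok)
    if bad.size:
        vals[bad] = np.interp(bad, good, values[good])
        # only accept short interior gaps
        run_start = None
        for i in range(len(ok) + 1):
            missing = i < len(ok) and not ok[i]
            if missing and run_start is None:
                run_start = i
            elif not missing and run_start is not None:
                interior = run_start > 0 and i < len(ok)
                if interior and (i - run_start) <= max_gap:
                    filled[run_start:i] = True
                run_start = None
    return vals, filled


def detect_edges_long(
    frame: np.ndarray,
    prev_upper: np.ndarray,
    prev_lower: np.ndarray,
    cols: np.ndarray,
    config: LongAxisConfig = LongAxisConfig(),
    frame_index: int = 0,
):
    """Detect both wall edges in the band around the previous edges.

    Per axial column the edge is the sub-pixel location of the strongest
    depth gradient of the Gaussian-smoothed intensity profile inside
    ``previous edge ± edge_band``, sign-constrained to the lumen→wall
    transition (negative gradient for the upper edge, positive for the
    lower).  Columns whose peak gradient is below ``gradient_min`` are
    flagged and, for interior runs of at most ``max_gap`` columns, filled
    by linear interpolation.  Raises :class:`TrackingLostError` when more
    than half of the columns fail.
    """
    sub = frame[:, cols].astype(np.float64)
    smooth = gaussian_filter1d(sub, config.edge_sigma, axis=0, mode="nearest")
    grad = np.gradient(smooth, axis=0)

    up, up_ok = _band_extrema(grad, prev_upper, config.edge_band, -1.0,
                              config.gradient_min)
    lo, lo_ok = _band_extrema(grad, prev_lower, config.edge_band, +1.0,
                              config.gradient_min)
    ok = up_ok & lo_ok & (lo > up)
    if ok.sum() < 0.5 * len(cols):
        raise TrackingLostError(frame_index,
                                f"frame {frame_index}: >50% edge columns failed")
    up, ok_u = _fill_gaps(up, ok, config.max_gap)
    lo, ok_l = _fill_gaps(lo, ok, config.max_gap)
    return up, lo, ok_u & ok_l


def _init_edges(frame: np.ndarray, cols: np.ndarray, band: tuple[int, int],
                config: LongAxisConfig):
    """Frame-0 edge search over the full strip between the reference rows."""
    r0, r1 = band
    sub = frame[r0:r1, cols].astype(np.float64)
    smooth = gaussian_filter1d(sub, config.edge_sigma, axis=0, mode="nearest")
    grad = np.gradient(smooth, axis=0)
    up_i = np.argmin(grad, axis=0)
    lo_i = np.argmax(grad, axis=0)
    colr = np.arange(len(cols))
    ok = ((-grad[up_i, colr] >= config.gradient_min)
          & (grad[lo_i, colr] >= config.gradient_min)
          & (lo_i > up_i + 2))
    if ok.sum() < 0.5 * len(cols):
        raise TrackingLostError(0, "frame 0: initial edge search failed")
    up = np.where(ok, up_i, np.nan)
    lo = np.where(ok, lo_i, np.nan)
    good = np.flatnonzero(ok)
    up = np.interp(colr, good, up[good]) + r0
    lo = np.interp(colr, good, lo[good]) + r0
    return up, lo


# ---------------------------------------------------------------------------
# midline and diameters
# ---------------------------------------------------------------------------

def estimate_midline(upper: np.ndarray, lower: np.ndarray, cols: np.ndarray,
                     ok: np.ndarray, degree: int = 2) -> np.ndarray:
    """Least-squares polynomial midline through the edge midpoints.

    Returns coefficients in ``np.polyval`` order (highest power first),
    mapping column → row.  Requires at least ``degree + 1`` valid columns.
    """
    valid = np.flatnonzero(ok)
    if valid.size < degree + 1:
        raise InputError(
            f"midline fit needs >= {degree + 1} valid columns, got {valid.size}"
        )
    mid = 0.5 * (upper[valid] + lower[valid])
    return np.polyfit(cols[valid], mid, degree)


def _intersect_polyline(start: np.ndarray, direction: np.ndarray,
                        cols: np.ndarray, edge: np.ndarray,
                        s_range: tuple[float, float]) -> float:
    """Signed distance along ``direction`` from ``start`` to the edge polyline.

    Solved by fixed-point iteration (the normal is near-vertical for
    near-horizontal vessels); returns NaN when the intersection leaves the
    measured column range.
    """
    nr, nc = direction
    if abs(nr) < 1e-9:
        return float("nan")
    tol = 1e-6
    s = 0.5 * (s_range[0] + s_range[1])
    for _ in range(30):
        c = start[1] + s * nc
        if c < cols[0] - tol or c > cols[-1] + tol:
            return float("nan")
        e = np.interp(c, cols, edge)
        s_new = (e - start[0]) / nr
        if abs(s_new - s) < 1e-9:
            s = s_new
            break
        s = s_new
    c = start[1] + s * nc
    if c < cols[0] - tol or c > cols[-1] + tol:
        return float("nan")
    return float(s)


def compute_diameters(upper: np.ndarray, lower: np.ndarray,
                      midline_coeffs: np.ndarray, cols: np.ndarray,
                      n_stations: int = 21,
                      station_cols: Optional[np.ndarray] = None):
    """Diameters along midline normals at equally spaced axial stations.

    The diameter is the Euclidean distance between the intersections of
    the station normal with the two edge polylines (linear interpolation
    between edge samples).  Stations whose normal exits the measured
    segment are flagged.
    """
    if station_cols is None:
        station_cols = np.linspace(cols[0], cols[-1], n_stations)
    dpoly = np.polyder(midline_coeffs)
    diam = np.full(len(station_cols), np.nan)
    ok = np.zeros(len(station_cols), dtype=bool)
    for i, xc in enumerate(station_cols):
        m_row = np.polyval(midline_coeffs, xc)
        slope = np.polyval(dpoly, xc)  # d(row)/d(col)
        n = np.array([1.0, -slope]) / math.hypot(1.0, slope)  # unit normal
        start = np.array([m_row, xc])
        span = float(np.nanmax(lower) - np.nanmin(upper)) + 4.0
        s_lo = _intersect_polyline(start, n, cols, lower, (0.0, span))
        s_up = _intersect_polyline(start, n, cols, upper, (-span, 0.0))
        if np.isfinite(s_lo) and np.isfinite(s_up) and s_lo > s_up:
            diam[i] = s_lo - s_up
            ok[i] = True
    return diam, ok, station_cols


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_long_axis(
    video: VideoSequence,
    p1_0: tuple[float, float],
    p2_0: tuple[float, float],
    config: LongAxisConfig = LongAxisConfig(),
) -> LongAxisTrace:
    """Run the complete long-axis pipeline on a cine loop.

    Frame 0 is initialized by an edge search over the full strip between
    the two reference points' rows ± the diameter guess; subsequent frames
    are stabilized into frame-0 coordinates and searched only in a band
    around the previous edges.
    """
    refs = track_reference_points(video, p1_0, p2_0, config)
    transforms = compensate_motion(refs)

    c_lo = int(math.ceil(min(p1_0[1], p2_0[1])))
    c_hi = int(math.floor(max(p1_0[1], p2_0[1])))
    cols = np.arange(c_lo, c_hi + 1)
    if len(cols) < config.n_stations:
        raise InputError("reference points too close axially")

    # generous frame-0 strip: the seeds may sit on the walls or on nearby
    # stable tissue, so cover a diameter above and 2.5 diameters below
    rows = video.shape[0]
    band0 = (max(int(min(p1_0[0], p2_0[0]) - config.D0_guess), 0),
             min(int(max(p1_0[0], p2_0[0]) + 2.5 * config.D0_guess), rows))
    frame0 = video.frames[0].astype(np.float64)
    up, lo = _init_edges(frame0, cols, band0, config)
    up, lo, ok = detect_edges_long(frame0, up, lo, cols, config, 0)

    n = video.n_frames
    uppers = np.empty((n, len(cols)))
    lowers = np.empty((n, len(cols)))
    col_ok = np.empty((n, len(cols)), dtype=bool)
    coeffs = np.empty((n, config.midline_degree + 1))
    diams = np.empty((n, config.n_stations))
    st_ok = np.empty((n, config.n_stations), dtype=bool)
    station_cols = np.linspace(cols[0], cols[-1], config.n_stations)

    for i in range(n):
        if i > 0:
            stab = stabilize_frame(video.frames[i], transforms[i])
            up, lo, ok = detect_edges_long(stab, up, lo, cols, config, i)
        uppers[i], lowers[i], col_ok[i] = up, lo, ok
        coeffs[i] = estimate_midline(up, lo, cols, ok, config.midline_degree)
        diams[i], st_ok[i], _ = compute_diameters(
            up, lo, coeffs[i], cols, station_cols=station_cols)

    return LongAxisTrace(
        cols=cols, upper=uppers, lower=lowers, col_ok=col_ok,
        midline_coeffs=coeffs, station_cols=station_cols,
        diameters=diams, station_ok=st_ok, refs=refs,
        transforms=transforms, fps=video.fps,
        pixel_spacing=video.pixel_spacing,
    )
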