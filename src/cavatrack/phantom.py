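"""Synthetic B-mode cine loops of a compliant vein with known ground truth.

The generator ties image geometry to venous physiology: a nonlinear
volume–pressure curve maps transmural pressure ``P_tm = P_in - P_out`` to
vessel volume, and the pressure is driven by a slow respiratory component
(raised-cosine inspiration bursts) plus a faster cardiac sinusoid.  In
spontaneous breathing inspiration lowers ``P_tm`` (the vessel narrows);
positive-pressure ventilation inverts the sign.  Diameter scales with the
square root of volume (area per unit length of a cylinder), so every frame
comes with exact wall positions, contours and pulsatility indices for
parameter-recovery testing.

Speckle is modelled as a multiplicative Rayleigh field that is *static in
tissue coordinates* — it translates and rotates with the vessel, which is
what makes template tracking of reference points physically meaningful —
followed by a Gaussian point-spread blur and per-frame additive sensor
noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .errors import GenerationError
from .video_io import VideoSequence

__all__ = [
    "PressureVolumeCurve",
    "PressureDrivers",
    "PhantomSpec",
    "GroundTruth",
    "pressure_series",
    "resp_wave",
    "generate_long_axis",
    "generate_short_axis",
    "preset",
    "PRESETS",
]


# ---------------------------------------------------------------------------
# physiology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PressureVolumeCurve:
    """Logistic volume–pressure relation of a collapsible vein.

    ``V(P_tm) = V_max / (1 + exp(-(P_tm - P_half)/k))``

    The curve is strictly increasing and flattens at high transmural
    pressure, so compliance ``C = dV/dP_tm`` is positive everywhere and
    decreases once the vessel distends (``P_tm > P_half``).

    Parameters
    ----------
    V_max : volume scale, arbitrary units.
    P_half : pressure of half-maximal volume, mmHg.
    k : steepness, mmHg; compliance at ``P_half`` is ``V_max / (4 k)``.
    """

    V_max: float = 100.0
    P_half: float = 2.0
    k: float = 3.0

    def __post_init__(self) -> None:
        if self.V_max <= 0 or self.k <= 0:
            raise GenerationError("V_max and k must be positive")

    def volume(self, p_tm):
        z = (np.asarray(p_tm, dtype=float) - self.P_half) / self.k
        return self.V_max / (1.0 + np.exp(-z))

    def compliance(self, p_tm):
        """Analytic slope dV/dP_tm of the curve."""
        v = self.volume(p_tm)
        return v * (1.0 - v / self.V_max) / self.k

    __call__ = volume


Mode = Literal["thoracic_inspiration", "abdominal_inspiration", "positive_pressure"]

_SPONTANEOUS = {"thoracic_inspiration", "abdominal_inspiration"}


@dataclass(frozen=True)
class PressureDrivers:
    """Respiratory and cardiac pressure drivers of the phantom.

    ``mode`` sets the sign of the inspiratory size change: during
    spontaneous inspiration (thoracic or abdominal) transmural pressure
    falls and the vein narrows, whereas positive-pressure ventilation
    raises it and the vein widens.
    """

    P_in_mean: float = 5.0     # mmHg
    A_card: float = 0.8        # mmHg
    f_card: float = 1.2        # Hz
    A_resp: float = 4.5        # mmHg
    f_resp: float = 0.25       # Hz
    mode: Mode = "thoracic_inspiration"
    # quiet breathing spends about a third of the cycle inspiring (I:E 1:2)
    insp_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.A_resp > 0 and self.A_card > 0 and not self.f_resp < self.f_card:
            raise GenerationError(
                f"respiratory rate ({self.f_resp} Hz) must be below cardiac "
                f"rate ({self.f_card} Hz)"
            )
        if self.mode not in _SPONTANEOUS | {"positive_pressure"}:
            raise GenerationError(f"unknown respiration mode: {self.mode!r}")
        if not 0.05 <= self.insp_fraction <= 0.95:
            raise GenerationError("insp_fraction must lie in [0.05, 0.95]")

    @property
    def sign(self) -> float:
        """+1 when inspiration lowers P_tm (spontaneous), -1 otherwise."""
        return 1.0 if self.mode in _SPONTANEOUS else -1.0


def resp_wave(phase: np.ndarray, insp_fraction: float = 0.4) -> np.ndarray:
    """Raised-cosine inspiration burst, 0 outside inspiration, peak 1.

    ``phase`` is the respiratory phase in radians; each cycle starts with
    an inspiration occupying ``insp_fraction`` of the cycle.
    """
    frac = (np.asarray(phase, dtype=float) / (2 * np.pi)) % 1.0
    u = frac / insp_fraction
    return np.where(u < 1.0, 0.5 * (1.0 - np.cos(2 * np.pi * u)), 0.0)


def pressure_series(drivers: PressureDrivers, fps: float, n_frames: int) -> np.ndarray:
    """Transmural pressure P_tm(t) in mmHg, sampled at the frame times.

    ``P_tm(t) = P_in_mean + A_card sin(2π f_card t)
    - s · A_resp · resp_wave(2π f_resp t)`` with ``s = +1`` for
    spontaneous breathing and ``s = -1`` for positive-pressure ventilation.
    """
    if n_frames < 2:
        raise GenerationError("need at least 2 frames")
    t = np.arange(n_frames) / fps
    card = drivers.A_card * np.sin(2 * np.pi * drivers.f_card * t)
    resp = drivers.A_resp * resp_wave(2 * np.pi * drivers.f_resp * t,
                                      drivers.insp_fraction)
    return drivers.P_in_mean + card - drivers.sign * resp


# ---------------------------------------------------------------------------
# phantom specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, brightness and noise of a synthetic cine loop.

    Brightness ordering must be wall > background > lumen (hypoechoic
    lumen between echogenic walls).  ``taper`` varies the diameter along
    the vessel axis; ``midline_slope``/``midline_curv`` bend the vessel
    midline (long axis).  ``eccentricity_coupling`` flattens the short-axis
    cross-section as transmural pressure falls; the section is circular at
    and above ``P_round`` mmHg.
    """

    view: Literal["long_axis", "short_axis"] = "long_axis"
    shape: tuple[int, int] = (128, 400)
    D0: float = 40.0                # baseline lumen diameter, px
    taper: float = 0.0              # relative diameter change across the segment
    midline_slope: float = 0.0      # px over half-width (long axis)
    midline_curv: float = 0.0       # px, quadratic midline coefficient
    wall_thickness: float = 6.0     # px
    wall_brightness: float = 200.0
    lumen_brightness: float = 20.0
    background_brightness: float = 90.0
    speckle_sigma: float = 0.0      # Rayleigh scale; 0 disables speckle
    noise_sigma: float = 0.0        # additive per-frame sensor noise, gray levels
    psf_sigma: float = 1.0          # Gaussian blur, px
    drift: tuple[float, float] = (0.0, 0.0)   # (row, col) px/frame
    rotation_rate: float = 0.0      # deg/frame, about the image centre
    eccentricity_coupling: float = 0.0  # flattening per mmHg below P_round
    P_round: float = 10.0           # mmHg at/above which the section is circular
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D0 < 8:
            raise GenerationError("baseline diameter must be >= 8 px")
        if not (self.wall_brightness > self.background_brightness
                > self.lumen_brightness):
            raise GenerationError(
                "brightness ordering must be wall > background > lumen"
            )


@dataclass
class GroundTruth:
    """Exact per-frame geometry and indices behind a phantom video.

    ``size_series`` is the station-mean lumen diameter (long axis) or the
    cross-sectional area (short axis), noise-free.  ``ci``, ``rci`` and
    ``cci`` are computed by brute-force per-cycle extrema on the noise-free
    series (cardiac-free series for ``rci``), never through the estimation
    pipeline.
    """

    p_tm: np.ndarray                       # (n_frames,)
    size_series: np.ndarray                # (n_frames,)
    resp_size_series: np.ndarray           # (n_frames,) cardiac amplitude = 0
    ci: float
    rci: float
    cci: float
    breath_onsets: np.ndarray              # frame indices, inspiration onsets
    transforms: np.ndarray                 # (n_frames, 3): rot_deg, drow, dcol
    # long axis
    station_x: Optional[np.ndarray] = None       # normalized axial coords
    diameters: Optional[np.ndarray] = None       # (n_frames, n_stations)
    midline_row: Optional[np.ndarray] = None     # midline row per station, frame 0
    reference_points: Optional[np.ndarray] = None  # (n_frames, 2, 2) (row,col)
    # short axis
    centroid: Optional[np.ndarray] = None        # (n_frames, 2) (row, col)
    area: Optional[np.ndarray] = None            # (n_frames,) px^2
    semi_axes: Optional[np.ndarray] = None       # (n_frames, 2) (a, b) px
    flattening: Optional[np.ndarray] = None      # (n_frames,)
    contours: Optional[np.ndarray] = None        # (n_frames, M, 2) (row, col)


# ---------------------------------------------------------------------------
# brute-force ground-truth indices
# ---------------------------------------------------------------------------

def _cycle_index(windows, series) -> list[float]:
    vals = []
    for a, b in windows:
        seg = series[a:b]
        if len(seg) >= 2:
            vals.append((seg.max() - seg.min()) / seg.max())
    return vals


def _ideal_lowpass(x: np.ndarray, fps: float, f_cut: float) -> np.ndarray:
    """The package-wide ideal band split (see indices.spectral_lowpass).

    The same operator defines the respiratory component in ground truth
    and measurement; a respiratory harmonic landing within one bin of the
    cutoff would otherwise be split differently by the two routes.
    """
    from .indices import spectral_lowpass

    return spectral_lowpass(x, fps, f_cut)


def _true_indices(size_full, size_resp, fps, drivers, n_frames, f_cut=0.6):
    """CI/RCI/CCI by brute-force extrema over analytically known cycles.

    RCI is defined on the respiratory component — the trend plus the band
    below ``f_cut`` — so its ground truth takes the ideal (spectral)
    low-pass of the cardiac-free series before the per-breath extrema.
    """
    t_breath = 1.0 / drivers.f_resp
    onsets = np.arange(0, n_frames / fps, t_breath) * fps
    onsets = np.unique(np.round(onsets).astype(int))
    onsets = onsets[onsets < n_frames]
    breaths = [(onsets[i], onsets[i + 1]) for i in range(len(onsets) - 1)]

    ci_vals = _cycle_index(breaths, size_full)
    rci_vals = _cycle_index(breaths, _ideal_lowpass(size_resp, fps, f_cut))
    ci = float(np.mean(ci_vals)) if ci_vals else 0.0
    rci = float(np.mean(rci_vals)) if rci_vals else 0.0

    if drivers.A_card > 0:
        # cardiac size minima sit at pressure minima: phase 3π/2 of the sine
        period = fps / drivers.f_card
        starts = np.round(np.arange(0.75 * period, n_frames, period)).astype(int)
        beats = [(starts[i], starts[i + 1]) for i in range(len(starts) - 1)
                 if starts[i + 1] <= n_frames]
        cci_vals = _cycle_index(beats, size_full)
        cci = float(np.median(cci_vals)) if cci_vals else 0.0
    else:
        cci = 0.0
    return ci, rci, cci, onsets


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------

def _smoothstep(x, width=0.7):
    """C1 ramp from 0 to 1 across ~width px; keeps edges at sub-pixel truth."""
    return 0.5 * (1.0 + np.tanh(x / width))


def _rigid_params(spec: PhantomSpec, n_frames: int) -> np.ndarray:
    t = np.arange(n_frames, dtype=float)
    out = np.empty((n_frames, 3))
    out[:, 0] = spec.rotation_rate * t
    out[:, 1] = spec.drift[0] * t
    out[:, 2] = spec.drift[1] * t
    return out


def _inverse_map(shape, rot_deg, drow, dcol):
    """Tissue coordinates for every image pixel under the frame's motion."""
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows, dtype=float),
                         np.arange(cols, dtype=float), indexing="ij")
    cr, ccen = (rows - 1) / 2.0, (cols - 1) / 2.0
    th = math.radians(rot_deg)
    ct, st = math.cos(th), math.sin(th)
    r0, c0 = rr - cr - drow, cc - ccen - dcol
    # inverse rotation
    rt = ct * r0 + st * c0 + cr
    cT = -st * r0 + ct * c0 + ccen
    return rt, cT


def _forward_point(shape, rot_deg, drow, dcol, pts):
    rows, cols = shape
    cr, ccen = (rows - 1) / 2.0, (cols - 1) / 2.0
    th = math.radians(rot_deg)
    ct, st = math.cos(th), math.sin(th)
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    r0, c0 = pts[:, 0] - cr, pts[:, 1] - ccen
    out = np.stack([ct * r0 - st * c0 + cr + drow,
                    st * r0 + ct * c0 + ccen + dcol], axis=1)
    return out


def _speckle_field(rng, shape, sigma):
    """Static multiplicative Rayleigh speckle, unit mean, on a padded grid."""
    pad = 40
    fld = rng.rayleigh(scale=sigma, size=(shape[0] + 2 * pad, shape[1] + 2 * pad))
    fld /= sigma * math.sqrt(math.pi / 2.0)  # Rayleigh mean -> 1
    return fld, pad


def _apply_noise(img, speckle, pad, rt, ct_, spec, rng):
    if speckle is not None:
        s = map_coordinates(speckle, [rt + pad, ct_ + pad], order=1, mode="nearest")
        img = img * s
    if spec.psf_sigma > 0:
        img = gaussian_filter(img, spec.psf_sigma, mode="nearest")
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# long-axis phantom
# ---------------------------------------------------------------------------

def generate_long_axis(
    spec: PhantomSpec,
    curve: PressureVolumeCurve,
    drivers: PressureDrivers,
    n_frames: int,
    fps: float = 30.0,
    n_stations: int = 21,
) -> tuple[VideoSequence, GroundTruth]:
    """Render a longitudinal view: two echogenic walls around a dark lumen.

    The lumen diameter at normalized axial position x̂ ∈ [-1, 1] and time t
    is ``D(x̂, t) = D0 (1 + taper·x̂) sqrt(V(P_tm(t)) / V(P_in_mean))``;
    ground truth carries the exact per-station diameters and the driving
    pressure.
    """
    if spec.view != "long_axis":
        raise GenerationError("spec.view must be 'long_axis'")
    rows, cols = spec.shape
    rng = np.random.default_rng(spec.seed)

    p_tm = pressure_series(drivers, fps, n_frames)
    g = np.sqrt(curve.volume(p_tm) / curve.volume(drivers.P_in_mean))
    p_resp = pressure_series(replace(drivers, A_card=0.0), fps, n_frames)
    g_resp = np.sqrt(curve.volume(p_resp) / curve.volume(drivers.P_in_mean))

    xhat_all = np.linspace(-1.0, 1.0, cols)
    mid_all = (rows - 1) / 2.0 + spec.midline_slope * xhat_all \
        + spec.midline_curv * xhat_all ** 2
    taper_all = 1.0 + spec.taper * xhat_all

    d_min = spec.D0 * taper_all.min() * g.min()
    if d_min < 2.0:
        raise GenerationError(
            f"lumen collapses to {d_min:.2f} px (< 2 px); unphysical spec"
        )

    # stations over the central 80% of the width (the tracked segment)
    station_x = np.linspace(-0.8, 0.8, n_stations)
    mid_st = (rows - 1) / 2.0 + spec.midline_slope * station_x \
        + spec.midline_curv * station_x ** 2
    diameters = spec.D0 * (1.0 + spec.taper * station_x)[None, :] * g[:, None]
    size_series = diameters.mean(axis=1)
    size_resp = spec.D0 * (1.0 + spec.taper * station_x).mean() * g_resp

    transforms = _rigid_params(spec, n_frames)
    speckle, pad = (None, 0)
    if spec.speckle_sigma > 0:
        speckle, pad = _speckle_field(rng, spec.shape, spec.speckle_sigma)

    # reference points in the echogenic tissue above the anterior wall's
    # full excursion range, at x̂ = ∓0.7 — stable landmarks, as an operator
    # would pick (a point on the moving wall itself decorrelates from its
    # first-frame template as the vessel pulses)
    g_max = g.max()
    ref0 = []
    for xh in (-0.7, 0.7):
        m = (rows - 1) / 2.0 + spec.midline_slope * xh + spec.midline_curv * xh ** 2
        d_max = spec.D0 * (1.0 + spec.taper * xh) * g_max
        # clear the wall's whole excursion range by a template half-width,
        # so the tracked patch never contains moving structure
        row = max(m - d_max / 2.0 - spec.wall_thickness - 14.0, 12.0)
        ref0.append((row, (xh + 1.0) / 2.0 * (cols - 1)))
    ref0 = np.asarray(ref0)
    ref_tracks = np.stack(
        [_forward_point(spec.shape, *transforms[i], ref0) for i in range(n_frames)]
    )

    wb, lb, bb = spec.wall_brightness, spec.lumen_brightness, \
        spec.background_brightness
    wt = spec.wall_thickness
    frames = np.empty((n_frames, rows, cols), dtype=np.uint8)
    for i in range(n_frames):
        rt, ct_ = _inverse_map(spec.shape, *transforms[i])
        xh = 2.0 * ct_ / (cols - 1) - 1.0
        mid = (rows - 1) / 2.0 + spec.midline_slope * xh + spec.midline_curv * xh ** 2
        half = 0.5 * spec.D0 * (1.0 + spec.taper * xh) * g[i]
        u, low = mid - half, mid + half
        img = np.full((rows, cols), bb, dtype=float)
        img += (wb - bb) * (_smoothstep(rt - (u - wt)) - _smoothstep(rt - u))
        img += (lb - bb) * (_smoothstep(rt - u) - _smoothstep(rt - low))
        img += (wb - bb) * (_smoothstep(rt - low) - _smoothstep(rt - (low + wt)))
        frames[i] = _apply_noise(img, speckle, pad, rt, ct_, spec, rng)

    ci, rci, cci, onsets = _true_indices(size_series, size_resp, fps,
                                         drivers, n_frames)
    truth = GroundTruth(
        p_tm=p_tm, size_series=size_series, resp_size_series=size_resp,
        ci=ci, rci=rci, cci=cci, breath_onsets=onsets, transforms=transforms,
        station_x=station_x, diameters=diameters, midline_row=mid_st,
        reference_points=ref_tracks,
    )
    return VideoSequence(frames, fps), truth


# ---------------------------------------------------------------------------
# short-axis phantom
# ---------------------------------------------------------------------------

def generate_short_axis(
    spec: PhantomSpec,
    curve: PressureVolumeCurve,
    drivers: PressureDrivers,
    n_frames: int,
    fps: float = 30.0,
    n_contour: int = 180,
) -> tuple[VideoSequence, GroundTruth]:
    """Render a cross-sectional view: a bright elliptical ring, dark inside.

    The cross-sectional area tracks vessel volume,
    ``A(t) = π (D0/2)² · V(P_tm(t)) / V(P_in_mean)``, and the section
    flattens as transmural pressure falls below ``P_round``:
    ``flattening = min(ecc_coupling · (P_round - P_tm), 0.85)`` with
    semi-axes ``a = sqrt(A / (π(1-f)))`` and ``b = a (1-f)``.
    """
    if spec.view != "short_axis":
        raise GenerationError("spec.view must be 'short_axis'")
    rows, cols = spec.shape
    rng = np.random.default_rng(spec.seed)

    p_tm = pressure_series(drivers, fps, n_frames)
    area = math.pi * (spec.D0 / 2.0) ** 2 \
        * curve.volume(p_tm) / curve.volume(drivers.P_in_mean)
    p_resp = pressure_series(replace(drivers, A_card=0.0), fps, n_frames)
    area_resp = math.pi * (spec.D0 / 2.0) ** 2 \
        * curve.volume(p_resp) / curve.volume(drivers.P_in_mean)

    flat = np.clip(spec.eccentricity_coupling * (spec.P_round - p_tm), 0.0, 0.85)
    ratio = 1.0 - flat
    a_ax = np.sqrt(area / (math.pi * ratio))   # semi-axis along columns
    b_ax = a_ax * ratio                        # semi-axis along rows
    if (2 * b_ax).min() < 2.0:
        raise GenerationError("minor axis collapses below 2 px; unphysical spec")
    if (a_ax + spec.wall_thickness).max() > min(rows, cols) / 2.0 - 2:
        raise GenerationError("vessel does not fit in the frame")

    transforms = _rigid_params(spec, n_frames)
    speckle, pad = (None, 0)
    if spec.speckle_sigma > 0:
        speckle, pad = _speckle_field(rng, spec.shape, spec.speckle_sigma)

    centre0 = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    centroid = np.stack(
        [_forward_point(spec.shape, *transforms[i], centre0)[0]
         for i in range(n_frames)]
    )

    theta = np.linspace(0.0, 2 * np.pi, n_contour, endpoint=False)
    contours = np.empty((n_frames, n_contour, 2))
    wb, lb, bb = spec.wall_brightness, spec.lumen_brightness, \
        spec.background_brightness
    wt = spec.wall_thickness
    frames = np.empty((n_frames, rows, cols), dtype=np.uint8)
    for i in range(n_frames):
        rt, ct_ = _inverse_map(spec.shape, *transforms[i])
        dr, dc = rt - centre0[0], ct_ - centre0[1]
        a, b = a_ax[i], b_ax[i]
        rho = np.sqrt((dc / a) ** 2 + (dr / b) ** 2)
        ang = np.arctan2(dr, dc)
        r_dir = a * b / np.sqrt((b * np.cos(ang)) ** 2 + (a * np.sin(ang)) ** 2)
        s = (rho - 1.0) * r_dir  # approx. signed distance to the lumen contour
        img = np.full((rows, cols), bb, dtype=float)
        img += (lb - bb) * (1.0 - _smoothstep(s))
        img += (wb - bb) * (_smoothstep(s) - _smoothstep(s - wt))
        frames[i] = _apply_noise(img, speckle, pad, rt, ct_, spec, rng)

        pts = np.stack([b * np.sin(theta) + centre0[0],
                        a * np.cos(theta) + centre0[1]], axis=1)
        contours[i] = _forward_point(spec.shape, *transforms[i], pts)

    ci, rci, cci, onsets = _true_indices(area, area_resp, fps, drivers, n_frames)
    truth = GroundTruth(
        p_tm=p_tm, size_series=area, resp_size_series=area_resp,
        ci=ci, rci=rci, cci=cci, breath_onsets=onsets, transforms=transforms,
        centroid=centroid, area=area,
        semi_axes=np.stack([a_ax, b_ax], axis=1), flattening=flat,
        contours=contours,
    )
    return VideoSequence(frames, fps), truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset(name: str, view: str = "long_axis", seed: int = 0):
    """Named (spec, curve, drivers) triples for typical volume states.

    ``default`` is a normovolemic spontaneously breathing subject;
    ``hypovolemic`` has low mean transmural pressure (small, pulsatile,
    flattened vessel) and ``hypervolemic`` a high one (large, round,
    barely pulsatile).
    """
    if name not in PRESETS:
        raise GenerationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[name]
    shape = (128, 400) if view == "long_axis" else (128, 128)
    spec = PhantomSpec(
        view=view, shape=shape, D0=p["D0"],
        speckle_sigma=0.35, noise_sigma=2.0, psf_sigma=1.0,
        eccentricity_coupling=p["ecc"] if view == "short_axis" else 0.0,
        seed=seed,
    )
    curve = PressureVolumeCurve()
    drivers = PressureDrivers(P_in_mean=p["P_in_mean"], A_resp=p["A_resp"],
                              mode=p.get("mode", "thoracic_inspiration"))
    return spec, curve, drivers


PRESETS = {
    "default": dict(P_in_mean=5.0, A_resp=4.5, D0=40.0, ecc=0.03),
    "hypovolemic": dict(P_in_mean=1.5, A_resp=4.5, D0=28.0, ecc=0.06),
    "hypervolemic": dict(P_in_mean=12.0, A_resp=4.5, D0=48.0, ecc=0.01),
}
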