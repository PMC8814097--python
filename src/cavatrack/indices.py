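"""Pulsatility indices and compliance relations of a vessel size series.

A tracked size series (station-mean diameter or cross-sectional area)
contains two oscillations: a slow respiratory component and a faster
cardiac one.  The series is split by zero-phase low-pass filtering at
``f_cut`` — the residual is the cardiac component, so the two parts always
add back to the input exactly.  Indices follow the (max − min)/max caval
index template:

* CI  — per respiratory cycle on the raw series, averaged over breaths;
* RCI — the same on the respiratory component (trend + sub-``f_cut`` band);
* CCI — per cardiac cycle on the locally reconstructed signal, aggregated
  by the median over beats (robust to occasional bad beats).

Compliance is the slope C = ΔV/ΔP_tm of the volume–pressure curve, and the
measurable total compliance combines the vascular and extravascular parts
in series: C_tot = 1/(1/C_v + 1/C_ev), always below either one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import signal

from .errors import ConfigError, InputError

__all__ = [
    "SizeSeries",
    "PulsatilityReport",
    "decompose",
    "segment_breaths",
    "caval_index",
    "respiratory_caval_index",
    "cardiac_caval_index",
    "compliance",
    "total_compliance",
    "analyze",
]


@dataclass
class SizeSeries:
    """A per-frame scalar vessel size with its sampling rate.

    ``quality`` marks frames trustworthy enough to enter extrema searches;
    flagged frames are excluded from the indices, never interpolated into
    them.
    """

    values: np.ndarray
    fps: float
    kind: Literal["diameter", "area"] = "diameter"
    quality: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InputError("size series must be one-dimensional")
        if self.quality is None:
            self.quality = np.ones(len(self.values), dtype=bool)
        else:
            self.quality = np.asarray(self.quality, dtype=bool)
        if not self.fps > 0:
            raise ConfigError("fps must be positive")


@dataclass
class PulsatilityReport:
    """Scalar pulsatility indices plus the series they were derived from."""

    mean_size: float               # Dm for diameters, Am for areas
    kind: str
    ci: float
    rci: float
    cci: float
    resp_component: np.ndarray
    card_component: np.ndarray
    breath_boundaries: np.ndarray  # frame indices of breath starts
    f_resp_est: float
    f_card_est: float

    def scalars(self) -> dict:
        key = "Dm" if self.kind == "diameter" else "Am"
        return {
            key: self.mean_size, "CI": self.ci, "RCI": self.rci,
            "CCI": self.cci, "f_resp_Hz": self.f_resp_est,
            "f_card_Hz": self.f_card_est,
            "n_breaths": max(len(self.breath_boundaries) - 1, 0),
        }


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

# physiological prior on heart rate for the cardiac spectral-peak search;
# respiratory harmonics leaking just above f_cut would otherwise win
_F_CARD_BAND = (0.8, 3.0)  # Hz, 48-180 bpm


def _spectral_peak(x: np.ndarray, fps: float, f_lo: float, f_hi: float) -> float:
    f, p = signal.periodogram(x - x.mean(), fs=fps)
    band = (f > f_lo) & (f < f_hi)
    if not band.any() or p[band].max() <= 0:
        return float("nan")
    return float(f[band][np.argmax(p[band])])


def spectral_lowpass(x: np.ndarray, fps: float, f_cut: float) -> np.ndarray:
    """Zero-phase low-pass: the trend plus the band up to ``f_cut``.

    Forward–backward 8th-order Butterworth filtering — no phase
    distortion, gentle edge transients, and a passband flat enough that a
    band-limited signal passes essentially unchanged.  This single operator *defines* the respiratory component
    throughout the package (the phantom's analytic ground truth applies
    the identical operator to its noise-free series), so passband rolloff
    near the cutoff affects both routes equally.
    """
    x = np.asarray(x, dtype=float)
    sos = signal.butter(8, f_cut, btype="low", fs=fps, output="sos")
    # padding must span the filter settling time (several cutoff periods)
    padlen = min(len(x) - 1, int(6.0 * fps / f_cut))
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def decompose(series: SizeSeries, f_cut: float = 0.6):
    """Split a size series into respiratory and cardiac components.

    A zero-phase ideal low-pass at ``f_cut`` (see
    :func:`spectral_lowpass`) yields the respiratory component including
    the trend; the cardiac component is the residual, so ``resp + card``
    reconstructs the input exactly at every sample.  Returns
    ``(resp, card, f_resp_est, f_card_est)``.
    """
    x, fps = series.values, series.fps
    if f_cut >= fps / 2.0:
        raise ConfigError(f"f_cut={f_cut} must be below the Nyquist rate {fps / 2}")
    if f_cut <= 0:
        raise ConfigError("f_cut must be positive")
    if len(x) < 4.0 / f_cut * fps:
        raise InputError(
            f"series too short: need >= {4.0 / f_cut:.0f} s at f_cut={f_cut} Hz"
        )
    resp = spectral_lowpass(x, fps, f_cut)
    card = x - resp
    f_resp = _f_resp_refined(resp, fps)
    f_card = _spectral_peak(card, fps, max(f_cut, _F_CARD_BAND[0]),
                            min(_F_CARD_BAND[1], fps / 2.0))
    return resp, card, f_resp, f_card


def segment_breaths(resp_component: np.ndarray, fps: float,
                    f_resp_est: Optional[float] = None,
                    p_min: float = 0.25,
                    raw: Optional[np.ndarray] = None,
                    f_card_est: Optional[float] = None) -> np.ndarray:
    """Breath boundaries: inspiration onsets of the respiratory component.

    Inspiratory troughs are located as local minima with prominence
    ≥ ``p_min`` of the component's range, separated by at least half an
    estimated respiratory period.  Each boundary is then walked back to
    the onset of its trough (the last sample within 5% of the local
    pre-inspiratory level), so every breath window contains exactly one
    complete excursion.  The sharp decomposition filter smears onsets by
    a fraction of a second, so when the ``raw`` series is supplied the
    onset is localized on a gentler smoother (4th-order zero-phase
    low-pass just below the cardiac band) instead.
    Raises :class:`InputError` when fewer than two troughs (no complete
    cycle) are found.
    """
    x = np.asarray(resp_component, dtype=float)
    rng = x.max() - x.min()
    if rng <= 0:
        raise InputError("flat respiratory component: no breath to segment")
    if f_resp_est is None or not np.isfinite(f_resp_est) or f_resp_est <= 0:
        f_resp_est = _spectral_peak(x, fps, 0.05, fps / 2.0)
    if np.isfinite(f_resp_est) and f_resp_est > 0:
        # locate troughs on the respiratory fundamental alone: harmonics of
        # a non-sinusoidal breath can ring into double minima per cycle
        smooth = spectral_lowpass(x, fps, 1.3 * f_resp_est)
        distance = max(int(0.5 * fps / f_resp_est), 1)
        half = max(int(0.25 * fps / f_resp_est), 1)
    else:
        smooth, distance, half = x, 1, 1
    coarse, _ = signal.find_peaks(-smooth, prominence=p_min * rng,
                                  distance=distance)
    if len(coarse) < 2 and smooth is not x:
        # a misjudged respiratory rate can over-smooth the troughs away;
        # fall back to the component itself
        coarse, _ = signal.find_peaks(-x, prominence=p_min * rng,
                                      distance=distance)
    minima = np.unique([
        max(m - half, 0) + int(np.argmin(x[max(m - half, 0):m + half + 1]))
        for m in coarse
    ]) if len(coarse) else coarse
    if len(minima) < 2:
        raise InputError("fewer than one complete respiratory cycle detected")

    if raw is not None and f_card_est is not None \
            and np.isfinite(f_card_est) and 0.8 * f_card_est < fps / 2.0:
        sos = signal.butter(4, 0.8 * f_card_est, btype="low", fs=fps,
                            output="sos")
        pad = min(len(raw) - 1, int(3.0 * fps / (0.8 * f_card_est)))
        b = signal.sosfiltfilt(sos, np.asarray(raw, dtype=float), padlen=pad)
    else:
        b = x

    onsets = []
    prev = 0
    for m in minima:
        base = float(np.percentile(b[prev:m + 1], 85))
        depth = base - b[m]
        onset = m
        while onset > prev and b[onset - 1] < base - 0.05 * depth:
            onset -= 1
        onsets.append(onset)
        prev = m
    return np.asarray(onsets)


# ---------------------------------------------------------------------------
# caval indices
# ---------------------------------------------------------------------------

def _windowed_index(values: np.ndarray, boundaries: np.ndarray,
                    quality: Optional[np.ndarray] = None) -> list[float]:
    out = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        seg = values[a:b + 1]
        if quality is not None:
            seg = seg[quality[a:b + 1]]
        if len(seg) >= 2 and seg.max() > 0:
            out.append(float((seg.max() - seg.min()) / seg.max()))
    return out


def caval_index(series: SizeSeries, breaths: np.ndarray) -> float:
    """CI: breath-wise (max − min)/max on the raw series, mean over breaths."""
    vals = _windowed_index(series.values, breaths, series.quality)
    if not vals:
        raise InputError("no complete breath window")
    return float(np.mean(vals))


def respiratory_caval_index(resp_component: np.ndarray,
                            breaths: np.ndarray,
                            quality: Optional[np.ndarray] = None) -> float:
    """RCI: the caval-index formula applied to the respiratory component."""
    vals = _windowed_index(np.asarray(resp_component, float), breaths, quality)
    if not vals:
        raise InputError("no complete breath window")
    return float(np.mean(vals))


def _parabolic_refine(f: np.ndarray, log_p: np.ndarray, i: int) -> float:
    """Sub-bin peak frequency by a log-parabola through three bins."""
    if 0 < i < len(log_p) - 1:
        den = log_p[i - 1] - 2 * log_p[i] + log_p[i + 1]
        if den < 0:
            d = 0.5 * (log_p[i - 1] - log_p[i + 1]) / den
            return float(f[i] + np.clip(d, -0.5, 0.5) * (f[1] - f[0]))
    return float(f[i])


def _f_resp_refined(resp: np.ndarray, fps: float) -> float:
    """Respiratory fundamental with sub-bin (log-parabolic) refinement.

    The spectral peak of a non-sinusoidal breath is not always the
    fundamental — a brief inspiration burst can put more power into the
    second harmonic — so sub-harmonics of the peak are also scored by
    their harmonic sum (standard pitch-detection logic) before refining.
    """
    fr, pr = signal.periodogram(resp - resp.mean(), fs=fps, window="hann")
    band_r = (fr > 0.05) & (fr < _F_CARD_BAND[0])
    if not band_r.any() or pr[band_r].max() <= 0:
        return float("nan")
    i_pk = int(np.argmax(pr * band_r))
    f_pk = fr[i_pk]

    def is_sub_line(f0: float) -> bool:
        """A genuine sub-harmonic line: a local periodogram peak with
        substantial power (leakage shoulders of the main line are
        monotone, not peaks)."""
        i = int(np.round(f0 / fr[1]))
        if not 1 <= i < len(pr) - 1:
            return False
        j = i + int(np.argmax(pr[i - 1:i + 2])) - 1  # snap to local max
        if not 1 <= j < len(pr) - 1:
            return False
        return (pr[j] >= pr[j - 1] and pr[j] >= pr[j + 1]
                and pr[j] >= 0.15 * pr[i_pk])

    best = f_pk
    for div in (3, 2):
        f0 = f_pk / div
        if f0 > 0.05 and is_sub_line(f0):
            best = f0
            break
    i0 = int(np.round(best / fr[1]))
    return _parabolic_refine(fr, np.log(pr + 1e-300), i0)


def _harmonic_coupling(band_sig: np.ndarray, resp_phase: np.ndarray,
                       k: int) -> float:
    """Phase coupling of a narrowband signal to the k-th respiratory harmonic.

    A true harmonic of the breath satisfies phase = k * resp_phase + const,
    giving coupling near 1; an independent cardiac oscillation gives a
    value near 0.
    """
    z = signal.hilbert(band_sig)
    amp = np.abs(z)
    if amp.max() <= 0:
        return 0.0
    unit = z / np.maximum(amp, 1e-12 * amp.max())
    return float(np.abs(np.mean(unit * np.exp(-1j * k * resp_phase))))


def _f_card_robust(card: np.ndarray, resp: np.ndarray, fps: float) -> float:
    """Heart-rate estimate immune to the respiratory harmonic comb.

    A non-sinusoidal breath leaks harmonics above the decomposition cutoff
    that can out-power the cardiac spectral peak.  Candidate peaks in the
    heart-rate band are therefore screened by their phase coupling to the
    respiratory fundamental: harmonics are phase-locked to the breath
    (phase = k * breath phase), the cardiac line is not.  Among weakly
    coupled candidates the most powerful wins; if every candidate is
    coupled (heart rate sitting exactly on a harmonic) the least coupled
    one is taken.
    """
    f, p = signal.periodogram(card - card.mean(), fs=fps, window="hann")
    band = (f > _F_CARD_BAND[0]) & (f < min(_F_CARD_BAND[1], fps / 2.0))
    if not band.any() or p[band].max() <= 0:
        return float("nan")
    fb, pb = f[band], p[band]
    log_pb = np.log(pb + 1e-300)
    i_full = int(np.argmax(pb))

    f_resp = _f_resp_refined(resp, fps)
    if not np.isfinite(f_resp) or f_resp <= 0:
        return _parabolic_refine(fb, log_pb, i_full)

    # respiratory phase from the band-limited fundamental
    sos_r = signal.butter(2, [0.7 * f_resp, 1.3 * f_resp], btype="band",
                          fs=fps, output="sos")
    resp_phase = np.unwrap(np.angle(signal.hilbert(
        signal.sosfiltfilt(sos_r, resp - resp.mean()))))

    pk, _ = signal.find_peaks(pb)
    if len(pk) == 0:
        return _parabolic_refine(fb, log_pb, i_full)
    cand = pk[np.argsort(pb[pk])[::-1][:8]]
    cand = cand[pb[cand] >= 1e-4 * pb[cand].max()]
    couplings = np.empty(len(cand))
    for j, i in enumerate(cand):
        fc = fb[i]
        # band narrower than the harmonic spacing, so the coupling of one
        # candidate is never diluted by a neighbouring line
        lo, hi = 0.94 * fc, min(1.06 * fc, 0.49 * fps)
        sos_c = signal.butter(2, [lo, hi], btype="band", fs=fps, output="sos")
        narrow = signal.sosfiltfilt(sos_c, card)
        couplings[j] = _harmonic_coupling(narrow, resp_phase,
                                          int(round(fc / f_resp)))
    free = couplings < 0.5
    if free.any():
        i_best = cand[free][int(np.argmax(pb[cand[free]]))]
    else:
        i_best = cand[int(np.argmin(couplings))]
    return _parabolic_refine(fb, log_pb, int(i_best))


def cardiac_caval_index(card_component: np.ndarray,
                        resp_component: np.ndarray,
                        fps: float,
                        f_card_est: Optional[float] = None,
                        quality: Optional[np.ndarray] = None) -> float:
    """CCI: beat-wise (max − min)/max, median over cardiac cycles.

    Cycles are segmented at minima of the cardiac component (minimum
    separation 0.4 cardiac periods); within each cycle the index is taken
    on the locally reconstructed signal resp + card, so the baseline the
    beat rides on is respected.
    """
    card = np.asarray(card_component, dtype=float)
    resp = np.asarray(resp_component, dtype=float)
    rng = card.max() - card.min()
    if rng <= 1e-12 * max(abs(resp).max(), 1.0):
        return 0.0
    if f_card_est is None or not np.isfinite(f_card_est) or f_card_est <= 0:
        f_card_est = _f_card_robust(card, resp, fps)
    if not np.isfinite(f_card_est):
        raise InputError("no cardiac spectral peak found")
    # beat boundaries from the instantaneous phase of the cardiac
    # fundamental: the cardiac component also carries respiratory harmonics
    # leaking above f_cut, whose transients would masquerade as beat minima
    # during steep inspirations
    sos = signal.butter(2, [0.85 * f_card_est, min(1.15 * f_card_est,
                                                   0.45 * fps)],
                        btype="band", fs=fps, output="sos")
    fundamental = signal.sosfiltfilt(sos, card)
    # notch away respiratory harmonics that fall inside the band but are
    # distinct from the cardiac line, so the phase cannot lock onto them
    f_resp_fine = _f_resp_refined(resp, fps)
    if np.isfinite(f_resp_fine) and f_resp_fine > 0:
        for k in range(2, int(1.3 * f_card_est / f_resp_fine) + 1):
            fh = k * f_resp_fine
            if (0.8 * f_card_est < fh < min(1.2 * f_card_est, 0.45 * fps)
                    and abs(fh - f_card_est) > 0.04):
                b, a = signal.iirnotch(fh, Q=30.0, fs=fps)
                fundamental = signal.filtfilt(b, a, fundamental)
    phase = np.unwrap(np.angle(signal.hilbert(fundamental)))
    # regularize the beat grid: a linear fit to the unwrapped phase rides
    # out local phase wobble caused by respiratory harmonics that happen to
    # fall inside the cardiac band, keeping every window one beat long
    t_idx = np.arange(len(phase))
    slope, intercept = np.polyfit(t_idx, phase, 1)
    fitted = slope * t_idx + intercept
    # the analytic phase of sin(wt) is wt - pi/2, so sine minima
    # (wt = 3pi/2) sit at analytic phase pi (mod 2pi)
    ticks = np.arange(np.ceil((fitted[0] - np.pi) / (2 * np.pi)),
                      (fitted[-1] - np.pi) / (2 * np.pi))
    crossings = np.interp(2 * np.pi * ticks + np.pi, fitted, t_idx)
    minima = np.unique(np.clip(np.round(crossings).astype(int),
                               0, len(card) - 1))
    if len(minima) < 4:  # need >= 3 complete cycles
        raise InputError("fewer than 3 cardiac cycles detected")
    vals = _windowed_index(resp + card, minima, quality)
    if not vals:
        raise InputError("no usable cardiac cycle")
    return float(np.median(vals))


# ---------------------------------------------------------------------------
# compliance
# ---------------------------------------------------------------------------

def compliance(dV: float, dP: float) -> float:
    """Vessel compliance C = ΔV/ΔP_tm, the slope of the V–P curve."""
    if dP == 0:
        raise InputError("dP must be nonzero")
    return dV / dP


def total_compliance(C_v: float, C_ev: float) -> float:
    """Series combination of vascular and extravascular compliance.

    ``C_tot = 1/(1/C_v + 1/C_ev)`` — always smaller than either term, so a
    stiff surrounding tissue masks the true vascular compliance.
    """
    if C_v <= 0 or C_ev <= 0:
        raise InputError("compliances must be positive")
    return 1.0 / (1.0 / C_v + 1.0 / C_ev)


# ---------------------------------------------------------------------------
# one-call analysis
# ---------------------------------------------------------------------------

def analyze(series: SizeSeries, f_cut: float = 0.6,
            p_min: float = 0.25) -> PulsatilityReport:
    """Full index computation: decompose, segment breaths, CI/RCI/CCI."""
    resp, card, f_resp, f_card = decompose(series, f_cut)
    f_card = _f_card_robust(card, resp, series.fps)
    breaths = segment_breaths(resp, series.fps, f_resp, p_min,
                              raw=series.values, f_card_est=f_card)
    ci = caval_index(series, breaths)
    rci = respiratory_caval_index(resp, breaths, series.quality)
    try:
        cci = cardiac_caval_index(card, resp, series.fps, f_card, series.quality)
    except InputError:
        cci = float("nan")
    mean_size = float(series.values[series.quality].mean())
    return PulsatilityReport(
        mean_size=mean_size, kind=series.kind, ci=ci, rci=rci, cci=cci,
        resp_component=resp, card_component=card, breath_boundaries=breaths,
        f_resp_est=f_resp, f_card_est=f_card,
    )
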