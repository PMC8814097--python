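# Methods

This note documents the models, estimators and numerical choices behind
`cavatrack`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not
show about real ultrasound data.

## Vessel physiology in the phantom

A collapsible vein is modelled by a logistic volume–pressure curve

    V(P_tm) = V_max / (1 + exp(−(P_tm − P_half)/k)),    P_tm = P_in − P_out

with defaults `P_half = 2 mmHg`, `k = 3 mmHg`, `V_max = 100` (arbitrary
units).  The family is a modelling choice: the qualitative physiology only
requires a strictly increasing, sigmoidal relation whose slope (the
compliance `C = dV/dP_tm = V(1 − V/V_max)/k`) falls as the vessel
distends.  Consequences used throughout: at low mean `P_tm` the vessel is
small and very pulsatile; at high mean `P_tm` it is large and stiff.

Transmural pressure is driven by

    P_tm(t) = P_in_mean + A_card·sin(2π f_card t) − s·A_resp·w(2π f_resp t)

where `w` is a raised-cosine inspiration burst occupying `insp_fraction`
of each breath and `s = +1` for spontaneous breathing (inspiration lowers
`P_tm`, the vein narrows) or `s = −1` for positive-pressure ventilation.
Defaults: `f_resp = 0.25 Hz`, `f_card = 1.2 Hz`, `A_card = 0.8 mmHg`,
`A_resp = 4.5 mmHg`, `insp_fraction = 1/3`.  The inspiration fraction
follows the textbook quiet-breathing I:E ratio of about 1:2.  This value
also matters statistically: the per-beat index distribution is bimodal
(expiratory-plateau beats versus beats overlapping the inspiratory
descent), and with inspiration near 40% of the cycle the beat *median*
sits exactly on the boundary between the two populations, where any
estimator's sample median is unstable at the tens-of-percent level; at
I:E = 1:2 the median lies safely inside the plateau population.

Long-axis geometry: the lumen diameter at normalized axial position
x̂ ∈ [−1, 1] is `D(x̂,t) = D0 (1 + taper·x̂) √(V(P_tm)/V(P_in_mean))` —
diameter scales with the square root of volume because volume per unit
length of a cylinder goes with the cross-sectional area.  Short-axis
geometry: an ellipse with area `A ∝ V(P_tm)` whose flattening
`1 − b/a = clip(κ·(P_round − P_tm), 0, 0.85)` grows as transmural
pressure falls (`κ` is a free coupling constant; no quantitative
volemia–eccentricity relation is established, so it is documented as a
tunable and the presets only assert the *ordering* hypovolemic >
hypervolemic).

Rendering: bright wall bands (thickness 6 px) around a dark lumen over a
mid-gray background, anti-aliased with a ~0.7 px smooth step so the true
edge sits exactly at the maximum intensity gradient; multiplicative
Rayleigh speckle normalized to unit mean; Gaussian point-spread blur
(σ = 1 px); additive Gaussian sensor noise (σ = 2 gray levels) per frame.
The speckle field is **static in tissue coordinates** and moves rigidly
with the vessel: per-frame independent speckle would carry no motion
information at all, whereas real speckle is quasi-stable frame to frame —
that stability is exactly what makes template tracking possible.  The
phantom does not model tissue deformation of the speckle near the moving
walls, angle-dependent wall echo, attenuation, or out-of-plane motion;
accuracy figures obtained on it are therefore upper bounds on real-data
performance, and the suite should be read as verifying the *algorithms*,
not as a clinical validation.

Phantom reference points are placed in the echogenic tissue above the
anterior wall, clear of the wall's whole excursion range by a template
half-width.  This mirrors what a trained operator does (pick stable
landmarks); a template centred on the moving wall itself decorrelates as
the vessel pulses and the match slides along the wall ridge.

## Long-axis tracker

1. **Reference points** — frame-0 templates (21×21 px), never updated (no
   drift accumulation), matched by normalized cross-correlation within
   ±12 px of the previous position, parabolic sub-pixel refinement.  A
   tiny centring penalty (10⁻⁶ per px of displacement) breaks the ties
   that arise on featureless ridges.  Correlation below 0.6 carries the
   previous position forward and flags the frame.
2. **Motion compensation** — the two point pairs define a rigid
   rotation + translation into frame-0 coordinates (scale fixed at 1);
   frames are resampled with cubic interpolation.  Linear interpolation
   was measurably worse: its smoothing biases the edge localization under
   rotation.
3. **Edges** — per column, the intensity profile is Gaussian-smoothed
   (σ = 2 px) along depth; the edge is the sub-pixel (parabolic) location
   of the strongest sign-constrained gradient within ±12 px of the
   previous edge — negative (bright→dark) for the upper lumen edge,
   positive for the lower.  Equal peaks break toward the previous edge.
   Columns with peak gradient < 3 gray/px are flagged; interior runs of
   ≤ 5 flagged columns are filled linearly; a frame with > 50% failed
   columns raises a tracking-lost error carrying the frame index.
   Frame 0 is initialized by an unconstrained extremum search over a
   strip from one diameter above to 2.5 diameters below the seed rows.
4. **Midline and diameters** — a degree-2 least-squares polynomial
   through the edge midpoints; at 21 equally spaced stations the diameter
   is the distance between the intersections of the midline normal with
   the two edge polylines (fixed-point iteration on the near-vertical
   normal; stations whose normal leaves the segment are flagged).
   `Dm` is the station mean per frame, then the mean over good frames.

Measured on the default speckled dynamic phantom (128×400 px, 30 fps,
60 s), the station-mean diameter tracks ground truth with an MAE well
under 1% of the 40 px baseline.  A small inward bias (~0.3 px) remains
under strong speckle — multiplicative noise grows with intensity, which
shifts the apparent steepest point slightly toward the dark side; it is
included in all reported error figures.

## Short-axis tracker

36 rays from the current centre sample the image at 0.5 px steps; the
edge per ray is the strongest dark→bright gradient within ±10 px of the
previous radius (full-ray search on frame 0), sub-pixel refined.  Failed
rays (< 3 gray/px) are interpolated circularly from neighbours; the
radius-versus-angle profile keeps its first 8 Fourier harmonics, which
enforces a closed smooth contour.  Area and centroid use the shoelace
formulas; the centroid seeds the next frame, so a seed several pixels off
centre self-corrects within a frame or two.  Circularity is `4πA/P²`;
flattening comes from the polygon's central second-moment ellipse
(`1 − √(λ_min/λ_max)`).  With anisotropic `pixel_spacing` the geometry is
computed in millimetres.

## Index estimation

* **Band split.**  The respiratory component is *defined* as the output
  of a zero-phase (forward–backward) 8th-order Butterworth low-pass at
  `f_cut = 0.6 Hz`; the cardiac component is the residual, so the two add
  back to the series exactly.  The identical operator generates the
  analytic ground-truth components in the phantom: a raised-cosine breath
  has harmonics arbitrarily close to any cutoff, and only a shared,
  fully specified operator makes "the respiratory component" a
  well-defined quantity on both routes.  Padding spans six cutoff
  periods, so edge transients are negligible.
* **Breath segmentation.**  Troughs are detected on a fundamental-only
  smoothed copy (low-pass at 1.3× the respiratory rate) — harmonics of a
  non-sinusoidal breath otherwise ring into double minima — then each
  boundary walks back to the inspiration onset (5%-of-depth crossing).
  Onset localization uses a gentler smoother (4th-order, cutoff just
  below the cardiac band) on the raw series, because the sharp
  decomposition filter is non-causal and smears onsets by a fraction of
  a second.  Boundaries land within ~2 frames of the true onsets at
  30 fps.
* **Respiratory rate.**  Periodogram peak below 0.8 Hz with log-parabolic
  sub-bin refinement, plus a sub-harmonic (pitch-halving) check: a brief
  inspiration can put more power into the second harmonic than into the
  fundamental.  A sub-harmonic is only accepted if it is itself a local
  spectral peak, which rejects leakage shoulders on short recordings.
* **Heart rate.**  Candidate peaks in the 0.8–3 Hz band (48–180 bpm) are
  screened by their phase coupling to the respiratory fundamental:
  respiratory harmonics satisfy `phase = k·(breath phase) + const`
  (coupling ≈ 1), the cardiac line does not (≈ 0).  Among weakly coupled
  candidates the most powerful wins; if all are coupled the heart rate
  genuinely sits on a harmonic and the least-coupled one is used.
* **Beat segmentation.**  The cardiac component is band-passed to
  ±15% around the heart rate, respiratory harmonics inside the band are
  notched out, and beat boundaries come from a linear fit to the
  unwrapped Hilbert phase (minima of a sine sit at analytic phase π).
  The fitted uniform grid rides out local phase wobble from interference;
  per-beat windows on the reconstructed signal `resp + card` then give
  CCI as the median over beats.  The uniform grid assumes a steady heart
  rate over the clip — marked RR variability would need adaptive
  segmentation.
* **Quality.**  Frames flagged by the trackers are excluded from all
  extrema searches, never interpolated into an index.

### Recovery and known identifiability limits

On 20 seeded volume states (P_in_mean 0.5–12 mmHg, A_resp 3–7 mmHg,
A_card 0.5–1.2 mmHg at the default rates), spanning CI ≈ 0.07–0.6, the
estimators recover CI within ±0.005 absolute and RCI/CCI within a few
percent relative of brute-force ground truth.  Two limits are worth
stating plainly.  First, when the heart rate coincides with a respiratory
harmonic (e.g. 0.3 Hz breathing and 72 bpm), the two lines overlap in
frequency and *no* estimator operating on the size series alone can
separate them; randomized-rate stress tests show CCI errors up to tens of
percent in such collisions, while CI and RCI stay accurate.  Second, the
per-beat median is intrinsically sensitive when the inspiratory descent
within one beat dwarfs the cardiac swing (deep, fast breathing with a
weak cardiac component); the aggregate is then honest but has high
variance.  Neither limit affects the mean diameter, CI, or the preset
contrasts.

## Compliance relations

`compliance(dV, dP) = dV/dP` is the finite-difference slope of the
volume–pressure curve; `total_compliance(C_v, C_ev) = 1/(1/C_v + 1/C_ev)`
combines vascular and extravascular compliance in series and is strictly
smaller than either — stiff surrounding tissue masks true vascular
compliance.  The extravascular term is treated as a scalar correction and
is not simulated as a tissue model in the phantom.

## Problem sizes

The validation suite uses 60 s clips at 30 fps (1800 frames, 128×400 px)
for the long-axis headline figure, 30 s for the short axis, 15 s clips for
the preset contrasts, and series-level sweeps (no rendering) for index
recovery; these sizes give stable statistics (≥ 7 breaths, ≥ 70 beats per
estimate) while keeping the full suite around two minutes.
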