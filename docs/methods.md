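# Methods

This note records the models, conventions, and numerical choices behind
`swimkin`, and what the synthetic-data validation does and does not show.

## 1. The synthetic swimmer

### Kinematic form

The body is parameterized by arc length fraction s ∈ [0, 1] (s·BL pixels of
body, nose at s = 0). In the swimming frame the lateral displacement is an
amplitude-enveloped traveling wave,

    y(s, t) = A · BL · E(s) · sin(2π(f·t − s/λ)),

with tail amplitude A (BL), body wave frequency f (Hz) and wavelength λ
(BL). The axial coordinate integrates dx/ds = sqrt(BL² − (∂y/∂s)²), so the
midline arc length is one body length in every frame: the wave bends the
body, it does not stretch it. The whole animal translates forward at U BL/s.
The construction fails (by design, with an explicit error) when the lateral
slope would reach 1 — at λ = 0.6 BL that caps A below ≈ 0.09 BL.

An arc-length-true body is not a pedantic choice. A "displace the midline
sideways" shortcut inflates the apparent body length by ≈ 3.5% at the study
amplitude, which silently deflates every BL-normalized variable (swimming
speed most visibly) by the same amount — more than the speed measurement's
own error.

### Amplitude envelope

The envelope has relative growth rate g(s) = α·sigmoid((b − s)/w), i.e.
E(s) = exp(−∫ₛ¹ g) (closed form through softplus; E(1) = 1 exactly).
Defaults: α = 0.9, b = 0.60, w = 0.06, giving a head amplitude ≈ 55% of the
tail's — pronounced anterior undulation, at the anguilliform end of the
spectrum.

The shape is load-bearing. An envelope gradient distorts the
body-curvature wave two ways:

* a *varying* relative gradient disperses the wave — curvature extrema
  drift away from the displacement wave's spacing λ, because the phase
  shift the envelope imprints on κ is atan(2E′k/(Ek² − E″)) (k = 2π/λ) and
  varies with s;
* at realistic amplitudes, a nonzero gradient under the tail interacts
  with the arc-length constraint (the sqrt(1 − y′²) factor) and
  *accelerates* curvature crests well beyond f·λ exactly in the 75–95% BL
  window where wave speed is measured. Measured against a dense analytic
  oracle, a power-law envelope s² pushes the transit speed to 163–179 %BL/s
  when f·λ = 150.

Constant relative growth (exponential, anterior body) makes the phase shift
s-independent, so extrema spacing and crest speed are exact there; the
smooth shut-off (g → 0 past b = 0.6) makes the tracking window an
undistorted traveling wave. With these defaults the dense-oracle crest
speed matches f·λ to well under 1% and the generated motion satisfies the
package's own recovery tolerances.

### Landmarks, fins, study design

Tracks contain nose, tail and both pectoral fin tips. Fin tips ride at 25%
BL on lateral offsets from the body edge; when beating they oscillate
between adducted and abducted extremes at f_fin, otherwise they rest
adducted. Gaussian jitter (default sd 1 px, the scale of pose-estimation
noise at this resolution) is added to every coordinate; everything is
deterministic given `rng_seed`.

`generate_study` emits the full factorial design (5 fish × 2 viscosities ×
2 light levels × 2 lateral-line states × 2 trials) with per-trial
parameters = base + condition shifts + per-fish normal intercepts + per-
trial normal noise, plus a Bernoulli fin-state draw whose "off" probability
shifts with condition. Defaults (fish sd 0.15 Hz on f and 0.05 BL/s on U;
trial sd 0.10 Hz and 0.04 BL/s; viscosity shifting f by +0.5 Hz, U by
−0.12 BL/s and fin-off probability by +0.45) were chosen once as effect
sizes a viscosity manipulation of this magnitude could plausibly produce,
large enough to be detected by an n = 5 design at its nominal power.

Rendering draws a disk of radius w(s) at each midline point (default
profile 0.05·BL·sqrt(1 − s²): blunt head, pointed tail); the disk union is
8-connected because point spacing (BL/100) is below the half-width
everywhere that matters.

### Image conventions

Raster convention: origin top-left, y down. With the fish heading along +x,
"fish-left" is the −y side; signed curvature is positive for fish-left
bending. Amplitude and side assignments only require consistency, and every
side-dependent quantity is defined through the same convention.

## 2. Measurement pipeline

### Filtering

Every scalar series derived from digitized points is low-passed with a
zero-phase 4th-order Butterworth (forward–backward, reflect padding of one
cutoff period) at 5× the series' own dominant frequency — body points at 5×
the body-wave frequency, fin points at 5× the fin-beat frequency, falling
back to the body frequency when no fin tone is resolvable. Zero phase is
non-negotiable: every variable is timed off peaks or adductions. The
dominant frequency comes from a Hann-windowed FFT with quadratic
interpolation of log-magnitude around the peak bin (residual error on a
pure tone ≪ 1%).

### Tail excursion and peaks

The lateral excursion of the tail is measured about a heading line fitted
(total least squares) to the *cycle-averaged* nose–tail midpoint
trajectory; averaging over one locomotor cycle first is essential because a
line fitted to the raw trajectory tilts toward the oscillation (a ramp and
a sinusoid correlate over a finite window) and the tail's ~0.5 BL lever arm
turns a small tilt into a large fake excursion. The excursion is then
detrended by its own one-cycle moving average. Peaks need prominence ≥ 10%
of the series range and spacing ≥ 0.3 periods; of two consecutive same-side
peaks the larger is kept, so sides alternate. Fewer than 3 same-side peaks,
fewer than 3 completed cycles, or a filtered excursion under 1% BL rejects
the trial — never a silent zero.

### The seven variables

* **U**: net displacement of the nose–tail midpoint between the first and
  last whole cycles (cycle averages over half-open windows so the
  oscillation cancels; peaks within ~a period of the record edges are not
  used as window anchors because detrending displaces them slightly).
* **A**: for each left–right–left peak triple, the perpendicular distance
  from the right-peak tail position to the chord through the two left-peak
  positions, halved and normalized by BL; mean over triples. The chord
  construction removes forward drift by geometry rather than detrending.
* **f**: mean of 1/Δt over consecutive same-side peak pairs, both sides.
* **f_fin**: adduction events are local minima of the fin tip's distance
  *to the midline curve itself* (nearest point over the anterior body).
  Distance to a chord or local tangent axis instead picks up the bending
  wave's sagitta (~9 px here), which would turn every resting fin into a
  false 2.5 Hz "beat". Absent (never zero) with fewer than two adductions,
  and gated by the amplitude of the detected spectral tone (≥ 1.5 px):
  broadband jitter always has a largest FFT bin somewhere, but its
  amplitude is two orders below a real fin beat.
* **Fin state**: On iff f_fin was recorded.
* **V**: local extrema of κ(s) (each bending sign separately; prominence ≥
  5% of the field maximum, or absolute height ≥ 50% — a crest running off
  the tail end has no right-hand saddle and loses its prominence while
  still being the strongest feature on the body) are tracked across frames
  by nearest-position continuity (max jump 0.1 s-units, 2-frame gap
  tolerance), positions refined by quadratic interpolation. For every track
  that crosses both stations tailward, V = 20/(t₉₅ − t₇₅) × 100 %BL/s,
  averaged over all complete crossings. A standing flexion produces no
  transit → missing value with a warning.
* **λ**: per frame, twice the chord distance between adjacent
  opposite-sign curvature extrema, normalized by BL, averaged over frames
  and pairs; the same-sign (full-wave) chord is emitted as a diagnostic
  column. On a body bent at A = 0.08 BL the full-wave chord is compressed
  ~12% (the axial span of one arc wavelength shrinks by the elliptic mean
  of sqrt(1 − y′²) while the endpoints' lateral offsets cancel), whereas in
  the half-wave chord the endpoints sit on opposite sides and their lateral
  separation compensates most of the axial compression. Both readings of
  the ambiguous phrase "distance between consecutive minimum or maximum
  curvature" are reported; the less biased one is primary. The residual
  ~5–9% low bias at study amplitude is geometric, not algorithmic: any
  chord-based wavelength on a bent body underestimates λ.

### Midlines and curvature

Midline extraction: medial-axis skeletonization of the single large
8-connected component; Dijkstra through the 8-connected skeleton pixel
graph between the endpoints nearest the nose and tail landmarks (side
branches from fins fall off the shortest path); extension to the landmark
points themselves (the skeleton of a blunt head stops ~half-width short of
the nose, a 5% BL error if uncorrected); resampling to N = 100 arc-length
points (all %BL stations refer to this grid); Savitzky–Golay smoothing
(window 11, cubic) of x(s), y(s); then two iterations of sub-pixel centroid
refinement — each point slides to the intensity centroid of the silhouette
chord along its local normal. Landmarks may sit up to 10 px off the
silhouette (digitization jitter must not abort extraction).

Signed curvature is the central difference of the unwrapped tangent angle
with respect to arc length. Because κ is a second derivative, per-frame
pixel noise is crushed in two further steps before the wave variables are
measured (`conditioned_curvature_field`): midline coordinates are low-passed
in *time* at 5× the body frequency (the same rule the tracks get), and the
κ(s) rows are low-passed in *space* at 4 cycles/BL — comfortably above the
wave's spatial frequency (1/λ ≈ 1.5–2.5 cycles/BL) and below pixel ripple
(≳ 10 cycles/BL). Without the spatial step, broad curvature extrema on
extracted midlines split into doublets and both wave variables fail.
Analytic midlines pass through the conditioning essentially unchanged.

Body length = median per-frame midline arc length; it is the denominator
for every BL unit.

## 3. Statistics

### Mixed model

Each variable is fitted by REML to

    y ~ swim_speed_U + viscosity + light + lateral_line
        (+ all two-way factor interactions)  +  (1 | fish)

with, optionally, a distinct residual variance per level of a grouping
factor (default grouping: viscosity) — the varIdent-style weighting used
when a treatment changes the noise level, not just the mean. With a single
random intercept the per-fish covariance block is σ_b²·11′ + diag(σ²_g),
which inverts in closed form (Sherman–Morrison), so the REML criterion over
(log σ_b², log σ²_g) is optimized directly with L-BFGS-B in milliseconds;
β̂ is the GLS solution at the optimum and Cov(β̂) = (Σ Xᵢ′Vᵢ⁻¹Xᵢ)⁻¹. The
homoscedastic case agrees with `statsmodels` MixedLM to ~1e-6 (tested). A
boundary fit (between-fish variance → 0) is retained with a warning. Rows
missing a response (unrecorded fin frequency) are dropped from that
variable's fit only. The covariate is excluded when the response is
swimming speed itself.

### Contrasts

Estimated marginal means are model predictions on the full 2×2×2 reference
grid at the covariate mean, averaged with equal weights over non-focal
factors; pairwise differences use Cov(β̂) with residual df (n − rank(X); the
df method is recorded in the output). Bonferroni multiplies by the number
of comparisons in the variable's family (default: the contrasts actually
produced); significance is adjusted p < 0.05. Calibration is verified by
simulation: 95% CI coverage of the four treatment fixed effects across 200
replicate studies, and familywise error ≤ 6% across 500 null studies.
Coverage is assessed on the treatment effects (speed, viscosity, light,
lateral line) — the quantities the contrasts exist for; the intercept's
interval would need between-fish df (n = 5) rather than residual df.

### Fin-state exact test

The 2×K fin-state table is tested by conditioning on both margins and
enumerating every table with those margins, summing the (multivariate)
hypergeometric probabilities of tables no more probable than the observed
one. Weights are exact integers (products of binomials), so ties cost no
floating-point tolerance; the enumeration is exponential in K but instant
for the 2×2 condition comparisons it serves (and capped at n = 10⁴). A zero
margin returns p = 1 with a warning.

### Outlier screen

Trials are flagged when |studentized conditional residual| > 3 *and*
removing the trial improves the Shapiro–Wilk statistic of the remaining
residuals. The screen only flags; removal is a user decision, mirroring how
an outlying trial should be handled and reported rather than silently
dropped.

## 4. Validation scope and problem sizes

The default validation sizes are: one 2 s reference trial (1000 frames) per
recovery path, an 80-trial study on the tracks path, 200 replicate studies
for coverage, 500 for FWER, and exhaustive 2×2 tables to n = 20 for the
exact test — sizes at which the full suite runs in a few minutes while the
Monte-Carlo intervals stay decisive.

What passing recovery shows: the event logic, the wave tracking, the
normalizations and the statistical calibration are correct on motion whose
ground truth is known, including under 1 px landmark noise and pixel-level
silhouette quantization. What it cannot show: robustness to real-video
pathologies the generator does not emulate — segmentation holes and
shadows, fish touching tank walls, body rolls that shorten the projected
midline, genuinely curved swimming paths, pose-estimation outliers beyond
Gaussian jitter, or fin silhouettes merging with the body. The
`--min-confidence` masking and the 10 px landmark anchoring tolerance are
the only concessions to such data; real deployments should inspect rejected
trials and the outlier screen rather than trust end-to-end automation.

Known limitations: the wavelength estimate inherits a geometric low bias at
high amplitude (quantified above); wave speed needs the curvature wave to
actually transit 75→95% BL (short or standing waves go missing by design);
the exact test's enumeration is impractical for many-column tables with
large counts; and the mixed model supports one random intercept — the
study's single grouping level — not crossed or nested random effects.
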