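# Methods

This note records the models behind each stage of the pipeline, the
parameters that matter, and the design choices made where the
underlying assay conventions leave room.

## Plate gradient model

The overnight gradient is modelled as 2-D diffusion of NaCl through the
thin (1.76 mm) agar layer, with each salt-containing block footprint
held at its concentration (a Dirichlet disk: the block is a large
reservoir relative to the layer beneath it) and a no-flux condition at
the plate rim.  A salt-free block on a salt-free plate exchanges
nothing and is treated as inert; its position still defines scoring
area A.  The solver is explicit FTCS on a masked square grid; off-mask
neighbours mirror the centre value, which makes the update a symmetric
exchange between on-plate cells, so total salt is conserved to machine
precision once sources are removed (verified in the tests to < 0.1%
over a simulated 15-min assay, and in practice ~1e-16).

Parameters:

| parameter | default | rationale |
|---|---|---|
| diffusion coefficient *D* | 1.5e-3 mm²/s | NaCl in dilute (2%) agar is close to its aqueous value |
| equilibration time | 68 400 s (19 h) | middle of the 18–20 h block-on-plate window |
| grid spacing | 0.5 mm | at 1 mm, halving the grid moved sampled concentrations by up to ~6% (O(h²) truncation at the steep source rim); at 0.5 mm the change on halving is < 2% everywhere probed |
| time step | 0.9 h²/4D | explicit-scheme stability; temporal error measured negligible (< 0.1%) |
| block centres | (±26, 0) mm | the A–B separation is an assay-rig choice not fixed by the plate dimensions; configurable, and documented as an assumption |

The field is frozen for the 15-min tracking assay: the assay is ~80×
shorter than the equilibration, so continued spreading is second order.
Whether the gradient sharpens appreciably over a 45-min endpoint assay
is likewise neglected; the endpoint indices use only the region
geometry, not the field.

Sampling: concentration is bilinear off the grid; gradients are
central differences interpolated the same way; off-plate cells are
back-filled with their nearest on-plate value before interpolation so
near-rim queries never mix in zeros.  d*C*/d*t* along a track is the
trailing mean of the 1-Hz concentration derivative over a 10-s window
(undefined until the window fills); d*C*/d*n* projects the gradient on
the left normal of the heading, so positive values mean salt increases
to the animal's left, and a positive weathervane slope means steering
toward higher salt.

## Navigation metrics

Endpoint: chemotaxis index (N_B − N_A)/(N_total − N_O) with strict
interior membership (distance < 20 mm of a block centre; start ellipse
(u/20)² + (v/10)² < 1 with the major axis along A–B).  The immobility
index defaults to the fraction N_O/N_total, with a strict mode
returning the literal difference N_O − N_total for compatibility with
the difference form of the formula; the fraction is the default
because high immobility should read as a high value in [0, 1].

Segmentation: a sample is a sharp turn when the wrapped bearing change
exceeds 90° per 1-s step; sharp turns closer than 8 s merge into one
pirouette bout; bouts shorter than 1 s are dropped.  These thresholds
are tracker conventions, not measurements, and are configurable.
Position smoothing (5-s centred moving average) is recommended before
segmenting real video tracks to suppress head-swing jitter; simulated
worms have no head swings, so the pipeline analyses them unsmoothed.

Pirouette index: per-sample pirouette probability contrasted between
negative and positive d*C*/d*t*, over 40–540 s and |d*C*/d*t*| ≤
0.3 mM/s (the units of the published ±0.3 and ±2 analysis ranges are
not printed anywhere we know of; mM/s and mM/mm are the natural
reading and are used throughout).  One estimator subtlety is handled
explicitly: the trailing d*C*/d*t* is only meaningful over forward
progression.  During a bout the worm's own jumbled motion produces a
concentration change whose mean is proportional to the local field
Laplacian, and in the curved radial field this biases a naive
per-sample pairing by about −0.003 index units even for a salt-blind
animal — the same order as real genotype differences in weak
phenotypes.  The pipeline therefore attributes to every bout sample
the d*C*/d*t* of the last pre-bout sample (the stimulus history that
could have triggered the bout) and excludes run samples whose trailing
window overlaps a bout.  Under the null, bout onsets are then a
uniform draw from run samples, so both states share one d*C*/d*t*
distribution and the index is centred on zero by construction
(verified: null mean −0.0016 ± 0.0014 over 40 seeds).  The literal
per-sample pairing remains available (`dcdt_attribution="sample"`).

Weathervane index: OLS slope (with intercept and standard error) of
curving rate on d*C*/d*n* over run samples with |d*C*/d*n*| ≤ 2 mM/mm
in the 40–540 s window.  The curving rate at sample *i* (the turn
between the steps ending and starting there, divided by the step's arc
length) is paired with the d*C*/d*n* of the *preceding* step — the
gradient the animal sensed while running into the turn.  With this
pairing the simulator's steering rule is exactly the regression's
generative model: in a linear field with heading noise off, curving
equals gain × d*C*/d*n* at every run step to 1e-9.

Tracks contributing less than 30 s to the analysis window are dropped
as collision-interrupted fragments.  Indices are computed per plate
and aggregated as mean ± s.e.m. across plates.

## Trace metrics

R is the background-corrected YFP/CFP ratio (or GCaMP/mCherry); R₀ is
the mean over the pre-stimulus baseline window (50 frames = 25 s at
2 frames/s; 50 frames = 12.5 s at 4 frames/s), so the normalised trace
has baseline mean 1 by construction and normalisation is idempotent.

* Chloride-sensor Δ(R/R₀): mean of the last 10 s of the low-salt epoch
  minus the mean of the 10 s just before the down-step (negative when
  chloride rises).
* Calcium-sensor per-stimulus metrics: the peak is the highest 10-s
  moving average of R/R₀ during the low-salt epoch, computed over
  every *full* 10-s window inside the epoch.  This choice (rather than
  edge-truncated centred windows) keeps every average over exactly
  10 s and makes the final 10-s window a peak candidate, so
  peak ≥ final-window mean and hence decay1 ≥ 0 hold for any trace.
  peak_delta = peak − 10-s pre-step mean; decay1 = peak − last-10-s
  mean of the epoch; decay2 = last-10-s mean of the epoch minus the
  last-10-s mean of the following high-salt epoch (undefined after the
  final stimulus).  The peak time is reported per animal since rise
  speed varies between genotypes.
* ΔF/F₀: mean over frames 125–175 minus frames 51–100, 1-based
  inclusive, anchored to the recording start (with the up-step at 25 s
  and 4 frames/s these bracket the stimulus); window anchoring is
  configurable.
* Reversals: an animal reverses iff a run of strictly more than 35
  consecutive frames (1 s at 33 frames/s) below −100 µm/s *starts*
  within 501 frames (15 s) after the stimulus onset.  The strict
  inequality excludes exactly-1-s runs; the start-in-window convention
  scores stimulus-evoked bouts while ignoring spontaneous reversals
  already in progress.  Traces shorter than the full window are scored
  on the available span and flagged truncated.

Traces with missing frames are rejected rather than interpolated: all
windows are frame-indexed.

## Simulators (synthetic ground truth)

The worm simulator is the two-strategy model made generative.  Per 1-s
step: the trailing-window d*C*/d*t* is computed exactly as the
analysis computes it; a pirouette bout starts with probability
clip(p₀·dt − g_kk·dC/dt·dt, 0, 1) (modulation engages once the window
fills); bout durations are exponential (mean 3 s) and every bout step
reorients the heading by ±U(90°, 180°); run steps drift by
N(0, 8°) plus the steering term g_wv·dC/dn·(speed·dt); the worm
advances 0.12 mm/s with specular reflection at the rim.  Defaults
describe a fed wild-type-like animal: g_wv = 2 (deg/mm)/(mM/mm) and
g_kk = 0.1 per (mM/s), which span pirouette rates of ~0.01–0.05 /s
over the usable d*C*/d*t* range and drive a clearly positive
chemotaxis index; zero gains give the null (salt-blind) worm.  The
linear clamped rate law is a modelling choice — the simplest monotone
coupling that makes both strategy indices identifiable — not an
empirical claim.  Cohorts start uniformly inside the start ellipse
with uniform headings; everything is driven by one seeded generator,
so output is bit-reproducible.

What the simulator deliberately omits: body posture and head swings
(reorientation is a heading jump), collisions and track breaks, omega
vs reversal substructure within bouts, speed modulation (basal
slowing), and any feedback of the worm on the field.  Passing
calibration and recovery tests therefore validates the *analysis
chain* — field sampling, segmentation, index estimators — under known
ground truth; it does not certify performance on real video, where
head-swing jitter (hence the smoothing option) and tracking errors
add structure the generator does not emulate.

The trace simulator relaxes a latent response toward a per-epoch
target (rise τ 2 s, decay τ 20 s, closed form at frame times); the two
channels move oppositely around their baselines (coupling ±0.5), share
a common exponential bleach (which cancels in the ratio), and carry
Gaussian noise.  Ground-truth metrics are the window definitions
applied to the noiseless latent ratio, so at zero noise the full
analysis path must reproduce them to 1e-9 — which is tested, including
with bleaching and non-zero backgrounds.  The velocity simulator is
piecewise-constant with reversal episodes and additive noise; its
ground-truth label applies the reversal rule to the noiseless series.

## Problem sizes

The shipped study uses cohorts of 200 worms × 900 s (calibration) and
50 worms × 540 s (gain recovery), 10 seeds each, on the 0.5-mm default
field; these sizes put the across-seed s.e.m. of every index well
below the effects being checked while keeping any single analysis
script in the seconds-to-minutes range on one core.

## Known limitations

* The diffusion model is 2-D: block contact resistance, vertical
  gradients in the agar and osmotic effects are not modelled; the
  absolute concentration scale mid-plate should be read as indicative.
* The A–B block separation is an explicit assumption (±26 mm).
* Pirouette detection thresholds are conventions; on real data they
  should be tuned against annotated bouts before the indices are
  compared across genotypes.
* The noiseless klinotaxis limit on the radial field is degenerate:
  with no heading noise worms align up-gradient, d*C*/d*n* collapses
  toward zero, and grid-interpolation error dominates the regressor
  (slope ~1.5 for a true gain of 2).  With realistic heading noise the
  regression recovers the gain to within a few percent; exactness is
  asserted only in the linear-field construction where it holds
  analytically.
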