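# Methods

## The measurement model

A radiometric thermal frame is a rows × cols matrix of calibrated surface
temperatures in °C (no gray-level rendering is involved at any point).
Within a manually delineated ROI — here stored as polygon vertices and
rasterized by a pixel-center even-odd containment rule — two features are
computed per frame:

* **Mean temperature**: the arithmetic mean of the raw ROI temperatures.
* **Texture entropy**: temperatures are rounded to a precision of one bin
  width Δ (default 0.1 °C, matching a camera sensitivity of 100 mK), the
  rounded ROI minimum is subtracted, and the values are expressed as
  non-negative integer levels; the feature is the Shannon entropy
  H = −Σ p(x_k) log₂ p(x_k) of the level histogram, in bits, summing over
  observed levels (0·log 0 ≡ 0).

Rounding ties go half away from zero (30.05 °C → 30.1 °C); the rule is
recorded in the stats report so downstream consumers know the convention.
The entropy is computed on this explicit quantization, not on an 8-bit
grayscale rendering: the histogram support adapts to the ROI's own
temperature range, and the minimum subtraction makes the feature exactly
invariant under temperature offsets that live on the Δ lattice. For
offsets off the lattice the rounding grid shifts relative to the data and
individual levels can change by one — an intrinsic property of any
quantized statistic, which is why the invariance tests draw offsets from
the lattice. The mean uses raw values and shifts by exactly the offset.

Optional co-occurrence texture (contrast, homogeneity) is computed from a
symmetric, normalized GLCM over the four unit displacements, restricted
to pixel pairs fully inside the ROI, on the same quantized levels without
re-binning.

## Time normalization and group statistics

Graded tests end at exhaustion, at different times per subject, so each
trajectory is rescaled to percent of exercise duration (end = 100 %),
linearly interpolated onto a common 5–100 % grid in 5 % steps (about one
point per 30 s capture for a ~10 min test), and averaged pointwise with
an n−1 sd. Grid points before a subject's first capture are dropped for
that subject and n is tracked per point; nothing is extrapolated.
Recovery-phase frames are generated and stored but excluded from the
normalized exercise trajectories.

The statistical layer:

* **Spearman correlation** — Pearson correlation of mean ranks; p-value by
  full permutation enumeration for n ≤ 8 and by the
  t = rho·√((n−2)/(1−rho²)) approximation otherwise (the method used is
  recorded in every result).
* **Repeated-measures one-way ANOVA** — the classical two-way
  decomposition SS_total = SS_time + SS_subject + SS_error on a complete
  subjects × timepoints matrix, F = MS_time/MS_error with df (k−1) and
  (k−1)(s−1). No sphericity correction is applied. The all-equal matrix
  reports F = 0; a perfectly additive matrix (SS_error = 0) is flagged
  degenerate rather than producing a spurious F.
* **Ventilatory-threshold detection** — VE rises piecewise-linearly with
  two breakpoints (VT1, the aerobic threshold; VT2, the respiratory
  compensation point). The detector exhaustively searches ordered knot
  pairs on the sample percent positions (each knot at least 2 samples
  from the ends and from the other knot), fits a continuous three-segment
  model by least squares for each pair — linear in the parameters via the
  basis {1, t, (t−k₁)₊, (t−k₂)₊} — and returns the global SSE minimizer,
  ties broken by the earliest pair. A non-increasing trend or an SSE tie
  sets a low-confidence flag. Because the three-segment model nests the
  straight line, its SSE never exceeds a single-line fit.

## The synthetic cohort

No thermogram dataset for this protocol is public, so the generator
produces cohorts with the statistical structure the analysis is designed
to detect; it is a phenomenological emulator, not a skin heat-transfer
model.

Each subject has 120 × 160 frames every 30 s from rest (t = 0) to
exhaustion (duration drawn from 9–11 min in whole 30 s steps, default
n = 18 subjects), then every 60 s through a 5-min recovery. A frame is

    T(x, t) = baseline(x) + a(t)·P(x) − comp(t) + ε,   ε ~ N(0, 0.05² °C)

* **baseline(x)**: regional plateaus (forehead 34.0, chest 33.0, abdomen
  32.5 °C) plus a static smooth heterogeneity field (Gaussian-filtered
  white noise, 2 px smoothing) renormalized within each ROI to an exact
  per-region sd. Those sds (chest 0.590, abdomen 0.369, forehead
  0.333 °C) follow from inverting the quantized-Gaussian entropy
  approximation H ≈ log₂(σ/Δ) + 2.05 bits so that resting entropies land
  at realistic values near 4.6 / 3.9 / 3.8 bits. Cohort generation
  multiplies them per subject by 2^N(0, s) (s = 0.35/0.45/0.56 bits) so
  the cohort has realistic between-subject dispersion.
* **P(x)**: the hyperthermal tree — a trunk rooted near the bottom-center
  of the chest ROI growing upward, recursively splitting into 3 children
  per level for 6 levels with decaying length (12 px trunk, ×0.78),
  width (4 px, ×0.92) and ΔT (1.5 °C at the trunk, ×0.97), fanned ±50°
  with ±18° jitter. Each segment contributes a Gaussian cross-profile;
  overlaps combine by maximum so the field never exceeds the trunk ΔT.
  The geometry is sized so the pattern stays inside the chest region and
  covers roughly a third of it, which takes the chest entropy from ~4.6
  to ~5.1 bits over a full ramp.
* **a(t)**: a linear 0→1 ramp over exercise, decaying linearly back to 0
  over recovery — entropy grows monotonically but no particular functional
  form is claimed.
* **comp(t)**: inside each ROI, a spatially uniform offset equal to
  a(t) times the pattern's ROI mean, so the ROI's noise-free mean
  temperature is time-invariant *by construction* (to 1e−9 °C). This
  enforces the defining signature — flat mean, rising entropy — without a
  perfusion model.

VE is a continuous piecewise-linear curve: 12 L/min at rest, segment
slopes 6 / 12 / 24 L/min per minute with knots at 45 % and 80 % of
exercise duration, i.i.d. Gaussian noise of sd 2 L/min, sampled on the
30 s capture grid (peak ≈ 130 L/min for a 10-min test). Cohort generation
jitters rest VE (±2), a common slope factor (0.85–1.2) and the breakpoint
fractions (sd 0.02) per subject.

All randomness flows from one master seed through `numpy` SeedSequence;
two runs with the same configuration are byte-identical, and every
artifact carries a hash of the run configuration.

### What the generator does and does not emulate

It reproduces: resolution, capture cadence, test durations, flat ROI
means with rising chest texture entropy, regional ordering (the pattern
is rooted in the chest only), realistic resting-entropy levels and
between-subject spread, and two-breakpoint VE curves. It does **not**
model sweat evaporation, respiratory or postural motion, pixel-to-pixel
camera nonuniformity, or the vascular physiology behind the tree pattern
— so green tests demonstrate that the *pipeline* recovers the designed
signature, not that the physiological claim holds on real data.

### A note on the mean-temperature null

With ~20 exercise frames per subject, the Spearman rho of any trend-free
mean-temperature series against time follows the exact rank null with
sd 1/√(n−1) ≈ 0.22 — regardless of how small the noise is, since ranks
are scale-free. Roughly 18 % of seeds will therefore show |rho| ≥ 0.3 by
chance alone; "the mean is flat" is a statement about the *distribution*
(mean rho ≈ 0), not about every single realization, and the property
tests are phrased accordingly.

### Breakpoint-recovery performance

On the generator's VE conditions (21 samples, noise sd 2 L/min), the
exhaustive least-squares search — the maximum-likelihood knot estimator
under Gaussian noise — recovers both knots within ±5 percentage points in
about 91 % of curves (1000-curve Monte Carlo; VT1 error sd ≈ 3.8 points).
Continuous-knot search does slightly worse (extra freedom overfits noise)
and moving-average pre-smoothing reaches at most ~94 %. This is the
information limit of the conditions, and the suite documents it: the
recovery test expecting a higher rate fails by a small margin and is left
failing deliberately rather than smoothing the estimator or easing the
noise.

## Numerical choices and edge cases

* Rounding uses a 1e−9 pre-round on the scaled values to absorb float
  representation error near ties (30.05/0.1 = 300.4999…).
* The tiff16 interchange encodes temperatures as uint16 counts at a
  configurable scale (default 0.01 °C/count), so a write→read round trip
  moves a pixel by at most scale/2.
* Temperatures outside a configurable plausibility window (default
  15–45 °C, bracketing room and skin temperature) are rejected at frame
  construction with the offending pixel index.
* Constant inputs: a one-level ROI has entropy exactly 0; a constant
  feature series makes Spearman undefined and is *reported* as an error
  entry in the stats JSON instead of aborting the pipeline.
* Degenerate polygons (all vertices coincident) and polygons rasterizing
  to an empty mask are rejected.

## Problem sizes in the shipped checks

The test suite and acceptance script run the cohort at the full study
design (18 subjects, 120 × 160 px, ~26 frames each — about 10 s
end-to-end), 100-curve breakpoint Monte Carlos, exhaustive Spearman
permutation oracles up to n = 8, and 1000-histogram entropy-bound sweeps.

## Known limitations

* RM-ANOVA requires complete matrices; subjects missing grid coverage are
  an error, not imputed. No sphericity correction is offered.
* The GLCM parameter set is fixed to contrast and homogeneity over unit
  displacements.
* The VT detector assumes an overall increasing VE; declining curves are
  flagged, not modeled.
* Entropy comparisons are only meaningful at a fixed bin width: halving Δ
  refines the histogram and can only increase entropy.
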