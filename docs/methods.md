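# Methods

This note documents the models, numerical choices and limitations of
`vtatlas` — what the code computes, why the defaults are what they
are, and what the synthetic phantom does and does not show about real
data.

## Image model and intensity normalization

Frames are non-negative `M×W` matrices of pixel density in arbitrary
units, 0-based and pixel-centered, with `x` the column and `y` the row
index.  Because acquisition gain varies across speakers and series,
**histogram matching precedes every transformation or averaging step**.
Matching is monotone CDF inversion against a binned reference
histogram: each distinct pixel value is assigned its empirical
quantile and mapped to the center of the lowest reference bin whose
cumulative mass reaches it; a value already inside its target bin
passes through untouched.  This makes the map deterministic (ties go to
the lowest admissible intensity), idempotent, and a bit-exact no-op on
an image that already matches — properties the averaging steps rely on.
Histograms default to 256 uniform bins over the observed per-dataset
range, which mirrors 8-bit-like magnitude exports; the cohort "average
histogram" averages *normalized* (probability) histograms so that
images of different size contribute equally, then rescales to the mean
input mass.

## Transform model

The composite transform is **additive**:

    T(x, y) = T_global(x, y) + T_local(x, y)

with an affine `T_global` and a cubic B-spline free-form deformation
`T_local(x,y) = Σ_{l,m} B_l(u) B_m(v) φ_{i+l,j+m}`,
`i = ⌊x/δx⌋ − 1`, `u = x/δx − ⌊x/δx⌋` (and likewise in y), using the
standard cubic basis `B0..B3`.  The control grid is padded so every
image pixel has a full 4×4 support neighborhood (`⌊(W−1)/δx⌋ + 4`
points per axis, one before the origin).  Consequences of additivity:

* transforms average **parameter-wise** (affine entries and control
  displacements), which realizes the unweighted mean transform
  `T̄_i = (1/(N−1)) Σ T_{i,j}` exactly;
* affine averaging happens in parameter space, not in log/matrix-group
  space — consistent with the plain unweighted mean above (rotations
  in this data are a few degrees, where the distinction is negligible);
* a transform estimated as "affine then FFD refinement" is converted to
  the additive form by mapping the FFD control displacements through
  the affine linear part (the FFD is linear in its control points, so
  this is exact).

Warping is backward mapping (`output(x) = input(T(x))`) with bilinear
interpolation and zero fill; FFD evaluation uses the exact cubic
basis.  Identity transforms reproduce images to float precision.

## Registration engine

Registration is implemented in-house on numpy/scipy so that the
recovered transforms live natively in the representation above.

**Affine stage.**  Similarity metric: mutual information on a 32-bin
joint histogram (robust to residual intensity differences).  Both
images are pre-smoothed with a σ = 1.2 px Gaussian *for metric
evaluation only*: hard-binned MI is piecewise-rough at subpixel scale,
and the smoothing restores a usable basin around the optimum (the
recovered transform is applied to the original images).  The search is
multi-resolution (up to 3 levels, factor 2, levels below 24 px dropped
as too poorly sampled to rank candidates), run by Powell's method over
6 center-anchored parameters with scale-normalized steps, restarted up
to 3 times (restarting re-seeds Powell's direction set, which
degenerates in the curved scale/translation valley of MI), and
finished with a Nelder–Mead polish.  A deterministic global
initializer protects against the identity local optimum: a small grid
of uniform scales (0.85…1.15), each given an integer translation from
a zero-padded FFT cross-correlation, scored by the metric at ~32 px.
For time series, consecutive frames warm-start from the previous
frame's solution (single level, one Powell iteration); the first frame
is seeded by the speaker's silence-to-reference affine.  Everything is
gradient-free, iteration-capped and fully deterministic.

**FFD stage.**  The non-rigid refinement minimizes the mean squared
difference between the fixed image and the warped moving image, plus a
first-difference smoothness penalty on the control grid (weight 2e−2),
with L-BFGS-B and an analytic gradient through the sparse B-spline
basis matrix; two resolution levels.  The penalty weight is set stiff
enough that the field cannot game SSD by expanding bright regions to
cover a blurrier target — against synthesized (averaged, hence
smoother) atlas frames a weakly regularized field inflates the warped
image's energy by several percent, which distorts the
correlation-ratio evaluation — while still recovering known
articulator-scale deformations well under 1 px.  SSD rather than MI here is a
deliberate deviation from using one metric throughout: every
registration in this pipeline operates on histogram-matched images, so
the problem is effectively mono-modal, and an analytic SSD gradient
over ~300 control parameters is vastly cheaper and better conditioned
than gradient-free MI.  Default control spacing is 16 px on 136×136
frames (≈ articulator scale; 8 px is used for 64 px frames) — the
source protocol does not pin this, so it is a declared choice.

Verified recovery on phantom frames: known affines with |shift| ≤ 6 px
and scale in [0.87, 1.15] are recovered below 0.5 px mean endpoint
error; known smooth FFD bumps below 1 px; two phantom speakers' silence
frames recover their true inter-speaker affine below 1 px at 136 px.

## Reference space, normalization, alignment

The reference ("silence") space is built independently per plane from
one caller-selected silence frame per speaker: all N(N−1) ordered
pairwise B-spline registrations, per-speaker parameter-wise averaging,
warping, then the pixel-wise *mean* (not median) of the neutralized
images.  The reference is not histogram-matched again after averaging.

Dynamic series are normalized with **one independent affine per
frame** — deliberately no non-rigid part, so inter-speaker anatomy is
removed while articulator configuration (the signal of interest)
survives.  Only the annotated C+V window is normalized; leading
silence and the trailing /p/ closure are dropped at ingest.

Temporal alignment is segment-wise linear and **start-anchored**: a
frame at offset `f` in a segment of `n` frames whose reference length
is `r` frames at rate `fps` gets time `segment_start + (f/n)·r/fps`.
The anchor convention is not pinned by the procedure being mirrored;
start-anchoring puts every utterance's consonant onset exactly at t = 0
and keeps the map monotone with no frame-to-frame correspondence
imposed.  Reference durations stay fractional (means over speakers and
planes); pooling is stable-sorted by (time, speaker, source frame).
In cross-validation, reference durations are computed from the
*training* speakers only, since the atlas must not see test timing.

## Adaptive kernel synthesis

At synthesis time τ the k nearest samples are selected
(tie-break: smaller |Δt|, then earlier time, then series order), and
σ is set from the farthest selected time τ_f by
`σ² = −(τ−τ_f)²/(2 ln 0.35)`, so the raw weight at τ_f is exactly 0.35
of the peak.  The implementation evaluates the algebraically equal
form `0.35^((Δt/(τ_f−τ))²)`, which keeps the floor exact to machine
precision and cannot underflow for tiny spans.  If all selected
samples sit at τ, weights are uniform.  Weights are normalized to sum
to 1 before pixel-wise averaging, making the synthesis a convex
combination.  Contributors are histogram-matched to the
nearest-in-time contributor first (the natural intensity reference for
that time point; matching to an evolving atlas estimate would make the
result order-dependent).  Defaults k = 7 and a 20 ms window (one
acquisition frame period) follow the tuning of the source protocol;
the window acts as the default synthesis-grid spacing and as a sanity
bound (a warning is emitted when the k-th neighbor falls outside it —
expected for sparsely covered cohorts, harmless for dense ones).

## Cross-validated evaluation

Folds are deterministic given a seed: with 4 male and 4 female
speakers, each of 4 folds tests one speaker of each gender, covering
everyone exactly once.  Test utterances are affinely normalized and
aligned, each atlas frame links to the temporally closest test frame
(earlier frame on ties; reuse allowed), the linked frames are
histogram-matched to the atlas frame and registered to it with the
B-spline method (starting from the identity affine — test frames are
already in atlas space).  BA and AA are the similarity ratios defined
in the README; the denominators use the per-stack atlas frame.  The
similarity formulas correlate the two test images with each other
(normalized by the atlas autocorrelation) — the accompanying prose in
the source describes the comparison loosely as "against row A", but the
printed formulas are what is implemented.  The implementation uses
FFT-based full correlation; a spatial-domain double-loop oracle in the
tests confirms exact agreement.  Values pool over frames, planes,
test pairs and folds into per-CV mean and population SD.

## Phantom cohort

The generator renders an articulated sagittal head with smooth
analytic indicator functions (logistic edges), so images are
anti-aliased, resolution-independent, and have the gradients
registration needs.  Speaker anatomy = a known affine (scale within
[0.85, 1.15], skewed by gender; tilt ±4°; shift ±2 % of the frame)
applied analytically to the canonical scene — so ground-truth
inter-speaker transforms are exact — plus deliberate *non-affine*
individuality: palate/jaw offsets (~1–2 px), tongue-thickness and
articulation-amplitude factors (±6–8 %), and a variable vertebra count
(4–6; real cohorts show exactly this spine-visibility variation).
All speakers share one gesture per CV (silence → consonant target held
through C → vowel target by mid-V → final /p/ closure, cosine-eased);
per-speaker integer C/V durations jitter by ±1 frame around the
configured cohort means, which default to the reference duration
table of the emulated study.  Off-center planes get increasing blur
and damped articulation (partial-volume effect); Gaussian noise
(σ = 1 % of range) is added everywhere.  One seeded generator drives
all randomness; outputs are bit-reproducible.

What passing on phantoms does **not** show: robustness to real MRI
artifacts (banding, off-resonance, coil shading), to genuinely
non-affine anatomy differences larger than a few pixels, to
mis-labeled segment boundaries, or to gestures that differ in *order*
across speakers (the alignment model assumes a shared event order).
The phantom's landmark geometry is proportionally simplified, so
absolute measurement values are not physiological, only their
invariances and scaling.

## Problem sizes

The cross-validated end-to-end check runs at 64×64 resolution on the
midsagittal plane with a 40 ms atlas grid, 8 speakers, all 12 CVs and
4 folds — about 5,000 affine and 700 non-rigid registrations — the
scale at which the full pattern (mean similarity up, SD down, for
every CV) is demonstrated on a single CPU in minutes.  Unit and
recovery tests use 40–64 px frames; the inter-speaker ground-truth
check runs at the nominal 136 px.

## Known limitations

* The affine metric's pre-smoothing trades a little peak sharpness for
  basin smoothness; sub-0.1 px accuracy would need a smoother MI
  estimator (Parzen windows) or a gradient-based formulation.
* Transform averaging in parameter space has no guarantee of
  invertibility for large deformations; for the deformation scales
  here (a few pixels) recovered fields stay well-behaved.
* `run_validation` recomputes the reference space per fold from
  scratch; pairwise registrations are not cached across folds because
  fold-specific histogram references change the inputs slightly.
* The CLI covers simulate/build-reference/align/measure/run; per-stage
  caching of transforms to JSON is available through the library API.
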