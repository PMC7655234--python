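# Methods

## Problem and model

During free breathing the internal anatomy of the thorax moves with the
respiratory cycle, and on hybrid MR-guidance systems the only real-time
imaging available during treatment is 2D cine-MR. A surrogate-driven
motion model estimates the full motion of the anatomy from one or more
low-dimensional *surrogate signals* that can be measured continuously.
This package implements and evaluates the 2D version of that workflow:

1. an interleaved acquisition provides a *surrogate* slice (from which
   signals are derived) and a *motion* slice (whose anatomy is modelled),
   alternating at roughly 1.9 frames per second each;
2. the motion of the motion slice is parameterized by the control-point
   displacements (CPD) of a cubic B-spline free-form deformation, with
   **two full control-point grids**, one for the thoracic wall and one for
   the lung/mediastinum/abdomen compartment, selected per pixel by a fixed
   segmentation of the reference image so the two regions can slide past
   each other discontinuously;
3. each CPD component `M_i` is a linear *correspondence model* in two or
   three surrogate signals,

       M_i(s1, s2)     = c2·s2 + c1·s1 + c0
       M_i(s1, s2, s3) = c3·s3 + c2·s2 + c1·s1 + c0

   fitted by ordinary least squares, independently per component (solved
   as one multi-right-hand-side factorization, which is algebraically
   identical);
4. accuracy is quantified by the deformation field error (DFE): the
   per-pixel Euclidean norm of the difference between the model-estimated
   and reference deformation vector fields (DVF), summarized by the mean
   and 95th percentile within an evaluation mask and a tumour mask.

The surrogate signals compared are local — sub-pixel tracking of the
diaphragm boundary (SI) and the skin surface (AP) — and global — the
first principal-component scores of either the raw image intensities or
the CPDs of a *non-sliding* FFD registration of the surrogate slice
(CPD_s). Models pair a signal with its temporal derivative or with a
second independent signal; the standard zoo has 7 two-signal and
3 three-signal combinations plus a no-model baseline (estimated motion
identically zero), which measures how much motion the test data contains.

## Synthetic data

Patient cine-MR for this problem is not publicly available, so the
package ships a first-class synthetic generator; every experiment here
runs on it, and all pipeline stages accept real data through the same
NIfTI/CSV/YAML interfaces.

**Phantom.** A 128×128, 1.98 mm/pixel sagittal-like slice: elliptical
body, dark lung with bright vessels and a tumour (radius ≈ 8 px), bright
sub-diaphragmatic abdomen with a sharp SI diaphragm edge, a chest-wall
band, and analytic masks (sliding region, body, tumour, evaluation =
body eroded by 2 px). A fixed smooth texture field (amplitude 8 % of the
intensity range, correlation length ≈ 1.5 px) is added inside the body:
MR soft tissue is textured well above the noise floor, and without that
texture intensity-based registration is ill-posed in flat regions.

**Breathing.** The primary respiratory component is a per-cycle
raised-cosine-power waveform `level + a·(1 − cos⁴(π t/T))` whose flat top
is the end-exhale plateau (positive peaks = end-exhale, where breathing
dwells); per-cycle amplitude (mean 1.0, SD 0.15), period (4.0 ± 0.4 s)
and baseline (SD 0.06) are drawn independently, and the trough level is
interpolated across cycle boundaries so the waveform is continuous. The
secondary component is the same waveform with a phase lead of T/8, so
(primary, secondary) trajectories form hysteresis loops. Breath-holds
stop the waveform clock, freezing both components at the current phase;
the breath-hold scenario uses one 12 s hold starting at 28 s.

**Ground truth.** True motion is defined *on* the model class:
`CPD(p,t) = c1(p)·primary(t) + c2(p)·secondary(t) + c0(p)` exactly, per
region. The visceral coefficient maps give 15 mm SI motion at the
diaphragm decaying smoothly to zero at the lung apex plus a 2.5 mm AP
(and 1 mm SI) hysteresis component; the chest wall gets 3 mm AP motion
weighted toward the anterior wall. Intercepts are chosen so the
reference frame (respiratory state closest to the trace mean) has zero
displacement. Because the truth is exactly linear in two latent signals,
an OLS fit against the true signals must recover the generating
coefficients to machine precision — the strongest end-to-end check the
design admits — and all evaluation noise is attributable to the signal
extraction chain, not to the reference motion.

**Rendering.** Frames pull the reference image back through the
numerically inverted forward DVF (fixed-point iteration, 20 iterations,
tolerance 0.01 px) with additive Gaussian noise of SD 2 % of the dynamic
range. Surrogate and motion frames alternate at 1.9 fps each over
63.5 s (120 motion frames); the first three surrogate frames are
intensity-inflated (+25/18/12 %) to emulate acquisition before the
magnetization steady state.

What the generator does **not** emulate: MR contrast physics and
reconstruction artefacts, cardiac motion, through-plane (out-of-slice)
motion, bulk patient shifts, and drifting breathing pattern changes
beyond cycle-to-cycle variability. Passing tests therefore demonstrate
the correctness and internal consistency of the pipeline and the
qualitative behaviour of the signal/model combinations under controlled
conditions — not clinical performance on patient data. In particular the
surrogate and motion "slices" share one phantom anatomy (adjacent-slice
approximation), which will flatter all surrogates equally rather than
favour one.

## Signal extraction

*Pre-steady-state trimming* removes the maximal leading run of frames
whose mean intensity exceeds (1 + 0.05) × the median frame mean.

*Edge tracking*: within a window centred on a seed point (defaults 20×10
px for the diaphragm, 10×20 px for the skin), each line parallel to the
tracked axis is Gaussian-smoothed (σ = 1 px), the maximum-|gradient|
sample is refined by a three-point quadratic fit, and the per-frame
position is the mean over lines; lines whose peak gradient falls below
2 % of the frame dynamic range are dropped, and a frame with no usable
line is a reported error. Signals are positions relative to their own
mean, in mm, signed so end-exhale is positive (superior diaphragm,
posterior skin).

*Reference frame*: the frame among the first 30 whose diaphragm is
closest to the mean diaphragm position of those frames.

*Body mask*: Otsu threshold, binary closing (disk radius 30 px, chosen to
bridge the lung interior), largest connected component.

*PCA*: frames (or retained CPD_s vectors — control points inside the
body mask, AP and SI components concatenated, both in mm and therefore
unweighted) are mean-centred and decomposed by SVD. Scores are left in
natural units. Component signs are arbitrary, so each component is
flipped to correlate positively with the diaphragm signal; if |r| < 0.1
the largest-|loading| entry is made positive instead.

*Resampling*: a cubic smoothing spline is fitted to each signal and
evaluated at the motion-frame times; motion frames outside the surrogate
time span are discarded, never extrapolated. The default smoothing level
is 0 (interpolation): at ~1.9 fps a breath cycle is sampled ~8 times, so
successive differences are dominated by respiratory curvature rather
than noise and any difference-based noise estimate grossly over-smooths
(on default data it lowered the correlation of the resampled diaphragm
signal with the true primary component from 0.998 to 0.91, and scipy's
GCV-based smoothing spline was far worse). Temporal-derivative signals
are the analytic derivative of the fitted spline.

## Surrogate-slice registration (CPD_s)

A compact single-region FFD registration: mean locally normalized
cross-correlation (LNCC, Gaussian window σ = 2 px) minus 0.005 × bending
energy, optimized by L-BFGS over three levels with control-point
spacings of 20/10/5 px (image downsampled 4/2/1×). Choices worth noting:

- the LNCC variance floor zeroes the correlation (and its gradient)
  where either image is locally flat; a naive additive floor makes the
  analytic gradient a difference of huge, nearly cancelling terms.
- inside the optimizer the bending energy is expressed in control-grid
  index units (a factor h⁴ for grid spacing h relative to the physical
  form). The 0.005 weight is calibrated for that registration-package
  convention; with physical mm⁻² units it is ~10⁴ times too weak and the
  similarity visibly over-fits (DVF errors grew with iteration count).
  The public `bending_energy` function keeps physical units.
- the analytic objective gradient chains the exact LNCC image gradient
  with a sampled image-gradient approximation of the warp derivative and
  the exact B-spline basis; it is verified against numeric differences.
- cine frames are registered outward from the reference frame, each
  warm-started from its temporal neighbour (finest level only, 8
  iterations); the first registration runs all levels with 40 iterations
  per level. On default data this reaches ≈ 0.3 mm RMS DVF error inside
  the body at ≈ 0.13 s per frame.

The sliding-preserving two-region registration used to *measure* motion
in patient studies is intentionally out of scope here: reference motion
comes from the synthetic ground truth (or imported CPD files), so models
are never evaluated against motion produced by the model itself.

## Evaluation protocol

Motion frames are split into a building set (first 80) and a test set
(the remainder; with trimming and span rejection the default dataset has
117 usable motion frames, hence 37 test frames). Training subsets of
n = 20…6 frames are evenly spaced with step 4; the four folds at n = 20
are [1,5,…,77], [2,6,…,78], [3,7,…,79], [4,8,…,80] (1-based) and
partition the building set; for n < 20 the earliest frames are dropped.
Every model is fitted per (n, fold) and evaluated on the full test set.

DVFs are forward displacements of the reference anatomy on the reference
pixel grid, in mm. The evaluation and tumour masks are transported to
each test frame through the frame's reference transform (numerical
inversion + nearest-neighbour pull-back) and the DFE statistics pool all
masked pixels of all test frames before taking the mean and the
95th-percentile (linear interpolation between order statistics);
per-frame values are also available so a per-frame-averaged convention
can be recomputed. With forward reference-grid DVFs the transported
evaluation mask differs from the source mask only near the body
boundary; transporting is kept because it is the convention the masked
statistics are defined under. Inside `run_experiment` the DFE is
evaluated only at the union of masked pixels through a sparse
region-aware B-spline basis matrix; this is exactly the masked subset of
the full sliding composition (asserted against the dense route in the
tests).

## Numerical choices and degenerate inputs

- OLS uses a minimum-norm least-squares factorization (never normal
  equations); a design condition number above 1e10 — e.g. a derivative
  column during a breath-hold — attaches a warning to the fit instead of
  failing, and the fit proceeds.
- Percentiles use linear interpolation; ties in the reference-frame
  choice break to the earliest frame.
- The B-spline grid always covers the image with one control point
  beyond each border; insufficient coverage is an error naming the
  offending range.
- A mask that is empty in one test frame skips that frame with a
  warning; empty in all frames is an error.
- DVF inversion stops early when the update falls below 0.01 px.

## Problem sizes

Default study runs use the full 120-frame-pair acquisition (117 retained
motion frames) at 128×128 resolution with a 10 mm model control-point
grid, ten seeds per condition, and the complete zoo over n = 20…6 × 4
folds; one study run takes well under a minute on one core. The
exact-recovery check uses a 64×64 phantom with a 16 mm grid, where the
arithmetic is the same but the run takes seconds.

## Known limitations

- The hysteresis magnitude of real patients is not characterized by any
  public reference; the defaults (2.5 mm AP) are plausibility choices
  exposed in the configuration.
- The intensity-PCA surrogate sees the same noise-free-of-artefact
  phantom as the CPD_s surrogate; contrasts between the two signal
  families on real data (blood flow, cardiac motion contaminating
  intensities) are not reproduced here.
- The 2-region sliding composition takes region membership from the
  fixed source segmentation; near-boundary pixels that change region
  under large motion are not re-assigned.
- Registration quality (and hence CPD_s signal quality) depends on the
  phantom's texture amplitude; far weaker texture degrades PC2/PC3
  toward registration noise, which is also the realistic failure mode.
- Because the reference motion is exact (noise-free by construction),
  over-fitting penalties at very small training sizes are weaker here
  than on registration-derived motion measurements: a third informative
  signal often still pays for its extra parameter at n = 6 on this
  generator, whereas on patient data — where the fitted targets carry
  registration error — three-signal models tend to lose to two-signal
  models at that size. Comparisons of model *capacity* at the smallest
  training sizes therefore do not transfer from this phantom to real
  data.
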