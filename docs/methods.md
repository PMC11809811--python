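# Methods

`seedtrack` is a combined tracking-and-segmentation pipeline for time-lapse
movies of a few highly motile, dividing cells (T-lymphocyte-like) in 2D
suspension, whose output is a cell lineage tree: per-cell centroid tracks,
instance masks, and parent–child links at divisions.  This note documents
the model, its assumptions, the parameters that matter, and the design
choices made where the design was genuinely open.

## The seed mechanism

The pipeline's central device is the *seed channel*: an artificial image
containing one fixed-intensity square per cell (side 40 px, roughly a cell
diameter; intensities 255, 125, 60, 30 by identity rank, continued by
halving for more cells).  Seeds carry a cell's identity and last known
position (i) between consecutive 4-frame clips, (ii) from tracking into
segmentation (which cell of several in a patch to segment), and (iii) from
segmentation back into tracking (refined centroids seed the next clip).
Cells without a seed are ignored by construction, which decomposes
multi-object tracking into independent single-object problems: a
single-cell "general" tracker run once per cell matches the contract of a
dedicated N-cell tracker.

Assumptions inherited from the imaging setting: 2D (no z-stacks), two
channels (fluorescent + bright-field), few cells per 382×382 px frame
(0.327 µm/px), negligible cell death and occlusion, cell count
non-decreasing (divisions only).

## Tracking

Tracking is centroid regression by a 3D CNN over a *clip* of 4 consecutive
fluorescent frames with the seed channel prepended as a fifth temporal
slice.  The stack uses 3×3×3 convolutions with ReLU and (2,2,1) max pools
— never pooling along time, so per-frame positional detail survives — and
ends in four parallel per-frame branches of fully connected layers, each
emitting 2N coordinates (no output activation).  Inputs are resized to
100×100 and standardized per slice; coordinate labels are divided by the
frame side, so training minimizes MSE on [0,1]² coordinates.  Training
quality is monitored with a *proxy-box IoU*: the IoU of 40×40 px squares
centred on the predicted and true centroids.

Full-scale architecture constructors (`build_tracker_spec`) define the
dedicated trackers (conv filters 64, 64, 128, 256, 512; branch
widths 256…1024 with dropout 0.03–0.05 and an FC-2 of 512 for N ≥ 2) and
the enlarged general variant (doubled 64/128 conv layers, an extra double
32-filter layer in front, FC-1 = FC-2 = 1024, no dropout; trained with
exactly one cell seeded among unseeded distractors).  Training defaults
are Adam, learning rate 0.009–0.01, batch 32, 150 epochs.

### Desk-scale training

The networks here train on CPU with a hand-written numpy engine (`nn.py`:
im2col convolutions, explicit backprop, Adam) — a deliberate, minimal
implementation of exactly the layers these architectures need.  Full-scale
training is out of scope; the test suite trains *reduced* trackers
(conv stack 8, P, 16, P; FC-1 64; 32×32 inputs) on ~500 simulated clips.
Two standard measures close the gap that full-scale training solved
with ~25 000 clips:

* **label-consistent augmentation** — 8-fold dihedral augmentation of each
  clip plus on-the-fly random translations during training.  A
  flatten-plus-FC readout has no built-in translation structure; at small
  sample sizes it must be taught explicitly.
* **seed-centred cropping (general tracker only)** — since the general
  tracker must ignore everything except the seeded cell, its reduced
  variant crops a 128 px window around the seed before resizing
  (`TrackerSpec.crop_side`).  This shrinks the position range the readout
  must cover and triples the effective resolution; predictions are mapped
  back to frame coordinates.  The full-scale spec keeps the
  full-frame configuration (`crop_side=None`).

With these, the reduced general tracker reaches held-out proxy-box IoU
above 0.5 (the full-scale figure is ≈ 0.88); in the pipeline its
residual error is absorbed by segmentation-based refinement, which
tolerates patch-centre errors up to ±35 px.

## Segmentation

Each tracked centroid is segmented in a 96×96 patch (≈ 6 % of the frame,
≈ 4 cell areas) with three planes: fluorescent, bright-field, and a seed
plane holding a single square of intensity 255 at the cell's
previous-frame position.  Two U-Nets run in series: the **Segmentor**
produces a first probability map P1; the **Refiner** receives the same
patch with the seed plane replaced by binarized P1 (threshold 0.5) and
produces P2.  The final mask is (P1+P2)/2 > 0.5, restricted to the
connected component with maximal seed overlap (ties and "adding outputs"
are otherwise ambiguous; averaging then thresholding is this package's
reading).  The full-scale specs are standard 4-level U-Nets for 96×96×3
with dropouts Drop2=0.5, Drop3=0.3, Drop4=Drop5=0.5 (Segmentor) and
Drop2=0.5, Drop3=0.3 with stock Drop4=Drop5=0.3 (Refiner); full-scale training defaults are Adam at 9×10⁻⁵, batch 32, 200 epochs (Segmentor) / 30
(Refiner), keeping the best-validation-IoU checkpoint.

Training patches are jittered by U(−35, 35) px per axis around the true
centroid to mimic tracker error, and augmented 6-fold (3 rotations + 2
reflections).  The pixel-wise cross-entropy is weighted per pixel:

    W_Segmentor(x) = W_c(x) + W0 · exp(−(d1+d2)² / (2σ²)) + W_fr(x)
    W_Refiner(x)   = W_Segmentor(x) + W_errors(x)

with W0 = 10, σ = 5 px, W_fr = 8 on unwanted-cell pixels, and
W_errors = 10 on pixels of the Segmentor's error mask
(|Segmentor − label|, a pixel-wise XOR).  Open details resolved here:
W_c is the inverse-class-frequency map normalized so that its
pixel-weighted mean is 1 (a "class probability map" has no unique
closed form, and inverse class frequency is the standard choice); d1/d2 are Euclidean distance transforms to the
nearest and second-nearest instance borders, where a *border* is the
morphological gradient (so a background pixel wedged between two touching
cells has d1 = d2 = 0 and the border term attains exactly W0); with a
single instance the border term vanishes (d2 = +∞).

After segmentation the mask centroid repositions the patch, the cell is
re-segmented once, and the resulting centroid becomes the recorded track
position and the seed for the next frame — segmentation correcting
tracking.  An empty mask falls back to the tracker centroid and is logged.
Where two refined masks claim a pixel, the cell with the larger seed-square
overlap wins.  The reduced suite nets use 48×48 two-level U-Nets
(filters 8/16); patches are resampled to and from the net's side.

## Division detection

Lymphocyte mitosis is stereotyped enough for classical geometry.  Two
independent detectors operate on segmented patches:

* **pre-division**: a single component whose contour has exactly two
  convexity defects deeper than `depth_frac` × equivalent radius
  (default 0.2) on roughly opposite sides (angular separation > 120°) —
  the "figure-eight" of a cell about to split.  Convexity defects are
  measured as the maximal distance from the contour to each convex-hull
  edge (scipy `ConvexHull` + skimage contours).
* **post-division**: exactly two components with equivalent-radius ratio
  within 1.25 and circularity (4πA/P²) ≥ 0.8 — twin round daughters.

The source method states no values for these thresholds; defaults were tuned on synthetic
shape banks and all are exposed in `DivisionParams`.  The two verdicts are
fused by a rule this package defines: a division is confirmed only when
post-division evidence arrives within `confirm_window` (3) frames of
pre-division evidence, suppressing false triggers on transiently bilobed
cells.  On confirmation the parent track is closed at the division frame
(its figure-eight frames keep the parent identity), two daughters open at
the detected component centroids, the tracker switches (dedicated N→N+1,
or one more general pass), and the next clip restarts at the division
frame.

Two robustness measures adapt the detector to masks produced by the
reduced-resolution ensemble, which rounds off the cleavage furrow:
(i) the clip loop uses a more sensitive defect threshold
(`PipelineConfig.division.depth_frac = 0.12` versus the detector-level
default 0.2) and, when the ensemble mask shows no figure-eight, also
checks the full-resolution component of a light intensity threshold of
the fluorescent patch under the cell; (ii) the post-division check first
examines the ensemble's thresholded union and falls back to the intensity
components near the parent — a seeded ensemble segments a single cell by
design and may hold only one daughter.  The extra sensitivity is absorbed
by the pre/post fusion rule plus two daughter-plausibility gates: the
candidate pair must sit closer than `max_daughter_separation` (48 px;
unrelated neighbours keep larger separations) and each candidate's
equivalent radius must stay below `max_daughter_radius_frac` (0.9) of the
parent's pre-division radius.

## Synthetic data

The simulator generates the training and test conditions end to end:

* **positions**: initial centroids i.i.d. uniform over the frame
  (optionally with a minimum pairwise separation by rejection).
* **motion**: per frame, each cell steps by distance R at angle
  A ~ U[0, 2π).  R follows the empirical step-size density
  f(t) = a·(t/b)·exp(−(t/b)²) with a = 0.25, b = 7 px.  f is an
  unnormalized Rayleigh density of scale b/√2; sampling uses the
  normalized form, so a has no effect and is retained only for fidelity
  to the fitted form.  The closed-form MLE b̂ = √(mean t²) recovers b.
  b = 0 is accepted as the stationary limit.  Steps that would exit the
  frame reflect at the borders; steps that would bring two cells closer
  than the minimum separation are resampled (so instance masks stay
  disjoint outside pre-division frames).
* **appearance**: the ground-truth mask is a dilated disk
  (base radius 18 px + dilation 2 px → ≈ 40 px diameter); the fluorescent
  rendering adds uniform interior texture (±60 around intensity 180),
  Gaussian blur (σ 1.5 px) and uniform background noise (0–8).  The
  bright-field channel is a synthetic stand-in (faint annulus per cell
  plus Gaussian noise, blurred) — real bright-field contrast is not
  modelled.
* **division**: at a scheduled fission frame the parent is replaced by two
  adjacent round daughters (radius 0.75× parent, centres 2.2 daughter
  radii apart along a random axis, the pair translated as a unit to stay
  in frame and rotated if it would land on another cell); for the 2
  preceding frames the parent renders as a widening figure-eight (two
  lobes of 1.05× daughter radius whose separation grows from 1.4 to 2.0
  lobe radii as the cleavage furrow deepens).  Phase durations and
  separations are modelling choices of this simulator, exposed as config
  knobs (`SimConfig.n_predivision_frames`, `ShapeModel`).

Everything is driven by one `numpy` generator seed; output is
bit-reproducible.  What the simulator does *not* emulate: real cell-shape
variability (uropods, elongation), photobleaching, drift, occlusions,
cell death, and true bright-field optics.  Tests passing on this synthetic
world therefore demonstrate the pipeline's mechanics (identity
preservation, seed propagation, division bookkeeping, metric correctness)
— not segmentation accuracy on real lymphocyte morphology.

## Evaluation

Instance-detection metrics use one-to-one matching by optimal assignment
(Hungarian; deterministic and order-independent, unlike greedy matching)
over pairs with IoU > t, giving TP/FP/FN and AP_t = TP/(TP+FP+FN); avAP
averages AP over t = 0.50 … 0.95 in steps of 0.05.  SEG is the mean over
ground-truth objects of the IoU with the prediction covering a strict
majority of the object's pixels (else 0).  Tracking error is summarised
by an **identity-swap count**: frames at which the pred↔truth
correspondence (optimal centroid assignment per frame) changes for a pair
that coexists in both frames; appearing/disappearing tracks around
divisions do not count, so a ±1-frame division offset is not penalised,
while exchanged identities are.  This is a simplified association-error
count, *not* the Cell Tracking Challenge DET/TRA (AOGM) score, and is
labelled `identity_swaps_non_ctc` in reports.

## Numerical and degenerate-input choices

* Coordinates are 0-based pixel indices, (x, y) = (column, row), sub-pixel
  floats; a mirrored coordinate maps to (side−1)/side − x.
* Constant frames standardize with sd replaced by 1 (warning logged).
* Seed squares are clipped at borders; overlapping squares render
  higher-intensity-wins; identity assignment ties break to the lowest
  identity (well defined because palette intensities strictly decrease).
* Tracker predictions are clipped to [0,1] before denormalization.
* AP with TP = FP = FN = 0 is 0 by convention; F1 with P = R = 0 is 0;
  SEG over zero ground-truth objects is 1.
* A final partial clip repeats its last frame; duplicate outputs are
  discarded.
* Empty segmentation masks fall back to the tracker centroid (logged).

## Problem sizes in the test suite

The suite trains one reduced general tracker (500 clips, 8 dihedral
variants each, 8 epochs), two small dedicated trackers (500 and 150
clips), and a reduced Segmentor/Refiner (300 patches ×6 augmentation,
5 and 3 epochs) once per session, then reuses them across tests.  The
end-to-end check runs five held-out 20-frame 2-cell movies with one
division each and requires zero identity swaps and SEG ≥ 0.7 — bounds set
for this synthetic desk scale, not the full-scale figures
(e.g. SEG ≈ 0.9 on real movies).

## Known limitations

* The bright-field model is synthetic; nothing here validates real
  bright-field contributions to segmentation.
* The division detector's thresholds were tuned on synthetic banks of
  disks/ellipses/figure-eights; strongly non-convex interphase cells
  (e.g. with uropods) could trigger false pre-division verdicts, which the
  confirmation window only partially suppresses.
* If post-division evidence never follows a pre-division verdict, no
  division is recorded — a missed division leaves a daughter untracked
  (visible as a drop in SEG, never as a silent identity swap).
* The identity-swap counter assumes centroid proximity resolves
  correspondence; in extreme crowding it would undercount.
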