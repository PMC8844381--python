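# Methods

This note documents the models, algorithms and numerical choices behind
`polarcall`, and what the synthetic benchmark does and does not show.

## Data model

A recording is a 5-D nonnegative intensity tensor with fixed internal
axis order (t, z, c, y, x), one DIC and one fluorescence channel, a
frame interval in seconds (1200–2400 s for this stage of development)
and a z-step in μm (4 μm default). Frame indices are 0-based and the
time of frame *i* is *i* × frame_interval_s. On disk a recording is one
TZCYX TIFF plus a JSON sidecar carrying id, timing and channel roles;
externally produced TIFFs with permuted or missing axes are normalized
on read (missing axes must have length 1).

## All-in-focus fusion

The DIC z-stack at each time point is compressed to one 2-D frame with
a dual-tree complex wavelet transform. The transform runs four real
separable DWTs (row-tree × column-tree); pairwise combination of the
four real subbands yields six complex, directionally selective subbands
per level whose magnitudes are nearly shift invariant — the property
that makes coefficient magnitude a stable local sharpness measure.
Filters: level 1 uses CDF 9/7 biorthogonal filters with the second tree
offset by one sample (the half-sample delay at the first scale); deeper
levels use Kingsbury's 14-tap Q-shift scaling filter, with the second
tree using its time reverse. The printed Q-shift coefficients are
projected onto the orthonormality constraints at import time
(`sum h = √2`, double-shift orthogonality), which restores perfect
reconstruction to ~1e-12 relative error without moving any tap by more
than ~1e-7. All filtering uses periodic extension, so images are
symmetrically padded to a multiple of 2^levels and cropped back.

Fusion rule: per highpass coefficient, take the coefficient of the
slice with the largest complex magnitude (`argmax`, so ties go to the
lowest z index and results are reproducible under slice permutation);
the residual lowpass is averaged across slices by default
(`max_local_energy`, a per-pixel 3×3 local-energy maximum, is
available). Decomposition depth defaults to 4 levels, clamped to
log₂(min side). The inverse transform of the fused pyramid is clipped
to the stack's intensity range — wavelet selection can overshoot near
strong edges, and clipping (rather than affine rescaling) preserves the
identity on stacks of identical slices. The fluorescence channel is
reduced by a plain maximum intensity projection: the apical cap is a
sparse bright structure, for which the per-pixel max over z is the
natural sufficient statistic.

## Annotation rules

* Polarization onset: first frame whose maximum closed-cap surface
  fraction is **≥ 1/3** (inclusive). All frames at/after onset are
  *after*, all earlier frames *before*; if the threshold is never
  reached no onset exists and all labels are *before*.
* Compaction: first frame whose smallest inter-blastomere angle is
  **strictly > 120°**.
* Inter-blastomere angle: defined analytically on circle-overlap
  geometry. For circles of radii r₁, r₂ at centre distance d, the
  intersection point is at distance a = (d² + r₁² − r₂²)/2d from the
  first centre and height h = √(r₁² − a²); the exterior angle between
  the membrane tangents is atan2(h, a) + atan2(h, d − a). For equal
  radii this reduces to 180° − 2·arcsin(d/2r): 120° at d = r, → 0° at
  point contact, → 180° as the circles merge, strictly decreasing in d.
  An analytic definition was chosen over image segmentation because the
  synthetic generator exposes exact geometry; a contour-based estimator
  (tangent fit over a ±5-pixel arc at each contour intersection point,
  mean over the two contact endpoints) is provided for mask images and
  agrees with the closed form within ±3° on rendered circle pairs.

## Synthetic embryo generator

The generator is the package's study-condition definition, not a
visualization toy. Per recording (defaults in parentheses):

* 8 blastomeres rendered as equal circles (radius 10 px) on a ring, in
  64×64 frames, 7 z-slices 4 μm apart, 24 frames, frame interval drawn
  uniformly from [1200, 2400] s.
* Compaction: the smallest-angle trajectory is piecewise linear from
  angle_start (95°) to angle_end (165°), constructed to cross 120°
  exactly between frames compaction_frame−1 and compaction_frame.
  Centre distances are derived from the angle by inverting the tangent
  geometry above, with the ring radius set so that the widest
  adjacent-pair gap (under per-embryo angular packing jitter, ±0.15
  rad) realizes the smallest angle; the generator therefore satisfies,
  by construction, the same angle definition the annotation module
  measures, and this is asserted in tests.
* Polarization: the closed-cap fraction ramps linearly
  (cap_growth_per_frame = 0.12) and equals exactly 1/3 at
  polarization_frame. The fluorescence channel draws the cap as a
  bright boundary arc spanning that fraction of the first polarized
  blastomere's circumference. The DIC channel carries a high-frequency
  membrane ripple (wavelength ≈ 2.5 px) of amplitude dic_cue_strength
  (0.35) from the onset frame on. A step-at-onset cue was chosen
  because nothing is known about how strongly (or through which
  feature) polarization manifests in real DIC texture; the cue strength
  is an explicit knob and no claim is made that it matches reality.
* Defocus: each blastomere has a focal z-slice; its contribution to
  slice j is blurred with σ = defocus_sigma_per_um × z_step × |j −
  focal| (0.30 px/μm). Noise is additive Gaussian (sd 0.03); Poisson
  photon statistics are out of scope.
* Cohorts: per-embryo seeds derive from a master seed; compaction frame
  and the compaction→polarization lag are drawn from inclusive ranges
  (4–9 and 2–5 frames), radii jittered ±10%. Lag ≥ 2 frames everywhere
  keeps compaction a genuinely earlier event, so a compaction-based
  onset proxy must err.

What passing tests on this generator show: the pipeline's mechanics —
fusion recovers in-focus structure, labels and onsets are recovered
end-to-end, the compaction proxy is beaten when compaction genuinely
precedes polarization. What they do not show: performance on real
microscopy, where the DIC signature of polarization is subtler and not
a clean step, optics and noise are more complex, and blastomeres
deform rather than stay circular. Near-perfect synthetic accuracy is
expected and is not a claim about real data.

## Classifier

Each ensemble member is a small CNN: three 3×3 conv + ReLU + 2×2
max-pool blocks with (8, 16, 32) channels on 64×64 single-channel
input, then global average pooling and a 2-way dense head; class order
is [before, after] and the positive class is after-onset. Members are
trained from scratch with per-image standardization, random
flip/rotation augmentation (embryos have no canonical orientation),
batch size 32, softmax cross-entropy; the first half of the members
use SGD (lr 0.05, momentum 0.9), the second half Adam (lr 1e-3), all
for the same number of epochs (default 40; the bundled synthetic
experiment uses 5, which suffices at the default cue strength). The
trainer is implemented in NumPy with explicit backprop, making runs
exactly reproducible from the member seed and keeping pre-GAP feature
maps accessible. A ResNet-style pretrained backbone is deliberately
not bundled: members are small nets trained from scratch, and the
backbone/channel stack is a config option.

Ensembling: element-wise mean of member probability vectors; label =
after iff mean p_after > threshold (0.5). A tie at the threshold goes
to before-onset (the conservative call). Majority voting over member
labels is available as `label_majority`, with ties also before.

CAM: raw map = Σ_f w[class, f] · featuremap_f over the pre-GAP maps.
Because GAP commutes with the weighted sum, mean(raw map) = logit −
bias exactly (asserted to 1e-4 on trained members); for overlays the
raw map is bilinearly upsampled to the input size.

## Temporal smoothing and onset calling

Smoothing is one simultaneous pass of a window-3 majority vote over the
*raw* labels; both end labels are untouched and series of length ≤ 2
pass through. The simultaneous (order-independent) update was chosen
over sequential in-place sliding because the latter lets early flips
propagate. The called onset is the first after-onset index of the
smoothed sequence; "first positive" and "majority switch point"
coincide on monotone sequences (unit-tested), and first-index semantics
are used for the non-monotone corner cases. Onset discrepancy =
(predicted − annotated) × frame_interval, rounded to the nearest
second, with a missing prediction scored at one frame past the end of
the recording; comparisons between methods use absolute values.

## Statistics

* Bootstrap CIs: percentile intervals (not BCa) over B = 1000
  replicates, resampling the analysis unit (frames for frame metrics,
  embryos for onset statistics), deterministic given the seed.
* ROC/AUC: threshold sweep over the ensemble mean p_after; AUC is the
  Mann–Whitney concordance with ties counted 1/2 (scikit-learn backed,
  cross-checked in tests against brute-force pair enumeration).
* Two-proportion z-test: pooled variance, two-tailed normal p.
* Wilcoxon matched-pairs signed-rank: zeros dropped, mid-ranks for
  ties, statistic W = min(W⁺, W⁻); exact p by full 2ⁿ sign-flip
  enumeration for n ≤ 15 (ties handled naturally), normal
  approximation with tie correction above. SciPy's exact mode refuses
  ties, which is why the test is implemented here; it agrees with
  SciPy wherever both apply.
* Rater aggregation: per-frame majority with an exact tie resolved by
  a seeded fair coin.

## Reproducibility

Stage seeds are derived as SHA-256(master_seed:stage_name) mod 2³¹, so
adding a stage never perturbs earlier stages' randomness; the full
pipeline report is byte-identical across runs with the same master
seed. The bundled experiment uses 40 training and 10 test embryos at
64×64 — large enough to exercise every stage, small enough that the
whole experiment (generation, fusion of 1 200 z-stacks, training 6
members for 5 epochs, evaluation with bootstrap CIs) runs in a few
minutes on one CPU.

## Known limitations

* The synthetic DIC polarization cue is a modelling choice; real
  label-free signatures of polarization are unknown (that question is
  exactly what the classifier approach exists to probe).
* The circle-overlap angle model ignores membrane deformation at high
  compaction; second-neighbour circle overlaps at late compaction are
  rendering artifacts, and ground-truth angles refer to ring-adjacent
  contacts.
* 8-cell-stage windowing is assumed: recordings are generated already
  windowed, and no cell-division detection is provided.
* Gaussian noise and Gaussian defocus are first-order approximations
  of microscope physics.
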