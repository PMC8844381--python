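# polarcall

Stain-free detection of embryo polarization onset from DIC time-lapse
recordings.

## The problem

At the late 8-cell stage, each blastomere of the mammalian embryo forms an
apical domain on its contact-free surface — *polarization*, the first
cell-fate bifurcation cue and a candidate marker of embryo quality.
Observing it directly requires fluorescent tagging of apical proteins
(e.g. Ezrin-RFP), which is impermissible for human embryos in the IVF
clinic. `polarcall` implements a label-free alternative: detect the onset
of polarization purely from differential interference contrast (DIC)
imaging, using the fluorescence channel only to build training labels.

The pipeline:

1. **Z-compression.** Each recording is a 5-D tensor (t, z, c, y, x).
   The DIC z-stack at each time point is fused into a single all-in-focus
   (AIF) frame with a dual-tree complex wavelet transform (DTCWT): per
   subband coefficient, keep the coefficient with the largest complex
   magnitude across slices; the fluorescence stack is reduced by maximum
   intensity projection.
2. **Annotation.** Polarization onset = first frame whose largest closed
   apical-cap fraction ≥ 1/3 of the cell surface; frames at/after onset
   are labelled *after*, earlier frames *before*. Compaction (the
   morphological event that normally precedes polarization) = first frame
   whose smallest inter-blastomere angle exceeds 120°, where the angle
   between two contacting cells of radii r₁, r₂ at centre distance d is
   the exterior angle between membrane tangents at the contact point
   (for r₁ = r₂ = r: θ = 180° − 2·arcsin(d/2r)).
3. **Classification.** An ensemble of K = 6 CNNs (conv backbone → global
   average pooling → 2-way dense head), half trained with SGD and half
   with Adam for the same number of epochs, classifies each AIF DIC frame.
   The ensemble prediction is the element-wise mean of the member
   probability vectors (majority voting over labels is available too).
4. **Onset calling.** The chronological label sequence is smoothed by a
   window-3 majority vote (ends untouched); the first *after* frame of the
   smoothed sequence is the called onset. Onset error is reported in
   seconds using each recording's frame interval; a recording with no
   positive frame falls back to one frame past the end.
5. **Evaluation.** Confusion metrics (positive class = after-onset),
   ROC/AUC, percentile bootstrap 95% CIs (1000 replicates), two-tailed
   two-proportion z-test, two-sided Wilcoxon matched-pairs signed-rank
   test (exact sign-flip enumeration for small n), Pearson correlation,
   and multi-rater majority aggregation with a seeded fair-coin tie-break.
6. **Interpretability.** Class activation maps: the dense-head-weighted
   sum of pre-GAP feature maps, whose spatial mean equals the class logit
   minus its bias.

Because microscope data cannot ship with the package, a synthetic
generator (`polarcall.synthetic_embryo`) renders 8-cell embryos with
exactly known compaction/polarization ground truth: circle-overlap
geometry drives the inter-blastomere angle trajectory, a growing apical
cap appears in the fluorescence channel, a polarization-coupled texture
cue appears in DIC, and z-slices carry depth-dependent defocus blur.

## Worked example

```python
from polarcall import PipelineConfig, EnsembleConfig, run_pipeline

cfg = PipelineConfig(master_seed=1, ensemble=EnsembleConfig(epochs=5))
report = run_pipeline(cfg, "out/")   # 40 train / 10 test synthetic embryos
fm = report["frame_metrics"]
print(fm["accuracy"], fm["auc"])
print(report["tests"]["pearson_model_vs_compaction"])
print(report["tests"]["wilcoxon_model_vs_compaction"])
print(report["mean_abs_model_discrepancy_s"],
      report["mean_abs_compaction_discrepancy_s"])
```

prints (≈5 minutes on one CPU):

```
1.0 1.0
0.757936728959867
{'W': 0.0, 'p': 0.001953125}
0.0 5754.7
```

meaning: every held-out test frame was classified correctly (accuracy and
AUC 1.0 — the synthetic task at the default cue strength is easier than
real microscopy), the model's called onset matched the ground truth on
every test embryo (mean absolute onset error 0 s), while calling onset
from compaction alone errs by ~5 755 s on average — significantly worse
than the model (Wilcoxon signed-rank p ≈ 0.002) although the two onset
series are strongly correlated (Pearson ρ ≈ 0.76), reflecting that
compaction precedes polarization by a few frames.

The same experiment is available from the shell:

```
polarcall run --out out/ --seed 1
```

and the individual stages as `polarcall simulate | fuse | annotate |
train | predict | smooth | evaluate` (see `polarcall --help`).

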