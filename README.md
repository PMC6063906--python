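# ceus-radiomics

Radiomic analysis of destruction–replenishment contrast-enhanced
ultrasound (CEUS), built for researchers who want to quantify tumour
phenotype from a single microbubble scan: preclinical imaging groups
differentiating xenograft models, and method developers studying the
stability of ultrasound imaging biomarkers.

A CEUS scan records B-mode frames while intravascular microbubbles
perfuse the tumour; a destructive pulse clears the imaging plane and the
re-inflow follows

&nbsp;&nbsp;&nbsp;&nbsp;*I(t) = I₀ + A·(1 − e^(−βt))*,

with plateau *A* tracking relative blood volume and rate *β* tracking
blood flow velocity (*v = β·w* for beam width *w*). From one scan the
package extracts a **235-feature radiomic vector** — 14 first-order
intensity statistics, 30 textural features (19 GLCM + 11 GLRLM), 15
morphological/functional vascular features from an automatic vessel
segmentation (rBV, network length, distance map, flow velocity, ...),
and 176 wavelet features (the 44 intensity+texture features on each of
the four level-1 stationary-wavelet subbands). A four-criterion ranking
— test/retest concordance (CCC), normalized dynamic range, observer
independence (Quade test over three delineations), and discriminative
power (Kruskal–Wallis) — is aggregated into a final ranking, and the
best feature per biomarker class, pruned to pairwise Pearson
|r| ≤ 0.75, forms the **radiomic signature** used by a linear SVM with
4-fold cross-validation (Wilson score interval on the accuracy).
Unsupervised structure is assessed by Euclidean average-linkage
clustering with exact multinomial enrichment tests.

Because raw CEUS study data of this kind are rarely shared, the package
includes a first-class synthetic phantom generator: speckle-textured
tumours with grown vessel networks, bolus/destruction/replenishment
kinetics, breathing artifacts, test/retest re-acquisitions and three
simulated observer delineations — with ground truth attached, so every
stage of the chain is testable end to end. See `docs/methods.md` for the
full model description.

## Worked example

`examples/01_simulate_and_segment.py` simulates one default-noise
phantom scan and recovers its vasculature and kinetics:

```
phantom: P2, 60 frames at 10.0 fps, destruction at frame 20
breathing frames excluded: [18, 19, 27, 36, 45, 54] (true: [18, 27, 36, 45, 54])
vessel Dice vs ground truth: 0.949
rBV estimated 0.128 vs true 0.140
beta fitted 0.841/s vs true 0.800/s (A = 8.33, rmse = 0.114)
```

The breathing-artifact detector finds all five simulated displaced
frames (plus one adjacent frame around the destruction event), the
frame-difference segmentation overlaps the true vessel network at Dice
0.95, and the relative blood volume and replenishment rate are recovered
within ~9 % and ~5 % of the generator's ground truth.

`examples/04_full_study.py` runs the whole pipeline on a reduced
test/retest study (2 animals per phenotype, 64×64 frames):

```
scans: 12 + 12, features per scan: 235
signature (one per biomarker class):
  first_order  -> fo_median
  textural     -> glcm_imc1
  vascular     -> vasc_rbv_periphery
  wavelet      -> wavH_glcm_imc1
4-fold CV accuracy: 91.7% (95% Wilson CI [0.65, 0.99])
```

Each scan yields exactly 235 features; the selection returns one
feature per biomarker class with all pairwise |r| ≤ 0.75; the
cross-validated SVM separates the three phenotypes well above the 33 %
chance level. The remaining examples demonstrate speckle denoising
(`02`) and single-scan feature extraction (`03`).

A `ceus-radiomics` CLI wraps the same library functions
(`simulate`, `denoise`, `segment`, `extract`, `select`, `classify`,
`cluster`, `run-all`) for manifest-driven batch runs on disk.

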