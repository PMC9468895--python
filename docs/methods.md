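# Methods

## The staging model

Early endometrial cancer is staged by the depth of myometrial invasion:
stage IA (< 50%) versus stage IB (≥ 50%). The package's staging score is
the tumor-to-uterus area ratio on one representative 2-D slice per MRI
sequence,

    TUR = n_tumor / (n_tumor + n_uterus),

a pure pixel-count ratio, unitless and independent of voxel size. The
implicit model is that on a slice that clearly shows both structures, the
fraction of the organ cross-section occupied by tumor is monotone in
invasion depth. TUR of exactly 0 (no tumor segmented) or 1 (no healthy
uterus segmented) is legal output; a segmentation with *no* uterus or tumor
pixels at all raises an error rather than coercing to 0, so segmentation
failures (e.g. a distractor-confused model) surface instead of silently
reading as stage IA.

Per sequence, the cohort's (TUR, stage) pairs define an ROC under the
decision rule "call IB when TUR ≥ t", with operating points at every
distinct score. The AUC is the trapezoid area, which equals the
Mann–Whitney U statistic with ties counted ½ (verified exactly against an
all-pairs count in the tests). The staging criterion maximizes Youden's
J = sensitivity + specificity − 1; ties break toward the smallest
threshold, favouring sensitivity. IB is the positive class throughout —
its mean TUR is larger in every sequence, which fixes the orientation of
the decision rule.

Votes from the three sequences (axial T2WI, axial DWI, sagittal T2WI) are
fused by a parameterized k-of-n rule: call IB when at least k sequences
vote IB. k = 1 maximizes sensitivity, k = n specificity. Published
multi-sequence operating points are label-ambiguous about which class the
votes reference, so the rule is exposed fully parameterized rather than
hard-coding one reading.

A two-Gaussian score model serves as the analytic oracle for all of this:
if the stage-conditional TUR distributions are N(μ₀, σ₀²) and N(μ₁, σ₁²),
the AUC is Φ((μ₁ − μ₀)/√(σ₀² + σ₁²)). Empirical cohort AUCs from the
truncated sampler match this closed form to within ±0.01 at the default
parameters (truncation bias is small there; it grows if μ/σ push real mass
outside [0, 1]).

## The phantom generator

The generator emulates exactly the features the downstream stages are
sensitive to, and nothing else:

- **Geometry.** One uterus per slice — a random filled ellipse covering
  5–50% of the image (axis ratio 0.55–0.95, random orientation, fully
  interior) — and one connected tumor grown inside it by randomized
  dilation from a deep interior seed, stopped at exactly
  round(TUR · organ area) pixels. The realized mask TUR is therefore
  within 1/(organ area) of the intended draw, far inside the ±0.01
  contract. Randomized dilation produces irregular outlines, emulating the
  variable tumor shapes that make tumors harder to segment than the organ.
- **Score distributions.** Intended TURs are drawn from stage- and
  sequence-conditional normals whose defaults are the clinically observed
  moments (axial T2WI 0.165 ± 0.083 / 0.307 ± 0.112; axial DWI
  0.190 ± 0.077 / 0.335 ± 0.117; sagittal T2WI 0.103 ± 0.077 /
  0.334 ± 0.125), rejection-truncated to (0.02, 0.95): the normals put a
  little mass below zero, and rejection keeps the moments nearly intact
  while guaranteeing every draw is renderable.
- **Appearance.** Per-class mean intensities with sequence-dependent
  contrast (tumor brightest on DWI, reflecting diffusion restriction at
  high b-value; background < uterus < tumor everywhere), plus additive
  Gaussian noise (default SD 6 on the 8-bit scale). No published appearance
  statistics exist for this choice; the contrast table is a free modelling
  decision and is exposed as a constant.
- **Confounds.** Optionally (off by default; `distractor_preset` turns it
  on) a bright blob with tumor-like intensity is placed outside the uterus
  and labelled background — the pelvic-effusion failure mode that fools
  intensity-driven tumor segmentation.

What the phantom does **not** model: anatomy beyond one organ and one
lesion, acquisition physics, partial-volume effects, intensity
inhomogeneity, multi-slice 3-D structure, or inter-patient appearance
variability. Passing tests on phantoms therefore demonstrate that the
pipeline's machinery is correct and well calibrated, not that the
segmenter would reach clinical accuracy on real MRI.

One slice per sequence per patient mirrors the clinical workflow of
staging from a single well-chosen slice; multi-slice patients are out of
scope.

## The segmenter

A U-net sized for CPUs: per level two same-padded 3×3 convolutions with
ReLU, 2×2 max-pool on the way down (channels double per level), learned
2×2 transposed convolution on the way up (channels halve) with skip
concatenation, and a final 1×1 convolution to three class scores.
Same-padding is a deliberate deviation from the classic unpadded variant:
the output grid matches the input exactly, removing crop bookkeeping, and
predictions are full-size overlays either way. Implemented in numpy
(im2col + BLAS matmul, manual backpropagation) because the target scale —
64–128 px slices, tens of training images — does not need a GPU framework.

Training: pixel-wise 3-class cross-entropy (unweighted by default; a
class-weight option exists for the strong background imbalance), Adam at
learning rate 3·10⁻⁴, early stopping on validation loss with configurable
patience, best-validation weights restored at the end. Horizontal-flip
augmentation is available behind a flag and off by default. All
randomness — initialization, shuffling, augmentation — derives from the
single config seed; identical seeds give bit-identical training histories.
Prediction is per-pixel argmax with ties resolved toward the lower class
index (so an all-zero network yields all-background, never spurious
tumor).

Defaults are desk-scale (128 px, base 16 channels, batch 4, patience 20,
at most 300 epochs); the scaled-down experiments in the test suite use
64 px / depth 3 / base 8 (40 training slices, where held-out organ DSC
reaches ≈ 0.99 and tumor ≈ 0.89, reproducing the organ-easier-than-tumor
ordering seen clinically) and 32 px / depth 2 for smoke tests. Small
tumors at coarse resolution are the hard regime: with very few training
slices the optimizer can settle into under-segmenting the tumor class, so
cohort sizes in the examples were chosen at the 40-slice scale where
training is reliable.

## Masks, annotations, splits

Label masks use codes 0 = background, 1 = uterus, 2 = tumor. Polygon
annotations follow the LabelMe JSON convention (0-based, x = column,
y = row); rasterization fills by the even-odd rule at integer pixel
centers with boundary pixels included, and paints tumor after uterus so
the nested tumor wins where polygons overlap. Inclusive boundary fill is
stated explicitly so DSC and TUR values recomputed from rasterized masks
are bit-reproducible; the implementation is verified against an
independent point-in-polygon oracle.

For the Dice coefficient, uterus membership is the whole organ — pixels
labelled uterus *or* tumor — because ground truth draws the tumor inside
the organ outline and organ overlap is only well defined on the full
region; a strict uterus-label-only mode exists. Both-empty sets score
DSC = 1 (perfect agreement on absence); empty-reference/non-empty
prediction scores 0. Group comparisons default to the Welch
unequal-variance t-test (two-sided), with paired and pooled variants
available.

Dataset splits are patient-level (never slice-level) in a 6:1:3
train/validation/test ratio by default, with partition sizes fixed by
largest-remainder apportionment — 117 patients yield 70/12/35 — and the
assignment determined by a seeded shuffle.

## Pipeline and reproducibility

`run_pipeline` chains phantom → split → per-sequence training (one model
per sequence by default; a joint model is a switch) → segmentation → DSC +
TUR tables → per-sequence ROC → fused staging report. Design choices worth
stating:

- Every patient is segmented and appears in the staging report; ROC
  criteria and the performance summary use the test partition only,
  mirroring a held-out evaluation. (Selecting criteria on the same
  held-out cohort one evaluates on is methodologically generous; the
  engine simply reproduces that protocol.)
- A slice whose predicted mask is empty gets TUR = NaN, is logged, and is
  excluded from ROC fitting; its staging vote defaults to IA. The
  low-level `compute_tur` still raises on empty input.
- Per-stage seeds derive from the master seed as the first four bytes of
  blake2b("turstage:<seed>:<stage>") mod 2³¹, so any stage can be re-run
  in isolation. Two runs with one master seed produce byte-identical
  outputs, PNGs included.
- Configuration is validated strictly (unknown keys rejected, offending
  field named); an empty document is the all-defaults run.

## Numerical conventions

- ROC thresholds are the distinct observed scores; "IB iff TUR ≥ t".
- Youden ties → smallest threshold; argmax ties in prediction → lowest
  class index; max-pool ties → first element.
- Sample SD uses the n−1 denominator; an n = 1 group reports SD 0.
- Sensitivity/specificity with an absent denominator class are reported as
  NaN, never 0.
- Acceptance-style simulations use 10,000 draws per class, where the
  Monte-Carlo SE of the AUC is ≈ 0.003.

## Known limitations

The phantom's simplicity means segmentation results on it say nothing
quantitative about clinical MRI. The numpy U-net is single-threaded-BLAS
fast but not suited to 512-px clinical resolution or large cohorts. The
fusion engine does not model per-patient correlation between sequences
(published multi-sequence rows depend on the joint error structure of the
clinical cohort, which is not reproducible from printed summaries).
Bootstrap confidence intervals beyond the basic machinery, surface-distance
metrics, DICOM ingestion and 3-D segmentation are out of scope.
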