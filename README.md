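# turstage

Automatic staging of early endometrial cancer (EC) from MRI slices via a
simple, interpretable imaging biomarker: the **tumor-to-uterus area ratio
(TUR)**.

Early EC is staged by how deeply the tumor invades the uterine muscle wall:
stage IA (< 50% myometrial invasion) has a markedly better prognosis and a
lighter treatment than stage IB (≥ 50%). On a well-chosen MRI slice, a
deeply invasive tumor occupies a larger fraction of the organ cross-section,
so the pixel-area ratio

```
TUR = |tumor| / (|tumor| + |uterus|)
```

computed from a semantic segmentation of the slice separates the two stages.
The package implements the full chain:

1. **Segmentation** — a U-net (encoder–decoder with skip connections,
   two 3×3 conv + ReLU per level, 2×2 max-pool down / learned 2×2
   up-convolution, final 1×1 conv to 3 classes) labels each pixel
   background / uterus / tumor. Implemented in pure numpy with manual
   backpropagation and Adam — no GPU framework needed at desk scale.
2. **Evaluation** — Dice similarity coefficient DSC = 2|X∩Y| / (|X|+|Y|)
   per structure, cohort summaries, and Welch t-tests between groups.
3. **Staging** — per-sequence ROC over cohort TUR scores (trapezoid AUC,
   identical to the tie-corrected Mann–Whitney U statistic), Youden-optimal
   criterion J = sensitivity + specificity − 1, the decision rule
   "stage IB iff TUR ≥ criterion", and k-of-n fusion of the votes from the
   three MRI sequences (axial T2WI, axial DWI, sagittal T2WI).
4. **Phantom** — a synthetic pelvic-slice generator whose stage-conditional
   TUR distributions default to the values observed clinically (e.g.
   sagittal T2WI: IA 0.103 ± 0.077, IB 0.334 ± 0.125), with
   sequence-dependent contrast, noise, and an optional bright
   pelvic-effusion-like distractor outside the uterus. Every stage of the
   pipeline is therefore testable end to end without clinical data.

It is aimed at researchers in quantitative MRI / radiomics who want a
transparent, fully reproducible reference implementation of area-ratio
staging, and at developers who need a controllable synthetic benchmark for
2-D organ+lesion segmentation.

## Worked example

```python
import numpy as np
from turstage import (DEFAULT_TUR_MOMENTS, TurRecord, gaussian_auc,
                      roc_curve, simulate_tur_cohort)

mu0, sd0, mu1, sd1 = DEFAULT_TUR_MOMENTS["sagittal_t2w"]
ia, ib = simulate_tur_cohort(mu0, sd0, mu1, sd1, 10_000, 10_000,
                             np.random.default_rng(20))
records = ([TurRecord(f"ia{i}", "sagittal_t2w", float(v), "IA")
            for i, v in enumerate(ia)]
           + [TurRecord(f"ib{i}", "sagittal_t2w", float(v), "IB")
              for i, v in enumerate(ib)])
roc = roc_curve(records)
print(f"AUC {roc.auc:.3f}  (closed form {gaussian_auc(mu0, sd0, mu1, sd1):.3f})")
print(f"criterion {roc.criterion:.3f}  "
      f"sens {roc.sens_at_criterion:.3f}  spec {roc.spec_at_criterion:.3f}")
```

prints

```
AUC 0.937  (closed form 0.942)
criterion 0.211  sens 0.835  spec 0.912
```

i.e. with the sagittal-T2WI stage-conditional TUR distributions, the ratio
alone separates IA from IB with an AUC of ~0.94, and the Youden-optimal
staging threshold sits near TUR ≈ 0.2 — a tumor filling about a fifth of
the organ cross-section reads as deep invasion.

The `examples/` directory holds one short script per capability (phantom
cohorts, LabelMe rasterization, U-net training, ROC staging and fusion, the
full pipeline); each prints what it computes and what the numbers mean.
A thin CLI mirrors the library:

```bash
turstage phantom --n-ia 22 --n-ib 13 --seed 7 --out cohort/
turstage run --out run/ --seed 17     # full pipeline on phantom data
```

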