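"""Train the U-net segmenter on a small phantom set and score it.

Desk-scale run (32x32 slices, depth-2 network, ~30 s): trains on the
sagittal sequence of 10 phantom patients and reports held-out Dice
similarity coefficients (DSC) for the organ and the tumor.
"""

import numpy as np

from turstage import (
    UnetConfig,
    build_unet,
    default_params,
    dsc,
    predict_mask,
    sample_cohort,
    split_dataset,
    train,
)

cases = sample_cohort(9, 6, default_params(image_size=32), seed=2)
split = split_dataset([c.patient_id for c in cases], (10, 2, 3), seed=0)
by_id = {c.patient_id: c for c in cases}

def pairs(ids):
    return [(by_id[i].slices["sagittal_t2w"].image.pixels,
             by_id[i].slices["sagittal_t2w"].mask) for i in ids]

config = UnetConfig(depth=2, base_channels=8, in_size=32,
                    max_epochs=80, patience=12, batch_size=4, seed=0)
model, history = train(build_unet(config), pairs(split.train),
                       pairs(split.validation), config)
print(f"stopped after epoch {history.stopped_epoch} "
      f"(best validation loss at epoch {history.best_epoch})")

for pid in split.test:
    img, mask = pairs([pid])[0]
    pred = predict_mask(model, img)
    print(f"{pid}: uterus DSC {dsc(mask, pred, 'uterus'):.3f}, "
          f"tumor DSC {dsc(mask, pred, 'tumor'):.3f}")

print("\nDSC of 1.0 is perfect overlap; the organ is typically segmented")
print("better than the irregular tumor, matching clinical experience.")
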