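"""Generate a synthetic pelvic cohort and inspect its TUR distributions.

Each phantom patient carries one slice per MRI sequence (axial T2WI, axial
DWI, sagittal T2WI); the tumor-to-uterus area ratio (TUR) of each slice is
drawn from that sequence's stage-conditional distribution, so stage IB
patients systematically show larger ratios than stage IA patients.
"""

import numpy as np

from turstage import SEQUENCES, default_params, sample_cohort, write_cohort

cases = sample_cohort(n_ia=22, n_ib=13, params=default_params(image_size=64), seed=7)
manifest = write_cohort(cases, "scratch/example_cohort")
print(f"wrote {len(cases)} patients (3 slices each) -> {manifest}\n")

print(f"{'sequence':>14}  {'IA mean TUR':>11}  {'IB mean TUR':>11}")
for seq in SEQUENCES:
    ia = [c.slices[seq].intended_tur for c in cases if c.stage == "IA"]
    ib = [c.slices[seq].intended_tur for c in cases if c.stage == "IB"]
    print(f"{seq:>14}  {np.mean(ia):11.3f}  {np.mean(ib):11.3f}")

print("\nIB tumors occupy roughly twice the organ fraction of IA tumors —")
print("that separation is what threshold-based staging exploits.")
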