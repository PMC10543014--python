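"""Generate a long-tailed multi-label dataset and inspect its structure.

Builds a 10-class scenario whose prevalence spans two orders of magnitude,
with one requested co-occurring pair, then prints the realized class
counts, the empirical IoU of the requested pair, and the patient-level
split sizes.
"""

import numpy as np

from pruneaudit.synth import generate_dataset, sample_class_structure

structure = sample_class_structure(
    C=10,
    head_prevalence=0.3,
    tail_prevalence=0.005,
    cooccur_pairs=[(2, 3, 0.7)],  # classes 2 and 3 co-occur strongly
    seed=0,
)
ds = generate_dataset(structure, N=3000, D=32, noise_sd=1.0, seed=0)

print("requested prevalence:", np.round(structure.prevalence, 4))
print("realized counts:     ", ds.class_counts())
lab = ds.labels.astype(bool)
iou_23 = (lab[:, 2] & lab[:, 3]).sum() / (lab[:, 2] | lab[:, 3]).sum()
iou_24 = (lab[:, 2] & lab[:, 4]).sum() / (lab[:, 2] | lab[:, 4]).sum()
print(f"IoU(2,3) = {iou_23:.3f} (requested 0.7 latent corr)")
print(f"IoU(2,4) = {iou_24:.3f} (independent baseline)")
for split in ("train", "val", "test"):
    print(f"{split}: {(ds.split == split).sum()} samples")

# Counts fall off by ~1.6x per class (log-linear tail); the requested pair's
# IoU is far above the independent baseline; the 70/10/20 split is exact up
# to one patient group, and no patient appears in two splits.
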