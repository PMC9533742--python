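"""Simulate synthetic scattering frames and build the augmented strip set.

Each 512 x 512 frame pair (masked input, ground truth) is cropped into 7
overlapping 512 x 128 strips; the 4 strips crossing a vertical detector
gap are discarded, and each survivor receives an artificial vertical gap
at one of the column positions the true gaps occupy - yielding exactly 3
training pairs per frame, with vertical-gap ground truth the real data
lacks.
"""

import numpy as np

from scattergap import (
    PILATUS3_2M,
    augment_dataset,
    build_full_mask,
    rescale_mask,
    simulate_dataset,
)

mask512 = rescale_mask(build_full_mask(PILATUS3_2M), 512, 512)
masked, truth = simulate_dataset(4, mask512, seed=42)
print(f"simulated {len(masked)} frame pairs at {masked.shape[1]} x {masked.shape[2]}")
print(f"mean intensity over horizontal gap bands (truth): "
      f"{truth[:, mask512.horizontal_only().raster].mean():.4f}")

pairs = augment_dataset(list(zip(masked, truth)), mask512, np.random.default_rng(0))
print(f"\naugmented pairs: {len(pairs)} (= 3 per frame)")
for p in pairs[:3]:
    gap = "none" if p.artificial_gap is None else f"cols [{p.artificial_gap[0]}, {p.artificial_gap[1]})"
    print(f"  frame {p.parent_id}, strip offset {p.offset:3d}, artificial gap: {gap}")

# 4641 frames would yield 3 * 4641 = 13923 augmented pairs, the size of the
# full-scale training set this pipeline is designed around.
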