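"""Generate a labeled LEAN/MASH synthetic cohort and inspect its ground truth.

The LEAN preset emulates a healthy microtissue (sparse, fine, short
fibrils); the MASH preset a steatohepatitic one (dense, wide, long,
reticulated networks).  The generator returns truth masks and per-fiber
geometry alongside each image.
"""

import numpy as np

import fibroquant as fq

samples = fq.make_cohort(n_per_group=4, base_seed=7)

print(f"{'sample':<10} {'group':<6} {'fibers':>6} {'truth area ratio':>17}")
for s in samples:
    print(f"{s.sample_id:<10} {s.group:<6} {len(s.fibers_truth):>6} "
          f"{s.truth_collagen_area_ratio:>17.4f}")

by_group = {}
for s in samples:
    by_group.setdefault(s.group, []).append(s.truth_collagen_area_ratio)
for group, ratios in by_group.items():
    print(f"mean truth collagen area ratio [{group}]: {np.mean(ratios):.4f}")

# The MASH group deposits several-fold more collagen than LEAN — the truth
# masks are the oracle every downstream detection stage is tested against.
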