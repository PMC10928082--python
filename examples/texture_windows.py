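"""Architecture features: 25 um computational windows and GLCM texture.

Tiles a microtissue into fixed 25 um x 25 um windows and computes, per
window, GLCM entropy, inertia (contrast), correlation and homogeneity on
the quantized collagen OD channel, plus the collagen area fraction.
"""

import fibroquant as fq
from fibroquant.architecture import glcm_features, summarize_architecture, tile_windows
from fibroquant.stain import default_stain_profile

sample = fq.render_sample(fq.MASH_PRESET, rng_seed=3)
profile = default_stain_profile()
od = fq.separate_collagen(fq.rgb_to_od(sample.image, profile), profile)
region = fq.find_microtissues(sample.image)[0]
mask = fq.segment_collagen(od, region)

grid = tile_windows(region.tissue_mask, pixel_size_um=1.0, window_side_um=25.0)
print(f"window side: {grid.side_px} px; included windows: {len(grid.included_windows)}")

features = [
    glcm_features(od.collagen[r0:r1, c0:c1], mask.mask[r0:r1, c0:c1], row=i, col=j)
    for i, j, (r0, c0, r1, c1) in grid.included_windows
]
summary = summarize_architecture(features)
for name, stats in summary.feature_stats.items():
    print(f"{name:<24} mean {stats['mean']:>8.4f}  sd {stats['sd']:>8.4f}")
print(f"uniform-inertia windows:    {summary.frac_uniform:.2f}")
print(f"contrasted-inertia windows: {summary.frac_contrasted:.2f}")

# High-inertia ("contrasted") windows mark strong local collagen texture;
# uniform windows are collagen-free or evenly stained tissue.
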