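# fibroquant

Single-fiber phenotypic quantification of fibrosis in Sirius Red (SR)
stained liver microtissue histology.

Semiquantitative pathologist scoring of fibrosis is coarse and variable,
and a plain collagen-area ratio is too blunt to resolve mild anti-fibrotic
drug effects in 3D liver microtissue (MASH) models. `fibroquant` implements
an open, testable version of the single-fiber phenotypic pipeline used for
that problem: it turns an RGB brightfield image of an SR-stained
microtissue section into per-fiber and per-window **quantitative fibrosis
traits (qFTs)** and aggregates them into a normalized continuous severity
score, the **phenotypic fibrosis composite score (Ph-FCS, 1–10)** with
collagen-content, morphometric and architecture sub-scores.

## Method

1. **Stain separation.** Intensities are converted to optical density under
   Beer–Lambert, `OD_c = −log10(I_c / I0_c)`, and each pixel's OD vector is
   decomposed by least squares onto a two-stain basis {SR collagen vector,
   residual vector}; the non-negative SR coefficient is the collagen
   channel.
2. **Detection.** Microtissues are found by color distance from the slide
   background; regions smaller than 50% of the batch-mean area are excluded
   (adequacy rule). Collagen is segmented by Otsu thresholding (with an OD
   floor) inside the tissue, and the mask is thinned to a skeleton graph of
   junction nodes (≥3 neighbors, merged within 2 px), endpoints and
   branches.
3. **Morphometry.** Each 8-connected collagen component is measured
   (skeleton length, width = area/length, area, perimeter, area/perimeter
   ratio, branch/node/endpoint counts, mean OD) and classified **fine**
   (small, narrow, minimally branched) or **assembled** (reticulated or
   long-and-thick).
4. **Architecture.** The tissue is tiled into 25 µm × 25 µm computational
   windows; per window a symmetric gray-level co-occurrence matrix of the
   quantized collagen channel yields entropy, inertia (contrast),
   correlation and homogeneity, plus the collagen area fraction.
5. **qFTs and scores.** The default catalog holds 32 traits (12 collagen
   content, 13 morphometry, 7 architecture), expanded by statistics
   {mean, median, sd, kurtosis, skew} and fine/assembled strata into 192
   qFTs per sample. Traits significantly altered versus the LEAN control
   (per-qFT Welch t-test, p ≤ α) are direction-aligned, min-max normalized
   over the cohort, and averaged: sub-FCS = 1 + 9·mean(u), Ph-FCS = mean of
   the sub-scores. Group contrasts use Welch's heteroscedastic one-way
   ANOVA with Šidák-adjusted pairwise Welch tests.

A synthetic microtissue generator (`fibroquant.synth`) renders SR-like
images with full ground truth (tissue mask, collagen mask, per-fiber
geometry) under LEAN/MASH presets, so every stage has an oracle.

## Worked example

```python
import fibroquant as fq
from fibroquant import PipelineConfig, pipeline

config = PipelineConfig(pixel_size_um=1.0)           # synthetic renders are 1 µm/px
samples = fq.make_cohort(n_per_group=8, base_seed=5) # 8 LEAN + 8 MASH images
measurements, qc = pipeline.quantify_cohort(samples, config)
table = pipeline.cohort_qft_table(measurements)      # 16 samples × 192 qFTs
out = pipeline.score_cohort(table, config)
print(out.scores.groupby("group")["ph_fcs"].mean())
```

prints (see `examples/score_cohort.py` for the full script):

```
selected qFTs (p <= 0.05): 106 (collagen 9, morphometric 76, architecture 21)

group-mean composite scores (1-10):
       ph_fcs  collagen_fcs  morphometric_fcs  architecture_fcs
group
LEAN     2.41          1.41              2.23              3.59
MASH     7.23          6.72              6.87              8.10

Welch ANOVA on Ph-FCS: F = 85.59, df = (1, 9.3), p = 5.54e-06
```

106 of the 192 qFTs separate the groups at α = 0.05; the diseased (MASH)
group scores near the top of the 1–10 severity scale on every sub-phenotype
while the healthy (LEAN) control stays near the bottom, and the group
difference in Ph-FCS is highly significant.

The `examples/` directory has one short script per capability (simulation,
per-fiber quantification, window texture, cohort scoring). A thin CLI wraps
the same pipeline: `fibroquant simulate | quantify | score`.

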