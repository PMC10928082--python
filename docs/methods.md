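# Methods

This note documents the models, conventions and free parameters behind
`fibroquant`, the design choices made where the underlying phenotypic
fibrosis-quantification method leaves the design open, and the limits of
what the synthetic validation shows.

## Stain model

Brightfield intensities are mapped to optical density per channel,
`OD_c = −log10(max(I_c, 1) / I0_c)`, clipped at 0. The intensity floor of 1
avoids infinite OD; pixels at or below the floor are flagged saturated
(their OD is a lower bound). The background intensity `I0` defaults to the
per-channel 99th percentile of the image — SR sections are white-balanced,
so the brightest percentile is a robust background estimate — and can be
fixed in the config for batch consistency.

Unmixing uses a **two-stain** linear Beer–Lambert model: the SR protocol
for microtissue sections carries no hematoxylin counterstain, so one
collagen vector plus one residual vector suffice. The default SR vector is
the normalized OD of the render color used by the synthetic generator
(RGB 200/60/60 over white — a literature-style red-stain direction that
absorbs green and blue strongly); the residual is the achromatic direction.
The per-pixel decomposition is ordinary least squares on the 3×2 basis with
the collagen coefficient clipped at 0. Whether the commercial platform uses
linear unmixing is not public; linear unmixing is adopted here without any
claim of equivalence. Automatic stain-vector estimation (Macenko/NMF) is
out of scope; users with real slides should supply a measured vector via
the config.

## Detection and the skeleton graph

Tissue detection thresholds the Euclidean RGB distance from the estimated
background (median of a border frame), default 20 intensity units, then
fills holes and drops components below 500 µm². The adequacy rule excludes
microtissues below 50% of the **batch-mean** area, the mean taken over the
full candidate batch including the regions being judged (the literal
reading of the stated rule); exclusions are logged with the triggering
cutoff.

Collagen segmentation is Otsu within the tissue mask with a floor at
OD 0.15: near-empty control images give Otsu a single noise mode, and the
floor keeps it from splitting that noise. Objects under 5 px (at 1 µm/px,
scaled by (1/pixel_size)²) are removed as sub-resolution specks.

The skeleton graph uses 8-connectivity throughout (standard for thin
structures). Junction pixels are skeleton pixels with ≥3 skeleton
neighbors; thinning produces junction *clusters* at crossings, so junction
pixels within a 2-px radius are merged into one node whose degree is the
number of skeleton arms leaving the cluster. Branches are the maximal
node-free skeleton paths; path length accumulates 1 per axial and √2 per
diagonal step, times the pixel size. Skeletonization erodes roughly one
half-width from each fiber end, which the bar-fixture tests bound at 10%.

The "single fiber" unit is ambiguous in the source method (connected
component vs skeleton branch); this package reports both levels — the
component is the morphometric unit, branch/node counts are traits on it.

## Morphometry and the fine/assembled boundary

Width follows a ribbon model, area / skeleton length, with a
distance-transform fallback (2 × mean EDT) for components whose skeleton is
empty. Perimeter is the exposed-pixel-edge count × pixel size — exact on
axis-aligned fixtures, which keeps the analytic tests sharp; it
overestimates smooth-boundary perimeter by up to ~√2 relative to a
marching-squares contour, a documented convention rather than an error.

The fine/assembled boundary is qualitative in the source method
("assembled" = reticulated, long, thick, many nodes). The rule here is:
assembled iff `n_nodes ≥ 2` **or** (`length ≥ 30 µm` **and**
`width ≥ 3 µm`); all three thresholds are configurable and recorded in
output metadata. On synthetic cohorts generated with branch rate 0 and
sub-threshold widths, ≥95% of detected fibers classify fine (tested).

## Architecture windows

Windows are 25 µm × 25 µm, side `round(25 / pixel_size)` px (113 px at the
0.221 µm/px 40× calibration), anchored at the tissue bounding-box origin;
partial edge windows are dropped and windows with <50% tissue overlap are
excluded, keeping feature support constant across windows. GLCMs are
symmetric, normalized, averaged over offsets {(0,1),(1,0),(1,1),(1,−1)},
on the collagen OD channel linearly quantized to 16 levels over a fixed
[0, 2] OD range (cohort-fixed quantization keeps windows comparable).
"Inertia" is read as GLCM contrast Σ P·(i−j)² — the standard usage — and
entropy is in bits; correlation is defined 0 when a marginal variance
vanishes (a constant window has no measurable linear structure).
Distribution moments use sample sd (n−1), Fisher skew and excess kurtosis,
all 0 by convention when undefined (n too small or zero variance).

## qFT catalog and expansion

The open catalog has exactly 12 collagen-content + 13 morphometric + 7
architecture = 32 traits. The proprietary qFT lists of the commercial
platform (316/336 identifiers) are not public and are not reproduced; the
expansion grid — statistics {mean, median, sd, kurtosis, skew} ×
strata {all, fine, assembled} for per-fiber traits — is configurable so
users can approximate either scale. The default configuration yields
17 + 10·5·3 + 5·5 = 192 qFTs per sample, identical across samples of a
cohort. Statistics over an empty stratum are 0, not missing: the zero is
meaningful (absence of that collagen class) and keeps scoring total. The
method's named qFT facets "severity, progression, distortion, variance"
are interpreted as mean, upper-tail behavior, kurtosis+skew, and sd
respectively; this mapping is an interpretation, not a disclosed formula.

## Selection and composite scores

Selection is a per-qFT Welch two-sample t-test, disease vs reference,
selected iff p ≤ α (default 0.05). No multiplicity correction is applied by
default — the source method reports per-trait significance without stating
one — and Benjamini–Hochberg is available as a flag. Zero-variance traits
with equal means give p = 1 (no evidence) rather than an exception, so the
pipeline is total over degenerate synthetic traits.

Normalization is **per-cohort**: each selected qFT is direction-aligned
(multiplied by the sign of the disease-minus-reference mean difference) and
min-max normalized over the cohort; a sample's sub-FCS is
`1 + 9 · mean(u)` over the sub-phenotype's retained qFTs and the Ph-FCS is
the unweighted mean of the sub-scores present. Equal weighting is a design
choice — the composition of the score is stated in the source but the
weights are not. Whether the commercial score normalizes per-cohort or
against a fixed reference population is not public; per-cohort
normalization is used here, which means scores are comparable **within** a
cohort, not across cohorts — the ladder test therefore scores all density
levels under one pooled normalization model.

The robust ANOVA named in the source conflates two distinct procedures
(Brown–Forsythe vs Welch); Welch's heteroscedastic F with
Welch–Satterthwaite df is implemented (cross-checked against an independent
statistics package in the tests), and Dunnett's T3 is approximated by
Šidák-adjusted pairwise Welch tests — conservative, since the studentized
maximum modulus distribution is impractical to tabulate.

## Synthetic generator

The generator renders a circular tissue disc with a faint tint
(RGB 228/213/209) over a near-white background (247/245/243) — the tint is
what makes the tissue detectable by color distance, standing in for the
eosin-free residual absorbance of real unstained tissue. Fibers are
bounded-curvature random walks (2 µm steps, heading sd 0.25 rad, steered
back at the disc edge, twice 1-2-1 smoothed) with Poisson side branches.
The truth mask is a **hard** stadium rasterization (pixel centers strictly
within width/2 of the centerline, floor of a 1-px line) so truth is binary
and countable; only the RGB render is anti-aliased (Gaussian-softened OD
map, σ 0.7 px) with i.i.d. Gaussian camera noise clipped to [0, 255].

Preset defaults encode the control-vs-disease contrast: LEAN 40 fibers/mm²,
width 1.5 ± 0.3 µm, length 25 ± 8 µm, branch rate 0.2; MASH 160 fibers/mm²,
3.0 ± 0.8 µm, 60 ± 20 µm, branch rate 1.5; tissue radius 150 µm, rendered
at 1 µm/px. The exact values are free parameters chosen once to give a
qualitative fine-vs-reticulated contrast at microtissue scale. What the
generator does **not** emulate: nuclei, steatosis vacuoles, polarized-light
birefringence, stain batch variation, scanner artifacts, touching
microtissues. Passing tests therefore demonstrate the pipeline's internal
correctness and its sensitivity under idealized imaging, not segmentation
performance on real slides.

## Problem sizes and sweeps

The end-to-end contrast uses 8 + 8 microtissues at the default 150 µm
radius (mirroring the ≥7-per-group design of the microtissue experiments).
The robustness sweeps (score bounds; density ladder) use 200 randomized
cohorts of 2 + 2 samples and 20 seeds per ladder level at 60–100 µm tissue
radii — the composite-score bounds are preset-independent by construction,
so smaller randomized tissues exercise them fully; the sweeps select at
α = 1 so that every non-degenerate qFT participates and the bounds are
stressed hardest. The trait-recovery check uses the stated 5-pooled-SD
effect size at n = 8/8 on a synthetic qFT table with known shifted traits.

## Known limitations

- Stain vectors are assumed, not estimated; badly white-balanced or
  counterstained slides need a measured profile.
- Touching fibers are not split beyond connected components + subgraph
  structure; a dense MASH network is one "assembled" component.
- Per-cohort normalization makes Ph-FCS a relative severity; absolute
  cross-study comparison requires a shared reference cohort.
- The Šidák step is an upper bound on T3-adjusted p-values (conservative).
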