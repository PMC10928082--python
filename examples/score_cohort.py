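"""End-to-end severity scoring: synthetic cohort to Ph-FCS group contrast.

Renders 8 LEAN + 8 MASH microtissues, quantifies every sample into a qFT
table, selects the qFTs significantly altered between groups, and
aggregates the normalized composite scores (1-10 scale).
"""

import fibroquant as fq
from fibroquant import PipelineConfig, pipeline

config = PipelineConfig(pixel_size_um=1.0)  # synthetic renders are 1 um/px

samples = fq.make_cohort(n_per_group=8, base_seed=5)
measurements, qc = pipeline.quantify_cohort(samples, config)
table = pipeline.cohort_qft_table(measurements)
print(f"qFT table: {table.shape[0]} samples x {table.shape[1] - 1} qFTs")

out = pipeline.score_cohort(table, config)
counts = out.selection.counts_by_sub_phenotype()
print(f"selected qFTs (p <= {config.alpha}): {len(out.selection.selected_ids)} "
      f"(collagen {counts['collagen']}, morphometric {counts['morphometric']}, "
      f"architecture {counts['architecture']})")

print("\ngroup-mean composite scores (1-10):")
print(out.scores.groupby("group")[["ph_fcs", "collagen_fcs", "morphometric_fcs",
                                   "architecture_fcs"]].mean().round(2))

a = out.anova
print(f"\nWelch ANOVA on Ph-FCS: F = {a.f_statistic:.2f}, "
      f"df = ({a.df1:.0f}, {a.df2:.1f}), p = {a.p_value:.2e}")

# The MASH group scores near the top of the 1-10 severity scale on every
# sub-phenotype; LEAN stays near the bottom — the synthetic analog of the
# disease-vs-control contrast the score is designed to resolve.
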