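"""Quantitative fibrosis traits (qFTs): catalog, expansion and cohort table.

A qFT is one continuous per-sample variable derived from a phenotypic trait
by applying a statistical feature (mean, median, sd, kurtosis, skew) and,
for per-fiber traits, a fine/assembled/all stratum.  The default open
catalog carries the documented 12 collagen-content + 13 morphometric + 7
architecture = 32 traits; the proprietary trait identifiers of commercial
platforms are not reproduced, but the expansion grid is configurable so the
resulting qFT vector can be scaled up or down.

Interpretation note: "severity, progression, distortion and variance" of a
trait distribution are represented here by the mean, the 95th-percentile
tail (captured through median+skew), kurtosis+skew, and the sample sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import ArchitectureSummary, WindowFeatures, descriptive_stats
from .morphometry import FiberMorphometry

__all__ = [
    "Trait",
    "TraitCatalog",
    "ExpansionGrid",
    "QFTVector",
    "SampleMeasurements",
    "catalog_default",
    "expand_qfts",
    "qft_table",
]

STATISTICS = ("mean", "median", "sd", "kurtosis", "skew")
STRATA = ("all", "fine", "assembled")


@dataclass(frozen=True)
class Trait:
    trait_id: str
    sub_phenotype: str  # collagen | morphometric | architecture
    level: str  # sample | per_fiber | per_window
    stratification: str  # all | none (per_fiber traits stratify by fiber class)


@dataclass
class TraitCatalog:
    traits: list[Trait]

    def counts(self) -> tuple[int, int, int]:
        subs = [t.sub_phenotype for t in self.traits]
        return (
            subs.count("collagen"),
            subs.count("morphometric"),
            subs.count("architecture"),
        )

    def by_level(self, level: str) -> list[Trait]:
        return [t for t in self.traits if t.level == level]


@dataclass(frozen=True)
class ExpansionGrid:
    statistics: tuple[str, ...] = STATISTICS
    strata: tuple[str, ...] = STRATA


@dataclass
class QFTVector:
    sample_id: str
    group: str | None
    values: dict[str, float]


@dataclass
class SampleMeasurements:
    """Everything measured on one sample, input to qFT expansion."""

    sample_id: str
    group: str | None
    pixel_size_um: float
    tissue_area_um2: float
    fibers: list[tuple[FiberMorphometry, str]]  # (morphometry, "fine"|"assembled")
    window_features: list[WindowFeatures]
    architecture: ArchitectureSummary | None


# Per-fiber morphometric traits, read off FiberMorphometry attributes.
_PER_FIBER_TRAITS = {
    "skeleton_length_um": "skeleton_length_um",
    "width_um": "width_um",
    "area_um2": "area_um2",
    "perimeter_um": "perimeter_um",
    "ap_ratio_um": "ap_ratio_um",
    "n_branches": "n_branches",
    "n_nodes": "n_nodes",
    "n_endpoints": "n_endpoints",
    "mean_collagen_od": "mean_collagen_od",
    "elongation": "elongation",
}

_PER_WINDOW_TRAITS = (
    "entropy",
    "inertia",
    "correlation",
    "homogeneity",
    "collagen_area_fraction",
)


def catalog_default() -> TraitCatalog:
    """The documented open 32-trait catalog (12 collagen / 13 morphometric / 7 architecture)."""
    traits: list[Trait] = []
    for tid in (
        "total_collagen_area_ratio",
        "fine_collagen_area_ratio",
        "assembled_collagen_area_ratio",
        "collagen_density_area_ratio",
        "fine_density_ratio",
        "assembled_density_ratio",
        "fiber_count_per_mm2",
        "fine_fiber_fraction",
        "assembled_fiber_fraction",
        "skeleton_node_density",
        "skeleton_branch_density",
        "collagen_structure_index",
    ):
        traits.append(Trait(tid, "collagen", "sample", "none"))
    for tid in _PER_FIBER_TRAITS:
        traits.append(Trait(tid, "morphometric", "per_fiber", "all"))
    for tid in (
        "total_skeleton_length_um",
        "total_fine_skeleton_length_um",
        "total_assembled_skeleton_length_um",
    ):
        traits.append(Trait(tid, "morphometric", "sample", "none"))
    for tid in _PER_WINDOW_TRAITS:
        traits.append(Trait(tid, "architecture", "per_window", "none"))
    for tid in ("frac_uniform", "frac_contrasted"):
        traits.append(Trait(tid, "architecture", "sample", "none"))
    return TraitCatalog(traits=traits)


def _sample_level_value(trait_id: str, m: SampleMeasurements) -> float:
    fibers = m.fibers
    areas = np.array([f.area_um2 for f, _ in fibers]) if fibers else np.zeros(0)
    labels = [lab for _, lab in fibers]
    fine = np.array([lab == "fine" for lab in labels], dtype=bool)
    tissue = m.tissue_area_um2
    od_weight = (
        np.array([f.mean_collagen_od * f.area_um2 for f, _ in fibers])
        if fibers
        else np.zeros(0)
    )
    skel = np.array([f.skeleton_length_um for f, _ in fibers]) if fibers else np.zeros(0)
    n_fibers = len(fibers)
    tissue_mm2 = tissue / 1e6

    if trait_id == "total_collagen_area_ratio":
        return float(areas.sum() / tissue) if tissue else 0.0
    if trait_id == "fine_collagen_area_ratio":
        return float(areas[fine].sum() / tissue) if tissue else 0.0
    if trait_id == "assembled_collagen_area_ratio":
        return float(areas[~fine].sum() / tissue) if tissue else 0.0
    if trait_id == "collagen_density_area_ratio":
        return float(od_weight.sum() / tissue) if tissue else 0.0
    if trait_id == "fine_density_ratio":
        return float(od_weight[fine].sum() / tissue) if tissue else 0.0
    if trait_id == "assembled_density_ratio":
        return float(od_weight[~fine].sum() / tissue) if tissue else 0.0
    if trait_id == "fiber_count_per_mm2":
        return n_fibers / tissue_mm2 if tissue_mm2 else 0.0
    if trait_id == "fine_fiber_fraction":
        return float(fine.sum() / n_fibers) if n_fibers else 0.0
    if trait_id == "assembled_fiber_fraction":
        return float((~fine).sum() / n_fibers) if n_fibers else 0.0
    if trait_id == "skeleton_node_density":
        n_nodes = sum(f.n_nodes for f, _ in fibers)
        return n_nodes / tissue_mm2 if tissue_mm2 else 0.0
    if trait_id == "skeleton_branch_density":
        n_branches = sum(f.n_branches for f, _ in fibers)
        return n_branches / tissue_mm2 if tissue_mm2 else 0.0
    if trait_id == "collagen_structure_index":
        fine_area = float(areas[fine].sum())
        return float(areas[~fine].sum() / fine_area) if fine_area > 0 else 0.0
    if trait_id == "total_skeleton_length_um":
        return float(skel.sum())
    if trait_id == "total_fine_skeleton_length_um":
        return float(skel[fine].sum())
    if trait_id == "total_assembled_skeleton_length_um":
        return float(skel[~fine].sum())
    if trait_id == "frac_uniform":
        return m.architecture.frac_uniform if m.architecture else 0.0
    if trait_id == "frac_contrasted":
        return m.architecture.frac_contrasted if m.architecture else 0.0
    raise KeyError(f"unknown sample-level trait {trait_id!r}")


def expand_qfts(
    measurements: SampleMeasurements,
    catalog: TraitCatalog | None = None,
    grid: ExpansionGrid = ExpansionGrid(),
) -> QFTVector:
    """Expand a sample's measurements into its full qFT vector.

    Per-fiber traits produce one qFT per (statistic, stratum); per-window
    traits one per statistic; sample-level traits exactly one.  Statistics
    over an empty fiber stratum are 0 by convention — the zero is meaningful
    (absence of that collagen class), and it keeps score aggregation total.
    """
    catalog = catalog or catalog_default()
    values: dict[str, float] = {}

    for trait in catalog.traits:
        if trait.level == "sample":
            tid = f"{trait.sub_phenotype}.{trait.trait_id}"
            values[tid] = _sample_level_value(trait.trait_id, measurements)
        elif trait.level == "per_fiber":
            attr = _PER_FIBER_TRAITS[trait.trait_id]
            for stratum in grid.strata:
                pool = [
                    getattr(f, attr)
                    for f, lab in measurements.fibers
                    if stratum == "all" or lab == stratum
                ]
                stats_map = (
                    descriptive_stats(np.array(pool))
                    if pool
                    else {s: 0.0 for s in STATISTICS}
                )
                for stat in grid.statistics:
                    values[f"{trait.sub_phenotype}.{trait.trait_id}.{stat}.{stratum}"] = (
                        stats_map[stat]
                    )
        elif trait.level == "per_window":
            pool = [getattr(w, trait.trait_id) for w in measurements.window_features]
            stats_map = (
                descriptive_stats(np.array(pool)) if pool else {s: 0.0 for s in STATISTICS}
            )
            for stat in grid.statistics:
                values[f"{trait.sub_phenotype}.{trait.trait_id}.{stat}"] = stats_map[stat]
        else:
            raise ValueError(f"unknown trait level {trait.level!r}")

    # Totality contract: every entry finite.
    for k, v in values.items():
        if not np.isfinite(v):
            values[k] = 0.0
    return QFTVector(
        sample_id=measurements.sample_id, group=measurements.group, values=values
    )


def expected_qft_count(
    catalog: TraitCatalog | None = None, grid: ExpansionGrid = ExpansionGrid()
) -> int:
    """Closed-form qFT count of a (catalog, grid) configuration."""
    catalog = catalog or catalog_default()
    n = len(catalog.by_level("sample"))
    n += len(catalog.by_level("per_fiber")) * len(grid.statistics) * len(grid.strata)
    n += len(catalog.by_level("per_window")) * len(grid.statistics)
    return n


def qft_table(vectors: list[QFTVector]) -> pd.DataFrame:
    """Samples x qFTs table with a ``group`` column, stable column order."""
    if not vectors:
        raise ValueError("qft_table requires at least one sample")
    columns = list(vectors[0].values.keys())
    for v in vectors[1:]:
        if list(v.values.keys()) != columns:
            raise ValueError(
                f"inconsistent qFT sets across samples (sample {v.sample_id!r})"
            )
    df = pd.DataFrame(
        [[v.values[c] for c in columns] for v in vectors],
        index=[v.sample_id for v in vectors],
        columns=columns,
    )
    df.insert(0, "group", [v.group for v in vectors])
    df.index.name = "sample_id"
    return df


def sub_phenotype_of(qft_id: str) -> str:
    """Sub-phenotype prefix of a qFT identifier."""
    return qft_id.split(".", 1)[0]
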