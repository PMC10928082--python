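"""End-to-end orchestration: image -> measurements -> qFT table -> scores.

``quantify_cohort`` runs deconvolution, microtissue detection, the batch
adequacy filter, collagen segmentation, skeleton-graph morphometry and
window texture for a list of calibrated images, and returns per-sample
measurements.  ``score_cohort`` turns a qFT table into trait selection,
composite scores and the group statistics report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import architecture, detect, morphometry, qft, scoring, stain
from .config import PipelineConfig

__all__ = [
    "load_image",
    "quantify_image_batch",
    "quantify_cohort",
    "cohort_qft_table",
    "score_cohort",
    "ScoringOutputs",
]

log = logging.getLogger(__name__)


def load_image(path: str | Path, pixel_size_um: float) -> stain.RGBImage:
    """Read a TIFF/PNG image; whole-slide .svs containers are rejected."""
    path = Path(path)
    if path.suffix.lower() == ".svs":
        raise ValueError(
            "whole-slide .svs input is not supported; convert to plain TIFF or PNG "
            "first (e.g. with bioformats or openslide tooling)"
        )
    import imageio.v3 as iio

    pixels = iio.imread(path)
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    if pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    return stain.RGBImage(pixels=pixels, pixel_size_um=pixel_size_um)


def _stain_profile_for(image: stain.RGBImage, config: PipelineConfig) -> stain.StainProfile:
    if config.background_intensity is not None:
        background = np.asarray(config.background_intensity, dtype=float)
    else:
        background = stain.estimate_background(image, config.background_percentile)
    if config.sr_vector is not None:
        sr = np.asarray(config.sr_vector, dtype=float)
        residual = (
            np.asarray(config.residual_vector, dtype=float)
            if config.residual_vector is not None
            else np.array([1.0, 1.0, 1.0])
        )
        return stain.StainProfile(
            sr_vector=sr, residual_vector=residual, background_intensity=background
        )
    profile = stain.default_stain_profile()
    return stain.StainProfile(
        sr_vector=profile.sr_vector,
        residual_vector=profile.residual_vector,
        background_intensity=background,
    )


def _measure_region(
    sample_id: str,
    group: str | None,
    od: stain.ODImage,
    region: detect.MicrotissueRegion,
    config: PipelineConfig,
) -> qft.SampleMeasurements:
    min_obj = detect.scaled_min_object_px(od.pixel_size_um, config.min_object_px_base)
    mask = detect.segment_collagen(
        od, region, od_floor=config.od_floor, min_object_px=min_obj
    )
    graph = detect.build_fiber_graph(mask)
    components = detect.extract_fibers(mask, graph)
    thresholds = morphometry.ClassThresholds(
        node_min=config.class_node_min,
        length_min_um=config.class_length_min_um,
        width_min_um=config.class_width_min_um,
    )
    fibers = []
    for comp in components:
        m = morphometry.measure_fiber(comp, od)
        label = morphometry.classify_fiber(m, thresholds).label
        fibers.append((m, label))

    grid = architecture.tile_windows(
        region.tissue_mask,
        od.pixel_size_um,
        window_side_um=config.window_side_um,
        overlap_min=config.window_overlap_min,
    )
    window_features = []
    for row, col, (r0, c0, r1, c1) in grid.included_windows:
        window_features.append(
            architecture.glcm_features(
                od.collagen[r0:r1, c0:c1],
                collagen_mask_window=mask.mask[r0:r1, c0:c1],
                levels=config.glcm_levels,
                od_range=tuple(config.glcm_od_range),
                row=row,
                col=col,
            )
        )
    summary = (
        architecture.summarize_architecture(
            window_features, config.tau_uniform, config.tau_contrasted
        )
        if window_features
        else None
    )
    return qft.SampleMeasurements(
        sample_id=sample_id,
        group=group,
        pixel_size_um=od.pixel_size_um,
        tissue_area_um2=region.area_um2,
        fibers=fibers,
        window_features=window_features,
        architecture=summary,
    )


def quantify_image_batch(
    images: list[tuple[str, str | None, stain.RGBImage]],
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[qft.SampleMeasurements], list[dict]]:
    """Quantify a batch of (sample_id, group, image) triplets.

    Microtissue adequacy is judged across the whole batch (the 50%-of-mean
    rule needs the batch mean).  Returns the per-sample measurements and a
    QC log of every detected region with its inclusion decision.
    """
    detected: list[tuple[str, str | None, stain.ODImage, detect.MicrotissueRegion]] = []
    qc: list[dict] = []
    regions_flat: list[detect.MicrotissueRegion] = []
    for sample_id, group, image in images:
        profile = _stain_profile_for(image, config)
        od = stain.separate_collagen(stain.rgb_to_od(image, profile), profile)
        regions = detect.find_microtissues(
            image,
            color_distance_threshold=config.color_distance_threshold,
            min_seed_area_um2=config.min_seed_area_um2,
        )
        if not regions:
            log.warning("sample %s: no microtissue found", sample_id)
            qc.append(
                {"sample_id": sample_id, "region_id": None, "included": False,
                 "reason": "no microtissue foreground"}
            )
            continue
        for region in regions:
            detected.append((sample_id, group, od, region))
            regions_flat.append(region)

    if regions_flat:
        detect.adequacy_filter(regions_flat)

    measurements = []
    for sample_id, group, od, region in detected:
        suffix = f"_r{region.region_id}" if region.region_id else ""
        qc.append(
            {
                "sample_id": sample_id,
                "region_id": region.region_id,
                "area_um2": region.area_um2,
                "included": region.included,
                "reason": region.exclusion_reason,
            }
        )
        if not region.included:
            continue
        measurements.append(
            _measure_region(f"{sample_id}{suffix}", group, od, region, config)
        )
    return measurements, qc


def quantify_cohort(samples, config: PipelineConfig = PipelineConfig()):
    """Quantify a list of synthetic samples (convenience over image triplets)."""
    images = [(s.sample_id, s.group, s.image) for s in samples]
    return quantify_image_batch(images, config)


def cohort_qft_table(
    measurements: list[qft.SampleMeasurements],
    catalog: qft.TraitCatalog | None = None,
    grid: qft.ExpansionGrid = qft.ExpansionGrid(),
) -> pd.DataFrame:
    vectors = [qft.expand_qfts(m, catalog, grid) for m in measurements]
    return qft.qft_table(vectors)


@dataclass
class ScoringOutputs:
    selection: scoring.SelectionResult
    model: scoring.NormalizationModel
    scores: pd.DataFrame  # per-sample ph_fcs + sub-scores
    heatmap: pd.DataFrame
    anova: scoring.GroupComparison  # Welch ANOVA on ph_fcs across groups


def score_cohort(
    table: pd.DataFrame, config: PipelineConfig = PipelineConfig()
) -> ScoringOutputs:
    """Trait selection, normalization, composite scores and group statistics."""
    selection = scoring.select_traits(
        table,
        reference_group=config.reference_group,
        disease_group=config.disease_group,
        alpha=config.alpha,
        bh_correction=config.bh_correction,
    )
    model = scoring.fit_normalization(table, selection)
    model.score_lo, model.score_hi = config.score_lo, config.score_hi
    scores = scoring.score_table(table, model)
    heatmap = scoring.heatmap_matrix(table, selection)
    groups = {
        g: scores.loc[scores["group"] == g, "ph_fcs"].to_numpy()
        for g in scores["group"].unique()
    }
    try:
        anova = scoring.dunnett_t3(groups, config.reference_group)
    except ValueError:
        anova = scoring.GroupComparison(
            f_statistic=float("nan"), df1=float("nan"), df2=float("nan"),
            p_value=float("nan"), pairwise=[],
        )
    return ScoringOutputs(
        selection=selection, model=model, scores=scores, heatmap=heatmap, anova=anova
    )
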