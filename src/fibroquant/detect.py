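"""Microtissue detection, collagen segmentation and the skeleton fiber graph.

The detection chain mirrors a digital-pathology fibrosis workflow: locate
tissue regions against the slide background, drop undersized microtissues
(adequacy rule: area below 50% of the batch-mean area), threshold the
unmixed collagen channel inside the tissue, and reduce the binary collagen
mask to a skeleton graph of junction nodes, endpoints and branches from
which per-fiber morphometry is read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .stain import ODImage, RGBImage

__all__ = [
    "MicrotissueRegion",
    "CollagenMask",
    "Branch",
    "FiberGraph",
    "FiberComponent",
    "find_microtissues",
    "adequacy_filter",
    "segment_collagen",
    "build_fiber_graph",
    "extract_fibers",
]

log = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class MicrotissueRegion:
    region_id: int
    tissue_mask: np.ndarray  # bool, full image frame
    area_um2: float
    included: bool = True
    exclusion_reason: str | None = None


@dataclass
class CollagenMask:
    mask: np.ndarray  # bool
    pixel_size_um: float
    min_object_px: int
    threshold_od: float = 0.0


@dataclass
class Branch:
    path: np.ndarray  # (N, 2) int pixel coordinates (row, col)
    length_um: float


@dataclass
class FiberGraph:
    nodes: list[tuple[tuple[float, float], int]]  # (centroid position, degree)
    branches: list[Branch]
    endpoints: int
    skeleton: np.ndarray | None = None  # bool skeleton mask

    @property
    def total_length_um(self) -> float:
        return float(sum(b.length_um for b in self.branches))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_branches(self) -> int:
        return len(self.branches)


@dataclass
class FiberComponent:
    component_id: int
    pixel_set: tuple[np.ndarray, np.ndarray]  # (rows, cols)
    subgraph: FiberGraph
    area_um2: float
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) inclusive

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_set[0])


def find_microtissues(
    image: RGBImage,
    color_distance_threshold: float = 20.0,
    min_seed_area_um2: float = 500.0,
) -> list[MicrotissueRegion]:
    """Segment tissue regions by color distance from the estimated background.

    The background color is the per-channel median of a border frame of the
    image; foreground pixels deviate from it by more than the Euclidean RGB
    threshold.  Holes are filled (tissue interiors can be near-background),
    and components below the minimal seed area are discarded.
    """
    pixels = image.pixels.astype(float)
    h, w = pixels.shape[:2]
    border = max(min(h, w) // 50, 2)
    frame = np.concatenate(
        [
            pixels[:border].reshape(-1, 3),
            pixels[-border:].reshape(-1, 3),
            pixels[:, :border].reshape(-1, 3),
            pixels[:, -border:].reshape(-1, 3),
        ]
    )
    background = np.median(frame, axis=0)
    dist = np.linalg.norm(pixels - background[None, None, :], axis=2)
    foreground = dist > color_distance_threshold
    foreground = ndi.binary_closing(foreground, structure=_EIGHT)
    foreground = ndi.binary_fill_holes(foreground)

    labels, n = ndi.label(foreground, structure=_EIGHT)
    px_area = image.pixel_size_um**2
    regions: list[MicrotissueRegion] = []
    rid = 0
    for lbl in range(1, n + 1):
        mask = labels == lbl
        area = float(mask.sum()) * px_area
        if area < min_seed_area_um2:
            continue
        regions.append(MicrotissueRegion(region_id=rid, tissue_mask=mask, area_um2=area))
        rid += 1
    if not regions:
        log.warning("no microtissue foreground found")
    return regions


def adequacy_filter(regions: list[MicrotissueRegion]) -> list[MicrotissueRegion]:
    """Exclude microtissues smaller than 50% of the batch-mean area.

    The mean is taken over the full candidate batch, including the regions
    being judged.  Flags are set in place and the list is returned.
    """
    if not regions:
        raise ValueError("adequacy_filter requires at least one region")
    mean_area = float(np.mean([r.area_um2 for r in regions]))
    cutoff = 0.5 * mean_area
    for r in regions:
        if r.area_um2 < cutoff:
            r.included = False
            r.exclusion_reason = (
                f"area {r.area_um2:.1f} um^2 < 50% of batch mean ({cutoff:.1f} um^2)"
            )
            log.info("microtissue %d excluded: %s", r.region_id, r.exclusion_reason)
        else:
            r.included = True
            r.exclusion_reason = None
    return regions


def segment_collagen(
    od: ODImage,
    region: MicrotissueRegion,
    od_floor: float = 0.15,
    min_object_px: int = 5,
) -> CollagenMask:
    """Threshold the collagen channel inside one microtissue.

    The threshold is the Otsu level of the collagen channel within the
    tissue mask, floored at a configured minimum OD — the floor guards
    near-empty images where Otsu splits noise.  Components smaller than
    ``min_object_px`` (scaled for the pixel size, see
    :func:`scaled_min_object_px`) are removed.
    """
    if od.collagen is None:
        raise ValueError("collagen channel not computed; run separate_collagen first")
    tissue = region.tissue_mask
    if not tissue.any():
        raise ValueError("empty tissue mask")
    values = od.collagen[tissue]
    if np.ptp(values) < 1e-12:
        thr = np.inf  # flat channel: nothing to segment
    else:
        thr = max(float(threshold_otsu(values)), od_floor)
    mask = (od.collagen >= thr) & tissue

    labels, n = ndi.label(mask, structure=_EIGHT)
    if n:
        sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_object_px) + 1
        mask = np.isin(labels, keep)
    return CollagenMask(
        mask=mask,
        pixel_size_um=od.pixel_size_um,
        min_object_px=min_object_px,
        threshold_od=float(thr) if np.isfinite(thr) else 0.0,
    )


def scaled_min_object_px(pixel_size_um: float, base_px: int = 5) -> int:
    """Minimum object size in pixels, scaled by (1 / pixel_size)^2 from 1 um/px."""
    return max(int(round(base_px / pixel_size_um**2)), 1)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    """Number of 8-connected skeleton neighbors per skeleton pixel."""
    kernel = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
    counts = ndi.convolve(skel.astype(np.uint8), kernel, mode="constant")
    return counts * skel


def _trace_paths(segment_mask: np.ndarray, offset: tuple[int, int] = (0, 0)) -> list[np.ndarray]:
    """Order the pixels of a node-free skeleton segment into paths.

    A segment is a connected set whose pixels have degree <= 2 within the
    segment; it is either an open path (two tips) or a closed loop.
    """
    coords = np.argwhere(segment_mask)
    if len(coords) == 0:
        return []
    coord_set = {tuple(c) for c in map(tuple, coords)}
    neighbors: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for r, c in coord_set:
        nb = [
            (r + dr, c + dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr or dc) and (r + dr, c + dc) in coord_set
        ]
        neighbors[(r, c)] = nb
    tips = [p for p, nb in neighbors.items() if len(nb) <= 1]
    start = min(tips) if tips else min(coord_set)  # loops: deterministic start
    path = [start]
    visited = {start}
    cur = start
    while True:
        nxt = [p for p in neighbors[cur] if p not in visited]
        if not nxt:
            break
        cur = min(nxt)
        path.append(cur)
        visited.add(cur)
    arr = np.array(path) + np.array(offset)
    return [arr]


def _path_length_um(path: np.ndarray, pixel_size_um: float) -> float:
    if len(path) < 2:
        return 0.0
    steps = np.abs(np.diff(path, axis=0))
    lengths = np.where(steps.sum(axis=1) == 2, np.sqrt(2.0), 1.0)
    return float(lengths.sum()) * pixel_size_um


def build_fiber_graph(mask: CollagenMask) -> FiberGraph:
    """Thin the collagen mask and decompose the skeleton into a graph.

    Junction pixels (>= 3 skeleton neighbors) merged within a 2-px radius
    become nodes; endpoint pixels have exactly 1 neighbor; branches are the
    maximal node-free skeleton paths, with lengths accumulated as 1 per
    axial step and sqrt(2) per diagonal step, times the pixel size.
    """
    if not mask.mask.any():
        return FiberGraph(nodes=[], branches=[], endpoints=0, skeleton=np.zeros_like(mask.mask))
    skel = skeletonize(mask.mask)
    counts = _neighbor_counts(skel)
    junctions = counts >= 3
    endpoints = int(np.count_nonzero(counts == 1))

    # Merge junction clusters within a 2-px radius into single nodes.
    nodes: list[tuple[tuple[float, float], int]] = []
    if junctions.any():
        # Cluster = connected component of the dilated junction set restricted
        # back to junction pixels (pixels within 2 px share a dilated pixel).
        dil_labels, _ = ndi.label(ndi.binary_dilation(junctions, structure=_EIGHT), structure=_EIGHT)
        cluster_ids = np.unique(dil_labels[junctions])
        for cid in cluster_ids:
            cluster = junctions & (dil_labels == cid)
            rr, cc = np.nonzero(cluster)
            centroid = (float(rr.mean()), float(cc.mean()))
            # Node degree = number of skeleton pixels adjacent to the cluster
            # but outside it (arms leaving the junction).
            ring = ndi.binary_dilation(cluster, structure=_EIGHT) & skel & ~cluster
            nodes.append((centroid, int(ring.sum())))

    # Branches: remove junction pixels, trace remaining node-free segments.
    segments = skel & ~junctions
    seg_labels, n_seg = ndi.label(segments, structure=_EIGHT)
    branches: list[Branch] = []
    for lbl in range(1, n_seg + 1):
        seg = seg_labels == lbl
        for path in _trace_paths(seg):
            branches.append(Branch(path=path, length_um=_path_length_um(path, mask.pixel_size_um)))

    return FiberGraph(nodes=nodes, branches=branches, endpoints=endpoints, skeleton=skel)


def extract_fibers(mask: CollagenMask, graph: FiberGraph) -> list[FiberComponent]:
    """Split the mask into 8-connected components with their subgraphs.

    Components partition the filtered mask; each branch and node of the
    skeleton graph is assigned to the component containing its pixels.
    """
    labels, n = ndi.label(mask.mask, structure=_EIGHT)
    px_area = mask.pixel_size_um**2
    components: list[FiberComponent] = []
    slices = ndi.find_objects(labels)
    for cid in range(1, n + 1):
        comp_mask = labels == cid
        rows, cols = np.nonzero(comp_mask)
        sub_branches = [
            b for b in graph.branches if labels[b.path[0][0], b.path[0][1]] == cid
        ]
        sub_nodes = [
            (pos, deg)
            for pos, deg in graph.nodes
            if labels[int(round(pos[0])), int(round(pos[1]))] == cid
        ]
        # Endpoints restricted to this component.
        if graph.skeleton is not None and graph.skeleton.any():
            counts = _neighbor_counts(graph.skeleton & comp_mask)
            sub_endpoints = int(np.count_nonzero(counts == 1))
            sub_skel = graph.skeleton & comp_mask
        else:
            sub_endpoints = 0
            sub_skel = None
        sl = slices[cid - 1]
        bbox = (sl[0].start, sl[1].start, sl[0].stop - 1, sl[1].stop - 1)
        components.append(
            FiberComponent(
                component_id=cid - 1,
                pixel_set=(rows, cols),
                subgraph=FiberGraph(
                    nodes=sub_nodes,
                    branches=sub_branches,
                    endpoints=sub_endpoints,
                    skeleton=sub_skel,
                ),
                area_um2=float(len(rows)) * px_area,
                bbox=bbox,
            )
        )
    return components
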