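"""Per-fiber morphometric traits and fine/assembled classification.

The single-fiber unit here is an 8-connected collagen component with its
skeleton subgraph.  Width follows a ribbon model (area / skeleton length);
perimeter is the exposed-pixel-edge count times the pixel size, which is
exact on axis-aligned fixtures.  A fiber is "assembled" when its network is
reticulated (enough junction nodes) or when it is both long and thick;
otherwise it is a "fine" fibril.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .detect import FiberComponent
from .stain import ODImage

__all__ = [
    "FiberMorphometry",
    "ClassThresholds",
    "FiberClass",
    "measure_fiber",
    "classify_fiber",
]


@dataclass
class FiberMorphometry:
    skeleton_length_um: float
    width_um: float
    area_um2: float
    perimeter_um: float
    ap_ratio_um: float
    n_branches: int
    n_nodes: int
    n_endpoints: int
    mean_collagen_od: float

    @property
    def elongation(self) -> float:
        """Skeleton length over width; 0 for degenerate width."""
        return self.skeleton_length_um / self.width_um if self.width_um > 0 else 0.0


@dataclass(frozen=True)
class ClassThresholds:
    """Fine/assembled decision boundary (configurable; defaults documented)."""

    node_min: int = 2
    length_min_um: float = 30.0
    width_min_um: float = 3.0


@dataclass
class FiberClass:
    label: str  # "fine" | "assembled"
    rule_fired: str


def _exposed_edges(mask: np.ndarray) -> int:
    """Count pixel edges bordering background (4-neighborhood)."""
    padded = np.pad(mask, 1)
    total = 0
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neighbor = np.roll(padded, shift, axis=axis)
        total += int(np.count_nonzero(padded & ~neighbor))
    return total


def measure_fiber(component: FiberComponent, od: ODImage) -> FiberMorphometry:
    """Measure one collagen component.

    Width = area / skeleton length (ribbon model); when the skeleton is
    empty (tiny blobs thinned to a point), the fallback is twice the mean
    distance-transform value over the component.
    """
    rows, cols = component.pixel_set
    if len(rows) == 0:
        raise ValueError("empty fiber component")
    px = od.pixel_size_um
    area = float(len(rows)) * px**2

    # Local mask cropped to the bounding box, for perimeter and distances.
    r0, c0, r1, c1 = component.bbox
    local = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    local[rows - r0, cols - c0] = True
    perimeter = _exposed_edges(local) * px

    skel_len = component.subgraph.total_length_um
    if skel_len > 0:
        width = area / skel_len
    else:
        dt = ndi.distance_transform_edt(local)
        width = 2.0 * float(dt[local].mean()) * px

    mean_od = float(od.collagen[rows, cols].mean()) if od.collagen is not None else 0.0

    return FiberMorphometry(
        skeleton_length_um=skel_len,
        width_um=width,
        area_um2=area,
        perimeter_um=perimeter,
        ap_ratio_um=area / perimeter if perimeter > 0 else 0.0,
        n_branches=component.subgraph.n_branches,
        n_nodes=component.subgraph.n_nodes,
        n_endpoints=component.subgraph.endpoints,
        mean_collagen_od=mean_od,
    )


def classify_fiber(
    m: FiberMorphometry, thresholds: ClassThresholds = ClassThresholds()
) -> FiberClass:
    """Assembled iff reticulated (nodes) or long-and-thick; else fine."""
    if m.n_nodes >= thresholds.node_min:
        return FiberClass(label="assembled", rule_fired=f"n_nodes >= {thresholds.node_min}")
    if (
        m.skeleton_length_um >= thresholds.length_min_um
        and m.width_um >= thresholds.width_min_um
    ):
        return FiberClass(
            label="assembled",
            rule_fired=(
                f"length >= {thresholds.length_min_um} um and "
                f"width >= {thresholds.width_min_um} um"
            ),
        )
    return FiberClass(label="fine", rule_fired="default")
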