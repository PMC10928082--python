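"""Computational-window tiling and GLCM texture features.

Fibrosis architecture is quantified per fixed 25 um x 25 um window: the
collagen OD channel is quantized to a fixed number of gray levels over a
cohort-fixed OD range, a symmetric normalized gray-level co-occurrence
matrix (GLCM) is averaged over four unit offsets, and four Haralick-style
features are read off it — entropy (bits), inertia (the GLCM contrast,
adopted as the formal reading of "inertia"), correlation and homogeneity —
plus the collagen area fraction of the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "WindowGrid",
    "WindowFeatures",
    "ArchitectureSummary",
    "DEFAULT_OFFSETS",
    "tile_windows",
    "quantize",
    "glcm_matrix",
    "glcm_features",
    "summarize_architecture",
    "descriptive_stats",
]

#: Unit pixel offsets averaged into the symmetric GLCM.
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class WindowGrid:
    window_side_um: float
    side_px: int
    windows: list[tuple[int, int, tuple[int, int, int, int]]]
    # each: (row index, col index, (r0, c0, r1, c1) pixel bounds, end-exclusive)
    included: list[bool]

    @property
    def included_windows(self) -> list[tuple[int, int, tuple[int, int, int, int]]]:
        return [w for w, ok in zip(self.windows, self.included) if ok]


@dataclass
class WindowFeatures:
    row: int
    col: int
    entropy: float  # bits
    inertia: float
    correlation: float  # in [-1, 1]
    homogeneity: float  # in (0, 1]
    collagen_area_fraction: float


@dataclass
class ArchitectureSummary:
    feature_stats: dict  # feature -> {mean, median, sd, kurtosis, skew}
    frac_uniform: float
    frac_contrasted: float
    n_windows: int


def tile_windows(
    tissue_mask: np.ndarray,
    pixel_size_um: float,
    window_side_um: float = 25.0,
    overlap_min: float = 0.5,
) -> WindowGrid:
    """Tile the tissue bounding box into disjoint full-size windows.

    The window side in pixels is ``round(window_side_um / pixel_size_um)``;
    the grid is anchored at the tissue bounding-box origin, partial edge
    windows are dropped, and a window is included only when its overlap with
    the tissue mask is at least ``overlap_min``.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    side = int(round(window_side_um / pixel_size_um))
    if side < 4:
        raise ValueError(
            f"window of {side} px is below 4 px; resolution too coarse for texture"
        )
    windows: list[tuple[int, int, tuple[int, int, int, int]]] = []
    included: list[bool] = []
    if tissue_mask.any():
        rows, cols = np.nonzero(tissue_mask)
        r_origin, c_origin = rows.min(), cols.min()
        r_end, c_end = rows.max() + 1, cols.max() + 1
        h, w = tissue_mask.shape
        i = 0
        r0 = r_origin
        while r0 < r_end and r0 + side <= h:
            j = 0
            c0 = c_origin
            while c0 < c_end and c0 + side <= w:
                bounds = (r0, c0, r0 + side, c0 + side)
                overlap = tissue_mask[r0 : r0 + side, c0 : c0 + side].mean()
                windows.append((i, j, bounds))
                included.append(bool(overlap >= overlap_min))
                j += 1
                c0 += side
            i += 1
            r0 += side
    return WindowGrid(
        window_side_um=window_side_um, side_px=side, windows=windows, included=included
    )


def quantize(values: np.ndarray, levels: int, od_range: tuple[float, float]) -> np.ndarray:
    """Linear quantization of OD values to integer gray levels [0, levels-1]."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    lo, hi = od_range
    if hi <= lo:
        raise ValueError("od_range must be increasing")
    scaled = (np.asarray(values, dtype=float) - lo) / (hi - lo)
    return np.clip((scaled * levels).astype(int), 0, levels - 1)


def glcm_matrix(
    quantized: np.ndarray,
    levels: int,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix averaged over offsets."""
    q = np.asarray(quantized)
    total = np.zeros((levels, levels), dtype=float)
    for dr, dc in offsets:
        h, w = q.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        m = np.zeros((levels, levels), dtype=float)
        np.add.at(m, (a, b), 1.0)
        m = m + m.T  # symmetric
        s = m.sum()
        if s > 0:
            total += m / s
    n_off = len(offsets)
    if n_off == 0:
        raise ValueError("at least one offset required")
    return total / n_off


def features_from_glcm(p: np.ndarray) -> tuple[float, float, float, float]:
    """(entropy bits, inertia, correlation, homogeneity) from a normalized GLCM."""
    levels = p.shape[0]
    i_idx, j_idx = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    diff2 = (i_idx - j_idx) ** 2
    inertia = float((p * diff2).sum())
    homogeneity = float((p / (1.0 + diff2)).sum())
    mu_i = float((p * i_idx).sum())
    mu_j = float((p * j_idx).sum())
    var_i = float((p * (i_idx - mu_i) ** 2).sum())
    var_j = float((p * (j_idx - mu_j) ** 2).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = 0.0  # sigma = 0 convention: no linear structure measurable
    else:
        correlation = float(
            (p * (i_idx - mu_i) * (j_idx - mu_j)).sum() / np.sqrt(var_i * var_j)
        )
    return entropy, inertia, correlation, homogeneity


def glcm_features(
    window_od: np.ndarray,
    collagen_mask_window: np.ndarray | None = None,
    levels: int = 16,
    od_range: tuple[float, float] = (0.0, 2.0),
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    row: int = 0,
    col: int = 0,
) -> WindowFeatures:
    """Texture + density features of one computational window.

    ``window_od`` is the collagen OD channel restricted to the window;
    ``collagen_mask_window`` (optional) supplies the binary collagen mask
    for the area fraction.
    """
    if window_od.size == 0:
        raise ValueError("empty window")
    q = quantize(window_od, levels, od_range)
    p = glcm_matrix(q, levels, offsets)
    entropy, inertia, correlation, homogeneity = features_from_glcm(p)
    if collagen_mask_window is not None:
        caf = float(np.count_nonzero(collagen_mask_window)) / collagen_mask_window.size
    else:
        caf = float("nan")
    return WindowFeatures(
        row=row,
        col=col,
        entropy=entropy,
        inertia=inertia,
        correlation=correlation,
        homogeneity=homogeneity,
        collagen_area_fraction=caf,
    )


def descriptive_stats(values: np.ndarray) -> dict:
    """Mean/median/sd/excess-kurtosis/skew with degenerate-case conventions.

    Sample sd uses n-1; skew and kurtosis are the bias-corrected Fisher
    definitions; any statistic undefined for the sample size or for zero
    variance is reported as 0.
    """
    v = np.asarray(values, dtype=float)
    out = {"mean": float(v.mean()), "median": float(np.median(v))}
    n = len(v)
    sd = float(v.std(ddof=1)) if n >= 2 else 0.0
    out["sd"] = sd
    if n >= 3 and sd > 0:
        out["skew"] = float(stats.skew(v, bias=False))
    else:
        out["skew"] = 0.0
    if n >= 4 and sd > 0:
        out["kurtosis"] = float(stats.kurtosis(v, fisher=True, bias=False))
    else:
        out["kurtosis"] = 0.0
    return out


def summarize_architecture(
    features: list[WindowFeatures],
    tau_uniform: float = 5.0,
    tau_contrasted: float = 50.0,
) -> ArchitectureSummary:
    """Moments per feature plus uniform/contrasted inertia window fractions."""
    if not features:
        raise ValueError("summarize_architecture requires at least one window")
    names = ["entropy", "inertia", "correlation", "homogeneity", "collagen_area_fraction"]
    feature_stats = {
        name: descriptive_stats(np.array([getattr(f, name) for f in features])) for name in names
    }
    inertia = np.array([f.inertia for f in features])
    return ArchitectureSummary(
        feature_stats=feature_stats,
        frac_uniform=float(np.mean(inertia <= tau_uniform)),
        frac_contrasted=float(np.mean(inertia >= tau_contrasted)),
        n_windows=len(features),
    )
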