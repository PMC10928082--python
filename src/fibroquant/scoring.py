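"""Trait selection, severity normalization and composite fibrosis scores.

qFTs significantly altered between the disease (MASH) and reference (LEAN)
groups are selected by per-trait Welch two-sample t-tests, direction-aligned
so that larger always means more severe, min-max normalized over the cohort
and averaged within each sub-phenotype.  Each sub-composite score maps the
[0, 1] severity mean to the continuous 1-10 scale via ``1 + 9 u``; the
phenotypic composite (Ph-FCS) is the mean of the available sub-scores.
Group contrasts use Welch's heteroscedastic one-way ANOVA with pairwise
Welch tests adjusted by the Šidák step (a documented approximation of
Dunnett's T3 studentized-maximum-modulus adjustment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .qft import sub_phenotype_of

__all__ = [
    "TraitSelection",
    "SelectionResult",
    "NormalizationModel",
    "CompositeScores",
    "GroupComparison",
    "select_traits",
    "fit_normalization",
    "composite_scores",
    "score_table",
    "welch_anova",
    "dunnett_t3",
    "heatmap_matrix",
    "plot_heatmap",
]

log = logging.getLogger(__name__)

SUB_PHENOTYPES = ("collagen", "morphometric", "architecture")


@dataclass
class TraitSelection:
    qft_id: str
    p_value: float
    direction: int  # +1 if disease mean > reference mean else -1
    selected: bool


@dataclass
class SelectionResult:
    traits: list[TraitSelection]
    alpha: float
    reference_group: str
    disease_group: str

    @property
    def selected_ids(self) -> list[str]:
        return [t.qft_id for t in self.traits if t.selected]

    def counts_by_sub_phenotype(self) -> dict[str, int]:
        out = {s: 0 for s in SUB_PHENOTYPES}
        for t in self.traits:
            if t.selected:
                out[sub_phenotype_of(t.qft_id)] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "qft_id": t.qft_id,
                    "p_value": t.p_value,
                    "direction": t.direction,
                    "selected": t.selected,
                }
                for t in self.traits
            ]
        )


@dataclass
class NormalizationModel:
    """Direction-aligned cohort min/max per selected qFT; maps to [1, 10]."""

    entries: dict[str, tuple[float, float, int]]  # qft_id -> (min, max, direction)
    score_lo: float = 1.0
    score_hi: float = 10.0


@dataclass
class CompositeScores:
    sample_id: str
    ph_fcs: float
    sub_scores: dict[str, float]  # sub-phenotype -> score in [1, 10]


@dataclass
class GroupComparison:
    f_statistic: float
    df1: float
    df2: float
    p_value: float
    pairwise: list[tuple[str, str, float, float, float]]
    # (group_a, group_b, t, df, p_adjusted)


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t, Welch-Satterthwaite df, two-sided p.

    Zero variance in both groups is a no-signal degenerate case: p = 1 when
    the means agree, p = 0 when they differ (deterministic separation).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        return np.inf if a.mean() > b.mean() else -np.inf, float(na + nb - 2), 0.0
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def select_traits(
    table: pd.DataFrame,
    reference_group: str = "LEAN",
    disease_group: str = "MASH",
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> SelectionResult:
    """Per-qFT Welch t-test disease vs reference; selected iff p <= alpha.

    ``table`` is a samples x qFTs frame with a ``group`` column.  Direction
    is the sign of the disease-minus-reference mean difference.  With
    ``bh_correction`` the Benjamini-Hochberg adjusted p-values are used for
    the selection decision.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    groups = table["group"]
    ref = table.loc[groups == reference_group]
    dis = table.loc[groups == disease_group]
    for name, sub in ((reference_group, ref), (disease_group, dis)):
        if len(sub) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    qft_cols = [c for c in table.columns if c != "group"]
    raw = []
    for col in qft_cols:
        t, _, p = _welch_t(dis[col].to_numpy(), ref[col].to_numpy())
        direction = 1 if dis[col].mean() >= ref[col].mean() else -1
        raw.append((col, p, direction))
    p_values = np.array([p for _, p, _ in raw])
    if bh_correction:
        order = np.argsort(p_values)
        m = len(p_values)
        adj = np.empty(m)
        ranked = p_values[order] * m / (np.arange(m) + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        decisions = np.minimum(adj, 1.0)
    else:
        decisions = p_values
    traits = [
        TraitSelection(qft_id=col, p_value=float(p), direction=d, selected=bool(dec <= alpha))
        for (col, p, d), dec in zip(raw, decisions)
    ]
    return SelectionResult(
        traits=traits,
        alpha=alpha,
        reference_group=reference_group,
        disease_group=disease_group,
    )


def fit_normalization(
    table: pd.DataFrame, selection: SelectionResult
) -> NormalizationModel:
    """Cohort min/max of direction-aligned selected qFTs; degenerates dropped."""
    selected = selection.selected_ids
    if not selected:
        raise ValueError("no selected qFTs to normalize")
    directions = {t.qft_id: t.direction for t in selection.traits}
    entries: dict[str, tuple[float, float, int]] = {}
    for qft_id in selected:
        d = directions[qft_id]
        aligned = d * table[qft_id].to_numpy(dtype=float)
        lo, hi = float(aligned.min()), float(aligned.max())
        if hi <= lo:
            log.info("qFT %s degenerate over the cohort; dropped from the model", qft_id)
            continue
        entries[qft_id] = (lo, hi, d)
    if not entries:
        raise ValueError("all selected qFTs are degenerate over the cohort")
    return NormalizationModel(entries=entries)


def composite_scores(
    sample_values: dict[str, float] | pd.Series,
    model: NormalizationModel,
    sample_id: str = "",
) -> CompositeScores:
    """Sub-phenotype composite scores and their Ph-FCS aggregate for one sample.

    Per selected qFT, ``u = clamp((direction * v - min) / (max - min), 0, 1)``;
    the sub-score is ``lo + (hi - lo) * mean(u)`` over that sub-phenotype's
    qFTs, and the Ph-FCS is the mean of the sub-scores present.  A
    sub-phenotype with no retained qFT is omitted (and logged).
    """
    if isinstance(sample_values, pd.Series):
        sample_values = sample_values.to_dict()
    per_sub: dict[str, list[float]] = {s: [] for s in SUB_PHENOTYPES}
    for qft_id, (lo, hi, d) in model.entries.items():
        v = d * float(sample_values[qft_id])
        u = min(max((v - lo) / (hi - lo), 0.0), 1.0)
        per_sub[sub_phenotype_of(qft_id)].append(u)
    sub_scores = {}
    for sub, us in per_sub.items():
        if us:
            sub_scores[sub] = model.score_lo + (model.score_hi - model.score_lo) * float(
                np.mean(us)
            )
        else:
            log.info("sub-phenotype %s has no selected qFTs; sub-score omitted", sub)
    if not sub_scores:
        raise ValueError("no sub-phenotype has selected qFTs")
    ph = float(np.mean(list(sub_scores.values())))
    return CompositeScores(sample_id=sample_id, ph_fcs=ph, sub_scores=sub_scores)


def score_table(table: pd.DataFrame, model: NormalizationModel) -> pd.DataFrame:
    """Composite scores for every sample of a qFT table."""
    rows = []
    for sample_id, row in table.drop(columns=["group"]).iterrows():
        cs = composite_scores(row, model, sample_id=str(sample_id))
        rows.append(
            {
                "sample_id": sample_id,
                "group": table.loc[sample_id, "group"],
                "ph_fcs": cs.ph_fcs,
                **{f"{k}_fcs": v for k, v in cs.sub_scores.items()},
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def welch_anova(groups: dict[str, np.ndarray]) -> GroupComparison:
    """Welch's heteroscedastic one-way ANOVA.

    F* = sum(w_k (m_k - m_bar)^2) / (k - 1) over a correction term, with
    w_k = n_k / s_k^2, m_bar the weighted grand mean, and Welch-Satterthwaite
    denominator df.  For k = 2 this reduces to the square of the Welch t.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("welch_anova requires at least 2 groups")
    arrays = {}
    for name in names:
        a = np.asarray(groups[name], dtype=float)
        if len(a) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        if a.var(ddof=1) == 0:
            raise ValueError(f"group {name!r} has zero variance")
        arrays[name] = a
    k = len(names)
    n = np.array([len(arrays[g]) for g in names], dtype=float)
    m = np.array([arrays[g].mean() for g in names])
    s2 = np.array([arrays[g].var(ddof=1) for g in names])
    w = n / s2
    m_bar = (w * m).sum() / w.sum()
    num = ((w * (m - m_bar) ** 2).sum()) / (k - 1)
    lam = (3.0 * ((1 - w / w.sum()) ** 2 / (n - 1)).sum()) / (k**2 - 1)
    f = num / (1 + 2 * lam * (k - 2) / 3)
    df1 = float(k - 1)
    df2 = 1.0 / lam if lam > 0 else np.inf
    p = float(stats.f.sf(f, df1, df2))
    return GroupComparison(
        f_statistic=float(f), df1=df1, df2=float(df2), p_value=p, pairwise=[]
    )


def dunnett_t3(
    groups: dict[str, np.ndarray], reference_group: str
) -> GroupComparison:
    """Pairwise Welch tests vs a reference with Šidák family-wise adjustment.

    ``p_adj = 1 - (1 - p)^m`` over the m comparisons — a conservative,
    documented approximation of the T3 studentized-maximum-modulus step.
    """
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} absent")
    others = [g for g in groups if g != reference_group]
    if not others:
        raise ValueError("dunnett_t3 requires at least one non-reference group")
    m = len(others)
    ref = np.asarray(groups[reference_group], dtype=float)
    pairwise = []
    for g in others:
        t, df, p = _welch_t(np.asarray(groups[g], dtype=float), ref)
        p_adj = float(min(1.0 - (1.0 - p) ** m, 1.0))
        pairwise.append((g, reference_group, t, df, p_adj))
    anova = welch_anova(groups) if all(
        np.asarray(v, dtype=float).var(ddof=1) > 0 and len(v) >= 2 for v in groups.values()
    ) else None
    return GroupComparison(
        f_statistic=anova.f_statistic if anova else float("nan"),
        df1=anova.df1 if anova else float("nan"),
        df2=anova.df2 if anova else float("nan"),
        p_value=anova.p_value if anova else float("nan"),
        pairwise=pairwise,
    )


def heatmap_matrix(table: pd.DataFrame, selection: SelectionResult) -> pd.DataFrame:
    """Row-normalized severity matrix: selected qFTs x samples in [0, 1].

    Rows are grouped by sub-phenotype (collagen, morphometric, architecture);
    cells are direction-aligned min-max normalized values; column order
    preserves the input sample order.
    """
    directions = {t.qft_id: t.direction for t in selection.traits}
    ordered = [
        t.qft_id
        for sub in SUB_PHENOTYPES
        for t in selection.traits
        if t.selected and sub_phenotype_of(t.qft_id) == sub
    ]
    data = {}
    for qft_id in ordered:
        aligned = directions[qft_id] * table[qft_id].to_numpy(dtype=float)
        lo, hi = aligned.min(), aligned.max()
        data[qft_id] = (aligned - lo) / (hi - lo) if hi > lo else np.zeros_like(aligned)
    return pd.DataFrame(data, index=table.index).T


def plot_heatmap(matrix: pd.DataFrame, out_path: str) -> None:
    """Render the severity matrix green (least) to red (most) and save it."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * matrix.shape[1]), max(4, 0.08 * matrix.shape[0]))
    )
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="RdYlGn_r", vmin=0, vmax=1)
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_xlabel("sample")
    ax.set_ylabel(f"{matrix.shape[0]} selected qFTs")
    fig.colorbar(im, ax=ax, label="relative severity")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
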