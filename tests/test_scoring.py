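"""Trait selection, normalization, composite scores and group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fibroquant as fq
from fibroquant.scoring import (
    _welch_t,
    composite_scores,
    dunnett_t3,
    fit_normalization,
    heatmap_matrix,
    select_traits,
    welch_anova,
)


def _table(columns: dict, groups=("LEAN",) * 4 + ("MASH",) * 4) -> pd.DataFrame:
    df = pd.DataFrame(columns)
    df.insert(0, "group", list(groups))
    df.index = [f"s{i}" for i in range(len(df))]
    df.index.name = "sample_id"
    return df


@pytest.fixture()
def shifted_table():
    rng = np.random.default_rng(42)
    n = 8
    shifted = np.concatenate([rng.normal(0, 1, n), rng.normal(5, 1, n)])
    noise = rng.normal(0, 1, 2 * n)
    return _table(
        {"collagen.shifted": shifted, "morphometric.noise": noise},
        groups=("LEAN",) * n + ("MASH",) * n,
    )


class TestWelchT:
    def test_hand_computed_example(self):
        t, df, p = _welch_t(np.array([1.0, 2, 3]), np.array([2.0, 3, 4]))
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0, abs=1e-10)

    def test_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 3, 7)
        t, df, p = _welch_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestSelectTraits:
    def test_identical_values_p_one_not_selected(self):
        table = _table({"collagen.flat": [1.0] * 8})
        result = select_traits(table)
        assert result.traits[0].p_value == 1.0
        assert not result.traits[0].selected

    def test_shifted_trait_selected_noise_not(self, shifted_table):
        result = select_traits(shifted_table)
        by_id = {t.qft_id: t for t in result.traits}
        assert by_id["collagen.shifted"].selected
        assert by_id["collagen.shifted"].direction == 1
        assert not by_id["morphometric.noise"].selected

    def test_small_group_rejected(self):
        table = _table({"collagen.x": [1.0, 2, 3]}, groups=("LEAN", "MASH", "MASH"))
        with pytest.raises(ValueError, match="fewer than 2"):
            select_traits(table)

    def test_alpha_one_selects_all_nondegenerate(self, shifted_table):
        result = select_traits(shifted_table, alpha=1.0)
        assert all(t.selected for t in result.traits)

    def test_parameter_recovery_5sd(self):
        """>=90% of 5-SD-shifted qFTs recovered, <=10% false positives."""
        rng = np.random.default_rng(42)
        n, n_shifted, n_noise = 8, 30, 30
        cols = {}
        for i in range(n_shifted):
            cols[f"collagen.shift{i}"] = np.concatenate(
                [rng.normal(0, 1, n), rng.normal(5, 1, n)]
            )
        for i in range(n_noise):
            cols[f"morphometric.noise{i}"] = rng.normal(0, 1, 2 * n)
        table = _table(cols, groups=("LEAN",) * n + ("MASH",) * n)
        result = select_traits(table)
        sel = set(result.selected_ids)
        recovered = sum(1 for i in range(n_shifted) if f"collagen.shift{i}" in sel)
        false_pos = sum(1 for i in range(n_noise) if f"morphometric.noise{i}" in sel)
        assert recovered / n_shifted >= 0.90
        assert false_pos / n_noise <= 0.10


class TestNormalizationAndScores:
    def test_degenerate_trait_dropped(self, shifted_table):
        shifted_table["architecture.const"] = 1.0
        result = select_traits(shifted_table, alpha=1.0)
        model = fit_normalization(shifted_table, result)
        assert "architecture.const" not in model.entries

    def test_direction_alignment_inverts_low_severity(self):
        rng = np.random.default_rng(0)
        down = np.concatenate([rng.normal(5, 1, 4), rng.normal(0, 1, 4)])
        table = _table({"collagen.down": down})
        result = select_traits(table)
        assert result.traits[0].direction == -1
        model = fit_normalization(table, result)
        scores = [
            composite_scores(row, model).ph_fcs
            for _, row in table.drop(columns="group").iterrows()
        ]
        # larger raw value -> lower severity score
        assert np.mean(scores[4:]) > np.mean(scores[:4])

    def test_permutation_invariance(self, shifted_table):
        result = select_traits(shifted_table)
        model_a = fit_normalization(shifted_table, result)
        permuted = shifted_table.sample(frac=1.0, random_state=5)
        model_b = fit_normalization(permuted, select_traits(permuted))
        assert model_a.entries == model_b.entries

    def test_anchor_samples_hit_score_bounds(self, shifted_table):
        result = select_traits(shifted_table)
        model = fit_normalization(shifted_table, result)
        aligned = {
            q: d * shifted_table[q].to_numpy() for q, (_, _, d) in model.entries.items()
        }
        # map aligned extrema back to raw values (direction is +/-1)
        lo_sample = {q: model.entries[q][2] * aligned[q].min() for q in model.entries}
        hi_sample = {q: model.entries[q][2] * aligned[q].max() for q in model.entries}
        assert composite_scores(lo_sample, model).ph_fcs == pytest.approx(1.0)
        assert composite_scores(hi_sample, model).ph_fcs == pytest.approx(10.0)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_scores_bounded_on_random_tables(self, seed):
        """Composite scores stay in [1, 10] for arbitrary cohort tables."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        cols = {
            f"{sub}.t{i}": rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), 2 * n)
            for sub in ("collagen", "morphometric", "architecture")
            for i in range(3)
        }
        table = _table(cols, groups=("LEAN",) * n + ("MASH",) * n)
        result = select_traits(table, alpha=1.0)
        model = fit_normalization(table, result)
        for _, row in table.drop(columns="group").iterrows():
            cs = composite_scores(row, model)
            assert 1.0 <= cs.ph_fcs <= 10.0
            assert all(1.0 <= v <= 10.0 for v in cs.sub_scores.values())

    def test_no_selection_raises(self):
        table = _table({"collagen.flat": [1.0] * 8})
        with pytest.raises(ValueError, match="no selected"):
            fit_normalization(table, select_traits(table))


class TestWelchAnova:
    def test_two_groups_equals_t_squared(self):
        a, b = np.array([1.0, 2, 3]), np.array([2.0, 3, 4])
        out = welch_anova({"LEAN": a, "MASH": b})
        t, df, p = _welch_t(a, b)
        assert out.f_statistic == pytest.approx(t**2, rel=1e-10)
        assert out.df1 == 1
        assert out.df2 == pytest.approx(4.0)
        assert out.p_value == pytest.approx(p, abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        groups = {
            "a": rng.normal(0, 1, 8),
            "b": rng.normal(0.5, 2, 6),
            "c": rng.normal(1, 0.5, 10),
        }
        out = welch_anova(groups)
        df = pd.DataFrame(
            [(g, v) for g, vals in groups.items() for v in vals], columns=["g", "y"]
        )
        ref = pg.welch_anova(data=df, dv="y", between="g").iloc[0]
        assert out.f_statistic == pytest.approx(ref["F"], rel=1e-9)
        assert out.df2 == pytest.approx(ref["ddof2"], rel=1e-9)
        assert out.p_value == pytest.approx(ref["p_unc"], rel=1e-9)

    def test_null_behavior_jittered_identical_groups(self):
        rng = np.random.default_rng(6)
        base = np.array([1.0, 2, 3, 4, 5])
        groups = {k: base + rng.normal(0, 1e-3, 5) for k in ("a", "b", "c")}
        assert welch_anova(groups).p_value > 0.9

    def test_zero_variance_group_named(self):
        with pytest.raises(ValueError, match="flatgrp"):
            welch_anova({"flatgrp": np.ones(3), "b": np.array([1.0, 2, 3])})


class TestDunnettT3:
    def test_single_comparison_unadjusted(self):
        a, b = np.array([1.0, 2, 3, 4]), np.array([2.0, 3, 4, 6])
        out = dunnett_t3({"LEAN": a, "MASH": b}, "LEAN")
        t, df, p = _welch_t(b, a)
        assert out.pairwise[0][4] == pytest.approx(p, rel=1e-12)

    def test_sidak_formula_three_comparisons(self):
        """Adjustment maps p=0.02 to 1-(1-0.02)^3 ~ 0.0588 for m=3."""
        assert 1 - (1 - 0.02) ** 3 == pytest.approx(0.0588, abs=1e-4)
        rng = np.random.default_rng(3)
        groups = {"ref": rng.normal(0, 1, 6)}
        groups.update({f"g{i}": rng.normal(2, 1, 6) for i in range(3)})
        out = dunnett_t3(groups, "ref")
        for g, _, t, df, p_adj in out.pairwise:
            from scipy import stats

            raw = 2 * stats.t.sf(abs(t), df)
            assert p_adj == pytest.approx(1 - (1 - raw) ** 3, rel=1e-9)

    def test_adjustment_monotone(self):
        rng = np.random.default_rng(4)
        groups = {"ref": rng.normal(0, 1, 5)}
        groups.update({f"g{i}": rng.normal(0.5, 1, 5) for i in range(4)})
        out = dunnett_t3(groups, "ref")
        for g, _, t, df, p_adj in out.pairwise:
            from scipy import stats

            raw = 2 * stats.t.sf(abs(t), df)
            assert p_adj >= raw - 1e-15

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            dunnett_t3({"a": np.ones(3)}, "REF")


class TestHeatmap:
    def test_rows_normalized_and_ordered(self, shifted_table):
        result = select_traits(shifted_table, alpha=1.0)
        matrix = heatmap_matrix(shifted_table, result)
        assert list(matrix.columns) == list(shifted_table.index)
        for _, row in matrix.iterrows():
            assert row.min() == pytest.approx(0.0)
            assert row.max() == pytest.approx(1.0)
        # rows grouped by sub-phenotype: collagen block first
        assert matrix.index[0].startswith("collagen.")

    def test_plot_heatmap_writes_file(self, tmp_path, shifted_table):
        result = select_traits(shifted_table, alpha=1.0)
        matrix = heatmap_matrix(shifted_table, result)
        out = tmp_path / "heatmap.png"
        fq.plot_heatmap(matrix, str(out))
        assert out.stat().st_size > 0
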