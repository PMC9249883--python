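import numpy as np
import pandas as pd
import pytest

from refselect import (
    DataFormatError,
    DesignError,
    ExpressionMatrix,
    ProbeMap,
    bonferroni_fwer,
    collapse_probes,
    flag_outliers,
    interaction_effect_size,
    relabel_subtypes,
    remove_batch_effect,
    two_group_effect_size,
)

from conftest import make_expression, make_metadata


class TestCollapseProbes:
    def _probe_matrix(self):
        values = pd.DataFrame(
            [[1.0, 3.0], [3.0, 5.0], [7.0, 9.0], [2.0, 2.0]],
            index=["p1", "p2", "p3", "p_unmapped"],
            columns=["s0", "s1"],
        )
        return ExpressionMatrix(values=values, scale_tag="log2")

    def test_mean_of_probe_rows(self):
        pm = ProbeMap({"p1": "GENE1", "p2": "GENE1", "p3": "GENE2"})
        out = collapse_probes(self._probe_matrix(), pm)
        assert out.values.loc["GENE1"].tolist() == [2.0, 4.0]

    def test_single_probe_identity(self):
        pm = ProbeMap({"p1": "GENE1", "p2": "GENE1", "p3": "GENE2"})
        out = collapse_probes(self._probe_matrix(), pm)
        assert out.values.loc["GENE2"].tolist() == [7.0, 9.0]

    def test_unmapped_probe_dropped_and_logged(self, caplog):
        pm = ProbeMap({"p1": "GENE1", "p2": "GENE1", "p3": "GENE2"})
        with caplog.at_level("INFO", logger="refselect.diffexpr"):
            out = collapse_probes(self._probe_matrix(), pm)
        assert "p_unmapped" not in out.values.index
        assert "dropped 1 unmapped" in caplog.text

    def test_empty_intersection_rejected(self):
        with pytest.raises(DataFormatError):
            collapse_probes(self._probe_matrix(), ProbeMap({"x": "G"}))


class TestRemoveBatchEffect:
    def test_single_batch_rejected(self):
        m, meta = make_expression([[1, 2, 3, 4]], ["A"] * 4, batches=["b1"] * 4)
        with pytest.raises(DesignError, match="2 batches"):
            remove_batch_effect(m, meta)

    def test_identical_batches_leave_matrix_unchanged(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(8, 1, size=(5, 8))
        arr[:, 4:] = arr[:, :4]  # batch 2 duplicates batch 1
        m, meta = make_expression(
            arr, ["A", "A", "B", "B"] * 2, batches=["b1"] * 4 + ["b2"] * 4
        )
        out = remove_batch_effect(m, meta)
        np.testing.assert_allclose(out.values.to_numpy(), arr, atol=1e-10)

    def test_constant_offset_removed_relative_structure_kept(self):
        rng = np.random.default_rng(1)
        base = rng.normal(8, 1, size=(10, 6))
        arr = base.copy()
        arr[:, 3:] += 5.0  # batch 2 shifted by +5 on every gene
        # same group mix in both batches, so the shift is pure batch effect
        m, meta = make_expression(
            arr, ["A", "B", "A", "A", "B", "A"],
            batches=["b1"] * 3 + ["b2"] * 3,
        )
        out = remove_batch_effect(m, meta).values.to_numpy()
        # within-batch relative differences preserved
        np.testing.assert_allclose(
            out[:, :3] - out[:, :1], arr[:, :3] - arr[:, :1], atol=1e-10
        )
        # the +5 offset is gone: batch means now agree
        np.testing.assert_allclose(
            out[:, :3].mean(axis=1), out[:, 3:].mean(axis=1), atol=1e-10
        )

    def test_idempotence_on_random_matrices(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(8, 1, size=(20, 12))
        groups = (["A"] * 3 + ["B"] * 3) * 2
        batches = ["b1"] * 6 + ["b2"] * 6
        arr[:, 6:] += rng.normal(0, 2, size=(20, 1))
        m, meta = make_expression(arr, groups, batches=batches)
        once = remove_batch_effect(m, meta)
        twice = remove_batch_effect(once, meta)
        np.testing.assert_allclose(
            twice.values.to_numpy(), once.values.to_numpy(), atol=1e-10
        )

    def test_balanced_design_preserves_group_mean_differences(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(8, 1, size=(15, 8))
        groups = ["A", "A", "B", "B"] * 2
        batches = ["b1"] * 4 + ["b2"] * 4
        arr[:, 4:] += 3.0
        m, meta = make_expression(arr, groups, batches=batches)
        out = remove_batch_effect(m, meta).values.to_numpy()
        a_cols = [i for i, g in enumerate(groups) if g == "A"]
        b_cols = [i for i, g in enumerate(groups) if g == "B"]
        before = arr[:, a_cols].mean(axis=1) - arr[:, b_cols].mean(axis=1)
        after = out[:, a_cols].mean(axis=1) - out[:, b_cols].mean(axis=1)
        np.testing.assert_allclose(after, before, atol=1e-10)

    def test_confounded_batch_group_rejected(self):
        m, meta = make_expression(
            [[1, 2, 3, 4]], ["A", "A", "B", "B"], batches=["b1", "b1", "b2", "b2"]
        )
        with pytest.raises(DesignError, match="confounded"):
            remove_batch_effect(m, meta)


class TestFlagOutliers:
    def test_identical_samples_not_flagged(self):
        arr = np.tile(np.arange(10.0)[:, None], (1, 5))
        m, _ = make_expression(arr, ["A"] * 5)
        assert flag_outliers(m) == []

    def test_negated_profile_flagged(self):
        rng = np.random.default_rng(4)
        profile = rng.normal(8, 2, size=50)
        cols = [profile + rng.normal(0, 0.3, 50) for _ in range(10)]
        cols.append(2 * profile.mean() - profile)  # mirror image
        m, _ = make_expression(np.column_stack(cols), ["A"] * 11)
        assert flag_outliers(m) == ["s10"]

    def test_fixed_cutoff_override(self):
        rng = np.random.default_rng(5)
        profile = rng.normal(8, 2, size=50)
        cols = [profile + rng.normal(0, 0.3, 50) for _ in range(4)]
        m, _ = make_expression(np.column_stack(cols), ["A"] * 4)
        assert flag_outliers(m, threshold_rule=0.5) == []
        assert len(flag_outliers(m, threshold_rule=1.01)) == 4

    def test_too_few_samples_rejected(self):
        m, _ = make_expression([[1, 2], [3, 4]], ["A", "A"])
        with pytest.raises(DesignError):
            flag_outliers(m)


class TestTwoGroupEffectSize:
    def test_identical_group_means_give_zero_es(self):
        m, meta = make_expression([[5, 6, 5, 6]], ["A", "A", "B", "B"])
        (rec,) = two_group_effect_size(m, meta, "A", "B")
        assert rec.es == 0.0

    def test_exact_unit_shift(self):
        m, meta = make_expression([[5, 6, 4, 5]], ["A", "A", "B", "B"])
        (rec,) = two_group_effect_size(m, meta, "A", "B")
        assert rec.es == pytest.approx(1.0)

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(6)
        m, meta = make_expression(rng.normal(8, 1, (5, 8)), ["A"] * 4 + ["B"] * 4)
        ab = two_group_effect_size(m, meta, "A", "B")
        ba = two_group_effect_size(m, meta, "B", "A")
        for r1, r2 in zip(ab, ba):
            assert r1.es == pytest.approx(-r2.es)
            assert r1.p == pytest.approx(r2.p)

    def test_closed_form_pooled_t_oracle(self):
        a = np.array([5.1, 5.9, 5.3])
        b = np.array([4.2, 4.8, 4.1])
        m, meta = make_expression([np.concatenate([a, b])], ["A"] * 3 + ["B"] * 3)
        (rec,) = two_group_effect_size(m, meta, "A", "B")
        # textbook pooled-variance t statistic
        sp2 = ((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(abs(t), 4)
        assert rec.es == pytest.approx(a.mean() - b.mean())
        assert rec.p == pytest.approx(p)

    def test_zero_residual_variance_handling(self, caplog):
        m, meta = make_expression(
            [[5, 5, 4, 4], [5, 5, 5, 5]], ["A", "A", "B", "B"]
        )
        with caplog.at_level("WARNING"):
            recs = two_group_effect_size(m, meta, "A", "B")
        assert recs[0].p == 0.0 and recs[1].p == 1.0
        assert "zero residual variance" in caplog.text

    def test_small_group_rejected(self):
        m, meta = make_expression([[5, 6, 5]], ["A", "A", "B"])
        with pytest.raises(DesignError, match="'B'"):
            two_group_effect_size(m, meta, "A", "B")

    def test_bonferroni_uses_gene_count(self):
        rng = np.random.default_rng(7)
        m, meta = make_expression(rng.normal(8, 1, (10, 8)), ["A"] * 4 + ["B"] * 4)
        for rec in two_group_effect_size(m, meta, "A", "B"):
            assert rec.fwer == pytest.approx(min(1.0, rec.p * 10))


class TestInteraction:
    @staticmethod
    def _four_cell(f_tum, f_norm, m_tum, m_norm):
        cells = [f_tum, f_norm, m_tum, m_norm]
        groups, sexes, values = [], [], []
        for vals, (sex, grp) in zip(
            cells,
            [("female", "PTC"), ("female", "Normal"),
             ("male", "PTC"), ("male", "Normal")],
        ):
            for v in vals:
                values.append(v)
                groups.append(grp)
                sexes.append(sex)
        return make_expression([values], groups, sexes=sexes)

    def test_equals_difference_of_sexwise_effects(self):
        rng = np.random.default_rng(8)
        m, meta = self._four_cell(*(rng.normal(8, 1, 4) for _ in range(4)))
        (rec,) = interaction_effect_size(m, meta, "PTC")
        (f,) = two_group_effect_size(m, meta, "PTC", "Normal", sex="female")
        (mm,) = two_group_effect_size(m, meta, "PTC", "Normal", sex="male")
        assert rec.es == pytest.approx(f.es - mm.es)

    def test_identical_sexwise_differences_give_zero(self):
        m, meta = self._four_cell([9, 9], [8, 8], [7, 7], [6, 6])
        (rec,) = interaction_effect_size(m, meta, "PTC")
        assert rec.es == pytest.approx(0.0)

    def test_empty_cell_named_in_error(self):
        m, meta = self._four_cell([9, 9], [8, 8], [7, 7], [6, 6])
        with pytest.raises(DesignError, match="male.tumor"):
            interaction_effect_size(m, meta, "FTA")

    def test_brute_force_and_statsmodels_oracle(self):
        rng = np.random.default_rng(9)
        cells = [rng.normal(8, 0.8, 3) for _ in range(4)]
        m, meta = self._four_cell(*cells)
        (rec,) = interaction_effect_size(m, meta, "PTC")
        es_oracle = (cells[0].mean() - cells[1].mean()) - (
            cells[2].mean() - cells[3].mean()
        )
        assert rec.es == pytest.approx(es_oracle)

        import statsmodels.api as sm

        y = np.concatenate(cells)
        labels = (["ft"] * 3 + ["fn"] * 3 + ["mt"] * 3 + ["mn"] * 3)
        X = pd.get_dummies(pd.Series(labels), dtype=float)[["ft", "fn", "mt", "mn"]]
        fit = sm.OLS(y, X).fit()
        tt = fit.t_test([1, -1, -1, 1])
        assert rec.es == pytest.approx(float(tt.effect[0]))
        assert rec.p == pytest.approx(float(tt.pvalue))

    def test_unknown_sex_excluded(self):
        m, meta = self._four_cell([9, 9], [8, 8], [7, 7], [6, 6])
        df = meta.table.copy()
        extra = pd.DataFrame(
            [{"sample_id": "sx", "group": "PTC", "sex": "unknown",
              "batch": "b1", "pair_id": ""}]
        )
        meta2 = make_metadata(pd.concat([df, extra]).to_dict("records"))
        vals = m.values.copy()
        vals["sx"] = 99.0
        m2 = ExpressionMatrix(values=vals, scale_tag="log2", metadata=meta2)
        (rec,) = interaction_effect_size(m2, meta2, "PTC")
        assert rec.es == pytest.approx(0.0)  # the unknown-sex sample is ignored


class TestBonferroni:
    def test_cap_and_scaling(self):
        assert bonferroni_fwer([0.001], 6331) == [1.0]
        assert bonferroni_fwer([1e-9], 6331)[0] == pytest.approx(6.331e-6)
        assert bonferroni_fwer([0.0], 100) == [0.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_fwer([1.2], 10)
        with pytest.raises(ValueError):
            bonferroni_fwer([-0.1], 10)


def test_relabel_subtypes_merges_variant_group():
    meta = make_metadata(
        [
            {"sample_id": "s0", "group": "FVPTC"},
            {"sample_id": "s1", "group": "PTC"},
        ]
    )
    out = relabel_subtypes(meta, {"FVPTC": "PTC"})
    assert set(out.table["group"]) == {"PTC"}
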