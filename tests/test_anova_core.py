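"""Nested ANOVA, BH-FDR, splicing filters and fold-change reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import exonsplice as xs
from exonsplice.errors import InputError

from _oracles import bh_oracle, nested_anova_oracle


def _design(n1=3, n2=3, groups=("g1", "g2")):
    ids = [f"{groups[0]}_a{i}" for i in range(n1)] + [f"{groups[1]}_a{i}" for i in range(n2)]
    return xs.GroupDesign(
        pd.Series([groups[0]] * n1 + [groups[1]] * n2, index=pd.Index(ids, name="array_id"))
    )


def _scores(design, n_exons, rng, group_shift=0.0, exon_shift=None):
    arrays = list(design.array_ids)
    data = rng.normal(0, 1, (n_exons, len(arrays)))
    g2 = [a in design.arrays_in(design.groups[1]) for a in arrays]
    data[:, g2] += group_shift
    if exon_shift is not None:
        e, delta = exon_shift
        data[e, g2] += delta
    return pd.DataFrame(data, index=[f"e{i}" for i in range(n_exons)], columns=arrays)


class TestFitNestedAnova:
    def test_all_equal_guarded_to_zero(self):
        design = _design(2, 2)
        scores = pd.DataFrame(1.0, index=["e0", "e1"], columns=design.array_ids)
        r = xs.fit_nested_anova(scores, design)
        assert (r.f_group, r.p_group) == (0.0, 1.0)
        assert (r.f_exon, r.p_exon) == (0.0, 1.0)
        assert (r.f_interaction, r.p_interaction) == (0.0, 1.0)

    def test_group_shift_matches_oracle(self):
        rng = np.random.default_rng(42)
        design = _design(3, 3)
        scores = _scores(design, 4, rng, group_shift=1.0)
        r = xs.fit_nested_anova(scores, design)
        o = nested_anova_oracle(scores, design)
        for key in ("f_group", "f_exon", "f_interaction"):
            assert getattr(r, key) == pytest.approx(o[key], rel=1e-10)

    def test_single_exon_shift_interaction(self):
        rng = np.random.default_rng(7)
        design = _design(3, 3)
        scores = _scores(design, 5, rng, exon_shift=(2, 4.0))
        r = xs.fit_nested_anova(scores, design)
        o = nested_anova_oracle(scores, design)
        assert r.f_interaction == pytest.approx(o["f_interaction"], rel=1e-10)
        assert r.p_interaction < r.p_group

    def test_unbalanced_cluster_rejected(self):
        design = _design(3, 3)
        scores = _scores(design, 3, np.random.default_rng(0)).drop(columns=["g2_a1"])
        with pytest.raises(InputError, match="unbalanced"):
            xs.fit_nested_anova(scores, design)

    def test_unequal_group_sizes_match_oracle(self):
        rng = np.random.default_rng(3)
        design = _design(2, 4)
        scores = _scores(design, 6, rng, group_shift=0.5)
        r = xs.fit_nested_anova(scores, design)
        o = nested_anova_oracle(scores, design)
        for key in ("f_group", "f_exon", "f_interaction", "p_group", "p_interaction"):
            assert getattr(r, key) == pytest.approx(o[key], rel=1e-9)

    def test_statsmodels_cross_check(self):
        sm = pytest.importorskip("statsmodels.api")
        smf = pytest.importorskip("statsmodels.formula.api")
        rng = np.random.default_rng(12)
        design = _design(3, 3)
        scores = _scores(design, 4, rng, group_shift=0.8, exon_shift=(1, 1.5))
        r = xs.fit_nested_anova(scores, design)

        long = scores.stack().rename("y").reset_index()
        long.columns = ["exon", "array", "y"]
        long["group"] = long["array"].map(design.assignments)
        # explicit nesting: replicate index within group, so the
        # array-within-group term is full rank with its own 4 df
        long["rep"] = long["array"].str.rsplit("a", n=1).str[-1]
        fit = smf.ols(
            "y ~ C(group) + C(group):C(rep) + C(exon) + C(group):C(exon)", data=long
        ).fit()
        tab = sm.stats.anova_lm(fit, typ=1)
        ms = tab["sum_sq"] / tab["df"]
        f_group = ms["C(group)"] / ms["C(group):C(rep)"]
        f_exon = ms["C(exon)"] / ms["Residual"]
        f_int = ms["C(group):C(exon)"] / ms["Residual"]
        assert r.f_group == pytest.approx(f_group, rel=1e-8)
        assert r.f_exon == pytest.approx(f_exon, rel=1e-8)
        assert r.f_interaction == pytest.approx(f_int, rel=1e-8)


class TestBhFdr:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.5], [0.5]),
            ([0.2, 0.2, 0.2, 0.2], [0.2, 0.2, 0.2, 0.2]),
        ],
    )
    def test_examples(self, p, expected):
        np.testing.assert_allclose(xs.bh_fdr(p), expected)

    def test_nan_rejected(self):
        with pytest.raises(InputError, match="NaN"):
            xs.bh_fdr([0.1, np.nan])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_matches_step_up_oracle(self, p):
        np.testing.assert_allclose(xs.bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_order_preserving(self):
        rng = np.random.default_rng(8)
        p = rng.random(200)
        adj = xs.bh_fdr(p)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestSplicingFpFilter:
    def _presence(self, per_gene_groups):
        rows = []
        for gene, groups in per_gene_groups.items():
            for g in ("g1", "g2"):
                rows.append(
                    {"transcript_cluster_id": gene, "group": g, "expressed": g in groups}
                )
        return pd.DataFrame(rows)

    def test_rules(self):
        pres = self._presence({"both": {"g1", "g2"}, "one": {"g2"}, "none": set()})
        kept, flags = xs.splicing_fp_filter(["both", "one", "none"], pres)
        assert kept == ["both"]
        assert flags == {"one": "near_background", "none": "near_background"}


class TestFoldChangeTtest:
    def _psm(self, g1_vals, g2_vals, cluster="c1"):
        design = _design(len(g1_vals), len(g2_vals))
        scores = pd.DataFrame(
            [list(g1_vals) + list(g2_vals)], index=["s1"], columns=design.array_ids
        )
        meta = pd.DataFrame(
            {"n_probes": [4], "transcript_cluster_id": [cluster]},
            index=pd.Index(["s1"], name="probe_set_id"),
        )
        probes = pd.DataFrame(
            {"probe_set_id": ["s1"], "gc_count": [10]},
            index=pd.Index(["p1"], name="probe_id"),
        )
        return xs.ProbeSetMatrix(scores, meta, probes), design

    def test_sign_convention(self):
        # log2 gene scores giving untransformed means 4 and 8 (offset 0)
        ps, design = self._psm([2.0, 2.0, 2.0], [3.0, 3.0, 3.0])
        row = xs.fold_change_and_ttest(ps, design, offset=0.0).iloc[0]
        assert row["fold_change"] == pytest.approx(2.0)
        ps, design = self._psm([3.0, 3.0, 3.0], [2.0, 2.0, 2.0])
        row = xs.fold_change_and_ttest(ps, design, offset=0.0).iloc[0]
        assert row["fold_change"] == pytest.approx(-2.0)

    def test_equal_means_unit(self):
        ps, design = self._psm([2.0] * 3, [2.0] * 3)
        row = xs.fold_change_and_ttest(ps, design, offset=0.0).iloc[0]
        assert row["fold_change"] == pytest.approx(1.0)
        assert row["t"] == 0.0 and row["p_value"] == 1.0

    def test_pooled_t_matches_hand_formula(self):
        # untransformed values g1 = [4, 5, 6], g2 = [8, 9, 10]
        g1 = np.log2([4.0, 5.0, 6.0])
        g2 = np.log2([8.0, 9.0, 10.0])
        ps, design = self._psm(g1, g2)
        row = xs.fold_change_and_ttest(ps, design, offset=0.0).iloc[0]
        # pooled: sp2 = 1, t = (9 - 5)/sqrt(1 * (1/3 + 1/3))
        t_hand = 4.0 / np.sqrt(2.0 / 3.0)
        p_hand = 2 * stats.t.sf(t_hand, 4)
        assert row["t"] == pytest.approx(t_hand, rel=1e-12)
        assert row["p_value"] == pytest.approx(p_hand, rel=1e-12)

    def test_reference_group_flips_sign(self):
        ps, design = self._psm([2.0] * 3, [3.0] * 3)
        fwd = xs.fold_change_and_ttest(ps, design, offset=0.0).iloc[0]
        rev = xs.fold_change_and_ttest(ps, design, offset=0.0, reference="g2").iloc[0]
        assert fwd["fold_change"] == pytest.approx(-rev["fold_change"])


class TestRunDifferentialAnalysis:
    def test_spiked_genes_called(self, sim_small_state):
        st_ = sim_small_state
        truth = st_.truth
        tested = set(st_.cascade.clusters)
        as_true = [g for g in truth.index[truth.is_as] if g in tested]
        assert as_true, "no AS gene survived the cascade"
        assert set(as_true) <= set(st_.differential.as_genes)
        de_true = [g for g in truth.index[truth.is_de] if g in tested]
        assert set(de_true) <= set(st_.differential.de_genes)

    def test_both_list_is_intersection(self, sim_small_state):
        d = sim_small_state.differential
        assert set(d.both) == set(d.de_genes) & set(d.as_genes)
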