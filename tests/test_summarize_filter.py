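"""Summarization, presence statistics and the filter cascade."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import exonsplice as xs
from exonsplice.errors import InputError

from conftest import make_background_model


def _annotation(set_sizes, cluster="c1", level="Core"):
    rows = []
    for s, size in set_sizes.items():
        for i in range(size):
            rows.append((f"{s}_p{i}", 10, s))
    probes = pd.DataFrame(
        [(r[1], r[2]) for r in rows],
        columns=["gc_count", "probe_set_id"],
        index=pd.Index([r[0] for r in rows], name="probe_id"),
    )
    sets = pd.DataFrame(
        {"transcript_cluster_id": [cluster] * len(set_sizes), "annotation_level": [level] * len(set_sizes)},
        index=pd.Index(list(set_sizes), name="probe_set_id"),
    )
    return xs.ChipAnnotation(probes, sets)


def _psm(score_rows, clusters=None, n_probes=4):
    """Hand-built ProbeSetMatrix; score_rows: {set_id: [per-array scores]}."""
    ids = list(score_rows)
    arrays = [f"a{i}" for i in range(len(next(iter(score_rows.values()))))]
    scores = pd.DataFrame(score_rows, index=arrays).T
    scores.index.name = "probe_set_id"
    meta = pd.DataFrame(
        {
            "n_probes": n_probes,
            "transcript_cluster_id": [clusters[s] if clusters else "c1" for s in ids],
        },
        index=scores.index,
    )
    probes = pd.DataFrame(
        {
            "probe_set_id": np.repeat(ids, 1),
            "gc_count": 10,
        },
        index=pd.Index([f"{s}_p0" for s in ids], name="probe_id"),
    )
    return xs.ProbeSetMatrix(scores, meta, probes)


class TestSummarize:
    def _corrected(self, ann, col):
        return xs.IntensityMatrix(
            pd.DataFrame({"A": col}, index=ann.probes.index), xs.Stage.BACKGROUND_CORRECTED
        )

    def test_median_odd_and_even(self):
        ann = _annotation({"s1": 3, "s2": 4})
        m = self._corrected(ann, [1.0, 2.0, 10.0, 1.0, 2.0, 3.0, 10.0])
        mask = pd.Series(True, index=ann.probes.index)
        ps = xs.summarize_probe_sets(m, ann, mask)
        assert ps.scores.loc["s1", "A"] == 2.0
        assert ps.scores.loc["s2", "A"] == 2.5

    def test_fewer_than_three_passing_probes_dropped(self):
        ann = _annotation({"s1": 2, "s2": 4})
        m = self._corrected(ann, [1.0] * 6)
        mask = pd.Series(True, index=ann.probes.index)
        ps = xs.summarize_probe_sets(m, ann, mask)
        assert "s1" not in ps.probe_set_ids
        assert "s2" in ps.probe_set_ids

    def test_mask_limits_probes(self):
        ann = _annotation({"s1": 4})
        m = self._corrected(ann, [1.0, 2.0, 3.0, 100.0])
        mask = pd.Series([True, True, True, False], index=ann.probes.index)
        ps = xs.summarize_probe_sets(m, ann, mask)
        assert ps.scores.loc["s1", "A"] == 2.0
        assert ps.meta.loc["s1", "n_probes"] == 3


class TestFilterCore:
    def test_core_kept_others_dropped(self):
        probes = pd.DataFrame(
            {"gc_count": [10, 10, 10], "probe_set_id": ["s1", "s2", "s3"]},
            index=pd.Index(["p1", "p2", "p3"], name="probe_id"),
        )
        sets = pd.DataFrame(
            {
                "transcript_cluster_id": ["c1"] * 3,
                "annotation_level": ["Core", "Extended", "Complete"],
            },
            index=pd.Index(["s1", "s2", "s3"], name="probe_set_id"),
        )
        assert list(xs.filter_core(xs.ChipAnnotation(probes, sets))) == ["s1"]

    def test_no_core_warns_empty(self):
        probes = pd.DataFrame(
            {"gc_count": [10], "probe_set_id": ["s1"]}, index=pd.Index(["p1"], name="probe_id")
        )
        sets = pd.DataFrame(
            {"transcript_cluster_id": ["c1"], "annotation_level": ["Extended"]},
            index=pd.Index(["s1"], name="probe_set_id"),
        )
        with pytest.warns(UserWarning, match="no Core"):
            assert len(xs.filter_core(xs.ChipAnnotation(probes, sets))) == 0


class TestProbeSetPresence:
    def _one_group(self, n_arrays=4):
        return xs.GroupDesign(
            pd.Series(["g1"] * n_arrays, index=pd.Index([f"a{i}" for i in range(n_arrays)], name="array_id"))
        )

    def test_t_equal_p_not_expressed(self):
        ps = _psm({"s1": [0.0, 0.0, 0.0, 0.0]})
        model = make_background_model(total_var=1.0)
        pres = xs.probe_set_presence(ps, model, self._one_group())
        row = pres.iloc[0]
        assert row["t0"] == pytest.approx(0.0)
        assert row["p_value"] == pytest.approx(0.5)
        assert not row["expressed"]

    def test_t0_of_3p1_is_expressed(self):
        # k = 2 probes, total_var = 4 -> Pvar = 1 (literal); 4 arrays at mean
        # 1.55 -> T0 = sqrt(4) * 1.55 = 3.1 -> p ~ 9.68e-4 <= 0.001
        ps = _psm({"s1": [1.55] * 4}, n_probes=2)
        ps.probes = pd.concat([ps.probes, ps.probes.rename(index=lambda s: s + "b")])
        model = make_background_model(total_var=4.0)
        pres = xs.probe_set_presence(ps, model, self._one_group())
        row = pres.iloc[0]
        assert row["t0"] == pytest.approx(3.1)
        assert row["p_value"] == pytest.approx(9.676e-4, rel=1e-3)
        assert row["expressed"]

    def test_negative_t_minus_p_not_expressed(self):
        ps = _psm({"s1": [-1.0] * 4})
        model = make_background_model(total_var=1.0)
        pres = xs.probe_set_presence(ps, model, self._one_group())
        assert pres.iloc[0]["p_value"] > 0.5

    def test_p_decreasing_in_t(self):
        ps = _psm({f"s{i}": [0.2 * i] * 4 for i in range(6)})
        model = make_background_model(total_var=1.0)
        pres = xs.probe_set_presence(ps, model, self._one_group()).sort_values("T")
        assert pres["p_value"].is_monotonic_decreasing

    def test_pvar_modes(self):
        ps = _psm({"s1": [1.0] * 4}, n_probes=4)
        model = make_background_model(total_var=16.0)
        lit = xs.probe_set_presence(ps, model, self._one_group(), pvar_mode="literal")
        mv = xs.probe_set_presence(ps, model, self._one_group(), pvar_mode="mean_variance")
        assert lit.iloc[0]["pvar"] == pytest.approx(1.0)  # 16 / 4^2
        assert mv.iloc[0]["pvar"] == pytest.approx(4.0)  # 16 / 4

    def test_null_rejection_rate_near_alpha(self):
        # scores and background drawn from the same unit normal (k = 1, so
        # T0 is exactly standard normal under the null)
        rng = np.random.default_rng(0)
        n_sets, n_arrays = 250, 4
        rows = {f"s{i}": rng.normal(0, 1, n_arrays) for i in range(n_sets)}
        ps = _psm(rows, n_probes=1)
        model = make_background_model(total_var=float(n_arrays))  # Pvar=n -> T0=mean*sqrt...
        # choose total_var so that sqrt(G)*(T)/sqrt(Pvar) ~ N(0,1):
        # Var(T) = 1/G, so Pvar must be 1 -> total_var = 1 with k = 1
        model = make_background_model(total_var=1.0)
        pres = xs.probe_set_presence(ps, model, self._one_group(n_arrays), alpha=0.001)
        count = int(pres["expressed"].sum())
        upper = int(stats.binom.ppf(0.995, n_sets, 0.001))
        assert count <= max(upper, 1)


class TestFilterExpressed:
    def _presence(self, flags):
        rows = []
        for (s, g), e in flags.items():
            rows.append({"probe_set_id": s, "group": g, "expressed": e})
        return pd.DataFrame(rows)

    def test_any_vs_all(self):
        pres = self._presence(
            {("s1", "g1"): True, ("s1", "g2"): False,
             ("s2", "g1"): False, ("s2", "g2"): False,
             ("s3", "g1"): True, ("s3", "g2"): True}
        )
        assert sorted(xs.filter_expressed(pres, require="any")) == ["s1", "s3"]
        assert sorted(xs.filter_expressed(pres, require="all")) == ["s3"]


class TestFilterInvariant:
    # N = 10 arrays: chi2 lower 10% quantile at 9 df is ~4.168
    def _scores(self, variances, cluster_map):
        base = np.arange(10, dtype=float)
        base = (base - base.mean()) / base.std(ddof=1)  # unit variance pattern
        rows = {s: np.sqrt(v) * base for s, v in variances.items()}
        return _psm(rows, clusters=cluster_map)

    def test_equal_variances_kept(self):
        ps = self._scores({"s1": 1.0, "s2": 1.0}, {"s1": "c1", "s2": "c1"})
        kept = xs.filter_invariant(ps, n_arrays=10)
        assert sorted(kept) == ["s1", "s2"]  # statistic 9 >= 4.168

    def test_zero_variance_dropped(self):
        ps = self._scores({"s1": 0.0, "s2": 1.0, "s3": 1.0}, {s: "c1" for s in ("s1", "s2", "s3")})
        kept = xs.filter_invariant(ps, n_arrays=10)
        assert "s1" not in kept and "s2" in kept

    def test_low_ratio_dropped(self):
        # s3 variance is 0.2x the cluster median -> statistic 1.8 < 4.168
        ps = self._scores({"s1": 1.0, "s2": 1.0, "s3": 0.2}, {s: "c1" for s in ("s1", "s2", "s3")})
        kept = xs.filter_invariant(ps, n_arrays=10)
        assert "s3" not in kept and sorted(kept) == ["s1", "s2"]

    def test_single_set_cluster_always_kept(self):
        ps = self._scores({"s1": 0.0}, {"s1": "c1"})
        assert list(xs.filter_invariant(ps, n_arrays=10)) == ["s1"]

    def test_median_reference_robust_to_one_loud_exon(self):
        var = {"s1": 10.0, "s2": 1.0, "s3": 1.0, "s4": 1.0}
        ps = self._scores(var, {s: "c1" for s in var})
        kept_median = xs.filter_invariant(ps, n_arrays=10, reference="median")
        kept_mean = xs.filter_invariant(ps, n_arrays=10, reference="mean")
        assert sorted(kept_median) == ["s1", "s2", "s3", "s4"]
        # mean reference (10+1+1+1)/4 = 3.25 -> statistic 9/3.25 < 4.168
        assert list(kept_mean) == ["s1"]


class TestFilterClusters:
    @pytest.mark.parametrize("n_sets,included", [(3, False), (4, True), (200, True), (201, False)])
    def test_four_to_two_hundred(self, n_sets, included):
        sets = pd.Index([f"s{i}" for i in range(n_sets)], name="probe_set_id")
        probes = pd.DataFrame(
            {"gc_count": 10, "probe_set_id": sets},
            index=pd.Index([f"p{i}" for i in range(n_sets)], name="probe_id"),
        )
        meta = pd.DataFrame(
            {"transcript_cluster_id": "c1", "annotation_level": "Core"}, index=sets
        )
        ann = xs.ChipAnnotation(probes, meta)
        clusters = xs.filter_clusters(sets, ann)
        assert ("c1" in clusters) is included


class TestCascade:
    def test_ledger_monotone_and_final_matrix(self, sim_small_state):
        ledger = sim_small_state.cascade.ledger
        ledger.validate_monotone()
        df = ledger.to_frame()
        assert list(df["step"]) == [0, 1, 2, 3, 4, 5]
        # step 4 is a no-op
        assert df.loc[3, "probes"] == df.loc[4, "probes"]
        assert df.loc[3, "probe_sets"] == df.loc[4, "probe_sets"]
        final = sim_small_state.cascade.probe_sets
        assert (final.meta["n_probes"] >= 3).all()
        counts = final.clusters().value_counts()
        assert counts.between(4, 200).all()

    def test_paper_style_ledger_markers(self, sim_small_state, tmp_path):
        p = tmp_path / "ledger.tsv"
        sim_small_state.cascade.ledger.to_tsv(p, paper_style=True)
        text = p.read_text()
        assert "(*)" in text and "(**)" in text
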