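"""False-positive filtering: thresholds, replicate confirmation, taxonomy
and rarefaction rules, and recovery of injected artifacts."""

import numpy as np
import pandas as pd
import pytest

from urbiome import filtering as flt
from urbiome import synthetic as syn


def _run(rep1, rep2, controls, ic=None, taxonomy=None):
    return flt.RawRun(rep1, rep2, controls, internal_control=ic,
                      taxonomy=taxonomy)


@pytest.fixture
def toy_run():
    features = ["f1", "f2", "f3"]
    samples = ["s1", "s2", "NEG1", "NEG2"]
    rep1 = pd.DataFrame(
        [[10, 100, 7], [0, 50, 3], [2, 0, 0], [5, 0, 0]],
        index=samples, columns=features,
    )
    rep2 = pd.DataFrame(
        [[20, 90, 0], [4, 60, 2], [0, 0, 0], [0, 0, 0]],
        index=samples, columns=features,
    )
    return _run(rep1, rep2, ["NEG1", "NEG2"])


class TestThresholds:
    def test_tcc_is_max_over_controls_both_replicates(self, toy_run):
        tcc = flt.compute_tcc(toy_run)
        assert tcc["f1"] == 5  # max of {2, 5, 0, 0}
        assert tcc["f2"] == 0
        assert tcc["f3"] == 0

    def test_tcc_requires_controls(self, toy_run):
        bad = flt.RawRun(toy_run.replicate1, toy_run.replicate2, [])
        with pytest.raises(ValueError):
            flt.compute_tcc(bad)

    def test_tfa_is_ceiling_of_run_total_times_rate(self):
        rep = pd.DataFrame({"f": [25000]}, index=["s1"])
        run = _run(rep, rep.copy(), ["s1"])  # content irrelevant to totals
        tfa = flt.compute_tfa(run, 1e-4)
        assert tfa["f"] == 5  # ceil(50000 * 1e-4)
        assert flt.compute_tfa(run, 0.0)["f"] == 0

    def test_tfa_rate_reestimated_from_internal_control_leakage(self):
        # IC feature: 12 of 60,000 reads observed outside its sample
        # -> estimated rate 2e-4 replaces the 1e-4 default
        rep1 = pd.DataFrame(
            {"ic": [29994, 6], "f": [0, 10000]}, index=["IC", "s1"]
        )
        rep2 = pd.DataFrame(
            {"ic": [29994, 6], "f": [0, 10000]}, index=["IC", "s1"]
        )
        run = _run(rep1, rep2, ["s1"], ic=("IC", "ic"))
        tfa = flt.compute_tfa(run, 1e-4)
        assert tfa["f"] == int(np.ceil(20000 * 2e-4))

    def test_apply_discards_at_or_below_threshold(self):
        table = pd.DataFrame({"f": [5, 6]}, index=["s1", "s2"])
        thr = flt.FilterThresholds(
            t_cc=pd.Series({"f": 5}), t_fa=pd.Series({"f": 3})
        )
        out = flt.apply_thresholds(table, thr)
        assert out.loc["s1", "f"] == 0  # 5 <= max(5, 3): discarded
        assert out.loc["s2", "f"] == 6
        strict = flt.apply_thresholds(table, thr, strict=True)
        assert strict.loc["s1", "f"] == 5  # strictly-below variant keeps ties

    def test_zero_thresholds_are_a_no_op_on_positive_counts(self, toy_run):
        thr = flt.FilterThresholds(
            t_cc=pd.Series(0, index=toy_run.replicate1.columns),
            t_fa=pd.Series(0, index=toy_run.replicate1.columns),
        )
        table = toy_run.replicate1 + 1
        pd.testing.assert_frame_equal(flt.apply_thresholds(table, thr), table)


class TestConfirmReplicates:
    @pytest.mark.parametrize(
        "a,b,expected", [(10, 20, 30), (10, 0, 0), (0, 0, 0)]
    )
    def test_summed_only_when_both_positive(self, a, b, expected):
        r1 = pd.DataFrame({"f": [a]}, index=["s"])
        r2 = pd.DataFrame({"f": [b]}, index=["s"])
        assert flt.confirm_replicates(r1, r2).loc["s", "f"] == expected

    def test_index_mismatch_rejected(self):
        r1 = pd.DataFrame({"f": [1]}, index=["s1"])
        r2 = pd.DataFrame({"f": [1]}, index=["s2"])
        with pytest.raises(ValueError):
            flt.confirm_replicates(r1, r2)


class TestTaxonomicFilter:
    def test_rules(self):
        table = pd.DataFrame(
            [[1, 1, 1, 1, 1]],
            index=["s"],
            columns=["ok", "euk", "chloro", "nophylum", "mito"],
        )
        taxonomy = pd.DataFrame(
            {
                "Kingdom": ["Bacteria", "Eukaryota", "Bacteria", "Bacteria",
                            "Bacteria"],
                "Phylum": ["Firmicutes", "X", "Chloroplast", "", "Proteo"],
                "Family": ["Lachnospiraceae", "Y", "Z", "W", "Mitochondria"],
            },
            index=["ok", "euk", "chloro", "nophylum", "mito"],
        )
        out = flt.taxonomic_filter(table, taxonomy)
        assert list(out.columns) == ["ok"]

    def test_missing_taxonomy_counts_as_unaffiliated(self):
        table = pd.DataFrame([[1, 1]], index=["s"], columns=["a", "b"])
        taxonomy = pd.DataFrame(
            {"Kingdom": ["Bacteria"], "Phylum": ["P"], "Family": ["F"]},
            index=["a"],
        )
        assert list(flt.taxonomic_filter(table, taxonomy).columns) == ["a"]


class TestRarefaction:
    def test_saturated_sample_kept(self):
        table = pd.DataFrame([[60, 80, 120]], index=["deep"],
                             columns=list("abc"))
        out = flt.rarefaction_check(table)
        assert bool(out.loc["deep", "keep"])

    def test_singleton_dominated_sample_dropped(self):
        row = {f"f{i}": 1 for i in range(95)}
        row["f_big"] = 5
        table = pd.DataFrame([row], index=["shallow"])
        out = flt.rarefaction_check(table)
        assert not bool(out.loc["shallow", "keep"])
        assert out.loc["shallow", "slope"] > 1.0

    def test_empty_sample_dropped_with_warning(self):
        table = pd.DataFrame([[0, 0]], index=["empty"], columns=["a", "b"])
        with pytest.warns(UserWarning):
            out = flt.rarefaction_check(table)
        assert not bool(out.loc["empty", "keep"])

    def test_curve_is_monotone_and_ends_at_observed_richness(self):
        row = pd.Series({"a": 50, "b": 30, "c": 1}, name="s")
        curve = flt.rarefaction_curve(row)
        assert (np.diff(curve.to_numpy()) >= -1e-9).all()
        assert curve.iloc[-1] == pytest.approx(3.0)


class TestGroupSizeFilter:
    @pytest.fixture
    def metadata(self):
        rows = []
        for i in range(5):
            rows.append({"sample": f"a{i}", "species": "sp1", "site": "X",
                         "dead": False})
        for i in range(4):
            rows.append({"sample": f"b{i}", "species": "sp2", "site": "X",
                         "dead": False})
        return pd.DataFrame(rows).set_index("sample")

    def test_boundary_at_min_n(self, metadata):
        kept = flt.group_size_filter(metadata, min_n=5)
        assert sorted(kept) == [f"a{i}" for i in range(5)]

    def test_min_n_one_is_identity(self, metadata):
        assert sorted(flt.group_size_filter(metadata, min_n=1)) == sorted(
            metadata.index
        )

    def test_dead_and_outliers_removed_before_counting(self, metadata):
        md = metadata.copy()
        md.loc["a0", "dead"] = True  # sp1 drops to 4: whole group removed
        assert flt.group_size_filter(md, min_n=5) == []
        assert flt.group_size_filter(metadata, min_n=5,
                                     exclude_species=("sp1",)) == []


class TestNormalize:
    def test_rows_sum_to_one(self):
        table = pd.DataFrame([[2, 2], [30, 70]], index=["s1", "s2"],
                             columns=["a", "b"])
        out = flt.normalize_proportions(table)
        assert out.loc["s1"].tolist() == [0.5, 0.5]
        assert out.loc["s2"].tolist() == [0.3, 0.7]

    def test_zero_row_rejected_by_name(self):
        table = pd.DataFrame([[0, 0]], index=["bad"], columns=["a", "b"])
        with pytest.raises(ValueError, match="bad"):
            flt.normalize_proportions(table)


@pytest.fixture(scope="module")
def raw():
    tree = syn.simulate_tree(100, 5)
    tabs = []
    for proc, s, seed in [("filtering", 5, 1), ("neutral", 1, 2)]:
        tb, _ = syn.simulate_assembly(tree, proc, s, 10, 20, seed=seed,
                                      depth=3000)
        tb.index = [f"{proc}{i}" for i in range(10)]
        tabs.append(tb)
    true = pd.concat(tabs).fillna(0).astype(int)
    rep1, rep2, controls, ic, _truth = syn.simulate_sequencing(
        true, depth=5000, contamination_rate=0.002,
        misassignment_rate=1e-4, n_negative_controls=3, seed=9,
    )
    return true, flt.RawRun(rep1, rep2, controls, internal_control=ic)


class TestPipelineRecovery:
    def test_contaminants_removed_true_signal_kept(self, raw):
        true, run = raw
        thr = flt.FilterThresholds(
            flt.compute_tcc(run), flt.compute_tfa(run, 1e-4)
        )
        f1 = flt.apply_thresholds(run.replicate1, thr)
        f2 = flt.apply_thresholds(run.replicate2, thr)
        confirmed = flt.confirm_replicates(f1, f2)
        real = list(true.index)
        contam = [c for c in run.replicate1.columns if c.startswith("CONT")]
        injected = (run.replicate1.loc[real, contam]
                    + run.replicate2.loc[real, contam]) > 0
        removed = injected & (confirmed.loc[real, contam] == 0)
        assert removed.to_numpy().sum() >= 0.95 * injected.to_numpy().sum()

        thr_c = thr.combined
        feats = list(true.columns)
        above = (
            (run.replicate1.loc[real, feats] > thr_c[feats])
            & (run.replicate2.loc[real, feats] > thr_c[feats])
            & (true.loc[real, feats] > 0)
        )
        lost = above & (confirmed.loc[real, feats] == 0)
        assert lost.to_numpy().sum() <= 0.05 * above.to_numpy().sum()

    def test_filter_never_increases_counts_and_is_idempotent(self, raw):
        true, run = raw
        thr = flt.FilterThresholds(
            flt.compute_tcc(run), flt.compute_tfa(run, 1e-4)
        )
        once = flt.apply_thresholds(run.replicate1, thr)
        assert (once.to_numpy() <= run.replicate1.to_numpy()).all()
        pd.testing.assert_frame_equal(flt.apply_thresholds(once, thr), once)
        confirmed = flt.confirm_replicates(once, once)
        # confirming an already-confirmed table with itself only rescales
        assert ((confirmed > 0) == (once > 0)).all().all()

    def test_full_pipeline_report_and_proportions(self, raw):
        true, run = raw
        metadata = pd.DataFrame(
            {
                "species": ["f"] * 10 + ["n"] * 10,
                "site": ["X"] * 20,
                "dead": [False] * 20,
            },
            index=list(true.index),
        )
        res = flt.run_filter_pipeline(run, metadata=metadata, min_group=5)
        props = res["proportions"]
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-12)
        assert res["report"]["final"]["n_samples"] == props.shape[0]
        # controls and internal control are gone
        assert not set(run.negative_control_ids) & set(props.index)
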