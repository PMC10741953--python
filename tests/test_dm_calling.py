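import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_force_dm, cluster_oracle
from imprintscan.dm_calling import (ClusterSet, ControlReference,
                                    aggregate_units, assign_bins,
                                    bin_membership, build_reference, call_dm,
                                    find_clusters, make_bin_id, parse_bin_id)
from imprintscan.io_model import (BetaMatrix, MMatrix, ProbeManifest,
                                  SampleSheet, ValidationError)
from imprintscan.preprocess import beta_to_m


def _sheet(controls, others=()):
    rows = [(c, "control", None, "iPSC") for c in controls]
    rows += [(s, "patient", None, "iPSC") for s in others]
    return SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "role", "parent_patient", "cell_type"]))


def _ref(mean_m, sd_m, median_beta, units=("u",)):
    return ControlReference(pd.DataFrame({
        "mean_m": mean_m, "sd_m": sd_m, "median_beta": median_beta,
        "n_controls": 3}, index=list(units)))


class TestBuildReference:
    def test_hand_arithmetic(self):
        beta = BetaMatrix(pd.DataFrame({"C1": [0.3], "C2": [0.5], "C3": [0.9]},
                                       index=["u"]))
        m = MMatrix(pd.DataFrame({"C1": [1.0], "C2": [2.0], "C3": [3.0]},
                                 index=["u"]))
        ref = build_reference(beta, m, _sheet(["C1", "C2", "C3"]))
        row = ref.table.loc["u"]
        assert row["mean_m"] == pytest.approx(2.0)
        assert row["sd_m"] == pytest.approx(1.0)       # n-1 denominator
        assert row["median_beta"] == pytest.approx(0.5)
        assert row["n_controls"] == 3

    def test_identical_controls_give_zero_sd(self):
        beta = BetaMatrix(pd.DataFrame({"C1": [0.8], "C2": [0.8]}, index=["u"]))
        ref = build_reference(beta, beta_to_m(beta), _sheet(["C1", "C2"]))
        assert ref.table.loc["u", "sd_m"] == 0.0

    def test_units_missing_in_a_control_dropped_with_warning(self):
        beta = BetaMatrix(pd.DataFrame({"C1": [0.5, np.nan], "C2": [0.5, 0.5]},
                                       index=["a", "b"]))
        with pytest.warns(UserWarning, match="missing in at least one control"):
            ref = build_reference(beta, beta_to_m(beta), _sheet(["C1", "C2"]))
        assert ref.unit_ids == ["a"]


class TestCallDm:
    def test_hyper_call(self):
        ref = _ref([0.0], [0.2], [0.5])
        beta = BetaMatrix(pd.DataFrame({"s": [0.8]}, index=["u"]))
        m = MMatrix(pd.DataFrame({"s": [1.0]}, index=["u"]))
        call = call_dm(beta, m, ref, "s").iloc[0]
        assert call["status"] == "hyper"
        assert call["delta_m"] == pytest.approx(1.0)
        assert call["delta_beta"] == pytest.approx(0.3)

    def test_beta_criterion_fails(self):
        ref = _ref([0.0], [0.2], [0.5])
        beta = BetaMatrix(pd.DataFrame({"s": [0.65]}, index=["u"]))
        m = MMatrix(pd.DataFrame({"s": [1.0]}, index=["u"]))
        assert call_dm(beta, m, ref, "s").iloc[0]["status"] == "unchanged"

    def test_identity_sample(self):
        ref = _ref([0.0], [0.2], [0.5])
        beta = BetaMatrix(pd.DataFrame({"s": [0.5]}, index=["u"]))
        m = MMatrix(pd.DataFrame({"s": [0.0]}, index=["u"]))
        call = call_dm(beta, m, ref, "s").iloc[0]
        assert call["status"] == "unchanged"
        assert call["delta_beta"] == 0.0 and call["delta_m"] == 0.0

    def test_strict_inequalities(self):
        # delta_beta exactly 0.2 and |delta_m| exactly 3*sd -> unchanged
        ref = _ref([0.0], [0.2], [0.5])
        beta = BetaMatrix(pd.DataFrame({"s": [0.7]}, index=["u"]))
        m = MMatrix(pd.DataFrame({"s": [0.6]}, index=["u"]))
        assert call_dm(beta, m, ref, "s").iloc[0]["status"] == "unchanged"

    def test_unknown_sample_rejected(self):
        ref = _ref([0.0], [0.2], [0.5])
        beta = BetaMatrix(pd.DataFrame({"s": [0.5]}, index=["u"]))
        m = MMatrix(pd.DataFrame({"s": [0.0]}, index=["u"]))
        with pytest.raises(ValidationError, match="unknown sample"):
            call_dm(beta, m, ref, "nope")

    def test_zero_sd_units_flagged_and_called_on_beta_criterion(self):
        ref = _ref([2.0], [0.0], [0.8])
        beta = BetaMatrix(pd.DataFrame({"s": [0.3]}, index=["u"]))
        m = MMatrix(pd.DataFrame({"s": [-1.0]}, index=["u"]))
        with pytest.warns(UserWarning, match="sd_m = 0"):
            call = call_dm(beta, m, ref, "s").iloc[0]
        assert call["status"] == "hypo"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        samples = [f"C{i}" for i in range(5)] + ["X"]
        data = pd.DataFrame(rng.random((60, 6)), columns=samples,
                            index=[f"u{i}" for i in range(60)])
        beta = BetaMatrix(data)
        m = beta_to_m(beta)
        ref = build_reference(beta, m, _sheet([f"C{i}" for i in range(5)], ["X"]))
        calls = call_dm(beta, m, ref, "X").set_index("unit_id")
        expected = brute_force_dm(data, "X", [f"C{i}" for i in range(5)])
        assert set(calls.index) == set(expected)
        for unit, (db, dm, status) in expected.items():
            assert calls.at[unit, "status"] == status
            assert calls.at[unit, "delta_beta"] == pytest.approx(db)
            assert calls.at[unit, "delta_m"] == pytest.approx(dm)

    def test_mirror_symmetry_swaps_labels(self):
        rng = np.random.default_rng(5)
        controls = [f"C{i}" for i in range(5)]
        data = pd.DataFrame(rng.random((200, 6)), columns=controls + ["X"],
                            index=[f"u{i}" for i in range(200)])
        sheet = _sheet(controls, ["X"])

        def run(df):
            beta = BetaMatrix(df)
            m = beta_to_m(beta)
            ref = build_reference(beta, m, sheet)
            return call_dm(beta, m, ref, "X").set_index("unit_id")["status"]

        direct = run(data)
        mirrored = run(1.0 - data)
        swap = {"hyper": "hypo", "hypo": "hyper", "unchanged": "unchanged"}
        assert (mirrored == direct.map(swap)).all()

    def test_no_false_calls_when_sample_equals_a_control(self):
        rng = np.random.default_rng(9)
        controls = [f"C{i}" for i in range(6)]
        data = pd.DataFrame(rng.random((300, 6)), columns=controls,
                            index=[f"u{i}" for i in range(300)])
        data["X"] = data["C0"]
        beta = BetaMatrix(data)
        m = beta_to_m(beta)
        ref = build_reference(beta, m, _sheet(controls, ["X"]))
        calls = call_dm(beta, m, ref, "X")
        nonzero_sd = calls["sd_m"] > 0
        assert (calls.loc[nonzero_sd, "status"] == "unchanged").all()

    def test_monotone_in_sample_beta_above_median(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            controls = rng.random(7)
            df = pd.DataFrame({f"C{i}": [c] for i, c in enumerate(controls)},
                              index=["u"])
            sheet = _sheet(list(df.columns), ["X"])
            statuses = []
            for b in np.linspace(np.median(controls) + 1e-6, 0.999, 40):
                data = df.copy()
                data["X"] = b
                beta = BetaMatrix(data)
                m = beta_to_m(beta)
                ref = build_reference(beta, m, sheet)
                statuses.append(call_dm(beta, m, ref, "X").iloc[0]["status"])
            for prev, cur in zip(statuses, statuses[1:]):
                assert not (prev == "hyper" and cur == "unchanged")


class TestBins:
    def test_floor_assignment(self):
        man = ProbeManifest(pd.DataFrame({
            "probe_id": ["a", "b", "c"], "chrom": "chr1",
            "pos": [1250, 1500, 0], "snp_overlap": False, "sex_chrom": False}))
        bins = assign_bins(man)
        assert bins.at["a", "bin_id"] == "chr1:1000-1500"
        assert bins.at["b", "bin_id"] == "chr1:1500-2000"  # half-open boundary
        assert bins.at["c", "bin_id"] == "chr1:0-500"

    def test_bin_id_round_trip(self):
        assert parse_bin_id(make_bin_id("chrX", 1500)) == ("chrX", 1500)
        with pytest.raises(ValidationError):
            parse_bin_id("garbage")


class TestAggregateUnits:
    def test_unweighted_mean(self):
        beta = BetaMatrix(pd.DataFrame({"s": [0.2, 0.4, 0.6]},
                                       index=["a", "b", "c"]))
        out = aggregate_units(beta, {"a": "g", "b": "g", "c": "g"}, min_cpgs=2)
        assert out.data.at["g", "s"] == pytest.approx(0.4)

    def test_small_groups_excluded(self):
        beta = BetaMatrix(pd.DataFrame({"s": [0.2, 0.4, 0.6]},
                                       index=["a", "b", "c"]))
        out = aggregate_units(beta, {"a": "g1", "b": "g2", "c": "g2"}, min_cpgs=2)
        assert out.unit_ids == ["g2"]
        out3 = aggregate_units(beta, {"a": "g", "b": "g", "c": "x"}, min_cpgs=3)
        assert out3.unit_ids == []

    def test_missing_member_blanks_that_sample_only(self):
        beta = BetaMatrix(pd.DataFrame({"s1": [0.2, np.nan], "s2": [0.2, 0.4]},
                                       index=["a", "b"]))
        out = aggregate_units(beta, {"a": "g", "b": "g"}, min_cpgs=2)
        assert np.isnan(out.data.at["g", "s1"])
        assert out.data.at["g", "s2"] == pytest.approx(0.3)

    def test_empty_membership_rejected(self):
        beta = BetaMatrix(pd.DataFrame({"s": [0.5]}, index=["a"]))
        with pytest.raises(ValidationError, match="empty membership"):
            aggregate_units(beta, {}, min_cpgs=2)

    def test_bin_call_equals_hand_built_bin_matrix(self):
        # 6 probes in 2 bins; aggregating then calling == calling on the
        # hand-averaged matrix
        rng = np.random.default_rng(2)
        man = ProbeManifest(pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(6)], "chrom": "chr1",
            "pos": [100, 200, 400, 600, 700, 900],
            "snp_overlap": False, "sex_chrom": False}))
        samples = ["C1", "C2", "C3", "X"]
        data = pd.DataFrame(rng.random((6, 4)), columns=samples,
                            index=man.probe_ids)
        beta = BetaMatrix(data)
        sheet = _sheet(["C1", "C2", "C3"], ["X"])
        agg = aggregate_units(beta, bin_membership(man), min_cpgs=2)
        m = beta_to_m(agg)
        ref = build_reference(agg, m, sheet)
        got = call_dm(agg, m, ref, "X")

        hand = pd.DataFrame({s: [data[s][:3].mean(), data[s][3:].mean()]
                             for s in samples},
                            index=["chr1:0-500", "chr1:500-1000"])
        hb = BetaMatrix(hand)
        hm = beta_to_m(hb)
        href = build_reference(hb, hm, sheet)
        want = call_dm(hb, hm, href, "X")
        pd.testing.assert_frame_equal(got, want)


class TestFindClusters:
    def test_worked_example(self):
        cs = find_clusters([("chr1", 1000), ("chr1", 1500), ("chr1", 3000)])
        assert cs.clusters == [["chr1:1000-1500", "chr1:1500-2000"]]
        assert cs.isolated == ["chr1:3000-3500"]

    def test_single_bin_isolated(self):
        cs = find_clusters([("chr1", 500)])
        assert cs.clusters == [] and cs.isolated == ["chr1:500-1000"]

    def test_run_of_three(self):
        cs = find_clusters([("chr1", 0), ("chr1", 500), ("chr1", 1000)])
        assert len(cs.clusters) == 1 and len(cs.clusters[0]) == 3
        assert cs.isolated == []

    def test_chromosome_break_splits_runs(self):
        cs = find_clusters([("chr1", 0), ("chr1", 500), ("chr2", 1000),
                            ("chr2", 1500)])
        assert len(cs.clusters) == 2

    def test_duplicates_collapsed(self):
        cs = find_clusters(["chr1:0-500", "chr1:0-500", "chr1:500-1000"])
        assert cs.n_cluster_bins == 2

    @settings(max_examples=200, deadline=None)
    @given(st.sets(st.integers(min_value=0, max_value=9), max_size=10))
    def test_agrees_with_run_enumeration_oracle(self, idx):
        starts = [500 * i for i in sorted(idx)]
        cs = find_clusters([("chr1", s) for s in starts])
        want_clusters, want_isolated = cluster_oracle(starts)
        got_clusters = [[parse_bin_id(b)[1] for b in c] for c in cs.clusters]
        got_isolated = [parse_bin_id(b)[1] for b in cs.isolated]
        assert got_clusters == sorted(want_clusters)
        assert sorted(got_isolated) == sorted(want_isolated)
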