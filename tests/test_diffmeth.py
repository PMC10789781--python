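"""Beta/M transforms, per-probe tests, filters, DMR chaining and CpG context."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import radlayers as rl
from radlayers import data_io, diffmeth


def _manifest(positions, chrom="chr1"):
    frame = pd.DataFrame(
        {
            "chrom": chrom,
            "pos0": np.asarray(positions) - 1,
            "cpg_relation": "OpenSea",
            "genic_group": "Intergenic",
        },
        index=pd.Index([f"p{i}" for i in range(len(positions))], name="probe_id"),
    )
    return data_io.ProbeManifest(frame)


class TestBetaM:
    def test_symmetry_point(self):
        assert diffmeth.beta_to_m(0.5) == 0.0

    def test_log2_value(self):
        assert diffmeth.beta_to_m(0.8) == pytest.approx(2.0, abs=1e-12)

    def test_boundary_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            m = diffmeth.beta_to_m(np.array([0.0, 1.0]))
        assert np.isfinite(m).all()

    def test_domain_error(self):
        with pytest.raises(ValueError):
            diffmeth.beta_to_m(1.5)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    def test_round_trip(self, beta):
        assert diffmeth.m_to_beta(diffmeth.beta_to_m(beta)) == pytest.approx(
            beta, abs=1e-12
        )


def _experiment(values: dict, doses: dict, manifest=None):
    df = pd.DataFrame(values)
    if manifest is None:
        manifest = _manifest(np.arange(len(df)) * 10_000 + 1)
        df.index = manifest.probe_ids
    sheet = pd.DataFrame(
        {
            "particle": "Fe",
            "dose_gy": [doses[s] for s in df.columns],
            "timepoint": "48h",
            "replicate": np.arange(len(df.columns)),
        },
        index=pd.Index(df.columns, name="sample_id"),
    )
    return diffmeth.MethylationExperiment(df, "m", sheet, manifest)


class TestDefineControl:
    def test_mean_of_pooled_controls(self):
        exp = _experiment(
            {"c1": [-1.0], "c2": [0.0], "c3": [1.0], "t1": [9.0]},
            {"c1": 0, "c2": 0, "c3": 0, "t1": 1.0},
        )
        assert diffmeth.define_control(exp).iloc[0] == 0.0

    def test_single_control_is_itself(self):
        exp = _experiment({"c1": [2.5], "t1": [0.0]}, {"c1": 0, "t1": 1.0})
        assert diffmeth.define_control(exp).iloc[0] == 2.5

    def test_missing_excluded_pairwise(self):
        exp = _experiment(
            {"c1": [1.0], "c2": [np.nan], "c3": [3.0], "t1": [0.0]},
            {"c1": 0, "c2": 0, "c3": 0, "t1": 1.0},
        )
        assert diffmeth.define_control(exp).iloc[0] == 2.0

    def test_no_control_is_config_error(self):
        exp = _experiment({"t1": [0.0], "t2": [1.0]}, {"t1": 1.0, "t2": 1.0})
        with pytest.raises(data_io.ValidationError):
            diffmeth.define_control(exp)


class TestCallDmps:
    def test_identical_groups_do_not_pass(self):
        exp = _experiment(
            {s: [1.0, 2.0] for s in ("a1", "a2", "a3", "b1", "b2", "b3")},
            {"a1": 1, "a2": 1, "a3": 1, "b1": 0, "b2": 0, "b3": 0},
        )
        ctrl = diffmeth.define_control(exp)
        out = diffmeth.call_dmps(exp, ["a1", "a2", "a3"], ["b1", "b2", "b3"], ctrl)
        assert (out["av_diff"] == 0).all()
        assert not out["passes"].any()
        assert (out["degenerate"]).all() and (out["p"] == 1).all()

    def test_strong_separation_tiny_jitter(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 0.01, size=(50, 3))
        b = rng.normal(0.0, 0.01, size=(50, 3))
        cols = {f"a{i}": a[:, i] for i in range(3)} | {f"b{i}": b[:, i] for i in range(3)}
        exp = _experiment(cols, {f"a{i}": 1.0 for i in range(3)} | {f"b{i}": 0.0 for i in range(3)})
        out = diffmeth.call_dmps(exp, [f"a{i}" for i in range(3)], [f"b{i}" for i in range(3)],
                                 diffmeth.define_control(exp))
        assert (out["f_stat"] > 1000).all()
        assert (out["p"] < 1e-6).all()

    def test_matches_anova_oracle(self):
        """Vectorised two-group F equals scipy's one-way ANOVA probe by probe."""
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, size=(200, 3))
        b = rng.normal(0.3, 1, size=(200, 4))
        cols = {f"a{i}": a[:, i] for i in range(3)} | {f"b{i}": b[:, i] for i in range(4)}
        doses = {f"a{i}": 1.0 for i in range(3)} | {f"b{i}": 0.0 for i in range(4)}
        exp = _experiment(cols, doses)
        out = diffmeth.call_dmps(exp, [f"a{i}" for i in range(3)], [f"b{i}" for i in range(4)],
                                 diffmeth.define_control(exp))
        for k in range(200):
            f, p = stats.f_oneway(a[k], b[k])
            assert out["f_stat"].iloc[k] == pytest.approx(f, abs=1e-10)
            assert out["p"].iloc[k] == pytest.approx(p, abs=1e-10)

    def test_degenerate_different_means(self):
        exp = _experiment(
            {"a1": [0.0], "a2": [0.0], "b1": [1.0], "b2": [1.0]},
            {"a1": 1, "a2": 1, "b1": 0, "b2": 0},
        )
        out = diffmeth.call_dmps(exp, ["a1", "a2"], ["b1", "b2"], diffmeth.define_control(exp))
        assert out["p"].iloc[0] == 0.0 and out["degenerate"].iloc[0]

    def test_small_group_rejected(self):
        exp = _experiment({"a1": [0.0], "b1": [1.0], "b2": [1.0]},
                          {"a1": 1, "b1": 0, "b2": 0})
        with pytest.raises(data_io.ValidationError):
            diffmeth.call_dmps(exp, ["a1"], ["b1", "b2"], diffmeth.define_control(exp))


class TestSubgroups:
    @pytest.mark.parametrize(
        "control,delta,state,direction",
        [(-2.0, 1.5, "hypo", "up"), (2.0, -1.5, "hyper", "down"), (1.0, 0.5, "hyper", "up")],
    )
    def test_sign_rules(self, control, delta, state, direction):
        dmps = pd.DataFrame({"delta_vs_control": [delta]}, index=["p0"])
        out = diffmeth.classify_subgroups(dmps, pd.Series({"p0": control}))
        assert out["baseline_state"].iloc[0] == state
        assert out["direction"].iloc[0] == direction

    def test_zero_control_is_hyper_with_tie_flag(self):
        dmps = pd.DataFrame({"delta_vs_control": [1.0]}, index=["p0"])
        out = diffmeth.classify_subgroups(dmps, pd.Series({"p0": 0.0}))
        assert out["baseline_state"].iloc[0] == "hyper" and out["baseline_tie"].iloc[0]


class TestBuildDmrs:
    def _passing(self, positions, deltas=None):
        manifest = _manifest(positions)
        deltas = deltas if deltas is not None else np.ones(len(positions))
        dmps = pd.DataFrame(
            {"delta_vs_control": deltas, "passes": True}, index=manifest.probe_ids
        )
        return dmps, manifest

    def test_worked_example_gap_arithmetic(self):
        # gaps 500 <= lambda < 1400: one 2-probe DMR, third probe outside
        dmps, manifest = self._passing([100, 600, 2000])
        table, in_dmr, frac = diffmeth.build_dmrs(dmps, manifest, lam=1000)
        assert len(table) == 1
        assert table["n_probes"].iloc[0] == 2
        assert list(in_dmr) == [True, True, False]
        assert frac == pytest.approx(2 / 3)

    def test_single_probe_never_a_region(self):
        dmps, manifest = self._passing([100])
        table, _, frac = diffmeth.build_dmrs(dmps, manifest)
        assert len(table) == 0 and frac == 0.0

    def test_zero_lambda_disables_chaining(self):
        dmps, manifest = self._passing([100, 200, 300])
        table, _, frac = diffmeth.build_dmrs(dmps, manifest, lam=0)
        assert len(table) == 0 and frac == 0.0

    def test_empty_input_is_empty_result(self):
        dmps, manifest = self._passing([100])
        table, flags, frac = diffmeth.build_dmrs(dmps.iloc[:0], manifest)
        assert len(table) == 0 and len(flags) == 0 and frac == 0.0

    def test_order_invariance_and_partition(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(200_000, size=120, replace=False)) + 1
        dmps, manifest = self._passing(pos, deltas=rng.normal(size=120))
        t1, f1, fr1 = diffmeth.build_dmrs(dmps, manifest)
        shuffled = dmps.sample(frac=1.0, random_state=1)
        t2, f2, fr2 = diffmeth.build_dmrs(shuffled, manifest)
        assert fr1 == fr2
        pd.testing.assert_frame_equal(
            t1.drop(columns="probe_ids"), t2.drop(columns="probe_ids")
        )
        # every passing probe is inside xor outside
        assert set(f1.index) == set(dmps.index)
        assert f1.isin([True, False]).all()

    def test_mean_delta_is_member_mean(self):
        dmps, manifest = self._passing([100, 600], deltas=[1.0, 2.0])
        table, _, _ = diffmeth.build_dmrs(dmps, manifest)
        assert table["mean_delta"].iloc[0] == pytest.approx(1.5)


class TestCpgRelation:
    ISLANDS = [data_io.GenomicInterval("chr1", 10_000, 11_000)]

    @pytest.mark.parametrize(
        "pos0,expected",
        [
            (10_500, "Island"),  # inside
            (9_999, "Shore"),  # 1 bp away
            (11_000, "Shore"),  # first bp past the end
            (8_000, "Shore"),  # 2000 bp: boundary inclusive
            (7_999, "Shelf"),
            (6_000, "Shelf"),  # 4000 bp boundary
            (5_999, "OpenSea"),  # 4001 bp
        ],
    )
    def test_distance_classes(self, pos0, expected):
        out = diffmeth.classify_cpg_relation(["chr1"], [pos0], self.ISLANDS)
        assert out[0] == expected

    def test_merged_variant(self):
        out = diffmeth.classify_cpg_relation(
            ["chr1", "chr1", "chr1"], [10_500, 9_000, 100], self.ISLANDS, merged=True
        )
        assert list(out) == ["Island", "ShoreShelf", "OpenSea"]

    def test_no_islands_on_chrom_is_open_sea(self):
        out = diffmeth.classify_cpg_relation(["chr9"], [5], self.ISLANDS)
        assert out[0] == "OpenSea"

    def test_overlapping_islands_rejected(self):
        bad = self.ISLANDS + [data_io.GenomicInterval("chr1", 10_500, 12_000)]
        with pytest.raises(data_io.ValidationError):
            diffmeth.classify_cpg_relation(["chr1"], [0], bad)


class TestFractionTable:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            (["Island"] * 2 + ["OpenSea"] * 2, {"Island": 0.5, "OpenSea": 0.5}),
            (["Body"], {"Body": 1.0}),
            (["a"] * 10 + ["b"] * 30 + ["c"] * 60, {"a": 0.1, "b": 0.3, "c": 0.6}),
        ],
    )
    def test_fractions(self, labels, expected):
        out = diffmeth.fraction_table(labels)
        assert out["fraction"].to_dict() == pytest.approx(expected)
        assert out["fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            diffmeth.fraction_table([])

    @given(st.lists(st.sampled_from("abcd"), min_size=1, max_size=60))
    def test_sums_to_one(self, labels):
        assert diffmeth.fraction_table(labels)["fraction"].sum() == pytest.approx(
            1.0, abs=1e-12
        )


class TestRecovery:
    def test_planted_effects_recovered_with_direction(self, bundle, fe_dmps):
        """Iron-condition calling recovers the planted probe set with the
        planted sign (persistent +1 particle)."""
        dmps, _ = fe_dmps
        passing = dmps[dmps["passes"]]
        truth = bundle.truth.true_dmp_ids["Fe"]
        recall = len(set(passing.index) & truth) / len(truth)
        assert recall >= 0.8
        hits = passing.index.intersection(list(truth))
        planted = bundle.truth.planted_delta["Fe"].loc[hits]
        agree = (np.sign(passing.loc[hits, "delta_vs_control"]) == np.sign(planted)).mean()
        assert agree >= 0.99
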