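"""Peak filtering, probe overlap, layer distributions, enrichment ratios and
regulatory-region groups."""

import numpy as np
import pandas as pd
import pytest

import radlayers as rl
from radlayers import chromatin_marks, data_io


def _iv(chrom, start, end, score=None, name=None):
    return data_io.GenomicInterval(chrom, start, end, score=score, name=name)


def _manifest(positions, chrom="chr1"):
    frame = pd.DataFrame(
        {
            "chrom": chrom,
            "pos0": np.asarray(positions),
            "cpg_relation": "OpenSea",
            "genic_group": "Intergenic",
        },
        index=pd.Index([f"p{i}" for i in range(len(positions))], name="probe_id"),
    )
    return data_io.ProbeManifest(frame)


class TestFilterPeaks:
    def test_length_bounds_inclusive(self):
        raw = chromatin_marks.PeakSet(
            "H3K4me3",
            [
                _iv("chr1", 0, 250, score=20),     # too short
                _iv("chr1", 0, 300, score=10),     # boundary length + boundary score
                _iv("chr1", 0, 2000, score=50),    # boundary length
                _iv("chr1", 0, 2001, score=50),    # too long
            ],
        )
        kept, removed = chromatin_marks.filter_peaks(raw, score_rule=("ge", 10))
        assert len(kept) == 2
        assert removed == {"too_short": 1, "too_long": 1, "score": 0, "no_score": 0}

    def test_gt_rule_drops_boundary(self):
        raw = chromatin_marks.PeakSet("H3K4me3", [_iv("chr1", 0, 500, score=0)])
        kept, removed = chromatin_marks.filter_peaks(raw, score_rule=("gt", 0))
        assert len(kept) == 0 and removed["score"] == 1

    def test_ge_rule_keeps_boundary(self):
        raw = chromatin_marks.PeakSet("H3K4me3", [_iv("chr1", 0, 500, score=10)])
        kept, _ = chromatin_marks.filter_peaks(raw, score_rule=("ge", 10))
        assert len(kept) == 1


class TestOverlapProbes:
    def test_flags_per_mark(self):
        m = _manifest([50, 450, 5000])
        sets = {
            "H3K9me3": chromatin_marks.PeakSet("H3K9me3", [_iv("chr1", 0, 100)]),
            "H3K4me3": chromatin_marks.PeakSet("H3K4me3", [_iv("chr1", 400, 800)]),
            "H3K27ac": chromatin_marks.PeakSet("H3K27ac", [_iv("chr1", 440, 460)]),
        }
        flags = chromatin_marks.overlap_probes(sets, m)
        assert flags.loc["p0"].tolist() == [True, False, False]
        assert flags.loc["p1", "H3K4me3"] and flags.loc["p1", "H3K27ac"]  # overlap zone
        assert not flags.loc["p2"].any()

    def test_matches_quadratic_scan_oracle(self):
        """Bisection-based point overlap equals the brute-force scan."""
        rng = np.random.default_rng(17)
        for trial in range(20):
            n_peaks, n_probes = rng.integers(1, 40), rng.integers(1, 50)
            peaks = [
                _iv("chr1", int(s), int(s + w))
                for s, w in zip(
                    rng.integers(0, 10_000, n_peaks), rng.integers(1, 800, n_peaks)
                )
            ]
            m = _manifest(np.sort(rng.choice(11_000, size=n_probes, replace=False)))
            flags = chromatin_marks.overlap_probes(
                {"X": chromatin_marks.PeakSet("X", peaks)}, m
            )["X"]
            for pid, pos0 in m.df["pos0"].items():
                brute = any(pk.contains(int(pos0)) for pk in peaks)
                assert flags[pid] == brute


class TestLayerMarkDistribution:
    def _model(self, n=50):
        m = _manifest(np.arange(n) * 100)
        scores = pd.Series(np.arange(n, dtype=float), index=m.probe_ids)
        return m, rl.build_layers(scores, m)

    def test_uniform_mark(self):
        m, model = self._model()
        flags = pd.DataFrame({"H3K4me3": True}, index=m.probe_ids)
        out = chromatin_marks.layer_mark_distribution(flags, model)
        assert out.loc["H3K4me3"].tolist() == [20.0] * 5
        assert out.loc["H3K4me3"].sum() == pytest.approx(100.0)

    def test_absent_mark_flagged_undefined(self):
        m, model = self._model()
        flags = pd.DataFrame({"H3K9me3": False}, index=m.probe_ids)
        out = chromatin_marks.layer_mark_distribution(flags, model)
        assert out.loc["H3K9me3"].isna().all()

    def test_planted_peripheral_mark_decreases_inward(self, bundle, layer_model):
        flags = bundle.truth.mark_flags
        out = chromatin_marks.layer_mark_distribution(flags, layer_model)
        k9 = out.loc["H3K9me3"].to_numpy()
        mk = rl.mann_kendall(k9)
        assert mk["s"] < 0 and mk["p_one_sided"] < 0.05  # decreasing L1 -> L5


class TestEnrichmentRatio:
    def test_counting_example(self):
        """10/100 DMPs in-region-in-layer over 200/1000 region probes in the
        layer gives 0.5."""
        n = 1000
        m = _manifest(np.arange(n))
        scores = pd.Series(np.arange(n, dtype=float), index=m.probe_ids)
        model = rl.build_layers(scores, m)
        region = pd.Series(True, index=m.probe_ids)  # all 1000 probes; 200/layer
        # 100 DMPs: 10 in L1, 90 in L2
        dmps = [f"p{i}" for i in range(10)] + [f"p{i}" for i in range(200, 290)]
        ratio = rl.dmp_enrichment_ratio(dmps, region, model, "L1")
        assert ratio == pytest.approx((10 / 100) / (200 / 1000), abs=1e-12)

    def test_null_value_is_one(self):
        n = 100
        m = _manifest(np.arange(n))
        scores = pd.Series(np.arange(n, dtype=float), index=m.probe_ids)
        model = rl.build_layers(scores, m)
        region = pd.Series(True, index=m.probe_ids)
        dmps = model.layer.groupby(model.layer).head(4).index  # 4 per layer
        for layer in ("L1", "L3", "L5"):
            assert rl.dmp_enrichment_ratio(dmps, region, model, layer) == pytest.approx(1.0)

    def test_zero_denominator_is_nan(self):
        n = 50
        m = _manifest(np.arange(n))
        scores = pd.Series(np.arange(n, dtype=float), index=m.probe_ids)
        model = rl.build_layers(scores, m)
        region = pd.Series(m.df["pos0"] < 10, index=m.probe_ids)  # only L1 probes
        out = rl.dmp_enrichment_ratio(["p0"], region, model, "L5")
        assert np.isnan(out)

    def test_matches_set_counting_oracle(self):
        rng = np.random.default_rng(5)
        n = 200
        m = _manifest(np.arange(n))
        scores = pd.Series(rng.normal(size=n), index=m.probe_ids)
        model = rl.build_layers(scores, m)
        for trial in range(30):
            dmps = pd.Index(rng.choice(m.probe_ids, size=40, replace=False))
            region = pd.Series(rng.random(n) < 0.3, index=m.probe_ids)
            layer = f"L{rng.integers(1, 6)}"
            got = rl.dmp_enrichment_ratio(dmps, region, model, layer)
            # brute-force set counting
            region_ids = set(region.index[region])
            layer_ids = set(model.probes_in(layer))
            num = len([d for d in dmps if d in region_ids and d in layer_ids]) / len(dmps)
            den = len(region_ids & layer_ids) / len(region_ids)
            if den == 0:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(num / den, abs=1e-12)

    def test_weighted_average_identity(self):
        """Sum over layers of ratio x layer-region-fraction equals the overall
        DMP-in-region fraction over the overall region fraction."""
        rng = np.random.default_rng(9)
        n = 500
        m = _manifest(np.arange(n))
        scores = pd.Series(rng.normal(size=n), index=m.probe_ids)
        model = rl.build_layers(scores, m)
        dmps = pd.Index(rng.choice(m.probe_ids, size=80, replace=False))
        region = pd.Series(rng.random(n) < 0.4, index=m.probe_ids)
        region_ids = region.index[region]
        total = 0.0
        for layer in ("L1", "L2", "L3", "L4", "L5"):
            r = rl.dmp_enrichment_ratio(dmps, region, model, layer)
            w = len(region_ids.intersection(model.probes_in(layer))) / len(region_ids)
            if not np.isnan(r):
                total += r * w
        overall = len(dmps.intersection(region_ids)) / len(dmps)
        assert total == pytest.approx(overall, abs=1e-12)


class TestRegulatoryGroups:
    TSS = pd.DataFrame(
        {"chrom": ["chr1"] * 4, "pos0": [10_000, 50_000, 90_000, 130_000]},
        index=pd.Index(["gA", "gB", "gC", "gD"], name="gene"),
    )
    BODIES = [_iv("chr1", 10_000, 30_000, name="gA"), _iv("chr1", 50_000, 60_000, name="gB"),
              _iv("chr1", 90_000, 95_000, name="gC"), _iv("chr1", 130_000, 140_000, name="gD")]

    def _groups(self):
        k4 = chromatin_marks.PeakSet("H3K4me3", [_iv("chr1", 9_000, 9_500, score=20),
                                                 _iv("chr1", 89_000, 89_400, score=20)])
        k27 = chromatin_marks.PeakSet("H3K27ac", [_iv("chr1", 49_000, 49_600, score=20),
                                                  _iv("chr1", 89_500, 89_900, score=20),
                                                  _iv("chr1", 20_000, 20_500, score=20),  # in gA body
                                                  _iv("chr1", 200_000, 200_700, score=20)])
        return chromatin_marks.build_regulatory_groups(self.TSS, self.BODIES, k4, k27)

    def test_single_mark_classes(self):
        g = self._groups()
        assert [r.name for r in g.k4_promoters] == ["gA"]
        assert [r.name for r in g.k27ac_promoters] == ["gB"]

    def test_dual_class_not_double_counted(self):
        g = self._groups()
        assert [r.name for r in g.dual_promoters] == ["gC"]
        assert [r.name for r in g.bare_promoters] == ["gD"]

    def test_promoter_classes_partition_tss_set(self):
        g = self._groups()
        n = sum(len(getattr(g, c)) for c in
                ("k4_promoters", "k27ac_promoters", "dual_promoters", "bare_promoters"))
        assert n == len(self.TSS)

    def test_enhancers_exclude_tss_and_bodies(self):
        g = self._groups()
        assert [(e.start, e.end) for e in g.k27ac_enhancers] == [(200_000, 200_700)]

    def test_partition_property_random(self):
        rng = np.random.default_rng(23)
        tss = pd.DataFrame(
            {"chrom": "chr1", "pos0": np.sort(rng.choice(10**6, 50, replace=False))},
            index=pd.Index([f"g{i}" for i in range(50)], name="gene"),
        )
        bodies = [_iv("chr1", int(p), int(p) + 5000) for p in tss["pos0"]]
        def peaks(name, k):
            return chromatin_marks.PeakSet(name, [
                _iv("chr1", int(s), int(s) + 400, score=20)
                for s in rng.choice(10**6, k, replace=False)
            ])
        g = chromatin_marks.build_regulatory_groups(tss, bodies, peaks("H3K4me3", 80),
                                                    peaks("H3K27ac", 80))
        n = sum(len(v) for k, v in g.as_dict().items() if k != "k27ac_enhancers")
        assert n == 50


class TestGroupMethylationChange:
    def test_all_dmp_row_reproduces_layer_profile(self, bundle, layer_model, fe_dmps):
        dmps, control = fe_dmps
        passing = dmps[dmps["passes"]]
        flags = bundle.truth.mark_flags
        out = chromatin_marks.group_methylation_change(passing, flags, layer_model, control)
        expected = rl.layer_mean_abs_change(passing, layer_model).values
        pd.testing.assert_series_equal(
            out["mean_abs_delta"].loc["all_dmps"], expected,
            check_names=False, atol=1e-12,
        )

    def test_mean_example_and_empty_cells(self):
        n = 10
        m = _manifest(np.arange(n) * 1000)
        scores = pd.Series(np.arange(n, dtype=float), index=m.probe_ids)
        model = rl.build_layers(scores, m)
        dmps = pd.DataFrame({"delta_vs_control": [0.6, 1.0]}, index=["p0", "p1"])
        flags = pd.DataFrame({"grp": [True] * 2 + [False] * 8}, index=m.probe_ids)
        baseline = pd.Series(2.0, index=m.probe_ids)
        out = chromatin_marks.group_methylation_change(dmps, flags, model, baseline)
        assert out["mean_abs_delta"].loc["grp", "L1"] == pytest.approx(0.8)
        assert np.isnan(out["mean_abs_delta"].loc["grp", "L3"])
        assert out["counts"].loc["grp", "L1"] == 2
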