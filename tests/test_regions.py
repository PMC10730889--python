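"""Enhancer definition, CGI classification, fragment partition, metaprofiles."""

import numpy as np
import pandas as pd
import pytest

from marktempo.intervals import (
    GenomicInterval,
    RegionSet,
    TssIndex,
    TssRecord,
)
from marktempo.regions import (
    EnhancerSet,
    FragmentMixture,
    cgi_stratify,
    classify_cgi_promoters,
    define_enhancers,
    enhancer_overlap_summary,
    estimate_mixture_weights,
    partition_fragments,
    tss_metaprofile,
)


def rs(*triples):
    return RegionSet([GenomicInterval(c, s, e) for c, s, e in triples])


class TestDefineEnhancers:
    tss_windows = rs(("chr1", 9000, 11000))

    def test_triple_overlap_far_from_tss(self):
        enh = define_enhancers(
            rs(("chr1", 2000, 2500)),
            rs(("chr1", 2000, 2500)),
            rs(("chr1", 2000, 2500)),
            self.tss_windows,
        )
        assert enh.regions.regions == [GenomicInterval("chr1", 2000, 2500)]
        assert enh.centers == [2250]

    def test_triple_overlap_inside_tss_window_excluded(self):
        enh = define_enhancers(
            rs(("chr1", 9500, 9800)),
            rs(("chr1", 9500, 9800)),
            rs(("chr1", 9500, 9800)),
            self.tss_windows,
        )
        assert len(enh) == 0

    def test_missing_k27ac_means_no_enhancer(self):
        enh = define_enhancers(
            rs(("chr1", 2000, 2500)),
            rs(("chr1", 4000, 4500)),  # no overlap with the others
            rs(("chr1", 2000, 2500)),
            self.tss_windows,
        )
        assert len(enh) == 0

    def test_empty_input_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty peak set"):
            enh = define_enhancers(
                RegionSet(), rs(("chr1", 0, 10)), rs(("chr1", 0, 10)),
                self.tss_windows,
            )
        assert len(enh) == 0

    def test_output_never_overlaps_tss_windows(self, small_ds):
        enh = define_enhancers(
            small_ds.peaks["H3K4me1"],
            small_ds.peaks["H3K27ac"],
            small_ds.peaks["ATAC"],
            small_ds.promoter_windows,
        )
        assert len(enh) > 0
        for e in enh.regions:
            for w in small_ds.promoter_windows:
                assert not e.overlaps(w)


class TestClassifyCgiPromoters:
    def test_cgi_spanning_tss(self):
        tss = [TssRecord("chr1", 5000, "+", "t1", "g1")]
        cgis = rs(("chr1", 4900, 5100))
        assert classify_cgi_promoters(tss, cgis, 1000).tolist() == [True]

    def test_cgi_ending_exactly_at_window_edge_excluded(self):
        tss = [TssRecord("chr1", 5000, "+", "t1", "g1")]
        cgis = rs(("chr1", 3800, 4000))  # end == position - window; no shared base
        assert classify_cgi_promoters(tss, cgis, 1000).tolist() == [False]

    def test_one_base_into_window_included(self):
        tss = [TssRecord("chr1", 5000, "+", "t1", "g1")]
        cgis = rs(("chr1", 3800, 4001))
        assert classify_cgi_promoters(tss, cgis, 1000).tolist() == [True]

    def test_random_layouts_match_per_base_oracle(self, rng):
        length = 10000
        for _ in range(100):
            tss = [
                TssRecord("chr1", int(p), "+", f"t{i}", f"g{i}")
                for i, p in enumerate(rng.integers(0, length, 5))
            ]
            cgis = RegionSet(
                [
                    GenomicInterval("chr1", int(s), int(s) + int(rng.integers(1, 500)))
                    for s in rng.integers(0, length - 1, 4)
                ]
            )
            paint = np.zeros(length + 600, dtype=bool)
            for iv in cgis:
                paint[iv.start : iv.end] = True
            expected = [
                paint[max(0, r.position - 250) : r.position + 250].any() for r in tss
            ]
            got = classify_cgi_promoters(tss, cgis, 250)
            assert got.tolist() == expected


class TestCgiStratify:
    idx = TssIndex(
        [
            TssRecord("chr1", 10000, "+", "t1", "g1"),
            TssRecord("chr1", 30000, "+", "t2", "g2"),
        ]
    )

    def test_all_cgi_gives_fraction_one(self):
        sites = rs(("chr1", 9500, 10500), ("chr1", 29500, 30500))
        out = cgi_stratify(
            sites, ["loss", "loss"], self.idx, {"t1": True, "t2": True}
        )
        assert out.loc[0, "frac_cgi"] == 1.0

    def test_four_of_five_cgi(self):
        tss = [TssRecord("chr1", p, "+", f"t{i}", f"g{i}") for i, p in
               enumerate([10000, 30000, 50000, 70000, 90000])]
        idx = TssIndex(tss)
        sites = RegionSet(
            [GenomicInterval("chr1", p - 100, p + 100) for p in
             [10000, 30000, 50000, 70000, 90000]]
        )
        flags = {"t0": True, "t1": True, "t2": True, "t3": True, "t4": False}
        out = cgi_stratify(sites, ["loss"] * 5, idx, flags)
        assert out.loc[0, "frac_cgi"] == pytest.approx(0.8)

    def test_distant_sites_ignored(self):
        sites = rs(("chr1", 20000, 20100))  # ~ 9.95 kb from both TSSs
        out = cgi_stratify(sites, ["loss"], self.idx, {"t1": True}, window=3000)
        assert out.empty


class TestPartitionFragments:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (60, "nucleosome_free"),
            (119, "nucleosome_free"),
            (120, "other"),
            (125, "other"),
            (129, "other"),
            (130, "mono_nucleosome"),
            (200, "mono_nucleosome"),
            (201, "other"),
            (500, "other"),
        ],
    )
    def test_boundary_enumeration(self, length, expected):
        assert partition_fragments(np.array([length]))[0] == expected

    def test_classes_exclusive_and_exhaustive(self):
        lengths = np.arange(1, 600)
        labels = partition_fragments(lengths)
        assert set(labels) == {"nucleosome_free", "mono_nucleosome", "other"}
        assert len(labels) == len(lengths)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            partition_fragments(np.array([0, 100]))

    def test_mixture_weights_recovered_within_003(self, rng):
        """100,000 fragments from the generator's mixture: estimated weights
        land within +/- 0.03 of the truth."""
        true_w = np.array([0.45, 0.40, 0.15])
        mix = FragmentMixture()
        comps = [mix.nfr, mix.mono, mix.long]
        comp = rng.choice(3, size=100_000, p=true_w)
        means = np.array([c[0] for c in comps])[comp]
        sds = np.array([c[1] for c in comps])[comp]
        lengths = np.maximum(1, np.rint(rng.normal(means, sds)).astype(int))
        est = estimate_mixture_weights(lengths, mix)
        assert np.all(np.abs(est - true_w) < 0.03)


class TestTssMetaprofile:
    def uniform_fragments(self, n=2000, length=100, span=20000):
        starts = np.arange(0, span, span // n)[:n]
        return pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + length}
        )

    def test_uniform_coverage_gives_flat_profile(self):
        frags = self.uniform_fragments()
        anchors = [("chr1", 10000, "+")]
        _, mean = tss_metaprofile(
            frags, anchors, flank=1000, bin_size=100, library_size=len(frags),
            chrom_lengths={"chr1": 30000},
        )
        assert np.ptp(mean) <= mean.mean() * 0.35  # flat up to edge granularity

    def test_single_fragment_lands_in_central_bins(self):
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [9990], "end": [10010]})
        anchors = [("chr1", 10000, "+")]
        mat, _ = tss_metaprofile(
            frags, anchors, flank=1000, bin_size=100, library_size=1,
            chrom_lengths={"chr1": 30000},
        )
        nonzero = np.nonzero(mat[0])[0]
        assert set(nonzero) == {9, 10}  # the two bins flanking the anchor

    def test_cpm_scaling_halves_when_library_doubles(self):
        frags = self.uniform_fragments()
        anchors = [("chr1", 10000, "+")]
        _, m1 = tss_metaprofile(frags, anchors, 1000, 100, len(frags), {"chr1": 30000})
        _, m2 = tss_metaprofile(frags, anchors, 1000, 100, 2 * len(frags), {"chr1": 30000})
        assert np.allclose(m1, 2 * m2)

    def test_minus_strand_anchor_mirrors_profile(self):
        frags = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [10100, 10150, 10200],
                              "end": [10150, 10200, 10260]})
        plus = [("chr1", 10000, "+")]
        minus = [("chr1", 10000, "-")]
        mat_p, _ = tss_metaprofile(frags, plus, 1000, 50, 3, {"chr1": 30000})
        mat_m, _ = tss_metaprofile(frags, minus, 1000, 50, 3, {"chr1": 30000})
        assert np.allclose(mat_p[0], mat_m[0][::-1])

    def test_edge_anchor_excluded_from_mean(self):
        frags = self.uniform_fragments()
        anchors = [("chr1", 10000, "+"), ("chr1", 500, "+")]  # second leaves chrom
        mat, mean = tss_metaprofile(frags, anchors, 1000, 100, len(frags), {"chr1": 30000})
        assert np.all(np.isnan(mat[1]))
        assert np.allclose(mean, mat[0])

    def test_column_sums_invariant_under_anchor_permutation(self):
        frags = self.uniform_fragments()
        anchors = [("chr1", p, "+") for p in (5000, 10000, 15000)]
        mat1, _ = tss_metaprofile(frags, anchors, 1000, 100, 10, {"chr1": 30000})
        mat2, _ = tss_metaprofile(frags, anchors[::-1], 1000, 100, 10, {"chr1": 30000})
        assert np.allclose(mat1.sum(axis=0), mat2.sum(axis=0))

    def test_flank_must_divide_into_bins(self):
        with pytest.raises(ValueError):
            tss_metaprofile(
                self.uniform_fragments(), [("chr1", 10000, "+")], 1000, 300, 10,
                {"chr1": 30000},
            )


class TestEnhancerOverlapSummary:
    enh = EnhancerSet(rs(("chr1", 5000, 5600)), [5300])

    def test_site_inside_enhancer_counted(self):
        out = enhancer_overlap_summary(rs(("chr1", 5100, 5200)), ["loss"], self.enh)
        assert out.set_index(["direction", "compartment"]).loc[
            ("loss", "enhancer"), "n"
        ] == 1

    def test_no_enhancers_all_remaining(self):
        empty = EnhancerSet(RegionSet(), [])
        out = enhancer_overlap_summary(
            rs(("chr1", 5100, 5200), ("chr1", 9000, 9100)), ["loss", "gain"], empty
        )
        assert (out["compartment"] == "remaining_genome").all()
        assert out["n"].sum() == 2

    def test_random_layouts_match_per_base_overlap_oracle(self, rng):
        length = 20000
        for _ in range(50):
            enh_regions = RegionSet(
                [
                    GenomicInterval("chr1", int(s), int(s) + int(rng.integers(1, 400)))
                    for s in rng.integers(0, length, 5)
                ]
            )
            enh = EnhancerSet(enh_regions, [iv.midpoint for iv in enh_regions])
            paint = np.zeros(length + 500, dtype=bool)
            for iv in enh_regions:
                paint[iv.start : iv.end] = True
            sites, calls, expected = [], [], 0
            for s in rng.integers(0, length, 30):
                iv = GenomicInterval("chr1", int(s), int(s) + 50)
                sites.append(iv)
                calls.append("loss")
                expected += int(paint[iv.start : iv.end].any())
            out = enhancer_overlap_summary(RegionSet(sites), calls, enh)
            got = out.set_index("compartment")["n"].to_dict()
            assert got.get("enhancer", 0) == expected
            assert got.get("enhancer", 0) + got.get("remaining_genome", 0) == 30
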