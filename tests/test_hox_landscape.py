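"""Hox-cluster mapping: axis normalisation, segment assignment, orientation
calls, profiles, and cross-cluster comparison."""

import numpy as np
import pytest

from ctcf_landscape import hox_landscape as H
from ctcf_landscape import peaks as P
from ctcf_landscape import synthetic_data as S
from ctcf_landscape.formats import GeneRecord

from conftest import make_peak


def toy_cluster(axis="+"):
    """Five genes Hox1..Hox5, 1 kb bodies at 10 kb spacing."""
    genes = []
    for g in range(1, 6):
        if axis == "+":
            s = 10_000 * g
        else:
            s = 10_000 * (6 - g)
        genes.append(GeneRecord(f"HoxA{g}", "chrH", s, s + 1_000, "+", g))
    return H.HoxCluster.from_genes(genes, species="toy", cluster_name="A")


class TestCluster:
    def test_axis_detection(self):
        assert toy_cluster("+").axis == "+"
        assert toy_cluster("-").axis == "-"

    def test_normalization_involution(self):
        for axis in "+-":
            cl = toy_cluster(axis)
            genes_n = cl.genes_by_paralog()
            groups = [g.paralog_group for g in genes_n]
            assert groups == sorted(groups)

    def test_needs_two_genes(self):
        with pytest.raises(ValueError):
            H.HoxCluster.from_genes([GeneRecord("HoxA1", "c", 0, 10, "+", 1)])


class TestPeaksInCluster:
    def test_summit_filter_half_open(self):
        cl = toy_cluster("+")
        inside = make_peak(chrom="chrH", start=30_000, end=30_300, name="in",
                           summit=30_150)
        edge = cl.span[1] + 1_000  # exactly span + flank: excluded (half-open)
        at_edge = make_peak(chrom="chrH", start=edge - 100, end=edge + 100,
                            name="edge", summit=edge)
        sel = H.peaks_in_cluster([inside, at_edge], cl, flank_bp=1_000)
        assert [p.name for p in sel] == ["in"]

    def test_matches_brute_force(self, rng):
        cl = toy_cluster("-")
        peaks = [
            make_peak(chrom="chrH", start=int(s), end=int(s) + 200, name=f"p{i}",
                      summit=int(s) + 100)
            for i, s in enumerate(rng.integers(0, 80_000, 50))
        ]
        flank = 5_000
        got = {p.name for p in H.peaks_in_cluster(peaks, cl, flank)}
        lo, hi = cl.span[0] - flank, cl.span[1] + flank
        expect = {p.name for p in peaks if lo <= p.summit < hi}
        assert got == expect


class TestSegments:
    def test_between_and_flanks(self):
        cl = toy_cluster("+")
        label, key = H.assign_segment(cl, cl.normalized(25_000))
        assert key == ("between", 2, 3)
        assert "HoxA2" in label and "HoxA3" in label
        assert H.assign_segment(cl, cl.normalized(5_000))[1] == ("flank3",)
        assert H.assign_segment(cl, cl.normalized(70_000))[1] == ("flank5",)
        assert H.assign_segment(cl, cl.normalized(10_500))[1] == ("within", 1)

    def test_axis_flip_preserves_segment(self):
        for axis in "+-":
            cl = toy_cluster(axis)
            genomic = 25_000 if axis == "+" else 35_000  # between groups 2 and 3
            assert H.assign_segment(cl, cl.normalized(genomic))[1] == ("between", 2, 3)


class TestCallsAndProfile:
    def make_calls(self, specs):
        return [
            H.BindingSiteCall(
                peak_id=f"p{i}", position=pos, orientation=o,
                has_core_motif=o != "none", overlaps_repeat=False,
                segment=str(key), segment_key=key,
            )
            for i, (pos, o, key) in enumerate(specs)
        ]

    def test_hox1_4_counting(self):
        cl = toy_cluster("+")
        calls = self.make_calls([
            (cl.normalized(25_000), "forward", ("between", 2, 3)),
        ])
        assert H.cluster_profile(calls, cl).hox1_4_count == 1
        calls = self.make_calls([
            (cl.normalized(45_000), "forward", ("between", 4, 5)),
        ])
        assert H.cluster_profile(calls, cl).hox1_4_count == 0

    def test_outward_convention(self):
        # outward at the 3' (group-1) end = reverse; at the 5' end = forward
        cl = toy_cluster("+")
        calls = self.make_calls([
            (1_000, "reverse", ("flank3",)),
            (60_000, "forward", ("flank5",)),
        ])
        prof = H.cluster_profile(calls, cl)
        assert prof.outward_3prime and prof.outward_5prime
        inward = self.make_calls([
            (1_000, "forward", ("flank3",)),
            (60_000, "reverse", ("flank5",)),
        ])
        prof = H.cluster_profile(inward, cl)
        assert not prof.outward_3prime and not prof.outward_5prime

    def test_profile_totals_conserved(self):
        cl = toy_cluster("+")
        calls = self.make_calls([
            (1_000, "reverse", ("flank3",)),
            (25_000, "none", ("between", 2, 3)),
            (26_000, "forward", ("between", 2, 3)),
        ])
        prof = H.cluster_profile(calls, cl)
        assert prof.total == 3
        assert sum(prof.segment_counts.values()) == 3

    def test_orientation_none_iff_no_motif(self):
        with pytest.raises(ValueError):
            H.BindingSiteCall("p", 0, "none", True, False, "s", ("flank3",))


class TestCompareProfiles:
    def mk_profile(self, name, keys):
        counts = {}
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
        return H.ClusterProfile(
            cluster_name=name, species="toy", segment_counts=counts,
            total=len(keys), hox1_4_count=0, outward_3prime=None, outward_5prime=None,
        )

    def test_identical_profiles_all_shared(self):
        keys = [("between", 5, 6), ("between", 8, 9)]
        comp = H.compare_profiles([self.mk_profile("A", keys), self.mk_profile("B", keys)])
        assert set(comp["shared_segments"]) == {"between 5-6", "between 8-9"}

    def test_disjoint_profiles_share_nothing(self):
        comp = H.compare_profiles([
            self.mk_profile("A", [("between", 1, 2)]),
            self.mk_profile("B", [("between", 8, 9)]),
        ])
        assert comp["shared_segments"] == []

    def test_totals_and_species_max(self):
        comp = H.compare_profiles([
            self.mk_profile("A", [("between", 1, 2)] * 3),
            self.mk_profile("B", [("between", 8, 9)]),
        ])
        assert comp["totals"]["toy:A"] == 3
        assert comp["max_per_species"]["toy"] == 3


class TestEndToEnd:
    @pytest.mark.parametrize("preset,expected_1_4", [("lamprey", 4), ("gnathostome", 0)])
    def test_toy_cluster_recovery(self, bundle, preset, expected_1_4):
        """Full pipeline on the toy clusters: orientations, Hox1-4 counts,
        repeat flags, and outward ends all match the planted truth."""
        hox = bundle.hox[preset]
        core_pwm = S.consensus_pwm(bundle.cfg.core_consensus)
        bg0 = np.full(4, 0.25)
        cons = P.consensus_peaks(hox.peaks["rep1"], hox.peaks["rep2"], hox.peaks["merged"])
        sig = P.significant_peaks(cons, P.SignificanceRule(10.0))
        for cname, chrom in (("A", "hoxI"), ("B", "hoxII")):
            genes = [g for g in hox.genes if g.chrom == chrom]
            cl = H.HoxCluster.from_genes(genes, species="toy", cluster_name=cname)
            tr = hox.truth[cname]
            assert cl.axis == tr.axis
            cp = H.peaks_in_cluster(sig, cl, 10_000)
            calls = H.call_binding_sites(cp, cl, core_pwm, bg0, hox.genome,
                                         repeats=hox.repeats)
            prof = H.cluster_profile(calls, cl)
            assert [c.orientation for c in calls] == tr.site_orientations
            assert [c.overlaps_repeat for c in calls] == tr.site_repeat_flags
            assert [c.segment_key for c in calls] == tr.site_segments
            assert prof.hox1_4_count == tr.hox1_4_count == expected_1_4
            assert prof.outward_3prime and prof.outward_5prime

    def test_render_text_track(self, bundle):
        hox = bundle.hox["lamprey"]
        genes = [g for g in hox.genes if g.chrom == "hoxI"]
        cl = H.HoxCluster.from_genes(genes, species="toy", cluster_name="A")
        calls = [
            H.BindingSiteCall("p", 15_000, "forward", True, True,
                              "between HoxA1 and HoxA2", ("between", 1, 2))
        ]
        track = H.render_text_track(calls, cl)
        assert ">" in track and "*" in track
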