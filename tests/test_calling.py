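"""Spike calibration, destranding, binomial calling and aggregation."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methylmorph import calling
from methylmorph.calling import CpGSite, MethCall
from methylmorph.formats import CytosineRecord, Exon, Gene, GenomeAnnotation


def rec(chrom, pos, strand, meth, unmeth, context="CpG"):
    return CytosineRecord(chrom, pos, strand, meth, unmeth, context)


class TestNonconversion:
    def test_pooled_ratio(self):
        recs = [rec("lambda", i + 1, "+", 0, 1) for i in range(9950)]
        recs += [rec("lambda", 20000 + i, "+", 1, 0) for i in range(50)]
        est = calling.estimate_nonconversion(recs)
        assert est.rate == pytest.approx(0.005)
        assert est.total_coverage == 10_000

    def test_zero_rate_becomes_pseudo_rate(self):
        recs = [rec("lambda", i + 1, "+", 0, 1) for i in range(10_000)]
        with pytest.warns(UserWarning, match="pseudo-rate"):
            est = calling.estimate_nonconversion(recs)
        assert est.rate == pytest.approx(1 / 10_001)

    def test_zero_coverage_is_error(self):
        with pytest.raises(ValueError, match="coverage"):
            calling.estimate_nonconversion([rec("lambda", 1, "+", 0, 0)])


GENOME = {"chr1": "ATCGATCGGG" + "A" * 200}  # CpG dyads at + pos 3 and 7


class TestDestrand:
    def test_dyad_merge(self):
        sites = calling.destrand(
            [rec("chr1", 3, "+", 5, 5), rec("chr1", 4, "-", 3, 7)], GENOME
        )
        (s,) = sites
        assert (s.pos, s.count_meth, s.count_unmeth) == (3, 8, 12)

    def test_unpaired_plus_passes_through(self):
        (s,) = calling.destrand([rec("chr1", 3, "+", 5, 5)], GENOME)
        assert (s.pos, s.count_meth, s.count_unmeth) == (3, 5, 5)

    def test_minus_singleton_mapped_to_dyad(self):
        (s,) = calling.destrand([rec("chr1", 4, "-", 2, 8)], GENOME)
        assert s.pos == 3

    def test_minus_without_dyad_warns_and_kept(self):
        with pytest.warns(UserWarning, match="no dyad"):
            (s,) = calling.destrand([rec("chr1", 50, "-", 1, 1)], GENOME)
        assert s.pos == 50

    @given(
        st.lists(
            st.tuples(
                st.sampled_from([3, 4, 7, 8, 50]),
                st.sampled_from("+-"),
                st.integers(0, 30),
                st.integers(0, 30),
            ),
            max_size=20,
        )
    )
    def test_count_conservation(self, entries):
        records = [rec("chr1", pos, strand, m, u) for pos, strand, m, u in entries]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sites = calling.destrand(records, GENOME)
        assert sum(s.count_meth for s in sites) == sum(r.count_meth for r in records)
        assert sum(s.count_unmeth for s in sites) == sum(r.count_unmeth for r in records)


class TestFilterAndCall:
    def test_coverage_filter(self):
        sites = [CpGSite("chr1", p, m, u) for p, m, u in [(1, 4, 5), (2, 5, 5), (3, 6, 5)]]
        kept = calling.filter_coverage(sites, min_cov=10)
        assert [s.pos for s in kept] == [2, 3]
        assert calling.filter_coverage(sites, min_cov=1) == sites
        assert calling.filter_coverage([], min_cov=10) == []

    def test_zero_meth_gives_p_one(self):
        assert calling.binomial_tail_p(0, 10, 0.005) == 1.0

    def test_closed_form_tails(self):
        # P(X >= 1) = 1 - 0.995^10 ; P(X >= 10) = 0.005^10
        assert calling.binomial_tail_p(1, 10, 0.005) == pytest.approx(
            1 - 0.995**10, rel=1e-12
        )
        assert calling.binomial_tail_p(10, 10, 0.005) == pytest.approx(
            0.005**10, rel=1e-9
        )

    def test_tail_matches_pmf_summation(self):
        # spot-check against direct PMF summation (full sweep in acceptance)
        rate = 0.02
        for cov in (1, 7, 23, 50):
            for k in range(cov + 1):
                direct = sum(
                    math.comb(cov, j) * rate**j * (1 - rate) ** (cov - j)
                    for j in range(k, cov + 1)
                )
                assert calling.binomial_tail_p(k, cov, rate) == pytest.approx(
                    direct, abs=1e-12
                )

    @given(st.integers(1, 60), st.floats(0.001, 0.2))
    def test_p_monotone_in_count(self, cov, rate):
        ps = [calling.binomial_tail_p(k, cov, rate) for k in range(cov + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_call_flag_matches_q_threshold(self):
        sites = [CpGSite("chr1", p + 1, m, 30 - m) for p, m in enumerate([0, 1, 2, 5, 10, 30])]
        calls = calling.call_methylated(sites, rate=0.005, alpha=0.05)
        for c in calls:
            assert c.methylated == (c.q_value < 0.05)
        assert not calls[0].methylated
        assert calls[-1].methylated

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            calling.call_methylated([CpGSite("chr1", 1, 1, 9)], rate=0.0)


def annotation():
    return GenomeAnnotation(
        genes=[
            Gene("gA", "chr1", 100, 500, "+"),
            Gene("gB", "chr1", 450, 900, "-"),
            Gene("gC", "chr2", 100, 300, "-"),
        ],
        exons=[
            Exon("gA", 1, "chr1", 100, 200),
            Exon("gA", 2, "chr1", 300, 400),
            Exon("gB", 1, "chr1", 800, 900),
            Exon("gB", 2, "chr1", 450, 550),
            Exon("gC", 1, "chr2", 200, 300),
        ],
    )


class TestAssignFeature:
    def test_exon_with_rank(self):
        fa = calling.assign_feature(("chr1", 350), annotation())
        assert (fa.category, fa.gene_id, fa.exon_rank) == ("exon", "gA", 2)

    def test_intron_inside_gene_outside_exons(self):
        fa = calling.assign_feature(("chr1", 250), annotation())
        assert (fa.category, fa.gene_id) == ("intron", "gA")

    def test_exon_beats_intron_of_other_gene(self):
        # 470 is exon 2 of gB and intron of gA
        fa = calling.assign_feature(("chr1", 470), annotation())
        assert (fa.category, fa.gene_id) == ("exon", "gB")

    def test_promoter_strand_aware(self):
        fa = calling.assign_feature(("chr1", 50), annotation(), promoter_bp=1000)
        assert (fa.category, fa.gene_id) == ("promoter", "gA")
        fa2 = calling.assign_feature(("chr2", 350), annotation(), promoter_bp=100)
        assert (fa2.category, fa2.gene_id) == ("promoter", "gC")

    def test_intergenic(self):
        fa = calling.assign_feature(("chr2", 5000), annotation())
        assert fa.category == "intergenic"


class TestGeneMethylation:
    def test_weighted_mean(self):
        sites = [CpGSite("chr1", 150, 8, 12), CpGSite("chr1", 350, 12, 8)]
        (gm,) = [
            g for g in calling.gene_methylation(sites, annotation()) if g.gene_id == "gA"
        ]
        assert gm.meth_pct == pytest.approx(50.0)
        assert gm.n_sites == 2

    def test_zero_sites_zero_pct(self):
        sites = [CpGSite("chr2", 250, 0, 10)]
        (gm,) = calling.gene_methylation(sites, annotation())
        assert gm.meth_pct == 0.0
        assert gm.meth_class == "unmethylated"

    def test_weighting_differs_from_plain_mean(self):
        # 3/10 and 90/100: weighted 84.5%, unweighted mean of pcts 60%
        sites = [CpGSite("chr1", 150, 3, 7), CpGSite("chr1", 350, 90, 10)]
        (gm,) = [
            g for g in calling.gene_methylation(sites, annotation()) if g.gene_id == "gA"
        ]
        assert gm.meth_pct == pytest.approx(84.545454, abs=1e-4)

    @pytest.mark.parametrize(
        "pct,cls",
        [
            (75, "high"),
            (0.4, "unmethylated"),
            (30, "medium"),
            (0.5, "low"),
            (70, "high"),
            (29.999, "low"),
            (0, "unmethylated"),
            (100, "high"),
        ],
    )
    def test_class_boundaries(self, pct, cls):
        assert calling.classify_gene(pct) == cls

    def test_class_out_of_range(self):
        with pytest.raises(ValueError):
            calling.classify_gene(101)


class TestStageOverlap:
    def test_identical_sets(self):
        s = {("chr1", i) for i in range(10)}
        regions, uniques = calling.stage_overlap({k: set(s) for k in "abcde"})
        assert regions[frozenset("abcde")] == 10
        assert sum(v for k, v in regions.items() if k != frozenset("abcde")) == 0
        assert all(len(u) == 0 for u in uniques.values())

    def test_disjoint_sets(self):
        sets = {k: {("chr1", 10 * i + j) for j in range(i + 1)} for i, k in enumerate("abc")}
        regions, uniques = calling.stage_overlap(sets)
        for i, k in enumerate("abc"):
            assert regions[frozenset([k])] == i + 1
            assert uniques[k] == sets[k]
        assert regions[frozenset("abc")] == 0

    def test_matches_membership_enumeration(self):
        rng = np.random.default_rng(0)
        sites = [("chr1", int(p)) for p in rng.choice(1000, 100, replace=False)]
        sets = {
            stage: {s for s in sites if rng.random() < 0.4}
            for stage in ("embryo", "larva", "prepupa", "pupa", "adult")
        }
        regions, _ = calling.stage_overlap(sets)
        union = set().union(*sets.values())
        assert sum(regions.values()) == len(union)
        for site in union:
            membership = frozenset(k for k, v in sets.items() if site in v)
            # site must be counted in exactly its membership region
            inside = {k: v for k, v in regions.items() if site in _region_sites(sets, k)}
            assert membership in inside


def _region_sites(sets, combo):
    inside = set.intersection(*(sets[s] for s in combo))
    outside = set().union(*(v for k, v in sets.items() if k not in combo))
    return inside - outside


class TestExonProfile:
    def _calls(self, positions_pcts):
        calls = []
        for pos, pct in positions_pcts:
            cov = 100
            m = int(round(cov * pct / 100))
            site = CpGSite("chr1", pos, m, cov - m)
            calls.append(MethCall(site, 0.0, 0.0, True))
        return calls

    def test_flat_profile(self):
        calls = self._calls([(150, 50), (350, 50), (820, 50), (470, 50)])
        prof = calling.exon_number_profile(calls, annotation(), max_rank=3)
        assert prof[1] == pytest.approx(50)
        assert prof[2] == pytest.approx(50)
        assert math.isnan(prof[3])

    def test_no_exonic_sites_all_missing(self):
        calls = self._calls([(250, 50)])  # intron
        prof = calling.exon_number_profile(calls, annotation(), max_rank=2)
        assert all(math.isnan(v) for v in prof.values())

    def test_elevated_rank_is_argmax(self):
        ann = GenomeAnnotation(
            genes=[Gene("g", "chr1", 1, 1000, "+")],
            exons=[Exon("g", r, "chr1", 100 * r, 100 * r + 50) for r in range(1, 6)],
        )
        calls = self._calls(
            [(100 * r + 10, 80 if r == 3 else 30) for r in range(1, 6)]
        )
        prof = calling.exon_number_profile(calls, ann, max_rank=5)
        assert max(prof, key=lambda r: prof[r]) == 3
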