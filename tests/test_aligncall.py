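"""Mapping, pileups, the threshold caller, surrogate quality and the
quality-gated shotgun caller."""

import random

import numpy as np
import pytest
from scipy.stats import binom

from radmarkers.aligncall import (HET, HOM_ALT, HOM_REF, MISSING,
                                  call_genotype_threshold, call_sites_rad,
                                  call_sites_shotgun, map_reads, pileup,
                                  site_quality, summarize_variants)


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestThresholdCaller:
    @pytest.mark.parametrize("ref,alt,expected", [
        (20, 1, HOM_REF),      # f ~ 0.048 < 0.075
        (10, 10, HET),
        (0, 20, HOM_ALT),
        (3, 1, MISSING),       # depth 4 < 5
        (37, 3, HET),          # f = 0.075 exactly: boundary calls het
        (3, 37, HET),          # f = 0.925 exactly
    ])
    def test_rule_arithmetic(self, ref, alt, expected):
        assert call_genotype_threshold(ref, alt) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            call_genotype_threshold(-1, 0)

    def test_recovery_at_one_percent_error_depth_30(self):
        """>= 99% of genotypes recovered from binomial read counts at
        depth 30 and 1% sequencing error, over 3000 simulated sites."""
        rng = np.random.default_rng(42)
        correct = total = 0
        for truth in (HOM_REF, HET, HOM_ALT):
            for _ in range(1000):
                depth = 30
                p_alt = {HOM_REF: 0.01 / 3, HET: 0.5, HOM_ALT: 1 - 0.01 / 3}[truth]
                alt = rng.binomial(depth, p_alt)
                total += 1
                correct += call_genotype_threshold(depth - alt, alt) == truth
        assert correct / total >= 0.99


class TestSiteQuality:
    def test_zero_alt_is_zero(self):
        assert site_quality(30, 0) == 0.0

    def test_five_of_ten_caps_at_60(self):
        # binomial tail P(X >= 5 | n=10, p=0.01) is far below 1e-6
        assert site_quality(5, 5, 0.01) == 60.0
        assert float(binom.sf(4, 10, 0.01)) < 1e-6

    def test_matches_independent_binomial_tail(self):
        q = site_quality(28, 2, 0.01)
        tail = float(binom.sf(1, 30, 0.01))
        assert q == pytest.approx(-10 * np.log10(tail))

    def test_monotone_in_alt_count(self):
        qs = [site_quality(30 - a, a) for a in range(0, 31)]
        assert qs == sorted(qs)


class TestRadMapping:
    CONTIG = _random_seq(400, 0)

    def _map(self, reads):
        return map_reads(reads, {"c1": self.CONTIG}, mode="rad")

    def test_exact_substring_maps_with_zero_mismatches(self):
        res = self._map([("r", "s", self.CONTIG[50:130])])
        (aln,) = res.alignments
        assert (aln.contig, aln.start, aln.end, aln.subs) == ("c1", 50, 130, [])

    def test_five_substitutions_unmapped(self):
        read = list(self.CONTIG[50:130])
        for i in (0, 25, 40, 60, 79):
            read[i] = "A" if read[i] != "A" else "C"
        res = self._map([("r", "s", "".join(read))])
        assert res.alignments == [] and res.n_unmapped == 1

    def test_four_substitutions_still_map(self):
        read = list(self.CONTIG[50:130])
        for i in (25, 40, 60, 75):
            read[i] = "A" if read[i] != "A" else "C"
        res = self._map([("r", "s", "".join(read))])
        assert len(res.alignments) == 1
        assert len(res.alignments[0].subs) == 4

    def test_equal_hits_on_two_contigs_is_ambiguous(self):
        contigs = {"c1": self.CONTIG, "c2": self.CONTIG[:200] + _random_seq(200, 9)}
        res = map_reads([("r", "s", self.CONTIG[10:90])], contigs, mode="rad")
        assert res.alignments == [] and res.n_ambiguous == 1


class TestPileup:
    def test_single_read_depth_one_everywhere(self):
        contig = _random_seq(200, 1)
        res = map_reads([("r", "s", contig[60:140])], {"c": contig}, mode="rad")
        pile = pileup(res.alignments, {"c": contig}, ["s"])
        assert pile.depth("c", 60, "s") == 1
        assert pile.depth("c", 139, "s") == 1
        assert pile.depth("c", 59, "s") == 0
        assert pile.depth("c", 140, "s") == 0

    def test_overlapping_reads_additive(self):
        contig = _random_seq(200, 2)
        reads = [("a", "s", contig[0:80]), ("b", "s", contig[40:120])]
        res = map_reads(reads, {"c": contig}, mode="rad")
        pile = pileup(res.alignments, {"c": contig}, ["s"])
        assert pile.depth("c", 60, "s") == 2
        assert pile.depth("c", 10, "s") == 1

    def test_substitution_recorded_in_base_counts(self):
        contig = _random_seq(200, 3)
        read = list(contig[20:100])
        alt = "A" if read[30] != "A" else "C"
        read[30] = alt
        res = map_reads([("r", "s", "".join(read))] +
                        [(f"x{i}", "s", contig[20:100]) for i in range(3)],
                        {"c": contig}, mode="rad")
        pile = pileup(res.alignments, {"c": contig}, ["s"])
        counts = pile.base_counts("c", 50, "s")
        assert counts[alt] == 1 and counts[contig[50]] == 3


class TestRadCalls:
    def _calls_for(self, alt_copies, ref_copies, seed=4):
        contig = _random_seq(300, seed)
        alt = "A" if contig[150] != "A" else "C"
        var = contig[100:180][:50] + alt + contig[151:180]
        reads = [(f"a{i}", "s", var) for i in range(alt_copies)]
        reads += [(f"r{i}", "s", contig[100:180]) for i in range(ref_copies)]
        res = map_reads(reads, {"c": contig}, mode="rad")
        pile = pileup(res.alignments, {"c": contig}, ["s"])
        return call_sites_rad(pile), alt

    def test_heterozygous_site_called(self):
        calls, alt = self._calls_for(10, 10)
        (c,) = calls
        assert c.pos == 150 and c.alt == alt and c.genotypes["s"] == HET

    def test_monomorphic_reference_sites_not_reported(self):
        calls, _ = self._calls_for(1, 29)  # f ~ 0.033 < t
        assert calls == []

    def test_calls_invariant_to_read_order(self):
        contig = _random_seq(300, 5)
        alt = "A" if contig[150] != "A" else "C"
        var = contig[100:150] + alt + contig[151:180]
        reads = [(f"a{i}", "s", var) for i in range(8)]
        reads += [(f"r{i}", "s", contig[100:180]) for i in range(8)]
        shuffled = reads[:]
        random.Random(0).shuffle(shuffled)
        out = []
        for batch in (reads, shuffled):
            res = map_reads(batch, {"c": contig}, mode="rad")
            pile = pileup(res.alignments, {"c": contig}, ["s"])
            out.append([(c.contig, c.pos, c.ref, c.alt, tuple(sorted(c.genotypes.items())))
                        for c in call_sites_rad(pile)])
        assert out[0] == out[1]


class TestShotgunCalls:
    def _pileup(self, reads, contig):
        res = map_reads(reads, {"c": contig}, mode="shotgun")
        assert res.n_unmapped == 0
        return pileup(res.alignments, {"c": contig}, ["s"])

    def test_substitution_gate_at_20(self):
        contig = _random_seq(400, 6)
        alt = "A" if contig[200] != "A" else "C"
        var = contig[100:200] + alt + contig[201:300]
        # 5 alt / 15 reads: quality far above 20 -> reported
        reads = [(f"a{i}", "s", var) for i in range(5)]
        reads += [(f"r{i}", "s", contig[100:300]) for i in range(10)]
        calls = call_sites_shotgun(self._pileup(reads, contig))
        assert any(c.pos == 200 and not c.is_indel for c in calls)

    def test_low_quality_substitution_suppressed(self):
        contig = _random_seq(400, 7)
        alt = "A" if contig[200] != "A" else "C"
        var = contig[100:200] + alt + contig[201:300]
        # 1 alt / 6 reads: P(X>=1 | n=6, p=0.01) ~ 0.059 -> Q ~ 12 < 20
        reads = [("a0", "s", var)]
        reads += [(f"r{i}", "s", contig[100:300]) for i in range(5)]
        calls = call_sites_shotgun(self._pileup(reads, contig))
        assert not any(c.pos == 200 and not c.is_indel for c in calls)

    def test_indel_gate_at_50(self):
        contig = _random_seq(400, 8)
        deleted = contig[100:200] + contig[203:300]   # 3 bp deletion
        # high depth: 12 del reads of 24 -> Q caps at 60 >= 50 -> reported
        reads = [(f"d{i}", "s", deleted) for i in range(12)]
        reads += [(f"r{i}", "s", contig[100:300]) for i in range(12)]
        calls = call_sites_shotgun(self._pileup(reads, contig))
        indels = [c for c in calls if c.is_indel]
        assert len(indels) == 1
        assert indels[0].pos == 199           # left-anchoring base
        assert indels[0].ref == contig[199:203] and indels[0].alt == contig[199]
        assert indels[0].genotypes["s"] == HET

    def test_indel_below_gate_suppressed(self):
        contig = _random_seq(400, 9)
        deleted = contig[100:200] + contig[203:300]
        # 2 del reads of 8: P(X>=2 | n=8, p=0.01) ~ 2.6e-3 -> Q ~ 26 < 50
        reads = [(f"d{i}", "s", deleted) for i in range(2)]
        reads += [(f"r{i}", "s", contig[100:300]) for i in range(6)]
        calls = call_sites_shotgun(self._pileup(reads, contig))
        assert not any(c.is_indel for c in calls)

    def test_insertion_event_recorded(self):
        # without indel realignment an insertion whose edge bases match the
        # contig boundary may be reported as adjacent sub-events; the total
        # inserted sequence near the anchor must still account for 3 bases
        contig = _random_seq(400, 10)
        inserted = contig[100:200] + "ACT" + contig[200:300]
        reads = [(f"i{i}", "s", inserted) for i in range(12)]
        reads += [(f"r{i}", "s", contig[100:300]) for i in range(12)]
        calls = call_sites_shotgun(self._pileup(reads, contig))
        indels = [c for c in calls if c.is_indel]
        assert indels, "insertion not reported"
        assert all(abs(c.pos - 199) <= 1 for c in indels)
        assert sum(len(c.alt) - len(c.ref) for c in indels) == 3
        assert all(c.genotypes["s"] == HET for c in indels)


class TestSummary:
    def test_hand_counted_totals(self):
        contig = "ACGT" * 100
        from radmarkers.aligncall import SiteCall
        calls = [
            SiteCall("c", 10, "A", "G", {"s1": HET, "s2": HOM_REF}, {}, 40.0),
            SiteCall("c", 20, "C", "T", {"s1": HOM_ALT, "s2": HOM_ALT}, {}, 40.0),
            SiteCall("c", 30, "G", "A", {"s1": HOM_REF, "s2": HET}, {}, 40.0),
        ]
        s = summarize_variants(calls)
        assert (s.n_sites, s.n_het_sites, s.n_hom_sites) == (3, 2, 1)
        assert s.substitution_classes == {"A-G": 2, "C-T": 1}

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            summarize_variants([])
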