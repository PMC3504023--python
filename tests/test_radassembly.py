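"""Demultiplexing, unitag clustering, the minimal assembler, filters and
assembly statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from radmarkers.radassembly import (AssemblyStats, LocusContig, UnitagCluster,
                                    build_unitags, debruijn_contigs,
                                    demultiplex, filter_assemblies, n50,
                                    select_reference_sample)
from radmarkers.simdata import ReadPair, simulate_rad_library, simulate_reference

from conftest import mini_config


def _pair(fwd, sample="x", rid="r1", rev="T" * 80):
    return ReadPair(rid, sample, fwd, "I" * len(fwd), rev, "I" * len(rev))


class TestDemultiplex:
    BARCODES = {"s1": "AACCG", "s2": "ACGTA"}

    def test_assigns_by_prefix_and_strips_barcode(self):
        pairs = [_pair("ACGTA" + "G" * 40)]
        out, rejected = demultiplex(pairs, self.BARCODES)
        assert rejected == 0
        assert len(out["s2"]) == 1 and out["s1"] == []
        assert out["s2"][0].forward == "G" * 40

    def test_unknown_prefix_rejected(self):
        out, rejected = demultiplex([_pair("TTTTT" + "G" * 40)], self.BARCODES)
        assert rejected == 1
        assert all(v == [] for v in out.values())

    def test_duplicate_barcodes_error(self):
        with pytest.raises(ValueError):
            demultiplex([], {"a": "AAAAA", "b": "AAAAA"})

    def test_simulated_assignment_matches_manifest(self):
        cfg = mini_config()
        truth = simulate_reference(cfg)
        pairs, manifest = simulate_rad_library(truth, cfg, reads_per_tag=5)
        out, rejected = demultiplex(pairs, cfg.barcode_map)
        assert rejected == 0
        expected = {}
        for m in manifest:
            expected.setdefault(m["sample"], set()).add(m["read_id"])
        got = {s: {p.id for p in ps} for s, ps in out.items()}
        assert got == expected


class TestUnitags:
    def test_ten_identical_reads_one_retained_cluster(self):
        pairs = [_pair("A" * 40, rid=f"r{i}") for i in range(10)]
        clusters = build_unitags(pairs)
        assert len(clusters) == 1
        assert clusters[0].depth == 10

    @pytest.mark.parametrize("n", [3, 600])
    def test_depth_outside_window_dropped(self, n):
        pairs = [_pair("A" * 40, rid=f"r{i}") for i in range(n)]
        assert build_unitags(pairs) == []

    def test_clusters_carry_their_reverse_reads(self):
        pairs = [_pair("A" * 40, rid=f"r{i}", rev="C" * 80) for i in range(6)]
        (cluster,) = build_unitags(pairs)
        assert cluster.reverse_reads == ["C" * 80] * 6


def _tiling_cluster(locus_seq, step=10, unitag_len=40, read_len=80):
    reads = [locus_seq[i : i + read_len]
             for i in range(0, len(locus_seq) - read_len + 1, step)]
    return UnitagCluster(unitag=locus_seq[:unitag_len], depth=len(reads),
                         read_ids=[f"r{i}" for i in range(len(reads))],
                         reverse_reads=reads)


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestAssembler:
    def test_error_free_tiling_reads_reconstruct_the_locus(self):
        from radmarkers.radassembly import assemble_locus
        locus = _random_seq(300, 3)
        contigs = assemble_locus(_tiling_cluster(locus), k=31, sample="s")
        assert len(contigs) == 1
        assert contigs[0].sequence == locus
        assert contigs[0].is_locus_contig

    def test_short_locus_yields_no_contig(self):
        from radmarkers.radassembly import assemble_locus
        locus = _random_seq(120, 4)
        cluster = UnitagCluster(unitag=locus[:40], depth=5, read_ids=["a"] * 5,
                                reverse_reads=[locus[40:]] * 5)
        assert assemble_locus(cluster, k=31) == []

    def test_two_disjoint_loci_assemble_independently(self):
        from radmarkers.radassembly import assemble_locus
        a, b = _random_seq(260, 5), _random_seq(260, 6)
        ca = assemble_locus(_tiling_cluster(a), k=31, sample="s", locus_counter=0)
        cb = assemble_locus(_tiling_cluster(b), k=31, sample="s", locus_counter=1)
        assert ca[0].sequence == a and cb[0].sequence == b

    def test_heterozygous_fork_resolved_by_majority(self):
        locus = _random_seq(300, 7)
        alt = locus[:150] + ("A" if locus[150] != "A" else "C") + locus[151:]
        reads = []
        for seq, copies in ((locus, 3), (alt, 1)):
            for _ in range(copies):
                reads.extend(seq[i : i + 80] for i in range(0, 221, 10))
        contigs = debruijn_contigs(reads, k=31, min_length=150)
        assert contigs[0][0] == locus  # majority haplotype wins the fork

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            debruijn_contigs(["ACGT" * 30], k=1)


class TestFilters:
    @staticmethod
    def _contig(depth, length=200, cid="c"):
        return LocusContig(id=cid, sample="s", sequence="A" * length,
                           mean_depth=depth, source_unitag="u")

    def test_outlier_depth_removed(self):
        contigs = [self._contig(d, cid=str(d)) for d in (10, 11, 12, 13, 100)]
        kept, removed = filter_assemblies(contigs)
        assert [c.mean_depth for c in removed] == [100]
        assert len(kept) == 4

    def test_equal_depths_all_retained(self):
        contigs = [self._contig(8, cid=str(i)) for i in range(5)]
        kept, removed = filter_assemblies(contigs)
        assert removed == [] and len(kept) == 5

    def test_double_coverage_paralog_survives_the_cap(self):
        contigs = [self._contig(d, cid=str(i)) for i, d in enumerate([10] * 8 + [20])]
        kept, _ = filter_assemblies(contigs)
        assert any(c.mean_depth == 20 for c in kept)

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            filter_assemblies([])


class TestReferenceSelection:
    @staticmethod
    def _contigs(n, length=100):
        return [LocusContig(id=str(i), sample="s", sequence="A" * length,
                            mean_depth=10, source_unitag="u") for i in range(n)]

    def test_highest_contig_count_wins(self):
        per_sample = {"s2": self._contigs(10008), "s3": self._contigs(10110),
                      "s4": self._contigs(10352), "s7": self._contigs(7918)}
        assert select_reference_sample(per_sample) == "s4"

    def test_single_sample(self):
        assert select_reference_sample({"only": self._contigs(3)}) == "only"

    def test_tie_broken_by_total_bases_then_id(self):
        per_sample = {"b": self._contigs(5, length=120),
                      "a": self._contigs(5, length=100)}
        assert select_reference_sample(per_sample) == "b"
        per_sample = {"b": self._contigs(5), "a": self._contigs(5)}
        assert select_reference_sample(per_sample) == "a"

    def test_all_empty_error(self):
        with pytest.raises(ValueError):
            select_reference_sample({"a": [], "b": []})


def n50_oracle(lengths):
    """Exhaustive prefix oracle."""
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    for i in range(len(ordered)):
        if sum(ordered[: i + 1]) * 2 >= total:
            return ordered[i]


class TestN50:
    @pytest.mark.parametrize("lengths,expected", [
        ([5, 4, 3, 2, 1], 4),
        ([42], 42),
        ([7, 7, 7], 7),
    ])
    def test_examples(self, lengths, expected):
        assert n50(lengths) == expected

    @given(st.lists(st.integers(min_value=1, max_value=1000), min_size=1,
                    max_size=50))
    def test_equals_exhaustive_oracle(self, lengths):
        assert n50(lengths) == n50_oracle(lengths)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            n50([])

    def test_stats_row(self):
        contigs = [LocusContig(id=str(i), sample="s", sequence="A" * n,
                               mean_depth=1, source_unitag="u")
                   for i, n in enumerate([150, 200, 250])]
        stats = AssemblyStats.from_contigs("s", contigs)
        assert (stats.n_contigs, stats.total_bp, stats.n50) == (3, 600, 200)
        assert (stats.min_length, stats.max_length) == (150, 250)
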