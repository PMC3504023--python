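"""The truth-linked simulator: determinism, composition, planted features,
read geometry, and replicate-error injection."""

import dataclasses

import numpy as np
import pytest

from radmarkers._util import revcomp
from radmarkers.digest import find_sites
from radmarkers.simdata import (SimConfig, SizingError, _haplotype_sequence,
                                simulate_rad_library, simulate_reference,
                                simulate_replicates, simulate_shotgun)

from conftest import mini_config


class TestConfigValidation:
    def test_insert_range_must_cover_read_lengths(self):
        with pytest.raises(ValueError):
            SimConfig(insert_range=(100, 800))

    def test_rates_in_unit_interval(self):
        with pytest.raises(ValueError):
            SimConfig(ado_rate=1.5)

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(barcodes={"a": "ACGTA", "b": "ACGTA"})

    def test_sizing_error_when_features_do_not_fit(self):
        with pytest.raises(SizingError):
            simulate_reference(SimConfig(genome_length=9000, n_enzyme_sites=40))


class TestReference:
    def test_deterministic_given_seed(self):
        cfg = mini_config()
        t1 = simulate_reference(cfg)
        t2 = simulate_reference(cfg)
        assert t1.reference == t2.reference
        assert t1.variant_sites == t2.variant_sites
        assert t1.ssr_loci == t2.ssr_loci

    def test_gc_zero_means_no_gc_outside_planted_sites(self):
        cfg = mini_config(gc_content=0.0, ssr_spec=(), n_duplicated_loci=0,
                          snp_density=0.0, n_private_per_individual=0)
        truth = simulate_reference(cfg)
        planted = set()
        for s in truth.site_positions:
            planted.update(range(s, s + 6))
        gc_positions = {i for i, b in enumerate(truth.reference) if b in "GC"}
        assert gc_positions <= planted

    def test_empirical_gc_within_3_binomial_sd(self):
        cfg = SimConfig(genome_length=1_000_000, gc_content=0.41, seed=1)
        truth = simulate_reference(cfg)
        masked = set()
        for s in truth.site_positions:
            masked.update(range(s, s + 6))
        for start, motif, reps in truth.ssr_loci:
            masked.update(range(start - 1, start + len(motif) * reps + 1))
        free = [b for i, b in enumerate(truth.reference) if i not in masked]
        n = len(free)
        gc = sum(b in "GC" for b in free)
        sd = np.sqrt(n * 0.41 * 0.59)
        assert abs(gc - 0.41 * n) < 3 * sd

    def test_digest_recovers_exactly_the_planted_sites(self):
        truth = simulate_reference(mini_config())
        planted = sorted({l.site_pos for l in truth.rad_loci})
        assert find_sites(truth.reference, truth.config.enzyme_site) == planted

    def test_planted_ssrs_present_verbatim(self):
        truth = simulate_reference(mini_config())
        for start, motif, reps in truth.ssr_loci:
            assert truth.reference[start : start + len(motif) * reps] == motif * reps

    def test_duplicated_copy_differs_at_exactly_the_planted_positions(self):
        truth = simulate_reference(mini_config())
        assert truth.duplicated_segments
        for src, copy, planted_diffs in truth.duplicated_segments:
            a = truth.reference[src[0] : src[1]]
            b = truth.reference[copy[0] : copy[1]]
            diffs = [copy[0] + i for i, (x, y) in enumerate(zip(a, b)) if x != y]
            assert diffs == sorted(planted_diffs)  # one per cut direction
            assert len(diffs) == 2

    def test_variant_positions_unique_and_in_range(self):
        truth = simulate_reference(mini_config())
        positions = [v.pos for v in truth.variant_sites]
        assert len(positions) == len(set(positions))
        assert all(0 <= p < len(truth.reference) for p in positions)

    def test_private_sites_are_singleton_heterozygotes(self):
        truth = simulate_reference(mini_config(n_private_per_individual=2))
        for v in truth.variant_sites:
            if v.private_to is None:
                continue
            for ind, (a, b) in v.genotypes.items():
                if ind == v.private_to:
                    assert a != b
                else:
                    assert a == b == v.ref


class TestRadLibrary:
    def test_fixed_read_count(self):
        cfg = mini_config()
        truth = simulate_reference(cfg)
        pairs, manifest = simulate_rad_library(truth, cfg, reads_per_tag=7)
        assert len(pairs) == 7 * len(truth.rad_loci) * cfg.n_individuals
        assert len(manifest) == len(pairs)

    def test_read_ids_unique_and_manifest_conserved(self):
        cfg = mini_config()
        truth = simulate_reference(cfg)
        pairs, manifest = simulate_rad_library(truth, cfg, reads_per_tag=5)
        ids = [p.id for p in pairs]
        assert len(ids) == len(set(ids))
        assert set(ids) == {m["read_id"] for m in manifest}

    def test_error_free_forward_reads_flank_the_cut(self):
        cfg = mini_config(n_duplicated_loci=0, snp_density=0.0,
                          n_private_per_individual=0)
        truth = simulate_reference(cfg)
        pairs, manifest = simulate_rad_library(truth, cfg, reads_per_tag=2)
        barcodes = cfg.barcode_map
        by_id = {m["read_id"]: m for m in manifest}
        for p in pairs[:200]:
            m = by_id[p.id]
            cut = m["site_pos"] + 1
            tag = p.forward[len(barcodes[p.sample]):]
            if m["direction"] > 0:
                assert tag == truth.reference[cut : cut + 40]
            else:
                assert tag == revcomp(truth.reference[cut - 40 : cut])

    def test_error_free_reverse_reads_at_the_sheared_end(self):
        cfg = mini_config(n_duplicated_loci=0, snp_density=0.0,
                          n_private_per_individual=0)
        truth = simulate_reference(cfg)
        pairs, manifest = simulate_rad_library(truth, cfg, reads_per_tag=2)
        by_id = {m["read_id"]: m for m in manifest}
        for p in pairs[:200]:
            m = by_id[p.id]
            locus = truth.locus_by_id(m["locus_id"])
            seq = truth.locus_sequence(locus)
            assert p.reverse == seq[m["insert"] - 80 : m["insert"]]

    def test_het_site_allele_balance_binomial(self):
        cfg = mini_config(snp_density=6e-4)
        truth = simulate_reference(cfg)
        het = next((v, ind)
                   for v in truth.variant_sites if v.private_to is None
                   for ind, (a, b) in v.genotypes.items() if a != b)
        v, ind = het
        locus = truth.locus_by_id(v.locus_id)
        off = truth.oriented_offset(locus, v.pos)
        alt_o = v.alt if locus.direction > 0 else revcomp(v.alt)
        pairs, manifest = simulate_rad_library(truth, cfg, reads_per_tag=120)
        by_id = {m["read_id"]: m for m in manifest}
        alt = depth = 0
        for p in pairs:
            m = by_id[p.id]
            if p.sample != ind or m["locus_id"] != v.locus_id:
                continue
            lo = m["insert"] - 80
            if lo <= off < m["insert"]:
                depth += 1
                alt += p.reverse[off - lo] == alt_o
        assert depth >= 10
        sd = np.sqrt(depth * 0.25)
        assert abs(alt - 0.5 * depth) < 3 * sd

    def test_determinism_of_read_stream(self):
        cfg = mini_config()
        truth = simulate_reference(cfg)
        p1, m1 = simulate_rad_library(truth, cfg, reads_per_tag=3)
        p2, m2 = simulate_rad_library(truth, cfg, reads_per_tag=3)
        assert p1 == p2 and m1 == m2

    def test_degenerate_truth_warns_and_returns_empty(self):
        cfg = mini_config()
        truth = simulate_reference(cfg)
        truth.rad_loci = []
        with pytest.warns(UserWarning):
            pairs, manifest = simulate_rad_library(truth, cfg)
        assert pairs == [] and manifest == []


class TestShotgun:
    def test_zero_reads(self):
        cfg = mini_config()
        truth = simulate_reference(cfg)
        assert simulate_shotgun(truth, cfg, n_reads=0) == ([], [])

    def test_mean_length_within_3_se(self):
        cfg = mini_config()
        truth = simulate_reference(cfg)
        reads, _ = simulate_shotgun(truth, cfg, n_reads=10_000)
        lengths = np.array([len(r.sequence) for r in reads])
        se = cfg.shotgun_len_sd / np.sqrt(len(lengths))
        assert abs(lengths.mean() - 348) < 3 * se

    def test_error_free_reads_are_haplotype_substrings(self):
        cfg = mini_config(error_rate=0.0)
        truth = simulate_reference(cfg)
        reads, manifest = simulate_shotgun(truth, cfg, n_reads=60)
        haps = {(ind, h): _haplotype_sequence(truth, ind, h)
                for ind in truth.individuals[:2] for h in (0, 1)}
        for r, m in zip(reads, manifest):
            src = haps[(r.sample, m["haplotype"])]
            assert src[m["start"] : m["start"] + m["length"]] == r.sequence


class TestReplicates:
    def _genotypes(self, n_het=50, n_hom=50):
        g = {}
        for i in range(n_het):
            g[("s1", f"het{i}")] = ("A", "G")
        for i in range(n_hom):
            g[("s1", f"hom{i}")] = ("C", "C")
        return g

    def test_no_errors_reproduces_truth(self):
        cfg = mini_config(ado_rate=0.0, fa_rate=0.0, fail_rate=0.0)
        genotypes = self._genotypes()
        table, events = simulate_replicates(genotypes, cfg)
        assert events == []
        for key, obs in table.items():
            assert all(o == tuple(sorted(genotypes[key])) for o in obs)

    def test_certain_dropout_makes_every_het_replicate_homozygous(self):
        cfg = mini_config(ado_rate=1.0, fa_rate=0.0, fail_rate=0.0)
        table, _ = simulate_replicates(self._genotypes(n_hom=0), cfg)
        for obs in table.values():
            assert all(o[0] == o[1] for o in obs)

    def test_empirical_dropout_rate_within_3_binomial_sd(self):
        cfg = mini_config(ado_rate=0.2, fa_rate=0.0, fail_rate=0.0,
                          n_replicates=4)
        genotypes = {("s1", f"L{i}"): ("A", "G") for i in range(500)}
        table, events = simulate_replicates(genotypes, cfg)
        n_amps = 500 * 4
        n_ado = sum(e["event"] == "ado" for e in events)
        sd = np.sqrt(n_amps * 0.2 * 0.8)
        assert abs(n_ado - 0.2 * n_amps) < 3 * sd

    def test_config_is_frozen(self):
        with pytest.raises(dataclasses.FrozenInstanceError):
            mini_config().seed = 5
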