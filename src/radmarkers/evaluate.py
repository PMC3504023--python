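"""Truth-linked evaluation of pipeline output.

Given a :class:`~radmarkers.pipeline.RadPipelineResult` whose inputs came
from the simulator, these helpers score each stage against the planted
ground truth: exact sequence recovery of planted loci, per-genotype
concordance of the threshold calls, recall/false-positive accounting of
the fixed-heterozygote (collapsed paralog) flags, and private-allele
counts. Contigs are tied back to their truth locus through the unitag
they were clustered on, and anchored to locus coordinates with exact
31-mers so that a contig carrying a variant allele still locates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .aligncall import HET, HOM_ALT, HOM_REF, MISSING
from .pipeline import RadPipelineResult
from .radassembly import LocusContig
from .simdata import RadLocus, TruthSet


def _unitag_map(truth: TruthSet) -> dict[str, list[RadLocus]]:
    """Unitag sequence -> truth loci sharing it (duplicated loci collapse
    onto their source's unitag)."""
    flen = truth.config.read_lengths[0]
    out: dict[str, list[RadLocus]] = {}
    for locus in truth.rad_loci:
        out.setdefault(truth.locus_sequence(locus)[:flen], []).append(locus)
    return out


def _anchor_offset(contig: str, locus_seq: str, k: int = 31) -> int | None:
    """Offset of ``contig`` within ``locus_seq`` via exact k-mer anchors
    (tried at several contig positions so a variant base cannot defeat
    all of them)."""
    probes = [0, len(contig) // 4, len(contig) // 2,
              3 * len(contig) // 4, len(contig) - k]
    for p in probes:
        if p < 0 or p + k > len(contig):
            continue
        idx = locus_seq.find(contig[p : p + k])
        if idx >= 0:
            return idx - p
    return None


@dataclass
class LocusRecovery:
    n_expected: int
    n_recovered: int

    @property
    def fraction(self) -> float:
        return self.n_recovered / self.n_expected if self.n_expected else 0.0


def locus_recovery(result: RadPipelineResult) -> LocusRecovery:
    """Fraction of (sample, planted locus) pairs whose flagged locus
    contig is an exact substring of one of that sample's true haplotype
    sequences (for collapsed duplicates: of either co-amplified copy).

    Exactness is over the assembled span; under uniform shearing the
    extreme insert sizes are sampled stochastically, so span endpoints
    vary while any internal mis-assembly fails the substring test.
    """
    truth = result.truth
    unitags = _unitag_map(truth)
    expected = recovered = 0
    for sample, contigs in result.assemblies.items():
        flagged = {c.source_unitag: c for c in contigs if c.is_locus_contig}
        for unitag, loci in unitags.items():
            expected += 1
            contig = flagged.get(unitag)
            if contig is None:
                continue
            ok = False
            for locus in loci:
                if locus.duplicate_of or any(l.duplicate_of for l in loci):
                    # collapsed cluster: reference sequence of either copy
                    if contig.sequence in truth.locus_sequence(locus):
                        ok = True
                        break
                for hap in (0, 1):
                    if contig.sequence in truth.locus_haplotype(locus, sample, hap):
                        ok = True
                        break
                if ok:
                    break
            recovered += ok
    return LocusRecovery(n_expected=expected, n_recovered=recovered)


@dataclass
class GenotypeConcordance:
    n_compared: int
    n_concordant: int
    n_variants_covered: int
    n_variants_total: int

    @property
    def fraction(self) -> float:
        return self.n_concordant / self.n_compared if self.n_compared else 0.0


def _reference_contig_map(result: RadPipelineResult) -> dict[str, tuple[RadLocus, int, LocusContig]]:
    """Mini-reference contig id -> (truth locus, offset in locus, contig)."""
    truth = result.truth
    unitags = _unitag_map(truth)
    ref_sample = result.reference_sample
    out: dict[str, tuple[RadLocus, int, LocusContig]] = {}
    for contig in result.assemblies[ref_sample]:
        if not contig.is_locus_contig:
            continue
        loci = unitags.get(contig.source_unitag)
        if not loci:
            continue
        # anchor against the non-duplicated representative (source copy)
        locus = next((l for l in loci if not l.duplicate_of), loci[0])
        off = _anchor_offset(contig.sequence, truth.locus_sequence(locus))
        if off is not None:
            out[contig.id] = (locus, off, contig)
    return out


def genotype_concordance(result: RadPipelineResult) -> GenotypeConcordance:
    """Compare threshold-model calls with planted genotypes.

    For every planted variant lying inside a located mini-reference
    contig, every individual's called allele pair (from the site call,
    or implicitly homozygous for the contig base when no site was
    reported) is compared with the truth allele pair; ``missing`` calls
    count as discordant.
    """
    truth = result.truth
    contig_map = _reference_contig_map(result)
    calls_by_pos = {(c.contig, c.pos): c for c in result.calls}

    n_compared = n_concordant = covered = 0
    n_variants = 0
    for locus in truth.rad_loci:
        if locus.duplicate_of:
            continue
        variants = truth.variants_in_locus(locus)
        n_variants += len(variants)

    for cid, (locus, off, contig) in contig_map.items():
        for v in truth.variants_in_locus(locus):
            loff = truth.oriented_offset(locus, v.pos)
            cpos = loff - off
            if not 0 <= cpos < contig.length:
                continue
            covered += 1
            call = calls_by_pos.get((cid, cpos))
            contig_base = contig.sequence[cpos]
            oriented = locus.direction > 0
            for ind in truth.individuals:
                truth_pair = sorted(
                    a if oriented else _comp(a) for a in v.genotypes[ind]
                )
                if call is None:
                    called_pair = [contig_base, contig_base]
                else:
                    g = call.genotypes[ind]
                    if g == HOM_REF:
                        called_pair = [call.ref, call.ref]
                    elif g == HET:
                        called_pair = sorted((call.ref, call.alt))
                    elif g == HOM_ALT:
                        called_pair = [call.alt, call.alt]
                    else:
                        called_pair = None
                n_compared += 1
                if called_pair is not None and called_pair == truth_pair:
                    n_concordant += 1
    return GenotypeConcordance(
        n_compared=n_compared, n_concordant=n_concordant,
        n_variants_covered=covered, n_variants_total=n_variants,
    )


def _comp(seq: str) -> str:
    from ._util import revcomp
    return revcomp(seq)


def heterozygosity_at_planted_snps(result: RadPipelineResult) -> float | None:
    """Mean observed heterozygosity of the called genotypes at planted
    regular variants (private and paralog-diff sites excluded, so the
    expectation under the simulator equals the configured target
    heterozygosity).

    Planted variants covered by the mini-reference but not reported by
    the caller are counted as homozygous-reference for every individual,
    mirroring how monomorphic loci enter a validation panel's Ho.
    """
    truth = result.truth
    contig_map = _reference_contig_map(result)
    calls_by_pos = {(c.contig, c.pos): c for c in result.calls}
    het = {ind: 0 for ind in truth.individuals}
    total = 0
    for cid, (locus, off, contig) in contig_map.items():
        for v in truth.variants_in_locus(locus):
            if v.private_to is not None:
                continue
            cpos = truth.oriented_offset(locus, v.pos) - off
            if not 0 <= cpos < contig.length:
                continue
            total += 1
            call = calls_by_pos.get((cid, cpos))
            if call is None:
                continue
            for ind in truth.individuals:
                if call.genotypes[ind] == HET:
                    het[ind] += 1
    if total == 0:
        return None
    per_ind = [het[ind] / total for ind in truth.individuals]
    return sum(per_ind) / len(per_ind)


@dataclass
class ParalogFlagging:
    expected: set[str]
    flagged: set[str]

    @property
    def recall(self) -> float:
        if not self.expected:
            return 0.0
        return len(self.expected & self.flagged) / len(self.expected)

    @property
    def false_flags(self) -> set[str]:
        return self.flagged - self.expected


def paralog_flagging(result: RadPipelineResult) -> ParalogFlagging:
    """Compare fixed-heterozygote flags with planted duplicated loci.

    The expected flag set contains one ``contig:pos`` key per planted
    copy divergence that lies inside a located mini-reference contig.
    """
    truth = result.truth
    unitags = _unitag_map(truth)
    contig_map = _reference_contig_map(result)
    expected: set[str] = set()
    for cid, (locus, off, contig) in contig_map.items():
        cluster_loci = unitags.get(contig.source_unitag, [])
        for member in cluster_loci:
            if member.fixed_diff_offset is None:
                continue
            cpos = member.fixed_diff_offset - off
            if 0 <= cpos < contig.length:
                expected.add(f"{cid}:{cpos}")
    return ParalogFlagging(expected=expected, flagged=set(result.fixed_het_loci))
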