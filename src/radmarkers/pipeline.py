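"""End-to-end orchestration of the RAD and shotgun discovery pipelines.

``run_rad_pipeline`` executes simulate -> demultiplex -> unitag
clustering -> local assembly -> depth filtering -> mini-reference
selection -> mapping -> threshold calling -> assay design -> summary
statistics, and ``run_shotgun_pipeline`` the combined-assembly path with
quality-gated SNP/indel calls and the SSR scan. Both return a result
object carrying every intermediate product plus a :class:`RunManifest`
with stage timings and record counts; when ``outdir`` is given the
standard-format outputs (FASTA, VCF, TSV reports) are written and
registered in the manifest.
"""

from __future__ import annotations

import os
import time
from dataclasses import dataclass, field, asdict

from . import aligncall, assaydesign, popstats, radassembly, ssr as ssrmod
from .aligncall import MISSING, SiteCall
from .radassembly import AssemblyStats, LocusContig
from .simdata import (ReadPair, ShotgunRead, SimConfig, TruthSet,
                      simulate_rad_library, simulate_reference, simulate_shotgun)
from .vcfio import write_vcf


@dataclass
class RunManifest:
    seed: int
    config: dict
    stages: list[dict] = field(default_factory=list)
    files: list[str] = field(default_factory=list)

    def record(self, name: str, seconds: float, **counts) -> None:
        self.stages.append({"stage": name, "seconds": round(seconds, 3), **counts})

    def register(self, path: str) -> None:
        self.files.append(path)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class _Timer:
    def __init__(self, manifest: RunManifest, stage: str):
        self.manifest = manifest
        self.stage = stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        self.counts: dict = {}
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise PipelineError(self.stage, exc) from exc
        self.manifest.record(self.stage, time.perf_counter() - self.t0, **self.counts)


@dataclass
class RadPipelineResult:
    truth: TruthSet
    read_manifest: list[dict]
    n_pairs: int
    n_rejected: int
    clusters_per_sample: dict[str, int]
    assemblies: dict[str, list[LocusContig]]
    removed: dict[str, list[LocusContig]]
    assembly_stats: dict[str, AssemblyStats]
    reference_sample: str
    reference_contigs: dict[str, str]
    mapping: aligncall.MappingResult
    calls: list[SiteCall]
    variant_summary: aligncall.VariantSummary | None
    markers: list[assaydesign.MarkerRecord]
    n_plexes: int
    fixed_het_loci: set[str]
    split_loci: list[str]
    private_counts: dict[str, int]
    genotype_matrix: dict[str, dict[str, str]]
    tstv: popstats.TsTv | None
    snp_density: float
    mean_ho: float | None
    manifest: RunManifest


def _genotype_label_matrix(calls: list[SiteCall]) -> dict[str, dict[str, str]]:
    return {f"{c.contig}:{c.pos}": dict(c.genotypes) for c in calls}


def _allele_matrix(calls: list[SiteCall]) -> dict[str, dict[str, str]]:
    out: dict[str, dict[str, str]] = {}
    for c in calls:
        row = {}
        for s, g in c.genotypes.items():
            if g == aligncall.HOM_REF:
                row[s] = f"{c.ref}/{c.ref}"
            elif g == aligncall.HET:
                a, b = sorted((c.ref, c.alt))
                row[s] = f"{a}/{b}"
            elif g == aligncall.HOM_ALT:
                row[s] = f"{c.alt}/{c.alt}"
            else:
                row[s] = "."
        out[f"{c.contig}:{c.pos}"] = row
    return out


def run_rad_pipeline(
    config: SimConfig,
    truth: TruthSet | None = None,
    outdir: str | None = None,
    min_cov: int = radassembly.DEFAULT_MIN_COV,
    max_cov: int = radassembly.DEFAULT_MAX_COV,
    k: int = radassembly.DEFAULT_K,
    min_contig_length: int = radassembly.DEFAULT_MIN_CONTIG,
    t: float = aligncall.DEFAULT_THRESHOLD,
    min_depth: int = aligncall.DEFAULT_MIN_DEPTH,
) -> RadPipelineResult:
    """The full RAD marker-discovery pipeline on simulated reads."""
    manifest = RunManifest(seed=config.seed, config=asdict(config))
    barcode_map = config.barcode_map

    with _Timer(manifest, "simulate") as tm:
        if truth is None:
            truth = simulate_reference(config)
        pairs, read_manifest = simulate_rad_library(truth, config)
        tm.counts = {"reads_in": len(pairs)}

    with _Timer(manifest, "demultiplex") as tm:
        per_sample, rejected = radassembly.demultiplex(pairs, barcode_map)
        tm.counts = {"assigned": sum(len(v) for v in per_sample.values()),
                     "rejected": rejected}
    del pairs

    assemblies: dict[str, list[LocusContig]] = {}
    removed: dict[str, list[LocusContig]] = {}
    clusters_per_sample: dict[str, int] = {}
    with _Timer(manifest, "assemble") as tm:
        for sample in sorted(per_sample):
            clusters = radassembly.build_unitags(per_sample[sample],
                                                 min_cov=min_cov, max_cov=max_cov)
            clusters_per_sample[sample] = len(clusters)
            contigs = radassembly.assemble_sample(clusters, k=k,
                                                  min_contig_length=min_contig_length,
                                                  sample=sample)
            if contigs:
                kept, dropped = radassembly.filter_assemblies(contigs)
            else:
                kept, dropped = [], []
            assemblies[sample] = kept
            removed[sample] = dropped
        tm.counts = {"clusters": sum(clusters_per_sample.values()),
                     "contigs": sum(len(v) for v in assemblies.values())}

    stats = {s: AssemblyStats.from_contigs(s, cs) for s, cs in assemblies.items() if cs}

    with _Timer(manifest, "select_reference") as tm:
        ref_sample = radassembly.select_reference_sample(assemblies)
        ref_contigs = {c.id: c.sequence for c in assemblies[ref_sample]}
        tm.counts = {"reference_sample_contigs": len(ref_contigs)}

    with _Timer(manifest, "map") as tm:
        reads = [(p.id, sample, p.reverse)
                 for sample in sorted(per_sample)
                 for p in per_sample[sample]]
        mapping = aligncall.map_reads(reads, ref_contigs, mode="rad")
        tm.counts = {"mapped": len(mapping.alignments),
                     "unmapped": mapping.n_unmapped,
                     "ambiguous": mapping.n_ambiguous}
    del reads

    with _Timer(manifest, "call") as tm:
        pile = aligncall.pileup(mapping.alignments, ref_contigs,
                                sorted(per_sample))
        calls = aligncall.call_sites_rad(pile, t=t, min_depth=min_depth)
        tm.counts = {"sites": len(calls)}

    with _Timer(manifest, "assay_design") as tm:
        contig_lengths = {cid: len(seq) for cid, seq in ref_contigs.items()}
        markers = assaydesign.filter_assayable(calls, contig_lengths)
        n_plexes = assaydesign.group_multiplexes(markers)
        label_matrix = _genotype_label_matrix(calls)
        fixed = assaydesign.flag_fixed_heterozygotes(label_matrix)
        split = assaydesign.split_duplicated_loci(sorted(label_matrix), fixed)
        private = assaydesign.private_alleles(label_matrix)
        tm.counts = {"assayable": len(markers), "plexes": n_plexes,
                     "fixed_het": len(fixed)}

    with _Timer(manifest, "popstats") as tm:
        allele_matrix = _allele_matrix(calls)
        summary = aligncall.summarize_variants(calls) if calls else None
        ts = popstats.tstv(summary.substitution_classes) if summary else None
        density = popstats.snp_density(len(calls), sum(contig_lengths.values())) \
            if contig_lengths else 0.0
        _, mean_ho = popstats.observed_heterozygosity(allele_matrix) \
            if allele_matrix else ({}, None)
        tm.counts = {"snps": len(calls)}

    result = RadPipelineResult(
        truth=truth, read_manifest=read_manifest,
        n_pairs=sum(len(v) for v in per_sample.values()) + rejected,
        n_rejected=rejected,
        clusters_per_sample=clusters_per_sample,
        assemblies=assemblies, removed=removed, assembly_stats=stats,
        reference_sample=ref_sample, reference_contigs=ref_contigs,
        mapping=mapping, calls=calls, variant_summary=summary,
        markers=markers, n_plexes=n_plexes, fixed_het_loci=fixed,
        split_loci=split, private_counts=private,
        genotype_matrix=allele_matrix, tstv=ts, snp_density=density,
        mean_ho=mean_ho, manifest=manifest,
    )
    if outdir:
        _write_rad_outputs(result, outdir)
    return result


def _write_fasta(contigs: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for cid in sorted(contigs):
            fh.write(f">{cid}\n")
            seq = contigs[cid]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def _write_rad_outputs(res: RadPipelineResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    fasta = os.path.join(outdir, "mini_reference.fasta")
    _write_fasta(res.reference_contigs, fasta)
    res.manifest.register(fasta)

    vcf = os.path.join(outdir, "rad_calls.vcf")
    write_vcf(res.calls, res.reference_contigs, vcf,
              samples=sorted(res.truth.individuals))
    res.manifest.register(vcf)

    markers = os.path.join(outdir, "markers.tsv")
    with open(markers, "w") as fh:
        fh.write("locus\tcontig\tpos\talleles\tassayable\ttri_allelic\t"
                 "fixed_het\tprivate_to\tplex\tdesign_score\n")
        for m in res.markers:
            fh.write(f"{m.locus_id}\t{m.contig}\t{m.pos}\t{'/'.join(m.alleles)}\t"
                     f"{int(m.assayable)}\t{int(m.tri_allelic)}\t{int(m.fixed_het)}\t"
                     f"{m.private_to or '.'}\t{m.plex or '.'}\t{m.design_score:.2f}\n")
    res.manifest.register(markers)

    stats = os.path.join(outdir, "assembly_stats.tsv")
    with open(stats, "w") as fh:
        fh.write("sample\tn_contigs\ttotal_bp\tmean_length\tn50\tmin_length\tmax_length\n")
        for s in sorted(res.assembly_stats):
            a = res.assembly_stats[s]
            fh.write(f"{s}\t{a.n_contigs}\t{a.total_bp}\t{a.mean_length:.1f}\t"
                     f"{a.n50}\t{a.min_length}\t{a.max_length}\n")
    res.manifest.register(stats)

    matrix = os.path.join(outdir, "genotypes.tsv")
    samples = sorted(res.truth.individuals)
    with open(matrix, "w") as fh:
        fh.write("locus\t" + "\t".join(samples) + "\n")
        for locus in sorted(res.genotype_matrix):
            row = res.genotype_matrix[locus]
            fh.write(locus + "\t" + "\t".join(row.get(s, ".") for s in samples) + "\n")
    res.manifest.register(matrix)


@dataclass
class ShotgunPipelineResult:
    truth: TruthSet
    reads: list[ShotgunRead]
    read_manifest: list[dict]
    contigs: dict[str, str]
    contig_depths: dict[str, float]
    mapping: aligncall.MappingResult
    calls: list[SiteCall]
    n_snps: int
    n_indels: int
    ssr_loci: list[ssrmod.SSRLocus]
    ssr_summary: ssrmod.SSRSummary
    assembly_stats: AssemblyStats | None
    manifest: RunManifest


def run_shotgun_pipeline(
    config: SimConfig,
    truth: TruthSet | None = None,
    n_reads: int = 2000,
    individuals: list[str] | None = None,
    outdir: str | None = None,
    k: int = radassembly.DEFAULT_K,
    min_contig_length: int = 100,
    snp_q_min: float = 20.0,
    indel_q_min: float = 50.0,
) -> ShotgunPipelineResult:
    """Combined shotgun assembly, quality-gated calling and SSR scan.

    Reads from all samples are pooled into one assembly (contigs of at
    least ``min_contig_length`` bases, the long-read convention), each
    sample's reads are mapped back with the gapped aligner, and variant
    sites pass class-specific quality gates (SNPs >= 20, indels >= 50).
    """
    manifest = RunManifest(seed=config.seed, config=asdict(config))

    with _Timer(manifest, "simulate") as tm:
        if truth is None:
            truth = simulate_reference(config)
        inds = individuals if individuals is not None else truth.individuals[:2]
        if not inds:
            raise ValueError("shotgun pipeline needs >= 1 sample")
        reads, read_manifest = simulate_shotgun(truth, config, n_reads=n_reads,
                                                individuals=inds)
        tm.counts = {"reads_in": len(reads)}

    with _Timer(manifest, "assemble") as tm:
        raw = radassembly.debruijn_contigs([r.sequence for r in reads], k=k,
                                           min_length=min_contig_length)
        contigs = {f"sc{i + 1:05d}": seq for i, (seq, _) in enumerate(raw)}
        depths = {f"sc{i + 1:05d}": depth for i, (_, depth) in enumerate(raw)}
        tm.counts = {"contigs": len(contigs)}

    with _Timer(manifest, "map") as tm:
        tuples = [(r.id, r.sample, r.sequence) for r in reads]
        mapping = aligncall.map_reads(tuples, contigs, mode="shotgun")
        tm.counts = {"mapped": len(mapping.alignments),
                     "unmapped": mapping.n_unmapped}

    with _Timer(manifest, "call") as tm:
        pile = aligncall.pileup(mapping.alignments, contigs, sorted(set(inds)))
        calls = aligncall.call_sites_shotgun(pile, snp_q_min=snp_q_min,
                                             indel_q_min=indel_q_min)
        n_indels = sum(c.is_indel for c in calls)
        tm.counts = {"sites": len(calls), "indels": n_indels}

    with _Timer(manifest, "ssr_scan") as tm:
        loci: list[ssrmod.SSRLocus] = []
        for cid in sorted(contigs):
            found = ssrmod.find_ssrs(contigs[cid], contig=cid)
            ssrmod.classify_compound(found)
            for s in found:
                ssrmod.classify_pal(s, contigs[cid])
            loci.extend(found)
        summary = ssrmod.summarize_ssrs(loci)
        tm.counts = {"ssrs": summary.total, "pal": summary.n_pal}

    lengths = [len(s) for s in contigs.values()]
    stats = AssemblyStats(
        sample="combined", n_contigs=len(lengths), total_bp=sum(lengths),
        mean_length=sum(lengths) / len(lengths) if lengths else 0.0,
        n50=radassembly.n50(lengths) if lengths else 0,
        min_length=min(lengths) if lengths else 0,
        max_length=max(lengths) if lengths else 0,
    ) if lengths else None

    result = ShotgunPipelineResult(
        truth=truth, reads=reads, read_manifest=read_manifest,
        contigs=contigs, contig_depths=depths, mapping=mapping,
        calls=calls, n_snps=len(calls) - n_indels, n_indels=n_indels,
        ssr_loci=loci, ssr_summary=summary, assembly_stats=stats,
        manifest=manifest,
    )
    if outdir:
        _write_shotgun_outputs(result, outdir)
    return result


def _write_shotgun_outputs(res: ShotgunPipelineResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    fasta = os.path.join(outdir, "shotgun_contigs.fasta")
    _write_fasta(res.contigs, fasta)
    res.manifest.register(fasta)

    vcf = os.path.join(outdir, "shotgun_calls.vcf")
    write_vcf(res.calls, res.contigs, vcf,
              samples=sorted({r.sample for r in res.reads}))
    res.manifest.register(vcf)

    table = os.path.join(outdir, "ssr_table.tsv")
    with open(table, "w") as fh:
        fh.write("contig\tstart\tend\tmotif\tclass\trepeats\tcompound\tpal\t"
                 "primer_candidate\n")
        for s in res.ssr_loci:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.motif}\t{s.ssr_class}\t"
                     f"{s.repeats}\t{int(s.compound)}\t{int(s.pal)}\t"
                     f"{int(s.primer_candidate)}\n")
    res.manifest.register(table)
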