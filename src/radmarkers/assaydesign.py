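"""Filtering candidate SNPs into genotyping-assayable markers.

Mass-spectrometry genotyping assays (single-base primer extension)
constrain which SNPs can be typed: the site must sit on a clean
template, so markers are required to be free of other polymorphisms
within a 60 bp window on either side, at least 30 bp from both contig
ends, bi-allelic, and unique within their contig. Surviving markers are
grouped into multiplexes of at most 40. Loci at which every individual
is heterozygous are flagged as collapsed paralogs (two co-amplifying
monomorphic loci) and split in two for population-genetic bookkeeping;
minor alleles confined to a single heterozygous individual are counted
as private alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .aligncall import HET, HOM_ALT, HOM_REF, MISSING, SiteCall

DEFAULT_WINDOW = 60
DEFAULT_EDGE = 30
DEFAULT_PLEX_CAP = 40

_N_RULES = 4  # window, edge, bi-allelic, unique-in-contig


@dataclass
class MarkerRecord:
    locus_id: str
    contig: str
    pos: int
    alleles: tuple[str, str]
    genotypes: dict[str, str]
    quality: float
    assayable: bool
    tri_allelic: bool
    design_score: float            # fraction of design rules passed
    fixed_het: bool = False
    private_to: str | None = None
    plex: int | None = None


def filter_assayable(
    calls: list[SiteCall],
    contig_lengths: dict[str, int],
    window: int = DEFAULT_WINDOW,
    edge: int = DEFAULT_EDGE,
) -> list[MarkerRecord]:
    """Apply the assay-design rules and keep one marker per contig.

    A SNP passes when (a) no other variant (including indels and
    tri-allelic residues) lies within ``window`` bp, (b) it sits at
    least ``edge`` bp from both contig ends, and (c) it is bi-allelic.
    Among per-contig survivors the highest-quality site wins (ties to
    the leftmost). A transparent ``design_score`` (fraction of rules
    passed) is emitted in place of the proprietary designability score.
    """
    by_contig: dict[str, list[SiteCall]] = {}
    for c in calls:
        by_contig.setdefault(c.contig, []).append(c)

    markers: list[MarkerRecord] = []
    for contig in sorted(by_contig):
        sites = sorted(by_contig[contig], key=lambda c: c.pos)
        length = contig_lengths[contig]
        survivors = []
        for i, c in enumerate(sites):
            clean_window = all(
                abs(other.pos - c.pos) > window
                for j, other in enumerate(sites) if j != i
            )
            clear_edges = c.pos >= edge and (length - 1 - c.pos) >= edge
            biallelic = not c.tri_allelic and not c.is_indel
            passed = sum((clean_window, clear_edges, biallelic))
            record = MarkerRecord(
                locus_id=f"{contig}:{c.pos}",
                contig=contig,
                pos=c.pos,
                alleles=(c.ref, c.alt),
                genotypes=dict(c.genotypes),
                quality=c.quality,
                assayable=passed == 3,
                tri_allelic=c.tri_allelic,
                design_score=passed / _N_RULES,
            )
            if record.assayable:
                survivors.append(record)
            markers.append(record)
        if len(survivors) > 1:
            survivors.sort(key=lambda m: (-m.quality, m.pos))
            for m in survivors[1:]:
                m.assayable = False
                m.design_score = 3 / _N_RULES
        for m in markers:
            if m.assayable:
                m.design_score = 1.0
    return [m for m in markers if m.assayable]


def group_multiplexes(markers: list[MarkerRecord],
                      cap: int = DEFAULT_PLEX_CAP) -> int:
    """Assign markers to consecutive multiplexes of at most ``cap`` SNPs,
    in input order; returns the number of plexes."""
    if cap < 1:
        raise ValueError("plex cap must be >= 1")
    for i, m in enumerate(markers):
        m.plex = i // cap + 1
    return (len(markers) + cap - 1) // cap


def flag_fixed_heterozygotes(
    genotype_matrix: dict[str, dict[str, str]],
    min_genotyped: int = 2,
) -> set[str]:
    """Loci where every non-missing genotype is heterozygous.

    ``genotype_matrix`` maps locus -> sample -> genotype label
    (hom_ref / het / hom_alt / missing). At least ``min_genotyped``
    non-missing genotypes are required before a locus is trusted as a
    fixed heterozygote (the co-amplifying-paralog signature).
    """
    flagged = set()
    for locus, genotypes in genotype_matrix.items():
        observed = [g for g in genotypes.values() if g != MISSING]
        if len(observed) >= min_genotyped and all(g == HET for g in observed):
            flagged.add(locus)
    return flagged


def split_duplicated_loci(loci: list[str], flagged: set[str]) -> list[str]:
    """Replace each flagged locus by two monomorphic co-amplified loci
    (suffixes .a/.b); unflagged loci pass through unchanged."""
    unknown = flagged - set(loci)
    if unknown:
        raise ValueError(f"flagged loci not in input: {sorted(unknown)[:3]}")
    out = []
    for locus in loci:
        if locus in flagged:
            out.extend([f"{locus}.a", f"{locus}.b"])
        else:
            out.append(locus)
    return out


def private_alleles(
    genotype_matrix: dict[str, dict[str, str]],
) -> dict[str, int]:
    """Count, per individual, loci where that individual is the only
    heterozygote and every other non-missing genotype is homozygous for
    the major allele."""
    counts: dict[str, int] = {}
    for locus, genotypes in genotype_matrix.items():
        for s in genotypes:
            counts.setdefault(s, 0)
        hets = [s for s, g in genotypes.items() if g == HET]
        others = [g for s, g in genotypes.items()
                  if s not in hets and g != MISSING]
        # private = a single heterozygote, everyone else homozygous for the
        # same (major) allele
        if len(hets) == 1 and others and len(set(others)) == 1 \
                and others[0] in (HOM_REF, HOM_ALT):
            counts[hets[0]] += 1
    return counts
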