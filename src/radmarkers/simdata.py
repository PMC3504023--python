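"""Truth-linked simulation of a low-diversity diploid genome and its reads.

Every input the marker-discovery pipeline consumes can be generated here
with full ground truth: a reference-like genome with planted restriction
sites, microsatellites and duplicated (paralogous) segments; a panel of
diploid individuals with a low-heterozygosity SNP spectrum and
individual-private alleles; barcoded asymmetric paired-end RAD reads;
long single-end shotgun reads; and replicate PCR genotypes with injected
allelic-dropout and false-allele events.

The genome is laid out locus-by-locus: each planted enzyme site is
surrounded by enough unique flanking sequence for both the upstream and
downstream RAD locus (one per cut direction) to be assembled without
interference. Duplicated segments are verbatim copies of a source locus
block differing at exactly one position per direction, which is the
mechanism that produces apparent fixed heterozygosity in a collapsed
assembly. Accidental occurrences of the recognition sequence in the
random background are scrubbed so that the digest of the reference
returns exactly the planted sites.

All randomness flows from ``SimConfig.seed``; identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._util import BASES, phred_char, revcomp
from .digest import CUT_OFFSET, find_sites

__all__ = [
    "SimConfig",
    "TruthSet",
    "RadLocus",
    "VariantSite",
    "ReadPair",
    "ShotgunRead",
    "SizingError",
    "simulate_reference",
    "simulate_rad_library",
    "simulate_shotgun",
    "simulate_replicates",
    "default_barcodes",
    "write_fastq",
]

# Stage tags mixed into the seed stream so that each simulation stage has
# an independent, reproducible RNG.
_STAGE_REFERENCE = 1
_STAGE_RAD = 2
_STAGE_SHOTGUN = 3
_STAGE_REPLICATES = 4

_SPACER = 150          # random bases between locus blocks
_CORE_PAD = 20         # variants kept this far inside the well-covered core
_SSR_GAP = 60          # random bases between planted SSR runs


class SizingError(ValueError):
    """Requested features do not fit in the configured genome length."""


def default_barcodes(n: int, length: int = 5) -> dict[str, str]:
    """Deterministic per-sample in-line barcodes (pairwise distinct)."""
    pool = [
        "AACCG", "ACGTA", "AGTCC", "ATCGT", "CAGAT", "CCTAA", "CGATC", "CTGGA",
        "GACTG", "GCAAC", "GGTAT", "GTCCA", "TAGGC", "TCAGG", "TGACT", "TTGCA",
    ]
    if length != 5 or n > len(pool):
        raise ValueError(f"only {len(pool)} built-in barcodes of length 5")
    return {f"sample{i + 1}": pool[i] for i in range(n)}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the sequencing design being emulated: an EagI
    (CGGCCG) digest, paired-end 40 x 80 bp reads over 300-800 bp inserts,
    shotgun reads of mean length 348 bp, eight barcoded individuals with
    mean observed heterozygosity near 0.057, and four PCR replicates per
    genotype with allelic dropout, false alleles and amplification
    failure at rates 0.2 / 0.01 / 0.1.
    """

    genome_length: int = 250_000
    gc_content: float = 0.41
    enzyme_site: str = "CGGCCG"
    n_individuals: int = 8
    snp_density: float = 8e-4
    target_het: float = 0.057
    n_private_per_individual: int = 3
    n_duplicated_loci: int = 10
    ssr_spec: tuple[tuple[int, int, int], ...] = ((1, 8, 4), (2, 6, 4), (3, 5, 3), (4, 4, 3))
    insert_range: tuple[int, int] = (300, 800)
    read_lengths: tuple[int, int] = (40, 80)
    shotgun_mean_len: int = 348
    shotgun_len_sd: int = 60
    error_rate: float = 0.01
    barcodes: dict[str, str] | None = None
    ado_rate: float = 0.2
    fa_rate: float = 0.01
    fail_rate: float = 0.1
    n_replicates: int = 4
    per_base_depth: float = 12.9
    n_enzyme_sites: int | None = None
    n_indels: int = 0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if self.insert_range[0] < sum(self.read_lengths):
            raise ValueError("insert_range minimum must be >= sum of read lengths")
        for name in ("error_rate", "ado_rate", "fa_rate", "fail_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        bc = self.barcodes
        if bc is not None:
            if len(set(bc.values())) != len(bc):
                raise ValueError("barcodes must be pairwise distinct")
            if len({len(b) for b in bc.values()}) > 1:
                raise ValueError("barcodes must be equal length")

    @property
    def individuals(self) -> list[str]:
        return list(self.barcode_map)

    @property
    def barcode_map(self) -> dict[str, str]:
        if self.barcodes is not None:
            return dict(self.barcodes)
        return default_barcodes(self.n_individuals)

    @property
    def flank(self) -> int:
        """Reference sequence reserved on each side of a cut (locus span)."""
        return self.insert_range[1] + 50

    @property
    def reads_per_tag(self) -> int:
        """Read pairs per tag per individual achieving ``per_base_depth``
        over the reverse-read span (insert_max - insert_min + reverse_len)."""
        imin, imax = self.insert_range
        span = imax - imin + self.read_lengths[1]
        return max(1, round(self.per_base_depth * span / self.read_lengths[1]))


@dataclass(frozen=True)
class RadLocus:
    """One RAD tag direction at one planted cut site.

    ``direction`` +1 reads downstream of the cut on the forward strand;
    -1 reads upstream (represented reverse-complemented so that every
    locus is a forward-oriented sequence starting at the cut).
    """

    id: str
    site_pos: int           # 0-based start of the recognition sequence
    direction: int          # +1 downstream, -1 upstream
    start: int              # reference interval covered by the locus
    end: int
    duplicate_of: str | None = None
    fixed_diff_offset: int | None = None   # oriented offset of the paralog diff

    @property
    def cut(self) -> int:
        return self.site_pos + CUT_OFFSET


@dataclass(frozen=True)
class VariantSite:
    """A planted variant with phased per-individual genotypes.

    ``genotypes`` maps individual -> (hap0 allele, hap1 allele); alleles
    are VCF-style strings (length > 1 or unequal lengths for indels).
    """

    pos: int
    ref: str
    alt: str
    genotypes: dict[str, tuple[str, str]]
    locus_id: str | None = None
    private_to: str | None = None

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def allele_set(self, individual: str) -> frozenset[str]:
        return frozenset(self.genotypes[individual])


@dataclass(frozen=True)
class ReadPair:
    id: str
    sample: str
    forward: str    # barcode + forward (tag) bases
    forward_qual: str
    reverse: str
    reverse_qual: str


@dataclass(frozen=True)
class ShotgunRead:
    id: str
    sample: str
    sequence: str
    qual: str


@dataclass
class TruthSet:
    """Simulated ground truth for all pipeline stages."""

    config: SimConfig
    reference: str
    individuals: list[str]
    site_positions: list[int]
    rad_loci: list[RadLocus]
    variant_sites: list[VariantSite]
    ssr_loci: list[tuple[int, str, int]]            # (start, motif, repeats)
    duplicated_segments: list[tuple[tuple[int, int], tuple[int, int], list[int]]]
    _locus_seq_cache: dict[str, str] = field(default_factory=dict, repr=False)
    _locus_variants: dict[str, list[VariantSite]] = field(default_factory=dict, repr=False)

    def locus_by_id(self, locus_id: str) -> RadLocus:
        return next(l for l in self.rad_loci if l.id == locus_id)

    def locus_sequence(self, locus: RadLocus) -> str:
        """Oriented reference sequence of a locus (cut outward, flank long)."""
        cached = self._locus_seq_cache.get(locus.id)
        if cached is None:
            if locus.direction > 0:
                cached = self.reference[locus.cut : locus.end]
            else:
                cached = revcomp(self.reference[locus.start : locus.cut])
            self._locus_seq_cache[locus.id] = cached
        return cached

    def variants_in_locus(self, locus: RadLocus) -> list[VariantSite]:
        return self._locus_variants.get(locus.id, [])

    def oriented_offset(self, locus: RadLocus, pos: int) -> int:
        """Map a reference coordinate into a locus's oriented coordinate."""
        if locus.direction > 0:
            return pos - locus.cut
        return locus.cut - 1 - pos

    def locus_haplotype(self, locus: RadLocus, individual: str, hap: int) -> str:
        """Oriented locus sequence carrying one haplotype's planted alleles."""
        seq = self.locus_sequence(locus)
        subs = []
        for v in self.variants_in_locus(locus):
            allele = v.genotypes[individual][hap]
            if allele != v.ref:
                off = self.oriented_offset(locus, v.pos)
                base = allele if locus.direction > 0 else revcomp(allele)
                subs.append((off, base))
        if not subs:
            return seq
        chars = list(seq)
        for off, base in subs:
            chars[off] = base
        return "".join(chars)

    def snp_genotype_matrix(self) -> dict[tuple[str, str], tuple[str, str]]:
        """(locus key, individual) -> unphased allele pair for planted SNPs."""
        out = {}
        for v in self.variant_sites:
            if v.is_indel:
                continue
            key = f"{v.pos}"
            for ind, (a, b) in v.genotypes.items():
                out[(key, ind)] = tuple(sorted((a, b)))
        return out


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, stage])


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return "".join(np.array(list(BASES))[idx])


def _aperiodic_motif(rng: np.random.Generator, length: int) -> str:
    """A motif whose smallest period equals its length."""
    while True:
        motif = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
        if all(any(motif[j] != motif[j + p] for j in range(length - p))
               for p in range(1, length)):
            return motif


def _calibrate_het(target: float, n: int) -> float:
    """Per-site heterozygote probability whose *conditional* expectation,
    given that the singleton-heterozygote and all-heterozygote genotype
    patterns are rejected (those patterns are reserved for explicitly
    planted private alleles and duplicated loci), equals ``target``.

    Solved by bisection on the closed-form conditional expectation of the
    per-individual het indicator under independent HWE genotypes.
    """
    if target <= 0:
        return 0.0

    def conditional(hp: float) -> float:
        p = (1 - math.sqrt(1 - 2 * hp)) / 2
        q0 = (1 - p) ** 2
        p_single = n * hp * q0 ** (n - 1)
        p_allhet = hp**n
        accept = 1 - p_single - p_allhet
        if accept <= 0:
            return 0.0
        # E[het_i | accept] = (E[het_i] - E[het_i; single] - E[het_i; all-het])
        #                    / P(accept)
        return (hp - hp * q0 ** (n - 1) - p_allhet) / accept

    lo, hi = 1e-9, 0.499
    if conditional(hi) < target:
        raise ValueError("target_het too large to calibrate")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if conditional(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_reference(config: SimConfig) -> TruthSet:
    """Build the reference genome and the full ground-truth tables.

    Raises :class:`SizingError` when the requested features (locus blocks,
    duplicated segments, SSR tail) cannot be packed into ``genome_length``.
    """
    if config.genome_length < 10 * config.insert_range[1]:
        raise SizingError("genome_length must be >= 10 x insert_range max")
    rng = _rng(config, _STAGE_REFERENCE)
    gc = config.gc_content
    site = config.enzyme_site.upper()
    m = len(site)
    flank = config.flank
    block = 2 * flank + m

    ssr_tail_len = sum(
        (mlen * reps + _SSR_GAP) * copies for mlen, reps, copies in config.ssr_spec
    ) + _SSR_GAP
    n_sites = config.n_enzyme_sites
    dup_cost = config.n_duplicated_loci * (block + _SPACER)
    budget = config.genome_length - ssr_tail_len - dup_cost - _SPACER
    max_sites = budget // (block + _SPACER)
    if n_sites is None:
        n_sites = int(max_sites)
    if n_sites < 1 or n_sites > max_sites:
        raise SizingError(
            f"cannot pack {n_sites or 1} locus blocks plus {config.n_duplicated_loci} "
            f"duplicates and the SSR tail into {config.genome_length} bases"
        )
    if config.n_duplicated_loci > n_sites:
        raise SizingError("more duplicated loci requested than planted sites")

    # --- main locus region ------------------------------------------------
    parts: list[str] = []
    pos = 0
    site_positions: list[int] = []
    for _ in range(n_sites):
        parts.append(_random_bases(rng, _SPACER + flank, gc))
        pos += _SPACER + flank
        site_positions.append(pos)
        parts.append(site)
        pos += m
        parts.append(_random_bases(rng, flank, gc))
        pos += flank

    # --- SSR tail ---------------------------------------------------------
    ssr_loci: list[tuple[int, str, int]] = []
    tail_parts: list[str] = []
    tail_pos = pos
    for mlen, reps, copies in config.ssr_spec:
        for _ in range(copies):
            gap = _random_bases(rng, _SSR_GAP, gc)
            motif = _aperiodic_motif(rng, mlen)
            run = motif * reps
            # guard bases so the planted run is maximal exactly as planted
            left_guard = next(b for b in BASES if b != motif[-1])
            right_guard = next(b for b in BASES if b != motif[0])
            chunk = gap[:-1] + left_guard + run + right_guard
            ssr_loci.append((tail_pos + len(gap), motif, reps))
            tail_parts.append(chunk)
            tail_pos += len(chunk)
    tail_parts.append(_random_bases(rng, _SSR_GAP, gc))
    parts.extend(tail_parts)
    genome = "".join(parts)

    # --- scrub accidental recognition sites (phase 1) ---------------------
    protected: set[int] = set()
    for s in site_positions:
        protected.update(range(s, s + m))
    for start, motif, reps in ssr_loci:
        protected.update(range(start - 1, start + len(motif) * reps + 1))
    genome = _scrub(genome, site, set(site_positions), protected, rng)

    # --- duplicated segments ----------------------------------------------
    rad_loci: list[RadLocus] = []
    loci_by_site: dict[int, list[RadLocus]] = {}
    for i, s in enumerate(site_positions):
        cut = s + CUT_OFFSET
        down = RadLocus(id=f"L{i + 1:04d}d", site_pos=s, direction=+1,
                        start=cut, end=cut + flank)
        up = RadLocus(id=f"L{i + 1:04d}u", site_pos=s, direction=-1,
                      start=cut - flank, end=cut)
        rad_loci.extend([down, up])
        loci_by_site[s] = [down, up]

    duplicated: list[tuple[tuple[int, int], tuple[int, int], list[int]]] = []
    dup_source_sites = list(
        rng.choice(np.array(site_positions), size=config.n_duplicated_loci, replace=False)
    ) if config.n_duplicated_loci else []
    imin, imax = config.insert_range
    rlen = config.read_lengths[1]
    core_lo, core_hi = imin + _CORE_PAD, imax - rlen - _CORE_PAD
    genome_list = [genome]
    dup_pos = len(genome)
    copy_spans: list[tuple[int, int]] = []
    for j, src_site in enumerate(sorted(int(s) for s in dup_source_sites)):
        src_cut = src_site + CUT_OFFSET
        block_seq = genome[src_site - flank : src_site + m + flank]
        copy_start = dup_pos + _SPACER
        copy_site = copy_start + flank
        copy_cut = copy_site + CUT_OFFSET
        # one fixed difference per direction, inside the well-covered core
        diffs: list[int] = []
        chars = list(block_seq)
        for direction in (+1, -1):
            off = int(rng.integers(core_lo, core_hi))
            rel = (flank + CUT_OFFSET + off) if direction > 0 else (flank + CUT_OFFSET - 1 - off)
            old = chars[rel]
            chars[rel] = "T" if old != "T" else "A"
            diffs.append(copy_start + rel)
            src_locus = loci_by_site[src_site][0 if direction > 0 else 1]
            copy_id = f"{src_locus.id}.copy"
            rad_loci.append(RadLocus(
                id=copy_id, site_pos=copy_site, direction=direction,
                start=copy_cut if direction > 0 else copy_cut - flank,
                end=copy_cut + flank if direction > 0 else copy_cut,
                duplicate_of=src_locus.id, fixed_diff_offset=off,
            ))
        genome_list.append(_random_bases(rng, _SPACER, gc))
        genome_list.append("".join(chars))
        duplicated.append(((src_site - flank, src_site + m + flank),
                           (copy_start, copy_start + len(block_seq)), diffs))
        copy_spans.append((copy_start, copy_start + len(block_seq)))
        dup_pos = copy_start + len(block_seq)
    if dup_pos < config.genome_length:
        genome_list.append(_random_bases(rng, config.genome_length - dup_pos, gc))
    genome = "".join(genome_list)

    # phase-2 scrub: only copy-junction artifacts are possible; protect the
    # copy interiors (they must stay identical to their sources + diffs)
    protected2 = set(protected)
    for a, b in copy_spans:
        protected2.update(range(a, b))
    genome = _scrub(genome, site, {l.site_pos for l in rad_loci}, protected2, rng)

    # --- variants ----------------------------------------------------------
    dup_ids = {l.duplicate_of for l in rad_loci if l.duplicate_of} | {
        l.id for l in rad_loci if l.duplicate_of
    }
    eligible = [l for l in rad_loci if l.id not in dup_ids]
    individuals = config.individuals
    h = config.target_het
    if h > 0.5:
        raise ValueError("target_het must be <= 0.5 under the bi-allelic model")
    h_eff = _calibrate_het(h, len(individuals))
    p_alt = (1 - math.sqrt(1 - 2 * h_eff)) / 2
    gt_probs = np.array([(1 - p_alt) ** 2, h_eff, p_alt**2])
    gt_probs = gt_probs / gt_probs.sum()

    n_variants = int(round(config.snp_density * config.genome_length))
    n_private = config.n_private_per_individual * len(individuals)
    core_positions: list[tuple[str, int]] = []
    for locus in eligible:
        for off in range(core_lo, core_hi):
            core_positions.append((locus.id, off))
    if n_variants + n_private + config.n_indels > len(core_positions) // 8:
        raise SizingError("variant load too dense for the available locus cores")
    order = rng.permutation(len(core_positions))
    picked = iter(order)
    locus_map = {l.id: l for l in rad_loci}

    def next_position() -> tuple[RadLocus, int, int]:
        for k in picked:
            lid, off = core_positions[k]
            locus = locus_map[lid]
            pos_ = locus.cut + off if locus.direction > 0 else locus.cut - 1 - off
            if pos_ not in used_positions:
                # keep indel anchors clear of each other
                if all(abs(pos_ - q) > 6 for q in used_positions):
                    return locus, off, pos_
        raise SizingError("ran out of core positions for variants")

    used_positions: set[int] = set()
    variants: list[VariantSite] = []

    for _ in range(n_variants):
        locus, off, pos_ = next_position()
        used_positions.add(pos_)
        ref_base = genome[pos_]
        alt_base = BASES[(BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
        while True:
            codes = rng.choice(3, size=len(individuals), p=gt_probs)
            n_het = int(np.sum(codes == 1))
            # the singleton-heterozygote (private) pattern and the all-het
            # pattern are reserved for explicitly planted features
            if n_het == 1 and np.all(codes[codes != 1] == 0):
                continue
            if n_het == len(individuals):
                continue
            break
        genotypes = {}
        for ind, code in zip(individuals, codes):
            if code == 0:
                genotypes[ind] = (ref_base, ref_base)
            elif code == 2:
                genotypes[ind] = (alt_base, alt_base)
            else:
                phase = int(rng.integers(0, 2))
                pair = [ref_base, ref_base]
                pair[phase] = alt_base
                genotypes[ind] = tuple(pair)
        variants.append(VariantSite(pos=pos_, ref=ref_base, alt=alt_base,
                                    genotypes=genotypes, locus_id=locus.id))

    for ind in individuals:
        for _ in range(config.n_private_per_individual):
            locus, off, pos_ = next_position()
            used_positions.add(pos_)
            ref_base = genome[pos_]
            alt_base = BASES[(BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
            genotypes = {other: (ref_base, ref_base) for other in individuals}
            phase = int(rng.integers(0, 2))
            pair = [ref_base, ref_base]
            pair[phase] = alt_base
            genotypes[ind] = tuple(pair)
            variants.append(VariantSite(pos=pos_, ref=ref_base, alt=alt_base,
                                        genotypes=genotypes, locus_id=locus.id,
                                        private_to=ind))

    for _ in range(config.n_indels):
        locus, off, pos_ = next_position()
        used_positions.add(pos_)
        if rng.random() < 0.5:  # deletion of 1-3 bases
            dlen = int(rng.integers(1, 4))
            ref_a = genome[pos_ : pos_ + 1 + dlen]
            alt_a = genome[pos_]
        else:                   # insertion of 1-3 bases
            ins = "".join(BASES[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 4))))
            ref_a = genome[pos_]
            alt_a = genome[pos_] + ins
        genotypes = {}
        for ind in individuals:
            code = int(rng.choice(3, p=gt_probs))
            if code == 0:
                genotypes[ind] = (ref_a, ref_a)
            elif code == 2:
                genotypes[ind] = (alt_a, alt_a)
            else:
                phase = int(rng.integers(0, 2))
                pair = [ref_a, ref_a]
                pair[phase] = alt_a
                genotypes[ind] = tuple(pair)
        variants.append(VariantSite(pos=pos_, ref=ref_a, alt=alt_a,
                                    genotypes=genotypes, locus_id=locus.id))

    variants.sort(key=lambda v: v.pos)
    truth = TruthSet(
        config=config,
        reference=genome,
        individuals=individuals,
        site_positions=sorted(l.site_pos for l in rad_loci if l.direction > 0),
        rad_loci=rad_loci,
        variant_sites=variants,
        ssr_loci=ssr_loci,
        duplicated_segments=duplicated,
    )
    by_locus: dict[str, list[VariantSite]] = {}
    for v in variants:
        if v.locus_id:
            by_locus.setdefault(v.locus_id, []).append(v)
    truth._locus_variants = by_locus
    return truth


def _scrub(genome: str, site: str, planted: set[int], protected: set[int],
           rng: np.random.Generator) -> str:
    """Break every non-planted occurrence of ``site`` by flipping one
    unprotected base to A/T (the recognition sequence is all-GC, so A/T
    substitutions can never create a new occurrence)."""
    chars = None
    for _ in range(4):
        hits = [h for h in find_sites(genome if chars is None else "".join(chars), site)
                if h not in planted]
        if not hits:
            break
        if chars is None:
            chars = list(genome)
        for hit in hits:
            for k in range(len(site)):
                if hit + k not in protected:
                    chars[hit + k] = "A" if rng.random() < 0.5 else "T"
                    break
    return genome if chars is None else "".join(chars)


# --------------------------------------------------------------------------
# RAD library
# --------------------------------------------------------------------------

def simulate_rad_library(
    truth: TruthSet,
    config: SimConfig | None = None,
    reads_per_tag: int | None = None,
) -> tuple[list[ReadPair], list[dict]]:
    """Barcoded asymmetric paired-end RAD reads plus the truth manifest.

    Every pair originates at a planted cut on one haplotype of one
    individual: the forward read is the sample barcode followed by the
    tag bases adjacent to the cut; the reverse read comes from the
    randomly sheared end of an insert drawn uniformly from
    ``insert_range``. Fixed-count mode: exactly ``reads_per_tag`` pairs
    per (locus, individual).
    """
    config = config or truth.config
    if not truth.rad_loci:
        warnings.warn("truth set has no enzyme sites; empty RAD library")
        return [], []
    rng = _rng(config, _STAGE_RAD)
    c = reads_per_tag if reads_per_tag is not None else config.reads_per_tag
    flen, rlen = config.read_lengths
    imin, imax = config.insert_range
    barcode_map = config.barcode_map
    e = config.error_rate
    q30 = phred_char(30)
    q10 = phred_char(10)

    pairs: list[ReadPair] = []
    manifest: list[dict] = []
    serial = 0
    for locus in truth.rad_loci:
        for ind in truth.individuals:
            barcode = barcode_map[ind]
            inserts = rng.integers(imin, imax + 1, size=c)
            haps = rng.integers(0, 2, size=c)
            for insert, hap in zip(inserts, haps):
                hap_seq = truth.locus_haplotype(locus, ind, int(hap))
                fwd = hap_seq[:flen]
                rev = hap_seq[insert - rlen : insert]
                fq = q30 * flen
                rq = q30 * rlen
                if e > 0:
                    fwd, fq = _inject_errors(fwd, fq, e, rng, q10)
                    rev, rq = _inject_errors(rev, rq, e, rng, q10)
                rid = f"rad|{ind}|{locus.id}|{serial}"
                serial += 1
                pairs.append(ReadPair(rid, ind, barcode + fwd, q30 * len(barcode) + fq,
                                      rev, rq))
                manifest.append({
                    "read_id": rid, "sample": ind, "haplotype": int(hap),
                    "locus_id": locus.id, "site_pos": locus.site_pos,
                    "direction": locus.direction, "insert": int(insert),
                })
    return pairs, manifest


def _inject_errors(seq: str, qual: str, rate: float, rng: np.random.Generator,
                   err_q: str) -> tuple[str, str]:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq, qual
    positions = rng.choice(len(seq), size=n_err, replace=False)
    s, q = list(seq), list(qual)
    for p in positions:
        s[p] = BASES[(BASES.index(s[p]) + int(rng.integers(1, 4))) % 4]
        q[p] = err_q
    return "".join(s), "".join(q)


# --------------------------------------------------------------------------
# Shotgun library
# --------------------------------------------------------------------------

def _haplotype_sequence(truth: TruthSet, individual: str, hap: int) -> str:
    """Materialize one haplotype (substitutions and indels applied)."""
    edits = []
    for v in truth.variant_sites:
        allele = v.genotypes[individual][hap]
        if allele != v.ref:
            edits.append((v.pos, v.ref, allele))
    if not edits:
        return truth.reference
    chars = list(truth.reference)
    for pos, ref_a, alt_a in sorted(edits, reverse=True):
        chars[pos : pos + len(ref_a)] = list(alt_a)
    return "".join(chars)


def simulate_shotgun(
    truth: TruthSet,
    config: SimConfig | None = None,
    n_reads: int = 0,
    individuals: list[str] | None = None,
) -> tuple[list[ShotgunRead], list[dict]]:
    """Long single-end shotgun reads with lengths from a truncated normal
    distribution (mean ``shotgun_mean_len``, sd ``shotgun_len_sd``,
    truncated to [100, 800])."""
    config = config or truth.config
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if n_reads == 0:
        return [], []
    rng = _rng(config, _STAGE_SHOTGUN)
    inds = individuals if individuals is not None else truth.individuals[:2]
    haplotypes = {(ind, h): _haplotype_sequence(truth, ind, h)
                  for ind in inds for h in (0, 1)}
    e = config.error_rate
    q30 = phred_char(30)
    q10 = phred_char(10)

    reads: list[ShotgunRead] = []
    manifest: list[dict] = []
    lengths = rng.normal(config.shotgun_mean_len, config.shotgun_len_sd, size=n_reads)
    lengths = np.clip(np.rint(lengths), 100, 800).astype(int)
    which = rng.integers(0, len(inds), size=n_reads)
    hap_pick = rng.integers(0, 2, size=n_reads)
    for i in range(n_reads):
        ind = inds[which[i]]
        hap = int(hap_pick[i])
        src = haplotypes[(ind, hap)]
        length = int(min(lengths[i], len(src)))
        start = int(rng.integers(0, len(src) - length + 1))
        seq = src[start : start + length]
        qual = q30 * length
        if e > 0:
            seq, qual = _inject_errors(seq, qual, e, rng, q10)
        rid = f"shot|{ind}|{i}"
        reads.append(ShotgunRead(rid, ind, seq, qual))
        manifest.append({"read_id": rid, "sample": ind, "haplotype": hap,
                         "start": start, "length": length})
    return reads, manifest


# --------------------------------------------------------------------------
# Replicate PCR genotypes
# --------------------------------------------------------------------------

def simulate_replicates(
    genotypes: dict[tuple[str, str], tuple[str, str]],
    config: SimConfig,
) -> tuple[dict[tuple[str, str], list[tuple[str, str] | None]], list[dict]]:
    """Replicate PCR observations of true genotypes with injected errors.

    Each replicate independently fails (missing) with ``fail_rate``;
    a heterozygous truth drops one allele with ``ado_rate``; any
    observation that is homozygous after the dropout step gains a
    spurious allele with ``fa_rate``. Returns the observation table keyed
    by (sample, locus) plus an event log.
    """
    rng = _rng(config, _STAGE_REPLICATES)
    n_rep = config.n_replicates
    table: dict[tuple[str, str], list[tuple[str, str] | None]] = {}
    events: list[dict] = []
    for key in sorted(genotypes):
        a, b = genotypes[key]
        obs: list[tuple[str, str] | None] = []
        for rep in range(n_rep):
            if rng.random() < config.fail_rate:
                obs.append(None)
                events.append({"sample": key[0], "locus": key[1], "rep": rep,
                               "event": "fail"})
                continue
            alleles = [a, b]
            if a != b and rng.random() < config.ado_rate:
                kept = alleles[int(rng.integers(0, 2))]
                alleles = [kept, kept]
                events.append({"sample": key[0], "locus": key[1], "rep": rep,
                               "event": "ado"})
            if alleles[0] == alleles[1] and rng.random() < config.fa_rate:
                choices = [x for x in BASES if x != alleles[0]]
                spurious = choices[int(rng.integers(0, len(choices)))]
                alleles = [alleles[0], spurious]
                events.append({"sample": key[0], "locus": key[1], "rep": rep,
                               "event": "fa"})
            obs.append(tuple(sorted(alleles)))
        table[key] = obs
    return table, events


# --------------------------------------------------------------------------
# FASTQ serialization
# --------------------------------------------------------------------------

def write_fastq(records, path) -> int:
    """Write (id, sequence, quality) records as 4-line Phred+33 FASTQ."""
    n = 0
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def rad_fastq_records(pairs: list[ReadPair], which: str):
    for p in pairs:
        if which == "forward":
            yield p.id + "/1", p.forward, p.forward_qual
        else:
            yield p.id + "/2", p.reverse, p.reverse_qual
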