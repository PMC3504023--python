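"""Read mapping, pileups, and genotype calling.

Two calling paths mirror the two sequencing designs:

* RAD path: 80 bp reverse reads are placed on the mini-reference contigs
  by exact 20-mer seeding and ungapped full-length extension (<= 4
  mismatches, unique best hit required). Genotypes come from a simple
  allele-frequency threshold model: with alternate-allele fraction f,
  f < t calls the homozygous reference, f > 1 - t the homozygous
  alternate, anything in between (boundaries included) a heterozygote;
  the default t = 0.075.

* shotgun path: long reads are seeded the same way and extended with a
  banded edit-distance alignment (edlib) that permits gaps, so small
  indels are observed and recorded against their left-anchoring base.
  Candidate sites are gated on a Phred-scaled surrogate quality
  Q = min(60, -10 log10 P(X >= alt_count)), X ~ Binomial(depth, e):
  substitutions need Q >= 20, indels Q >= 50.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

import edlib

SEED_LENGTH = 20
RAD_MAX_MISMATCHES = 4
DEFAULT_THRESHOLD = 0.075
DEFAULT_MIN_DEPTH = 5
DEFAULT_ERROR_RATE = 0.01
MAX_QUAL = 60.0

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"


@dataclass(slots=True)
class Alignment:
    read_id: str
    sample: str
    contig: str
    start: int
    end: int                                  # half-open contig interval
    subs: list = field(default_factory=list)  # (contig_pos, read_base)
    ins: list = field(default_factory=list)   # (anchor_pos, inserted_seq)
    dels: list = field(default_factory=list)  # (anchor_pos, length)


@dataclass
class MappingResult:
    alignments: list[Alignment]
    n_unmapped: int
    n_ambiguous: int


@dataclass
class SiteCall:
    """A called variant site on one contig position (0-based)."""

    contig: str
    pos: int
    ref: str
    alt: str
    genotypes: dict[str, str]
    counts: dict[str, tuple[int, int]]
    quality: float
    is_indel: bool = False
    tri_allelic: bool = False


def _seed_index(contigs: dict[str, str], seed: int = SEED_LENGTH) -> dict[str, list]:
    index: dict[str, list] = defaultdict(list)
    for cid in sorted(contigs):
        seq = contigs[cid]
        for i in range(len(seq) - seed + 1):
            index[seq[i : i + seed]].append((cid, i))
    return index


def map_reads(
    reads: list[tuple[str, str, str]],
    contigs: dict[str, str],
    mode: str = "rad",
    max_mismatches: int = RAD_MAX_MISMATCHES,
    seed: int = SEED_LENGTH,
    band: int = 10,
) -> MappingResult:
    """Place reads (``(read_id, sample, sequence)`` tuples) on contigs.

    rad mode: ungapped, full containment, unique best hit or unmapped.
    shotgun mode: best banded semi-global (infix) alignment with gaps.
    """
    index = _seed_index(contigs, seed)
    alignments: list[Alignment] = []
    unmapped = ambiguous = 0
    for read_id, sample, seq in reads:
        if mode == "rad":
            aln, flag = _map_rad(read_id, sample, seq, contigs, index, seed, max_mismatches)
        else:
            aln, flag = _map_shotgun(read_id, sample, seq, contigs, index, seed, band)
        if aln is not None:
            alignments.append(aln)
        elif flag == "ambiguous":
            ambiguous += 1
        else:
            unmapped += 1
    return MappingResult(alignments, unmapped, ambiguous)


def _map_rad(read_id, sample, seq, contigs, index, seed, max_mm):
    L = len(seq)
    candidates = set()
    for off in range(0, max(1, L - seed + 1), seed):
        for cid, pos in index.get(seq[off : off + seed], ()):
            start = pos - off
            if start >= 0 and start + L <= len(contigs[cid]):
                candidates.add((cid, start))
    best = None
    best_mm = max_mm + 1
    ties = 0
    for cid, start in sorted(candidates):
        ref = contigs[cid][start : start + L]
        if ref == seq:
            mm = 0
        else:
            mm = 0
            for a, b in zip(ref, seq):
                if a != b:
                    mm += 1
                    if mm > max_mm:
                        break
        if mm < best_mm:
            best, best_mm, ties = (cid, start), mm, 1
        elif mm == best_mm and mm <= max_mm:
            ties += 1
    if best is None or best_mm > max_mm:
        return None, "unmapped"
    if ties > 1:
        return None, "ambiguous"
    cid, start = best
    subs = []
    if best_mm:
        ref = contigs[cid][start : start + L]
        subs = [(start + i, seq[i]) for i in range(L) if ref[i] != seq[i]]
    return Alignment(read_id, sample, cid, start, start + L, subs=subs), "mapped"


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _map_shotgun(read_id, sample, seq, contigs, index, seed, band):
    L = len(seq)
    cids = set()
    for off in range(0, max(1, L - seed + 1), seed):
        for cid, pos in index.get(seq[off : off + seed], ()):
            cids.add(cid)
    best = None  # (distance, cid, result)
    for cid in sorted(cids):
        res = edlib.align(seq, contigs[cid], mode="HW", task="path",
                          k=max(band, L // 10))
        if res["editDistance"] < 0:
            continue
        if best is None or res["editDistance"] < best[0]:
            best = (res["editDistance"], cid, res)
    if best is None:
        return None, "unmapped"
    _, cid, res = best
    tstart = res["locations"][0][0]
    aln = Alignment(read_id, sample, cid, tstart, tstart)
    tpos, qpos = tstart, 0
    ref = contigs[cid]
    for num, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(num)
        if op in "=M":
            if op == "M":  # resolve matches/mismatches explicitly
                for i in range(n):
                    if ref[tpos + i] != seq[qpos + i]:
                        aln.subs.append((tpos + i, seq[qpos + i]))
            tpos += n
            qpos += n
        elif op == "X":
            for i in range(n):
                aln.subs.append((tpos + i, seq[qpos + i]))
            tpos += n
            qpos += n
        elif op == "I":      # bases present in the read, absent from contig
            aln.ins.append((tpos - 1, seq[qpos : qpos + n]))
            qpos += n
        elif op == "D":      # contig bases deleted in the read
            aln.dels.append((tpos - 1, n))
            tpos += n
    aln.end = tpos
    return aln, "mapped"


# --------------------------------------------------------------------------
# Pileups
# --------------------------------------------------------------------------

class Pileup:
    """Per-contig, per-sample base counts in compressed form.

    Stores full-depth coverage as difference arrays plus sparse
    dictionaries of non-reference observations, so per-position allele
    counts are recovered as depth minus recorded alternates.
    """

    def __init__(self, contigs: dict[str, str], samples: list[str]):
        self.contigs = contigs
        self.samples = list(samples)
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}
        self._diff = {
            cid: np.zeros((len(self.samples), len(seq) + 1), dtype=np.int32)
            for cid, seq in contigs.items()
        }
        self._depth: dict[str, np.ndarray] | None = None
        # contig -> pos -> sample -> Counter(base/event -> count)
        self.subs: dict[str, dict[int, dict[str, Counter]]] = defaultdict(dict)
        self.ins: dict[str, dict[int, dict[str, Counter]]] = defaultdict(dict)
        self.dels: dict[str, dict[int, dict[str, Counter]]] = defaultdict(dict)

    def add(self, aln: Alignment) -> None:
        d = self._diff[aln.contig]
        si = self._sample_idx[aln.sample]
        d[si, aln.start] += 1
        d[si, aln.end] -= 1
        self._depth = None
        for pos, base in aln.subs:
            self._bump(self.subs, aln.contig, pos, aln.sample, base)
        for pos, seqi in aln.ins:
            self._bump(self.ins, aln.contig, pos, aln.sample, seqi)
        for pos, n in aln.dels:
            self._bump(self.dels, aln.contig, pos, aln.sample, str(n))

    @staticmethod
    def _bump(store, contig, pos, sample, key):
        store[contig].setdefault(pos, {}).setdefault(sample, Counter())[key] += 1

    def depth(self, contig: str, pos: int, sample: str) -> int:
        if self._depth is None:
            self._depth = {cid: np.cumsum(d[:, :-1], axis=1)
                           for cid, d in self._diff.items()}
        return int(self._depth[contig][self._sample_idx[sample], pos])

    def base_counts(self, contig: str, pos: int, sample: str) -> Counter:
        """Counter of observed bases at one position for one sample."""
        total = self.depth(contig, pos, sample)
        counts = Counter()
        alt = self.subs.get(contig, {}).get(pos, {}).get(sample)
        n_alt = 0
        if alt:
            counts.update(alt)
            n_alt = sum(alt.values())
        # reads with a deletion spanning this position contribute no base
        n_del = 0
        for anchor, per_sample in self.dels.get(contig, {}).items():
            c = per_sample.get(sample)
            if c:
                for length_s, cnt in c.items():
                    if anchor < pos <= anchor + int(length_s):
                        n_del += cnt
        ref_base = self.contigs[contig][pos]
        counts[ref_base] += max(0, total - n_alt - n_del)
        return counts

    def candidate_positions(self, contig: str) -> list[int]:
        pos = set(self.subs.get(contig, {}).keys())
        pos |= set(self.ins.get(contig, {}).keys())
        pos |= set(self.dels.get(contig, {}).keys())
        return sorted(pos)


def pileup(alignments: list[Alignment], contigs: dict[str, str],
           samples: list[str]) -> Pileup:
    """Accumulate alignments into a :class:`Pileup`."""
    p = Pileup(contigs, samples)
    for aln in alignments:
        p.add(aln)
    return p


# --------------------------------------------------------------------------
# Genotype calling
# --------------------------------------------------------------------------

def call_genotype_threshold(
    ref_count: int,
    alt_count: int,
    t: float = DEFAULT_THRESHOLD,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> str:
    """Threshold-model genotype from allele counts.

    f = alt / (ref + alt); sites below ``min_depth`` total reads are
    missing; f < t is homozygous reference, f > 1 - t homozygous
    alternate, otherwise heterozygous (a fraction exactly equal to the
    threshold counts as alternate evidence and calls het).
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("allele counts must be >= 0")
    depth = ref_count + alt_count
    if depth < min_depth:
        return MISSING
    f = alt_count / depth
    if f < t:
        return HOM_REF
    if f > 1 - t:
        return HOM_ALT
    return HET


def site_quality(ref_count: int, alt_count: int,
                 error_rate: float = DEFAULT_ERROR_RATE) -> float:
    """Phred-scaled surrogate site quality: the binomial tail probability
    of seeing >= alt_count error reads at depth ref+alt."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("allele counts must be >= 0")
    if alt_count == 0:
        return 0.0
    depth = ref_count + alt_count
    tail = float(binom.sf(alt_count - 1, depth, error_rate))
    if tail <= 0.0:
        return MAX_QUAL
    return min(MAX_QUAL, -10.0 * np.log10(tail))


def _call_substitution_sites(pile: Pileup, t: float, min_depth: int,
                             error_rate: float) -> list[SiteCall]:
    calls = []
    for contig in sorted(pile.contigs):
        for pos in pile.candidate_positions(contig):
            if pos not in pile.subs.get(contig, {}):
                continue
            ref_base = pile.contigs[contig][pos]
            pooled = Counter()
            per_sample = {}
            for sample in pile.samples:
                counts = pile.base_counts(contig, pos, sample)
                per_sample[sample] = counts
                pooled.update(counts)
            alts = [(n, b) for b, n in pooled.items() if b != ref_base and n > 0]
            if not alts:
                continue
            alts.sort(key=lambda x: (-x[0], x[1]))
            alt_base = alts[0][1]
            pooled_depth = sum(pooled.values())
            tri = len(alts) > 1 and alts[1][0] >= max(2, t * pooled_depth)
            genotypes = {}
            counts_out = {}
            variable = False
            for sample in pile.samples:
                rc = per_sample[sample][ref_base]
                ac = per_sample[sample][alt_base]
                gt = call_genotype_threshold(rc, ac, t=t, min_depth=min_depth)
                genotypes[sample] = gt
                counts_out[sample] = (rc, ac)
                if gt in (HET, HOM_ALT):
                    variable = True
            if not variable:
                continue
            q = site_quality(pooled[ref_base], pooled[alt_base], error_rate)
            calls.append(SiteCall(contig, pos, ref_base, alt_base, genotypes,
                                  counts_out, q, is_indel=False, tri_allelic=tri))
    return calls


def call_sites_rad(pile: Pileup, t: float = DEFAULT_THRESHOLD,
                   min_depth: int = DEFAULT_MIN_DEPTH,
                   error_rate: float = DEFAULT_ERROR_RATE) -> list[SiteCall]:
    """Threshold-model substitution calls for the RAD path (count-based;
    no indels, mirroring the ungapped mapper)."""
    return _call_substitution_sites(pile, t, min_depth, error_rate)


def call_sites_shotgun(
    pile: Pileup,
    snp_q_min: float = 20.0,
    indel_q_min: float = 50.0,
    t: float = DEFAULT_THRESHOLD,
    min_depth: int = DEFAULT_MIN_DEPTH,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> list[SiteCall]:
    """Quality-gated shotgun calls: substitutions require surrogate
    quality >= ``snp_q_min``, indel events >= ``indel_q_min``; only
    variable sites are reported."""
    calls = [c for c in _call_substitution_sites(pile, t, min_depth, error_rate)
             if c.quality >= snp_q_min]
    for contig in sorted(pile.contigs):
        events: dict[int, list[tuple[str, str]]] = defaultdict(list)
        for pos, per_sample in pile.ins.get(contig, {}).items():
            for sample, counter in per_sample.items():
                for seq, n in counter.items():
                    events[pos].append(("ins", seq))
        for pos, per_sample in pile.dels.get(contig, {}).items():
            for sample, counter in per_sample.items():
                for length_s, n in counter.items():
                    events[pos].append(("del", length_s))
        for pos in sorted(events):
            kinds = Counter(events[pos])
            (kind, payload), _ = kinds.most_common(1)[0]
            genotypes = {}
            counts_out = {}
            pooled_ref = pooled_alt = 0
            variable = False
            for sample in pile.samples:
                depth = pile.depth(contig, pos, sample)
                store = pile.ins if kind == "ins" else pile.dels
                ac = store.get(contig, {}).get(pos, {}).get(sample, Counter()).get(payload, 0)
                rc = max(0, depth - ac)
                gt = call_genotype_threshold(rc, ac, t=t, min_depth=min_depth)
                genotypes[sample] = gt
                counts_out[sample] = (rc, ac)
                pooled_ref += rc
                pooled_alt += ac
                if gt in (HET, HOM_ALT):
                    variable = True
            if not variable:
                continue
            q = site_quality(pooled_ref, pooled_alt, error_rate)
            if q < indel_q_min:
                continue
            ref_base = pile.contigs[contig][pos]
            if kind == "ins":
                ref_a, alt_a = ref_base, ref_base + payload
            else:
                dlen = int(payload)
                ref_a = pile.contigs[contig][pos : pos + 1 + dlen]
                alt_a = ref_base
            calls.append(SiteCall(contig, pos, ref_a, alt_a, genotypes,
                                  counts_out, q, is_indel=True))
    calls.sort(key=lambda c: (c.contig, c.pos))
    return calls


@dataclass
class VariantSummary:
    n_sites: int
    n_het_sites: int          # >= 1 sample heterozygous
    n_hom_sites: int
    substitution_classes: dict[str, int]   # unordered pair, e.g. "A-G"

    @property
    def het_fraction(self) -> float:
        return self.n_het_sites / self.n_sites if self.n_sites else 0.0


def summarize_variants(calls: list[SiteCall]) -> VariantSummary:
    """Tabulate het/hom site counts and substitution classes.

    A site counts as heterozygous when at least one sample is het;
    substitutions are classed by unordered base pair (A-G, C-T, A-C,
    G-T, A-T, C-G).
    """
    if not calls:
        raise ValueError("summarize_variants requires >= 1 call")
    n_het = 0
    classes: Counter = Counter()
    for c in calls:
        if any(g == HET for g in c.genotypes.values()):
            n_het += 1
        if not c.is_indel and len(c.ref) == 1 and len(c.alt) == 1:
            classes["-".join(sorted((c.ref, c.alt)))] += 1
    return VariantSummary(
        n_sites=len(calls),
        n_het_sites=n_het,
        n_hom_sites=len(calls) - n_het,
        substitution_classes=dict(classes),
    )
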