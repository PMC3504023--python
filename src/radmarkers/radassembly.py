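"""Per-sample RAD locus assembly.

Reads are demultiplexed by their in-line barcode, clustered by *unitag*
(the unique single-end sequence adjacent to a cut site), and each
cluster's paired reverse reads are locally assembled with a minimal
single-k de Bruijn assembler. Clusters outside the 5x-500x coverage
window and contigs with outlying mean depth (repetitive regions) are
discarded; the best-assembling sample becomes the "mini-reference" that
all samples' reads are later mapped against.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .simdata import ReadPair

DEFAULT_MIN_COV = 5
DEFAULT_MAX_COV = 500
DEFAULT_MIN_CONTIG = 150
DEFAULT_K = 31


@dataclass
class UnitagCluster:
    """All read pairs sharing one exact forward-read sequence."""

    unitag: str
    depth: int
    read_ids: list[str]
    reverse_reads: list[str]


@dataclass
class LocusContig:
    id: str
    sample: str
    sequence: str
    mean_depth: float
    source_unitag: str
    is_locus_contig: bool = True

    @property
    def length(self) -> int:
        return len(self.sequence)


def demultiplex(
    pairs: list[ReadPair], barcode_map: dict[str, str]
) -> tuple[dict[str, list[ReadPair]], int]:
    """Assign read pairs to samples by exact match of the forward-read
    prefix against the barcode map; the barcode is stripped before any
    downstream use. Returns per-sample pairs and the rejected count."""
    if len(set(barcode_map.values())) != len(barcode_map):
        raise ValueError("duplicate barcodes in map")
    lengths = {len(b) for b in barcode_map.values()}
    if len(lengths) != 1:
        raise ValueError("barcodes must be equal length")
    blen = lengths.pop()
    lookup = {b: s for s, b in barcode_map.items()}
    out: dict[str, list[ReadPair]] = {s: [] for s in barcode_map}
    rejected = 0
    for p in pairs:
        sample = lookup.get(p.forward[:blen])
        if sample is None:
            rejected += 1
            continue
        out[sample].append(ReadPair(
            id=p.id, sample=sample,
            forward=p.forward[blen:], forward_qual=p.forward_qual[blen:],
            reverse=p.reverse, reverse_qual=p.reverse_qual,
        ))
    return out, rejected


def build_unitags(
    pairs: list[ReadPair],
    min_cov: int = DEFAULT_MIN_COV,
    max_cov: int = DEFAULT_MAX_COV,
) -> list[UnitagCluster]:
    """Cluster pairs by identical (barcode-stripped) forward read and drop
    clusters whose depth falls outside [min_cov, max_cov]."""
    groups: dict[str, list[ReadPair]] = defaultdict(list)
    for p in pairs:
        groups[p.forward].append(p)
    clusters = []
    for unitag in sorted(groups):
        members = groups[unitag]
        if not (min_cov <= len(members) <= max_cov):
            continue
        clusters.append(UnitagCluster(
            unitag=unitag,
            depth=len(members),
            read_ids=[p.id for p in members],
            reverse_reads=[p.reverse for p in members],
        ))
    return clusters


# --------------------------------------------------------------------------
# Minimal de Bruijn assembler
# --------------------------------------------------------------------------

def _kmer_counts(sequences: list[str], k: int) -> Counter:
    counts: Counter = Counter()
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += 1
    return counts


def debruijn_contigs(
    sequences: list[str],
    k: int = DEFAULT_K,
    min_length: int = DEFAULT_MIN_CONTIG,
) -> list[tuple[str, float]]:
    """Greedy walks over the k-mer graph of ``sequences``.

    Walks extend through forks by taking the strictly-majority edge
    (k-mer count); exact ties are broken toward the lexicographically
    smallest base, so a heterozygous site is represented by one allele
    rather than breaking the contig. Returns (sequence, mean k-mer
    depth) pairs for paths of at least ``min_length`` bases, longest
    first. Deterministic for a given input multiset.
    """
    if not (1 < k <= max((len(s) for s in sequences), default=k + 1)):
        raise ValueError("k must satisfy 1 < k <= read length")
    counts = _kmer_counts(sequences, k)
    if not counts:
        return []
    succ: dict[str, list[str]] = defaultdict(list)
    pred: dict[str, list[str]] = defaultdict(list)
    for kmer in counts:
        succ[kmer[:-1]].append(kmer)
        pred[kmer[1:]].append(kmer)

    used: set[str] = set()
    contigs: list[tuple[str, float]] = []
    seeds = sorted(counts, key=lambda km: (-counts[km], km))
    for seed in seeds:
        if seed in used:
            continue
        path = [seed]
        used.add(seed)
        # extend right
        while True:
            nxt = _pick_edge(succ.get(path[-1][1:], ()), counts, used)
            if nxt is None:
                break
            path.append(nxt)
            used.add(nxt)
        # extend left
        left: list[str] = []
        while True:
            prv = _pick_edge(pred.get((left[-1] if left else path[0])[:-1], ()),
                             counts, used)
            if prv is None:
                break
            left.append(prv)
            used.add(prv)
        if left:
            path = left[::-1] + path
        seq = path[0] + "".join(km[-1] for km in path[1:])
        depth = sum(counts[km] for km in path) / len(path)
        if len(seq) >= min_length:
            contigs.append((seq, depth))
    contigs.sort(key=lambda c: (-len(c[0]), c[0]))
    return contigs


def assemble_locus(
    cluster: UnitagCluster,
    k: int = DEFAULT_K,
    min_contig_length: int = DEFAULT_MIN_CONTIG,
    sample: str = "",
    locus_counter: int = 0,
) -> list[LocusContig]:
    """Assemble one cluster over the unitag plus all paired reverse reads.

    The path containing the unitag is flagged as the locus contig when
    it survives the length filter; otherwise the longest retained path
    is flagged (under wide insert ranges the unitag k-mers form a short
    disconnected island).
    """
    retained = debruijn_contigs([cluster.unitag] + cluster.reverse_reads,
                                k=k, min_length=min_contig_length)
    if not retained:
        return []
    unitag_kmers = {cluster.unitag[i : i + k]
                    for i in range(len(cluster.unitag) - k + 1)}
    locus_idx = 0
    for i, (seq, _) in enumerate(retained):
        kmers = {seq[j : j + k] for j in range(len(seq) - k + 1)}
        if kmers & unitag_kmers:
            locus_idx = i
            break
    out = []
    for i, (seq, depth) in enumerate(retained):
        out.append(LocusContig(
            id=f"{sample}.{locus_counter}.{i}",
            sample=sample,
            sequence=seq,
            mean_depth=depth,
            source_unitag=cluster.unitag,
            is_locus_contig=(i == locus_idx),
        ))
    return out


def _pick_edge(candidates, counts, used) -> str | None:
    best = None
    for km in candidates:
        if km in used:
            continue
        if best is None or (counts[km], _lexinv(km)) > (counts[best], _lexinv(best)):
            best = km
    return best


def _lexinv(km: str):
    # higher tuple wins in _pick_edge; invert lexicographic order so that
    # ties in count resolve toward the lexicographically smallest k-mer
    return tuple(-ord(c) for c in km[-1])


def assemble_sample(
    clusters: list[UnitagCluster],
    k: int = DEFAULT_K,
    min_contig_length: int = DEFAULT_MIN_CONTIG,
    sample: str = "",
) -> list[LocusContig]:
    """Assemble every cluster of one sample; clusters yielding no contig
    of sufficient length are dropped."""
    contigs: list[LocusContig] = []
    for i, cluster in enumerate(clusters):
        contigs.extend(assemble_locus(cluster, k=k, min_contig_length=min_contig_length,
                                      sample=sample, locus_counter=i))
    return contigs


def filter_assemblies(
    contigs: list[LocusContig],
    low: float = 0.25,
    high: float = 4.0,
) -> tuple[list[LocusContig], list[LocusContig]]:
    """Remove contigs whose mean depth lies outside [low x, high x] the
    median mean-depth of the sample's contigs (repetitive or under-covered
    assemblies). Returns (retained, removed)."""
    if not contigs:
        raise ValueError("filter_assemblies requires >= 1 contig")
    depths = sorted(c.mean_depth for c in contigs)
    n = len(depths)
    median = depths[n // 2] if n % 2 else 0.5 * (depths[n // 2 - 1] + depths[n // 2])
    retained, removed = [], []
    for c in contigs:
        (retained if low * median <= c.mean_depth <= high * median else removed).append(c)
    return retained, removed


def select_reference_sample(per_sample: dict[str, list[LocusContig]]) -> str:
    """The sample with the most contigs; ties broken by total assembled
    bases, then by the smallest sample id."""
    scored = [
        (len(contigs), sum(c.length for c in contigs), sample)
        for sample, contigs in per_sample.items()
        if contigs
    ]
    if not scored:
        raise ValueError("no sample has any contig")
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return scored[0][2]


def n50(lengths: list[int]) -> int:
    """Weighted median contig length: the largest length at which the
    cumulative sum of descending lengths first reaches half the total."""
    if not lengths:
        raise ValueError("n50 of empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("contig lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for x in ordered:
        acc += x
        if acc >= half:
            return x
    raise AssertionError("unreachable")


@dataclass
class AssemblyStats:
    """The per-sample summary row (contig count, bases, mean length, N50,
    length range)."""

    sample: str
    n_contigs: int
    total_bp: int
    mean_length: float
    n50: int
    min_length: int
    max_length: int

    @classmethod
    def from_contigs(cls, sample: str, contigs: list[LocusContig]) -> "AssemblyStats":
        lengths = [c.length for c in contigs]
        return cls(
            sample=sample,
            n_contigs=len(lengths),
            total_bp=sum(lengths),
            mean_length=sum(lengths) / len(lengths) if lengths else 0.0,
            n50=n50(lengths) if lengths else 0,
            min_length=min(lengths) if lengths else 0,
            max_length=max(lengths) if lengths else 0,
        )
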