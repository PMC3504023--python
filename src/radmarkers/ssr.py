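"""Microsatellite (SSR) detection, classification and PAL flagging.

Finds maximal *perfect* tandem runs of 1-4 bp motifs, reports each run
under its smallest period and its canonical motif (the lexicographic
minimum over all rotations of the motif and of its reverse complement,
so TG, GT, CA and AC are all the one class AC). Nearby runs are marked
as compound; runs with adequate unambiguous flanking sequence and at
least 3 repeats are flagged as potentially amplifiable loci (PAL), with
a stricter >= 4-repeat flag for actual primer-design candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import revcomp, truncate_percent

#: Minimum repeat counts per motif length. The di/tri/tetra minimum of 3
#: matches the ">= 3 repeats" convention of microsatellite surveys; a
#: mononucleotide run needs 8 copies before it is worth reporting.
DEFAULT_MIN_REPEATS = {1: 8, 2: 3, 3: 3, 4: 3}

DEFAULT_MAX_GAP = 10
DEFAULT_MIN_FLANK = 30
PAL_MIN_REPEATS = 3
PRIMER_MIN_REPEATS = 4

CLASS_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra"}


@dataclass
class SSRLocus:
    contig: str
    start: int
    end: int            # 0-based half-open; end - start = motif_length * repeats
    motif: str          # canonical form
    repeats: int
    compound: bool = False
    pal: bool = False
    primer_candidate: bool = False

    @property
    def motif_length(self) -> int:
        return len(self.motif)

    @property
    def ssr_class(self) -> str:
        return CLASS_NAMES[self.motif_length]


def canonical_motif(motif: str) -> str:
    """Lexicographically least rotation of the motif or of its reverse
    complement."""
    rc = revcomp(motif)
    forms = {motif[i:] + motif[:i] for i in range(len(motif))}
    forms |= {rc[i:] + rc[:i] for i in range(len(rc))}
    return min(forms)


def _smallest_period(motif: str) -> int:
    for p in range(1, len(motif)):
        if all(motif[i] == motif[i % p] for i in range(len(motif))):
            return p
    return len(motif)


def find_ssrs(
    sequence: str,
    min_repeats: dict[int, int] | None = None,
    contig: str = "",
) -> list[SSRLocus]:
    """Maximal perfect tandem runs of period 1-4 meeting their class
    minimum, reported at the smallest period; overlapping runs of
    different periods are resolved in favour of the longer run (ties to
    the smaller start)."""
    min_repeats = dict(DEFAULT_MIN_REPEATS if min_repeats is None else min_repeats)
    for p in (1, 2, 3, 4):
        if p not in min_repeats:
            raise ValueError(f"min_repeats must define motif length {p}")
    n = len(sequence)
    candidates: list[tuple[int, int, int]] = []   # (start, end, period)
    for p in (1, 2, 3, 4):
        i = 0
        while i + p < n:
            if sequence[i] != sequence[i + p] or sequence[i] == "N":
                i += 1
                continue
            j = i
            while j + p < n and sequence[j + p] == sequence[j] and sequence[j] != "N":
                j += 1
            # run of period p spans [i, j + p)
            run_start, run_end = i, j + p
            length = run_end - run_start
            repeats = length // p
            motif = sequence[run_start : run_start + p]
            if repeats >= min_repeats[p] and _smallest_period(motif) == p:
                candidates.append((run_start, run_start + p * repeats, p))
            i = j + 1
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    chosen: list[tuple[int, int, int]] = []
    for start, end, p in candidates:
        if all(end <= s or start >= e for s, e, _ in chosen):
            chosen.append((start, end, p))
    chosen.sort()
    return [
        SSRLocus(contig=contig, start=s, end=e,
                 motif=canonical_motif(sequence[s : s + p]),
                 repeats=(e - s) // p)
        for s, e, p in chosen
    ]


def classify_compound(ssrs: list[SSRLocus], max_gap: int = DEFAULT_MAX_GAP) -> list[SSRLocus]:
    """Mark SSRs separated by at most ``max_gap`` bases on the same contig
    as compound (both members); input must be sorted by (contig, start)."""
    for a, b in zip(ssrs, ssrs[1:]):
        if a.contig == b.contig and b.start - a.end <= max_gap:
            a.compound = b.compound = True
    return ssrs


def classify_pal(
    ssr: SSRLocus,
    contig_sequence: str,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> SSRLocus:
    """Flag a run as a potentially amplifiable locus.

    PAL requires >= ``min_flank`` unambiguous (non-N) bases on each side
    of the run and at least 3 repeats; the ``primer_candidate`` flag
    additionally requires >= 4 repeats."""
    left = contig_sequence[max(0, ssr.start - min_flank) : ssr.start]
    right = contig_sequence[ssr.end : ssr.end + min_flank]
    flanks_ok = (len(left) >= min_flank and "N" not in left
                 and len(right) >= min_flank and "N" not in right)
    ssr.pal = flanks_ok and ssr.repeats >= PAL_MIN_REPEATS
    ssr.primer_candidate = ssr.pal and ssr.repeats >= PRIMER_MIN_REPEATS
    return ssr


@dataclass
class SSRSummary:
    class_counts: dict[str, int]
    total: int
    n_compound: int
    n_pal: int
    n_di_tri_tetra: int
    pal_percent: float          # PAL share of di+tri+tetra loci, one decimal

    @property
    def pal_fraction(self) -> float:
        return self.n_pal / self.n_di_tri_tetra if self.n_di_tri_tetra else 0.0


def summarize_ssrs(loci: list[SSRLocus]) -> SSRSummary:
    """Per-class counts plus the PAL percentage among di-, tri- and
    tetra-nucleotide loci (truncated at one decimal, the convention of
    published marker tables)."""
    class_counts = {name: 0 for name in CLASS_NAMES.values()}
    n_pal = n_compound = n_dtt = 0
    for s in loci:
        class_counts[s.ssr_class] += 1
        if s.compound:
            n_compound += 1
        if s.motif_length >= 2:
            n_dtt += 1
            if s.pal:
                n_pal += 1
    frac = n_pal / n_dtt if n_dtt else 0.0
    return SSRSummary(
        class_counts=class_counts,
        total=sum(class_counts.values()),
        n_compound=n_compound,
        n_pal=n_pal,
        n_di_tri_tetra=n_dtt,
        pal_percent=truncate_percent(frac, 1),
    )
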