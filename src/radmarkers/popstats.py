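"""Replicate-genotype QC and marker summary statistics.

Validation genotyping amplifies every sample x locus in several PCR
replicates. A consensus genotype keeps the alleles seen in at least two
replicates; against that consensus, an allelic dropout (ADO) is a
positive amplification of a heterozygous consensus showing only one of
its alleles, and a false allele (FA) is any positive amplification
showing an allele absent from the consensus. Diversity summaries
(observed heterozygosity Ho, mean number of alleles, polymorphic
fraction) and the transition/transversion tabulation match the usual
conventions of SNP-panel validation reports.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from ._util import truncate_percent

TRANSITIONS = {"A-G", "C-T"}
TRANSVERSIONS = {"A-C", "G-T", "A-T", "C-G"}

Genotype = tuple[str, str]          # unphased allele pair, sorted
Observation = Genotype | None      # None = failed amplification


@dataclass
class ReplicateEntry:
    sample: str
    locus: str
    observations: list[Observation]
    consensus: Genotype | None      # None => no consensus / all missing
    no_consensus: bool
    n_positive: int
    ado_events: int
    fa_events: int


@dataclass
class ReplicateTable:
    entries: list[ReplicateEntry] = field(default_factory=list)

    def het_entries(self) -> list[ReplicateEntry]:
        return [e for e in self.entries
                if e.consensus is not None and e.consensus[0] != e.consensus[1]]


def consensus_genotype(replicates: list[Observation]) -> tuple[Genotype | None, bool]:
    """Consensus from replicate observations.

    An allele enters the consensus when observed in >= 2 replicates.
    Exactly two such alleles give a heterozygous consensus, one a
    homozygous consensus; zero (all alleles conflicting singletons)
    is a no-consensus; all-missing returns (None, False) = missing.
    Returns (consensus or None, no_consensus_flag).
    """
    positive = [obs for obs in replicates if obs is not None]
    if not positive:
        return None, False
    seen: Counter = Counter()
    for obs in positive:
        for allele in set(obs):
            seen[allele] += 1
    accepted = sorted(a for a, n in seen.items() if n >= 2)
    if len(accepted) == 1:
        return (accepted[0], accepted[0]), False
    if len(accepted) == 2:
        return (accepted[0], accepted[1]), False
    if len(accepted) == 0:
        return None, True
    # >2 recurrent alleles: conflicting multi-allelic signal
    return None, True


def build_replicate_table(
    observations: dict[tuple[str, str], list[Observation]],
) -> ReplicateTable:
    """Resolve consensuses and count ADO/FA events per (sample, locus)."""
    table = ReplicateTable()
    for (sample, locus) in sorted(observations):
        obs = observations[(sample, locus)]
        consensus, no_cons = consensus_genotype(obs)
        positive = [o for o in obs if o is not None]
        ado = fa = 0
        if consensus is not None:
            cset = set(consensus)
            het = consensus[0] != consensus[1]
            for o in positive:
                oset = set(o)
                if het and len(oset & cset) == 1:
                    ado += 1
                if oset - cset:
                    fa += 1
        table.entries.append(ReplicateEntry(
            sample=sample, locus=locus, observations=list(obs),
            consensus=consensus, no_consensus=no_cons,
            n_positive=len(positive), ado_events=ado, fa_events=fa,
        ))
    return table


@dataclass
class ErrorRates:
    ado_rate: float | None
    fa_rate: float | None
    positive_pcr_rate: float | None
    per_sample: dict[str, dict[str, float | None]] = field(default_factory=dict)


def error_rates(table: ReplicateTable) -> ErrorRates:
    """Genotyping error rates against resolved consensuses.

    ADO rate = dropout observations / positive amplifications of
    heterozygous-consensus entries; FA rate = observations carrying a
    non-consensus allele / all positive amplifications; positive PCR
    rate = positive / attempted amplifications. Undefined denominators
    report None.
    """
    def rates(entries: list[ReplicateEntry]) -> dict[str, float | None]:
        het = [e for e in entries
               if e.consensus is not None and e.consensus[0] != e.consensus[1]]
        het_pos = sum(e.n_positive for e in het)
        ado = sum(e.ado_events for e in het)
        resolved = [e for e in entries if e.consensus is not None]
        all_pos = sum(e.n_positive for e in resolved)
        fa = sum(e.fa_events for e in resolved)
        attempted = sum(len(e.observations) for e in entries)
        positive = sum(e.n_positive for e in entries)
        return {
            "ado_rate": ado / het_pos if het_pos else None,
            "fa_rate": fa / all_pos if all_pos else None,
            "positive_pcr_rate": positive / attempted if attempted else None,
        }

    overall = rates(table.entries)
    samples = sorted({e.sample for e in table.entries})
    per_sample = {s: rates([e for e in table.entries if e.sample == s])
                  for s in samples}
    return ErrorRates(per_sample=per_sample, **overall)


# --------------------------------------------------------------------------
# Diversity summaries over an allele-pair genotype matrix
# --------------------------------------------------------------------------
# The matrix maps locus -> sample -> "A/G"-style genotype string, "." for
# missing; helpers below parse it once.

def _iter_matrix(matrix: dict[str, dict[str, str]]):
    for locus, row in matrix.items():
        parsed = {}
        for sample, g in row.items():
            if g in (".", "./.", "", None):
                parsed[sample] = None
            else:
                a, _, b = g.partition("/")
                parsed[sample] = (a, b)
        yield locus, parsed


def observed_heterozygosity(matrix: dict[str, dict[str, str]]) -> tuple[dict[str, float | None], float | None]:
    """Per-individual Ho (het loci / non-missing loci) and the mean over
    individuals with at least one genotyped locus."""
    het: Counter = Counter()
    total: Counter = Counter()
    for _, row in _iter_matrix(matrix):
        for sample, g in row.items():
            total[sample] += 0
            if g is None:
                continue
            total[sample] += 1
            if g[0] != g[1]:
                het[sample] += 1
    per = {s: (het[s] / total[s] if total[s] else None) for s in total}
    values = [v for v in per.values() if v is not None]
    return per, (sum(values) / len(values) if values else None)


def mna(matrix: dict[str, dict[str, str]]) -> float:
    """Mean number of distinct alleles per locus among non-missing
    genotypes."""
    if not matrix:
        raise ValueError("mna requires >= 1 locus")
    counts = []
    for _, row in _iter_matrix(matrix):
        alleles = {a for g in row.values() if g is not None for a in g}
        counts.append(len(alleles))
    return sum(counts) / len(counts)


def polymorphic_fraction(matrix: dict[str, dict[str, str]]) -> tuple[float, int]:
    """Fraction of loci with >= 2 observed alleles, and that fraction as
    a whole-number percentage (truncated)."""
    if not matrix:
        raise ValueError("polymorphic_fraction requires >= 1 locus")
    poly = 0
    for _, row in _iter_matrix(matrix):
        alleles = {a for g in row.values() if g is not None for a in g}
        if len(alleles) >= 2:
            poly += 1
    frac = poly / len(matrix)
    return frac, int(truncate_percent(frac, 0))


@dataclass
class TsTv:
    transitions: dict[str, int]
    transversions: dict[str, int]
    ts_total: int
    tv_total: int
    ratio: float | None     # rounded to 2 decimals; None when tv_total == 0


def tstv(substitutions: dict[str, int] | Counter) -> TsTv:
    """Class totals and the ts/tv ratio from unordered base-pair counts
    (keys like "A-G" or "G-A"; transitions are A-G and C-T)."""
    ts: dict[str, int] = {k: 0 for k in sorted(TRANSITIONS)}
    tv: dict[str, int] = {k: 0 for k in sorted(TRANSVERSIONS)}
    for pair, n in substitutions.items():
        key = "-".join(sorted(pair.upper().split("-")))
        if key in TRANSITIONS:
            ts[key] += n
        elif key in TRANSVERSIONS:
            tv[key] += n
        else:
            raise ValueError(f"invalid substitution class {pair!r}")
    ts_total = sum(ts.values())
    tv_total = sum(tv.values())
    ratio = round(ts_total / tv_total, 2) if tv_total else None
    return TsTv(ts, tv, ts_total, tv_total, ratio)


def snp_density(n_snps: int, total_contig_bases: int) -> float:
    """SNPs per base of screened contig sequence, to 2 significant
    figures."""
    if total_contig_bases <= 0:
        raise ValueError("total_contig_bases must be > 0")
    if n_snps == 0:
        return 0.0
    d = n_snps / total_contig_bases
    exponent = math.floor(math.log10(abs(d)))
    return round(d, -exponent + 1)
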