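"""Restriction-site scanning and in-silico RAD-tag prediction.

A RAD library sequences short "tags" anchored at the cut sites of a
restriction endonuclease (here, by default, EagI with recognition sequence
CGGCCG, cutting between the first C and the G). Before sequencing, the
number of tags a genome will yield can be predicted either by scanning an
available reference sequence for the recognition site, or -- with nothing
but the genome length and GC content in hand -- from the base-composition
model that assumes independent, identically distributed bases.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import revcomp

#: Offset of the cut within the recognition sequence (C*GGCCG).
CUT_OFFSET = 1

DEFAULT_RECOGNITION = "CGGCCG"


@dataclass(frozen=True)
class DigestResult:
    """Outcome of digesting one sequence.

    ``site_positions`` are 0-based start offsets of the recognition
    sequence; ``n_tags`` counts extractable tags (two per interior site,
    fewer at the sequence edges); ``expected_sites`` is the value of the
    iid base-composition model for a sequence of the same length and GC.
    """

    site_positions: list[int]
    n_tags: int
    expected_sites: float


def find_sites(sequence: str, recognition: str = DEFAULT_RECOGNITION) -> list[int]:
    """All 0-based offsets where ``recognition`` occurs in ``sequence``.

    Overlapping occurrences are counted separately. For a non-palindromic
    recognition sequence the reverse-complement strand is scanned as well
    and hits are reported in forward coordinates. ``N`` never matches.
    """
    if not recognition:
        raise ValueError("recognition sequence must be non-empty")
    recognition = recognition.upper()
    if set(recognition) - set("ACGT"):
        raise ValueError("recognition sequence must be over ACGT")
    sequence = sequence.upper()

    hits = _scan(sequence, recognition)
    rc = revcomp(recognition)
    if rc != recognition:
        hits = sorted(set(hits) | set(_scan(sequence, rc)))
    return hits


def _scan(sequence: str, pattern: str) -> list[int]:
    """Overlapping exact-match scan via str.find."""
    hits = []
    i = sequence.find(pattern)
    while i != -1:
        hits.append(i)
        i = sequence.find(pattern, i + 1)
    return hits


def expected_site_count(length: int, gc: float, recognition: str = DEFAULT_RECOGNITION) -> float:
    """Expected number of recognition-site occurrences in a random iid
    sequence of ``length`` bases with the given GC fraction.

    Under the model p(G) = p(C) = gc/2 and p(A) = p(T) = (1-gc)/2, each of
    the ``length - m + 1`` windows matches independently with probability
    equal to the product of its per-base probabilities.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    m = len(recognition)
    if length < m:
        return 0.0
    p = 1.0
    for base in recognition.upper():
        p *= gc / 2 if base in "GC" else (1 - gc) / 2
    return (length - m + 1) * p


def extract_rad_tags(sequence: str, sites: list[int], tag_length: int) -> list[str]:
    """Tag sequences flanking each cut.

    For a site starting at ``s`` the cut falls at ``s + CUT_OFFSET``.  The
    downstream tag is the ``tag_length`` bases to the right of the cut; the
    upstream tag is the ``tag_length`` bases to the left, reverse-
    complemented so that both tags read away from the cut on their own
    strand. Directions with insufficient flanking sequence are skipped.
    """
    if tag_length < 1:
        raise ValueError("tag_length must be >= 1")
    tags = []
    for s in sites:
        cut = s + CUT_OFFSET
        if cut - tag_length >= 0:
            tags.append(revcomp(sequence[cut - tag_length : cut]))
        if cut + tag_length <= len(sequence):
            tags.append(sequence[cut : cut + tag_length])
    return tags


def digest(sequence: str, recognition: str = DEFAULT_RECOGNITION, tag_length: int = 40,
           gc: float | None = None) -> DigestResult:
    """Scan one sequence and summarize sites, tags and the model expectation."""
    sites = find_sites(sequence, recognition)
    tags = extract_rad_tags(sequence, sites, tag_length)
    if gc is None:
        n = len(sequence)
        gc = (sequence.count("G") + sequence.count("C")) / n if n else 0.0
    return DigestResult(
        site_positions=sites,
        n_tags=len(tags),
        expected_sites=expected_site_count(len(sequence), gc, recognition),
    )
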