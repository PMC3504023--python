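"""Small shared helpers: sequence alphabet, reverse complement, reporting."""

from __future__ import annotations

import math

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N allowed)."""
    return seq.translate(_COMP)[::-1]


def truncate_percent(fraction: float, decimals: int = 0) -> float:
    """Report ``fraction`` as a percentage truncated (not rounded) at
    ``decimals`` places.

    Published marker-survey tables conventionally floor percentages at the
    printed precision (e.g. 1706/9038 = 18.876% printed as 18.8%), so the
    reporting layer follows the same convention.
    """
    scale = 10**decimals
    value = math.floor(fraction * 100 * scale + 1e-9) / scale
    return value


def phred_char(q: int) -> str:
    return chr(q + 33)
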