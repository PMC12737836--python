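"""IUPAC genotype codes and identity-by-state site scoring.

A genotype call is a single character: a homozygous base (A, C, G, T), a
heterozygous two-allele code (R, Y, S, W, K, M), or the missing sentinel
``N``. Every call therefore denotes an unordered pair of alleles, and the
IBS score of two calls is the size of the multiset intersection of their
allele pairs divided by two: 1.0 (identical genotype), 0.5 (one shared
allele), or 0.0 (disjoint).
"""

from __future__ import annotations

import numpy as np

MISSING = "N"

#: call code -> unordered allele pair
ALLELE_PAIRS: dict[str, tuple[str, str]] = {
    "A": ("A", "A"),
    "C": ("C", "C"),
    "G": ("G", "G"),
    "T": ("T", "T"),
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}

#: unordered allele pair -> call code
PAIR_CODES: dict[frozenset, str] = {
    frozenset(pair): code for code, pair in ALLELE_PAIRS.items()
}

VALID_CALLS = set(ALLELE_PAIRS) | {MISSING}


def alleles(call: str) -> tuple[str, str]:
    """Unordered allele pair of a non-missing call."""
    try:
        return ALLELE_PAIRS[call]
    except KeyError:
        raise ValueError(f"not a genotype call: {call!r}") from None


def site_score(call1: str, call2: str) -> float:
    """IBS score of two calls: shared-allele count / 2."""
    a1, b1 = alleles(call1)
    a2, b2 = alleles(call2)
    if a1 == a2 and b1 == b2:
        return 1.0
    # one shared allele of the two
    if a1 in (a2, b2) or b1 in (a2, b2):
        return 0.5
    return 0.0


def _build_score_table() -> np.ndarray:
    """256 x 256 lookup of site scores indexed by call byte; NaN where
    either call is missing or invalid."""
    table = np.full((256, 256), np.nan)
    for c1 in ALLELE_PAIRS:
        for c2 in ALLELE_PAIRS:
            table[ord(c1), ord(c2)] = site_score(c1, c2)
    return table


#: vectorised site-score lookup (NaN = not comparable)
SCORE_TABLE = _build_score_table()


def score_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-site IBS scores for two equal-length uint8 call arrays."""
    return SCORE_TABLE[x, y]
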