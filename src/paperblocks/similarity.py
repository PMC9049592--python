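"""Gestalt pattern matching (Ratcliff–Obershelp) string similarity.

The similarity between two strings S1, S2 is

    Dro = 2 * Km / (|S1| + |S2|)

where Km, the number of *matching characters*, is found by locating the
longest common substring (the anchor), then recursing on the unmatched text to
the left of the anchor in both strings and on the unmatched text to the right.

Anchor ties (several equally long common substrings) are broken by the
leftmost occurrence in S1, then the leftmost in S2.  Km can differ across
tie-break conventions; the convention here matches stdlib
``difflib.SequenceMatcher(autojunk=False)``, which implements the same
algorithm and serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass

__all__ = ["SimilarityScore", "gestalt_similarity", "matching_characters", "canonicalize"]


@dataclass(frozen=True)
class SimilarityScore:
    """Bookkeeping for one Gestalt similarity comparison."""

    s1_len: int
    s2_len: int
    km: int
    dro: float


def _longest_match(a: str, alo: int, ahi: int, b: str, blo: int, bhi: int):
    """Longest common substring of a[alo:ahi] and b[blo:bhi].

    Returns (i, j, size) with the leftmost-in-a, then leftmost-in-b maximal
    match; size 0 when nothing matches.
    """
    best_i, best_j, best_size = alo, blo, 0
    # j2len[j] = length of longest common suffix of a[:i+1] and b[:j+1]
    j2len: dict[int, int] = {}
    for i in range(alo, ahi):
        new: dict[int, int] = {}
        ch = a[i]
        for j in range(blo, bhi):
            if b[j] == ch:
                k = j2len.get(j - 1, 0) + 1
                new[j] = k
                if k > best_size:
                    best_i, best_j, best_size = i - k + 1, j - k + 1, k
        j2len = new
    return best_i, best_j, best_size


def matching_characters(s1: str, s2: str) -> int:
    """Km: recursive longest-common-substring matching-character count."""
    km = 0
    stack = [(0, len(s1), 0, len(s2))]
    while stack:
        alo, ahi, blo, bhi = stack.pop()
        if alo >= ahi or blo >= bhi:
            continue
        i, j, size = _longest_match(s1, alo, ahi, s2, blo, bhi)
        if size == 0:
            continue
        km += size
        stack.append((alo, i, blo, j))
        stack.append((i + size, ahi, j + size, bhi))
    return km


def canonicalize(text: str) -> str:
    """Whitespace-collapse and NFC-normalize before comparison (case kept)."""
    return " ".join(unicodedata.normalize("NFC", text).split())


def gestalt_similarity(s1: str, s2: str, *, normalize: bool = False) -> SimilarityScore:
    """Compare two strings; two empty strings are defined as identical (Dro 1)."""
    if normalize:
        s1, s2 = canonicalize(s1), canonicalize(s2)
    total = len(s1) + len(s2)
    if total == 0:
        return SimilarityScore(0, 0, 0, 1.0)
    km = matching_characters(s1, s2)
    return SimilarityScore(len(s1), len(s2), km, 2.0 * km / total)
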