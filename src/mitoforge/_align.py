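"""Alignment primitives: Myers bit-vector edit distance and seed-and-extend
pairwise scanning for dispersed-repeat and cross-genome homology detection.

The scanner finds locally maximal ungapped alignments: exact k-mer seeds are
extended outward exactly, then (when ``min_identity`` < 100) extended further
by greedily crossing single mismatches while the overall identity stays at or
above the threshold.  Gap openings are therefore always zero.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, List, Optional, Tuple

__all__ = [
    "pattern_masks",
    "search_scores",
    "best_infix",
    "min_score_in",
    "scan_pair",
]


def pattern_masks(pattern: str) -> Dict[str, int]:
    masks: Dict[str, int] = {}
    for i, c in enumerate(pattern):
        masks[c] = masks.get(c, 0) | (1 << i)
    return masks


def search_scores(
    pattern: str, text: str, masks: Optional[Dict[str, int]] = None
) -> List[int]:
    """Myers bit-parallel approximate search (Hyyro's formulation).

    Returns, for every end position j (0-based) in ``text``, the minimum edit
    distance of ``pattern`` against any substring of ``text`` ending at j
    (start position free).
    """
    m = len(pattern)
    if m == 0:
        return [0] * len(text)
    if masks is None:
        masks = pattern_masks(pattern)
    full = (1 << m) - 1
    high = 1 << (m - 1)
    pv = full
    mv = 0
    score = m
    out = []
    append = out.append
    get = masks.get
    for c in text:
        eq = get(c, 0)
        xv = eq | mv
        xh = ((((eq & pv) + pv) & full) ^ pv) | eq
        ph = mv | (~(xh | pv) & full)
        mh = pv & xh
        if ph & high:
            score += 1
        elif mh & high:
            score -= 1
        ph = (ph << 1) & full
        mh = (mh << 1) & full
        pv = mh | (~(xv | ph) & full)
        mv = ph & xv
        append(score)
    return out


def best_infix(
    pattern: str, text: str, masks: Optional[Dict[str, int]] = None
) -> Tuple[int, int]:
    """(best distance, 0-based end index) of the best occurrence of pattern."""
    scores = search_scores(pattern, text, masks)
    if not scores:
        return len(pattern), -1
    best = min(scores)
    return best, scores.index(best)


def min_score_in(
    pattern: str,
    text: str,
    lo: int,
    hi: int,
    masks: Optional[Dict[str, int]] = None,
) -> int:
    """Minimum search score over end positions in [lo, hi] (clamped)."""
    scores = search_scores(pattern, text, masks)
    lo = max(lo, 0)
    hi = min(hi, len(scores) - 1)
    if lo > hi:
        return len(pattern) + len(text)  # effectively +inf
    return min(scores[lo : hi + 1])


# ---------------------------------------------------------------------------
# seed-and-extend scanning
# ---------------------------------------------------------------------------

Hit = Tuple[int, int, int, int, int]  # a0, a1, b0, b1, mismatches (0-based, half-open)


def _identity_ok(length: int, mm: int, min_identity: float) -> bool:
    return length > 0 and 100.0 * (length - mm) / length >= min_identity


def _cross_extend(
    sa: str, sb: str, a0: int, a1: int, b0: int, b1: int, mm: int, min_identity: float
) -> Tuple[int, int, int, int, int]:
    """Greedily cross single mismatches on either side while identity holds."""
    na, nb = len(sa), len(sb)
    while True:
        extended = False
        # rightward: cross one mismatch then take the following exact run
        if a1 < na and b1 < nb:
            run = 0
            while (
                a1 + 1 + run < na
                and b1 + 1 + run < nb
                and sa[a1 + 1 + run] == sb[b1 + 1 + run]
            ):
                run += 1
            if run > 0 and _identity_ok((a1 - a0) + 1 + run, mm + 1, min_identity):
                a1 += 1 + run
                b1 += 1 + run
                mm += 1
                extended = True
        # leftward
        if a0 > 0 and b0 > 0:
            run = 0
            while (
                a0 - 2 - run >= 0
                and b0 - 2 - run >= 0
                and sa[a0 - 2 - run] == sb[b0 - 2 - run]
            ):
                run += 1
            if run > 0 and _identity_ok((a1 - a0) + 1 + run, mm + 1, min_identity):
                a0 -= 1 + run
                b0 -= 1 + run
                mm += 1
                extended = True
        if not extended:
            return a0, a1, b0, b1, mm


def scan_pair(
    sa: str,
    sb: str,
    *,
    seed_size: int,
    min_length: int,
    min_identity: float,
    same_sequence: bool = False,
) -> List[Hit]:
    """Locally maximal ungapped alignments between ``sa`` and ``sb``.

    With ``same_sequence`` True (self-comparison in the same orientation),
    only pairs with a-start < b-start are reported and the trivial
    self-diagonal is skipped.
    """
    k = min(seed_size, min_length)
    if k < 1:
        raise ValueError("seed size must be >= 1")
    index: Dict[str, List[int]] = defaultdict(list)
    for i in range(len(sa) - k + 1):
        index[sa[i : i + k]].append(i)
    covered: Dict[int, int] = {}
    hits: Dict[Tuple[int, int, int, int], int] = {}
    na, nb = len(sa), len(sb)
    for j in range(nb - k + 1):
        seeds = index.get(sb[j : j + k])
        if not seeds:
            continue
        for i in seeds:
            if same_sequence and i >= j:
                continue
            diag = i - j
            if covered.get(diag, -1) >= i:
                continue
            # exact extension
            left = 0
            while i - left - 1 >= 0 and j - left - 1 >= 0 and sa[i - left - 1] == sb[j - left - 1]:
                left += 1
            right = 0
            while (
                i + k + right < na
                and j + k + right < nb
                and sa[i + k + right] == sb[j + k + right]
            ):
                right += 1
            a0, a1 = i - left, i + k + right
            b0, b1 = j - left, j + k + right
            mm = 0
            if min_identity < 100.0:
                a0, a1, b0, b1, mm = _cross_extend(
                    sa, sb, a0, a1, b0, b1, mm, min_identity
                )
            covered[diag] = max(covered.get(diag, -1), a1)
            if a1 - a0 >= min_length and _identity_ok(a1 - a0, mm, min_identity):
                key = (a0, a1, b0, b1)
                if key not in hits or hits[key] > mm:
                    hits[key] = mm
    return [(a0, a1, b0, b1, mm) for (a0, a1, b0, b1), mm in sorted(hits.items())]
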