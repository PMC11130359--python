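"""Brute-force reference implementations used as independent oracles.

These deliberately avoid the package's seed-and-extend / linear-scan code
paths: exact repeat pairs are enumerated per diagonal with numpy run-length
encoding; SSR candidates are expanded per position with circular indexing;
edit distances come from a full dynamic-programming table.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Set, Tuple

import numpy as np


def _runs(eq: np.ndarray) -> List[Tuple[int, int]]:
    """(start, length) of maximal True runs in a boolean array."""
    padded = np.concatenate(([0], eq.astype(np.int8), [0]))
    idx = np.flatnonzero(np.diff(padded))
    return [(int(s), int(e - s)) for s, e in zip(idx[::2], idx[1::2])]


def maximal_exact_pairs(
    a_seq: str, b_seq: str, min_len: int, same_direct: bool = False
) -> Set[Tuple[int, int, int, int]]:
    """All maximal exact matches >= min_len as 0-based half-open
    (a0, a1, b0, b1).  With ``same_direct`` (self-comparison, same strand),
    each unordered pair is kept once (a0 < b0) and overlapping footprints are
    dropped."""
    a = np.frombuffer(a_seq.encode(), dtype=np.uint8)
    b = np.frombuffer(b_seq.encode(), dtype=np.uint8)
    out: Set[Tuple[int, int, int, int]] = set()
    for d in range(-(len(b) - 1), len(a)):
        i0 = max(0, d)
        j0 = i0 - d
        span = min(len(a) - i0, len(b) - j0)
        if span < min_len:
            continue
        eq = a[i0 : i0 + span] == b[j0 : j0 + span]
        for s, ln in _runs(eq):
            if ln < min_len:
                continue
            a0, a1 = i0 + s, i0 + s + ln
            b0, b1 = j0 + s, j0 + s + ln
            if same_direct:
                if a0 >= b0:
                    continue
                if a1 > b0:  # overlapping footprints
                    continue
            out.add((a0, a1, b0, b1))
    return out


def dp_search_scores(pattern: str, text: str) -> List[int]:
    """Edit distance of the best occurrence of ``pattern`` ending at each
    text position (start free), by full DP."""
    m, n = len(pattern), len(text)
    prev = list(range(m + 1))  # column for text prefix length 0
    # dp[i][j]: pattern[:i] vs best suffix of text[:j]; dp[0][j] = 0
    scores = []
    for j in range(1, n + 1):
        cur = [0] * (m + 1)
        for i in range(1, m + 1):
            cost = 0 if pattern[i - 1] == text[j - 1] else 1
            cur[i] = min(prev[i] + 1, cur[i - 1] + 1, prev[i - 1] + cost)
        scores.append(cur[m])
        prev = cur
    return scores


def _circ(seq: str, i: int) -> str:
    return seq[i % len(seq)]


def ssr_candidates_brute(
    seq: str, circular: bool, min_copies: Mapping[int, int]
) -> List[Tuple[int, int, str, int]]:
    """(start0, unit, motif, copies) for every maximal primitive perfect run
    meeting the class minimum, by per-position expansion."""
    n = len(seq)
    cands = []
    for u in range(1, 7):
        for start in range(n):
            if circular:
                motif = "".join(_circ(seq, start + k) for k in range(u))
            else:
                if start + u > n:
                    continue
                motif = seq[start : start + u]
            # primitivity
            if any(u % d == 0 and motif == motif[: d] * (u // d) for d in range(1, u)):
                continue
            # left-maximality: the preceding base must not extend the run
            if circular:
                if _circ(seq, start - 1) == _circ(seq, start - 1 + u):
                    continue
            elif start > 0 and start - 1 + u < n and seq[start - 1] == seq[start - 1 + u]:
                continue
            copies = 1
            while True:
                nxt = start + copies * u
                if circular:
                    if copies * u + u > n:  # run cannot exceed the circle
                        break
                    ok = all(
                        _circ(seq, nxt + k) == motif[k] for k in range(u)
                    )
                else:
                    if nxt + u > n:
                        break
                    ok = seq[nxt : nxt + u] == motif
                if not ok:
                    break
                copies += 1
            if copies >= min_copies[u]:
                cands.append((start, u, motif, copies))
    return cands


def ssr_select_brute(
    cands: List[Tuple[int, int, str, int]], n: int
) -> List[Tuple[int, int, str, int]]:
    """Greedy non-overlap selection: start, then unit size, then longer run."""
    chosen: List[Tuple[int, int, str, int]] = []
    taken: Set[int] = set()
    for start, u, motif, copies in sorted(cands, key=lambda c: (c[0], c[1], -c[3])):
        covered = {(start + k) % n for k in range(copies * u)}
        if covered & taken:
            continue
        taken |= covered
        chosen.append((start, u, motif, copies))
    return chosen


def translate_codon(codon: str) -> str:
    table = {
        "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
        "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
        "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
        "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
        "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
        "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
        "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
        "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
        "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
        "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
        "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
        "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
        "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
        "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
        "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
        "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
    }
    return table[codon]
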