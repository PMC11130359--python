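"""Dispersed repeat pairs, microsatellites (SSRs), and a simplified tandem
repeat detector.

Dispersed repeats are found by exact k-mer seeding with ungapped extension
(see :mod:`mitoforge._align`); with ``min_identity`` = 100 the output equals
the set of maximal exact repeated pairs, which the test suite checks against
a brute-force diagonal oracle.  Repeats spanning the circular origin are not
detected (scan is linear); planted and real repeats of interest do not wrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from . import _align
from .genome import (
    CircularChromosome,
    CircularInterval,
    GenomeConfiguration,
    reverse_complement,
)

__all__ = [
    "RepeatPair",
    "SSRRecord",
    "TandemRepeat",
    "SSRSummary",
    "DEFAULT_SSR_MIN_COPIES",
    "find_dispersed_repeats",
    "find_ssrs",
    "summarize_ssrs",
    "find_tandem_repeats_simple",
]

#: MISA-style class minima: unit size -> minimum copy number ("1-10 2-6 3-5 4-5 5-5 6-5")
DEFAULT_SSR_MIN_COPIES: Mapping[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

_MATCH_SCORE = 2
_MISMATCH_SCORE = -3


@dataclass(frozen=True)
class RepeatPair:
    """Two genomic intervals forming a dispersed repeat pair."""

    id: str
    unit1: CircularInterval
    unit2: CircularInterval
    orientation: str  # "direct" | "inverted"
    alignment_length: int
    identity_percent: float
    mismatches: int
    gap_openings: int
    score: int

    def __post_init__(self) -> None:
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if not (0.0 <= self.identity_percent <= 100.0):
            raise ValueError("identity out of range")
        if (self.unit1.chrom, self.unit1.start, self.unit1.end) == (
            self.unit2.chrom,
            self.unit2.start,
            self.unit2.end,
        ):
            raise ValueError("repeat pair must not be a self-match")


@dataclass(frozen=True)
class SSRRecord:
    chrom: str
    motif: str
    unit_size: int
    copies: int
    start: int
    end: int

    @property
    def total_length(self) -> int:
        return self.unit_size * self.copies


@dataclass(frozen=True)
class TandemRepeat:
    chrom: str
    period: int
    copy_number: float
    consensus: str
    interval: CircularInterval


@dataclass(frozen=True)
class SSRSummary:
    """Per-chromosome counts by unit-size class plus overall class proportions."""

    per_chrom: Mapping[str, Mapping[int, int]]
    class_counts: Mapping[int, int]
    proportions: Mapping[int, float]  # percent, rounded to 1 decimal
    total: int


# ---------------------------------------------------------------------------
# dispersed repeats
# ---------------------------------------------------------------------------


def _intervals_overlap(a: CircularInterval, b: CircularInterval) -> bool:
    if a.chrom != b.chrom:
        return False
    alo, ahi = min(a.start, a.end), max(a.start, a.end)
    blo, bhi = min(b.start, b.end), max(b.start, b.end)
    return alo <= bhi and blo <= ahi


def _canonical_pair(
    u1: CircularInterval, u2: CircularInterval, order: Mapping[str, int]
) -> Tuple[CircularInterval, CircularInterval]:
    k1 = (order[u1.chrom], min(u1.start, u1.end))
    k2 = (order[u2.chrom], min(u2.start, u2.end))
    return (u1, u2) if k1 <= k2 else (u2, u1)


def find_dispersed_repeats(
    config: GenomeConfiguration,
    min_length: int = 1000,
    min_identity: float = 99.0,
    seed_size: int = 13,
) -> List[RepeatPair]:
    """Direct and inverted repeat pairs with length >= ``min_length`` and
    identity >= ``min_identity``, each unordered pair reported once.

    Ids are assigned deterministically: descending alignment length, then
    coordinates.
    """
    if not config.chromosomes:
        raise ValueError("empty configuration")
    if not (0.0 < min_identity <= 100.0):
        raise ValueError("min_identity must be in (0, 100]")
    order = {c.id: i for i, c in enumerate(config.chromosomes)}
    raw: Dict[Tuple, Tuple[CircularInterval, CircularInterval, str, int, int]] = {}

    def record(u1: CircularInterval, u2: CircularInterval, orientation: str,
               length: int, mm: int) -> None:
        if _intervals_overlap(u1, u2):
            return
        u1, u2 = _canonical_pair(u1, u2, order)
        if u1.strand == "-":  # keep unit1 on the plus strand
            u1 = CircularInterval(u1.chrom, u1.start, u1.end, "+")
            u2 = CircularInterval(
                u2.chrom, u2.start, u2.end, "-" if u2.strand == "+" else "+"
            )
        key = (
            u1.chrom, min(u1.start, u1.end), max(u1.start, u1.end),
            u2.chrom, min(u2.start, u2.end), max(u2.start, u2.end),
            orientation,
        )
        prev = raw.get(key)
        if prev is None or mm < prev[4]:
            raw[key] = (u1, u2, orientation, length, mm)

    chroms = config.chromosomes
    for i, ca in enumerate(chroms):
        for cb in chroms[i:]:
            same = ca.id == cb.id
            # direct orientation
            for a0, a1, b0, b1, mm in _align.scan_pair(
                ca.sequence,
                cb.sequence,
                seed_size=seed_size,
                min_length=min_length,
                min_identity=min_identity,
                same_sequence=same,
            ):
                record(
                    CircularInterval(ca.id, a0 + 1, a1, "+"),
                    CircularInterval(cb.id, b0 + 1, b1, "+"),
                    "direct",
                    a1 - a0,
                    mm,
                )
            # inverted orientation: compare against the reverse complement
            rcb = reverse_complement(cb.sequence)
            nb = len(cb)
            for a0, a1, b0, b1, mm in _align.scan_pair(
                ca.sequence,
                rcb,
                seed_size=seed_size,
                min_length=min_length,
                min_identity=min_identity,
                same_sequence=False,
            ):
                # map RC coordinates back to the plus strand of cb
                lo, hi = nb - b1 + 1, nb - b0
                record(
                    CircularInterval(ca.id, a0 + 1, a1, "+"),
                    CircularInterval(cb.id, lo, hi, "-"),
                    "inverted",
                    a1 - a0,
                    mm,
                )

    entries = sorted(
        raw.values(),
        key=lambda e: (
            -e[3],
            order[e[0].chrom],
            min(e[0].start, e[0].end),
            order[e[1].chrom],
            min(e[1].start, e[1].end),
            e[2],
        ),
    )
    # collapse near-duplicate pairs produced by divergent seeds reaching
    # slightly different endpoints (only arises when min_identity < 100)
    kept: List[Tuple[CircularInterval, CircularInterval, str, int, int]] = []
    for e in entries:
        dup = False
        for f in kept:
            if e[2] == f[2] and _overlap_frac(e[0], f[0]) > 0.8 and _overlap_frac(e[1], f[1]) > 0.8:
                dup = True
                break
        if not dup:
            kept.append(e)

    pairs = []
    for idx, (u1, u2, orientation, length, mm) in enumerate(kept, start=1):
        identity = 100.0 * (length - mm) / length
        pairs.append(
            RepeatPair(
                id=f"R{idx}",
                unit1=u1,
                unit2=u2,
                orientation=orientation,
                alignment_length=length,
                identity_percent=identity,
                mismatches=mm,
                gap_openings=0,
                score=_MATCH_SCORE * (length - mm) + _MISMATCH_SCORE * mm,
            )
        )
    return pairs


def _overlap_frac(a: CircularInterval, b: CircularInterval) -> float:
    if a.chrom != b.chrom:
        return 0.0
    alo, ahi = min(a.start, a.end), max(a.start, a.end)
    blo, bhi = min(b.start, b.end), max(b.start, b.end)
    inter = min(ahi, bhi) - max(alo, blo) + 1
    if inter <= 0:
        return 0.0
    return inter / min(ahi - alo + 1, bhi - blo + 1)


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------


def _is_primitive(motif: str) -> bool:
    u = len(motif)
    for d in range(1, u):
        if u % d == 0 and motif == motif[:d] * (u // d):
            return False
    return True


def _ssr_candidates(
    seq: str, n: int, circular: bool, min_copies: Mapping[int, int], overhang: int
) -> List[Tuple[int, int, str, int]]:
    """(start0, unit, motif, copies) candidates on ``seq`` (= chromosome
    sequence plus circular overhang); start0 is 0-based in original coords."""
    ext = len(seq)
    out = []
    for u in range(1, 7):
        need = min_copies[u]
        i = 0
        while i + u < ext:
            if seq[i] != seq[i + u]:
                i += 1
                continue
            # maximal run of period-u matches starting at i
            j = i
            while j + u < ext and seq[j] == seq[j + u]:
                j += 1
            run = j - i  # region seq[i : i+run+u] has period u
            copies = (run + u) // u
            motif = seq[i : i + u]
            if (
                copies >= need
                and i < n
                and _is_primitive(motif)
                and not (
                    circular
                    and seq[(i - 1) % n] == seq[(i - 1 + u) % n]
                )  # circular left-maximality: found at an earlier start instead
            ):
                out.append((i, u, motif, copies))
            i = j + 1
    return out


def find_ssrs(
    config: GenomeConfiguration,
    min_copies: Optional[Mapping[int, int]] = None,
) -> List[SSRRecord]:
    """Maximal perfect tandem runs of 1-6 bp motifs meeting MISA-style class
    minima.

    A run reportable at several unit sizes appears once, at the smallest unit
    size whose primitive motif generates it; overlapping candidates are
    resolved by start position, then smaller unit size, then longer run.
    Circular chromosomes are scanned across the origin via a bounded overhang.
    """
    min_copies = dict(DEFAULT_SSR_MIN_COPIES if min_copies is None else min_copies)
    for u in range(1, 7):
        if u not in min_copies:
            raise ValueError(f"min_copies must define unit size {u}")
    records: List[SSRRecord] = []
    for chrom in config.chromosomes:
        n = len(chrom)
        overhang = min(n - 1, 600) if chrom.is_circular else 0
        seq = chrom.sequence + chrom.sequence[:overhang]
        cands = _ssr_candidates(seq, n, chrom.is_circular, min_copies, overhang)
        cands.sort(key=lambda c: (c[0], c[1], -c[3]))
        taken: List[Tuple[int, int]] = []  # (start0, end0_exclusive) possibly > n
        for start0, u, motif, copies in cands:
            end0 = start0 + copies * u  # exclusive, may extend past n (wrap)
            covered = {p % n for p in range(start0, end0)}
            clash = False
            for ts, te in taken:
                if covered & {p % n for p in range(ts, te)}:
                    clash = True
                    break
            if clash:
                continue
            taken.append((start0, end0))
            records.append(
                SSRRecord(
                    chrom=chrom.id,
                    motif=motif,
                    unit_size=u,
                    copies=copies,
                    start=start0 + 1,
                    end=(end0 - 1) % n + 1,
                )
            )
    records.sort(key=lambda r: (r.chrom, r.start, r.unit_size))
    return records


def summarize_ssrs(records: Sequence[SSRRecord]) -> SSRSummary:
    """Counts per chromosome per unit-size class, plus overall class
    proportions as percentages rounded to one decimal."""
    per_chrom: Dict[str, Dict[int, int]] = {}
    class_counts = {u: 0 for u in range(1, 7)}
    for r in records:
        per_chrom.setdefault(r.chrom, {u: 0 for u in range(1, 7)})
        per_chrom[r.chrom][r.unit_size] += 1
        class_counts[r.unit_size] += 1
    total = len(records)
    proportions = (
        {u: round(100.0 * class_counts[u] / total, 1) for u in range(1, 7)}
        if total
        else {}
    )
    return SSRSummary(
        per_chrom=per_chrom,
        class_counts=class_counts,
        proportions=proportions,
        total=total,
    )


# ---------------------------------------------------------------------------
# simplified tandem repeats
# ---------------------------------------------------------------------------


def find_tandem_repeats_simple(
    chrom: CircularChromosome,
    min_period: int = 7,
    max_period: int = 500,
    min_total: int = 14,
    max_mismatch_fraction: float = 0.2,
) -> List[TandemRepeat]:
    """Maximal regions where a period-p consensus repeats at least twice.

    This is a deliberately simplified detector, not a reimplementation of the
    Tandem Repeats Finder scoring model: a region qualifies when its
    period-p self-match mismatch fraction is at most ``max_mismatch_fraction``
    and its total length is at least ``min_total``.  Smaller periods take
    precedence where regions overlap.
    """
    if not (2 <= min_period <= max_period):
        raise ValueError("need 2 <= min_period <= max_period")
    seq = chrom.sequence
    n = len(seq)
    results: List[TandemRepeat] = []
    claimed: List[Tuple[int, int]] = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        i = 0
        while i + p < n:
            if seq[i] != seq[i + p]:
                i += 1
                continue
            # exact run, then greedy single-mismatch crossing
            j = i
            mm = 0
            while True:
                while j + p < n and seq[j] == seq[j + p]:
                    j += 1
                if j + p >= n:
                    break
                run = 0
                while (
                    j + 1 + run + p < n and seq[j + 1 + run] == seq[j + 1 + run + p]
                ):
                    run += 1
                length = (j - i) + 1 + run + p
                if run > 0 and (mm + 1) / length <= max_mismatch_fraction:
                    j += 1 + run
                    mm += 1
                else:
                    break
            region_len = (j - i) + p
            if region_len >= max(min_total, 2 * p):
                lo, hi = i, i + region_len  # half-open
                if not any(lo < te and ts < hi for ts, te in claimed):
                    claimed.append((lo, hi))
                    consensus = _consensus(seq[lo:hi], p)
                    results.append(
                        TandemRepeat(
                            chrom=chrom.id,
                            period=p,
                            copy_number=round(region_len / p, 2),
                            consensus=consensus,
                            interval=CircularInterval(chrom.id, lo + 1, hi, "+"),
                        )
                    )
            i = j + 1
    results.sort(key=lambda t: (t.interval.start, t.period))
    return results


def _consensus(region: str, period: int) -> str:
    cols: List[Dict[str, int]] = [{} for _ in range(period)]
    for idx, base in enumerate(region):
        col = cols[idx % period]
        col[base] = col.get(base, 0) + 1
    return "".join(max(sorted(c), key=c.get) for c in cols)
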