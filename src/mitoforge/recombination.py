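"""Repeat-mediated recombination: product enumeration, junction reference
construction, spanning-read classification, and configuration abundance.

Topology algebra for a crossover between two copies of a repeat:

* direct repeat, both copies on one circle  -> the circle splits into two,
  each product retaining one copy;
* direct repeat, copies on two circles      -> the circles fuse into one,
  retaining both copies;
* inverted repeat, both copies on one circle -> the segment between the
  copies is reverse-complemented in place (inversion).

Inverted repeats whose copies lie on different circles have no described
product topology and are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from . import _align
from .genome import (
    CircularChromosome,
    CircularInterval,
    GenomeConfiguration,
    Topology,
    canonical_rotation,
    extract_subsequence,
    reverse_complement,
)
from .repeats import RepeatPair

__all__ = [
    "JunctionModel",
    "ReadSupport",
    "RecombinationEvent",
    "UnsupportedRecombination",
    "enumerate_recombinants",
    "build_junctions",
    "classify_spanning_reads",
    "minor_fraction",
    "recombination_screen",
]

JUNCTION_LABELS = ("ref1", "ref2", "alt1", "alt2")


class UnsupportedRecombination(ValueError):
    """Raised for repeat geometries whose product topology is undefined."""


@dataclass(frozen=True)
class JunctionModel:
    """Four junction references (flank + repeat unit + flank) for one repeat.

    ``ref1``/``ref2`` splice flanks as found in the input configuration;
    ``alt1``/``alt2`` are the two crossover products.
    """

    repeat: RepeatPair
    flank_length: int
    junctions: Mapping[str, str]
    label_map: Mapping[str, Tuple[CircularInterval, CircularInterval]]
    units: Mapping[int, str]  # oriented unit sequences, keys 1 and 2
    warnings: Tuple[str, ...] = ()


@dataclass(frozen=True)
class ReadSupport:
    counts: Mapping[str, int]
    unassigned: int

    @property
    def major_count(self) -> int:
        return self.counts.get("ref1", 0) + self.counts.get("ref2", 0)

    @property
    def minor_count(self) -> int:
        return self.counts.get("alt1", 0) + self.counts.get("alt2", 0)

    @property
    def minor_percent(self) -> Optional[float]:
        denom = self.major_count + self.minor_count
        if denom == 0:
            return None
        return round(100.0 * self.minor_count / denom, 2)


@dataclass(frozen=True)
class RecombinationEvent:
    parent: GenomeConfiguration
    repeat: RepeatPair
    products: Tuple[GenomeConfiguration, ...]
    event_class: str  # "split" | "fusion" | "inversion"


def minor_fraction(major: int, minor: int) -> float:
    """100 * minor / (major + minor), to two decimals."""
    if major < 0 or minor < 0:
        raise ValueError("counts must be non-negative")
    if major + minor == 0:
        raise ValueError("both counts are zero")
    return round(100.0 * minor / (major + minor), 2)


# ---------------------------------------------------------------------------
# product enumeration
# ---------------------------------------------------------------------------


def _unit_footprints(repeat: RepeatPair) -> Tuple[Tuple[str, int, int, str], ...]:
    out = []
    for u in (repeat.unit1, repeat.unit2):
        lo, hi = min(u.start, u.end), max(u.start, u.end)
        out.append((u.chrom, lo, hi, u.strand))
    return tuple(out)


def enumerate_recombinants(
    config: GenomeConfiguration, repeat: RepeatPair
) -> RecombinationEvent:
    """Apply one crossover between the two repeat copies and return the
    resulting configuration (other chromosomes pass through unchanged)."""
    (c1, lo1, hi1, s1), (c2, lo2, hi2, s2) = _unit_footprints(repeat)
    if s1 != "+":
        raise ValueError("unit1 must be stored on the plus strand")
    chrom1 = config.chromosome(c1)
    chrom2 = config.chromosome(c2)
    if not (chrom1.is_circular and chrom2.is_circular):
        raise UnsupportedRecombination("recombination defined on circles only")

    name = f"{config.name}x{repeat.id}"
    passthrough = tuple(
        c for c in config.chromosomes if c.id not in (c1, c2)
    )

    if c1 == c2:
        if hi1 >= lo2 and lo1 <= hi2:
            raise ValueError("repeat units overlap")
        if lo1 > lo2:
            (lo1, hi1), (lo2, hi2) = (lo2, hi2), (lo1, hi1)
        seq = chrom1.sequence
        if repeat.orientation == "direct":
            p1 = seq[lo1 - 1 : lo2 - 1]
            p2 = seq[lo2 - 1 :] + seq[: lo1 - 1]
            chroms = passthrough + (
                canonical_rotation(CircularChromosome(f"{name}.1", p1)),
                canonical_rotation(CircularChromosome(f"{name}.2", p2)),
            )
            product = GenomeConfiguration(
                name=name, chromosomes=chroms,
                provenance=f"{config.name} split by {repeat.id}",
            )
            return RecombinationEvent(config, repeat, (product,), "split")
        # inversion: reverse-complement the segment strictly between the units
        inner = seq[hi1 : lo2 - 1]
        p = seq[:hi1] + reverse_complement(inner) + seq[lo2 - 1 :]
        chroms = passthrough + (
            canonical_rotation(CircularChromosome(f"{name}.1", p)),
        )
        product = GenomeConfiguration(
            name=name, chromosomes=chroms,
            provenance=f"{config.name} inverted by {repeat.id}",
        )
        return RecombinationEvent(config, repeat, (product,), "inversion")

    # two circles
    if repeat.orientation == "inverted":
        raise UnsupportedRecombination(
            "inverted repeat spanning two circles: product topology undefined"
        )
    a = chrom1.sequence[lo1 - 1 :] + chrom1.sequence[: lo1 - 1]
    b = chrom2.sequence[lo2 - 1 :] + chrom2.sequence[: lo2 - 1]
    if s2 == "-":
        raise UnsupportedRecombination(
            "direct pair with a minus-strand unit across circles is unsupported"
        )
    fused = canonical_rotation(CircularChromosome(f"{name}.1", a + b))
    product = GenomeConfiguration(
        name=name,
        chromosomes=passthrough + (fused,),
        provenance=f"{config.name} fused by {repeat.id}",
    )
    return RecombinationEvent(config, repeat, (product,), "fusion")


# ---------------------------------------------------------------------------
# junction references
# ---------------------------------------------------------------------------


def _flank_intervals(
    chrom: CircularChromosome, lo: int, hi: int, strand: str, flank: int
) -> Tuple[CircularInterval, CircularInterval, List[str]]:
    """Upstream/downstream flank intervals in the unit's own orientation."""
    n = len(chrom)
    warnings: List[str] = []
    eff = min(flank, n - (hi - lo + 1))  # cannot borrow more than the rest
    if eff < flank:
        warnings.append(
            f"flank truncated to {eff} bp on {chrom.id} (chromosome too short)"
        )
    if chrom.is_circular:
        before = CircularInterval(chrom.id, (lo - 1 - eff) % n + 1, (lo - 2) % n + 1, "+")
        after = CircularInterval(chrom.id, hi % n + 1, (hi + eff - 1) % n + 1, "+")
    else:
        b_lo = max(1, lo - eff)
        a_hi = min(n, hi + eff)
        if b_lo > lo - 1 or a_hi < hi + 1:
            warnings.append(f"flank truncated at linear chromosome end on {chrom.id}")
        before = CircularInterval(chrom.id, b_lo, max(b_lo, lo - 1), "+")
        after = CircularInterval(chrom.id, min(hi + 1, a_hi), a_hi, "+")
    if strand == "+":
        return before, after, warnings
    flip = lambda iv: CircularInterval(iv.chrom, iv.start, iv.end, "-")
    return flip(after), flip(before), warnings


def build_junctions(
    config: GenomeConfiguration, repeat: RepeatPair, flank_length: int = 500
) -> JunctionModel:
    """Extract the four flank+unit+flank junction references for a repeat."""
    if flank_length < 1:
        raise ValueError("flank_length must be >= 1")
    warnings: List[str] = []
    (c1, lo1, hi1, _), (c2, lo2, hi2, _) = _unit_footprints(repeat)
    if c1 == c2:
        a, b = sorted([(lo1, hi1), (lo2, hi2)])
        if b[0] - a[1] == 1:
            warnings.append(
                "repeat units are adjacent (zero gap); reference and "
                "alternative junctions are degenerate"
            )
    ups: Dict[int, str] = {}
    downs: Dict[int, str] = {}
    units: Dict[int, str] = {}
    srcs: Dict[int, Tuple[CircularInterval, CircularInterval]] = {}
    for k, unit in ((1, repeat.unit1), (2, repeat.unit2)):
        chrom = config.chromosome(unit.chrom)
        lo, hi = min(unit.start, unit.end), max(unit.start, unit.end)
        if hi - lo + 1 > len(chrom):
            raise ValueError(f"repeat unit longer than chromosome {chrom.id}")
        up_iv, down_iv, w = _flank_intervals(chrom, lo, hi, unit.strand, flank_length)
        warnings.extend(w)
        ups[k] = extract_subsequence(chrom, up_iv)
        downs[k] = extract_subsequence(chrom, down_iv)
        units[k] = extract_subsequence(
            chrom, CircularInterval(unit.chrom, lo, hi, unit.strand)
        )
        srcs[k] = (up_iv, down_iv)

    junctions = {
        "ref1": ups[1] + units[1] + downs[1],
        "ref2": ups[2] + units[2] + downs[2],
        "alt1": ups[1] + units[1] + downs[2],
        "alt2": ups[2] + units[2] + downs[1],
    }
    label_map = {
        "ref1": (srcs[1][0], srcs[1][1]),
        "ref2": (srcs[2][0], srcs[2][1]),
        "alt1": (srcs[1][0], srcs[2][1]),
        "alt2": (srcs[2][0], srcs[1][1]),
    }
    seen: Dict[str, str] = {}
    for label in JUNCTION_LABELS:
        s = junctions[label]
        if s in seen:
            warnings.append(f"junctions {seen[s]} and {label} coincide")
        else:
            seen[s] = label
    return JunctionModel(
        repeat=repeat,
        flank_length=flank_length,
        junctions=junctions,
        label_map=label_map,
        units=units,
        warnings=tuple(warnings),
    )


# ---------------------------------------------------------------------------
# spanning-read classification
# ---------------------------------------------------------------------------

_JUNCTION_PARTS = {
    # label -> (unit index, upstream anchor owner, downstream anchor owner)
    "ref1": (1, 1, 1),
    "ref2": (2, 2, 2),
    "alt1": (1, 1, 2),
    "alt2": (2, 2, 1),
}


def _read_seq(read: Union[str, Tuple[str, str]]) -> str:
    return read if isinstance(read, str) else read[1]


def classify_spanning_reads(
    reads: Iterable[Union[str, Tuple[str, str]]],
    jm: JunctionModel,
    min_anchor: int = 100,
    max_divergence: float = 0.15,
) -> ReadSupport:
    """Count reads spanning each junction.

    A read supports a junction when it (or its reverse complement) covers the
    full repeat unit plus at least ``min_anchor`` bases of both flanks, each
    part within ``max_divergence``.  A read matching several junctions goes to
    the best-scoring one; ties are left unassigned, as are non-spanning reads.
    """
    if not jm.junctions:
        raise ValueError("empty junction model")
    if min_anchor < 1:
        raise ValueError("min_anchor must be >= 1")
    if not (0.0 <= max_divergence < 1.0):
        raise ValueError("max_divergence must be in [0, 1)")
    if min_anchor > jm.flank_length:
        raise ValueError("min_anchor exceeds available flank length")

    u1, u2 = jm.units[1], jm.units[2]
    lu1, lu2 = len(u1), len(u2)
    # anchors: the flank bases immediately adjacent to the unit
    up_anchor = {
        k: jm.junctions[f"ref{k}"][jm.flank_length - min_anchor : jm.flank_length]
        if jm.flank_length >= min_anchor
        else jm.junctions[f"ref{k}"][: jm.flank_length]
        for k in (1, 2)
    }
    down_anchor = {
        k: jm.junctions[f"ref{k}"][
            jm.flank_length + len(jm.units[k]) : jm.flank_length
            + len(jm.units[k])
            + min_anchor
        ]
        for k in (1, 2)
    }
    masks_u1 = _align.pattern_masks(u1)
    masks_u2 = _align.pattern_masks(u2)
    probe = u1[max(0, lu1 // 2 - 32) : lu1 // 2 + 32]
    masks_probe = _align.pattern_masks(probe)
    masks_up = {k: _align.pattern_masks(up_anchor[k][::-1]) for k in (1, 2)}
    masks_down = {k: _align.pattern_masks(down_anchor[k]) for k in (1, 2)}

    counts = {label: 0 for label in JUNCTION_LABELS}
    unassigned = 0

    for read in reads:
        fwd = _read_seq(read).upper()
        if len(fwd) < lu1:
            unassigned += 1
            continue
        rc = reverse_complement(fwd)
        d_pf, _ = _align.best_infix(probe, fwd, masks_probe)
        d_pr, _ = _align.best_infix(probe, rc, masks_probe)
        seq = fwd if d_pf <= d_pr else rc
        d_u1, end1 = _align.best_infix(u1, seq, masks_u1)
        slack = math.ceil(max_divergence * lu1) + 5
        # unit2 localized near unit1's hit (units are near-identical)
        w_lo = max(0, end1 - lu2 - slack + 1)
        w_hi = min(len(seq), end1 + slack + 1)
        d_u2, end2w = _align.best_infix(u2, seq[w_lo:w_hi], masks_u2)
        end2 = w_lo + end2w
        d_unit = {1: d_u1, 2: d_u2}
        end = {1: end1, 2: end2}
        start_est = {1: end1 - lu1 + 1, 2: end2 - lu2 + 1}

        d_up: Dict[int, int] = {}
        d_down: Dict[int, int] = {}
        rseq = seq[::-1]
        nread = len(seq)
        for k in (1, 2):
            # upstream anchor must END just before the unit start: search the
            # reversed read for the reversed anchor ending near the mirrored
            # position of (start_est - 1).
            center_rev = nread - start_est[k]  # mirrored end index minus offset
            d_up[k] = _align.min_score_in(
                up_anchor[k][::-1], rseq,
                center_rev + min_anchor - 1 - slack,
                center_rev + min_anchor - 1 + slack,
                masks_up[k],
            )
            d_down[k] = _align.min_score_in(
                down_anchor[k], seq,
                end[k] + min_anchor - slack,
                end[k] + min_anchor + slack,
                masks_down[k],
            )

        best_label = None
        best_score = None
        tie = False
        for label, (uk, upk, downk) in _JUNCTION_PARTS.items():
            lu = len(jm.units[uk])
            if d_unit[uk] > max_divergence * lu:
                continue
            if d_up[upk] > max_divergence * min_anchor:
                continue
            if d_down[downk] > max_divergence * min_anchor:
                continue
            score = d_unit[uk] + d_up[upk] + d_down[downk]
            if best_score is None or score < best_score:
                best_score, best_label, tie = score, label, False
            elif score == best_score:
                tie = True
        if best_label is None or tie:
            unassigned += 1
        else:
            counts[best_label] += 1

    return ReadSupport(counts=counts, unassigned=unassigned)


# ---------------------------------------------------------------------------
# per-repeat screen
# ---------------------------------------------------------------------------


def recombination_screen(
    config: GenomeConfiguration,
    repeats: Sequence[RepeatPair],
    reads: Sequence[Union[str, Tuple[str, str]]],
    flank_length: int = 500,
    min_anchor: int = 100,
    max_divergence: float = 0.15,
    min_minor_reads: int = 3,
) -> Tuple[Dict[str, ReadSupport], List[str]]:
    """Junction building plus read classification for every repeat.

    A repeat is flagged recombination-supported when its pooled minor count
    reaches ``min_minor_reads`` (an artifact threshold; see docs).
    """
    supports: Dict[str, ReadSupport] = {}
    supported: List[str] = []
    for repeat in repeats:
        jm = build_junctions(config, repeat, flank_length)
        rs = classify_spanning_reads(reads, jm, min_anchor, max_divergence)
        supports[repeat.id] = rs
        if rs.minor_count >= min_minor_reads:
            supported.append(repeat.id)
    return supports, supported
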