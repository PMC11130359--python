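"""Circular-genome data model, coordinate arithmetic, and base composition.

Coordinates are 1-based inclusive everywhere at the API surface.  On a
circular chromosome an interval whose ``start`` exceeds its ``end`` wraps
through the origin.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Tuple

__all__ = [
    "Topology",
    "CircularChromosome",
    "GenomeConfiguration",
    "CircularInterval",
    "CompositionReport",
    "reverse_complement",
    "extract_subsequence",
    "rotate",
    "base_composition",
    "least_rotation_offset",
    "canonical_rotation",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
ALPHABET = frozenset("ACGTN")


class Topology(str, enum.Enum):
    CIRCULAR = "circular"
    LINEAR = "linear"


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement, reversed.  N complements to N."""
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"unknown character(s) in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularChromosome:
    """A named circular (or linear) DNA sequence."""

    id: str
    sequence: str
    topology: Topology = Topology.CIRCULAR

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"chromosome {self.id!r}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"chromosome {self.id!r}: illegal character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology is Topology.CIRCULAR


@dataclass(frozen=True)
class GenomeConfiguration:
    """One arrangement of a multipartite genome: an ordered set of chromosomes."""

    name: str
    chromosomes: Tuple[CircularChromosome, ...]
    provenance: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError(f"configuration {self.name!r} has no chromosomes")
        ids = [c.id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"configuration {self.name!r}: duplicate chromosome ids")
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))

    def chromosome(self, chrom_id: str) -> CircularChromosome:
        for c in self.chromosomes:
            if c.id == chrom_id:
                return c
        raise KeyError(f"no chromosome {chrom_id!r} in configuration {self.name!r}")

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.chromosomes)


@dataclass(frozen=True)
class CircularInterval:
    """1-based inclusive interval; start > end denotes wrap through the origin."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"interval positions must be >= 1: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-': {self.strand!r}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, chrom_length: int) -> int:
        if self.wraps:
            return chrom_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def footprint(self) -> Tuple[int, int]:
        """(low, high) plus-strand footprint; only valid for non-wrapping intervals."""
        if self.wraps:
            raise ValueError(f"footprint undefined for wrapping interval {self}")
        return self.start, self.end

    def positions(self, chrom_length: int) -> Iterable[int]:
        """Genomic positions in 5'->3' order along ``strand``."""
        if self.wraps:
            fwd = list(range(self.start, chrom_length + 1)) + list(
                range(1, self.end + 1)
            )
        else:
            fwd = list(range(self.start, self.end + 1))
        return reversed(fwd) if self.strand == "-" else fwd


def extract_subsequence(chrom: CircularChromosome, iv: CircularInterval) -> str:
    """Bases from start to end inclusive, wrapping through the origin if needed.

    Strand "-" returns the reverse complement.
    """
    if iv.chrom != chrom.id:
        raise ValueError(f"interval chrom {iv.chrom!r} does not match {chrom.id!r}")
    n = len(chrom)
    if iv.start > n or iv.end > n:
        raise ValueError(f"interval {iv} out of range for length-{n} chromosome")
    if iv.wraps:
        if not chrom.is_circular:
            raise ValueError(f"wrap requested on linear chromosome {chrom.id!r}")
        seq = chrom.sequence[iv.start - 1 :] + chrom.sequence[: iv.end]
    else:
        seq = chrom.sequence[iv.start - 1 : iv.end]
    return reverse_complement(seq) if iv.strand == "-" else seq


def rotate(chrom: CircularChromosome, offset: int) -> CircularChromosome:
    """Rotate so that former position ``offset + 1`` becomes position 1."""
    if not chrom.is_circular:
        raise ValueError(f"rotation requested on linear chromosome {chrom.id!r}")
    k = offset % len(chrom)
    return CircularChromosome(
        id=chrom.id,
        sequence=chrom.sequence[k:] + chrom.sequence[:k],
        topology=chrom.topology,
    )


def least_rotation_offset(s: str) -> int:
    """Offset of the lexicographically minimal rotation (Booth's algorithm)."""
    ss = s + s
    n = len(s)
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k % n


def canonical_rotation(chrom: CircularChromosome) -> CircularChromosome:
    """Rotate a circular chromosome to its lexicographically minimal rotation."""
    if not chrom.is_circular:
        return chrom
    return rotate(chrom, least_rotation_offset(chrom.sequence))


@dataclass(frozen=True)
class CompositionReport:
    """Pooled per-base counts and proportions for a genome configuration."""

    counts: Mapping[str, int]  # keys A,C,G,T,N
    proportions: Mapping[str, float] = field(default_factory=dict)  # keys A,C,G,T
    gc_percent: float = 0.0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def base_composition(
    config: GenomeConfiguration, include_n_in_denominator: bool = True
) -> CompositionReport:
    """Base counts pooled over all chromosomes, with GC percentage.

    ``include_n_in_denominator`` keeps N in the denominator of all
    proportions (the default); with the flag off, N bases are counted but
    excluded from the GC and proportion denominators.
    """
    counts = {b: 0 for b in "ACGTN"}
    for c in config.chromosomes:
        for b in "ACGTN":
            counts[b] += c.sequence.count(b)
    denom = sum(counts.values()) if include_n_in_denominator else (
        counts["A"] + counts["C"] + counts["G"] + counts["T"]
    )
    if denom == 0:
        raise ValueError("empty configuration: nothing to summarize")
    proportions = {b: counts[b] / denom for b in "ACGT"}
    gc = 100.0 * (counts["G"] + counts["C"]) / denom
    return CompositionReport(counts=counts, proportions=proportions, gc_percent=gc)
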