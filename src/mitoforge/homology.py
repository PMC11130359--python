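"""Homologous segments between the mitogenome and another genome
(plastome for MTPT, nuclear contigs for NUMT), with summaries.

Thresholds are plain length/identity filters rather than E-values; extension
scoring uses the +2/-3 match/mismatch scheme.  Segments repeated in the
subject (e.g. plastome inverted-repeat copies) are reported once per copy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

from . import _align
from .genome import CircularInterval, GenomeConfiguration, reverse_complement
from .editing import GeneModel

__all__ = [
    "HomologySegment",
    "TransferSummary",
    "PRESETS",
    "find_homologous_segments",
    "summarize_transfers",
    "classify_transferred_genes",
]

_MATCH_SCORE = 2
_MISMATCH_SCORE = -3

#: parameter presets per comparison direction
PRESETS: Mapping[str, Mapping[str, float]] = {
    "mtpt": {"min_length": 100, "min_identity": 70.0, "seed_size": 11},
    "numt": {"min_length": 100, "min_identity": 70.0, "seed_size": 11},
}


@dataclass(frozen=True)
class HomologySegment:
    query: CircularInterval
    subject: CircularInterval
    length: int
    identity_percent: float
    score: int


@dataclass(frozen=True)
class TransferSummary:
    n_segments: int
    total_bp: int
    fraction_percent: float
    longest_bp: int
    shortest_bp: int


def find_homologous_segments(
    query: GenomeConfiguration,
    subject: GenomeConfiguration,
    min_length: int = 100,
    min_identity: float = 70.0,
    seed_size: int = 11,
) -> List[HomologySegment]:
    """Locally maximal ungapped alignments between two genomes, both strands,
    each reported once; hits shorter than ``min_length`` are discarded."""
    if not query.chromosomes or not subject.chromosomes:
        raise ValueError("empty input genome")
    segments: List[HomologySegment] = []
    for qc in query.chromosomes:
        for sc in subject.chromosomes:
            for strand in ("+", "-"):
                text = sc.sequence if strand == "+" else reverse_complement(sc.sequence)
                for a0, a1, b0, b1, mm in _align.scan_pair(
                    qc.sequence,
                    text,
                    seed_size=seed_size,
                    min_length=min_length,
                    min_identity=min_identity,
                    same_sequence=False,
                ):
                    if strand == "+":
                        s_iv = CircularInterval(sc.id, b0 + 1, b1, "+")
                    else:
                        ns = len(sc)
                        s_iv = CircularInterval(sc.id, ns - b1 + 1, ns - b0, "-")
                    length = a1 - a0
                    segments.append(
                        HomologySegment(
                            query=CircularInterval(qc.id, a0 + 1, a1, "+"),
                            subject=s_iv,
                            length=length,
                            identity_percent=100.0 * (length - mm) / length,
                            score=_MATCH_SCORE * (length - mm) + _MISMATCH_SCORE * mm,
                        )
                    )
    segments.sort(
        key=lambda s: (-s.length, s.query.chrom, s.query.start, s.subject.chrom,
                       s.subject.start, s.subject.strand)
    )
    return segments


def summarize_transfers(
    segments: Sequence[HomologySegment], mito_length: int
) -> TransferSummary:
    """Count, total bp, genome fraction (two decimals), longest and shortest.

    Overlapping query segments are NOT merged: total_bp is the simple sum.
    """
    if mito_length <= 0:
        raise ValueError("mito_length must be positive")
    if not segments:
        return TransferSummary(0, 0, 0.0, 0, 0)
    lengths = [s.length for s in segments]
    total = sum(lengths)
    return TransferSummary(
        n_segments=len(segments),
        total_bp=total,
        fraction_percent=round(100.0 * total / mito_length, 2),
        longest_bp=max(lengths),
        shortest_bp=min(lengths),
    )


def classify_transferred_genes(
    segments: Sequence[HomologySegment], annotation: Sequence[GeneModel]
) -> Dict[str, str]:
    """Per-gene transfer status on the subject genome.

    complete: some segment's subject interval fully contains the gene span;
    partial: properly overlapped; absent: no overlap.
    """
    result: Dict[str, str] = {}
    for gene in annotation:
        glo = min(min(e.start, e.end) for e in gene.exons)
        ghi = max(max(e.start, e.end) for e in gene.exons)
        status = "absent"
        for seg in segments:
            if seg.subject.chrom != gene.chrom:
                continue
            slo = min(seg.subject.start, seg.subject.end)
            shi = max(seg.subject.start, seg.subject.end)
            if slo <= glo and ghi <= shi:
                status = "complete"
                break
            if slo <= ghi and glo <= shi:
                status = "partial"
        result[gene.gene_id] = status
    return result
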