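"""C-to-U RNA editing: site calling from pileups with DNA SNP masking, and
codon-consequence annotation (including start/stop-codon acquisition).

Plant mitochondria translate with the standard genetic code, which is what
makes the canonical ACG->AUG start gain and UAA/UAG/UGA stop gains possible
through a single C->U event.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from Bio.Seq import Seq

from .genome import (
    CircularChromosome,
    CircularInterval,
    GenomeConfiguration,
    extract_subsequence,
)

__all__ = [
    "GeneModel",
    "SiteCoverage",
    "EditingSite",
    "SNPMask",
    "EditingSummary",
    "build_cds",
    "cds_genomic_positions",
    "call_dna_variants",
    "call_editing_sites",
    "annotate_effect",
    "summarize_editing",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
#: Kyte-Doolittle hydropathy > 0
HYDROPHOBIC: FrozenSet[str] = frozenset("ACFILMV")


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene as an ordered list of exon intervals.

    Exons are listed in transcription order (which may differ from genomic
    order, e.g. for trans-spliced genes); minus-strand exons are extracted as
    reverse complements.
    """

    gene_id: str
    chrom: str
    exons: Tuple[CircularInterval, ...]
    strand: str
    codon_start: int = 0
    copy: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id!r} has no exons")

    @property
    def key(self) -> Tuple[str, int]:
        return (self.gene_id, self.copy)


@dataclass(frozen=True)
class SiteCoverage:
    """Per-position base counts from aligned reads (RNA or DNA)."""

    chrom: str
    position: int  # 1-based
    ref_base: str
    counts: Mapping[str, int]  # keys A,C,G,T
    source: str = "RNA"

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class SNPMask:
    positions: FrozenSet[Tuple[str, int]]

    def __contains__(self, item: Tuple[str, int]) -> bool:
        return item in self.positions


@dataclass(frozen=True)
class EditingSite:
    gene_id: str
    copy: int
    chrom: str
    genomic_position: int
    cds_position: int  # 1-based offset in the spliced CDS
    codon_index: int  # 1-based codon number
    codon_position: int  # 1 | 2 | 3
    ref_codon: str
    edited_codon: str
    ref_aa: str
    edited_aa: str
    extent: float
    effect: str = ""
    hydropathy_shift: str = "none"


@dataclass(frozen=True)
class EditingSummary:
    per_gene: Mapping[str, int]
    aa_changes: Mapping[Tuple[str, str], int]
    codon_positions: Mapping[int, int]
    effects: Mapping[str, int]
    total: int


# ---------------------------------------------------------------------------
# CDS assembly
# ---------------------------------------------------------------------------


def build_cds(gene: GeneModel, genome: GenomeConfiguration) -> str:
    """Spliced CDS: strand-aware, wrap-aware exon extraction, concatenated in
    the listed (transcription) order."""
    chrom = genome.chromosome(gene.chrom)
    parts = []
    for exon in gene.exons:
        iv = CircularInterval(exon.chrom, exon.start, exon.end, gene.strand)
        parts.append(extract_subsequence(chrom, iv))
    return "".join(parts)


def cds_genomic_positions(gene: GeneModel, genome: GenomeConfiguration) -> List[int]:
    """Genomic position (1-based) of every spliced-CDS base, in CDS order."""
    chrom = genome.chromosome(gene.chrom)
    n = len(chrom)
    out: List[int] = []
    for exon in gene.exons:
        iv = CircularInterval(exon.chrom, exon.start, exon.end, gene.strand)
        out.extend(iv.positions(n))
    return out


# ---------------------------------------------------------------------------
# variant and editing-site calling
# ---------------------------------------------------------------------------


def call_dna_variants(
    pileups: Iterable[SiteCoverage], min_cov: int = 5, min_freq: float = 0.1
) -> SNPMask:
    """Mask positions where DNA coverage >= ``min_cov`` and any non-reference
    base reaches frequency >= ``min_freq``."""
    masked: Set[Tuple[str, int]] = set()
    for p in pileups:
        total = p.total
        if total < min_cov:
            continue
        for base, count in p.counts.items():
            if base != p.ref_base and count / total >= min_freq:
                masked.add((p.chrom, p.position))
                break
    return SNPMask(positions=frozenset(masked))


def call_editing_sites(
    rna_pileups: Iterable[SiteCoverage],
    genes: Sequence[GeneModel],
    genome: GenomeConfiguration,
    mask: Optional[SNPMask] = None,
    min_cov: int = 5,
    min_freq: float = 0.1,
) -> List[EditingSite]:
    """Call C->U editing sites inside spliced CDS regions.

    A site is called when the coding-strand reference base is C, RNA coverage
    is at least ``min_cov``, the editing extent (T / (C + T) on the coding
    strand) is at least ``min_freq``, and the position is not SNP-masked.
    Duplicate gene copies yield one site per copy.
    """
    mask = mask or SNPMask(frozenset())
    lookup: Dict[Tuple[str, int], SiteCoverage] = {
        (p.chrom, p.position): p for p in rna_pileups
    }
    sites: List[EditingSite] = []
    for gene in genes:
        cds = build_cds(gene, genome)
        positions = cds_genomic_positions(gene, genome)
        for idx0, gpos in enumerate(positions):
            if idx0 < gene.codon_start:
                continue
            if cds[idx0] != "C":
                continue
            cov = lookup.get((gene.chrom, gpos))
            if cov is None or cov.total < min_cov:
                continue
            if gene.strand == "+":
                edited, unedited = cov.counts.get("T", 0), cov.counts.get("C", 0)
            else:  # C->U on a minus-strand gene appears as G->A on the genome
                edited, unedited = cov.counts.get("A", 0), cov.counts.get("G", 0)
            informative = edited + unedited
            if informative == 0:
                continue
            extent = edited / informative
            if extent < min_freq:
                continue
            if (gene.chrom, gpos) in mask:
                continue
            frame = idx0 - gene.codon_start
            codon_index = frame // 3 + 1
            codon_position = frame % 3 + 1
            c0 = gene.codon_start + 3 * (codon_index - 1)
            ref_codon = cds[c0 : c0 + 3]
            if len(ref_codon) < 3:
                continue  # trailing partial codon
            edited_codon = (
                ref_codon[: codon_position - 1] + "T" + ref_codon[codon_position:]
            )
            site = EditingSite(
                gene_id=gene.gene_id,
                copy=gene.copy,
                chrom=gene.chrom,
                genomic_position=gpos,
                cds_position=idx0 + 1,
                codon_index=codon_index,
                codon_position=codon_position,
                ref_codon=ref_codon,
                edited_codon=edited_codon,
                ref_aa="",
                edited_aa="",
                extent=extent,
            )
            sites.append(annotate_effect(site))
    return sites


# ---------------------------------------------------------------------------
# codon consequences
# ---------------------------------------------------------------------------


def _translate(codon: str) -> str:
    if codon in STOP_CODONS:
        return "*"
    return str(Seq(codon).translate())


def annotate_effect(site: EditingSite) -> EditingSite:
    """Fill effect and hydropathy-shift from the standard genetic code.

    Effects: start_gain (first codon becomes ATG), stop_gain, stop_loss,
    synonymous, nonsynonymous.
    """
    ref_codon, edited_codon = site.ref_codon, site.edited_codon
    if "N" in ref_codon or "N" in edited_codon:
        raise ValueError(f"codon with N at {site.gene_id}:{site.cds_position}")
    if edited_codon == ref_codon:
        raise ValueError("edited codon equals reference codon")
    if ref_codon[site.codon_position - 1] != "C":
        raise ValueError("edit is not at a reference C")
    ref_aa = _translate(ref_codon)
    edited_aa = _translate(edited_codon)
    if site.codon_index == 1 and edited_codon == "ATG" and ref_codon != "ATG":
        effect = "start_gain"
    elif edited_codon in STOP_CODONS and ref_codon not in STOP_CODONS:
        effect = "stop_gain"
    elif ref_codon in STOP_CODONS and edited_codon not in STOP_CODONS:
        effect = "stop_loss"
    elif ref_aa == edited_aa:
        effect = "synonymous"
    else:
        effect = "nonsynonymous"
    shift = "none"
    if "*" not in (ref_aa, edited_aa):
        ref_h = ref_aa in HYDROPHOBIC
        new_h = edited_aa in HYDROPHOBIC
        if not ref_h and new_h:
            shift = "hydrophilic->hydrophobic"
        elif ref_h and not new_h:
            shift = "hydrophobic->hydrophilic"
    return EditingSite(
        **{
            **site.__dict__,
            "ref_aa": ref_aa,
            "edited_aa": edited_aa,
            "effect": effect,
            "hydropathy_shift": shift,
        }
    )


def summarize_editing(sites: Sequence[EditingSite]) -> EditingSummary:
    per_gene = Counter(s.gene_id for s in sites)
    aa_changes = Counter((s.ref_aa, s.edited_aa) for s in sites)
    codon_positions = Counter(s.codon_position for s in sites)
    effects = Counter(s.effect for s in sites)
    return EditingSummary(
        per_gene=dict(per_gene),
        aa_changes=dict(aa_changes),
        codon_positions={k: codon_positions.get(k, 0) for k in (1, 2, 3)},
        effects=dict(effects),
        total=len(sites),
    )
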