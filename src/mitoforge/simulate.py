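"""Synthetic multipartite mitogenomes, long-read mixtures, and RNA/DNA
pileups with planted truth, so every pipeline stage is testable offline.

All generators are deterministic for a fixed seed.  Long-read errors use a
substitution:insertion:deletion mix of 2:1:1 (nanopore-like); pileup errors
are substitutions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .editing import GeneModel, SiteCoverage
from .genome import (
    CircularChromosome,
    CircularInterval,
    GenomeConfiguration,
    Topology,
    extract_subsequence,
    reverse_complement,
)
from .repeats import RepeatPair, SSRRecord

__all__ = [
    "PlantedRepeat",
    "PlantedSSR",
    "PlantedGene",
    "MitogenomeSpec",
    "MitogenomeTruth",
    "LongReadSpec",
    "ReadTruth",
    "EditingPlan",
    "EditingTruth",
    "generate_mitogenome",
    "simulate_long_reads",
    "simulate_editing_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class PlantedRepeat:
    length: int
    identity: float  # percent
    orientation: str  # "direct" | "inverted"
    chrom1: int  # index into chromosome list
    chrom2: int


@dataclass(frozen=True)
class PlantedSSR:
    motif: str
    copies: int
    chrom: int


@dataclass(frozen=True)
class PlantedGene:
    length: int  # CDS length, rounded up to a codon multiple
    strand: str
    exon_count: int = 1
    chrom: int = 0


@dataclass(frozen=True)
class MitogenomeSpec:
    chromosome_lengths: Tuple[int, ...]
    gc_target: float = 0.45
    repeats: Tuple[PlantedRepeat, ...] = ()
    ssrs: Tuple[PlantedSSR, ...] = ()
    genes: Tuple[PlantedGene, ...] = ()
    seed: int = 0
    name: str = "synthetic"


@dataclass(frozen=True)
class MitogenomeTruth:
    repeats: Tuple[RepeatPair, ...]
    ssrs: Tuple[SSRRecord, ...]
    genes: Tuple[GeneModel, ...]


@dataclass(frozen=True)
class LongReadSpec:
    mixture: Mapping[str, float]  # configuration name -> proportion
    n_reads: Optional[int] = None
    depth: Optional[float] = None
    length_mean: float = 8000.0
    length_sd: float = 2000.0
    error_rate: float = 0.0
    seed: int = 0
    #: optional per-configuration interval every read must fully span
    span_targets: Mapping[str, Tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")
        if not (0.0 <= self.error_rate <= 0.3):
            raise ValueError("error_rate must be in [0, 0.3]")
        if self.n_reads is None and self.depth is None:
            raise ValueError("specify n_reads or depth")


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    config: str
    chrom: str
    start: int  # 1-based template start (before errors)
    length: int  # template length
    strand: str


@dataclass(frozen=True)
class EditingPlan:
    sites: Tuple[Tuple[str, int, float], ...]  # (gene_id, cds_position, extent)
    snps: Tuple[Tuple[str, int, str, float], ...] = ()  # (chrom, pos, alt, freq)
    rna_depth: float = 30.0
    dna_depth: float = 30.0
    error_rate: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class EditingTruth:
    sites: Tuple[Tuple[str, int, int, float], ...]  # (gene_id, cds_pos, genomic_pos, extent)
    snp_positions: Tuple[Tuple[str, int], ...]


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=length, p=p)


def _find_slot(
    rng: np.random.Generator,
    occupied: List[Tuple[int, int]],
    chrom_len: int,
    size: int,
    margin: int = 2,
    tries: int = 200,
) -> int:
    """0-based start of a free [start, start+size) slot, margin-separated."""
    for _ in range(tries):
        start = int(rng.integers(margin, chrom_len - size - margin))
        if all(start + size + margin <= lo or start >= hi + margin for lo, hi in occupied):
            occupied.append((start, start + size))
            return start
    raise RuntimeError("infeasible placement: no free slot after bounded retries")


def _mutate_copy(
    rng: np.random.Generator, unit: np.ndarray, identity: float
) -> Tuple[np.ndarray, int]:
    n_mut = int(round(len(unit) * (1.0 - identity / 100.0)))
    copy = unit.copy()
    if n_mut == 0:
        return copy, 0
    # avoid the outermost bases so planted endpoints stay maximal
    pos = rng.choice(np.arange(2, len(unit) - 2), size=n_mut, replace=False)
    for p in pos:
        choices = _BASES[_BASES != copy[p]]
        copy[p] = rng.choice(choices)
    return copy, n_mut


_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def generate_mitogenome(spec: MitogenomeSpec) -> Tuple[GenomeConfiguration, MitogenomeTruth]:
    """Random multipartite genome with planted repeats, SSRs, and genes.

    Byte-identical output for a fixed seed; truth tables carry the exact
    planted coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    arrays = [
        _random_sequence(rng, n, spec.gc_target) for n in spec.chromosome_lengths
    ]
    occupied: Dict[int, List[Tuple[int, int]]] = {i: [] for i in range(len(arrays))}
    chrom_ids = [f"chr{i + 1}" for i in range(len(arrays))]

    truth_repeats: List[RepeatPair] = []
    for ridx, pr in enumerate(spec.repeats, start=1):
        unit = _random_sequence(rng, pr.length, spec.gc_target)
        s1 = _find_slot(rng, occupied[pr.chrom1], len(arrays[pr.chrom1]), pr.length)
        arrays[pr.chrom1][s1 : s1 + pr.length] = unit
        copy, mm = _mutate_copy(rng, unit, pr.identity)
        if pr.orientation == "inverted":
            placed = np.frombuffer(
                reverse_complement(copy.tobytes().decode()).encode(), dtype="S1"
            ).copy()
        else:
            placed = copy
        s2 = _find_slot(rng, occupied[pr.chrom2], len(arrays[pr.chrom2]), pr.length)
        arrays[pr.chrom2][s2 : s2 + pr.length] = placed
        u1 = CircularInterval(chrom_ids[pr.chrom1], s1 + 1, s1 + pr.length, "+")
        u2 = CircularInterval(
            chrom_ids[pr.chrom2],
            s2 + 1,
            s2 + pr.length,
            "-" if pr.orientation == "inverted" else "+",
        )
        truth_repeats.append(
            RepeatPair(
                id=f"PR{ridx}",
                unit1=u1,
                unit2=u2,
                orientation=pr.orientation,
                alignment_length=pr.length,
                identity_percent=100.0 * (pr.length - mm) / pr.length,
                mismatches=mm,
                gap_openings=0,
                score=2 * (pr.length - mm) - 3 * mm,
            )
        )

    truth_ssrs: List[SSRRecord] = []
    for ps in spec.ssrs:
        run = (ps.motif * ps.copies).encode()
        size = len(run)
        start = _find_slot(rng, occupied[ps.chrom], len(arrays[ps.chrom]), size)
        arr = arrays[ps.chrom]
        arr[start : start + size] = np.frombuffer(run, dtype="S1")
        u = len(ps.motif)
        # break the run at both boundaries so the planted copy number is exact
        left_block = ps.motif[u - 1].encode()
        right_block = ps.motif[0].encode()
        arr[start - 1] = rng.choice(_BASES[_BASES != np.bytes_(left_block)])
        arr[start + size] = rng.choice(_BASES[_BASES != np.bytes_(right_block)])
        truth_ssrs.append(
            SSRRecord(
                chrom=chrom_ids[ps.chrom],
                motif=ps.motif,
                unit_size=u,
                copies=ps.copies,
                start=start + 1,
                end=start + size,
            )
        )

    truth_genes: List[GeneModel] = []
    for gidx, pg in enumerate(spec.genes, start=1):
        n_codons = max(3, -(-pg.length // 3))
        body = ["ATG"]
        body += [
            _NON_STOP_CODONS[int(rng.integers(len(_NON_STOP_CODONS)))]
            for _ in range(n_codons - 2)
        ]
        body.append("TAA")
        cds = "".join(body)
        exon_count = max(1, pg.exon_count)
        cuts = sorted(
            int(c)
            for c in rng.choice(
                np.arange(30, len(cds) - 30), size=exon_count - 1, replace=False
            )
        ) if exon_count > 1 else []
        pieces = [
            cds[a:b] for a, b in zip([0] + cuts, cuts + [len(cds)])
        ]
        introns = [int(rng.integers(60, 200)) for _ in range(exon_count - 1)]
        block = sum(len(p) for p in pieces) + sum(introns)
        start = _find_slot(rng, occupied[pg.chrom], len(arrays[pg.chrom]), block)
        arr = arrays[pg.chrom]
        exons: List[CircularInterval] = []
        cursor = start
        ordered = pieces if pg.strand == "+" else pieces[::-1]
        for i, piece in enumerate(ordered):
            seq = piece if pg.strand == "+" else reverse_complement(piece)
            arr[cursor : cursor + len(piece)] = np.frombuffer(seq.encode(), dtype="S1")
            exons.append(
                CircularInterval(
                    chrom_ids[pg.chrom], cursor + 1, cursor + len(piece), pg.strand
                )
            )
            if i < len(introns):
                cursor += len(piece) + introns[i]
            else:
                cursor += len(piece)
        if pg.strand == "-":
            exons = exons[::-1]  # transcription order
        truth_genes.append(
            GeneModel(
                gene_id=f"g{gidx}",
                chrom=chrom_ids[pg.chrom],
                exons=tuple(exons),
                strand=pg.strand,
            )
        )

    chroms = tuple(
        CircularChromosome(chrom_ids[i], arrays[i].tobytes().decode())
        for i in range(len(arrays))
    )
    config = GenomeConfiguration(name=spec.name, chromosomes=chroms)
    return config, MitogenomeTruth(
        repeats=tuple(truth_repeats),
        ssrs=tuple(truth_ssrs),
        genes=tuple(truth_genes),
    )


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------


def _apply_long_read_errors(
    rng: np.random.Generator, seq: str, error_rate: float
) -> str:
    if error_rate <= 0:
        return seq
    out: List[str] = []
    for base in seq:
        if rng.random() < error_rate:
            kind = rng.random()
            if kind < 0.5:  # substitution
                choices = [b for b in "ACGT" if b != base]
                out.append(choices[int(rng.integers(3))])
            elif kind < 0.75:  # insertion
                out.append(base)
                out.append("ACGT"[int(rng.integers(4))])
            # else deletion: emit nothing
        else:
            out.append(base)
    return "".join(out)


def simulate_long_reads(
    configs: Sequence[GenomeConfiguration], spec: LongReadSpec
) -> Tuple[List[Tuple[str, str]], List[ReadTruth]]:
    """Reads drawn from circular templates at the given mixture proportions.

    Returns (reads, truth); reads are (id, sequence) pairs.  When
    ``span_targets`` names an interval for a configuration, every read from
    that configuration is placed to cover the interval entirely.
    """
    by_name = {c.name: c for c in configs}
    for key in spec.mixture:
        if key not in by_name:
            raise ValueError(f"mixture names unknown configuration {key!r}")
    rng = np.random.default_rng(spec.seed)
    names = sorted(spec.mixture)
    probs = np.array([spec.mixture[n] for n in names])

    if spec.n_reads is not None:
        n_reads = spec.n_reads
        target_bases = None
    else:
        avg_total = sum(
            spec.mixture[n] * by_name[n].total_length for n in names
        )
        target_bases = spec.depth * avg_total
        n_reads = None

    reads: List[Tuple[str, str]] = []
    truth: List[ReadTruth] = []
    bases = 0
    i = 0
    while True:
        if n_reads is not None and i >= n_reads:
            break
        if target_bases is not None and bases >= target_bases:
            break
        cfg_name = names[int(rng.choice(len(names), p=probs))]
        cfg = by_name[cfg_name]
        length = max(50, int(rng.normal(spec.length_mean, spec.length_sd)))
        target = spec.span_targets.get(cfg_name)
        if target is not None:
            chrom = cfg.chromosome(target[0])
            span = target[2] - target[1] + 1
            length = max(length, span + 2)
            lo = target[2] - length + 1
            start0 = int(rng.integers(lo, target[1] + 1)) - 1  # 1-based -> 0-based
            start0 %= len(chrom)
        else:
            weights = np.array([len(c) for c in cfg.chromosomes], dtype=float)
            chrom = cfg.chromosomes[
                int(rng.choice(len(cfg.chromosomes), p=weights / weights.sum()))
            ]
            start0 = int(rng.integers(0, len(chrom)))
        n = len(chrom)
        if chrom.is_circular:
            length = min(length, n)
            end0 = (start0 + length - 1) % n
            template = extract_subsequence(
                chrom, CircularInterval(chrom.id, start0 + 1, end0 + 1, "+")
            )
        else:
            template = chrom.sequence[start0 : start0 + length]
            length = len(template)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = template if strand == "+" else reverse_complement(template)
        seq = _apply_long_read_errors(rng, seq, spec.error_rate)
        rid = f"read{i:06d}"
        reads.append((rid, seq))
        truth.append(
            ReadTruth(
                read_id=rid,
                config=cfg_name,
                chrom=chrom.id,
                start=start0 + 1,
                length=length,
                strand=strand,
            )
        )
        bases += len(seq)
        i += 1
    return reads, truth


# ---------------------------------------------------------------------------
# RNA/DNA pileups
# ---------------------------------------------------------------------------


def _count_with_errors(
    rng: np.random.Generator, n: int, base: str, error_rate: float
) -> Dict[str, int]:
    counts = {b: 0 for b in "ACGT"}
    if error_rate <= 0:
        counts[base] = n
        return counts
    errors = rng.binomial(n, error_rate)
    counts[base] = n - errors
    others = [b for b in "ACGT" if b != base]
    for _ in range(errors):
        counts[others[int(rng.integers(3))]] += 1
    return counts


def _merge(a: Dict[str, int], b: Dict[str, int]) -> Dict[str, int]:
    return {k: a.get(k, 0) + b.get(k, 0) for k in "ACGT"}


def simulate_editing_reads(
    genome: GenomeConfiguration,
    genes: Sequence[GeneModel],
    plan: EditingPlan,
) -> Tuple[List[SiteCoverage], List[SiteCoverage], EditingTruth]:
    """RNA and DNA pileups over all CDS positions with planted editing sites
    and DNA-level SNPs.

    Each RNA read at a planted site carries T (coding strand) independently
    with probability = extent.  SNP alleles appear in both DNA and RNA at the
    planted allele frequency.
    """
    from .editing import build_cds, cds_genomic_positions

    rng = np.random.default_rng(plan.seed)
    gene_by_id = {g.gene_id: g for g in genes}
    site_map: Dict[Tuple[str, int], float] = {}
    truth_sites: List[Tuple[str, int, int, float]] = []
    for gene_id, cds_pos, extent in plan.sites:
        gene = gene_by_id[gene_id]
        cds = build_cds(gene, genome)
        if not (1 <= cds_pos <= len(cds)):
            raise ValueError(f"cds position {cds_pos} outside {gene_id}")
        if cds[cds_pos - 1] != "C":
            raise ValueError(
                f"planted site {gene_id}:{cds_pos} is not a coding-strand C"
            )
        gpos = cds_genomic_positions(gene, genome)[cds_pos - 1]
        site_map[(gene.chrom, gpos)] = extent
        truth_sites.append((gene_id, cds_pos, gpos, extent))

    snp_map: Dict[Tuple[str, int], Tuple[str, float]] = {
        (chrom, pos): (alt, freq) for chrom, pos, alt, freq in plan.snps
    }

    covered: Dict[Tuple[str, int], str] = {}  # (chrom, gpos) -> gene strand
    for gene in genes:
        for gpos in cds_genomic_positions(gene, genome):
            covered[(gene.chrom, gpos)] = gene.strand

    rna: List[SiteCoverage] = []
    dna: List[SiteCoverage] = []
    for (chrom_id, gpos), strand in sorted(covered.items()):
        chrom = genome.chromosome(chrom_id)
        ref = chrom.sequence[gpos - 1]

        n_rna = int(rng.poisson(plan.rna_depth))
        extent = site_map.get((chrom_id, gpos))
        snp = snp_map.get((chrom_id, gpos))
        counts = {b: 0 for b in "ACGT"}
        remaining = n_rna
        if extent is not None:
            edited_base = "T" if strand == "+" else "A"
            n_ed = int(rng.binomial(n_rna, extent))
            counts = _merge(
                counts, _count_with_errors(rng, n_ed, edited_base, plan.error_rate)
            )
            remaining -= n_ed
        if snp is not None:
            alt, freq = snp
            n_alt = int(rng.binomial(remaining, freq))
            counts = _merge(counts, _count_with_errors(rng, n_alt, alt, plan.error_rate))
            remaining -= n_alt
        counts = _merge(counts, _count_with_errors(rng, remaining, ref, plan.error_rate))
        rna.append(
            SiteCoverage(chrom=chrom_id, position=gpos, ref_base=ref, counts=counts,
                         source="RNA")
        )

        n_dna = int(rng.poisson(plan.dna_depth))
        counts_d = {b: 0 for b in "ACGT"}
        rem = n_dna
        if snp is not None:
            alt, freq = snp
            n_alt = int(rng.binomial(n_dna, freq))
            counts_d = _merge(
                counts_d, _count_with_errors(rng, n_alt, alt, plan.error_rate)
            )
            rem -= n_alt
        counts_d = _merge(counts_d, _count_with_errors(rng, rem, ref, plan.error_rate))
        dna.append(
            SiteCoverage(chrom=chrom_id, position=gpos, ref_base=ref, counts=counts_d,
                         source="DNA")
        )

    return rna, dna, EditingTruth(
        sites=tuple(truth_sites), snp_positions=tuple(sorted(snp_map))
    )
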