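"""Readers and writers for FASTA, FASTQ, GFF3, SAM pileups, and the TSV
dialects shared by the pipeline stages.

TSV conventions: tab-separated, header row mandatory, "." for missing.
Inverted repeat units are written with start > end (minus-strand unit
occupying [end, start] on the plus strand), matching the usual tabular
convention for repeat pairs; the reader reverses the transformation.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pysam
from Bio import SeqIO
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .editing import EditingSite, GeneModel, SiteCoverage
from .genome import (
    ALPHABET,
    CircularChromosome,
    CircularInterval,
    CompositionReport,
    GenomeConfiguration,
    Topology,
)
from .homology import HomologySegment
from .recombination import JunctionModel, ReadSupport
from .repeats import RepeatPair, SSRRecord, TandemRepeat

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_gff3",
    "read_sam_pileup",
    "read_pileup_tsv",
    "write_pileup_tsv",
    "write_repeats_tsv",
    "read_repeats_tsv",
    "write_ssr_tsv",
    "write_tandem_tsv",
    "write_segments_tsv",
    "write_support_tsv",
    "write_editing_tsv",
    "write_composition_tsv",
    "write_junctions_fasta",
]

PathLike = Union[str, Path]


def _validate_fasta_characters(path: PathLike) -> None:
    record = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                record = line[1:].split()[0] if len(line) > 1 else "<unnamed>"
                continue
            bad = set(line.upper()) - ALPHABET
            if bad:
                raise ValueError(
                    f"illegal character(s) {sorted(bad)} in record "
                    f"{record!r} at line {lineno} of {path}"
                )


def read_fasta(
    path: PathLike,
    name: Optional[str] = None,
    default_topology: Topology = Topology.CIRCULAR,
) -> GenomeConfiguration:
    """Load a multi-record FASTA as a genome configuration.

    Sequences are uppercased; topology defaults to circular and can be
    overridden per record with a ``topology=linear`` header token.
    """
    _validate_fasta_characters(path)
    chroms: List[CircularChromosome] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        topology = default_topology
        if "topology=linear" in rec.description:
            topology = Topology.LINEAR
        elif "topology=circular" in rec.description:
            topology = Topology.CIRCULAR
        chroms.append(
            CircularChromosome(rec.id, str(rec.seq).upper(), topology)
        )
    if not chroms:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeConfiguration(
        name=name or Path(path).stem, chromosomes=tuple(chroms)
    )


def write_fasta(config: GenomeConfiguration, path: PathLike, wrap: int = 70) -> None:
    records = [
        SeqRecord(
            Seq(c.sequence), id=c.id, description=f"topology={c.topology.value}"
        )
        for c in config.chromosomes
    ]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=wrap).write_file(records)


def read_fastq(path: PathLike) -> List[Tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[Tuple[str, str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _parse_attributes(field: str) -> Dict[str, str]:
    attrs = {}
    for item in field.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path: PathLike, genome: GenomeConfiguration) -> List[GeneModel]:
    """Gene models from GFF3 CDS features grouped by ``Parent`` (or ``ID``).

    Exons are ordered by an explicit integer ``exon_order`` attribute when
    present, otherwise by genomic position (reverse order on the minus
    strand).  Coordinates are validated against the genome.
    """
    groups: Dict[str, List[Tuple[int, CircularInterval, str, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _, ftype, start, end, _, strand, phase, attr_field = cols
            if ftype != "CDS":
                continue
            try:
                chrom = genome.chromosome(seqid)
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {seqid!r}") from exc
            start_i, end_i = int(start), int(end)
            if end_i > len(chrom) or start_i < 1:
                raise ValueError(
                    f"{path}:{lineno}: feature {start_i}..{end_i} outside "
                    f"chromosome {seqid} (length {len(chrom)})"
                )
            attrs = _parse_attributes(attr_field)
            parent = attrs.get("Parent") or attrs.get("ID")
            if not parent:
                raise ValueError(f"{path}:{lineno}: CDS without Parent or ID")
            order = int(attrs["exon_order"]) if "exon_order" in attrs else -1
            frame = int(phase) if phase in ("0", "1", "2") else 0
            groups.setdefault(parent, []).append(
                (order, CircularInterval(seqid, start_i, end_i, strand), strand, frame)
            )
    genes: List[GeneModel] = []
    for gene_id in sorted(groups):
        rows = groups[gene_id]
        strand = rows[0][2]
        if any(r[0] >= 0 for r in rows):
            rows.sort(key=lambda r: r[0])
        else:
            rows.sort(key=lambda r: r[1].start, reverse=(strand == "-"))
        first_frame = rows[0][3]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=rows[0][1].chrom,
                exons=tuple(r[1] for r in rows),
                strand=strand,
                codon_start=first_frame,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# SAM pileup
# ---------------------------------------------------------------------------


def read_sam_pileup(
    path: PathLike, genome: GenomeConfiguration, source: str = "RNA"
) -> List[SiteCoverage]:
    """Per-position base counts from primary, mapped SAM alignments.

    Clipped bases, deletions and reference skips contribute nothing;
    duplicates are not removed.
    """
    counts: Dict[Tuple[str, int], Dict[str, int]] = {}
    known = {c.id for c in genome.chromosomes}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.reference_name not in known:
                raise ValueError(
                    f"alignment reference {aln.reference_name!r} not in genome"
                )
            seq = aln.query_sequence
            if seq is None:
                continue
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                base = seq[qpos].upper()
                if base not in "ACGT":
                    continue
                key = (aln.reference_name, rpos + 1)
                counts.setdefault(key, {b: 0 for b in "ACGT"})[base] += 1
    out = []
    for (chrom_id, pos), c in sorted(counts.items()):
        ref = genome.chromosome(chrom_id).sequence[pos - 1]
        out.append(
            SiteCoverage(chrom=chrom_id, position=pos, ref_base=ref, counts=c,
                         source=source)
        )
    return out


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------


def _write_tsv(path: PathLike, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        for row in rows:
            w.writerow(["." if v is None else v for v in row])


PILEUP_HEADER = ["chrom", "pos", "ref", "A", "C", "G", "T", "source"]


def write_pileup_tsv(pileups: Iterable[SiteCoverage], path: PathLike) -> None:
    _write_tsv(
        path,
        PILEUP_HEADER,
        (
            [p.chrom, p.position, p.ref_base, p.counts.get("A", 0),
             p.counts.get("C", 0), p.counts.get("G", 0), p.counts.get("T", 0),
             p.source]
            for p in pileups
        ),
    )


def read_pileup_tsv(path: PathLike) -> List[SiteCoverage]:
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                SiteCoverage(
                    chrom=row["chrom"],
                    position=int(row["pos"]),
                    ref_base=row["ref"],
                    counts={b: int(row[b]) for b in "ACGT"},
                    source=row.get("source", "RNA"),
                )
            )
    return out


REPEATS_HEADER = [
    "id", "identity_percent", "alignment_length", "mismatches", "gap_openings",
    "unit1_chrom", "unit1_start", "unit1_end",
    "unit2_chrom", "unit2_start", "unit2_end", "orientation",
]


def _unit_coords(iv: CircularInterval) -> Tuple[int, int]:
    lo, hi = min(iv.start, iv.end), max(iv.start, iv.end)
    return (hi, lo) if iv.strand == "-" else (lo, hi)


def write_repeats_tsv(pairs: Iterable[RepeatPair], path: PathLike) -> None:
    rows = []
    for p in pairs:
        s1, e1 = _unit_coords(p.unit1)
        s2, e2 = _unit_coords(p.unit2)
        rows.append(
            [p.id, f"{p.identity_percent:.3f}", p.alignment_length, p.mismatches,
             p.gap_openings, p.unit1.chrom, s1, e1, p.unit2.chrom, s2, e2,
             p.orientation]
        )
    _write_tsv(path, REPEATS_HEADER, rows)


def read_repeats_tsv(path: PathLike) -> List[RepeatPair]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            def iv(prefix: str) -> CircularInterval:
                s, e = int(row[f"{prefix}_start"]), int(row[f"{prefix}_end"])
                if s > e:
                    return CircularInterval(row[f"{prefix}_chrom"], e, s, "-")
                return CircularInterval(row[f"{prefix}_chrom"], s, e, "+")

            length = int(row["alignment_length"])
            mm = int(row["mismatches"])
            out.append(
                RepeatPair(
                    id=row["id"],
                    unit1=iv("unit1"),
                    unit2=iv("unit2"),
                    orientation=row["orientation"],
                    alignment_length=length,
                    identity_percent=float(row["identity_percent"]),
                    mismatches=mm,
                    gap_openings=int(row["gap_openings"]),
                    score=2 * (length - mm) - 3 * mm,
                )
            )
    return out


def write_ssr_tsv(records: Iterable[SSRRecord], path: PathLike) -> None:
    _write_tsv(
        path,
        ["chrom", "motif", "unit_size", "copies", "start", "end"],
        ([r.chrom, r.motif, r.unit_size, r.copies, r.start, r.end] for r in records),
    )


def write_tandem_tsv(repeats: Iterable[TandemRepeat], path: PathLike) -> None:
    _write_tsv(
        path,
        ["chrom", "period", "copy_number", "consensus", "start", "end"],
        (
            [t.chrom, t.period, t.copy_number, t.consensus, t.interval.start,
             t.interval.end]
            for t in repeats
        ),
    )


def write_segments_tsv(segments: Iterable[HomologySegment], path: PathLike) -> None:
    _write_tsv(
        path,
        ["query_chrom", "q_start", "q_end", "subject_chrom", "s_start", "s_end",
         "length", "identity", "score"],
        (
            [s.query.chrom, s.query.start, s.query.end, s.subject.chrom,
             *_unit_coords(s.subject), s.length, f"{s.identity_percent:.3f}",
             s.score]
            for s in segments
        ),
    )


def write_support_tsv(
    supports: Dict[str, ReadSupport],
    orientations: Dict[str, str],
    path: PathLike,
) -> None:
    rows = []
    for rid in sorted(supports):
        rs = supports[rid]
        rows.append(
            [rid, orientations.get(rid), rs.major_count, rs.minor_count,
             None if rs.minor_percent is None else f"{rs.minor_percent:.2f}",
             rs.unassigned]
        )
    _write_tsv(
        path,
        ["repeat_id", "orientation", "major", "minor", "minor_percent", "unassigned"],
        rows,
    )


def write_editing_tsv(sites: Iterable[EditingSite], path: PathLike) -> None:
    _write_tsv(
        path,
        ["gene", "copy", "genomic_pos", "cds_pos", "codon_index", "codon_pos",
         "ref_codon", "edited_codon", "ref_aa", "edited_aa", "extent", "effect",
         "hydropathy_shift"],
        (
            [s.gene_id, s.copy, s.genomic_position, s.cds_position, s.codon_index,
             s.codon_position, s.ref_codon, s.edited_codon, s.ref_aa, s.edited_aa,
             f"{s.extent:.4f}", s.effect, s.hydropathy_shift]
            for s in sites
        ),
    )


def write_composition_tsv(
    per_chrom: Dict[str, CompositionReport], path: PathLike
) -> None:
    rows = []
    for chrom_id, rep in per_chrom.items():
        rows.append(
            [chrom_id, rep.total, rep.counts["A"], rep.counts["C"],
             rep.counts["G"], rep.counts["T"], rep.counts["N"],
             f"{rep.gc_percent:.8f}"]
        )
    _write_tsv(path, ["chrom", "total", "A", "C", "G", "T", "N", "gc_percent"], rows)


def write_junctions_fasta(jm: JunctionModel, path: PathLike) -> None:
    with open(path, "w") as fh:
        for label in ("ref1", "ref2", "alt1", "alt2"):
            fh.write(f">{jm.repeat.id}_{label}\n")
            seq = jm.junctions[label]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
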