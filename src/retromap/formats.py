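"""Readers, writers and reference containers for the external formats the
pipeline touches.

Internal convention is 0-based half-open intervals everywhere; 1-based
fully-closed coordinates appear only at the GFF3 boundary and in printed
reports.  Host chromosomes may contain N bases; provirus anchors may not.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Structurally valid file whose content violates an invariant."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A protein-coding gene as a strand plus sorted, disjoint exon intervals.

    Exons are [start, end) in chromosome coordinates; the gene span is
    [exons[0][0], exons[-1][1]) and everything between exons is intron.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: gene has no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValidationError(f"{self.gene_id}: empty exon [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValidationError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]


@dataclass
class GenomeRef:
    """Host reference: chromosome sequences plus gene annotation.

    The coordinate frame for every call the pipeline emits.  The
    mitochondrion, if present, is an ordinary sequence.
    """

    sequences: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def validate(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValidationError(f"chromosome {name}: invalid bases {sorted(bad)}")
        for gene in self.genes:
            if gene.chromosome not in self.sequences:
                raise ValidationError(
                    f"{gene.gene_id}: unknown chromosome {gene.chromosome!r}"
                )
            start, end = gene.span
            if start < 0 or end > len(self.sequences[gene.chromosome]):
                raise ValidationError(
                    f"{gene.gene_id}: interval [{start}, {end}) outside "
                    f"chromosome {gene.chromosome}"
                )


@dataclass
class ProvirusRef:
    """Provirus reference with its LTR anchor subsequences.

    ``anchor_3`` is the terminal 37 nt of the 3'-LTR as it appears at the
    start of a 3'-library read (ends with the CA dinucleotide); ``anchor_5``
    is the reverse complement of the first 32 nt of the 5'-LTR, i.e. the
    expected 5'-library read prefix (also ends with CA in read orientation,
    the complement of the genomic 5'-terminal TG).
    """

    sequence: str
    ltr_length: int
    anchor_3: str = ""
    anchor_5: str = ""
    terminal_5_dinucleotide: str = "TG"
    terminal_3_dinucleotide: str = "CA"

    ANCHOR_3_LENGTH = 37
    ANCHOR_5_LENGTH = 32

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.anchor_3:
            self.anchor_3 = self.sequence[-self.ANCHOR_3_LENGTH:]
        if not self.anchor_5:
            self.anchor_5 = revcomp(self.sequence[: self.ANCHOR_5_LENGTH])
        self.validate()

    def validate(self) -> None:
        seq = self.sequence
        if len(seq) < 2 * self.ltr_length:
            raise ValidationError("provirus shorter than two LTRs")
        if not seq.startswith(self.terminal_5_dinucleotide):
            raise ValidationError("provirus must begin with the 5' terminal TG")
        if not seq.endswith(self.terminal_3_dinucleotide):
            raise ValidationError("provirus must end with the 3' terminal CA")
        three_ltr = seq[-self.ltr_length:]
        if not three_ltr.endswith(self.anchor_3):
            raise ValidationError("anchor_3 is not a suffix of the 3'-LTR")
        if revcomp(self.anchor_5) != seq[: len(self.anchor_5)]:
            raise ValidationError("anchor_5 does not match the 5'-LTR terminus")
        for anchor in (self.anchor_3, self.anchor_5):
            if "N" in anchor:
                raise ValidationError("N bases are forbidden inside anchors")

    def anchor(self, which_end: int) -> str:
        if which_end == 3:
            return self.anchor_3
        if which_end == 5:
            return self.anchor_5
        raise ValueError(f"which_end must be 3 or 5, got {which_end!r}")

    @classmethod
    def from_fasta(cls, path: str | os.PathLike, ltr_length: int) -> "ProvirusRef":
        records = read_fasta(path)
        if len(records) != 1:
            raise FormatError(f"{path}: expected one provirus record, found {len(records)}")
        (seq,) = records.values()
        return cls(sequence=seq, ltr_length=ltr_length)


@dataclass
class Read:
    """One sequencing read (FASTQ record)."""

    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise FormatError(f"{self.id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# coordinate conversions (internal 0-based half-open <-> GFF 1-based closed)
# ---------------------------------------------------------------------------

def to_gff_interval(start: int, end: int) -> tuple[int, int]:
    """Internal [start, end) -> GFF3 1-based fully-closed (start, end)."""
    return start + 1, end


def from_gff_interval(start: int, end: int) -> tuple[int, int]:
    """GFF3 1-based fully-closed (start, end) -> internal [start, end)."""
    return start - 1, end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase-sequence map.

    Duplicate record names and non-ACGTN characters raise :class:`FormatError`.
    """
    result: dict[str, str] = {}
    with open(path) as handle:
        first = handle.readline()
        if first and not first.startswith(">"):
            raise FormatError(f"{path}: line 1: expected FASTA header, got {first!r}")
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in result:
                raise FormatError(f"{path}: duplicate record name {record.id!r}")
            seq = str(record.seq).upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"{path}: record {record.id!r}: invalid characters {sorted(bad)}"
                )
            result[record.id] = seq
    return result


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | os.PathLike) -> list[Read]:
    reads = []
    for record in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in record.letter_annotations["phred_quality"]
        )
        reads.append(Read(record.id, str(record.seq).upper(), qual))
    return reads


def write_fastq(reads: Iterable[Read], path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        for read in reads:
            out.write(f"@{read.id}\n{read.seq}\n+\n{read.qual}\n")


# ---------------------------------------------------------------------------
# GFF3 (gene/mRNA/exon only)
# ---------------------------------------------------------------------------

def read_gff(path: str | os.PathLike, genome: GenomeRef) -> list[GeneModel]:
    """Parse gene models from GFF3, converting to internal coordinates.

    Exons are taken from the first mRNA of each gene (the synthetic
    annotation is single-transcript), or from direct exon children when no
    mRNA is present.  Features on unknown chromosomes, or exons outside
    chromosome bounds, raise :class:`ValidationError`.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.seqid not in genome.sequences:
            raise ValidationError(f"{gene.id}: unknown chromosome {gene.seqid!r}")
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        exons = [
            from_gff_interval(exon.start, exon.end)
            for exon in db.children(parent, featuretype="exon", order_by="start")
        ]
        if not exons:
            raise ValidationError(f"{gene.id}: gene has no exons")
        chrom_len = len(genome.sequences[gene.seqid])
        for start, end in exons:
            if start < 0 or end > chrom_len:
                raise ValidationError(
                    f"{gene.id}: exon [{start}, {end}) outside chromosome {gene.seqid}"
                )
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, exons))
    return genes


def write_gff(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for gene in genes:
            gstart, gend = to_gff_interval(*gene.span)
            base = f"{gene.chromosome}\tretromap\t"
            tail = f"\t.\t{gene.strand}\t."
            out.write(f"{base}gene\t{gstart}\t{gend}{tail}\tID={gene.gene_id}\n")
            mrna_id = f"{gene.gene_id}.1"
            out.write(
                f"{base}mRNA\t{gstart}\t{gend}{tail}\tID={mrna_id};Parent={gene.gene_id}\n"
            )
            for i, (start, end) in enumerate(gene.exons, start=1):
                estart, eend = to_gff_interval(start, end)
                out.write(
                    f"{base}exon\t{estart}\t{eend}{tail}\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------

def write_calls_bed(calls: Iterable, path: str | os.PathLike) -> None:
    """Write junction calls as BED6 (0-based half-open single-base features).

    Name column holds the junction class, score the supporting-read count.
    """
    with open(path, "w") as out:
        out.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for call in calls:
            support = len(getattr(call, "read_ids", []) or []) or 1
            out.write(
                f"{call.chromosome}\t{call.position}\t{call.position + 1}\t"
                f"{call.junction_class}\t{support}\t{call.strand}\n"
            )


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str, int, str]]:
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            score = int(float(fields[4])) if len(fields) > 4 and fields[4] != "." else 0
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((chrom, start, end, name, score, strand))
    return rows


def write_rates_tsv(rates, path: str | os.PathLike) -> None:
    """Write a per-chromosome rate table; rates printed at 1 decimal."""
    with open(path, "w") as out:
        out.write(
            "chromosome\tassembly_length\tcount_5\trate_5_per_mb\tcount_3\trate_3_per_mb\n"
        )
        for row in rates:
            out.write(
                f"{row.chromosome}\t{row.assembly_length}\t{row.count_5}\t"
                f"{row.rate_5:.1f}\t{row.count_3}\t{row.rate_3:.1f}\n"
            )


# ---------------------------------------------------------------------------
# SAM interop
# ---------------------------------------------------------------------------

def write_sam(alignments: Sequence, lengths: Mapping[str, int], path: str | os.PathLike) -> None:
    """Write internal alignments as plain-text SAM (soft-clipped ungapped)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in lengths.items()],
    }
    refs = list(lengths)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_id
            seg.reference_id = refs.index(aln.reference)
            seg.reference_start = aln.start
            seg.mapping_quality = aln.mapq
            seg.flag = 16 if aln.strand == "-" else 0
            span = aln.qend - aln.qstart
            lead, trail = aln.qstart, aln.query_length - aln.qend
            if aln.strand == "-":
                lead, trail = trail, lead
            cigar = []
            if lead:
                cigar.append((4, lead))
            cigar.append((0, span))
            if trail:
                cigar.append((4, trail))
            seg.cigartuples = cigar
            seg.set_tag("NM", aln.mismatches)
            seg.set_tag("XM", aln.matched_bp)
            seg.set_tag("XC", aln.n_cooptimal)
            out.write(seg)


def read_sam(path: str | os.PathLike) -> list:
    """Read a SAM file back into internal :class:`retromap.align.Alignment`s."""
    from .align import Alignment

    alignments = []
    with pysam.AlignmentFile(str(path), "r") as handle:
        for seg in handle:
            if seg.is_unmapped:
                continue
            cig = seg.cigartuples or []
            lead = cig[0][1] if cig and cig[0][0] == 4 else 0
            trail = cig[-1][1] if len(cig) > 1 and cig[-1][0] == 4 else 0
            span = sum(n for op, n in cig if op == 0)
            strand = "-" if seg.is_reverse else "+"
            qlen = lead + span + trail
            if strand == "-":
                lead, trail = trail, lead
            matched = seg.get_tag("XM") if seg.has_tag("XM") else span
            alignments.append(
                Alignment(
                    read_id=seg.query_name,
                    reference=seg.reference_name,
                    start=seg.reference_start,
                    end=seg.reference_start + span,
                    strand=strand,
                    qstart=lead,
                    qend=lead + span,
                    query_length=qlen,
                    matched_bp=matched,
                    mismatches=seg.get_tag("NM") if seg.has_tag("NM") else 0,
                    mapq=seg.mapping_quality,
                    n_cooptimal=seg.get_tag("XC") if seg.has_tag("XC") else 1,
                )
            )
    return alignments
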