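"""Genomic-region annotation of integration sites and the bias test.

Sites (unique clusters by default, represented by their minimum member
position) are classified exon / intron / intergenic with exon taking
precedence over intron wherever transcripts overlap, the same precedence
used to compute the genome's own region composition.  The test for a
non-coding integration preference is a single one-tailed exact binomial
comparison of the observed non-coding site fraction against the genome's
non-coding base fraction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import binomtest

from .formats import GenomeRef

EXON, INTRON, INTERGENIC = "exon", "intron", "intergenic"


@dataclass
class RegionStats:
    """Genome composition, site counts and the non-coding bias probability."""

    genome_fractions: tuple[float, float, float]  # exon, intron, intergenic
    site_counts: tuple[int, int, int]
    n_sites: int
    p_noncoding_bias: float | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.genome_fractions) - 1.0) > 1e-9:
            raise ValueError("genome fractions must sum to 1")
        if sum(self.site_counts) != self.n_sites:
            raise ValueError("site counts must sum to n_sites")

    @property
    def site_fractions(self) -> tuple[float, float, float]:
        if self.n_sites == 0:
            return (0.0, 0.0, 0.0)
        return tuple(c / self.n_sites for c in self.site_counts)


@dataclass
class RateRow:
    """Per-chromosome integration counts and per-Mb rates for both ends."""

    chromosome: str
    assembly_length: int
    count_5: int
    count_3: int

    @property
    def rate_5(self) -> float:
        return self.count_5 / (self.assembly_length / 1e6)

    @property
    def rate_3(self) -> float:
        return self.count_3 / (self.assembly_length / 1e6)


class RegionIndex:
    """Interval lookup of exon and gene spans for site classification."""

    def __init__(self, genome: GenomeRef):
        self.exons: dict[str, IntervalTree] = {}
        self.genes: dict[str, IntervalTree] = {}
        for gene in genome.genes:
            etree = self.exons.setdefault(gene.chromosome, IntervalTree())
            for start, end in gene.exons:
                etree.addi(start, end)
            start, end = gene.span
            self.genes.setdefault(gene.chromosome, IntervalTree()).addi(start, end)

    def classify(self, chromosome: str, position: int) -> str:
        if chromosome in self.exons and self.exons[chromosome].overlaps_point(position):
            return EXON
        if chromosome in self.genes and self.genes[chromosome].overlaps_point(position):
            return INTRON
        return INTERGENIC


def genome_composition(genome: GenomeRef) -> tuple[float, float, float]:
    """Base-pair fractions of exon, intron and intergenic sequence.

    Overlapping transcripts resolve with exon precedence: a base inside any
    exon counts as exon; a non-exonic base inside any gene span counts as
    intron; everything else is intergenic.
    """
    total = genome.total_length
    if total == 0:
        raise ValueError("empty genome")
    exon_bp = 0
    intron_bp = 0
    for chrom, seq in genome.sequences.items():
        length = len(seq)
        exon_mask = np.zeros(length, dtype=bool)
        gene_mask = np.zeros(length, dtype=bool)
        for gene in genome.genes:
            if gene.chromosome != chrom:
                continue
            start, end = gene.span
            gene_mask[start:end] = True
            for estart, eend in gene.exons:
                exon_mask[estart:eend] = True
        exon_bp += int(exon_mask.sum())
        intron_bp += int((gene_mask & ~exon_mask).sum())
    fe = exon_bp / total
    fi = intron_bp / total
    return (fe, fi, 1.0 - fe - fi)


def classify_sites(
    sites: Iterable[tuple[str, int]], genome: GenomeRef
) -> RegionStats:
    """Count exon / intron / intergenic assignments of integration sites.

    ``sites`` are (chromosome, position) pairs -- typically one
    representative (minimum member) position per unique cluster.
    """
    index = RegionIndex(genome)
    counts: Counter = Counter()
    n = 0
    for chrom, pos in sites:
        if chrom not in genome.sequences:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < len(genome.sequences[chrom]):
            raise ValueError(f"position {pos} outside chromosome {chrom}")
        counts[index.classify(chrom, pos)] += 1
        n += 1
    return RegionStats(
        genome_fractions=genome_composition(genome),
        site_counts=(counts[EXON], counts[INTRON], counts[INTERGENIC]),
        n_sites=n,
    )


def noncoding_bias_test(
    k_noncoding: int, n: int, expected_fraction: float
) -> float:
    """One-tailed exact binomial probability P(X >= k | n, expected_fraction).

    Tests whether integrations favour non-coding sequence beyond its share
    of the genome.
    """
    if not 0 < expected_fraction < 1:
        raise ValueError("expected_fraction must lie strictly in (0, 1)")
    if not 0 <= k_noncoding <= n:
        raise ValueError("need 0 <= k <= n")
    return float(
        binomtest(k_noncoding, n, expected_fraction, alternative="greater").pvalue
    )


def region_stats(
    sites: Iterable[tuple[str, int]], genome: GenomeRef
) -> RegionStats:
    """Classify sites and attach the non-coding bias probability."""
    stats = classify_sites(sites, genome)
    noncoding_fraction = stats.genome_fractions[2]
    if stats.n_sites and 0 < noncoding_fraction < 1:
        stats.p_noncoding_bias = noncoding_bias_test(
            stats.site_counts[2], stats.n_sites, noncoding_fraction
        )
    return stats


def rate_table(
    counts_5: Mapping[str, int],
    counts_3: Mapping[str, int],
    lengths: Mapping[str, int],
    unplaced: Sequence[str] = (),
) -> list[RateRow]:
    """Per-chromosome counts and per-Mb rates for the two library ends.

    Chromosomes named in ``unplaced`` are aggregated into a single
    "Unplaced" row.  Counts for chromosomes absent from ``lengths`` raise.
    """
    for counts in (counts_5, counts_3):
        unknown = set(counts) - set(lengths)
        if unknown:
            raise ValueError(f"counts for unknown chromosomes: {sorted(unknown)}")
    unplaced = set(unplaced)
    rows = []
    for chrom, length in lengths.items():
        if chrom in unplaced:
            continue
        rows.append(
            RateRow(
                chromosome=chrom,
                assembly_length=length,
                count_5=counts_5.get(chrom, 0),
                count_3=counts_3.get(chrom, 0),
            )
        )
    if unplaced:
        rows.append(
            RateRow(
                chromosome="Unplaced",
                assembly_length=sum(lengths[c] for c in unplaced),
                count_5=sum(counts_5.get(c, 0) for c in unplaced),
                count_3=sum(counts_3.get(c, 0) for c in unplaced),
            )
        )
    return rows
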