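"""Integration evidence in whole-genome sequencing and the per-nucleus
burden estimator.

Read pairs aligned jointly to host and provirus fall into three evidence
categories:

* ``partial`` -- a single read spans the virus-host junction: a prefix
  aligns to one reference and the remaining suffix (>= 20 bp) to the other;
* ``independent`` -- one mate maps only to the host, the other only to the
  provirus, so the junction lies between them;
* ``virus_only`` -- both mates are provirus-internal (unintegrated or
  deep-internal fragments; no positional evidence).

The burden estimator treats every properly mapped pair as one sequenced
100-base segment of some nucleus' diploid genome: with ``x`` detected
integrations among ``R`` pairs and ``S`` segments per diploid genome, the
expected number of integrations per nucleus is ``x * S / R``, with an exact
(Clopper-Pearson) binomial confidence interval on ``x/R`` scaled by ``S``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import beta

from .align import Alignment, ReferenceIndex, build_index, encode, kmer_codes, map_read
from .formats import GenomeRef, ProvirusRef, revcomp
from .synthetic import decode

PROVIRUS_REF = "provirus"

#: minimum aligned bases on each side of a split for partial evidence
MIN_SEGMENT = 20
#: tolerated query-coordinate slop when testing span complementarity
SPAN_SLACK = 12


@dataclass
class PairCategory:
    """Evidence category of one read pair."""

    pair_id: str
    category: str  # "partial" | "independent" | "virus_only"
    chromosome: str | None = None
    junction: int | None = None  # partial only
    host_interval: tuple[int, int] | None = None  # independent only


@dataclass
class WgsEstimate:
    """Per-nucleus integration burden with its exact confidence interval."""

    x: int
    r_pairs: int
    segments_per_diploid: float
    per_nucleus: float
    ci: tuple[float, float]
    confidence: float = 0.95
    nuclei_per_organism: int = 1000

    @property
    def per_organism(self) -> float:
        return self.per_nucleus * self.nuclei_per_organism

    @property
    def per_organism_ci(self) -> tuple[float, float]:
        return (
            self.ci[0] * self.nuclei_per_organism,
            self.ci[1] * self.nuclei_per_organism,
        )

    def __post_init__(self) -> None:
        if not (0 <= self.ci[0] <= self.per_nucleus <= self.ci[1]):
            raise ValueError("CI must bracket the point estimate")


# ---------------------------------------------------------------------------
# read-pair categorization
# ---------------------------------------------------------------------------

def _split_best(alns: Sequence[Alignment], host_names: frozenset | set) -> tuple:
    best_host = None
    best_virus = None
    for aln in alns:
        if aln.reference in host_names:
            if best_host is None or aln.score > best_host.score:
                best_host = aln
        else:
            if best_virus is None or aln.score > best_virus.score:
                best_virus = aln
    return best_host, best_virus


def _overlap(a: Alignment, b: Alignment) -> int:
    return max(0, min(a.qend, b.qend) - max(a.qstart, b.qstart))


def _label_read(
    alns: Sequence[Alignment], host_names: set, read_length: int
) -> tuple[str, Alignment | None, Alignment | None]:
    """Label one read host / virus / chimeric / none from its alignments."""
    host, virus = _split_best(alns, host_names)
    full = read_length - SPAN_SLACK
    if host is not None and virus is not None:
        h_span = host.qend - host.qstart
        v_span = virus.qend - virus.qstart
        union = max(host.qend, virus.qend) - min(host.qstart, virus.qstart)
        if (
            h_span >= MIN_SEGMENT
            and v_span >= MIN_SEGMENT
            and _overlap(host, virus) <= SPAN_SLACK
            and union >= full
        ):
            # guard against endogenous look-alikes: the virus-side segment
            # must not be equally well explained by a host placement
            lookalike = any(
                a.reference in host_names
                and a is not host
                and _overlap(a, virus) > SPAN_SLACK
                and a.score >= virus.score
                for a in alns
            )
            if not lookalike:
                return "chimeric", host, virus
    if virus is not None and virus.qend - virus.qstart >= full:
        if host is None or virus.score > host.score:
            return "virus", host, virus
    if host is not None and host.qend - host.qstart >= full:
        return "host", host, virus
    return "none", host, virus


def _junction_coordinate(host: Alignment, virus: Alignment) -> int:
    """Host coordinate of the junction implied by a chimeric read."""
    host_first = host.qstart <= virus.qstart
    if host_first:  # host prefix, junction at the host segment's far edge
        return host.end - 1 if host.strand == "+" else host.start
    return host.start if host.strand == "+" else host.end - 1


def categorize_read_pairs(
    pair_alignments: Iterable[tuple[str, Sequence[Alignment], Sequence[Alignment]]],
    host_names: set,
    read_length: int,
) -> list[PairCategory]:
    """Assign read pairs to partial / independent / virus_only evidence.

    ``pair_alignments`` yields (pair id, mate-1 alignments, mate-2
    alignments) where each alignment list covers both references.
    Host-only and unassignable pairs are dropped.
    """
    categories: list[PairCategory] = []
    for pair_id, alns1, alns2 in pair_alignments:
        labels = []
        for alns in (alns1, alns2):
            labels.append(_label_read(alns, host_names, read_length))
        kinds = [lab[0] for lab in labels]
        if "chimeric" in kinds:
            lab = labels[kinds.index("chimeric")]
            _, host, virus = lab
            categories.append(
                PairCategory(
                    pair_id=pair_id,
                    category="partial",
                    chromosome=host.reference,
                    junction=_junction_coordinate(host, virus),
                )
            )
        elif set(kinds) == {"host", "virus"}:
            host = labels[kinds.index("host")][1]
            categories.append(
                PairCategory(
                    pair_id=pair_id,
                    category="independent",
                    chromosome=host.reference,
                    host_interval=(host.start, host.end),
                )
            )
        elif kinds == ["virus", "virus"]:
            categories.append(PairCategory(pair_id=pair_id, category="virus_only"))
    return categories


# ---------------------------------------------------------------------------
# event counting
# ---------------------------------------------------------------------------

def _chain(values: list[int], radius: int) -> list[list[int]]:
    values = sorted(values)
    groups: list[list[int]] = [[values[0]]]
    for v in values[1:]:
        if v - groups[-1][-1] <= radius:
            groups[-1].append(v)
        else:
            groups.append([v])
    return groups


def integration_events(
    categories: Iterable[PairCategory],
    merge_radius: int = 100,
    suppression_radius: int = 400,
    suppress: bool = True,
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Deduplicated (chromosome, position) events by category.

    Partial junctions are chained at ``merge_radius``; independent pairs
    whose host-side interval lies within ``suppression_radius`` of a counted
    partial junction are treated as re-observations of it (unless
    ``suppress`` is False, which reproduces purely additive counting), and
    the remaining independents are chained among themselves at
    ``suppression_radius``.
    """
    partial_pos: dict[str, list[int]] = defaultdict(list)
    indep: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for cat in categories:
        if cat.category == "partial":
            partial_pos[cat.chromosome].append(cat.junction)
        elif cat.category == "independent":
            indep[cat.chromosome].append(cat.host_interval)
    partial_events = [
        (chrom, group[0])
        for chrom in sorted(partial_pos)
        for group in _chain(partial_pos[chrom], merge_radius)
    ]
    indep_events: list[tuple[str, int]] = []
    for chrom in sorted(indep):
        anchors = [p for c, p in partial_events if c == chrom]
        kept = []
        for start, end in sorted(set(indep[chrom])):
            near = any(
                start - suppression_radius <= p <= end + suppression_radius
                for p in anchors
            )
            if suppress and near:
                continue
            kept.append(start)
        if kept:
            indep_events.extend(
                (chrom, group[0]) for group in _chain(kept, suppression_radius)
            )
    return partial_events, indep_events


def count_integrations(
    categories: Iterable[PairCategory],
    merge_radius: int = 100,
    suppression_radius: int = 400,
    suppress: bool = True,
) -> int:
    """Number of distinct integrations supported by the evidence categories."""
    partial, indep = integration_events(
        categories, merge_radius, suppression_radius, suppress
    )
    return len(partial) + len(indep)


# ---------------------------------------------------------------------------
# burden estimator
# ---------------------------------------------------------------------------

def segments_per_diploid_genome(
    lengths: Mapping[str, int] | Iterable[int], read_length: int = 100
) -> float:
    """Number of read-length segments in a diploid copy of the genome."""
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    values = lengths.values() if isinstance(lengths, Mapping) else lengths
    total = sum(values)
    if total <= 0:
        raise ValueError("genome length must be positive")
    return 2 * total / read_length


def clopper_pearson(x: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via the incomplete-beta inverse."""
    if not 0 <= x <= n or n <= 0:
        raise ValueError("need 0 <= x <= n with n > 0")
    alpha = 1 - confidence
    lo = 0.0 if x == 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def per_nucleus_estimate(
    x: int,
    r_pairs: int,
    segments: float,
    confidence: float = 0.95,
    nuclei_per_organism: int = 1000,
) -> WgsEstimate:
    """Integrations per nucleus: ``x * S / R`` with exact binomial CI.

    ``x`` detected integrations among ``r_pairs`` properly mapped pairs,
    scaled by ``segments`` per diploid genome; the Clopper-Pearson interval
    on the proportion is scaled identically.
    """
    if r_pairs <= 0:
        raise ValueError("r_pairs must be positive")
    if segments <= 0:
        raise ValueError("segments must be positive")
    if not 0 <= x <= r_pairs:
        raise ValueError("need 0 <= x <= r_pairs")
    lo, hi = clopper_pearson(x, r_pairs, confidence)
    return WgsEstimate(
        x=x,
        r_pairs=r_pairs,
        segments_per_diploid=segments,
        per_nucleus=x * segments / r_pairs,
        ci=(lo * segments, hi * segments),
        confidence=confidence,
        nuclei_per_organism=nuclei_per_organism,
    )


def nuclei_from_mass(dna_mass_ng: float, diploid_genome_mass_pg: float = 0.79) -> float:
    """Nuclei represented in a DNA mass (1 ng = 1000 pg)."""
    if dna_mass_ng <= 0 or diploid_genome_mass_pg <= 0:
        raise ValueError("masses must be positive")
    return dna_mass_ng * 1000.0 / diploid_genome_mass_pg


def per_organism(estimate: WgsEstimate, nuclei_per_organism: int = 1000) -> float:
    """Scale a per-nucleus estimate to a whole organism."""
    return estimate.per_nucleus * nuclei_per_organism


# ---------------------------------------------------------------------------
# high-throughput screening + end-to-end analysis on read arrays
# ---------------------------------------------------------------------------

def provirus_kmer_table(provirus: ProvirusRef, k: int = 15) -> np.ndarray:
    """Sorted k-mer codes of the provirus and its reverse complement."""
    kmers = []
    for seq in (provirus.sequence, revcomp(provirus.sequence)):
        km = kmer_codes(encode(seq), k)
        kmers.append(km[km >= 0])
    return np.unique(np.concatenate(kmers))


def screen_pairs(
    r1: np.ndarray,
    r2: np.ndarray,
    table: np.ndarray,
    k: int = 15,
    stride: int | None = None,
) -> np.ndarray:
    """Boolean mask of pairs sharing at least one k-mer with the provirus.

    Pure-host pairs (the overwhelming majority) are excluded from full
    alignment by this screen; they still count toward the properly mapped
    pair total.  K-mer start positions are sampled at a stride of
    ``MIN_SEGMENT - k + 1`` so that any error-free provirus segment long
    enough to constitute evidence (>= ``MIN_SEGMENT`` bases) is guaranteed
    to contain a sampled k-mer.
    """
    n, rl = r1.shape
    hit = np.zeros(n, dtype=bool)
    if len(table) == 0 or rl < k:
        return hit
    if stride is None:
        stride = max(1, MIN_SEGMENT - k + 1)
    width = rl - k + 1
    positions = list(range(0, width, stride))
    if positions[-1] != width - 1:
        positions.append(width - 1)
    for arr in (r1, r2):
        for p in positions:
            vals = np.zeros(n, dtype=np.int64)
            invalid = np.zeros(n, dtype=bool)
            for j in range(k):
                col = arr[:, p + j]
                vals = (vals << 2) | (col & 3)
                invalid |= col >= 4
            idx = np.searchsorted(table, vals)
            idx[idx == len(table)] = 0
            hit |= (table[idx] == vals) & ~invalid
    return hit


@dataclass
class WgsRunResult:
    n_pairs: int
    n_candidates: int
    categories: list[PairCategory]
    x: int
    r_pairs: int
    estimate: WgsEstimate

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {"partial": 0, "independent": 0, "virus_only": 0}
        for cat in self.categories:
            counts[cat.category] += 1
        return counts


def analyze_wgs_arrays(
    r1: np.ndarray,
    r2: np.ndarray,
    genome: GenomeRef,
    provirus: ProvirusRef,
    read_length: int = 100,
    index: ReferenceIndex | None = None,
    merge_radius: int = 100,
    max_insert: int = 400,
    confidence: float = 0.95,
    suppress: bool = True,
) -> WgsRunResult:
    """Full WGS analysis of mate code arrays against host + provirus.

    Pairs passing the provirus k-mer screen are aligned jointly and
    categorized; the properly mapped pair total ``R`` excludes pairs with
    provirus-only or split-across-references mates (screened-out pairs are
    host-proper by construction of the screen).  Returns categories, the
    deduplicated integration count ``x`` and the per-nucleus estimate.
    """
    n_pairs = len(r1)
    table = provirus_kmer_table(provirus)
    mask = screen_pairs(r1, r2, table)
    if index is None:
        refs = dict(genome.sequences)
        refs[PROVIRUS_REF] = provirus.sequence
        index = build_index(refs)
    host_names = set(genome.sequences)
    pair_alignments = []
    for i in np.nonzero(mask)[0]:
        pid = f"pair_{int(i)}"
        alns1 = map_read(decode(r1[int(i)]), index, read_id=pid + "/1")
        alns2 = map_read(decode(r2[int(i)]), index, read_id=pid + "/2")
        pair_alignments.append((pid, alns1, alns2))
    categories = categorize_read_pairs(pair_alignments, host_names, read_length)
    counts = {"partial": 0, "independent": 0, "virus_only": 0}
    for cat in categories:
        counts[cat.category] += 1
    r_pairs = n_pairs - counts["virus_only"] - counts["independent"]
    x = count_integrations(
        categories,
        merge_radius=merge_radius,
        suppression_radius=max_insert,
        suppress=suppress,
    )
    segments = segments_per_diploid_genome(genome.lengths, read_length)
    estimate = per_nucleus_estimate(x, r_pairs, segments, confidence=confidence)
    return WgsRunResult(
        n_pairs=n_pairs,
        n_candidates=int(mask.sum()),
        categories=categories,
        x=x,
        r_pairs=r_pairs,
        estimate=estimate,
    )
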