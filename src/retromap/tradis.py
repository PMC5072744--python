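"""LTR-anchored (TraDIS-style) integration-site calling.

A prepped read becomes a junction call only if it passes four authenticity
criteria, applied in order:

i.   the read began with the library's LTR anchor;
ii.  the anchor was not immediately followed by splinkerette adapter
     (an empty, host-free insert);
iii. the remaining sequence maps uniquely to the host with >= 30 matched
     bases, starting at the first host base so the junction coordinate is
     the alignment's anchor-proximal boundary;
iv.  the mapping quality is at least Q30.

Surviving calls are deduplicated (PCR duplicates: identical chromosome,
position, strand and library end count once), unique positions within
250 bp of one another are chained into clusters, and each junction is
classified integrase-catalyzed (intact LTR terminal dinucleotide
immediately adjacent to host sequence) or process-unresolved.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import Alignment
from .formats import GenomeRef, ProvirusRef
from .readprep import PreppedRead

INTEGRASE = "integrase_catalyzed"
UNRESOLVED = "unresolved"


@dataclass
class FilterParams:
    """Thresholds of the four authenticity criteria plus the cluster radius."""

    min_overlap_merge: int = 10
    min_host_match: int = 30
    min_mapq: int = 30
    cluster_radius: int = 250
    anchor_mismatch_tolerance: int = 0

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if name != "anchor_mismatch_tolerance" and value <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class JunctionCall:
    """One detected integration junction.

    ``position`` is the first host base adjacent to the LTR terminus
    (0-based); ``strand`` is the strand of the host-flank alignment.
    """

    chromosome: str
    position: int
    strand: str
    ltr_end: int
    junction_class: str
    evidence: str
    read_ids: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple:
        return (self.chromosome, self.position, self.strand, self.ltr_end)


@dataclass
class Cluster:
    chromosome: str
    positions: list[int]

    @property
    def span(self) -> tuple[int, int]:
        return self.positions[0], self.positions[-1]

    @property
    def size(self) -> int:
        return len(self.positions)

    @property
    def representative(self) -> int:
        return self.positions[0]


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    radius: int

    def __len__(self) -> int:
        return len(self.clusters)


class ConsistencyError(KeyError):
    """Alignments and prepped reads disagree about read identity."""


def classify_junction(
    call_or_none, prepped: PreppedRead, provirus: ProvirusRef
) -> str:
    """Integrase-catalyzed vs unresolved for one junction-bearing read.

    Integrase-catalyzed requires the complete anchor -- so the LTR terminal
    dinucleotide (CA in read orientation for both library ends) is intact --
    with host sequence starting at the very next base, and no microhomology:
    a host flank that itself begins with the terminal dinucleotide makes the
    boundary unassignable and the event stays unresolved.
    """
    if not prepped.anchor_found or not prepped.anchor_complete:
        return UNRESOLVED
    terminal = provirus.anchor(prepped.ltr_end)[-2:]
    if prepped.host_sequence[: len(terminal)] == terminal:
        return UNRESOLVED
    return INTEGRASE


def call_sites(
    prepped: Sequence[PreppedRead],
    alignments: Mapping[str, Sequence[Alignment]],
    params: FilterParams,
    genome: GenomeRef,
    provirus: ProvirusRef,
) -> tuple[list[JunctionCall], Counter]:
    """Apply the authenticity criteria; returns (calls, rejection tally).

    ``alignments`` maps read id -> alignments of that read's host flank
    (best first).  Reads are tallied under the first criterion they fail:
    ``no_anchor``, ``splinkerette``, ``not_host``, ``short_match``,
    ``ambiguous``, ``not_junction_adjacent`` or ``low_mapq``.
    """
    calls: list[JunctionCall] = []
    tally: Counter = Counter()
    host_names = set(genome.sequences)
    for read in prepped:
        if not read.anchor_found:
            tally["no_anchor"] += 1
            continue
        if read.splinkerette_immediately_after_anchor:
            tally["splinkerette"] += 1
            continue
        if read.id not in alignments:
            raise ConsistencyError(f"no alignment entry for read {read.id!r}")
        alns = alignments[read.id]
        if not alns:
            tally["short_match"] += 1
            continue
        best = max(alns, key=lambda a: a.score)
        if best.reference not in host_names:
            tally["not_host"] += 1
            continue
        if best.matched_bp < params.min_host_match:
            tally["short_match"] += 1
            continue
        if best.n_cooptimal > 1:
            tally["ambiguous"] += 1
            continue
        if best.qstart != 0:
            tally["not_junction_adjacent"] += 1
            continue
        if best.mapq < params.min_mapq:
            tally["low_mapq"] += 1
            continue
        position = best.start if best.strand == "+" else best.end - 1
        calls.append(
            JunctionCall(
                chromosome=best.reference,
                position=position,
                strand=best.strand,
                ltr_end=read.ltr_end,
                junction_class=classify_junction(None, read, provirus),
                evidence=read.evidence,
                read_ids=[read.id],
            )
        )
        tally["passed"] += 1
    return calls, tally


def dedup_and_unique(calls: Iterable[JunctionCall]) -> list[JunctionCall]:
    """Collapse PCR duplicates: one call per (chrom, position, strand, end).

    Supporting read ids are merged; the junction class of a unique position
    is the majority class of its supporting reads (ties are conservative:
    unresolved).  Output is sorted by (chromosome, position).
    """
    grouped: dict[tuple, list[JunctionCall]] = defaultdict(list)
    for call in calls:
        grouped[call.key].append(call)
    unique: list[JunctionCall] = []
    for key in sorted(grouped):
        members = grouped[key]
        classes = Counter(m.junction_class for m in members)
        n_int = classes.get(INTEGRASE, 0)
        n_unr = classes.get(UNRESOLVED, 0)
        evidence = Counter(m.evidence for m in members).most_common(1)[0][0]
        unique.append(
            JunctionCall(
                chromosome=key[0],
                position=key[1],
                strand=key[2],
                ltr_end=key[3],
                junction_class=INTEGRASE if n_int > n_unr else UNRESOLVED,
                evidence=evidence,
                read_ids=sorted(set(sum((m.read_ids for m in members), []))),
            )
        )
    return unique


def cluster_positions(
    unique_calls: Sequence[JunctionCall], radius: int = 250
) -> ClusterSet:
    """Chain unique positions into clusters by transitive single linkage.

    Walking each chromosome's sorted positions, a new cluster starts when
    the gap to the previous position exceeds ``radius``; a chain 0, 200,
    400 is therefore a single cluster.  Deterministic and independent of
    input order.
    """
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for call in unique_calls:
        by_chrom[call.chromosome].append(call.position)
    clusters: list[Cluster] = []
    for chrom in sorted(by_chrom):
        positions = sorted(set(by_chrom[chrom]))
        current = [positions[0]]
        for pos in positions[1:]:
            if pos - current[-1] <= radius:
                current.append(pos)
            else:
                clusters.append(Cluster(chrom, current))
                current = [pos]
        clusters.append(Cluster(chrom, current))
    return ClusterSet(clusters=clusters, radius=radius)


def library_summary(
    calls: Sequence[JunctionCall],
    clusters_by_end: Mapping[int, ClusterSet] | None = None,
    radius: int = 250,
) -> pd.DataFrame:
    """Per-end summary table: read-level class counts, unique positions,
    unique clusters -- one row per (library end, evidence type) plus a
    per-end totals row."""
    rows = []
    for end in (5, 3):
        end_calls = [c for c in calls if c.ltr_end == end]
        for evidence in ("merged", "paired"):
            sub = [c for c in end_calls if c.evidence == evidence]
            n_int = sum(1 for c in sub if c.junction_class == INTEGRASE)
            total = len(sub)
            rows.append(
                {
                    "ltr_end": end,
                    "evidence": evidence,
                    "integrase_catalyzed": n_int,
                    "unresolved": total - n_int,
                    "total": total,
                    "pct_integrase": round(100 * n_int / total, 1) if total else 0.0,
                }
            )
        unique = dedup_and_unique(end_calls)
        if clusters_by_end is not None and end in clusters_by_end:
            n_clusters = len(clusters_by_end[end])
        else:
            n_clusters = len(cluster_positions(unique, radius)) if unique else 0
        rows.append(
            {
                "ltr_end": end,
                "evidence": "all",
                "integrase_catalyzed": sum(
                    1 for c in end_calls if c.junction_class == INTEGRASE
                ),
                "unresolved": sum(
                    1 for c in end_calls if c.junction_class == UNRESOLVED
                ),
                "total": len(end_calls),
                "pct_integrase": round(
                    100
                    * sum(1 for c in end_calls if c.junction_class == INTEGRASE)
                    / len(end_calls),
                    1,
                )
                if end_calls
                else 0.0,
                "unique_positions": len(unique),
                "unique_clusters": n_clusters,
            }
        )
    return pd.DataFrame(rows)
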