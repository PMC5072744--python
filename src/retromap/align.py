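"""Seed-and-extend ungapped read mapping against host + provirus references.

The two references are indexed together so every read competes across both;
the reference of the best-scoring placement decides its assignment.  The
aligner is deliberately ungapped: the junction criteria downstream operate
on clipped prefix/suffix structure, not indels, and alignments from an
external gapped aligner can be supplied via SAM instead.

Alignments are local in the query: the reported segment is the
maximum-scoring contiguous run (match +1 / mismatch -1) along the best seed
diagonal, so a chimeric virus-host read yields a soft-clipped placement on
each reference with complementary query spans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .formats import GenomeRef

_CODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i

MAPQ_CAP = 60
MAPQ_PER_SCORE = 2  # phred points per unit of best-vs-second score gap


def encode(seq: str) -> np.ndarray:
    """2-bit-encode a nucleotide string (N and anything else -> code 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_revcomp(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    valid = out < 4
    out[valid] = 3 - out[valid]
    return out


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit k-mer integers; k-mers containing N are set to -1."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        vals = (vals << 2) | (window & 3)
        invalid |= window >= 4
    vals[invalid] = -1
    return vals


@dataclass
class Alignment:
    """One ungapped placement of (part of) a read on a reference.

    ``qstart``/``qend`` are in the coordinates of the read as given (not of
    its reverse complement); ``start``/``end`` are 0-based half-open on the
    forward reference strand.  ``mapq`` is 0 whenever the best score is tied
    (``n_cooptimal > 1``), otherwise scaled from the best-vs-second-best
    score gap and capped at 60.
    """

    read_id: str
    reference: str
    start: int
    end: int
    strand: str
    qstart: int
    qend: int
    query_length: int
    matched_bp: int
    mismatches: int
    mapq: int
    n_cooptimal: int = 1

    @property
    def score(self) -> int:
        return self.matched_bp - self.mismatches

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("alignment interval must be non-empty")


class ReferenceIndex:
    """Exact k-mer positions over a set of reference sequences.

    Positions are stored for the forward strand only; reverse-strand hits
    are found by also seeding with the reverse complement of the query.
    Lookup is by binary search on the sorted k-mer array (no per-k-mer dict).
    """

    def __init__(self, sequences: Mapping[str, str], k: int = 15):
        if k < 8:
            raise ValueError("k must be >= 8")
        self.k = k
        self.names: list[str] = []
        self.codes: list[np.ndarray] = []
        self.offsets: list[int] = []
        all_kmers = []
        all_positions = []
        offset = 0
        for name, seq in sequences.items():
            if len(seq) < k:
                warnings.warn(f"reference {name!r} shorter than k={k}; skipped")
                continue
            codes = encode(seq)
            km = kmer_codes(codes, k)
            valid = km >= 0
            all_kmers.append(km[valid])
            all_positions.append(np.nonzero(valid)[0].astype(np.int64) + offset)
            self.names.append(name)
            self.codes.append(codes)
            self.offsets.append(offset)
            offset += len(seq)
        self.total_length = offset
        if all_kmers:
            kmers = np.concatenate(all_kmers)
            positions = np.concatenate(all_positions)
            order = np.argsort(kmers, kind="stable")
            self.sorted_kmers = kmers[order]
            self.sorted_positions = positions[order]
        else:
            self.sorted_kmers = np.empty(0, dtype=np.int64)
            self.sorted_positions = np.empty(0, dtype=np.int64)
        self._bounds = np.array(self.offsets + [offset], dtype=np.int64)

    def lookup(self, kmer: int) -> np.ndarray:
        """Global positions (concatenated coordinate space) of one k-mer."""
        lo = np.searchsorted(self.sorted_kmers, kmer, side="left")
        hi = np.searchsorted(self.sorted_kmers, kmer, side="right")
        return self.sorted_positions[lo:hi]

    def locate(self, global_pos: int) -> tuple[str, int]:
        """Map a concatenated-space position back to (reference, position)."""
        idx = int(np.searchsorted(self._bounds, global_pos, side="right")) - 1
        return self.names[idx], int(global_pos - self.offsets[idx])

    def reference_slice(self, ref_idx: int, start: int, end: int) -> np.ndarray:
        return self.codes[ref_idx][start:end]


def build_index(genome: GenomeRef | Mapping[str, str], k: int = 15) -> ReferenceIndex:
    """Index reference sequences for seeding (both strands retrievable)."""
    sequences = genome.sequences if isinstance(genome, GenomeRef) else genome
    return ReferenceIndex(sequences, k=k)


def _best_segment(match: np.ndarray) -> tuple[int, int, int, int]:
    """Maximum-scoring contiguous segment of a +1/-1 match profile.

    Returns (qstart, qend, matched, mismatches) of the best segment
    (leftmost on ties).  Empty input -> zero-width segment.
    """
    if len(match) == 0:
        return 0, 0, 0, 0
    scores = np.where(match, 1, -1).astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(scores)))
    running_min = np.minimum.accumulate(csum[:-1])
    gains = csum[1:] - running_min
    end = int(np.argmax(gains)) + 1
    start = int(np.argmin(csum[:end]))
    seg = match[start:end]
    matched = int(np.count_nonzero(seg))
    return start, end, matched, len(seg) - matched


def map_read(
    sequence: str,
    index: ReferenceIndex,
    read_id: str = "read",
    seed_stride: int | None = None,
    max_hits_per_seed: int = 64,
) -> list[Alignment]:
    """Map one read; returns alignments sorted best-first.

    Seeds are sampled from both the read and its reverse complement at
    ``seed_stride`` (default k//3, always including the final k-mer), every
    seeded diagonal is evaluated by ungapped extension, and mapq is derived
    from the gap between the best and second-best diagonal scores.
    """
    k = index.k
    qlen = len(sequence)
    if qlen < k:
        return []
    fwd = encode(sequence)
    rev = encode_revcomp(fwd)
    stride = seed_stride if seed_stride else max(1, k // 3)

    # candidate diagonals: (strand, reference index, query start on reference)
    candidates: set[tuple[str, int, int]] = set()
    bounds = index._bounds
    for strand, codes in (("+", fwd), ("-", rev)):
        kms = kmer_codes(codes, k)
        qpositions = list(range(0, len(kms), stride))
        if qpositions[-1] != len(kms) - 1:
            qpositions.append(len(kms) - 1)
        for qpos in qpositions:
            kmer = int(kms[qpos])
            if kmer < 0:
                continue
            hits = index.lookup(kmer)
            if len(hits) > max_hits_per_seed:
                continue
            for gpos in hits:
                ref_idx = int(np.searchsorted(bounds, int(gpos), side="right")) - 1
                local = int(gpos) - index.offsets[ref_idx] - qpos
                candidates.add((strand, ref_idx, local))

    alignments: list[Alignment] = []
    for strand, ref_idx, local in candidates:
        codes = fwd if strand == "+" else rev
        ref_codes = index.codes[ref_idx]
        q_lo = max(0, -local)
        q_hi = min(qlen, len(ref_codes) - local)
        if q_hi - q_lo < k:
            continue
        window = ref_codes[local + q_lo : local + q_hi]
        query = codes[q_lo:q_hi]
        match = (window == query) & (query < 4) & (window < 4)
        seg_start, seg_end, matched, mism = _best_segment(match)
        if matched == 0:
            continue
        qstart = q_lo + seg_start
        qend = q_lo + seg_end
        rstart = local + qstart
        rend = local + qend
        if strand == "-":
            qstart, qend = qlen - qend, qlen - qstart
        alignments.append(
            Alignment(
                read_id=read_id,
                reference=index.names[ref_idx],
                start=rstart,
                end=rend,
                strand=strand,
                qstart=qstart,
                qend=qend,
                query_length=qlen,
                matched_bp=matched,
                mismatches=mism,
                mapq=0,
                n_cooptimal=1,
            )
        )

    if not alignments:
        return []
    alignments.sort(key=lambda a: (-a.score, a.reference, a.start, a.strand))
    best = alignments[0].score
    n_cooptimal = sum(1 for a in alignments if a.score == best)
    second = alignments[1].score if len(alignments) > 1 else None
    if n_cooptimal > 1:
        mapq = 0
    elif second is None:
        mapq = MAPQ_CAP
    else:
        mapq = min(MAPQ_CAP, MAPQ_PER_SCORE * (best - second))
    for aln in alignments:
        aln.n_cooptimal = n_cooptimal if aln.score == best else 1
        aln.mapq = mapq if aln.score == best else 0
    return alignments


def best_by_reference(alignments: list[Alignment]) -> dict[str, Alignment]:
    """Best-scoring alignment per reference name (input need not be sorted)."""
    best: dict[str, Alignment] = {}
    for aln in alignments:
        cur = best.get(aln.reference)
        if cur is None or aln.score > cur.score:
            best[aln.reference] = aln
    return best


def pair_status(
    aln1: Alignment | None, aln2: Alignment | None, max_insert: int
) -> str:
    """Classify a mate pair: properly_paired | discordant | single.

    Properly paired means same reference, opposite strands, and an implied
    insert no longer than ``max_insert``.
    """
    if aln1 is None or aln2 is None:
        return "single"
    if aln1.reference != aln2.reference or aln1.strand == aln2.strand:
        return "discordant"
    left, right = (aln1, aln2) if aln1.start <= aln2.start else (aln2, aln1)
    insert = right.end - left.start
    if insert <= max_insert and insert > 0:
        return "properly_paired"
    return "discordant"
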