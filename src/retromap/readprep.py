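"""Pre-alignment stages of the LTR-anchored (TraDIS-style) analysis.

A raw read pair passes through three steps before mapping:

1. overlap merging of the mates (>= 10 bp overlap, FLASH-style);
2. detection and removal of the library-specific LTR anchor prefix -- the
   terminal 37 nt of the 3'-LTR for 3'-end libraries, or the reverse
   complement of the first 32 nt of the 5'-LTR for 5'-end libraries;
3. removal of splinkerette adapter read-through at the 3' end.

A read whose anchor is immediately followed by the splinkerette adapter
carries no host insert and is flagged for rejection downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats import ProvirusRef, Read, revcomp

# Splinkerette V1.2 annealed adapter oligos (phosphorothioate marks removed).
SPLINKERETTE_TOP = "GTTCCCATGGTACTACTCATATAATACGACTCACTATAGGTGACAGCGAGCGCT"
SPLINKERETTE_BOTTOM = "GCGCTCGCTGTCACCTATAGTGAGTCGTATTATAATTTTTTTTTCAAAAAAA"

# Anchor prefixes expected at the start of every authentic library read.
ANCHOR_3 = "CTCAGACCCTTTTAGTCAGTGTGGAAAATCTCTAGCA"  # 3'-LTR terminal 37 nt
ANCHOR_5 = "TTGTCTTTTTTGGGACCAAATTAGCCCTTCCA"  # revcomp of 5'-LTR first 32 nt

#: bases of adapter required to call splinkerette read-through
MIN_ADAPTER_OVERLAP = 10
#: anchor may start this close after a sequencing-error-shifted position
SPLINK_WINDOW = 5
#: shortest anchor prefix accepted (terminus-eroded junctions keep less)
MIN_ANCHOR_MATCH = 20


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


@dataclass
class PreppedRead:
    """One library read after merging, anchor removal and adapter trimming.

    ``anchor_complete`` records whether the full anchor -- including the LTR
    terminal dinucleotide -- was present; junctions from terminus-eroded
    proviruses retain only a partial anchor and can never be classified as
    integrase-catalyzed.
    """

    id: str
    host_sequence: str
    evidence: str  # "merged" | "paired"
    ltr_end: int | None  # 5 | 3 | None
    anchor_found: bool
    anchor_complete: bool = False
    anchor_match_len: int = 0
    splinkerette_immediately_after_anchor: bool = False
    host_qual: str = ""


def merge_pairs(
    read1: Read,
    read2: Read,
    min_overlap: int = 10,
    max_mismatch_fraction: float = 0.1,
) -> Read | None:
    """Merge a mate pair into one read if they overlap by >= ``min_overlap``.

    Read 2 is reverse-complemented, all suffix/prefix overlaps satisfying
    the mismatch bound are scored, and the overlap with the most matching
    columns wins (longer overlap on ties).  Disagreeing columns take the
    higher-quality base; quality ties take read 1.  Returns ``None`` when no
    acceptable overlap exists -- a valid outcome, the pair is analyzed
    unmerged.
    """
    seq2 = revcomp(read2.seq)
    qual2 = read2.qual[::-1]
    best: tuple[int, int] | None = None  # (matches, overlap_len)
    max_olap = min(len(read1), len(read2))
    for olap in range(max_olap, min_overlap - 1, -1):
        mism = _hamming(read1.seq[-olap:], seq2[:olap])
        if mism <= max_mismatch_fraction * olap:
            cand = (olap - mism, olap)
            if best is None or cand > best:
                best = cand
    if best is None:
        return None
    olap = best[1]
    head = read1.seq[: len(read1) - olap]
    head_q = read1.qual[: len(read1) - olap]
    tail = seq2[olap:]
    tail_q = qual2[olap:]
    mid = []
    mid_q = []
    for i in range(olap):
        b1, q1 = read1.seq[len(read1) - olap + i], read1.qual[len(read1) - olap + i]
        b2, q2 = seq2[i], qual2[i]
        if b1 == b2 or q1 >= q2:
            mid.append(b1)
            mid_q.append(max(q1, q2) if b1 == b2 else q1)
        else:
            mid.append(b2)
            mid_q.append(q2)
    return Read(read1.id, head + "".join(mid) + tail, head_q + "".join(mid_q) + tail_q)


def strip_anchor(
    read: Read,
    provirus: ProvirusRef,
    which_end: int,
    mismatch_tolerance: int = 0,
    min_anchor_match: int = MIN_ANCHOR_MATCH,
    splinkerette: str = SPLINKERETTE_TOP,
    evidence: str = "merged",
) -> PreppedRead:
    """Detect and remove the end-specific LTR anchor from a read prefix.

    The longest anchor prefix of length >= ``min_anchor_match`` matching the
    read start within ``mismatch_tolerance`` substitutions is removed; the
    remainder is the candidate host flank.  ``anchor_complete`` is True only
    when the whole anchor (hence the LTR terminal dinucleotide) matched.
    The splinkerette flag marks adapter sequence starting within
    ``SPLINK_WINDOW`` bases after the anchor (an empty, host-free insert).
    """
    anchor = provirus.anchor(which_end)
    matched_len = 0
    for length in range(min(len(anchor), len(read)), min_anchor_match - 1, -1):
        if _hamming(read.seq[:length], anchor[:length]) <= mismatch_tolerance:
            matched_len = length
            break
    if matched_len == 0:
        return PreppedRead(
            id=read.id,
            host_sequence=read.seq,
            evidence=evidence,
            ltr_end=None,
            anchor_found=False,
            host_qual=read.qual,
        )
    rest = read.seq[matched_len:]
    rest_q = read.qual[matched_len:]
    probe = splinkerette[:MIN_ADAPTER_OVERLAP + 2]
    splink = False
    for offset in range(0, SPLINK_WINDOW + 1):
        window = rest[offset : offset + len(probe)]
        if len(window) < MIN_ADAPTER_OVERLAP:
            break
        if _hamming(window, probe[: len(window)]) <= len(window) // 10:
            splink = True
            break
    return PreppedRead(
        id=read.id,
        host_sequence=rest,
        evidence=evidence,
        ltr_end=which_end,
        anchor_found=True,
        anchor_complete=matched_len == len(anchor),
        anchor_match_len=matched_len,
        splinkerette_immediately_after_anchor=splink,
        host_qual=rest_q,
    )


def trim_splinkerette(read: Read, adapter: str = SPLINKERETTE_TOP) -> Read:
    """Remove splinkerette read-through from the 3' end of a read.

    The longest read suffix matching an adapter prefix (>= 10 bp, at most
    one mismatch per 10 bp) is removed; reads without adapter are returned
    unchanged.
    """
    if len(adapter) < MIN_ADAPTER_OVERLAP:
        raise ValueError("adapter must be at least 10 bp")
    n = len(read)
    for start in range(0, n - MIN_ADAPTER_OVERLAP + 1):
        olap = n - start
        window = adapter[:olap]
        if len(window) < MIN_ADAPTER_OVERLAP:
            break
        suffix = read.seq[start : start + len(window)]
        if _hamming(suffix, window) <= len(window) // 10:
            return Read(read.id, read.seq[:start], read.qual[:start])
    return read


@dataclass
class PrepReport:
    """Per-category tallies of the pre-alignment stage."""

    n_pairs: int = 0
    n_merged: int = 0
    n_paired: int = 0
    n_anchor_found: int = 0
    n_anchor_complete: int = 0
    n_splinkerette_rejected: int = 0

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write("category\tcount\n")
            for key, value in vars(self).items():
                out.write(f"{key[2:]}\t{value}\n")


def prep_pairs(
    pairs: list[tuple[Read, Read]],
    provirus: ProvirusRef,
    which_end: int,
    min_overlap: int = 10,
    mismatch_tolerance: int = 0,
    adapter: str = SPLINKERETTE_TOP,
) -> tuple[list[PreppedRead], PrepReport]:
    """Run merge -> anchor strip -> adapter trim over a library of pairs.

    Merged reads carry evidence "merged"; pairs without sufficient overlap
    are analyzed through the anchor-bearing mate (read 1) with evidence
    "paired".
    """
    report = PrepReport()
    prepped: list[PreppedRead] = []
    for read1, read2 in pairs:
        report.n_pairs += 1
        merged = merge_pairs(read1, read2, min_overlap=min_overlap)
        if merged is not None:
            report.n_merged += 1
            source, evidence = merged, "merged"
        else:
            report.n_paired += 1
            source, evidence = read1, "paired"
        prep = strip_anchor(
            source,
            provirus,
            which_end,
            mismatch_tolerance=mismatch_tolerance,
            splinkerette=adapter,
            evidence=evidence,
        )
        # adapter read-through is trimmed from the host flank *after* anchor
        # detection so that empty inserts are still flagged under the
        # splinkerette criterion rather than silently shortened
        trimmed = trim_splinkerette(Read(prep.id, prep.host_sequence, prep.host_qual), adapter)
        prep.host_sequence = trimmed.seq
        prep.host_qual = trimmed.qual
        if prep.anchor_found:
            report.n_anchor_found += 1
            if prep.anchor_complete:
                report.n_anchor_complete += 1
            if prep.splinkerette_immediately_after_anchor:
                report.n_splinkerette_rejected += 1
        prepped.append(prep)
    return prepped, report
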