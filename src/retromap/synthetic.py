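"""Synthetic study generator: host genomes, planted proviruses, and reads.

The generator emulates the statistical structure the analysis assumes:

* a multi-chromosome host genome with gene models tiled so that realized
  exon / intron / intergenic base fractions land within 2 percentage points
  of the configured targets (default 4% / 39% / 57%);
* proviruses planted either intact -- integrase-style, with the TG...CA
  terminal dinucleotides and a short target-site duplication -- or as
  recombination-style events with both termini eroded and no duplication;
* LTR-anchored amplicon libraries (anchor prefix, host flank, splinkerette
  adapter at the far end, 200-400 bp nominal fragments with a short-fragment
  tail that lets mates merge) plus host-only decoys and empty inserts;
* uniform paired whole-genome sequencing of a small population of nuclei,
  each nucleus carrying its own independently placed integrations, which is
  the desk-scale stand-in for a library made from millions of nuclei.

Every stage derives its random stream from ``SimConfig.seed`` alone, so a
configuration reproduces its study bit-for-bit.

Proviruses are planted only at junction-unambiguous sites: positions whose
host flank would extend the LTR terminal dinucleotide (microhomology, which
makes the boundary unassignable by definition) are redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .formats import GeneModel, GenomeRef, ProvirusRef, Read, revcomp
from .readprep import ANCHOR_3, ANCHOR_5, SPLINKERETTE_TOP

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

# rng stream labels, combined with the seed so stages are independent
_STREAM_GENOME = 1
_STREAM_PLANT = 2
_STREAM_TRADIS = 3
_STREAM_WGS = 4
_STREAM_PROVIRUS = 5


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults mirror the real study where it states a value: region fractions
    4/39/57%, ~300 bp amplicon fragments, 100-base paired reads, 48x WGS
    coverage, 250 bp between distinguishable sites.  The amplicon fragment
    minimum is set below twice the read length so that a realistic share of
    mate pairs overlaps and merges.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_lengths: tuple[int, ...] = ()
    target_region_fractions: tuple[float, float, float] = (0.04, 0.39, 0.57)
    n_integrations: int = 20
    integrase_fraction: float = 1.0
    truncation_spectrum: tuple[int, int] = (1, 200)
    tsd_length: int = 5
    fragment_size: tuple[int, int] = (150, 400)
    read_length: int = 100
    wgs_coverage: float = 48.0
    sequencing_error_rate: float = 0.001
    tradis_fragments_per_event: int = 6
    decoy_fraction: float = 0.10
    empty_insert_fraction: float = 0.05
    n_nuclei: int = 16
    min_event_spacing: int = 1000
    mean_gene_length: int = 8000

    def __post_init__(self) -> None:
        if not self.chromosome_lengths:
            self.chromosome_lengths = tuple([1_000_000] * self.n_chromosomes)
        self.n_chromosomes = len(self.chromosome_lengths)
        fe, fi, fn = self.target_region_fractions
        if min(fe, fi, fn) < 0 or abs(fe + fi + fn - 1.0) > 1e-9:
            raise ConfigError("region fractions must be non-negative and sum to 1")
        if self.read_length > self.fragment_size[0]:
            raise ConfigError("read_length must not exceed the fragment minimum")
        if self.fragment_size[0] > self.fragment_size[1]:
            raise ConfigError("fragment_size must be (min, max) with min <= max")
        if min(self.n_integrations, self.read_length, self.tsd_length, self.n_nuclei) < 0:
            raise ConfigError("counts must be non-negative")
        if not 0 <= self.integrase_fraction <= 1:
            raise ConfigError("integrase_fraction must lie in [0, 1]")
        if self.truncation_spectrum[0] < 1:
            raise ConfigError("truncation spectrum minimum is 1 bp")
        if not 0 <= self.tsd_length <= 10:
            raise ConfigError("tsd_length must lie in 0..10")


@dataclass
class IntegrationTruth:
    """Ground truth for one planted provirus.

    ``position`` is the insertion point in *original* host coordinates: the
    provirus sits between host bases position-1 and position.  Integrase
    events duplicate ``tsd_length`` host bases flanking the insert;
    recombination-style events erode ``missing_bp = (at 5' terminus, at 3'
    terminus)`` and duplicate nothing.  ``modified_start`` locates the first
    inserted base in the modified chromosome.
    """

    chromosome: str
    position: int
    orientation: str
    completeness: str  # "full" | "truncated"
    missing_bp: tuple[int, int]
    tsd_length: int
    insert_length: int = 0
    modified_start: int = 0

    def expected_junction(self, which_end: int) -> tuple[str, int, str]:
        """(chrom, position, strand) a caller should report for this end."""
        right_side = (which_end == 3) == (self.orientation == "+")
        if right_side:
            return self.chromosome, self.position - self.tsd_length, "+"
        return self.chromosome, self.position - 1, "-"

    def detectable(self, which_end: int, min_anchor_match: int = 20) -> bool:
        """Whether the end retains enough anchor for the caller to see it."""
        from .readprep import ANCHOR_3 as A3, ANCHOR_5 as A5

        missing = self.missing_bp[1] if which_end == 3 else self.missing_bp[0]
        anchor_len = len(A3) if which_end == 3 else len(A5)
        return anchor_len - missing >= min_anchor_match


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def genome_codes(genome: GenomeRef) -> dict[str, np.ndarray]:
    from .align import encode

    return {name: encode(seq) for name, seq in genome.sequences.items()}


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def mutate(seq: str, rng: np.random.Generator, rate: float) -> tuple[str, str]:
    """Apply uniform substitution errors; returns (sequence, quality).

    Qualities are a constant Q37 with error-injected positions at Q10 --
    base quality is not used by any downstream filter, only mapping quality
    is, so a flat profile suffices.
    """
    qual = ["F"] * len(seq)
    if rate <= 0:
        return seq, "".join(qual)
    arr = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        orig = arr[i]
        if orig not in "ACGT":
            continue
        choices = [b for b in "ACGT" if b != orig]
        arr[i] = choices[rng.integers(0, 3)]
        qual[i] = "+"
    return "".join(arr), "".join(qual)


def synthetic_provirus(
    seed: int = 0, ltr_length: int = 634, internal_length: int = 732
) -> ProvirusRef:
    """A miniature provirus with authentic LTR termini.

    The two LTRs are identical, begin with the real 5'-terminal 32 nt
    (reverse complement of the 5'-library anchor, so the genome starts TG)
    and end with the real 3'-terminal 37 nt (the 3'-library anchor, ending
    CA); everything between is random.  Default total length 2 kb keeps
    whole-genome simulations desk-sized while preserving the junction
    structure the callers interrogate.
    """
    rng = np.random.default_rng([seed, _STREAM_PROVIRUS])
    head = revcomp(ANCHOR_5)
    tail = ANCHOR_3
    filler = ltr_length - len(head) - len(tail)
    if filler < 0:
        raise ConfigError("ltr_length shorter than the two anchor regions")
    ltr = head + _random_sequence(rng, filler) + tail
    internal = _random_sequence(rng, internal_length)
    return ProvirusRef(sequence=ltr + internal + ltr, ltr_length=ltr_length)


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def _tile_genes(
    rng: np.random.Generator, chrom: str, length: int, config: SimConfig
) -> list[GeneModel]:
    fe, fi, _ = config.target_region_fractions
    genic = fe + fi
    if genic <= 0:
        return []
    gene_mean = config.mean_gene_length
    if length < 2 * gene_mean:
        raise ConfigError(
            f"chromosome {chrom}: length {length} too short for gene tiling "
            f"at mean gene length {gene_mean}"
        )
    gap_mean = gene_mean * (1 - genic) / genic
    exon_frac = fe / genic
    genes: list[GeneModel] = []
    pos = 0
    n = 0
    while True:
        gap = int(round(gap_mean * rng.uniform(0.75, 1.25)))
        gene_len = int(round(gene_mean * rng.uniform(0.75, 1.25)))
        start = pos + gap
        if start + gene_len > length:
            break
        exon_total = max(2, int(round(gene_len * exon_frac)))
        n_exons = int(rng.integers(3, 7))
        if exon_total < n_exons or gene_len - exon_total < n_exons - 1:
            n_exons = 1
        exon_sizes = [exon_total // n_exons] * n_exons
        for i in range(exon_total - sum(exon_sizes)):
            exon_sizes[i] += 1
        intron_total = gene_len - exon_total
        n_introns = n_exons - 1
        intron_sizes = [intron_total // n_introns] * n_introns if n_introns else []
        for i in range(intron_total - sum(intron_sizes)):
            intron_sizes[i] += 1
        exons = []
        cursor = start
        for i, size in enumerate(exon_sizes):
            exons.append((cursor, cursor + size))
            cursor += size
            if i < n_introns:
                cursor += intron_sizes[i]
        n += 1
        genes.append(
            GeneModel(
                gene_id=f"g{chrom}_{n:04d}",
                chromosome=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                exons=exons,
            )
        )
        pos = start + gene_len
    return genes


def simulate_genome(config: SimConfig) -> GenomeRef:
    """Random host genome whose region composition matches the targets.

    Genes alternate with intergenic gaps sized so that realized exon /
    intron / intergenic fractions land within +-2 percentage points of
    ``target_region_fractions``; each gene starts and ends with an exon.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, _STREAM_GENOME])
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    for i, length in enumerate(config.chromosome_lengths, start=1):
        chrom = f"chr{i}"
        sequences[chrom] = _random_sequence(rng, length)
        genes.extend(_tile_genes(rng, chrom, length, config))
    genome = GenomeRef(sequences=sequences, genes=genes)
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# provirus planting
# ---------------------------------------------------------------------------

def _junction_unambiguous(host: str, p: int, tsd_eff: int) -> bool:
    # right flank must not begin with CA (would extend the 3'-terminal CA of
    # the read-orientation anchor); left flank must not end with TG (its
    # reverse complement would do the same for the opposite-side library)
    return host[p - tsd_eff : p - tsd_eff + 2] != "CA" and host[p - 2 : p] != "TG"


def plant_integrations(
    genome: GenomeRef,
    provirus: ProvirusRef,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenomeRef, list[IntegrationTruth]]:
    """Insert ``config.n_integrations`` proviruses; return modified genome + truth.

    Integrase events insert the intact provirus (terminal TG...CA preserved)
    with a ``tsd_length`` target-site duplication; recombination-style
    events erode both termini by draws from ``truncation_spectrum`` and
    duplicate nothing.  Events are spaced by at least ``min_event_spacing``
    and placed only at junction-unambiguous sites (bounded redraws).

    The returned :class:`GenomeRef` carries no gene models: its coordinates
    are shifted by the insertions, so annotation stays with the original
    reference frame.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, _STREAM_PLANT])
    if config.n_integrations == 0:
        return GenomeRef(dict(genome.sequences), []), []
    margin = config.fragment_size[1] + 10
    names = list(genome.sequences)
    lengths = np.array([len(genome.sequences[n]) for n in names], dtype=float)
    weights = lengths / lengths.sum()
    chosen: dict[str, list[int]] = {name: [] for name in names}
    events: list[IntegrationTruth] = []
    lo, hi = config.truncation_spectrum
    for _ in range(config.n_integrations):
        integrase = rng.random() < config.integrase_fraction
        tsd_eff = config.tsd_length if integrase else 0
        for attempt in range(1000):
            chrom = names[rng.choice(len(names), p=weights)]
            host = genome.sequences[chrom]
            if len(host) < 2 * margin:
                continue
            p = int(rng.integers(margin, len(host) - margin))
            if any(abs(p - q) < config.min_event_spacing for q in chosen[chrom]):
                continue
            if not _junction_unambiguous(host, p, tsd_eff):
                continue
            break
        else:
            raise ConfigError("could not place integration after 1000 redraws")
        chosen[chrom].append(p)
        if integrase:
            missing = (0, 0)
            completeness = "full"
        else:
            missing = (int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1)))
            completeness = "truncated"
        insert_len = len(provirus.sequence) - missing[0] - missing[1]
        events.append(
            IntegrationTruth(
                chromosome=chrom,
                position=p,
                orientation="+" if rng.random() < 0.5 else "-",
                completeness=completeness,
                missing_bp=missing,
                tsd_length=tsd_eff,
                insert_length=insert_len,
            )
        )

    modified: dict[str, str] = {}
    for name in names:
        host = genome.sequences[name]
        todo = sorted(
            (e for e in events if e.chromosome == name), key=lambda e: e.position
        )
        pieces = []
        prev = 0
        shift = 0
        for event in todo:
            m5, m3 = event.missing_bp
            insert = provirus.sequence[m5 : len(provirus.sequence) - m3]
            if event.orientation == "-":
                insert = revcomp(insert)
            p = event.position
            pieces.append(host[prev:p])
            pieces.append(insert)
            event.modified_start = p + shift
            prev = p - event.tsd_length
            shift += len(insert) + event.tsd_length
        pieces.append(host[prev:])
        modified[name] = "".join(pieces)
    return GenomeRef(sequences=modified, genes=[]), events


# ---------------------------------------------------------------------------
# TraDIS amplicon simulation
# ---------------------------------------------------------------------------

def _amplicon(
    modified_seq: str,
    truth: IntegrationTruth,
    provirus: ProvirusRef,
    which_end: int,
    fraglen: int,
) -> str | None:
    """LTR-anchored amplicon sequence for one event end, or None if the
    anchor region is fully eroded (no priming possible)."""
    anchor = provirus.anchor(which_end)
    missing = truth.missing_bp[1] if which_end == 3 else truth.missing_bp[0]
    anchor_eff = len(anchor) - missing
    if anchor_eff <= 0:
        return None
    flanklen = max(fraglen - anchor_eff, 30)
    right_side = (which_end == 3) == (truth.orientation == "+")
    if right_side:
        junction = truth.modified_start + truth.insert_length
        return modified_seq[junction - anchor_eff : junction + flanklen]
    junction = truth.modified_start
    return revcomp(modified_seq[junction - flanklen : junction + anchor_eff])


def simulate_tradis_reads(
    modified: GenomeRef,
    truths: Sequence[IntegrationTruth],
    provirus: ProvirusRef,
    config: SimConfig,
    which_end: int,
) -> list[tuple[Read, Read]]:
    """Simulate one LTR-anchored library (paired reads) for the chosen end.

    Signal amplicons begin at the (possibly eroded) anchor and run into the
    flanking host sequence; both fragment ends are read at ``read_length``,
    so fragments shorter than twice the read length produce overlapping
    (mergeable) mates.  Host-only decoy fragments and splinkerette-adjacent
    empty inserts are mixed in at the configured rates.
    """
    if which_end not in (3, 5):
        raise ValueError(f"which_end must be 3 or 5, got {which_end!r}")
    rng = np.random.default_rng([config.seed, _STREAM_TRADIS, which_end])
    rl = config.read_length
    fmin, fmax = config.fragment_size
    pairs: list[tuple[Read, Read]] = []

    def emit(name: str, amplicon: str) -> None:
        r1_seq = amplicon[:rl]
        r2_seq = revcomp(amplicon[-rl:])
        s1, q1 = mutate(r1_seq, rng, config.sequencing_error_rate)
        s2, q2 = mutate(r2_seq, rng, config.sequencing_error_rate)
        pairs.append((Read(name, s1, q1), Read(name, s2, q2)))

    n_signal = 0
    for idx, truth in enumerate(truths):
        seq = modified.sequences[truth.chromosome]
        for frag in range(config.tradis_fragments_per_event):
            fraglen = int(rng.integers(fmin, fmax + 1))
            amplicon = _amplicon(seq, truth, provirus, which_end, fraglen)
            if amplicon is None:
                continue
            emit(f"t{which_end}_ev{idx:03d}_f{frag}", amplicon)
            n_signal += 1

    names = list(modified.sequences)
    n_decoy = int(round(config.decoy_fraction * n_signal))
    for i in range(n_decoy):
        chrom = names[int(rng.integers(0, len(names)))]
        seq = modified.sequences[chrom]
        fraglen = int(rng.integers(fmin, fmax + 1))
        start = int(rng.integers(0, max(1, len(seq) - fraglen)))
        emit(f"decoy_{i:03d}", seq[start : start + fraglen])

    n_empty = int(round(config.empty_insert_fraction * n_signal))
    anchor = provirus.anchor(which_end)
    for i in range(n_empty):
        stub = _random_sequence(rng, int(rng.integers(0, 5)))
        pad = _random_sequence(rng, rl)
        emit(f"empty_{i:03d}", anchor + stub + SPLINKERETTE_TOP + pad)
    return pairs


# ---------------------------------------------------------------------------
# WGS simulation
# ---------------------------------------------------------------------------

def draw_wgs_pairs(
    codes_by_chrom: dict[str, np.ndarray],
    n_pairs: int,
    rng: np.random.Generator,
    fragment_size: tuple[int, int],
    read_length: int,
    error_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform paired sampling, vectorized; returns two (n, read_length)
    uint8 code arrays (mate 2 already reverse-complemented to read
    orientation)."""
    fmin, fmax = fragment_size
    rl = read_length
    names = list(codes_by_chrom)
    lengths = np.array([len(codes_by_chrom[n]) for n in names], dtype=float)
    alloc = rng.multinomial(n_pairs, lengths / lengths.sum())
    r1_parts, r2_parts = [], []
    for name, count in zip(names, alloc):
        if count == 0:
            continue
        codes = codes_by_chrom[name]
        fraglen = rng.integers(fmin, fmax + 1, size=count)
        fraglen = np.minimum(fraglen, len(codes))
        starts = (rng.random(count) * (len(codes) - fraglen + 1)).astype(np.int64)
        idx = np.arange(rl)
        left = codes[starts[:, None] + idx]
        right = codes[(starts + fraglen - rl)[:, None] + idx]
        # mate 2 reads the right fragment end on the opposite strand
        right_rc = right[:, ::-1].copy()
        valid = right_rc < 4
        right_rc[valid] = 3 - right_rc[valid]
        # half the fragments are sequenced from the other strand, which
        # swaps which physical end becomes mate 1
        flip = rng.random(count) < 0.5
        r1 = np.where(flip[:, None], right_rc, left)
        r2 = np.where(flip[:, None], left, right_rc)
        r1_parts.append(r1)
        r2_parts.append(r2)
    r1 = np.concatenate(r1_parts) if r1_parts else np.empty((0, rl), dtype=np.uint8)
    r2 = np.concatenate(r2_parts) if r2_parts else np.empty((0, rl), dtype=np.uint8)
    if error_rate > 0 and len(r1):
        for arr in (r1, r2):
            mask = (rng.random(arr.shape) < error_rate) & (arr < 4)
            arr[mask] = (arr[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    return r1, r2


def wgs_pair_count(total_length: int, config: SimConfig) -> int:
    return int(round(config.wgs_coverage * total_length / (2 * config.read_length)))


def simulate_wgs_reads(
    modified: GenomeRef, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform paired WGS of one (modified) genome at ``wgs_coverage``.

    Junction-spanning (partial), junction-straddling (independent) and
    provirus-internal (virus-only) evidence arises purely from fragment
    geometry.  Returns mate code arrays; use :func:`write_wgs_fastq` to
    materialize FASTQ.
    """
    if config.wgs_coverage <= 0:
        raise ConfigError("wgs_coverage must be positive")
    rng = np.random.default_rng([config.seed, _STREAM_WGS])
    codes = genome_codes(modified)
    n_pairs = wgs_pair_count(modified.total_length, config)
    return draw_wgs_pairs(
        codes, n_pairs, rng, config.fragment_size, config.read_length,
        config.sequencing_error_rate,
    )


def simulate_wgs_study(
    genome: GenomeRef,
    provirus: ProvirusRef,
    config: SimConfig,
    burden_per_nucleus: int = 2,
) -> tuple[np.ndarray, np.ndarray, list[list[IntegrationTruth]]]:
    """WGS of a population of ``config.n_nuclei`` nuclei.

    Each nucleus receives ``burden_per_nucleus`` independently placed
    integrations (via :func:`plant_integrations`); the joint library is
    sequenced to ``wgs_coverage`` of the base genome, i.e. each nucleus
    contributes coverage/n_nuclei.  This reproduces, at desk scale, the key
    property of a real library from many nuclei: integration sites are
    (almost) private to a nucleus and each is sampled by only a few pairs.
    """
    rng = np.random.default_rng([config.seed, _STREAM_WGS, 1])
    n_total = wgs_pair_count(genome.total_length, config)
    alloc = rng.multinomial(n_total, np.full(config.n_nuclei, 1 / config.n_nuclei))
    r1_parts, r2_parts, truths = [], [], []
    nucleus_cfg = replace(config, n_integrations=burden_per_nucleus)
    for k in range(config.n_nuclei):
        nucleus_rng = np.random.default_rng([config.seed, _STREAM_WGS, 2, k])
        modified, truth = plant_integrations(
            genome, provirus, nucleus_cfg, rng=nucleus_rng
        )
        truths.append(truth)
        r1, r2 = draw_wgs_pairs(
            genome_codes(modified), int(alloc[k]), nucleus_rng,
            config.fragment_size, config.read_length, config.sequencing_error_rate,
        )
        r1_parts.append(r1)
        r2_parts.append(r2)
    return np.concatenate(r1_parts), np.concatenate(r2_parts), truths


def write_wgs_fastq(
    r1: np.ndarray, r2: np.ndarray, prefix: str, id_prefix: str = "wgs"
) -> tuple[str, str]:
    """Write mate code arrays as a FASTQ pair; returns the two paths."""
    paths = (f"{prefix}_1.fastq", f"{prefix}_2.fastq")
    for arr, path in zip((r1, r2), paths):
        with open(path, "w") as out:
            qual = "F" * arr.shape[1] if len(arr) else ""
            for i in range(len(arr)):
                out.write(f"@{id_prefix}_{i}\n{decode(arr[i])}\n+\n{qual}\n")
    return paths


def write_truth_bed(truths: Sequence[IntegrationTruth], path: str) -> None:
    """Ground-truth insertion points as BED (0-based, single-base)."""
    with open(path, "w") as out:
        out.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for i, t in enumerate(truths):
            out.write(
                f"{t.chromosome}\t{t.position}\t{t.position + 1}\t"
                f"{t.completeness}\t{i}\t{t.orientation}\n"
            )
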