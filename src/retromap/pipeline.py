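"""End-to-end orchestration: simulate -> prep -> align -> call -> annotate
-> report, with a JSON manifest (parameters, output checksums) per run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import annotate as annotate_mod
from .align import ReferenceIndex, build_index, map_read
from .formats import (
    GenomeRef,
    ProvirusRef,
    Read,
    write_calls_bed,
    write_fasta,
    write_fastq,
    write_gff,
    write_rates_tsv,
)
from .readprep import prep_pairs
from .synthetic import (
    SimConfig,
    plant_integrations,
    simulate_genome,
    simulate_tradis_reads,
    simulate_wgs_study,
    synthetic_provirus,
    write_truth_bed,
)
from .tradis import (
    ClusterSet,
    FilterParams,
    JunctionCall,
    call_sites,
    cluster_positions,
    dedup_and_unique,
    library_summary,
)
from .wgs import PROVIRUS_REF, analyze_wgs_arrays

log = logging.getLogger("retromap")


@dataclass
class TradisResult:
    """Everything one LTR-end library run produces."""

    which_end: int
    prepped: list
    rejections: dict
    calls: list[JunctionCall]
    unique: list[JunctionCall]
    clusters: ClusterSet


def run_tradis_library(
    pairs: Sequence[tuple[Read, Read]],
    genome: GenomeRef,
    provirus: ProvirusRef,
    which_end: int,
    params: FilterParams | None = None,
    index: ReferenceIndex | None = None,
) -> TradisResult:
    """Prep, align and call one LTR-anchored library against the reference.

    Host flanks compete across host and provirus in a joint index; the
    four authenticity criteria then gate every call.
    """
    params = params or FilterParams()
    if index is None:
        refs = dict(genome.sequences)
        refs[PROVIRUS_REF] = provirus.sequence
        index = build_index(refs)
    prepped, _report = prep_pairs(
        pairs,
        provirus,
        which_end,
        min_overlap=params.min_overlap_merge,
        mismatch_tolerance=params.anchor_mismatch_tolerance,
    )
    alignments = {}
    for read in prepped:
        if read.anchor_found and not read.splinkerette_immediately_after_anchor:
            alignments[read.id] = map_read(read.host_sequence, index, read_id=read.id)
    calls, tally = call_sites(prepped, alignments, params, genome, provirus)
    unique = dedup_and_unique(calls)
    clusters = cluster_positions(unique, radius=params.cluster_radius)
    return TradisResult(
        which_end=which_end,
        prepped=prepped,
        rejections=dict(tally),
        calls=calls,
        unique=unique,
        clusters=clusters,
    )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(65536), b""):
            digest.update(block)
    return digest.hexdigest()


def run_pipeline(config: SimConfig, outdir: str | os.PathLike,
                 params: FilterParams | None = None,
                 wgs: bool = True) -> dict:
    """Run a complete synthetic study and write report files + manifest.

    Stages: simulate genome and provirus, plant integrations, simulate and
    call both LTR-end amplicon libraries, classify sites against the gene
    annotation, build the per-chromosome rate table, and (optionally) run a
    small whole-genome-sequencing burden estimate.  Returns the manifest,
    which is also written as ``manifest.json``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or FilterParams()
    log.info("simulating genome (%d chromosomes)", config.n_chromosomes)
    genome = simulate_genome(config)
    provirus = synthetic_provirus(config.seed)
    modified, truths = plant_integrations(genome, provirus, config)

    write_fasta(genome.sequences, out / "reference.fa")
    write_gff(genome.genes, out / "genes.gff3")
    write_fasta({PROVIRUS_REF: provirus.sequence}, out / "provirus.fa")
    write_truth_bed(truths, out / "truth.bed")

    refs = dict(genome.sequences)
    refs[PROVIRUS_REF] = provirus.sequence
    index = build_index(refs)

    results: dict[int, TradisResult] = {}
    all_calls: list[JunctionCall] = []
    for end in (5, 3):
        log.info("TraDIS library, %d'-end", end)
        pairs = simulate_tradis_reads(modified, truths, provirus, config, end)
        reads1, reads2 = zip(*pairs) if pairs else ((), ())
        write_fastq(reads1, out / f"tradis_{end}p_1.fastq")
        write_fastq(reads2, out / f"tradis_{end}p_2.fastq")
        result = run_tradis_library(pairs, genome, provirus, end, params, index)
        results[end] = result
        all_calls.extend(result.calls)
        write_calls_bed(result.unique, out / f"calls_{end}p.bed")

    summary = library_summary(all_calls, {e: r.clusters for e, r in results.items()})
    summary.to_csv(out / "library_summary.tsv", sep="\t", index=False)

    counts = {
        end: pd.Series([c.chromosome for c in results[end].unique])
        .value_counts()
        .to_dict()
        if results[end].unique
        else {}
        for end in (5, 3)
    }
    rates = annotate_mod.rate_table(counts[5], counts[3], genome.lengths)
    write_rates_tsv(rates, out / "rates.tsv")

    sites = [
        (cl.chromosome, cl.representative)
        for end in (5, 3)
        for cl in results[end].clusters.clusters
    ]
    stats = annotate_mod.region_stats(sites, genome) if sites else None
    if stats:
        with open(out / "region_stats.json", "w") as handle:
            json.dump(
                {
                    "genome_fractions": stats.genome_fractions,
                    "site_counts": stats.site_counts,
                    "site_fractions": stats.site_fractions,
                    "n_sites": stats.n_sites,
                    "p_noncoding_bias": stats.p_noncoding_bias,
                },
                handle,
                indent=2,
            )

    manifest: dict = {
        "config": asdict(config),
        "filter_params": asdict(params),
        "n_truth_events": len(truths),
        "tradis": {
            str(end): {
                "n_calls": len(results[end].calls),
                "unique_positions": len(results[end].unique),
                "unique_clusters": len(results[end].clusters),
                "rejections": results[end].rejections,
            }
            for end in (5, 3)
        },
    }

    if wgs:
        log.info("WGS burden estimate")
        r1, r2, nucleus_truths = simulate_wgs_study(genome, provirus, config)
        run = analyze_wgs_arrays(
            r1, r2, genome, provirus,
            read_length=config.read_length, index=index,
            max_insert=config.fragment_size[1],
        )
        estimate = {
            "x": run.x,
            "r_pairs": run.r_pairs,
            "segments_per_diploid": run.estimate.segments_per_diploid,
            "per_nucleus": run.estimate.per_nucleus,
            "ci": list(run.estimate.ci),
            "per_organism": run.estimate.per_organism,
            "category_counts": run.category_counts(),
            "n_planted": sum(len(t) for t in nucleus_truths),
        }
        with open(out / "wgs_estimate.json", "w") as handle:
            json.dump(estimate, handle, indent=2)
        manifest["wgs"] = estimate

    manifest["outputs"] = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest
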