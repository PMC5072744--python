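"""Synthetic study generator: composition targets, junction structure,
read geometry, determinism."""

import numpy as np
import pytest

from retromap.annotate import genome_composition
from retromap.formats import revcomp
from retromap.readprep import ANCHOR_3, SPLINKERETTE_TOP
from retromap.synthetic import (
    ConfigError,
    SimConfig,
    plant_integrations,
    simulate_genome,
    simulate_tradis_reads,
    simulate_wgs_reads,
    synthetic_provirus,
    wgs_pair_count,
)
from retromap.wgs import provirus_kmer_table, screen_pairs


class TestConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SimConfig(target_region_fractions=(0.5, 0.5, 0.5))

    def test_read_length_bounded_by_fragment_minimum(self):
        with pytest.raises(ConfigError):
            SimConfig(read_length=200, fragment_size=(150, 400))

    def test_integrase_fraction_bounds(self):
        with pytest.raises(ConfigError):
            SimConfig(integrase_fraction=1.5)


class TestSimulateGenome:
    def test_region_fractions_within_two_points(self, annotated_genome):
        genome, config = annotated_genome
        realized = genome_composition(genome)
        for got, want in zip(realized, config.target_region_fractions):
            assert abs(got - want) <= 0.02

    def test_all_intergenic_yields_no_genes(self):
        config = SimConfig(seed=3, chromosome_lengths=(100_000,),
                           target_region_fractions=(0.0, 0.0, 1.0))
        genome = simulate_genome(config)
        assert genome.genes == []

    def test_same_seed_reproduces_genome(self):
        config = SimConfig(seed=9, chromosome_lengths=(60_000,))
        g1 = simulate_genome(config)
        g2 = simulate_genome(config)
        assert g1.sequences == g2.sequences
        assert [g.exons for g in g1.genes] == [g.exons for g in g2.genes]

    def test_infeasible_length_rejected(self):
        config = SimConfig(seed=0, chromosome_lengths=(5_000,))
        with pytest.raises(ConfigError, match="too short"):
            simulate_genome(config)


@pytest.fixture(scope="module")
def planted(small_genome, provirus):
    config = SimConfig(seed=21, n_integrations=8, integrase_fraction=1.0,
                       chromosome_lengths=(50_000,))
    return plant_integrations(small_genome, provirus, config) + (config,)


class TestPlantIntegrations:

    def test_all_full_events_have_intact_termini(self, planted, provirus):
        modified, truths, _ = planted
        assert len(truths) == 8
        for t in truths:
            assert t.completeness == "full" and t.missing_bp == (0, 0)
            insert = modified.sequences[t.chromosome][
                t.modified_start : t.modified_start + t.insert_length
            ]
            assert insert.startswith("TG") and insert.endswith("CA")
            expected = provirus.sequence
            if t.orientation == "-":
                expected = revcomp(expected)
            assert insert == expected

    def test_target_site_duplication_flanks_insert(self, planted, small_genome):
        modified, truths, config = planted
        host = small_genome.sequences["chr1"]
        for t in truths:
            mod = modified.sequences[t.chromosome]
            left = mod[t.modified_start - 50 : t.modified_start]
            right = mod[
                t.modified_start + t.insert_length : t.modified_start
                + t.insert_length + 50
            ]
            assert left == host[t.position - 50 : t.position]
            assert right == host[t.position - t.tsd_length : t.position - t.tsd_length + 50]
            # the tsd_length bases immediately flanking both junctions agree
            assert left[-t.tsd_length:] == right[: t.tsd_length]

    def test_zero_integrations_leaves_genome_unchanged(self, small_genome, provirus):
        config = SimConfig(seed=1, n_integrations=0)
        modified, truths = plant_integrations(small_genome, provirus, config)
        assert truths == []
        assert modified.sequences == small_genome.sequences

    def test_truncated_events_lack_terminal_dinucleotides(self, small_genome, provirus):
        config = SimConfig(seed=5, n_integrations=6, integrase_fraction=0.0,
                           truncation_spectrum=(5, 5), chromosome_lengths=(50_000,))
        modified, truths = plant_integrations(small_genome, provirus, config)
        for t in truths:
            assert t.completeness == "truncated"
            assert t.missing_bp == (5, 5)
            assert t.tsd_length == 0
            insert = modified.sequences[t.chromosome][
                t.modified_start : t.modified_start + t.insert_length
            ]
            oriented = insert if t.orientation == "+" else revcomp(insert)
            assert not oriented.startswith("TG")
            assert not oriented.endswith("CA")


class TestSimulateTradisReads:
    def test_signal_read1_begins_with_full_anchor(self, small_genome, provirus):
        config = SimConfig(seed=33, n_integrations=4, integrase_fraction=1.0,
                           sequencing_error_rate=0.0, decoy_fraction=0.0,
                           empty_insert_fraction=0.0)
        modified, truths = plant_integrations(small_genome, provirus, config)
        pairs = simulate_tradis_reads(modified, truths, provirus, config, 3)
        assert pairs
        for r1, _ in pairs:
            assert r1.seq.startswith(ANCHOR_3)

    def test_short_fragment_mates_overlap_by_expected_amount(self, small_genome, provirus):
        config = SimConfig(seed=34, n_integrations=2, integrase_fraction=1.0,
                           sequencing_error_rate=0.0, decoy_fraction=0.0,
                           empty_insert_fraction=0.0, fragment_size=(150, 150))
        modified, truths = plant_integrations(small_genome, provirus, config)
        pairs = simulate_tradis_reads(modified, truths, provirus, config, 3)
        for r1, r2 in pairs:
            assert r1.seq[-50:] == revcomp(r2.seq)[:50]

    def test_truncated_junction_lacks_terminal_adjacency(self, small_genome, provirus):
        config = SimConfig(seed=35, n_integrations=4, integrase_fraction=0.0,
                           truncation_spectrum=(5, 5), sequencing_error_rate=0.0,
                           decoy_fraction=0.0, empty_insert_fraction=0.0)
        modified, truths = plant_integrations(small_genome, provirus, config)
        pairs = simulate_tradis_reads(modified, truths, provirus, config, 3)
        assert pairs
        for r1, _ in pairs:
            assert not r1.seq.startswith(ANCHOR_3)
            assert r1.seq.startswith(ANCHOR_3[:-5])

    def test_empty_inserts_carry_adjacent_splinkerette(self, small_genome, provirus):
        config = SimConfig(seed=36, n_integrations=4, integrase_fraction=1.0,
                           sequencing_error_rate=0.0, decoy_fraction=0.0,
                           empty_insert_fraction=0.5)
        modified, truths = plant_integrations(small_genome, provirus, config)
        pairs = simulate_tradis_reads(modified, truths, provirus, config, 3)
        empties = [r1 for r1, _ in pairs if r1.id.startswith("empty")]
        assert empties
        for r1 in empties:
            tail = r1.seq[len(ANCHOR_3):]
            assert SPLINKERETTE_TOP[:10] in tail[:15]

    def test_invalid_end_rejected(self, small_genome, provirus):
        config = SimConfig(seed=1, n_integrations=1)
        modified, truths = plant_integrations(small_genome, provirus, config)
        with pytest.raises(ValueError, match="which_end"):
            simulate_tradis_reads(modified, truths, provirus, config, 4)


class TestSimulateWgsReads:
    def test_pair_count_matches_coverage_arithmetic(self):
        config = SimConfig(seed=0, wgs_coverage=40.0, read_length=100)
        assert wgs_pair_count(1_000_000, config) == 200_000

    def test_unmodified_genome_has_no_provirus_evidence(self, small_genome, provirus):
        config = SimConfig(seed=44, chromosome_lengths=(50_000,), wgs_coverage=4.0,
                           sequencing_error_rate=0.0)
        r1, r2 = simulate_wgs_reads(small_genome, config)
        table = provirus_kmer_table(provirus)
        assert screen_pairs(r1, r2, table).sum() == 0

    def test_reproducible_from_seed(self, small_genome):
        config = SimConfig(seed=45, chromosome_lengths=(50_000,), wgs_coverage=2.0)
        a1, a2 = simulate_wgs_reads(small_genome, config)
        b1, b2 = simulate_wgs_reads(small_genome, config)
        assert np.array_equal(a1, b1) and np.array_equal(a2, b2)

    def test_coverage_must_be_positive(self, small_genome):
        config = SimConfig(seed=0, wgs_coverage=48.0)
        config.wgs_coverage = 0.0
        with pytest.raises(ConfigError):
            simulate_wgs_reads(small_genome, config)


class TestIntegraseFractionConvergence:
    def test_realized_fraction_tracks_config(self, small_genome, provirus):
        # binomial sampling bound: pooled over seeds, the realized integrase
        # fraction lands inside a 4-sigma band around the configured value
        n_full = 0
        total = 0
        for seed in range(6):
            config = SimConfig(seed=seed, n_integrations=10, integrase_fraction=0.3,
                               chromosome_lengths=(50_000,))
            _, truths = plant_integrations(small_genome, provirus, config)
            n_full += sum(1 for t in truths if t.completeness == "full")
            total += len(truths)
        p = n_full / total
        sigma = (0.3 * 0.7 / total) ** 0.5
        assert abs(p - 0.3) <= 4 * sigma
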