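"""Synthetic-data generator: planted truth, determinism, round trips."""

import numpy as np
import pytest

from fbxscape import seqs
from fbxscape.intervals import read_fasta, read_gff3
from fbxscape.simulate import (PlantedTruth, SimulationConfig, SizingError,
                               generate_est_library, generate_family_genome,
                               plant_pseudogene, replay_event_log,
                               simulate_birth_death_scenario,
                               write_simulation)
from fbxscape.spliced import spliced_align


class TestGenerateFamilyGenome:
    def test_locus_counts_follow_config(self, sim_data, sim_config):
        _, _, truth = sim_data
        assert len(truth.loci) == (sim_config.n_coding_loci
                                   + sim_config.n_pseudogene_loci)
        n_pseudo = sum(l.locus_class == "pseudogene" for l in truth.loci)
        assert n_pseudo == sim_config.n_pseudogene_loci

    def test_no_pseudogenes_means_no_lesions(self):
        cfg = SimulationConfig(seed=3, n_coding_loci=12, n_pseudogene_loci=0,
                               tandem_array_sizes=(2,), n_segmental_blocks=0)
        _, _, truth = generate_family_genome(cfg)
        assert all(l.events == [] for l in truth.loci)

    def test_same_seed_reproduces_identical_genome(self, sim_config, sim_data):
        genome2, refs2, _ = generate_family_genome(
            SimulationConfig(seed=sim_config.seed))
        genome, refs, _ = sim_data
        assert genome2 == genome and refs2 == refs

    def test_locus_spans_stay_compact(self, sim_data):
        _, _, truth = sim_data
        frac = np.mean([len(l.interval) < 5000 for l in truth.loci])
        assert frac >= 0.95

    def test_exons_splice_to_cds(self, sim_data):
        genome, _, truth = sim_data
        for locus in truth.loci:
            ex = sorted(locus.exons, key=lambda e: e.start)
            spliced = "".join(genome[e.sequence_id][e.start : e.end]
                              for e in ex)
            if locus.strand == "-":
                spliced = seqs.reverse_complement(spliced)
            assert spliced == locus.cds

    def test_coding_cds_translates_to_protein(self, sim_data):
        _, _, truth = sim_data
        for locus in truth.loci:
            if locus.locus_class == "coding":
                assert seqs.translate(locus.cds) == locus.protein

    def test_chromosome_too_short_raises(self):
        cfg = SimulationConfig(seed=0, chromosome_length=5000,
                               n_coding_loci=40, n_pseudogene_loci=10)
        with pytest.raises(SizingError):
            generate_family_genome(cfg)

    def test_truth_round_trips_through_json(self, sim_data):
        _, _, truth = sim_data
        again = PlantedTruth.from_json(truth.to_json())
        assert [l.interval for l in again.loci] \
            == [l.interval for l in truth.loci]
        assert [l.cds for l in again.loci] == [l.cds for l in truth.loci]
        assert again.config == truth.config

    def test_files_round_trip(self, sim_data, tmp_path):
        genome, refs, truth = sim_data
        write_simulation(tmp_path, genome, refs, truth)
        assert read_fasta(tmp_path / "genome.fa") == genome
        assert read_fasta(tmp_path / "references.fa") == refs
        again = PlantedTruth.from_json((tmp_path / "truth.json").read_text())
        assert len(again.loci) == len(truth.loci)
        features = read_gff3(tmp_path / "loci.gff3")
        genes = [f for f in features if f.feature_type in ("gene",
                                                           "pseudogene")]
        assert len(genes) == len(truth.loci)
        by_id = truth.by_id()
        for feat in genes:
            assert feat.interval == by_id[feat.attributes["ID"]].interval


class TestPlantPseudogene:
    @pytest.fixture()
    def clean_locus(self, rng):
        protein = seqs.random_protein(80, rng)
        cds = seqs.back_translate(protein, rng)
        intron = "GT" + seqs.random_dna(96, rng) + "AG"
        segment = cds[:120] + intron + cds[120:]
        exons = [(0, 120), (220, 220 + len(cds) - 120)]
        return protein, cds, segment, exons

    def test_single_deletion_reports_one_frameshift(self, clean_locus):
        protein, _, segment, exons = clean_locus
        mutated = plant_pseudogene(segment, exons, frameshift_positions=[150])
        aln = spliced_align(protein, mutated)
        assert len(aln.frameshifts) == 1
        assert aln.stops == []

    def test_stop_substitution_reports_one_stop(self, clean_locus):
        protein, _, segment, exons = clean_locus
        mutated = plant_pseudogene(segment, exons, stop_positions=[20])
        aln = spliced_align(protein, mutated)
        assert aln.frameshifts == []
        assert len(aln.stops) == 1

    def test_empty_spec_leaves_segment_unchanged(self, clean_locus):
        _, _, segment, exons = clean_locus
        assert plant_pseudogene(segment, exons) == segment

    def test_position_outside_exons_rejected(self, clean_locus):
        _, cds, segment, exons = clean_locus
        with pytest.raises(ValueError):
            plant_pseudogene(segment, exons,
                             frameshift_positions=[len(cds) + 5])


class TestEstLibrary:
    def test_depth_zero_means_empty_library(self, sim_data):
        _, _, truth = sim_data
        cfg = SimulationConfig(seed=1, est_depth=0.0)
        assert generate_est_library(truth, cfg) == {}

    def test_full_identity_reads_are_exact_substrings(self, sim_data):
        _, _, truth = sim_data
        cfg = SimulationConfig(seed=1, est_identity=1.0)
        ests = generate_est_library(truth, cfg)
        cds_by_id = {l.locus_id: l.cds for l in truth.loci}
        assert ests
        for name, read in ests.items():
            locus_id = name.split("_")[1]
            assert read in cds_by_id[locus_id]

    def test_reads_meet_identity_and_length_floor(self, sim_data,
                                                  sim_config):
        _, _, truth = sim_data
        ests = generate_est_library(truth, sim_config)
        expressed = {l.locus_id for l in truth.loci if l.expressed}
        for name, read in ests.items():
            assert len(read) >= 50
            assert name.split("_")[1] in expressed

    def test_uninformative_identity_rejected(self, sim_data):
        _, _, truth = sim_data
        cfg = SimulationConfig(seed=1, est_identity=0.4)
        with pytest.raises(ValueError):
            generate_est_library(truth, cfg)


class TestBirthDeath:
    TREE = "((A,B),(C,D));"

    def test_zero_rates_keep_root_size_everywhere(self):
        leaves, log = simulate_birth_death_scenario(self.TREE, 0.0, 0.0, 5)
        assert log == []
        assert all(len(genes) == 10 for genes in leaves.values())

    def test_replay_matches_leaf_sizes(self):
        leaves, log = simulate_birth_death_scenario(self.TREE, 1.2, 0.8, 9)
        sizes = replay_event_log(self.TREE, 10, log)
        assert {sp: len(g) for sp, g in leaves.items()} == sizes

    def test_loss_only_shrinks_families(self):
        leaves, log = simulate_birth_death_scenario(self.TREE, 0.0, 4.0, 2,
                                                    root_size=4)
        assert all(ev["type"] == "loss" for ev in log)
        assert min(len(g) for g in leaves.values()) < 4

    def test_fixed_seed_reproduces_event_log(self):
        _, log1 = simulate_birth_death_scenario(self.TREE, 1.0, 1.0, 11)
        _, log2 = simulate_birth_death_scenario(self.TREE, 1.0, 1.0, 11)
        assert log1 == log2

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_birth_death_scenario(self.TREE, -1.0, 0.0, 1)
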