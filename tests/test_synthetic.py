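"""The synthetic data generator: determinism, ledger fidelity, rate control."""

import math

import numpy as np
import pytest

import apes


class TestEvolveSequence:
    def test_zero_rate_identity(self, rng):
        seq = "ACDEFGHIKL" * 10
        assert apes.evolve_sequence(seq, 0.0, 50.0, rng) == seq

    def test_substituted_fraction_matches_expectation(self, rng):
        seq = "A" * 1000
        rate_t = 0.1
        out = apes.evolve_sequence(seq, rate_t, 1.0, rng)
        frac = sum(a != b for a, b in zip(seq, out)) / len(seq)
        p = 1 - math.exp(-rate_t)
        sigma = math.sqrt(p * (1 - p) / len(seq))
        assert abs(frac - p) <= 3 * sigma

    def test_saturation_limit(self, rng):
        # rate*t -> infinity: every site replaced by a uniformly random
        # *different* residue, so identity fraction ~ 0
        seq = "C" * 10000
        out = apes.evolve_sequence(seq, 100.0, 100.0, rng)
        frac_same = sum(a == b for a, b in zip(seq, out)) / len(seq)
        assert frac_same < 0.01

    def test_length_preserved_without_indels(self, rng):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 5
        assert len(apes.evolve_sequence(seq, 1e-2, 100.0, rng)) == len(seq)


class TestSimulationDeterminism:
    def test_identical_seeds_identical_datasets(self):
        cfg = dict(n_species=3, chromosomes=2, genes_per_chromosome=30,
                   inversion_rate=1e-3, deletion_rate=1e-3, seed=42,
                   duplications=[apes.DuplicationSpec(time=20, branch="S1",
                                                      n_genes=4)])
        ds1 = apes.simulate_dataset(apes.SimulationConfig(**cfg))
        ds2 = apes.simulate_dataset(apes.SimulationConfig(**cfg))
        assert ds1.sequences == ds2.sequences
        for sp in ds1.gene_tables:
            assert ds1.gene_tables[sp] == ds2.gene_tables[sp]
        assert [t.__dict__ for t in ds1.truth] == [t.__dict__ for t in ds2.truth]

    def test_different_seeds_differ(self):
        mk = lambda s: apes.simulate_dataset(
            apes.SimulationConfig(n_species=3, genes_per_chromosome=30, seed=s)
        )
        assert mk(1).sequences != mk(2).sequences


class TestZeroMutationIdentity:
    def test_shared_order_and_sequences(self):
        cfg = apes.SimulationConfig(n_species=3, chromosomes=2,
                                    genes_per_chromosome=25, base_rate=0.0,
                                    seed=50)
        ds = apes.simulate_dataset(cfg)
        ogs = {}
        for sp, table in ds.gene_tables.items():
            ogs[sp] = [g.orthogroup for g in table.genes()]
        ref = next(iter(ogs.values()))
        assert all(v == ref for v in ogs.values())
        by_og = {}
        for gid, seq in ds.sequences.items():
            og = ds.orthogroups.orthogroup_of(gid)
            by_og.setdefault(og, set()).add(seq)
        assert all(len(s) == 1 for s in by_og.values())

    def test_full_diagonal_nano_block(self):
        cfg = apes.SimulationConfig(n_species=2, chromosomes=1,
                                    genes_per_chromosome=30, base_rate=0.0,
                                    seed=51)
        ds = apes.simulate_dataset(cfg)
        a, b = (ds.condensed(sp) for sp in sorted(ds.gene_tables))
        nano, _ = apes.compare_genomes(a, b)
        assert len(nano) == 1 and nano[0].k == 30


class TestPlantedDuplications:
    def test_zero_rate_duplication_gives_zero_delta(self):
        cfg = apes.SimulationConfig(
            n_species=2, chromosomes=1, genes_per_chromosome=40,
            base_rate=0.0, seed=52,
            duplications=[apes.DuplicationSpec(time=20, branch="S1",
                                               n_genes=4, r_source=0.0,
                                               r_target=0.0)],
        )
        ds = apes.simulate_dataset(cfg)
        truth = ds.truth[0]
        sp = truth.species_with_copy[0]
        for u_src, u_tgt in zip(truth.source_uids, truth.target_uids):
            assert ds.sequences[f"{sp}_g{u_src}"] == \
                ds.sequences[f"{sp}_g{u_tgt}"]

    def test_ledger_matches_recovered_events(self):
        # battery of configurations: every planted event recovered, no
        # false positives, source/target correct
        for seed in (60, 61, 62):
            cfg = apes.SimulationConfig(
                n_species=4, chromosomes=2, genes_per_chromosome=50,
                seed=seed,
                duplications=[
                    apes.DuplicationSpec(time=25, branch="S1", n_genes=5),
                    apes.DuplicationSpec(time=40, branch="S2", n_genes=6,
                                         target_chromosome="chr2",
                                         source_chromosome="chr1"),
                ],
            )
            ds = apes.simulate_dataset(cfg)
            assert len(ds.truth) == 2
            for truth in ds.truth:
                focal = truth.species_with_copy[0]
                ct = ds.condensed(focal)
                _, micro_self = apes.compare_genomes(ct, ct)
                events = apes.find_within_genome_duplications(micro_self, ct)
                matches = [
                    ev for ev in events
                    if set(ev.copy1.tdec_ids) | set(ev.copy2.tdec_ids) ==
                    set(truth.source_gene_ids(focal)) |
                    set(truth.target_gene_ids(focal))
                ]
                assert len(matches) == 1
            # no false positives: every recovered event maps to a ledger entry
            focal_all = set(sp for t in ds.truth for sp in t.species_with_copy)
            for sp in focal_all:
                ct = ds.condensed(sp)
                _, micro_self = apes.compare_genomes(ct, ct)
                events = apes.find_within_genome_duplications(micro_self, ct)
                planted_ids = set()
                for t in ds.truth:
                    if sp in t.species_with_copy:
                        planted_ids |= set(t.source_gene_ids(sp))
                        planted_ids |= set(t.target_gene_ids(sp))
                for ev in events:
                    ids = set(ev.copy1.tdec_ids) | set(ev.copy2.tdec_ids)
                    assert ids <= planted_ids

    def test_interchromosomal_duplication_distance(self):
        cfg = apes.SimulationConfig(
            n_species=2, chromosomes=2, genes_per_chromosome=40, seed=63,
            duplications=[apes.DuplicationSpec(
                time=20, branch="S1", n_genes=4, source_chromosome="chr1",
                target_chromosome="chr2")],
        )
        ds = apes.simulate_dataset(cfg)
        truth = ds.truth[0]
        sp = truth.species_with_copy[0]
        ct = ds.condensed(sp)
        _, micro_self = apes.compare_genomes(ct, ct)
        ev = apes.find_within_genome_duplications(micro_self, ct)[0]
        assert math.isinf(ev.inter_copy_distance)


class TestRateAsymmetryGrid:
    def test_polarity_monotone_in_rate_ratio(self):
        p_by_ratio = {}
        for ratio in (1, 2, 4):
            trips, _ = apes.simulate_triplet_battery(
                600, r_source=1e-3, r_target=ratio * 1e-3,
                t_dup=40, t_div=90, seed=70 + ratio,
            )
            p_by_ratio[ratio] = apes.overall_polarity(trips).p_neg
        assert p_by_ratio[1] < p_by_ratio[2] < p_by_ratio[4]
        assert abs(p_by_ratio[1] - 0.5) < 0.1


class TestGeneTrees:
    def test_single_copy_trees_match_species_tree_leaves(self):
        cfg = apes.SimulationConfig(n_species=4, chromosomes=1,
                                    genes_per_chromosome=20, seed=80)
        ds = apes.simulate_dataset(cfg)
        og = sorted(ds.gene_trees)[0]
        labels = {lf.taxon.label for lf in
                  ds.gene_trees[og].leaf_node_iter()}
        assert len(labels) == 4
        assert {l.rsplit("_g", 1)[0] for l in labels} == set(ds.gene_tables)

    def test_duplicated_tree_has_paralog_pairs(self, planted_dataset):
        truth = planted_dataset.truth[0]
        og = truth.orthogroups[2]
        gt = planted_dataset.gene_trees[og]
        labels = {lf.taxon.label for lf in gt.leaf_node_iter()}
        for sp in truth.species_with_copy:
            assert sum(1 for l in labels if l.startswith(f"{sp}_")) == 2


class TestValidation:
    def test_bad_duplication_time_rejected(self):
        with pytest.raises(apes.ValidationError):
            apes.simulate_dataset(apes.SimulationConfig(
                crown_age=50,
                duplications=[apes.DuplicationSpec(time=60, branch="S1",
                                                   n_genes=4)],
            ))

    def test_tiny_duplication_rejected(self):
        with pytest.raises(apes.ValidationError):
            apes.SimulationConfig(
                duplications=[apes.DuplicationSpec(time=10, branch="S1",
                                                   n_genes=2)],
            ).validate()
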