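"""Duplication filters, source/target assignment and triplet extraction."""

import math

import pytest

import apes
from conftest import make_block, make_tdec_table


@pytest.fixture
def self_table():
    # chr1 carries two copies of the segment [d, e, f, g]
    return make_tdec_table(
        "A", {"chr1": ["a", "b", "c", "d", "e", "f", "g", "h",
                       "d", "e", "f", "g", "i", "j"]}
    )


def self_block(pairs, **kw):
    kw.setdefault("species_a", "A")
    kw.setdefault("species_b", "A")
    return make_block(pairs, **kw)


class TestFilters:
    def test_identity_diagonal_removed(self, self_table):
        diag = self_block([(i, i) for i in range(14)])
        assert apes.find_within_genome_duplications([diag], self_table) == []

    def test_repeated_tdec_removed(self, self_table):
        # pair list visiting row 3 twice -> same TDEC twice
        b = self_block([(3, 8), (3, 9), (5, 10), (6, 11)])
        assert apes.filter_self_blocks([b], self_table) == []

    def test_larger_of_overlapping_blocks_kept(self, self_table):
        big = self_block([(3, 8), (4, 9), (5, 10), (6, 11), (7, 12)])
        small = self_block([(3, 9), (4, 10), (5, 11)])
        kept = apes.filter_self_blocks([big, small], self_table)
        assert kept == [big]

    def test_filters_idempotent(self, self_table):
        blocks = [
            self_block([(i, i) for i in range(14)]),
            self_block([(3, 8), (4, 9), (5, 10), (6, 11)]),
            self_block([(3, 9), (4, 10), (5, 11)]),
        ]
        once = apes.filter_self_blocks(blocks, self_table)
        twice = apes.filter_self_blocks(once, self_table)
        assert once == twice

    def test_no_shared_genes_after_filtering(self, self_table):
        blocks = [
            self_block([(3, 8), (4, 9), (5, 10), (6, 11)]),
            self_block([(4, 9), (5, 10), (6, 11), (7, 12)]),
            self_block([(0, 8), (1, 9), (2, 10)]),
        ]
        kept = apes.filter_self_blocks(blocks, self_table)
        for i, b1 in enumerate(kept):
            for b2 in kept[i + 1:]:
                assert not (b1.rows() & b2.rows()) or \
                    not (b1.cols() & b2.cols())


class TestEventConstruction:
    def test_event_from_planted_segment(self, self_table):
        b = self_block([(3, 8), (4, 9), (5, 10), (6, 11)])
        mirror = self_block([(8, 3), (9, 4), (10, 5), (11, 6)])
        events = apes.find_within_genome_duplications([b, mirror], self_table)
        assert len(events) == 1
        ev = events[0]
        assert ev.orthogroup_sequence == ("d", "e", "f", "g")
        assert ev.copy1.indices == (3, 4, 5, 6)
        assert ev.copy2.indices == (8, 9, 10, 11)

    def test_inter_copy_distance_same_chromosome(self, self_table):
        b = self_block([(3, 8), (4, 9), (5, 10), (6, 11)])
        ev = apes.find_within_genome_duplications([b], self_table)[0]
        # gap between TDEC 6 end and TDEC 8 start (one intervening gene)
        assert 0 < ev.inter_copy_distance < 2 * 2000

    def test_inter_chromosomal_distance_infinite(self):
        t = make_tdec_table("A", {"chr1": ["a", "b", "c", "d", "e"],
                                  "chr2": ["x", "b", "c", "d", "y"]})
        b = self_block([(1, 1), (2, 2), (3, 3)], chrom_a="chr1",
                       chrom_b="chr2")
        ev = apes.find_within_genome_duplications([b], t)[0]
        assert math.isinf(ev.inter_copy_distance)


class TestPrimaryMicrosynteny:
    def test_largest_block_wins(self):
        t = make_tdec_table("A", {"chr1": list("abcdefgh")})
        tdec = t.get("chr1", 2)
        b_small = make_block([(2, 5), (3, 6), (4, 7)], species_a="A")
        b_big = make_block([(0, 0), (1, 1), (2, 2), (3, 3), (4, 4)],
                           species_a="A")
        got = apes.primary_microsynteny(tdec, [b_small, b_big], {"A": t})
        assert got is b_big

    def test_single_block_identity(self):
        t = make_tdec_table("A", {"chr1": list("abc")})
        b = make_block([(0, 0), (1, 1), (2, 2)], species_a="A")
        assert apes.primary_microsynteny(t.get("chr1", 1), [b], {"A": t}) is b

    def test_gene_in_no_block(self):
        t = make_tdec_table("A", {"chr1": list("abc")})
        assert apes.primary_microsynteny(t.get("chr1", 0), [], {"A": t}) is None

    def test_matches_argmax_oracle(self, rng):
        t = make_tdec_table("A", {"chr1": [f"og{i}" for i in range(30)]})
        for _ in range(100):
            idx = int(rng.integers(0, 30))
            tdec = t.get("chr1", idx)
            blocks = []
            for _ in range(int(rng.integers(1, 6))):
                lo = int(rng.integers(0, idx + 1))
                hi = int(rng.integers(idx, 30))
                blocks.append(make_block([(i, i) for i in range(lo, hi + 1)],
                                         species_a="A"))
            got = apes.primary_microsynteny(tdec, blocks, {"A": t})
            best_k = max(b.k for b in blocks)
            assert got.k == best_k


class TestAssignSourceTarget:
    def _event(self):
        t = make_tdec_table(
            "A", {"chr1": ["a", "b", "c", "d", "e", "f", "g", "h",
                           "c", "d", "e", "i", "j", "k"]}
        )
        b = self_block([(2, 8), (3, 9), (4, 10)])
        ev = apes.find_within_genome_duplications([b], t)[0]
        return t, ev

    def test_larger_cross_block_is_source(self):
        t, ev = self._event()
        # copy1 (idx 2..4) flanked context: big block vs reference B
        big = make_block([(i, i) for i in range(8)], species_a="A",
                         species_b="B")
        small = make_block([(8, 2), (9, 3), (10, 4)], species_a="A",
                           species_b="B")
        ev = apes.assign_source_target(ev, [big, small])
        assert ev.source_copy == "copy1"
        assert ev.source.indices == (2, 3, 4)
        assert ev.l_target == ev.copy2.length_bp

    def test_tie_gives_undetermined(self):
        t, ev = self._event()
        b1 = make_block([(2, 2), (3, 3), (4, 4)], species_a="A", species_b="B")
        b2 = make_block([(8, 2), (9, 3), (10, 4)], species_a="A", species_b="B")
        ev = apes.assign_source_target(ev, [b1, b2])
        assert ev.source_copy == "undetermined"

    def test_missing_cross_synteny_undetermined(self):
        t, ev = self._event()
        only1 = make_block([(2, 2), (3, 3), (4, 4)], species_a="A",
                           species_b="B")
        ev = apes.assign_source_target(ev, [only1])
        assert ev.source_copy == "undetermined"

    def test_antisymmetric_under_copy_swap(self):
        t, ev = self._event()
        big = make_block([(i, i) for i in range(8)], species_a="A",
                         species_b="B")
        small = make_block([(8, 2), (9, 3), (10, 4)], species_a="A",
                           species_b="B")
        ev = apes.assign_source_target(ev, [big, small])
        swapped = apes.DuplicationEvent(
            event_id=ev.event_id, species=ev.species, copy1=ev.copy2,
            copy2=ev.copy1, orthogroup_sequence=ev.orthogroup_sequence,
        )
        swapped = apes.assign_source_target(swapped, [big, small])
        assert {ev.source_copy, swapped.source_copy} == {"copy1", "copy2"}
        assert ev.source == swapped.source


class TestPlantedRecovery:
    def test_planted_duplication_recovered_with_correct_source(
            self, planted_dataset, planted_condensed):
        truth = planted_dataset.truth[0]
        focal = truth.species_with_copy[0]
        ct = planted_condensed[focal]
        _, micro_self = apes.compare_genomes(ct, ct)
        events = apes.find_within_genome_duplications(micro_self, ct)
        assert len(events) == 1
        ev = events[0]
        src_ids = set(truth.source_gene_ids(focal))
        tgt_ids = set(truth.target_gene_ids(focal))
        assert set(ev.copy1.tdec_ids) | set(ev.copy2.tdec_ids) == \
            src_ids | tgt_ids

        # reference: species that diverged before the duplication
        ref = next(sp for sp in planted_dataset.gene_tables
                   if sp not in truth.species_with_copy)
        _, cross = apes.compare_genomes(ct, planted_condensed[ref])
        ev = apes.assign_source_target(ev, cross)
        assert ev.source is not None
        assert set(ev.source.tdec_ids) == src_ids

    def test_triplet_extraction_counts(self, planted_dataset,
                                       planted_condensed):
        truth = planted_dataset.truth[0]
        focal = truth.species_with_copy[0]
        ct = planted_condensed[focal]
        _, micro_self = apes.compare_genomes(ct, ct)
        ev = apes.find_within_genome_duplications(micro_self, ct)[0]
        ref = next(sp for sp in planted_dataset.gene_tables
                   if sp not in truth.species_with_copy)
        cr = planted_condensed[ref]
        _, cross = apes.compare_genomes(ct, cr)
        ev = apes.assign_source_target(ev, cross)
        trips = apes.extract_triplets(ev, cr, ct, cross)
        # every planted orthogroup position present in all three regions
        assert len(trips) == len(truth.orthogroups)
        for t in trips:
            assert t.a1.tdec_id in truth.source_gene_ids(focal)
            assert t.a2.tdec_id in truth.target_gene_ids(focal)
            assert t.b1.species == ref
            assert t.b1.orthogroup == t.orthogroup
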