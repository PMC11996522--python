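"""Synthetic multi-species datasets with planted duplications.

Generates everything the analysis consumes — per-species gene tables,
orthogroup assignments, protein sequences, a calibrated species tree
and per-orthogroup gene trees — from a shared ancestral gene order
evolved down a species tree with segmental rearrangements, planted
multi-gene duplications (known source/target, size, insertion distance
and timing) and controlled per-copy substitution rates.  A ground-truth
ledger records every planted event so recovered events can be checked
against what was planted.

Sequence evolution uses per-site uniform replacement: over time t at
rate r (substitutions/site/MY) each site is replaced with probability
1 - exp(-r t) by a uniformly chosen different residue.  The default
model has no indels, so Levenshtein distance reduces to Hamming
distance on equal-length pairs, isolating the rate-asymmetry signal
from alignment-length effects; an indel mode exists to exercise true
edit distances.

Defaults describe a mammal-like regime: base rate 1e-3
substitutions/site/MY (about 0.2 substitutions/site across an 87 MY
divergence), 300-residue proteins, two chromosomes of 100 genes, crown
age 100 MYA.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from .duplications import GeneTriplet
from .genome_io import (GeneRecord, GeneTable, OrthogroupMap, ValidationError,
                        annotate_node_ages, tree_from_string)
from .homology import TDEC, TdecTable, condense_tandem

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class DuplicationSpec:
    """One planted multi-gene duplication.

    ``branch`` names a leaf species; the duplication is placed on the
    root-to-leaf path at ``time`` MYA, so every species descending from
    that point inherits both copies.  ``target_chromosome`` None means
    the target copy inserts on the source chromosome,
    ``target_offset_genes`` genes downstream of the source segment.
    """

    time: float
    branch: str
    n_genes: int
    source_chromosome: Optional[str] = None
    target_chromosome: Optional[str] = None
    target_offset_genes: Optional[int] = None
    r_source: Optional[float] = None
    r_target: Optional[float] = None


@dataclass
class SimulationConfig:
    n_species: int = 4
    crown_age: float = 100.0
    species_tree: Optional[str] = None  # newick; None -> random topology
    chromosomes: int = 2
    genes_per_chromosome: int = 100
    tandem_array_rate: float = 0.0
    dispersed_duplicate_rate: float = 0.0  # gene joins an earlier gene's orthogroup
    inversion_rate: float = 0.0       # per branch per gene
    translocation_rate: float = 0.0
    deletion_rate: float = 0.0
    duplications: List[DuplicationSpec] = field(default_factory=list)
    sequence_length: int = 300
    base_rate: float = 1e-3           # substitutions/site/MY
    indel_rate: float = 0.0           # per-sequence per-MY indel events
    gene_spacing: int = 2000          # bp between consecutive gene starts
    gene_length: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValidationError("need at least one species")
        for r in (self.tandem_array_rate, self.inversion_rate,
                  self.translocation_rate, self.deletion_rate,
                  self.base_rate, self.indel_rate):
            if r < 0:
                raise ValidationError("rates must be nonnegative")
        for d in self.duplications:
            if not (0 < d.time < self.crown_age):
                raise ValidationError(
                    f"duplication time {d.time} outside (0, crown_age)"
                )
            if d.n_genes < 3:
                raise ValidationError("planted duplications need >= 3 genes")


@dataclass
class PlantedDuplication:
    """Ground-truth ledger entry for one planted event."""

    event_id: str
    time: float
    species_with_copy: Tuple[str, ...]
    source_uids: Tuple[int, ...]
    target_uids: Tuple[int, ...]
    orthogroups: Tuple[str, ...]
    r_source: float
    r_target: float
    source_chromosome: str
    target_chromosome: str

    def source_gene_ids(self, species: str) -> Tuple[str, ...]:
        return tuple(f"{species}_g{u}" for u in self.source_uids)

    def target_gene_ids(self, species: str) -> Tuple[str, ...]:
        return tuple(f"{species}_g{u}" for u in self.target_uids)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    gene_tables: Dict[str, GeneTable]
    orthogroups: OrthogroupMap
    sequences: Dict[str, str]
    species_tree: dendropy.Tree
    gene_trees: Dict[str, dendropy.Tree]
    truth: List[PlantedDuplication]

    def condensed(self, species: str) -> TdecTable:
        return condense_tandem(self.gene_tables[species], self.orthogroups)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def evolve_sequence(seq: str, rate: float, t: float,
                    rng: np.random.Generator) -> str:
    """Per-site uniform replacement over time t at the given rate."""
    if rate * t < 0:
        raise ValidationError("rate * t must be nonnegative")
    if rate == 0 or t == 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    p = 1.0 - math.exp(-rate * t)
    mask = rng.random(arr.size) < p
    n = int(mask.sum())
    if n:
        cur = np.searchsorted(_AA, arr[mask])
        repl = (cur + rng.integers(1, len(_AA), size=n)) % len(_AA)
        arr[mask] = _AA[repl]
    return arr.tobytes().decode()


def _apply_indels(seq: str, rate: float, t: float,
                  rng: np.random.Generator) -> str:
    n_events = rng.poisson(rate * t)
    for _ in range(n_events):
        if len(seq) < 10:
            break
        pos = int(rng.integers(0, len(seq)))
        length = 1 + int(rng.geometric(0.5))
        if rng.random() < 0.5:
            seq = seq[:pos] + seq[pos + length:]
        else:
            ins = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=length))
            seq = seq[:pos] + ins + seq[pos:]
    return seq


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


def random_species_tree(n_species: int, crown_age: float,
                        rng: np.random.Generator) -> dendropy.Tree:
    """Random topology by sequential coalescence with sorted uniform ages."""
    names = [f"S{i+1}" for i in range(n_species)]
    if n_species == 1:
        return tree_from_string(f"{names[0]};")
    ages = np.sort(rng.uniform(0.0, crown_age, size=n_species - 1))
    ages[-1] = crown_age
    nodes: List[Tuple[str, float]] = [(nm, 0.0) for nm in names]
    for age in ages:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, aa), (nb, ab) = nodes[i], nodes[j]
        merged = f"({na}:{age - aa},{nb}:{age - ab})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append((merged, float(age)))
    return tree_from_string(nodes[0][0] + ";")


# ---------------------------------------------------------------------------
# Genome state during simulation
# ---------------------------------------------------------------------------


@dataclass
class _SimGene:
    uid: int
    orthogroup: str
    seq: str
    rate: float
    role: Optional[str] = None      # "source" | "target"
    event_id: Optional[str] = None

    def copy(self) -> "_SimGene":
        return _SimGene(self.uid, self.orthogroup, self.seq, self.rate,
                        self.role, self.event_id)


class _Simulator:
    def __init__(self, config: SimulationConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.uid_counter = 0
        self.truth: List[PlantedDuplication] = []
        self.event_info: Dict[str, dict] = {}
        if config.species_tree is not None:
            self.tree = tree_from_string(config.species_tree)
        else:
            self.tree = random_species_tree(config.n_species, config.crown_age,
                                            self.rng)
        annotate_node_ages(self.tree)
        self.leaf_genomes: Dict[str, Dict[str, List[_SimGene]]] = {}

    # -- helpers ----------------------------------------------------------

    def _new_uid(self) -> int:
        self.uid_counter += 1
        return self.uid_counter

    def _random_seq(self) -> str:
        idx = self.rng.integers(0, 20, size=self.cfg.sequence_length)
        return "".join(AA_ALPHABET[i] for i in idx)

    def _ancestral_genome(self) -> Dict[str, List[_SimGene]]:
        genome: Dict[str, List[_SimGene]] = {}
        og_counter = 0
        og_seqs: List[Tuple[str, str]] = []  # (orthogroup, founder sequence)
        for c in range(self.cfg.chromosomes):
            chrom = f"chr{c+1}"
            genes: List[_SimGene] = []
            while len(genes) < self.cfg.genes_per_chromosome:
                if og_seqs and self.cfg.dispersed_duplicate_rate > 0 and \
                        self.rng.random() < self.cfg.dispersed_duplicate_rate:
                    # dispersed single-gene duplicate: reuse an existing
                    # family, placing an off-diagonal homology dot
                    og, seq = og_seqs[int(self.rng.integers(0, len(og_seqs)))]
                    genes.append(_SimGene(self._new_uid(), og, seq,
                                          self.cfg.base_rate))
                    continue
                og_counter += 1
                og = f"OG{og_counter:05d}"
                n_copies = 1
                if self.cfg.tandem_array_rate > 0 and \
                        self.rng.random() < self.cfg.tandem_array_rate:
                    n_copies = 2 + int(self.rng.integers(0, 2))
                seq = self._random_seq()
                og_seqs.append((og, seq))
                for _ in range(n_copies):
                    genes.append(_SimGene(self._new_uid(), og, seq,
                                          self.cfg.base_rate))
            genome[chrom] = genes
        return genome

    def _evolve_genome(self, genome: Dict[str, List[_SimGene]], dt: float) -> None:
        if dt <= 0:
            return
        for chrom in sorted(genome):
            for g in genome[chrom]:
                seq = evolve_sequence(g.seq, g.rate, dt, self.rng)
                if self.cfg.indel_rate > 0:
                    seq = _apply_indels(seq, self.cfg.indel_rate, dt, self.rng)
                g.seq = seq

    # -- planted duplications ---------------------------------------------

    def _leaf_set(self, node) -> FrozenSet[str]:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def _events_on_edge(self, parent_age: float, child) -> List[DuplicationSpec]:
        leaves = self._leaf_set(child)
        out = [d for d in self.cfg.duplications
               if d.branch in leaves and child.age <= d.time < parent_age]
        out.sort(key=lambda d: -d.time)  # oldest first
        return out

    def _apply_duplication(self, genome: Dict[str, List[_SimGene]],
                           spec: DuplicationSpec, child) -> None:
        cfg = self.cfg
        margin = 5
        src_chrom = spec.source_chromosome
        if src_chrom is None:
            src_chrom = sorted(genome)[int(self.rng.integers(0, len(genome)))]
        genes = genome[src_chrom]
        if len(genes) < spec.n_genes + 2 * margin:
            raise ValidationError(
                f"chromosome {src_chrom} too short for a {spec.n_genes}-gene "
                "duplication with flanking margins"
            )
        # source segment must not touch genes of other planted events
        for _ in range(50):
            start = int(self.rng.integers(margin,
                                          len(genes) - spec.n_genes - margin + 1))
            seg = genes[start:start + spec.n_genes]
            if all(g.event_id is None for g in seg):
                break
        else:
            raise ValidationError("could not place duplication source segment")
        event_id = f"planted{len(self.truth)}"
        r_src = spec.r_source if spec.r_source is not None else cfg.base_rate
        r_tgt = spec.r_target if spec.r_target is not None else cfg.base_rate
        for g in seg:
            g.role, g.event_id, g.rate = "source", event_id, r_src
        copies = [_SimGene(self._new_uid(), g.orthogroup, g.seq, r_tgt,
                           "target", event_id) for g in seg]
        tgt_chrom = spec.target_chromosome or src_chrom
        if tgt_chrom == src_chrom:
            offset = spec.target_offset_genes
            if offset is None:
                offset = int(self.rng.integers(margin, max(margin + 1, 20)))
            ins = min(start + spec.n_genes + offset, len(genes))
            genome[src_chrom] = genes[:ins] + copies + genes[ins:]
        else:
            tgenes = genome[tgt_chrom]
            ins = int(self.rng.integers(margin, len(tgenes) - margin + 1))
            genome[tgt_chrom] = tgenes[:ins] + copies + tgenes[ins:]
        self.truth.append(
            PlantedDuplication(
                event_id=event_id, time=spec.time,
                species_with_copy=tuple(sorted(self._leaf_set(child))),
                source_uids=tuple(g.uid for g in seg),
                target_uids=tuple(g.uid for g in copies),
                orthogroups=tuple(g.orthogroup for g in seg),
                r_source=r_src, r_target=r_tgt,
                source_chromosome=src_chrom, target_chromosome=tgt_chrom,
            )
        )
        self.event_info[event_id] = {
            "attach_leaves": self._leaf_set(child),
            "time": spec.time,
            "source_uid_of_og": {g.orthogroup: g.uid for g in seg},
            "target_uid_of_og": {c.orthogroup: c.uid for c in copies},
        }

    # -- rearrangements ----------------------------------------------------

    def _segment(self, genes: List[_SimGene], mean_len: int = 4
                 ) -> Optional[Tuple[int, int]]:
        """A random planted-gene-free segment [i, j) (None if none found)."""
        if len(genes) < 2:
            return None
        for _ in range(20):
            length = min(1 + int(self.rng.geometric(1.0 / mean_len)), len(genes) - 1)
            i = int(self.rng.integers(0, len(genes) - length + 1))
            if all(g.event_id is None for g in genes[i:i + length]):
                return i, i + length
        return None

    def _insertion_point(self, genes: List[_SimGene]) -> int:
        """Random insertion index that does not split a planted copy."""
        for _ in range(20):
            pos = int(self.rng.integers(0, len(genes) + 1))
            left = genes[pos - 1] if pos > 0 else None
            right = genes[pos] if pos < len(genes) else None
            if (left is None or right is None or left.event_id is None
                    or left.event_id != right.event_id
                    or left.role != right.role):
                return pos
        return len(genes)

    def _apply_rearrangements(self, genome: Dict[str, List[_SimGene]]) -> None:
        cfg = self.cfg
        n_genes = sum(len(v) for v in genome.values())
        chroms = sorted(genome)
        for _ in range(self.rng.poisson(cfg.inversion_rate * n_genes)):
            chrom = chroms[int(self.rng.integers(0, len(chroms)))]
            seg = self._segment(genome[chrom])
            if seg:
                i, j = seg
                genome[chrom][i:j] = genome[chrom][i:j][::-1]
        for _ in range(self.rng.poisson(cfg.translocation_rate * n_genes)):
            chrom = chroms[int(self.rng.integers(0, len(chroms)))]
            seg = self._segment(genome[chrom])
            if not seg:
                continue
            i, j = seg
            moved = genome[chrom][i:j]
            genome[chrom] = genome[chrom][:i] + genome[chrom][j:]
            dest = chroms[int(self.rng.integers(0, len(chroms)))]
            pos = self._insertion_point(genome[dest])
            genome[dest] = genome[dest][:pos] + moved + genome[dest][pos:]
        for _ in range(self.rng.poisson(cfg.deletion_rate * n_genes)):
            chrom = chroms[int(self.rng.integers(0, len(chroms)))]
            genes = genome[chrom]
            candidates = [k for k, g in enumerate(genes) if g.event_id is None]
            if candidates:
                del genes[candidates[int(self.rng.integers(0, len(candidates)))]]

    # -- main recursion ----------------------------------------------------

    def run(self) -> SimulatedDataset:
        root_genome = self._ancestral_genome()
        self._descend(self.tree.seed_node, root_genome, self.tree.seed_node.age)
        return self._finalize()

    def _descend(self, node, genome: Dict[str, List[_SimGene]],
                 entry_age: float) -> None:
        # entry_age: age at which `genome` state is current on this lineage
        if node.is_leaf():
            self.leaf_genomes[node.taxon.label] = genome
            return
        for child in node.child_nodes():
            child_genome = {c: [g.copy() for g in genes]
                            for c, genes in genome.items()}
            t_top = entry_age
            for spec in self._events_on_edge(entry_age, child):
                self._evolve_genome(child_genome, t_top - spec.time)
                self._apply_duplication(child_genome, spec, child)
                t_top = spec.time
            self._evolve_genome(child_genome, t_top - child.age)
            self._apply_rearrangements(child_genome)
            self._descend(child, child_genome, child.age)

    # -- outputs -----------------------------------------------------------

    def _finalize(self) -> SimulatedDataset:
        cfg = self.cfg
        gene_tables: Dict[str, GeneTable] = {}
        sequences: Dict[str, str] = {}
        og_members: Dict[str, Set[str]] = {}
        presence: Dict[Tuple[str, int], bool] = {}
        for sp in sorted(self.leaf_genomes):
            genome = self.leaf_genomes[sp]
            records: List[GeneRecord] = []
            for chrom in sorted(genome):
                for pos, g in enumerate(genome[chrom]):
                    gid = f"{sp}_g{g.uid}"
                    start = 1 + cfg.gene_spacing * pos
                    records.append(
                        GeneRecord(gid, sp, chrom, start,
                                   start + cfg.gene_length - 1, "+",
                                   g.orthogroup)
                    )
                    sequences[gid] = g.seq
                    og_members.setdefault(g.orthogroup, set()).add(gid)
                    presence[(sp, g.uid)] = True
            gene_tables[sp] = GeneTable.from_records(sp, records)
        orthogroups = OrthogroupMap.from_groups(og_members)
        gene_trees = self._gene_trees(presence)
        return SimulatedDataset(
            config=cfg, gene_tables=gene_tables, orthogroups=orthogroups,
            sequences=sequences, species_tree=self.tree,
            gene_trees=gene_trees, truth=self.truth,
        )

    # -- true gene trees ---------------------------------------------------

    def _gene_trees(self, presence: Dict[Tuple[str, int], bool]
                    ) -> Dict[str, dendropy.Tree]:
        """Emit the true gene tree for each single-copy or once-duplicated
        orthogroup (tandem-array orthogroups are skipped)."""
        # orthogroup -> ancestral uid(s); skip ogs with >1 ancestral copy
        og_uid: Dict[str, int] = {}
        og_skip: Set[str] = set()
        og_event: Dict[str, str] = {}
        for eid, info in self.event_info.items():
            for og in info["source_uid_of_og"]:
                og_event[og] = eid
        seen: Dict[str, Set[int]] = {}
        for sp, genome in self.leaf_genomes.items():
            for chrom, genes in genome.items():
                for g in genes:
                    seen.setdefault(g.orthogroup, set()).add(g.uid)
        for og, uids in seen.items():
            if og in og_event:
                continue  # handled via event info
            if len(uids) > 1:
                og_skip.add(og)  # tandem array: no simple true tree emitted
            else:
                og_uid[og] = next(iter(uids))
        trees: Dict[str, dendropy.Tree] = {}
        for og, uid in og_uid.items():
            nwk = self._gene_tree_newick(og, uid, None, presence)
            if nwk:
                trees[og] = tree_from_string(nwk + ";")
        for og, eid in og_event.items():
            info = self.event_info[eid]
            nwk = self._gene_tree_newick(
                og, info["source_uid_of_og"][og], eid, presence
            )
            if nwk:
                trees[og] = tree_from_string(nwk + ";")
        return trees

    def _gene_tree_newick(self, og: str, uid: int, event_id: Optional[str],
                          presence: Dict[Tuple[str, int], bool]
                          ) -> Optional[str]:
        info = self.event_info.get(event_id) if event_id else None

        def sub(node, cur_uid: int, allow_dup: bool):
            # returns (newick, age) or None if the lineage left no leaves
            if node.is_leaf():
                sp = node.taxon.label
                if presence.get((sp, cur_uid)):
                    return f"{sp}_g{cur_uid}", 0.0
                return None
            parts = []
            for child in node.child_nodes():
                r = edge(node, child, cur_uid, allow_dup)
                if r is not None:
                    parts.append(r)
            if not parts:
                return None
            if len(parts) == 1:
                return parts[0]  # suppress unifurcation; age kept
            inner = ",".join(
                f"{nwk}:{node.age - age:g}" for nwk, age in parts
            )
            return f"({inner})", node.age

        def edge(parent, child, cur_uid: int, allow_dup: bool):
            dup_here = (
                allow_dup and info is not None
                and self._leaf_set(child) == info["attach_leaves"]
                and child.age <= info["time"] < parent.age
            )
            if dup_here:
                t = info["time"]
                src = sub(child, info["source_uid_of_og"][og], False)
                tgt = sub(child, info["target_uid_of_og"][og], False)
                if src and tgt:
                    inner = ",".join(
                        f"{nwk}:{t - age:g}" for nwk, age in (src, tgt)
                    )
                    return f"({inner})", t
                return src or tgt
            return sub(child, cur_uid, allow_dup)

        r = sub(self.tree.seed_node, uid, True)
        if r is None:
            return None
        return r[0]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full forward simulation described by *config*."""
    return _Simulator(config).run()


# ---------------------------------------------------------------------------
# Lightweight batteries (triplets and polarity signs without full genomes)
# ---------------------------------------------------------------------------


def _dummy_tdec(gene_id: str, species: str, og: str) -> TDEC:
    return TDEC(tdec_id=gene_id, species=species, chromosome="chr1",
                orthogroup=og, member_gene_ids=(gene_id,), order_index=0,
                representative_gene_id=gene_id, span_start=1, span_end=1000)


def simulate_triplet_battery(n_triplets: int, r_source: float, r_target: float,
                             t_dup: float, t_div: float,
                             sequence_length: int = 300,
                             base_rate: float = 1e-3,
                             seed: int = 0) -> Tuple[List[GeneTriplet],
                                                     Dict[str, str]]:
    """Independent gene triplets evolved on the after-speciation topology.

    The reference lineage B1 splits at t_div MYA and evolves at the
    base rate; the focal lineage evolves at the base rate until the
    duplication at t_dup (< t_div), after which the source copy A1
    evolves at r_source and the target copy A2 at r_target.  Distances
    and delta_dL are filled from the evolved sequences.
    """
    if not 0 < t_dup < t_div:
        raise ValidationError("need 0 < t_dup < t_div")
    rng = np.random.default_rng(seed)
    from .divergence import fill_delta_dL

    triplets: List[GeneTriplet] = []
    sequences: Dict[str, str] = {}
    for i in range(n_triplets):
        og = f"OG{i:05d}"
        anc = "".join(AA_ALPHABET[k] for k in rng.integers(0, 20,
                                                           size=sequence_length))
        b1 = evolve_sequence(anc, base_rate, t_div, rng)
        pre = evolve_sequence(anc, base_rate, t_div - t_dup, rng)
        a1 = evolve_sequence(pre, r_source, t_dup, rng)
        a2 = evolve_sequence(pre, r_target, t_dup, rng)
        ids = (f"F_a1_{i}", f"F_a2_{i}", f"R_b1_{i}")
        sequences[ids[0]], sequences[ids[1]], sequences[ids[2]] = a1, a2, b1
        trip = GeneTriplet(
            a1=_dummy_tdec(ids[0], "F", og), a2=_dummy_tdec(ids[1], "F", og),
            b1=_dummy_tdec(ids[2], "R", og), event_id=f"ev{i}",
            species_focal="F", species_ref="R", orthogroup=og,
            duplication_time=t_dup,
        )
        fill_delta_dL(trip, sequences)
        triplets.append(trip)
    return triplets, sequences


def simulate_polarity_signs(n_blocks: int, triplets_per_block,
                            mode: str = "independent", p_neg: float = 0.5,
                            p_zero: float = 0.0,
                            seed: int = 0) -> List[GeneTriplet]:
    """Sign-only triplet batteries for the block-wise polarization null.

    ``mode="block"`` draws one polarity sign per duplication and gives
    it to all member triplets (fully block-polarized data);
    ``mode="independent"`` draws each triplet's sign independently.
    ``triplets_per_block`` may be an int or a sequence of candidate
    block sizes sampled uniformly per block.
    """
    if mode not in {"block", "independent"}:
        raise ValidationError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    sizes = ([triplets_per_block] if isinstance(triplets_per_block, int)
             else list(triplets_per_block))
    out: List[GeneTriplet] = []
    for b in range(n_blocks):
        block_size = sizes[int(rng.integers(0, len(sizes)))]
        if mode == "block":
            block_sign = -1.0 if rng.random() < p_neg else 1.0
        for k in range(block_size):
            if rng.random() < p_zero:
                delta = 0.0
            elif mode == "block":
                delta = block_sign * 0.1
            else:
                delta = (-0.1 if rng.random() < p_neg else 0.1)
            gid = f"b{b}t{k}"
            trip = GeneTriplet(
                a1=_dummy_tdec(f"{gid}_a1", "F", gid),
                a2=_dummy_tdec(f"{gid}_a2", "F", gid),
                b1=_dummy_tdec(f"{gid}_b1", "R", gid),
                event_id=f"block{b}", species_focal="F", species_ref="R",
                orthogroup=gid, delta_dL=delta,
            )
            out.append(trip)
    return out


# ---------------------------------------------------------------------------
# On-disk emission (same formats genome_io reads)
# ---------------------------------------------------------------------------


def write_dataset(ds: SimulatedDataset, outdir: str) -> None:
    from .genome_io import write_fasta, write_gene_table, write_orthogroups

    os.makedirs(outdir, exist_ok=True)
    for sp, table in ds.gene_tables.items():
        write_gene_table(table, os.path.join(outdir, f"{sp}.genes.tsv"))
    write_orthogroups(ds.orthogroups, os.path.join(outdir, "Orthogroups.tsv"))
    write_fasta(ds.sequences, os.path.join(outdir, "proteins.faa"))
    ds.species_tree.write(path=os.path.join(outdir, "species_tree.nwk"),
                          schema="newick")
    with open(os.path.join(outdir, "gene_trees.nwk"), "w") as fh:
        for og in sorted(ds.gene_trees):
            fh.write(f"{og}\t{ds.gene_trees[og].as_string(schema='newick').strip()}\n")
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump([asdict(t) for t in ds.truth], fh, indent=1, default=str)
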