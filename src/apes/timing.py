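"""Dating multi-gene duplications on a calibrated species tree.

Two independent methods date each duplication, and their consensus is
deliberately conservative (we prefer to overestimate than
underestimate duplication times, keeping the after-speciation triplet
set clean):

1. *Gene-tree method.*  Duplication nodes in each orthogroup's gene
   tree are found by species-overlap (LCA) mapping: an internal node
   whose children's species sets intersect is a duplication, mapped to
   the species-tree MRCA of its leaf species.  Its support is the
   fraction of species descending from that species-tree node that
   retain both paralogs.  For a multi-gene duplication we take the
   oldest well-supported (support >= 0.5) node over its paralog pairs,
   falling back to the oldest node if none qualify.
2. *Multiple-copy MRCA.*  Every genome is scanned for two or more
   disjoint occurrences of the duplicated orthogroup sequence; the
   species-tree MRCA of all multiple-copy species upper-bounds the
   duplication age (assuming no recurrent duplication of one region).

The consensus node is the older of the two, and the duplication time
is the midpoint between the consensus node's age and its parent's age
(the root, having no parent, uses its own age).  A duplication is
classified after-speciation relative to a reference species iff its
time is strictly less than the species-pair divergence time; equality
counts as before-speciation, again the conservative choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import dendropy

from .duplications import DuplicationEvent
from .genome_io import TimeTable, ValidationError, annotate_node_ages
from .homology import TdecTable


@dataclass(frozen=True)
class DuplicationNode:
    """A duplication mapped to a species-tree node with an age in MYA."""

    species_set: FrozenSet[str]  # leaf species below the species-tree node
    age: float
    method: str  # {"gene_tree", "multi_copy_mrca", "consensus"}
    support: Optional[float] = None  # defined only for gene_tree


@dataclass
class TimedEvent:
    """A duplication event with its dated consensus node."""

    event: DuplicationEvent
    node_gene_tree: Optional[DuplicationNode]
    node_mrca: Optional[DuplicationNode]
    consensus_node: DuplicationNode
    t_dup: float


def default_species_of(label: str) -> str:
    """Species from a gene label of the form ``<species>_g<uid>``."""
    return label.rsplit("_g", 1)[0]


def _species_node_info(species_tree: dendropy.Tree
                       ) -> Dict[FrozenSet[str], float]:
    """Map each species-tree clade (as a leaf-label frozenset) to its age."""
    annotate_node_ages(species_tree)
    info: Dict[FrozenSet[str], float] = {}
    for node in species_tree.postorder_node_iter():
        leaves = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        info[leaves] = node.age
    return info


def _mrca_clade(clades: Iterable[FrozenSet[str]], species: Set[str]
                ) -> FrozenSet[str]:
    """Smallest species-tree clade containing all the given species."""
    best: Optional[FrozenSet[str]] = None
    for clade in clades:
        if species <= clade and (best is None or len(clade) < len(best)):
            best = clade
    if best is None:
        raise ValidationError(f"species {sorted(species)} not all in species tree")
    return best


def lca_map_duplications(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
                         species_of: Callable[[str], str] = default_species_of
                         ) -> List[Tuple[Tuple[str, str], DuplicationNode]]:
    """Species-overlap duplication mapping of a gene tree.

    Returns one entry per paralogous leaf pair split by a duplication
    node: ((leaf1, leaf2), DuplicationNode).  An internal gene-tree
    node is a duplication iff its children's species sets overlap; it
    maps to the species-tree MRCA of all its leaf species.
    """
    clades = _species_node_info(species_tree)
    tree_species = set().union(*clades) if clades else set()
    out: List[Tuple[Tuple[str, str], DuplicationNode]] = []
    leafsets: Dict[int, List[str]] = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = [node.taxon.label]
            continue
        children = node.child_nodes()
        child_leaves = [leafsets[id(c)] for c in children]
        child_species = [set(species_of(l) for l in ls) for ls in child_leaves]
        merged_species: Set[str] = set().union(*child_species)
        unknown = merged_species - tree_species
        if unknown:
            raise ValidationError(f"unknown species in gene tree: {sorted(unknown)}")
        is_dup = any(
            child_species[i] & child_species[j]
            for i in range(len(children)) for j in range(i + 1, len(children))
        )
        if is_dup:
            clade = _mrca_clade(clades, merged_species)
            both = set.intersection(*child_species) if len(child_species) > 1 else set()
            support = len(both & clade) / len(clade)
            dup = DuplicationNode(
                species_set=clade, age=clades[clade], method="gene_tree",
                support=support,
            )
            for ci in range(len(children)):
                for cj in range(ci + 1, len(children)):
                    for la in child_leaves[ci]:
                        for lb in child_leaves[cj]:
                            out.append(((la, lb), dup))
        merged: List[str] = []
        for c in children:
            merged.extend(leafsets.pop(id(c)))
        leafsets[id(node)] = merged
    return out


def best_supported_node(pairs: Sequence[Tuple[Tuple[str, str], DuplicationNode]],
                        support_min: float = 0.5) -> DuplicationNode:
    """Oldest well-supported duplication node; fallback: oldest overall."""
    if not pairs:
        raise ValidationError("no duplication nodes to choose from")
    nodes = [n for _, n in pairs]
    supported = [n for n in nodes
                 if n.support is not None and n.support >= support_min]
    pool = supported if supported else nodes
    return max(pool, key=lambda n: (n.age, len(n.species_set)))


# ---------------------------------------------------------------------------
# Multiple-copy MRCA method
# ---------------------------------------------------------------------------


def _count_occurrences(chrom_ogs: Sequence[Optional[str]], query: Sequence[str],
                       max_gap: int) -> List[Tuple[int, int]]:
    """Greedy disjoint order-preserving matches of *query* in one chromosome.

    A match places consecutive query orthogroups at increasing
    positions with index gaps of at most ``max_gap`` (max_gap = 0 means
    strictly contiguous).
    """
    matches: List[Tuple[int, int]] = []
    pos = 0
    n = len(chrom_ogs)
    while pos < n:
        if chrom_ogs[pos] != query[0]:
            pos += 1
            continue
        cur = pos
        ok = True
        for og in query[1:]:
            nxt = None
            for step in range(1, max_gap + 2):
                if cur + step < n and chrom_ogs[cur + step] == og:
                    nxt = cur + step
                    break
            if nxt is None:
                ok = False
                break
            cur = nxt
        if ok:
            matches.append((pos, cur))
            pos = cur + 1
        else:
            pos += 1
    return matches


def multi_copy_mrca(event: DuplicationEvent,
                    tables: Dict[str, TdecTable],
                    species_tree: dendropy.Tree,
                    max_gap: int = 3,
                    exact: bool = False) -> Optional[DuplicationNode]:
    """MRCA of all species carrying >= 2 copies of the duplicated sequence.

    The orthogroup sequence is searched order-preserving in both
    orientations across every chromosome of every genome; occurrences
    are disjoint.  Returns None if no species has two copies.
    """
    query = list(dict.fromkeys(event.orthogroup_sequence))
    if len(query) < 3:
        raise ValidationError("orthogroup sequence too short")
    gap = 0 if exact else max_gap
    multi: Set[str] = set()
    for sp, table in tables.items():
        count = 0
        for chrom in sorted(table.chromosomes):
            ogs = [t.orthogroup for t in table.chromosomes[chrom]]
            fwd = _count_occurrences(ogs, query, gap)
            rev = _count_occurrences(ogs, query[::-1], gap)
            # merge disjointly: drop reverse matches overlapping forward ones
            taken = [iv for iv in fwd]
            for iv in rev:
                if all(iv[1] < f[0] or iv[0] > f[1] for f in taken):
                    taken.append(iv)
            count += len(taken)
        if count >= 2:
            multi.add(sp)
    if not multi:
        return None
    clades = _species_node_info(species_tree)
    clade = _mrca_clade(clades, multi)
    return DuplicationNode(species_set=clade, age=clades[clade],
                           method="multi_copy_mrca", support=None)


# ---------------------------------------------------------------------------
# Consensus and classification
# ---------------------------------------------------------------------------


def _parent_age(species_tree: dendropy.Tree, clade: FrozenSet[str]
                ) -> Optional[float]:
    annotate_node_ages(species_tree)
    for node in species_tree.postorder_node_iter():
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if leaves == clade:
            return node.parent_node.age if node.parent_node else None
    raise ValidationError("clade not found in species tree")


def consensus_time(node_a: Optional[DuplicationNode],
                   node_b: Optional[DuplicationNode],
                   species_tree: dendropy.Tree) -> Tuple[DuplicationNode, float]:
    """Older of the two method nodes, dated by the midpoint rule.

    t_dup = (age(node) + age(parent)) / 2; a root-mapped duplication
    has no parent, so t_dup = root age (a lower bound on the midpoint,
    consistent with never wanting to underestimate the time).
    """
    candidates = [n for n in (node_a, node_b) if n is not None]
    if not candidates:
        raise ValidationError("both dating methods returned nothing")
    node = max(candidates, key=lambda n: (n.age, len(n.species_set)))
    consensus = DuplicationNode(species_set=node.species_set, age=node.age,
                                method="consensus", support=None)
    p_age = _parent_age(species_tree, node.species_set)
    t_dup = node.age if p_age is None else 0.5 * (node.age + p_age)
    return consensus, t_dup


def time_event(event: DuplicationEvent,
               gene_tree_pairs: Sequence[Tuple[Tuple[str, str], DuplicationNode]],
               tables: Dict[str, TdecTable],
               species_tree: dendropy.Tree,
               support_min: float = 0.5,
               max_gap: int = 3) -> TimedEvent:
    """Full dating pipeline for one event: both methods plus consensus."""
    node_gt: Optional[DuplicationNode] = None
    if gene_tree_pairs:
        node_gt = best_supported_node(gene_tree_pairs, support_min)
    node_mc = multi_copy_mrca(event, tables, species_tree, max_gap=max_gap)
    consensus, t_dup = consensus_time(node_gt, node_mc, species_tree)
    event.duplication_time = t_dup
    return TimedEvent(event=event, node_gene_tree=node_gt, node_mrca=node_mc,
                      consensus_node=consensus, t_dup=t_dup)


def classify_event(timed: TimedEvent, focal: str, reference: str,
                   times: TimeTable) -> str:
    """after_speciation iff t_dup < t_s; equality is before (conservative)."""
    t_s = times.divergence(focal, reference)
    if t_s is None:
        timed.event.classification = "unclassified"
    elif timed.t_dup < t_s:
        timed.event.classification = "after_speciation"
    else:
        timed.event.classification = "before_speciation"
    return timed.event.classification
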