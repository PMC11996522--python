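"""Input/output and the internal data model for gene annotations.

Reads per-species gene annotations (GFF3 gene features or a simple
tab-separated gene table), OrthoFinder-style orthogroup tables, protein
FASTA files and newick trees, normalising everything into the small set
of containers the synteny machinery operates on.

Coordinates follow the GFF3 convention: 1-based, inclusive.  Gene order
on a chromosome is defined by the start coordinate and indexed from 0.
Strand is stored but never affects gene order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
from Bio import SeqIO


class ApesError(Exception):
    """Base class for errors raised by this package."""


class ParseError(ApesError):
    """A file could not be parsed."""


class ValidationError(ApesError):
    """Parsed data violated an invariant."""


# ---------------------------------------------------------------------------
# Gene records and tables
# ---------------------------------------------------------------------------

VALID_STRANDS = {"+", "-"}


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: id, location and (optionally) its orthogroup."""

    gene_id: str
    species: str
    chromosome: str
    start: int  # 1-based inclusive, bp
    end: int    # 1-based inclusive, bp
    strand: str = "+"
    orthogroup: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GeneTable:
    """Ordered genes per chromosome for one species.

    Within each chromosome the gene list is sorted by start coordinate;
    the position of a gene in that list is its 0-based order index.
    """

    species: str
    chromosomes: Dict[str, List[GeneRecord]] = field(default_factory=dict)

    @classmethod
    def from_records(cls, species: str, records: Iterable[GeneRecord]) -> "GeneTable":
        chroms: Dict[str, List[GeneRecord]] = {}
        seen: Set[str] = set()
        for rec in records:
            if rec.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {rec.gene_id!r} in {species}")
            seen.add(rec.gene_id)
            chroms.setdefault(rec.chromosome, []).append(rec)
        for chrom in chroms:
            chroms[chrom].sort(key=lambda r: (r.start, r.end, r.gene_id))
        return cls(species=species, chromosomes=chroms)

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    def genes(self) -> Iterable[GeneRecord]:
        for chrom in sorted(self.chromosomes):
            yield from self.chromosomes[chrom]

    def with_orthogroups(self, og: "OrthogroupMap") -> "GeneTable":
        """Return a copy with each gene's orthogroup filled in from *og*."""
        out: Dict[str, List[GeneRecord]] = {}
        for chrom, recs in self.chromosomes.items():
            out[chrom] = [
                GeneRecord(
                    r.gene_id, r.species, r.chromosome, r.start, r.end, r.strand,
                    og.orthogroup_of(r.gene_id),
                )
                for r in recs
            ]
        return GeneTable(self.species, out)


def read_gene_table(path: str, format: str = "tsv", species: Optional[str] = None) -> GeneTable:
    """Read gene annotations from a TSV gene table or a GFF3 file.

    The TSV dialect has columns gene_id, chromosome, start, end, strand
    (tab-separated; a header line starting with ``gene_id`` is allowed).
    For GFF3, only features of type ``gene`` are used, and the gene id is
    taken from the ``ID`` attribute.
    """
    if species is None:
        species = os.path.splitext(os.path.basename(path))[0]
    if format == "tsv":
        return _read_gene_tsv(path, species)
    if format == "gff3":
        return _read_gene_gff3(path, species)
    raise ValueError(f"unknown gene table format {format!r}")


def _read_gene_tsv(path: str, species: str) -> GeneTable:
    records: List[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "gene_id":
                continue
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 tab-separated fields")
            gene_id, chrom, start, end, strand = fields[:5]
            try:
                rec = GeneRecord(gene_id, species, chrom, int(start), int(end), strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return GeneTable.from_records(species, records)


def _read_gene_gff3(path: str, species: str) -> GeneTable:
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    records = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        strand = feat.strand if feat.strand in VALID_STRANDS else "+"
        records.append(
            GeneRecord(gene_id, species, feat.seqid, feat.start, feat.end, strand)
        )
    return GeneTable.from_records(species, records)


def write_gene_table(table: GeneTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchromosome\tstart\tend\tstrand\n")
        for rec in table.genes():
            fh.write(f"{rec.gene_id}\t{rec.chromosome}\t{rec.start}\t{rec.end}\t{rec.strand}\n")


# ---------------------------------------------------------------------------
# Orthogroups
# ---------------------------------------------------------------------------


@dataclass
class OrthogroupMap:
    """Disjoint orthogroups: orthogroup id -> set of gene ids, plus inverse."""

    groups: Dict[str, Set[str]]
    gene_to_group: Dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_groups(cls, groups: Mapping[str, Iterable[str]]) -> "OrthogroupMap":
        g: Dict[str, Set[str]] = {}
        inverse: Dict[str, str] = {}
        for og_id, genes in groups.items():
            members = set(genes)
            g[og_id] = members
            for gene in members:
                if gene in inverse:
                    raise ValidationError(
                        f"gene {gene!r} listed in both {inverse[gene]!r} and {og_id!r}"
                    )
                inverse[gene] = og_id
        return cls(groups=g, gene_to_group=inverse)

    def orthogroup_of(self, gene_id: str) -> Optional[str]:
        return self.gene_to_group.get(gene_id)

    def __len__(self) -> int:
        return len(self.groups)


def read_orthogroups(path: str) -> OrthogroupMap:
    """Read an OrthoFinder-style Orthogroups.tsv.

    First column is the orthogroup id; remaining columns hold
    comma-separated gene lists (one column per species).  A header line
    is detected by its first cell being ``Orthogroup`` or ``HOG``.
    """
    groups: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if lineno == 1 and cells[0] in {"Orthogroup", "HOG", "orthogroup"}:
                continue
            og_id, gene_cells = cells[0], cells[1:]
            members: Set[str] = set()
            for cell in gene_cells:
                for gene in cell.split(","):
                    gene = gene.strip()
                    if gene:
                        members.add(gene)
            if og_id in groups:
                raise ParseError(f"{path}:{lineno}: orthogroup {og_id!r} repeated")
            groups[og_id] = members
    return OrthogroupMap.from_groups(groups)


def write_orthogroups(og: OrthogroupMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("Orthogroup\tGenes\n")
        for og_id in sorted(og.groups):
            fh.write(f"{og_id}\t{', '.join(sorted(og.groups[og_id]))}\n")


# ---------------------------------------------------------------------------
# Trees and divergence times
# ---------------------------------------------------------------------------


def annotate_node_ages(tree: dendropy.Tree) -> dendropy.Tree:
    """Set ``node.age`` on every node: max path length to a descendant leaf.

    For an ultrametric, time-calibrated tree this is the node's age in the
    units of the branch lengths (MYA throughout this package).
    """
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.age = 0.0
        else:
            node.age = max(
                child.age + (child.edge.length or 0.0) for child in node.child_nodes()
            )
    return tree


def read_tree(path: str) -> dendropy.Tree:
    """Read a newick tree from a file path and annotate node ages."""
    try:
        tree = dendropy.Tree.get(path=path, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises various error types
        raise ParseError(f"cannot parse newick file {path}: {exc}") from exc
    return annotate_node_ages(tree)


def tree_from_string(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise ParseError(f"cannot parse newick string: {exc}") from exc
    return annotate_node_ages(tree)


@dataclass
class TimeTable:
    """Pairwise species divergence times (MYA), optionally tree-backed."""

    pair_times: Dict[frozenset, float] = field(default_factory=dict)
    tree: Optional[dendropy.Tree] = None

    @classmethod
    def from_tree(cls, tree: dendropy.Tree) -> "TimeTable":
        annotate_node_ages(tree)
        pair_times: Dict[frozenset, float] = {}
        # Postorder with assign-if-unset: the first (deepest) node splitting
        # a leaf pair across its children is their MRCA.
        leafsets: Dict[int, List[str]] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                leafsets[id(node)] = [node.taxon.label]
                continue
            children = node.child_nodes()
            merged: List[str] = []
            for ci, ca in enumerate(children):
                for cb in children[ci + 1:]:
                    for la in leafsets[id(ca)]:
                        for lb in leafsets[id(cb)]:
                            key = frozenset((la, lb))
                            if key not in pair_times:
                                pair_times[key] = node.age
            for ch in children:
                merged.extend(leafsets.pop(id(ch)))
            leafsets[id(node)] = merged
        return cls(pair_times=pair_times, tree=tree)

    def divergence(self, species_a: str, species_b: str) -> Optional[float]:
        if species_a == species_b:
            return 0.0
        return self.pair_times.get(frozenset((species_a, species_b)))


# ---------------------------------------------------------------------------
# Protein sequences
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> Dict[str, str]:
    """Read a protein FASTA into a dict gene_id -> sequence."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n{sequences[name]}\n")


# ---------------------------------------------------------------------------
# Synteny block serialization
# ---------------------------------------------------------------------------

_BLOCK_HEADER = (
    "species_a\tchrom_a\tspecies_b\tchrom_b\tkind\torientation\tn_pairs\tpairs\n"
)


def write_blocks(blocks: Sequence, path: str) -> None:
    """Write synteny blocks as one tab-separated row per block.

    The pair list is serialized as ``i:j`` items separated by commas;
    :func:`read_blocks` inverts this bit-exactly.
    """
    with open(path, "w") as fh:
        fh.write(_BLOCK_HEADER)
        for b in blocks:
            pair_txt = ",".join(f"{i}:{j}" for i, j in b.pairs)
            orient = {1: "+1", -1: "-1", 0: "mixed"}[b.orientation]
            fh.write(
                f"{b.species_a}\t{b.chrom_a}\t{b.species_b}\t{b.chrom_b}\t"
                f"{b.kind}\t{orient}\t{len(b.pairs)}\t{pair_txt}\n"
            )


def read_blocks(path: str) -> List:
    from .nanosynteny import SyntenyBlock  # local import: avoid cycle

    blocks: List[SyntenyBlock] = []
    with open(path) as fh:
        header = fh.readline()
        if header != _BLOCK_HEADER:
            raise ParseError(f"{path}: unexpected block-file header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != 8:
                raise ParseError(f"{path}:{lineno}: expected 8 fields")
            sa, ca, sb, cb, kind, orient_txt, n_pairs, pair_txt = cells
            orientation = {"+1": 1, "-1": -1, "mixed": 0}[orient_txt]
            pairs = []
            if pair_txt:
                for item in pair_txt.split(","):
                    i, j = item.split(":")
                    pairs.append((int(i), int(j)))
            if len(pairs) != int(n_pairs):
                raise ParseError(f"{path}:{lineno}: n_pairs mismatch")
            blocks.append(
                SyntenyBlock(
                    kind=kind, species_a=sa, species_b=sb, chrom_a=ca, chrom_b=cb,
                    pairs=tuple(pairs), orientation=orientation,
                )
            )
    return blocks
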