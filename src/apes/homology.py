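"""Tandem-array collapse and homology (dot-plot) matrix construction.

Simple tandem duplications — runs of consecutive genes on one chromosome
all in the same orthogroup — are collapsed into a single representative
unit, a tandem duplication equivalence class (TDEC).  Homology matrices
are then binary relations between the TDEC orders of two chromosomes: a
dot at (i, j) means TDEC i and TDEC j share an orthogroup.  Dot plots of
these matrices are the substrate for all synteny detection downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .genome_io import GeneTable, OrthogroupMap, ValidationError


@dataclass(frozen=True)
class TDEC:
    """A tandem duplication equivalence class (maximal same-orthogroup run).

    ``member_gene_ids`` are consecutive in gene order and share one
    orthogroup (or the TDEC is a single unassigned gene).  The
    representative is the first member by coordinate.
    """

    tdec_id: str
    species: str
    chromosome: str
    orthogroup: Optional[str]
    member_gene_ids: Tuple[str, ...]
    order_index: int
    representative_gene_id: str
    span_start: int
    span_end: int

    @property
    def size(self) -> int:
        return len(self.member_gene_ids)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.span_start + self.span_end)


@dataclass
class TdecTable:
    """TDEC-condensed gene order for one species."""

    species: str
    chromosomes: Dict[str, List[TDEC]] = field(default_factory=dict)

    @property
    def n_tdecs(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    def tdecs(self) -> Iterable[TDEC]:
        for chrom in sorted(self.chromosomes):
            yield from self.chromosomes[chrom]

    def get(self, chromosome: str, index: int) -> TDEC:
        return self.chromosomes[chromosome][index]


def condense_tandem(table: GeneTable, og: OrthogroupMap) -> TdecTable:
    """Collapse maximal runs of consecutive same-orthogroup genes into TDECs.

    Unassigned genes (no orthogroup) are kept as singleton TDECs so they
    still occupy order indices, but they never generate homology dots.
    The operation is idempotent: condensing an already condensed order
    changes nothing, because maximal runs cannot merge further.
    """
    out: Dict[str, List[TDEC]] = {}
    for chrom in sorted(table.chromosomes):
        genes = table.chromosomes[chrom]
        tdecs: List[TDEC] = []
        i = 0
        while i < len(genes):
            g = genes[i]
            group = og.orthogroup_of(g.gene_id)
            j = i + 1
            if group is not None:
                while j < len(genes) and og.orthogroup_of(genes[j].gene_id) == group:
                    j += 1
            members = genes[i:j]
            tdecs.append(
                TDEC(
                    tdec_id=members[0].gene_id,
                    species=table.species,
                    chromosome=chrom,
                    orthogroup=group,
                    member_gene_ids=tuple(m.gene_id for m in members),
                    order_index=len(tdecs),
                    representative_gene_id=members[0].gene_id,
                    span_start=min(m.start for m in members),
                    span_end=max(m.end for m in members),
                )
            )
            i = j
        out[chrom] = tdecs
    return TdecTable(species=table.species, chromosomes=out)


@dataclass
class HomologyMatrix:
    """Sparse binary homology relation between two TDEC-ordered chromosomes.

    A dot at (i, j) is present iff the i-th TDEC of chromosome A and the
    j-th TDEC of chromosome B share a (non-null) orthogroup.  Works for a
    genome against itself (species_a == species_b), in which case the
    trivial main diagonal is present and removed only by the duplication
    filters downstream.
    """

    species_a: str
    species_b: str
    chrom_a: str
    chrom_b: str
    n_a: int
    n_b: int
    dots: FrozenSet[Tuple[int, int]]
    og_a: Optional[Tuple[Optional[str], ...]] = None
    og_b: Optional[Tuple[Optional[str], ...]] = None

    @property
    def n_dots(self) -> int:
        return len(self.dots)

    def pair_orthogroup(self, i: int, j: int) -> Optional[str]:
        if self.og_a is not None:
            return self.og_a[i]
        return None

    @classmethod
    def from_dots(cls, dots: Iterable[Tuple[int, int]], n_a: int, n_b: int,
                  species_a: str = "A", species_b: str = "B",
                  chrom_a: str = "chr1", chrom_b: str = "chr1") -> "HomologyMatrix":
        """Build a bare matrix from explicit dots (no orthogroup labels)."""
        dots = frozenset(dots)
        for (i, j) in dots:
            if not (0 <= i < n_a and 0 <= j < n_b):
                raise ValidationError(f"dot ({i},{j}) outside {n_a}x{n_b} matrix")
        return cls(species_a, species_b, chrom_a, chrom_b, n_a, n_b, dots)


def build_homology_matrix(tdecs_a: Sequence[TDEC], tdecs_b: Sequence[TDEC],
                          species_a: str, species_b: str,
                          chrom_a: str, chrom_b: str) -> HomologyMatrix:
    """Place a dot wherever two TDECs share a non-null orthogroup."""
    by_og: Dict[str, List[int]] = {}
    for j, t in enumerate(tdecs_b):
        if t.orthogroup is not None:
            by_og.setdefault(t.orthogroup, []).append(j)
    dots: Set[Tuple[int, int]] = set()
    for i, t in enumerate(tdecs_a):
        if t.orthogroup is None:
            continue
        for j in by_og.get(t.orthogroup, ()):
            dots.add((i, j))
    return HomologyMatrix(
        species_a=species_a, species_b=species_b, chrom_a=chrom_a, chrom_b=chrom_b,
        n_a=len(tdecs_a), n_b=len(tdecs_b), dots=frozenset(dots),
        og_a=tuple(t.orthogroup for t in tdecs_a),
        og_b=tuple(t.orthogroup for t in tdecs_b),
    )


def genome_matrices(a: TdecTable, b: TdecTable) -> List[HomologyMatrix]:
    """All chromosome-pair homology matrices with at least one dot."""
    out: List[HomologyMatrix] = []
    for ca in sorted(a.chromosomes):
        for cb in sorted(b.chromosomes):
            m = build_homology_matrix(
                a.chromosomes[ca], b.chromosomes[cb], a.species, b.species, ca, cb
            )
            if m.n_dots:
                out.append(m)
    return out


@dataclass
class PairManifest:
    """Enumeration of genome comparisons for a species list."""

    unordered_with_self: List[Tuple[str, str]]
    ordered_non_self: List[Tuple[str, str]]

    @property
    def n_unordered_with_self(self) -> int:
        return len(self.unordered_with_self)

    @property
    def n_ordered_non_self(self) -> int:
        return len(self.ordered_non_self)


def pair_manifest(species: Sequence[str]) -> PairManifest:
    """All N(N+1)/2 unordered-with-self and N(N-1) ordered non-self pairs."""
    if not species:
        raise ValidationError("species list is empty")
    sp = list(species)
    unordered = [(sp[i], sp[j]) for i in range(len(sp)) for j in range(i, len(sp))]
    ordered = [(a, b) for a in sp for b in sp if a != b]
    return PairManifest(unordered_with_self=unordered, ordered_non_self=ordered)
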