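"""Multi-gene duplication detection and source/target assignment.

Within-genome (self-comparison) microsynteny blocks that survive three
filters indicate multi-gene duplications:

1. blocks that merely align each gene of a chromosome with itself
   (the trivial main diagonal) are discarded;
2. blocks containing the same TDEC twice are discarded;
3. overlapping blocks on the same chromosome pair are resolved by
   keeping the block with more TDEC pairs.

Each surviving off-diagonal block pairs two regions of the genome — the
two copies of a duplication.  The source copy (the one in the ancestral
genomic location) is identified through primary microsynteny with a
reference species that diverged before the duplication: the copy whose
genes sit in the larger cross-species microsynteny block retains the
ancestral flanking context and is labeled the source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .genome_io import ValidationError
from .homology import TDEC, TdecTable
from .nanosynteny import SyntenyBlock, Pair


@dataclass(frozen=True)
class Region:
    """One copy of a duplicated segment: a run of TDECs on a chromosome."""

    species: str
    chromosome: str
    tdec_ids: Tuple[str, ...]
    indices: Tuple[int, ...]
    span_start: int
    span_end: int

    @property
    def length_bp(self) -> int:
        return self.span_end - self.span_start + 1

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.span_start + self.span_end)


@dataclass
class DuplicationEvent:
    """A within-genome multi-gene duplication (two paired regions)."""

    event_id: str
    species: str
    copy1: Region
    copy2: Region
    orthogroup_sequence: Tuple[str, ...]
    source_copy: str = "undetermined"  # {"copy1", "copy2", "undetermined"}
    duplication_time: Optional[float] = None
    classification: str = "unclassified"

    @property
    def inter_copy_distance(self) -> float:
        """bp gap between nearest span edges; inf across chromosomes."""
        if self.copy1.chromosome != self.copy2.chromosome:
            return math.inf
        lo, hi = sorted((self.copy1, self.copy2), key=lambda r: r.span_start)
        return max(0, hi.span_start - lo.span_end)

    @property
    def source(self) -> Optional[Region]:
        if self.source_copy == "copy1":
            return self.copy1
        if self.source_copy == "copy2":
            return self.copy2
        return None

    @property
    def target(self) -> Optional[Region]:
        if self.source_copy == "copy1":
            return self.copy2
        if self.source_copy == "copy2":
            return self.copy1
        return None

    @property
    def l_target(self) -> Optional[int]:
        t = self.target
        return t.length_bp if t is not None else None


@dataclass
class GeneTriplet:
    """(source paralog A1, target paralog A2, reference syntenic ortholog B1).

    Distances are per-site Levenshtein distances; delta_dL is
    d_L(A1,B1) - d_L(A2,B1), negative when the source copy is the less
    diverged one.
    """

    a1: TDEC
    a2: TDEC
    b1: TDEC
    event_id: str
    species_focal: str
    species_ref: str
    orthogroup: str
    d_a1_b1: Optional[float] = None
    d_a2_b1: Optional[float] = None
    delta_dL: Optional[float] = None
    duplication_time: Optional[float] = None
    r_source: Optional[float] = None
    r_target: Optional[float] = None


# ---------------------------------------------------------------------------
# Self-comparison filters
# ---------------------------------------------------------------------------


def _is_trivial_diagonal(block: SyntenyBlock) -> bool:
    return block.chrom_a == block.chrom_b and all(i == j for i, j in block.pairs)


def _has_repeated_tdec(block: SyntenyBlock, table: TdecTable) -> bool:
    ids: List[str] = []
    for i, j in block.pairs:
        ids.append(table.get(block.chrom_a, i).tdec_id)
        ids.append(table.get(block.chrom_b, j).tdec_id)
    return len(set(ids)) < len(ids)


def _overlap(b1: SyntenyBlock, b2: SyntenyBlock) -> int:
    """Smaller of the shared-TDEC counts on the two axes."""
    shared_a = len(b1.rows() & b2.rows())
    shared_b = len(b1.cols() & b2.cols())
    return min(shared_a, shared_b)


def filter_self_blocks(micro_self: Sequence[SyntenyBlock],
                       table: TdecTable) -> List[SyntenyBlock]:
    """Apply the three duplication filters to self-comparison blocks.

    Filter 3 processes blocks in descending size order (ties broken by
    earliest chromosome/start position) and greedily keeps a block only
    if it overlaps no already-kept block on the same chromosome pair,
    so the larger of two overlapping blocks always survives.  The
    procedure is idempotent.
    """
    survivors = [b for b in micro_self
                 if not _is_trivial_diagonal(b) and not _has_repeated_tdec(b, table)]
    order = sorted(
        survivors,
        key=lambda b: (-b.k, b.chrom_a, b.chrom_b, b.pairs[0]),
    )
    kept: List[SyntenyBlock] = []
    for b in order:
        clash = any(
            (k.chrom_a, k.chrom_b) == (b.chrom_a, b.chrom_b) and _overlap(b, k) > 0
            for k in kept
        )
        if not clash:
            kept.append(b)
    kept.sort(key=lambda b: (b.chrom_a, b.chrom_b, b.pairs))
    return kept


def _region_from_axis(block: SyntenyBlock, table: TdecTable, axis: str) -> Region:
    chrom = block.chrom_a if axis == "a" else block.chrom_b
    idx = sorted({i for i, _ in block.pairs} if axis == "a"
                 else {j for _, j in block.pairs})
    tds = [table.get(chrom, i) for i in idx]
    return Region(
        species=table.species, chromosome=chrom,
        tdec_ids=tuple(t.tdec_id for t in tds), indices=tuple(idx),
        span_start=min(t.span_start for t in tds),
        span_end=max(t.span_end for t in tds),
    )


def find_within_genome_duplications(micro_self: Sequence[SyntenyBlock],
                                    table: TdecTable,
                                    min_shared_orthogroups: int = 3
                                    ) -> List[DuplicationEvent]:
    """Duplication events from filtered self-comparison microsynteny.

    Each surviving off-diagonal block whose shared orthogroup sequence
    has length >= 3 yields one event; the mirror block (axes swapped)
    describes the same event and is deduplicated, with copy1 the copy
    earlier in (chromosome, span start) order.
    """
    kept = filter_self_blocks(micro_self, table)
    events: List[DuplicationEvent] = []
    seen: Set[frozenset] = set()
    for block in kept:
        ogs = tuple(
            table.get(block.chrom_a, i).orthogroup
            for i, _ in block.pairs
            if table.get(block.chrom_a, i).orthogroup is not None
        )
        if len(set(ogs)) < min_shared_orthogroups:
            continue
        r_a = _region_from_axis(block, table, "a")
        r_b = _region_from_axis(block, table, "b")
        key = frozenset((r_a.tdec_ids, r_b.tdec_ids))
        if key in seen:
            continue
        seen.add(key)
        copy1, copy2 = sorted(
            (r_a, r_b), key=lambda r: (r.chromosome, r.span_start)
        )
        events.append(
            DuplicationEvent(
                event_id=f"{table.species}:dup{len(events)}",
                species=table.species, copy1=copy1, copy2=copy2,
                orthogroup_sequence=ogs,
            )
        )
    return events


# ---------------------------------------------------------------------------
# Primary microsynteny & source/target assignment
# ---------------------------------------------------------------------------


def blocks_containing(tdec: TDEC, blocks: Sequence[SyntenyBlock],
                      tables: Dict[str, TdecTable]) -> List[SyntenyBlock]:
    """All blocks in which the given TDEC participates on either axis."""
    out = []
    for b in blocks:
        if b.species_a == tdec.species and b.chrom_a == tdec.chromosome:
            if any(i == tdec.order_index for i, _ in b.pairs):
                out.append(b)
                continue
        if b.species_b == tdec.species and b.chrom_b == tdec.chromosome:
            if any(j == tdec.order_index for _, j in b.pairs):
                out.append(b)
    return out


def primary_microsynteny(tdec: TDEC, blocks: Sequence[SyntenyBlock],
                         tables: Dict[str, TdecTable]) -> Optional[SyntenyBlock]:
    """Largest block containing the TDEC; ties broken by earliest position."""
    containing = blocks_containing(tdec, blocks, tables)
    if not containing:
        return None
    return min(containing, key=lambda b: (-b.k, b.chrom_a, b.chrom_b, b.pairs[0]))


def _copy_block_size(region: Region, blocks: Sequence[SyntenyBlock]) -> Tuple[int, Optional[SyntenyBlock]]:
    """Pair count of the largest cross-species block touching the region."""
    best: Optional[SyntenyBlock] = None
    idx = set(region.indices)
    for b in blocks:
        hit = False
        if b.species_a == region.species and b.chrom_a == region.chromosome:
            hit = any(i in idx for i, _ in b.pairs)
        if not hit and b.species_b == region.species and b.chrom_b == region.chromosome:
            hit = any(j in idx for _, j in b.pairs)
        if hit and (best is None or (-b.k, b.chrom_a, b.chrom_b, b.pairs[0])
                    < (-best.k, best.chrom_a, best.chrom_b, best.pairs[0])):
            best = b
    return (best.k if best else 0), best


def assign_source_target(event: DuplicationEvent,
                         micro_cross: Sequence[SyntenyBlock]) -> DuplicationEvent:
    """Label source/target copies by primary microsynteny block size.

    The copy whose genes lie in the larger cross-species block keeps the
    ancestral flanking context and is the source.  Ties and missing
    cross-species synteny leave the event undetermined, excluding it
    from polarity statistics.
    """
    s1, _ = _copy_block_size(event.copy1, micro_cross)
    s2, _ = _copy_block_size(event.copy2, micro_cross)
    if s1 == 0 or s2 == 0 or s1 == s2:
        source = "undetermined"
    elif s1 > s2:
        source = "copy1"
    else:
        source = "copy2"
    event.source_copy = source
    return event


def extract_triplets(event: DuplicationEvent, reference_table: TdecTable,
                     focal_table: TdecTable,
                     micro_cross: Sequence[SyntenyBlock]) -> List[GeneTriplet]:
    """One triplet per orthogroup present in source, target and reference.

    The reference ortholog B1 is the partner of the source paralog A1
    inside the source copy's largest cross-species block; positions
    missing from any of the three regions are skipped.
    """
    if event.source is None:
        return []
    source, target = event.source, event.target
    _, src_block = _copy_block_size(source, micro_cross)
    if src_block is None:
        return []
    focal_is_a = src_block.species_a == event.species
    partner: Dict[int, int] = {}
    for i, j in src_block.pairs:
        fi, ri = (i, j) if focal_is_a else (j, i)
        partner.setdefault(fi, ri)
    ref_chrom = src_block.chrom_b if focal_is_a else src_block.chrom_a
    focal_chrom = src_block.chrom_a if focal_is_a else src_block.chrom_b

    src_by_og: Dict[str, TDEC] = {}
    for idx in source.indices:
        t = focal_table.get(source.chromosome, idx)
        if t.orthogroup is not None:
            src_by_og.setdefault(t.orthogroup, t)
    tgt_by_og: Dict[str, TDEC] = {}
    for idx in target.indices:
        t = focal_table.get(target.chromosome, idx)
        if t.orthogroup is not None:
            tgt_by_og.setdefault(t.orthogroup, t)

    triplets: List[GeneTriplet] = []
    for og in dict.fromkeys(event.orthogroup_sequence):
        a1 = src_by_og.get(og)
        a2 = tgt_by_og.get(og)
        if a1 is None or a2 is None:
            continue
        if source.chromosome != focal_chrom:
            continue
        ridx = partner.get(a1.order_index)
        if ridx is None:
            continue
        b1 = reference_table.get(ref_chrom, ridx)
        if b1.orthogroup != og:
            continue
        triplets.append(
            GeneTriplet(
                a1=a1, a2=a2, b1=b1, event_id=event.event_id,
                species_focal=event.species, species_ref=reference_table.species,
                orthogroup=og,
            )
        )
    return triplets
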