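"""Microsynteny assembly from nanosynteny anchors.

Nanosynteny blocks act as statistically reliable anchors.  Pairs of
anchors on the same chromosome pair that lie within ``d_nano_max`` of
each other (Chebyshev distance in dot-plot coordinates) are candidate
merges; a merge happens when a bridging path of homology dots exists in
which consecutive dots are within ``d_dot_max`` of each other.  The
connected components of the resulting merge relation become
microsynteny blocks, whose pair lists are the union of the member
anchors and the bridging-path dots.

All distances are Chebyshev (max of the axis gaps), so that
``d_dot_max = 1`` coincides with diagonal adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .genome_io import ValidationError
from .homology import HomologyMatrix, TdecTable
from .nanosynteny import SyntenyBlock, Pair, find_nanosynteny


@dataclass(frozen=True)
class ApesParams:
    """Hyperparameters of the synteny-assembly algorithm.

    k_min
        Minimum anchoring nanosynteny block size (gene pairs).
    d_nano_max
        Maximum Chebyshev distance between nanosynteny blocks for a
        candidate merge, in TDEC index units.
    d_dot_max
        Maximum Chebyshev distance between consecutive gene pairs on a
        bridging path.
    min_unique_orthogroups
        Minimum distinct orthogroups in a retained nanosynteny block.
    exclusive_paths
        Forbid bridging paths from passing through dots of other
        retained nanosynteny blocks.
    expand_tdecs
        Expand TDECs back into constituent genes in reported blocks
        (off by default: blocks are relations between TDECs).
    """

    k_min: int = 3
    d_nano_max: int = 5
    d_dot_max: int = 3
    min_unique_orthogroups: int = 3
    exclusive_paths: bool = False
    expand_tdecs: bool = False
    orientations: Tuple[int, ...] = (1, -1)

    def __post_init__(self) -> None:
        if min(self.k_min, self.d_nano_max, self.d_dot_max) < 1:
            raise ValidationError("k_min, d_nano_max, d_dot_max must all be >= 1")


def _chebyshev(p: Pair, q: Pair) -> int:
    return max(abs(p[0] - q[0]), abs(p[1] - q[1]))


def block_distance(b1: SyntenyBlock, b2: SyntenyBlock) -> int:
    """Chebyshev distance between the nearest endpoints of two blocks."""
    if (b1.chrom_a, b1.chrom_b) != (b2.chrom_a, b2.chrom_b):
        raise ValidationError("block distance requires the same chromosome pair")
    ends1 = (b1.pairs[0], b1.pairs[-1])
    ends2 = (b2.pairs[0], b2.pairs[-1])
    return min(_chebyshev(p, q) for p in ends1 for q in ends2)


def bridge_path(H: HomologyMatrix, b1: SyntenyBlock, b2: SyntenyBlock,
                d_dot_max: int,
                forbidden: Optional[Set[Pair]] = None) -> Optional[Tuple[Pair, ...]]:
    """Shortest dot path linking an endpoint of b1 to an endpoint of b2.

    Consecutive dots on the path must be within Chebyshev distance
    ``d_dot_max``.  Among fewest-hop paths the lexicographically
    smallest is returned (deterministic tie-break); None if no path
    exists.  ``forbidden`` dots may not appear as path interior.
    """
    dots = H.dots
    sources = sorted({b1.pairs[0], b1.pairs[-1]})
    targets = set((b2.pairs[0], b2.pairs[-1]))

    def neighbors(p: Pair) -> List[Pair]:
        i, j = p
        out = []
        for di in range(-d_dot_max, d_dot_max + 1):
            for dj in range(-d_dot_max, d_dot_max + 1):
                if di == 0 and dj == 0:
                    continue
                qd = (i + di, j + dj)
                if qd in dots:
                    if forbidden and qd in forbidden and qd not in targets:
                        continue
                    out.append(qd)
        out.sort()
        return out

    best: Optional[Tuple[Pair, ...]] = None
    for src in sources:
        # BFS distances from src, then greedy lexicographic reconstruction.
        dist: Dict[Pair, int] = {src: 0}
        frontier = [src]
        hit: Optional[int] = None
        while frontier and hit is None:
            nxt: List[Pair] = []
            for p in frontier:
                if p in targets:
                    hit = dist[p]
                    break
                for qd in neighbors(p):
                    if qd not in dist:
                        dist[qd] = dist[p] + 1
                        nxt.append(qd)
            frontier = nxt
        reached = sorted(t for t in targets if t in dist)
        if not reached:
            continue
        dmin = min(dist[t] for t in reached)
        # walk forward choosing the smallest next dot that stays on a
        # shortest path to some minimal-distance target
        path = [src]
        cur = src
        while cur not in targets or dist[cur] != dmin:
            cands = [qd for qd in neighbors(cur)
                     if qd in dist and dist[qd] == dist[cur] + 1]
            # keep only candidates from which a target at dmin is reachable
            step = None
            for qd in sorted(cands):
                if _target_reachable(qd, dist, dmin, targets, neighbors):
                    step = qd
                    break
            if step is None:  # pragma: no cover - BFS guarantees progress
                break
            path.append(step)
            cur = step
        cand = tuple(path)
        key = (len(cand), cand)
        if best is None or key < (len(best), best):
            best = cand
    return best


def _target_reachable(p: Pair, dist: Dict[Pair, int], dmin: int,
                      targets: Set[Pair], neighbors) -> bool:
    if dist[p] > dmin:
        return False
    if p in targets and dist[p] == dmin:
        return True
    stack = [p]
    seen = {p}
    while stack:
        cur = stack.pop()
        for qd in neighbors(cur):
            if qd in seen or qd not in dist or dist[qd] != dist[cur] + 1:
                continue
            if dist[qd] > dmin:
                continue
            if qd in targets and dist[qd] == dmin:
                return True
            seen.add(qd)
            stack.append(qd)
    return False


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def assemble_microsynteny(H: HomologyMatrix, nano: Sequence[SyntenyBlock],
                          params: ApesParams) -> List[SyntenyBlock]:
    """Merge nanosynteny anchors into microsynteny blocks.

    Candidate anchor pairs within ``d_nano_max`` are processed in
    ascending block-distance order; each successful bridge unions the
    two anchors and records the bridging dots.  Because merging is a
    union over connected components the final partition is independent
    of the processing order.  Anchors that merge with nothing become
    single-anchor micro blocks, so every micro block contains at least
    one nanosynteny block.
    """
    nano = [b for b in nano
            if (b.chrom_a, b.chrom_b) == (H.chrom_a, H.chrom_b)]
    if not nano:
        return []
    uf = _UnionFind(len(nano))
    extra_dots: Dict[int, Set[Pair]] = {i: set() for i in range(len(nano))}

    nano_dots: Set[Pair] = set()
    for b in nano:
        nano_dots.update(b.pairs)

    edges = []
    for i in range(len(nano)):
        for j in range(i + 1, len(nano)):
            d = block_distance(nano[i], nano[j])
            if d <= params.d_nano_max:
                edges.append((d, i, j))
    edges.sort()

    for _, i, j in edges:
        forbidden = None
        if params.exclusive_paths:
            forbidden = nano_dots - set(nano[i].pairs) - set(nano[j].pairs)
        path = bridge_path(H, nano[i], nano[j], params.d_dot_max, forbidden)
        if path is not None:
            uf.union(i, j)
            root = uf.find(i)
            extra_dots.setdefault(root, set()).update(path)

    comps: Dict[int, List[int]] = {}
    for i in range(len(nano)):
        comps.setdefault(uf.find(i), []).append(i)

    blocks: List[SyntenyBlock] = []
    for root, members in sorted(comps.items()):
        pairs: Set[Pair] = set()
        orients = set()
        for i in members:
            pairs.update(nano[i].pairs)
            orients.add(nano[i].orientation)
            pairs.update(extra_dots.get(i, ()))
        pairs.update(extra_dots.get(root, ()))
        ordered = tuple(sorted(pairs))
        orientation = orients.pop() if len(orients) == 1 else 0
        if H.og_a is not None:
            n_unique = len({H.og_a[i] for i, _ in ordered})
        else:
            n_unique = len(ordered)
        blocks.append(
            SyntenyBlock(
                kind="micro", species_a=H.species_a, species_b=H.species_b,
                chrom_a=H.chrom_a, chrom_b=H.chrom_b, pairs=ordered,
                orientation=orientation, n_unique_orthogroups=n_unique,
            )
        )
    blocks.sort(key=lambda b: b.pairs)
    return blocks


def find_microsynteny(H: HomologyMatrix, params: Optional[ApesParams] = None
                      ) -> Tuple[List[SyntenyBlock], List[SyntenyBlock]]:
    """Run the full pipeline on one homology matrix: nano then micro."""
    params = params or ApesParams()
    nano = find_nanosynteny(H, k_min=params.k_min,
                            min_unique_orthogroups=params.min_unique_orthogroups,
                            orientations=params.orientations)
    micro = assemble_microsynteny(H, nano, params)
    return nano, micro


def compare_genomes(a: TdecTable, b: TdecTable,
                    params: Optional[ApesParams] = None
                    ) -> Tuple[List[SyntenyBlock], List[SyntenyBlock]]:
    """Nano and micro blocks over all chromosome pairs of two genomes."""
    from .homology import genome_matrices

    params = params or ApesParams()
    nano_all: List[SyntenyBlock] = []
    micro_all: List[SyntenyBlock] = []
    for H in genome_matrices(a, b):
        nano, micro = find_microsynteny(H, params)
        nano_all.extend(nano)
        micro_all.extend(micro)
    return nano_all, micro_all


def genome_coverage(table: TdecTable, micro: Sequence[SyntenyBlock]) -> float:
    """Fraction of a genome's TDECs inside at least one micro block."""
    total = table.n_tdecs
    if total == 0:
        return 0.0
    covered: Set[Tuple[str, int]] = set()
    for b in micro:
        if b.species_a == table.species:
            covered.update((b.chrom_a, i) for i, _ in b.pairs)
        if b.species_b == table.species:
            covered.update((b.chrom_b, j) for _, j in b.pairs)
    # guard against indices referencing other species' chromosomes
    valid = {(chrom, t.order_index) for chrom, tds in table.chromosomes.items()
             for t in tds}
    return len(covered & valid) / total
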