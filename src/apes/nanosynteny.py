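"""Nanosynteny detection and its statistical null models.

Nanosynteny is perfectly conserved gene (TDEC) order: an unbroken
diagonal (+1) or antidiagonal (-1, i.e. inverted) run of dots in a
homology matrix.  Because short runs arise by chance in random matrices,
two nulls quantify significance:

* a permutation null that repeatedly swaps random row pairs and column
  pairs of the observed matrix and recounts runs (this preserves row and
  column sums exactly), and
* an analytic expectation treating dots as independent Bernoulli(q)
  with q = n_dots / (n_a * n_b), with exact edge-effect terms.

The minimum retained block size k_min is chosen so that the expected
chance fraction of nanosynteny blocks stays below a significance level
(0.05 by default) across all genome comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .genome_io import ValidationError
from .homology import HomologyMatrix

Pair = Tuple[int, int]


@dataclass(frozen=True)
class SyntenyBlock:
    """An ordered run of TDEC index pairs in a dot plot.

    ``kind`` is "nano" for perfectly conserved runs and "micro" for
    assembled blocks.  Orientation is +1 (diagonal), -1 (antidiagonal)
    or 0 (mixed, only possible for micro blocks).
    """

    kind: str
    species_a: str
    species_b: str
    chrom_a: str
    chrom_b: str
    pairs: Tuple[Pair, ...]
    orientation: int
    n_unique_orthogroups: Optional[int] = None

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def start(self) -> Pair:
        return self.pairs[0]

    @property
    def end(self) -> Pair:
        return self.pairs[-1]

    def rows(self) -> Set[int]:
        return {i for i, _ in self.pairs}

    def cols(self) -> Set[int]:
        return {j for _, j in self.pairs}


def _maximal_runs(dots: FrozenSet[Pair], orientation: int) -> List[Tuple[Pair, ...]]:
    """All maximal runs of step (+1, orientation) through the dot set."""
    runs: List[Tuple[Pair, ...]] = []
    for (i, j) in dots:
        if (i - 1, j - orientation) in dots:
            continue  # not a run start
        run = [(i, j)]
        while (i + 1, j + orientation) in dots:
            i, j = i + 1, j + orientation
            run.append((i, j))
        runs.append(tuple(run))
    runs.sort()
    return runs


def census_runs(dots: FrozenSet[Pair], orientations: Tuple[int, ...] = (1, -1)
                ) -> Dict[int, int]:
    """Count maximal runs by length, both orientations.

    Length-1 antidiagonal runs are suppressed so an isolated dot is
    counted exactly once (as a +1 run of length 1).
    """
    counts: Dict[int, int] = {}
    for orient in orientations:
        for run in _maximal_runs(dots, orient):
            if orient == -1 and len(run) == 1:
                continue
            counts[len(run)] = counts.get(len(run), 0) + 1
    return counts


def find_nanosynteny(H: HomologyMatrix, k_min: int = 3,
                     min_unique_orthogroups: int = 3,
                     orientations: Tuple[int, ...] = (1, -1)) -> List[SyntenyBlock]:
    """All maximal diagonal/antidiagonal runs with k >= k_min.

    Retained blocks must span at least ``min_unique_orthogroups``
    distinct orthogroups, which discards runs that only reflect complex
    tandem duplications.  When the matrix carries no orthogroup labels
    every pair counts as its own orthogroup, so the filter reduces to
    the size threshold.
    """
    blocks: List[SyntenyBlock] = []
    for orient in orientations:
        for run in _maximal_runs(H.dots, orient):
            if len(run) < k_min:
                continue
            if orient == -1 and len(run) == 1:
                continue
            if H.og_a is not None:
                n_unique = len({H.og_a[i] for i, _ in run})
            else:
                n_unique = len(run)
            if n_unique < min_unique_orthogroups:
                continue
            blocks.append(
                SyntenyBlock(
                    kind="nano", species_a=H.species_a, species_b=H.species_b,
                    chrom_a=H.chrom_a, chrom_b=H.chrom_b,
                    pairs=run, orientation=orient, n_unique_orthogroups=n_unique,
                )
            )
    blocks.sort(key=lambda b: (b.pairs[0], b.orientation, b.pairs))
    return blocks


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


@dataclass
class NullSummary:
    """Observed vs. randomized run counts for one block size k."""

    k: int
    n_observed: int        # block count at 0 swaps
    n_randomized: int      # block count after n_swaps swaps
    f_hat: Optional[float]  # n_randomized / n_observed, None if n_observed == 0
    e_f: Optional[float]    # analytic expected fraction, same convention
    q: float                # per-cell dot probability


def permute_dots(dots: FrozenSet[Pair], n_a: int, n_b: int, n_swaps: int,
                 rng: np.random.Generator) -> FrozenSet[Pair]:
    """Apply ``n_swaps`` paired row+column transpositions to the dot set.

    Each swap picks two rows and two columns at random and exchanges
    them, exactly as in the randomisation of the observed dot plots.
    """
    if n_swaps < 0:
        raise ValidationError("n_swaps must be >= 0")
    row_perm = np.arange(n_a)
    col_perm = np.arange(n_b)
    if n_swaps:
        rows = rng.integers(0, n_a, size=(n_swaps, 2))
        cols = rng.integers(0, n_b, size=(n_swaps, 2))
        for (r1, r2), (c1, c2) in zip(rows, cols):
            row_perm[r1], row_perm[r2] = row_perm[r2], row_perm[r1]
            col_perm[c1], col_perm[c2] = col_perm[c2], col_perm[c1]
    return frozenset((int(row_perm[i]), int(col_perm[j])) for i, j in dots)


def permutation_null(H: HomologyMatrix, k_min: int = 2, n_swaps: int = 30000,
                     seed: int = 0) -> Dict[int, NullSummary]:
    """Randomise the matrix by row/column swaps and recount runs per k.

    Returns one :class:`NullSummary` for every k >= k_min present in
    either the observed or the randomized census.  Deterministic given
    the seed.
    """
    if not H.dots:
        raise ValidationError("homology matrix has no dots")
    rng = np.random.default_rng(seed)
    obs = census_runs(H.dots)
    perm_dots = permute_dots(H.dots, H.n_a, H.n_b, n_swaps, rng)
    rand = census_runs(perm_dots)
    q = H.n_dots / (H.n_a * H.n_b)
    out: Dict[int, NullSummary] = {}
    for k in sorted(set(obs) | set(rand)):
        if k < k_min:
            continue
        n0 = obs.get(k, 0)
        ninf = rand.get(k, 0)
        f_hat = ninf / n0 if n0 > 0 else None
        e_f = expected_run_count(H.n_a, H.n_b, H.n_dots, k) / n0 if n0 > 0 else None
        out[k] = NullSummary(k=k, n_observed=n0, n_randomized=ninf,
                             f_hat=f_hat, e_f=e_f, q=q)
    return out


# ---------------------------------------------------------------------------
# Analytic (Bernoulli) null
# ---------------------------------------------------------------------------


def _expected_runs_on_line(L: int, k: int, q: float) -> float:
    """E[# maximal runs of length exactly k] on a line of L iid Bernoulli(q) cells."""
    if k > L or k < 1:
        return 0.0
    if k == L:
        return q ** k
    # placements touching one end need a single empty flank; interior two
    return 2 * q ** k * (1 - q) + max(L - k - 1, 0) * q ** k * (1 - q) ** 2


def expected_run_count(n_a: int, n_b: int, n_dots: int, k: int) -> float:
    """Expected number of maximal runs of length exactly k, both orientations.

    Dots are modeled as independent Bernoulli(q) with
    q = n_dots / (n_a * n_b).  Diagonals of an n_a x n_b matrix come in
    lengths 1..m-1 (twice each) and m = min(n_a, n_b)
    (max(n_a, n_b) - m + 1 times); antidiagonals have the same length
    multiset, so both orientations contribute equally.  Note that for
    k = 1 this counts isolated dots once per orientation, whereas the
    empirical census counts them once; all analyses use k >= 2 where the
    conventions agree.
    """
    if n_dots > n_a * n_b:
        raise ValidationError("n_dots exceeds matrix size")
    q = n_dots / (n_a * n_b)
    if q > 1:
        raise ValidationError("per-cell probability exceeds 1")
    if n_dots == 0:
        return 0.0
    m, M = min(n_a, n_b), max(n_a, n_b)
    total = 0.0
    for L in range(1, m):
        total += 2 * _expected_runs_on_line(L, k, q)
    total += (M - m + 1) * _expected_runs_on_line(m, k, q)
    return 2.0 * total  # diagonal + antidiagonal orientations


def expected_chance_fraction(n_a: int, n_b: int, n_dots: int, k: int,
                             n_observed: int) -> float:
    """Analytic E[f_k]: expected random run count over the observed count."""
    if n_observed <= 0:
        raise ValidationError("expected fraction needs n_observed > 0")
    return expected_run_count(n_a, n_b, n_dots, k) / n_observed


def choose_k_min(summaries: Iterable[NullSummary], alpha: float = 0.05,
                 use_analytic: bool = False) -> int:
    """Smallest k whose chance fraction is below alpha in every comparison.

    ``summaries`` may pool NullSummary records from many genome
    comparisons.  A comparison with no observed blocks at some k puts no
    constraint on that k.  By default the permutation estimate f_hat is
    used; ``use_analytic`` switches to the Bernoulli expectation.
    """
    worst: Dict[int, float] = {}
    for s in summaries:
        frac = s.e_f if use_analytic else s.f_hat
        if frac is None:
            frac = s.e_f if s.e_f is not None else s.f_hat
        if frac is None:
            continue
        worst[s.k] = max(worst.get(s.k, 0.0), frac)
    for k in sorted(worst):
        if worst[k] < alpha:
            return k
    raise ValidationError(
        "no k in the summarised range meets the chance-fraction bound; "
        "extend the range of k"
    )
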