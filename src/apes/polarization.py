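"""Aggregate polarity statistics over gene triplets.

The central quantity is P(delta_dL < 0 | delta_dL != 0): among triplets
with a measurable rate difference, how often the source copy is the
less diverged one.  Values above 0.5 mean target copies tend to evolve
faster — the polarization of paralog evolution.  The module bins this
probability by duplication age, target-copy size and inter-copy
distance, tests block-wise polarization against a resampling null, and
checks robustness by species subsampling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .duplications import DuplicationEvent, GeneTriplet
from .genome_io import ValidationError


@dataclass
class PolarityStats:
    """Sign counts of delta_dL and the conditional polarity probability."""

    n_neg: int
    n_pos: int
    n_zero: int
    p_neg: Optional[float]  # P(delta_dL < 0 | delta_dL != 0); None if undefined

    @property
    def n_total(self) -> int:
        return self.n_neg + self.n_pos + self.n_zero


def _signs(triplets: Sequence[GeneTriplet]) -> np.ndarray:
    vals = [t.delta_dL for t in triplets]
    if any(v is None for v in vals):
        raise ValidationError("all triplets must have delta_dL filled")
    return np.sign(np.asarray(vals, dtype=float)).astype(int)


def overall_polarity(triplets: Sequence[GeneTriplet]) -> PolarityStats:
    """Pooled sign counts and P(delta_dL<0 | delta_dL!=0).

    p_neg is None when every triplet has delta_dL = 0 (no measurable
    rate difference anywhere).
    """
    s = _signs(triplets)
    n_neg = int(np.sum(s < 0))
    n_pos = int(np.sum(s > 0))
    n_zero = int(np.sum(s == 0))
    p = n_neg / (n_neg + n_pos) if (n_neg + n_pos) else None
    return PolarityStats(n_neg=n_neg, n_pos=n_pos, n_zero=n_zero, p_neg=p)


# ---------------------------------------------------------------------------
# Polarity vs. duplication age
# ---------------------------------------------------------------------------


@dataclass
class AgeCurve:
    """Binned and cumulative polarity vs. duplication age, plus rank corr."""

    bin_edges: np.ndarray
    p_neg: np.ndarray          # per bin; nan where no nonzero triplets
    n: np.ndarray              # nonzero-delta triplets per bin
    cumulative_t: np.ndarray   # sorted ages
    cumulative_p: np.ndarray   # P over triplets of age <= t
    rho: float                 # Spearman corr of sign(delta_dL) with age
    p_value: float


def polarity_vs_age(triplets: Sequence[GeneTriplet],
                    bin_width: float = 10.0) -> AgeCurve:
    """Polarity as a function of duplication age (MYA)."""
    ages = np.array([t.duplication_time for t in triplets], dtype=float)
    if np.any(np.isnan(ages)):
        raise ValidationError("all triplets must carry a duplication time")
    s = _signs(triplets)
    nz = s != 0
    edges = np.arange(0.0, ages.max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    idx = np.clip(np.digitize(ages, edges) - 1, 0, len(edges) - 2)
    p_bins = np.full(len(edges) - 1, np.nan)
    n_bins = np.zeros(len(edges) - 1, dtype=int)
    for b in range(len(edges) - 1):
        m = nz & (idx == b)
        n_bins[b] = int(m.sum())
        if n_bins[b]:
            p_bins[b] = np.mean(s[m] < 0)
    order = np.argsort(ages[nz], kind="stable")
    t_sorted = ages[nz][order]
    neg_sorted = (s[nz][order] < 0).astype(float)
    cumulative_p = np.cumsum(neg_sorted) / np.arange(1, len(neg_sorted) + 1)
    if nz.sum() >= 2 and len(set(ages[nz])) > 1:
        rho, p_value = stats.spearmanr(s[nz], ages[nz])
    else:
        rho, p_value = float("nan"), float("nan")
    return AgeCurve(bin_edges=edges, p_neg=p_bins, n=n_bins,
                    cumulative_t=t_sorted, cumulative_p=cumulative_p,
                    rho=float(rho), p_value=float(p_value))


# ---------------------------------------------------------------------------
# Polarity vs. target size and inter-copy distance
# ---------------------------------------------------------------------------


@dataclass
class BinnedPolarity:
    """Per-bin sign fractions; the final bin collects interchromosomal events."""

    bin_edges: List[float]     # last edge inf: interchromosomal pool
    p_neg: np.ndarray
    p_pos: np.ndarray
    p_zero: np.ndarray
    n: np.ndarray


def _default_bp_bins() -> List[float]:
    # log-spaced up to 1 Mb; polarization persists to at least that scale
    return [0.0, 1e4, 3e4, 1e5, 3e5, 1e6, math.inf]


def _bin_triplets(values: np.ndarray, s: np.ndarray, edges: List[float]
                  ) -> BinnedPolarity:
    nb = len(edges) - 1
    p_neg = np.full(nb, np.nan)
    p_pos = np.full(nb, np.nan)
    p_zero = np.full(nb, np.nan)
    n = np.zeros(nb, dtype=int)
    for b in range(nb):
        lo, hi = edges[b], edges[b + 1]
        if math.isinf(hi):
            m = np.isinf(values) if math.isinf(lo) else (values >= lo)
        else:
            m = (values >= lo) & (values < hi)
        n[b] = int(m.sum())
        if n[b]:
            p_neg[b] = np.mean(s[m] < 0)
            p_pos[b] = np.mean(s[m] > 0)
            p_zero[b] = np.mean(s[m] == 0)
    return BinnedPolarity(bin_edges=list(edges), p_neg=p_neg, p_pos=p_pos,
                          p_zero=p_zero, n=n)


def polarity_vs_size_distance(triplets: Sequence[GeneTriplet],
                              events: Dict[str, DuplicationEvent],
                              size_bins: Optional[List[float]] = None,
                              distance_bins: Optional[List[float]] = None
                              ) -> Tuple[BinnedPolarity, BinnedPolarity]:
    """Polarity binned by target-copy size (bp) and inter-copy distance.

    Interchromosomal duplications (infinite distance) pool into the
    final distance bin.  Fractions in every nonempty bin satisfy
    p_neg + p_pos + p_zero = 1.
    """
    size_bins = size_bins or _default_bp_bins()[:-1] + [math.inf]
    distance_bins = distance_bins or _default_bp_bins()
    if not math.isinf(distance_bins[-1]):
        distance_bins = list(distance_bins) + [math.inf]
    s = _signs(triplets)
    sizes = np.array(
        [events[t.event_id].l_target or np.nan for t in triplets], dtype=float
    )
    dists = np.array(
        [events[t.event_id].inter_copy_distance for t in triplets], dtype=float
    )
    # distance binning: finite bins plus the inf pool; the inf bin of the
    # distance axis is selected by actual infinity, so pass lo=inf for it
    dist_edges = list(distance_bins)
    by_size = _bin_triplets(sizes, s, list(size_bins))
    nb = len(dist_edges) - 1
    p_neg = np.full(nb, np.nan)
    p_pos = np.full(nb, np.nan)
    p_zero = np.full(nb, np.nan)
    n = np.zeros(nb, dtype=int)
    for b in range(nb):
        lo, hi = dist_edges[b], dist_edges[b + 1]
        if math.isinf(hi):
            m = np.isinf(dists)
        else:
            m = (dists >= lo) & (dists < hi)
        n[b] = int(m.sum())
        if n[b]:
            p_neg[b] = np.mean(s[m] < 0)
            p_pos[b] = np.mean(s[m] > 0)
            p_zero[b] = np.mean(s[m] == 0)
    by_dist = BinnedPolarity(bin_edges=dist_edges, p_neg=p_neg, p_pos=p_pos,
                             p_zero=p_zero, n=n)
    return by_size, by_dist


# ---------------------------------------------------------------------------
# Block-wise polarization null
# ---------------------------------------------------------------------------


@dataclass
class BlockPolarity:
    """Fraction of a duplication's triplets with delta_dL < 0."""

    event_id: str
    n_triplets: int
    p_sb: float

    @property
    def fully_polarized(self) -> bool:
        return self.p_sb in (0.0, 1.0)


@dataclass
class BlockwiseNullResult:
    p_value: float
    t_observed: float          # fraction of blocks with P_SB in {0, 1}
    null_t: np.ndarray
    blocks: List[BlockPolarity]


def block_polarities(triplets: Sequence[GeneTriplet]) -> List[BlockPolarity]:
    groups: Dict[str, List[int]] = {}
    s = _signs(triplets)
    for i, t in enumerate(triplets):
        groups.setdefault(t.event_id, []).append(i)
    out = []
    for eid in sorted(groups):
        idx = groups[eid]
        neg = int(np.sum(s[idx] < 0))
        out.append(BlockPolarity(event_id=eid, n_triplets=len(idx),
                                 p_sb=neg / len(idx)))
    return out


def blockwise_null_test(triplets: Sequence[GeneTriplet],
                        n_resamples: int = 10000,
                        seed: int = 0) -> BlockwiseNullResult:
    """Test whether polarity is determined block-wise rather than per gene.

    The statistic T is the fraction of multi-triplet duplications whose
    P_SB is exactly 0 or 1 (fully polarized blocks).  The null
    randomly resorts triplet delta_dL signs into duplications of the
    same sizes; p = (1 + #{null T >= observed T}) / (1 + n_resamples).
    Blocks with a single triplet are excluded (their P_SB is trivially
    extreme).
    """
    s_all = _signs(triplets)
    groups: Dict[str, List[int]] = {}
    for i, t in enumerate(triplets):
        groups.setdefault(t.event_id, []).append(i)
    eligible = {eid: idx for eid, idx in groups.items() if len(idx) >= 2}
    if not eligible:
        raise ValidationError("no duplication has two or more triplets")
    order = [i for eid in sorted(eligible) for i in eligible[eid]]
    sizes = np.array([len(eligible[eid]) for eid in sorted(eligible)])
    bounds = np.concatenate([[0], np.cumsum(sizes)])[:-1]
    signs = s_all[order]
    neg = (signs < 0).astype(np.int64)

    def t_stat(neg_vec: np.ndarray) -> float:
        per_block = np.add.reduceat(neg_vec, bounds)
        return float(np.mean((per_block == 0) | (per_block == sizes)))

    t_obs = t_stat(neg)
    rng = np.random.default_rng(seed)
    null_t = np.empty(n_resamples)
    for r in range(n_resamples):
        null_t[r] = t_stat(rng.permutation(neg))
    p = (1 + int(np.sum(null_t >= t_obs))) / (1 + n_resamples)
    blocks = block_polarities([triplets[i] for i in order])
    return BlockwiseNullResult(p_value=p, t_observed=t_obs, null_t=null_t,
                               blocks=blocks)


# ---------------------------------------------------------------------------
# Bootstrap species subsampling
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    sample_size: int
    values: np.ndarray        # P(delta_dL<0 | !=0) per retained sample
    n_skipped: int

    @property
    def pr_le_half(self) -> float:
        return float(np.mean(self.values <= 0.5)) if len(self.values) else float("nan")


def bootstrap_species(triplets: Sequence[GeneTriplet],
                      species_list: Sequence[str],
                      sample_sizes: Sequence[int],
                      n_samples: int = 1000,
                      seed: int = 0) -> Dict[int, BootstrapResult]:
    """Subsample species without replacement and recompute polarity.

    A triplet is retained in a sample only when both its focal and
    reference species are drawn.  Samples with no nonzero-delta triplet
    are skipped with a warning.
    """
    species = list(dict.fromkeys(species_list))
    for size in sample_sizes:
        if size > len(species):
            raise ValidationError(
                f"sample size {size} exceeds species count {len(species)}"
            )
    s = _signs(triplets)
    focal = np.array([t.species_focal for t in triplets])
    ref = np.array([t.species_ref for t in triplets])
    rng = np.random.default_rng(seed)
    out: Dict[int, BootstrapResult] = {}
    for size in sample_sizes:
        vals: List[float] = []
        skipped = 0
        for _ in range(n_samples):
            subset = set(rng.choice(species, size=size, replace=False))
            keep = np.array([f in subset and r in subset
                             for f, r in zip(focal, ref)])
            sk = s[keep]
            n_neg = int(np.sum(sk < 0))
            n_pos = int(np.sum(sk > 0))
            if n_neg + n_pos == 0:
                skipped += 1
                continue
            vals.append(n_neg / (n_neg + n_pos))
        if skipped:
            warnings.warn(
                f"{skipped}/{n_samples} samples of size {size} had no "
                "nonzero-delta triplet and were skipped"
            )
        out[size] = BootstrapResult(sample_size=size,
                                    values=np.asarray(vals),
                                    n_skipped=skipped)
    return out
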