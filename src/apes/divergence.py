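"""Protein divergence, rate asymmetry and the f / f* statistics.

Divergence between two proteins is the Levenshtein (edit) distance —
the minimum number of substitutions, insertions and deletions turning
one sequence into the other — normalised per site by the longer
sequence length, so it lies in [0, 1] and is symmetric.  Amino-acid
distances avoid the saturation of non-synonymous nucleotide
substitutions at the deep divergence times considered here.

For a gene triplet (source paralog A1, target paralog A2, reference
ortholog B1), delta_dL = d_L(A1,B1) - d_L(A2,B1) is negative when the
source copy is the less diverged one.  Dividing the two distances by
the time since duplication gives substitution rates for the source and
target copies; since both share the denominator, every sign-based
statistic downstream is invariant to that choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import edlib

from .duplications import GeneTriplet
from .genome_io import ValidationError
from .homology import TDEC, TdecTable
from .nanosynteny import SyntenyBlock


@dataclass(frozen=True)
class DivergenceRecord:
    """Raw and per-site edit distance between two sequences."""

    gene_pair: Tuple[str, str]
    d_raw: int
    d_per_site: float
    lengths: Tuple[int, int]


NORMALIZATIONS = {"max", "mean"}


def levenshtein(seq_a: str, seq_b: str, ids: Tuple[str, str] = ("a", "b"),
                normalization: str = "max") -> DivergenceRecord:
    """Edit distance between two protein sequences, normalised per site."""
    if not seq_a or not seq_b:
        raise ValidationError("sequences must be nonempty")
    if normalization not in NORMALIZATIONS:
        raise ValidationError(f"unknown normalization {normalization!r}")
    d_raw = edlib.align(seq_a, seq_b, task="distance", mode="NW")["editDistance"]
    if normalization == "max":
        denom = max(len(seq_a), len(seq_b))
    else:
        denom = 0.5 * (len(seq_a) + len(seq_b))
    return DivergenceRecord(
        gene_pair=ids, d_raw=d_raw, d_per_site=d_raw / denom,
        lengths=(len(seq_a), len(seq_b)),
    )


def fill_delta_dL(triplet: GeneTriplet, sequences: Mapping[str, str],
                  normalization: str = "max") -> Optional[GeneTriplet]:
    """Fill d_L(A1,B1), d_L(A2,B1) and delta_dL on a triplet.

    Sequences are looked up by the representative gene id of each TDEC;
    a missing sequence skips the triplet (returns None).
    """
    ids = (triplet.a1.representative_gene_id,
           triplet.a2.representative_gene_id,
           triplet.b1.representative_gene_id)
    if any(i not in sequences for i in ids):
        return None
    d1 = levenshtein(sequences[ids[0]], sequences[ids[2]], (ids[0], ids[2]),
                     normalization)
    d2 = levenshtein(sequences[ids[1]], sequences[ids[2]], (ids[1], ids[2]),
                     normalization)
    triplet.d_a1_b1 = d1.d_per_site
    triplet.d_a2_b1 = d2.d_per_site
    triplet.delta_dL = d1.d_per_site - d2.d_per_site
    return triplet


def substitution_rates(triplet: GeneTriplet, t_dup: float) -> GeneTriplet:
    """Per-copy substitution rates: distance over time since duplication."""
    if t_dup is None or t_dup <= 0:
        raise ValidationError("duplication time must be positive")
    if triplet.d_a1_b1 is None or triplet.d_a2_b1 is None:
        raise ValidationError("distances must be filled before rates")
    triplet.duplication_time = t_dup
    triplet.r_source = triplet.d_a1_b1 / t_dup
    triplet.r_target = triplet.d_a2_b1 / t_dup
    return triplet


# ---------------------------------------------------------------------------
# f and f* statistics
# ---------------------------------------------------------------------------


@dataclass
class FStatistic:
    """Fraction of reference genes whose primary-block homolog is closest."""

    value: Optional[float]
    n_success: int
    n_failure: int
    n_tie: int

    @property
    def n_eligible(self) -> int:
        return self.n_success + self.n_failure + self.n_tie


def compute_f(reference: TdecTable, focal: TdecTable,
              micro: Sequence[SyntenyBlock], sequences: Mapping[str, str],
              restrict_to_duplicated: bool = False,
              normalization: str = "max") -> FStatistic:
    """How often the primary-microsynteny homolog is the closest homolog.

    For each reference TDEC with >= 2 focal homologs (same orthogroup)
    and a defined primary microsynteny block whose partner lies in the
    focal genome, count whether that partner is strictly closest in
    per-site Levenshtein distance among all focal homologs.  Ties
    (equal minimal distance) are tracked but excluded from the
    fraction, which conditions on a measurable difference.  With
    ``restrict_to_duplicated`` only reference genes participating in
    >= 2 microsynteny blocks are considered (the f* statistic, probing
    duplicated regions in the focal genome).
    """
    focal_by_og: Dict[str, List[TDEC]] = {}
    for t in focal.tdecs():
        if t.orthogroup is not None:
            focal_by_og.setdefault(t.orthogroup, []).append(t)

    # membership: reference (chrom, idx) -> blocks, and partner focal TDEC
    ref_is_a = {}
    blocks_of: Dict[Tuple[str, int], List[Tuple[SyntenyBlock, int]]] = {}
    for b in micro:
        if b.species_a == reference.species and b.species_b == focal.species:
            for i, j in b.pairs:
                blocks_of.setdefault((b.chrom_a, i), []).append((b, j))
        elif b.species_b == reference.species and b.species_a == focal.species:
            for i, j in b.pairs:
                blocks_of.setdefault((b.chrom_b, j), []).append((b, i))

    n_success = n_failure = n_tie = 0
    for t in reference.tdecs():
        if t.orthogroup is None:
            continue
        homologs = focal_by_og.get(t.orthogroup, [])
        if len(homologs) < 2:
            continue
        entries = blocks_of.get((t.chromosome, t.order_index), [])
        if not entries:
            continue
        if restrict_to_duplicated and len({id(b) for b, _ in entries}) < 2:
            continue
        block, focal_idx = min(
            entries, key=lambda e: (-e[0].k, e[0].chrom_a, e[0].chrom_b, e[0].pairs[0])
        )
        focal_chrom = (block.chrom_b if block.species_a == reference.species
                       else block.chrom_a)
        primary = focal.get(focal_chrom, focal_idx)
        if primary.orthogroup != t.orthogroup:
            continue
        ref_seq = sequences.get(t.representative_gene_id)
        if ref_seq is None:
            continue
        dists = {}
        for h in homologs:
            seq = sequences.get(h.representative_gene_id)
            if seq is not None:
                dists[h.tdec_id] = levenshtein(
                    ref_seq, seq, (t.tdec_id, h.tdec_id), normalization
                ).d_per_site
        if primary.tdec_id not in dists or len(dists) < 2:
            continue
        d_primary = dists[primary.tdec_id]
        d_others = min(v for k, v in dists.items() if k != primary.tdec_id)
        if d_primary < d_others:
            n_success += 1
        elif d_primary == d_others:
            n_tie += 1
        else:
            n_failure += 1
    denom = n_success + n_failure
    value = n_success / denom if denom else None
    return FStatistic(value=value, n_success=n_success, n_failure=n_failure,
                      n_tie=n_tie)
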