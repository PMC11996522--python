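"""Shared fixtures: small genomes, orthogroup maps and a simulated dataset."""

import numpy as np
import pytest

import apes


def make_tdec_table(species, chrom_ogs, spacing=2000, length=1000):
    """Build a TdecTable from {chromosome: [orthogroup, ...]} sequences.

    Each orthogroup entry becomes a singleton TDEC; None entries are
    unassigned genes.  Gene ids are ``<species>_<chrom>_<pos>``.
    """
    chroms = {}
    for chrom, ogs in chrom_ogs.items():
        tds = []
        for pos, og in enumerate(ogs):
            gid = f"{species}_{chrom}_{pos}"
            start = 1 + spacing * pos
            tds.append(
                apes.TDEC(
                    tdec_id=gid, species=species, chromosome=chrom,
                    orthogroup=og, member_gene_ids=(gid,), order_index=pos,
                    representative_gene_id=gid, span_start=start,
                    span_end=start + length - 1,
                )
            )
        chroms[chrom] = tds
    return apes.TdecTable(species=species, chromosomes=chroms)


def make_block(pairs, kind="micro", orientation=1, species_a="A", species_b="B",
               chrom_a="chr1", chrom_b="chr1"):
    return apes.SyntenyBlock(
        kind=kind, species_a=species_a, species_b=species_b,
        chrom_a=chrom_a, chrom_b=chrom_b, pairs=tuple(pairs),
        orientation=orientation,
    )


def random_matrix(n_a, n_b, n_dots, rng):
    """Uniformly random dot placement without replacement."""
    cells = rng.choice(n_a * n_b, size=n_dots, replace=False)
    dots = {(int(c) // n_b, int(c) % n_b) for c in cells}
    return apes.HomologyMatrix.from_dots(dots, n_a, n_b)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_dataset():
    """Four species, one 6-gene duplication planted after the S2 split.

    The duplication occurs 30 MYA on the branch leading to the
    (S1, S3, S4) clade of a 100 MY crown-age tree, with the target copy
    evolving twice as fast as the source.  S2 (no copy) serves as the
    pre-duplication reference species.
    """
    cfg = apes.SimulationConfig(
        n_species=4, crown_age=100.0, chromosomes=2, genes_per_chromosome=60,
        seed=3,
        duplications=[
            apes.DuplicationSpec(time=30.0, branch="S1", n_genes=6,
                                 r_target=2e-3)
        ],
    )
    return apes.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_condensed(planted_dataset):
    return {sp: planted_dataset.condensed(sp)
            for sp in planted_dataset.gene_tables}
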