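import numpy as np
import pytest

from cmfscan.annotation_io import (
    FeatureType,
    GeneRecord,
    GenomeAnnotation,
    SourceGroup,
)
from cmfscan.screening import PresenceMatrix


def rec(product, symbol=None, ftype=FeatureType.CDS, locus=None):
    """Shorthand gene-record constructor with auto locus ids."""
    if locus is None:
        rec._counter += 1
        locus = f"LOC_{rec._counter:05d}"
    return GeneRecord(ftype, symbol, product, locus)


rec._counter = 0


def genome(gid, products, group=SourceGroup.OTHER):
    """Genome whose CDS records carry the given product strings."""
    return GenomeAnnotation(
        gid,
        group,
        [
            GeneRecord(FeatureType.CDS, None, p, f"{gid}_{i:04d}")
            for i, p in enumerate(products, 1)
        ],
    )


@pytest.fixture
def two_group_matrix():
    """Planted 10+10 matrix: two disjoint key blocks, perfectly separable."""
    n_per, p = 10, 12
    cells = np.zeros((2 * n_per, p), dtype="int8")
    cells[:n_per, : p // 2] = 1
    cells[n_per:, p // 2 :] = 1
    return PresenceMatrix(
        genome_ids=[f"g{i}" for i in range(2 * n_per)],
        source_groups=[SourceGroup.NCBI] * n_per + [SourceGroup.UMGS] * n_per,
        cmf_keys=[f"k{j}" for j in range(p)],
        cells=cells,
    )


@pytest.fixture
def random_binary_matrix():
    rng = np.random.default_rng(42)
    cells = (rng.random((25, 30)) < 0.5).astype("int8")
    cells[0] = 1  # avoid an all-zero row for Jaccard
    return PresenceMatrix(
        genome_ids=[f"g{i}" for i in range(25)],
        source_groups=[SourceGroup.NCBI] * 12 + [SourceGroup.UMGS] * 13,
        cmf_keys=[f"k{j}" for j in range(30)],
        cells=cells,
    )
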