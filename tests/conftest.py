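import numpy as np
import pytest

from palmscan.io_core import GenotypeMatrix


@pytest.fixture
def toy_matrix():
    """3 samples, 2 populations, 2 sites on one chromosome."""
    return GenotypeMatrix(
        samples=["s1", "s2", "s3"],
        populations=["A", "A", "B"],
        chrom=["chr1", "chr1"],
        pos=[100, 200],
        ref=["A", "C"],
        alt=["T", "G"],
        gt=np.array([[0, 1, 2], [0, 0, 1]], dtype=np.int8),
    )


def make_two_pop_matrix(g_pop1, g_pop2, pos=None, chrom="chr1"):
    """Single- or multi-site matrix from per-population genotype lists.

    g_pop1/g_pop2: (n_sites, n_samples) nested lists of dosage codes.
    """
    g1 = np.asarray(g_pop1, dtype=np.int8)
    g2 = np.asarray(g_pop2, dtype=np.int8)
    if g1.ndim == 1:
        g1, g2 = g1[None, :], g2[None, :]
    n_sites = g1.shape[0]
    if pos is None:
        pos = list(range(1, n_sites + 1))
    gt = np.hstack([g1, g2])
    samples = [f"a{i}" for i in range(g1.shape[1])] + [
        f"b{i}" for i in range(g2.shape[1])
    ]
    pops = ["A"] * g1.shape[1] + ["B"] * g2.shape[1]
    return GenotypeMatrix(
        samples,
        pops,
        [chrom] * n_sites,
        pos,
        ["A"] * n_sites,
        ["T"] * n_sites,
        gt,
    )
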