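"""Shared fixtures: toy partitions and session-cached simulations."""

import numpy as np
import pytest

from ccnorm.interactions import InteractionSet, iterative_coverage_filter, neutral_filter
from ccnorm.distance import fit_hic_distance
from ccnorm.partition import Fragment, Partition
from ccnorm import simdata


@pytest.fixture
def two_fragment_partition():
    """Two 100-bp fragments on one chromosome, HiC (4 fends)."""
    frags = [Fragment(0, "chr1", 0, 100), Fragment(1, "chr1", 100, 200)]
    return Partition(frags, assay="hic")


@pytest.fixture
def fivec_partition():
    """Six alternating-orientation fragments in one region."""
    frags = [
        Fragment(k, "chr1", 1000 * k, 1000 * k + 800, region=0,
                 primer_orientation="forward" if k % 2 == 0 else "reverse")
        for k in range(6)
    ]
    return Partition(frags, assay="fivec",
                     regions=[("chr1", 0, 5800)])


@pytest.fixture(scope="session")
def hic_sim():
    """Stochastic HiC simulation: 200 fends, deep coverage, fixed seed."""
    return simdata.simulate_hic(n_fragments=100, depth=600, seed=1)


@pytest.fixture(scope="session")
def hic_sim_filtered(hic_sim):
    part, ints, truth = hic_sim
    filt = iterative_coverage_filter(ints, 10)
    df = fit_hic_distance(ints, part, filt, n_bins=30,
                          smallest_bin_upper=50_000)
    return part, ints, truth, filt, df


@pytest.fixture(scope="session")
def hic_exact():
    """Noise-free HiC data generated exactly from a fitted distance model.

    Counts are lambda_ij = exp(D_fit(d_ij)) * b_i * b_j with no sampling,
    so the multiplicative model holds exactly and normalizers must recover
    b up to machine precision.
    """
    part, ints, truth = simdata.simulate_hic(n_fragments=80, depth=100,
                                             seed=3)
    filt = neutral_filter(part)
    df = fit_hic_distance(ints, part, filt, n_bins=20,
                          smallest_bin_upper=50_000)
    b = truth.biases
    mids = part.element_mids()
    frag_of = np.array([f.fragment_index for f in part.fends])
    iu, ju = np.triu_indices(part.n_elements, k=1)
    keep = frag_of[iu] != frag_of[ju]
    iu, ju = iu[keep], ju[keep]
    d = np.abs(mids[iu] - mids[ju]).astype(float)
    lam = np.exp(df.evaluate(d)) * b[iu] * b[ju]
    exact = InteractionSet(part)
    for i, j, c in zip(iu, ju, lam):
        exact.pairs[(int(i), int(j))] = float(c)
    return part, exact, b, filt, df


@pytest.fixture(scope="session")
def fivec_sim():
    """Stochastic 5C simulation: 100 fragments, sigma = 0.4 noise."""
    return simdata.simulate_5c(n_regions=2, frags_per_region=50,
                               noise_sigma=0.4, seed=2)
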