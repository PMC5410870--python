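"""Synthetic HiC and 5C datasets with known ground truth.

The generators emulate the statistical structure the normalization models
assume: multiplicative per-fend biases (lognormal), a power-law decay of
contact frequency with genomic separation, Poisson count noise for HiC and
lognormal noise for 5C, and 5C region structure with alternating primer
orientations (only opposite-orientation fragment pairs can be observed).
Every generator is seed-deterministic and returns a :class:`SimTruth`
carrying the exact biases and decay parameters used, so estimators can be
scored by parameter recovery.

Defaults: decay exponent gamma = -1.0 (the classic fractal-globule-like
power law seen in cis contact data) and bias_sigma = 0.3 (lognormal scale
of per-element efficiency, a plausible magnitude for restriction/ligation
bias spread).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ccnorm.interactions import InteractionSet, ReadPair
from ccnorm.partition import Fragment, Partition

__all__ = ["SimTruth", "simulate_hic", "simulate_5c",
           "paired_enzyme_simulation"]


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated dataset."""

    biases: np.ndarray  # multiplicative (HiC) or additive-log (5C)
    gamma: float
    mu: float
    depth: float
    noise_model: str
    seed: int
    covariates: dict | None = None  # observable per-element feature tracks

    def to_text(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(f"noise_model: {self.noise_model}\n")
            handle.write(f"gamma: {self.gamma!r}\n")
            handle.write(f"mu: {self.mu!r}\n")
            handle.write(f"depth: {self.depth!r}\n")
            handle.write(f"seed: {self.seed}\n")
            handle.write("biases: " + ",".join(
                repr(b) for b in self.biases) + "\n")


def _random_partition(rng, n_fragments: int, chrom_length: int,
                      chrom: str = "chr1") -> Partition:
    """Fragment lengths jittered around chrom_length / n (min 100 bp)."""
    mean = chrom_length / n_fragments
    lengths = np.maximum(rng.normal(mean, 0.25 * mean, n_fragments), 100.0)
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    bounds *= chrom_length / bounds[-1]
    bounds = np.unique(np.round(bounds).astype(np.int64))
    fragments = [Fragment(k, chrom, int(bounds[k]), int(bounds[k + 1]))
                 for k in range(len(bounds) - 1)]
    return Partition(fragments, assay="hic")


def simulate_hic(n_fragments: int = 100, chrom_length: int = 10_000_000,
                 bias_sigma: float = 0.3, gamma: float = -1.0,
                 depth: float = 50.0, seed: int = 0,
                 partition: Partition | None = None,
                 biases: np.ndarray | None = None,
                 log_enrichment: np.ndarray | None = None,
                 enrichment_block: int = 0):
    """Simulate a single-chromosome HiC dataset at fend resolution.

    Pair intensities are lambda_ij = s * b_i * b_j * d_ij^gamma over all
    fend pairs of distinct fragments, with s chosen so the mean expected
    count per fend is ``depth``; counts are Poisson.  Biases are lognormal
    (0, bias_sigma), regauged to unit geometric mean.  An optional latent
    ``log_enrichment`` grid (indexed by midpoint // enrichment_block per
    axis) injects shared structure beyond the distance decay.

    Returns (partition, interactions, truth).
    """
    if n_fragments < 10:
        raise ValueError("n_fragments must be >= 10")
    if bias_sigma < 0 or depth <= 0:
        raise ValueError("bias_sigma must be >= 0 and depth > 0")
    rng = np.random.default_rng(seed)
    if partition is None:
        partition = _random_partition(rng, n_fragments, chrom_length)
    n = partition.n_elements
    if biases is None:
        b = rng.lognormal(0.0, bias_sigma, n) if bias_sigma > 0 else np.ones(n)
    else:
        b = np.asarray(biases, dtype=float).copy()
    b /= np.exp(np.log(b).mean())
    mids = partition.element_mids()
    frag_of = np.array([f.fragment_index for f in partition.fends])
    iu, ju = np.triu_indices(n, k=1)
    keep = frag_of[iu] != frag_of[ju]  # filters expect no same-fragment pairs
    iu, ju = iu[keep], ju[keep]
    d = np.abs(mids[iu] - mids[ju]).astype(float)
    d = np.maximum(d, 1.0)
    lam = b[iu] * b[ju] * d ** gamma
    if log_enrichment is not None:
        blk = max(int(enrichment_block), 1)
        gi = np.minimum(mids[iu] // blk, log_enrichment.shape[0] - 1)
        gj = np.minimum(mids[ju] // blk, log_enrichment.shape[1] - 1)
        lam = lam * np.exp(log_enrichment[gi, gj])
    scale = depth * n / 2.0 / lam.sum()
    lam *= scale
    counts = rng.poisson(lam)
    ints = InteractionSet(partition)
    for i, j, c in zip(iu, ju, counts):
        if c > 0:
            ints.add(int(i), int(j), int(c))
    truth = SimTruth(b, gamma, float(np.log(scale)), depth, "poisson", seed)
    return partition, ints, truth


def simulate_5c(n_regions: int = 2, frags_per_region: int = 20,
                bias_sigma: float = 0.3, gamma: float = -1.0,
                noise_sigma: float = 0.4, mu: float = 14.0, seed: int = 0,
                frag_length: int = 4000, round_counts: bool = True):
    """Simulate a 5C dataset over regions of alternating primer orientation.

    Only opposite-orientation intra-region pairs receive counts:
    ln c_ij = mu + gamma * ln d_ij + f_i + f_j + Normal(0, noise_sigma),
    exponentiated and (by default) rounded to integers, dropping pairs that
    round to zero.  Additive-log biases f are Normal(0, bias_sigma),
    recentered to mean zero.
    """
    if frags_per_region < 4:
        raise ValueError("frags_per_region must be >= 4")
    rng = np.random.default_rng(seed)
    fragments = []
    regions = []
    index = 0
    for r in range(n_regions):
        chrom = "chr1"
        base = r * 10_000_000
        for k in range(frags_per_region):
            start = base + k * frag_length
            orientation = "forward" if k % 2 == 0 else "reverse"
            fragments.append(Fragment(index, chrom, start, start + frag_length,
                                      region=r,
                                      primer_orientation=orientation))
            index += 1
        regions.append((chrom, base, base + frags_per_region * frag_length))
    partition = Partition(fragments, assay="fivec", regions=regions)
    n = partition.n_elements
    f = rng.normal(0.0, bias_sigma, n) if bias_sigma > 0 else np.zeros(n)
    f -= f.mean()
    mids = partition.element_mids()
    groups = partition.element_regions()
    orient = partition.orientations()
    ints = InteractionSet(partition)
    iu, ju = np.triu_indices(n, k=1)
    keep = (groups[iu] == groups[ju]) & (orient[iu] != orient[ju])
    iu, ju = iu[keep], ju[keep]
    d = np.abs(mids[iu] - mids[ju]).astype(float)
    noise = rng.normal(0.0, noise_sigma, len(iu)) if noise_sigma > 0 \
        else np.zeros(len(iu))
    lnc = mu + gamma * np.log(d) + f[iu] + f[ju] + noise
    counts = np.exp(lnc)
    if round_counts:
        counts = np.round(counts)
    for i, j, c in zip(iu, ju, counts):
        if c > 0:
            ints.add(int(i), int(j), int(c) if round_counts else float(c))
    truth = SimTruth(f, gamma, mu, float(np.exp(mu)), "lognormal", seed)
    return partition, ints, truth


def _correlated_biases(rng, mids: np.ndarray, chrom_length: int,
                       bias_sigma: float, bias_block: int,
                       white_fraction: float = 0.3) -> np.ndarray:
    """Lognormal biases with a smooth along-genome component.

    Real fend biases track sequence features (GC content, mappability,
    cut-site density) that vary slowly along the chromosome, so they do not
    average out under binning; the smooth part is a block-level Gaussian
    field linearly interpolated at fend midpoints, plus independent
    per-fend noise.  Total log-variance is bias_sigma**2.
    """
    n_blocks = max(int(np.ceil(chrom_length / bias_block)) + 1, 2)
    track = rng.normal(0.0, 1.0, n_blocks)
    smooth = np.interp(mids / bias_block, np.arange(n_blocks), track)
    white = rng.normal(0.0, 1.0, len(mids))
    mix = (np.sqrt(1.0 - white_fraction) * smooth
           + np.sqrt(white_fraction) * white)
    return np.exp(bias_sigma * mix), smooth


def paired_enzyme_simulation(seed: int = 0, n_fragments_a: int = 80,
                             n_fragments_b: int = 110,
                             chrom_length: int = 8_000_000,
                             bias_sigma: float = 0.5, gamma: float = -1.0,
                             depth: float = 100.0,
                             enrichment_sigma: float = 0.6,
                             enrichment_block: int = 250_000,
                             bias_block: int = 400_000):
    """Two HiC datasets sampling one latent contact surface.

    Emulates the comparison of different restriction digests of the same
    genome: a shared symmetric log-enrichment field on coarse blocks
    modulates both datasets' intensities on top of the distance decay,
    while each dataset draws independent per-fend biases (spatially
    correlated, see :func:`_correlated_biases`) and Poisson counts.
    Normalization should raise the inter-dataset correlation of the
    enrichment maps above that of the raw maps.

    Returns ((part_a, ints_a, truth_a), (part_b, ints_b, truth_b), field).
    """
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(chrom_length / enrichment_block))
    half = rng.normal(0.0, enrichment_sigma, (n_blocks, n_blocks))
    field = (half + half.T) / np.sqrt(2.0)
    out = []
    for n_fragments in (n_fragments_a, n_fragments_b):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        part = _random_partition(np.random.default_rng(sub), n_fragments,
                                 chrom_length)
        biases, smooth = _correlated_biases(
            rng, part.element_mids().astype(float), chrom_length,
            bias_sigma, bias_block)
        part_out, ints_out, truth_out = simulate_hic(
            n_fragments, chrom_length, bias_sigma, gamma, depth, sub,
            partition=part, biases=biases, log_enrichment=field,
            enrichment_block=enrichment_block)
        lengths = np.array(
            [part.fragments[fe.fragment_index].stop
             - part.fragments[fe.fragment_index].start
             for fe in part.fends], dtype=float)
        # the smooth bias component doubles as an observable covariate,
        # playing the role a mappability track plays for real data
        truth_out.covariates = {"mappability": smooth, "length": lengths}
        out.append((part_out, ints_out, truth_out))
    return out[0], out[1], field


def emit_read_pairs(ints: InteractionSet, seed: int = 0):
    """Expand a HiC interaction set into plausible mapped read pairs.

    Each counted fend pair is emitted ``count`` times with 5' positions
    drawn inside the fend's fragment half pointing at the fend's cut site,
    exercising the full assignment and filtering path.
    """
    rng = np.random.default_rng(seed)
    partition = ints.partition
    pairs = []
    for (i, j), c in sorted(ints.pairs.items()):
        for _ in range(int(c)):
            rec = []
            for e in (i, j):
                fend = partition.fends[e]
                frag = partition.fragments[fend.fragment_index]
                if fend.side == "right":  # read points rightward -> "+"
                    pos = int(rng.integers(frag.mid, frag.stop))
                    rec.extend([fend.chrom, pos, "+"])
                else:
                    pos = int(rng.integers(frag.start, frag.mid))
                    rec.extend([fend.chrom, pos, "-"])
            pairs.append(ReadPair(*rec))
    return pairs
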