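"""Distance-dependence signal estimation.

The contact frequency between two loci on the same chromosome is dominated
by their genomic separation (approximately a power law), and every
normalization in this package can condition on that relationship, denoted
D(i, j).  Two estimators are provided:

* 5C: ordinary least squares of ln(count) on ln(distance) over valid
  non-zero intra-region pairs — D(i, j) = gamma * ln(d_ij) + mu.
* HiC: a piecewise-linear function in (ln d, signal) space.  The distance
  range is split into equal-width log bins, except the smallest bin whose
  upper bound is user-set; each non-empty bin contributes one anchor at its
  mean ln(distance).  Two variants are fitted simultaneously: *counts*
  (anchor value = ln of the mean read count over all valid pairs in the
  bin, zeros included) and *binary* (fraction of valid pairs observed).
  Evaluation interpolates linearly between anchors and extends the terminal
  segments beyond them.

All distances are measured between fragment or fend midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ccnorm.interactions import FilterState, InteractionSet
from ccnorm.partition import Partition

__all__ = [
    "FiveCDistanceFit", "HiCDistanceFunction", "fit_5c_distance",
    "fit_hic_distance", "valid_cis_pairs",
]

PROB_EPS = 1e-6


class DistanceEstimationError(ValueError):
    pass


@dataclass
class FiveCDistanceFit:
    """Log-log linear fit: D(d) = gamma * ln(d) + mu."""

    gamma: float
    mu: float
    n_pairs: int

    def evaluate(self, d) -> np.ndarray | float:
        d = np.asarray(d, dtype=float)
        if np.any(d <= 0):
            raise ValueError("distances must be positive")
        return self.gamma * np.log(d) + self.mu


@dataclass
class HiCDistanceFunction:
    """Piecewise-linear distance signal with counts and binary variants.

    ``anchors_counts``: (mean ln d, ln mean count) rows;
    ``anchors_binary``: (mean ln d, fraction observed) rows.
    """

    anchors_counts: np.ndarray
    anchors_binary: np.ndarray
    bin_edges: np.ndarray  # log-distance partition, len n_bins + 1
    n_bins: int

    def evaluate(self, d, variant: str = "counts"):
        """Evaluate the piecewise-linear signal at distance(s) ``d`` (bp).

        The counts variant returns a log-scale value (use inside exp());
        the binary variant returns an observation probability clipped to
        (eps, 1 - eps).
        """
        anchors = (self.anchors_counts if variant == "counts"
                   else self.anchors_binary)
        d = np.asarray(d, dtype=float)
        if np.any(d <= 0):
            raise ValueError("distances must be positive")
        out = _piecewise_eval(anchors, np.log(d))
        if variant == "binary":
            out = np.clip(out, PROB_EPS, 1.0 - PROB_EPS)
        return out


def _piecewise_eval(anchors: np.ndarray, logd: np.ndarray) -> np.ndarray:
    x, y = anchors[:, 0], anchors[:, 1]
    if len(x) == 1:
        return np.full_like(logd, y[0], dtype=float)
    # linear interpolation with terminal-segment extrapolation
    k = np.clip(np.searchsorted(x, logd) - 1, 0, len(x) - 2)
    slope = (y[k + 1] - y[k]) / (x[k + 1] - x[k])
    return y[k] + slope * (logd - x[k])


def valid_cis_pairs(ints: InteractionSet, partition: Partition,
                    filt: FilterState, intra_region_only: bool = False):
    """All valid same-chromosome element pairs within the set-A limits.

    Returns (i, j, distance, count) arrays over *all* valid pairs, observed
    or not — pair enumeration is dense so that unobserved (zero-count) pairs
    can enter mean-count and binary statistics.
    """
    mids = partition.element_mids()
    chroms = partition.element_chroms()
    groups = partition.element_regions() if intra_region_only else None
    # same-fragment fend pairs are structurally unobservable (discarded by
    # phase-1 filtering) and never belong to set A
    frag_of = (np.array([f.fragment_index for f in partition.fends])
               if partition.assay == "hic" else None)
    valid_idx = np.flatnonzero(filt.valid)
    pairs_i, pairs_j = [], []
    # group valid elements by chromosome to enumerate cis pairs
    by_chrom: dict[str, list[int]] = {}
    for e in valid_idx:
        by_chrom.setdefault(chroms[e], []).append(e)
    for elems in by_chrom.values():
        arr = np.array(elems, dtype=np.int64)
        iu, ju = np.triu_indices(len(arr), k=1)
        i, j = arr[iu], arr[ju]
        if groups is not None:
            same = groups[i] == groups[j]
            i, j = i[same], j[same]
        if frag_of is not None:
            distinct = frag_of[i] != frag_of[j]
            i, j = i[distinct], j[distinct]
        pairs_i.append(i)
        pairs_j.append(j)
    if not pairs_i:
        z = np.zeros(0, dtype=np.int64)
        return z, z.copy(), z.copy(), np.zeros(0)
    i = np.concatenate(pairs_i)
    j = np.concatenate(pairs_j)
    d = np.abs(mids[i] - mids[j])
    ok = d >= max(filt.min_distance, 1)
    if filt.max_distance is not None:
        ok &= d <= filt.max_distance
    i, j, d = i[ok], j[ok], d[ok]
    counts = np.array([ints.get(a, b) for a, b in zip(i, j)], dtype=np.float64)
    return i, j, d, counts


def fit_5c_distance(ints: InteractionSet, partition: Partition,
                    filt: FilterState) -> FiveCDistanceFit:
    """OLS of ln(count) on ln(distance) over valid non-zero cis pairs.

    Only intra-region pairs are used; 5C probes cover discontiguous regions
    and inter-region separations are not informative for the decay.
    """
    _, _, d, counts = valid_cis_pairs(ints, partition, filt,
                                      intra_region_only=True)
    nz = counts > 0
    d, counts = d[nz], counts[nz]
    if len(d) < 2:
        raise DistanceEstimationError(
            f"need >= 2 valid non-zero cis pairs, got {len(d)}")
    gamma, mu = np.polyfit(np.log(d.astype(float)),
                           np.log(counts.astype(float)), 1)
    return FiveCDistanceFit(float(gamma), float(mu), int(len(d)))


def fit_hic_distance(ints: InteractionSet, partition: Partition,
                     filt: FilterState, n_bins: int = 90,
                     smallest_bin_upper: int = 40_000,
                     max_distance: int | None = None) -> HiCDistanceFunction:
    """Fit the piecewise-linear HiC distance function (counts + binary).

    Bin 1 covers (0, smallest_bin_upper]; the rest of the range up to
    ``max_distance`` (default: the largest valid pair separation) is split
    into ``n_bins - 1`` equal log-width bins.  Bins without pairs, or whose
    mean count is zero, are dropped and their neighbors connected directly.
    """
    if n_bins < 2:
        raise DistanceEstimationError("n_bins must be >= 2")
    _, _, d, counts = valid_cis_pairs(ints, partition, filt)
    if len(d) == 0:
        raise DistanceEstimationError("no valid cis pairs")
    if max_distance is None:
        max_distance = int(d.max())
    if smallest_bin_upper >= max_distance:
        raise DistanceEstimationError(
            "smallest_bin_upper must be below max_distance")
    edges = np.empty(n_bins + 1)
    edges[0] = np.log(max(float(d.min()), 1.0)) - 1e-9
    edges[1:] = np.linspace(np.log(smallest_bin_upper),
                            np.log(max_distance) + 1e-9, n_bins)
    logd = np.log(d.astype(float))
    keep = (logd >= edges[0]) & (logd <= edges[-1])
    logd, counts = logd[keep], counts[keep]
    bin_idx = np.clip(np.searchsorted(edges, logd, side="left") - 1,
                      0, n_bins - 1)
    anchors_counts, anchors_binary = [], []
    for b in range(n_bins):
        sel = bin_idx == b
        if not sel.any():
            continue
        mean_logd = float(logd[sel].mean())
        mean_count = float(counts[sel].mean())
        frac_obs = float((counts[sel] > 0).mean())
        if mean_count > 0:
            anchors_counts.append((mean_logd, np.log(mean_count)))
        anchors_binary.append((mean_logd, frac_obs))
    if len(anchors_counts) < 2 or len(anchors_binary) < 2:
        raise DistanceEstimationError(
            "fewer than 2 non-empty distance bins")
    return HiCDistanceFunction(
        anchors_counts=np.array(anchors_counts),
        anchors_binary=np.array(anchors_binary),
        bin_edges=edges, n_bins=n_bins)


def export_anchors(df: HiCDistanceFunction, path, variant: str = "counts"):
    """Write anchors as two columns: log10 distance, value."""
    anchors = (df.anchors_counts if variant == "counts"
               else df.anchors_binary)
    with open(path, "w") as handle:
        handle.write("# log10_distance\tvalue\n")
        for logd, value in anchors:
            handle.write(f"{logd / np.log(10):.6f}\t{value:.6f}\n")
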