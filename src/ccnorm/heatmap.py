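"""Observed/expected heatmaps, dynamic binning, and map correlation.

A pair contributes to bin (b1, b2) when its two element midpoints fall in
those bins (half-open bin intervals).  Observed grids sum read counts;
expected grids sum model expectations E_ij over *all* valid element pairs
in each bin pair, with the distance term included on request.  For 5C the
log-scale E_ij is exponentiated before summation so both assays produce
count-scale expected grids.

Dynamic binning compensates for sparse coverage: bins below a minimum
observed count absorb observed and expected mass from progressively larger
square rings of neighbors (complete rings only, nearest first) until the
threshold is met or a radius limit is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ccnorm.interactions import FilterState, InteractionSet, neutral_filter
from ccnorm.normalize import ExpectedModel

__all__ = [
    "Heatmap", "DynamicBinResult", "bin_heatmap", "dynamic_bin",
    "normalized_signal", "correlate", "write_heatmap_dense",
    "read_heatmap_dense",
]


@dataclass
class Heatmap:
    """Aligned observed and expected grids over genomic bins (cis map)."""

    chrom: str
    bin_starts: np.ndarray  # bp start per axis bin
    bin_stops: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    valid: np.ndarray
    resolution: int  # 0 = element-resolution bins

    @property
    def n_bins(self) -> int:
        return len(self.bin_starts)

    def bin_mids(self) -> np.ndarray:
        return (self.bin_starts + self.bin_stops) // 2


@dataclass
class DynamicBinResult:
    observed: np.ndarray
    expected: np.ndarray
    radius: np.ndarray
    valid: np.ndarray
    threshold: int


def bin_heatmap(ints: InteractionSet, model: ExpectedModel, resolution: int,
                chrom: str | None = None, region: int | None = None,
                include_distance: bool = True,
                filt: FilterState | None = None) -> Heatmap:
    """Bin observed counts and model expectations into a symmetric cis map.

    Selection is by chromosome (HiC) or 5C region; ``resolution`` in bp, or
    0 for one bin per element (fragment/fend resolution).  Expected values
    include the distance term only when ``include_distance`` is set.
    """
    partition = ints.partition
    if filt is None:
        filt = neutral_filter(partition)
    mids = partition.element_mids()
    chroms = partition.element_chroms()
    if region is not None:
        groups = partition.element_regions()
        sel = np.flatnonzero((groups == region) & filt.valid)
        if len(sel) == 0:
            raise ValueError(f"no valid elements in region {region}")
        chrom = str(chroms[sel[0]])
        span_lo, span_hi = partition.regions[region][1], partition.regions[region][2]
    elif chrom is not None:
        sel = np.flatnonzero((chroms == chrom) & filt.valid)
        if len(sel) == 0:
            raise ValueError(f"no valid elements on {chrom}")
        span_lo = 0
        span_hi = int(mids[sel].max()) + 1
    else:
        raise ValueError("select a chromosome or a region")
    if resolution < 0:
        raise ValueError("resolution must be >= 0")
    if resolution == 0:
        order = sel[np.argsort(mids[sel], kind="stable")]
        starts = mids[order].astype(np.int64)
        stops = starts + 1
        bin_of = {int(e): k for k, e in enumerate(order)}
        n_bins = len(order)
        elem_bin = np.array([bin_of[int(e)] for e in sel])
    else:
        n_bins = int(np.ceil((span_hi - span_lo) / resolution))
        starts = span_lo + resolution * np.arange(n_bins, dtype=np.int64)
        stops = starts + resolution
        elem_bin = ((mids[sel] - span_lo) // resolution).astype(np.int64)
    observed = np.zeros((n_bins, n_bins))
    expected = np.zeros((n_bins, n_bins))
    # observed: iterate stored sparse pairs inside the selection
    pos = -np.ones(partition.n_elements, dtype=np.int64)
    pos[sel] = elem_bin
    ii, jj, cc = ints.arrays()
    for i, j, c in zip(ii, jj, cc):
        b1, b2 = pos[i], pos[j]
        if b1 < 0 or b2 < 0:
            continue
        if not filt.pair_in_set_a(i, j, mids, chroms):
            continue
        lo, hi = min(b1, b2), max(b1, b2)
        observed[lo, hi] += c
        if lo != hi:
            observed[hi, lo] += c
    # expected: dense over valid element pairs in the selection
    iu, ju = np.triu_indices(len(sel), k=1)
    ei, ej = sel[iu], sel[ju]
    if partition.assay == "hic":
        # same-fragment fend pairs are structurally unobservable
        frag_of = np.array([f.fragment_index for f in partition.fends])
        distinct = frag_of[ei] != frag_of[ej]
        ei, ej = ei[distinct], ej[distinct]
    in_a = np.array([filt.pair_in_set_a(a, b, mids, chroms)
                     for a, b in zip(ei, ej)])
    ei, ej = ei[in_a], ej[in_a]
    d = np.abs(mids[ei] - mids[ej]).astype(float)
    f = model.corrections.f
    theta = model.corrections.theta
    D = model.distance_term(d) if include_distance else np.zeros_like(d)
    if partition.assay == "hic":
        E = np.exp(D + theta) * f[ei] * f[ej]
        if model.binning is not None:
            E = E * model.binning.pair_correction(ei, ej)
    else:
        E = np.exp(D + theta + f[ei] + f[ej])
    b1, b2 = pos[ei], pos[ej]
    lo, hi = np.minimum(b1, b2), np.maximum(b1, b2)
    np.add.at(expected, (lo, hi), E)
    off = lo != hi
    np.add.at(expected, (hi[off], lo[off]), E[off])
    bin_has_valid = np.zeros(n_bins, dtype=bool)
    bin_has_valid[elem_bin] = True
    valid = (expected > 0) & bin_has_valid[:, None] & bin_has_valid[None, :]
    return Heatmap(chrom, starts, stops, observed, expected, valid,
                   resolution)


def dynamic_bin(h: Heatmap, threshold: int,
                max_radius: int = 10) -> DynamicBinResult:
    """Expand sparse bins over complete neighbor rings until covered.

    Each bin below ``threshold`` observed counts accumulates observed and
    expected mass from rings of increasing Chebyshev radius (whole rings
    only, so expansion is deterministic and isotropic); bins still below
    threshold at ``max_radius`` are marked invalid.  Bins already at the
    threshold keep radius 0 and their original values.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    n = h.n_bins
    obs = h.observed.copy()
    exp = h.expected.copy()
    radius = np.zeros((n, n), dtype=np.int64)
    valid = h.valid.copy()
    base_obs = np.where(h.valid, h.observed, 0.0)
    base_exp = np.where(h.valid, h.expected, 0.0)
    for a in range(n):
        for b in range(n):
            if not h.valid[a, b]:
                continue
            if obs[a, b] >= threshold:
                continue
            tot_o, tot_e = base_obs[a, b], base_exp[a, b]
            r = 0
            while tot_o < threshold and r < max_radius:
                r += 1
                lo_a, hi_a = a - r, a + r
                lo_b, hi_b = b - r, b + r
                for x in range(lo_a, hi_a + 1):
                    if not 0 <= x < n:
                        continue
                    for y in range(lo_b, hi_b + 1):
                        if not 0 <= y < n:
                            continue
                        if max(abs(x - a), abs(y - b)) != r:
                            continue
                        tot_o += base_obs[x, y]
                        tot_e += base_exp[x, y]
            obs[a, b] = tot_o
            exp[a, b] = tot_e
            radius[a, b] = r
            if tot_o < threshold:
                valid[a, b] = False
    valid &= exp > 0
    return DynamicBinResult(obs, exp, radius, valid, threshold)


def normalized_signal(h: Heatmap | DynamicBinResult) -> np.ndarray:
    """Observed/expected ratio; invalid bins are NaN, never zero-filled."""
    out = np.full(h.observed.shape, np.nan)
    mask = h.valid & (h.expected > 0)
    out[mask] = h.observed[mask] / h.expected[mask]
    return out


def default_distance_ranges(h: Heatmap, n_ranges: int = 10):
    """Logarithmically spaced cis distance strata: resolution to map span."""
    span = float(h.bin_stops[-1] - h.bin_starts[0])
    lo = float(max(h.resolution, 1))
    edges = np.exp(np.linspace(np.log(lo), np.log(span + 1), n_ranges + 1))
    return [(edges[k], edges[k + 1]) for k in range(n_ranges)]


def correlate(h1: Heatmap, h2: Heatmap,
              distance_ranges=None,
              log_transform: bool = True) -> dict:
    """Pearson correlation of enrichment between two aligned maps.

    Computed per cis distance stratum and overall, over bin pairs valid and
    non-zero in both maps; with ``log_transform`` the correlated quantity
    is ln(observed/expected).  Strata with fewer than 3 shared bins are
    reported as None.
    """
    if h1.observed.shape != h2.observed.shape:
        raise ValueError("heatmaps are not aligned")
    if not (np.array_equal(h1.bin_starts, h2.bin_starts)
            and np.array_equal(h1.bin_stops, h2.bin_stops)):
        raise ValueError("bin coordinates differ between maps")
    if distance_ranges is None:
        distance_ranges = default_distance_ranges(h1)
    mids = h1.bin_mids().astype(float)
    n = h1.n_bins
    iu = np.triu_indices(n)
    dist = np.abs(mids[iu[0]] - mids[iu[1]])
    shared = (h1.valid[iu] & h2.valid[iu]
              & (h1.observed[iu] > 0) & (h2.observed[iu] > 0)
              & (h1.expected[iu] > 0) & (h2.expected[iu] > 0))
    v1 = h1.observed[iu] / h1.expected[iu]
    v2 = h2.observed[iu] / h2.expected[iu]
    if log_transform:
        with np.errstate(divide="ignore", invalid="ignore"):
            v1, v2 = np.log(v1), np.log(v2)

    def pearson(mask):
        if mask.sum() < 3:
            return None
        a, b = v1[mask], v2[mask]
        if a.std() == 0 or b.std() == 0:
            return None
        return float(np.corrcoef(a, b)[0, 1])

    result = {"overall": pearson(shared), "ranges": []}
    for lo, hi in distance_ranges:
        mask = shared & (dist >= lo) & (dist < hi)
        result["ranges"].append({"lo": float(lo), "hi": float(hi),
                                 "r": pearson(mask),
                                 "n": int(mask.sum())})
    return result


def write_heatmap_dense(h: Heatmap, path, grid: str = "observed") -> None:
    """Dense tab-delimited export with a coordinate header row/column."""
    data = getattr(h, grid)
    with open(path, "w") as handle:
        handle.write("# chrom=%s resolution=%d grid=%s\n"
                     % (h.chrom, h.resolution, grid))
        handle.write("bin\t" + "\t".join(
            f"{s}-{e}" for s, e in zip(h.bin_starts, h.bin_stops)) + "\n")
        for k in range(h.n_bins):
            row = "\t".join(f"{v:.6g}" for v in data[k])
            handle.write(f"{h.bin_starts[k]}-{h.bin_stops[k]}\t{row}\n")


def read_heatmap_dense(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a dense export back: (starts, stops, grid)."""
    with open(path) as handle:
        handle.readline()
        header = handle.readline().strip().split("\t")[1:]
        starts = np.array([int(c.split("-")[0]) for c in header])
        stops = np.array([int(c.split("-")[1]) for c in header])
        grid = np.loadtxt(handle, usecols=range(1, len(header) + 1))
    return starts, stops, np.atleast_2d(grid)
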