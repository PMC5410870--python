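"""Read-pair ingestion, filtering, and the valid interaction set.

Filtering happens in two phases.  Phase one acts on individual read pairs:
5C pairs are kept only when the two probed fragments carry
opposite-orientation primers (only those pairs can arise from a ligation
junction); HiC pairs are kept when the summed insert size is within a
user-set limit and the two fragments are non-adjacent, or adjacent with
both mates in the same orientation (adjacent opposite-orientation pairs are
dominated by re-ligation/self-circle products).  Phase two removes
fragments/fends with too few interaction partners, iterating to a fixed
point so that every survivor has enough surviving partners.

The valid interaction set A used by all normalizations consists of pairs
whose two elements both survive filtering and whose cis separation lies in
user-set distance limits (trans pairs bypass the distance limits); for 5C,
only non-zero counts belong to A because counts are log-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ccnorm.partition import Partition

__all__ = [
    "ReadPair", "InteractionSet", "FilterState", "assign_read",
    "filter_5c_pair", "filter_hic_pair", "accumulate",
    "iterative_coverage_filter", "read_pairs_from_table",
    "read_counts_table", "write_counts_table",
]

UNASSIGNED = -1


@dataclass(frozen=True)
class ReadPair:
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str

    def __post_init__(self):
        if self.pos1 < 0 or self.pos2 < 0:
            raise ValueError("read positions must be non-negative")
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise ValueError("strands must be '+' or '-'")


class InteractionSet:
    """Sparse symmetric pair -> count map over fends (HiC) or fragments (5C)."""

    def __init__(self, partition: Partition):
        self.partition = partition
        self.assay = partition.assay
        self.pairs: dict[tuple[int, int], int] = {}

    def add(self, i: int, j: int, count: int = 1) -> None:
        if i == j:
            raise ValueError("self-pairs are not storable")
        key = (i, j) if i < j else (j, i)
        self.pairs[key] = self.pairs.get(key, 0) + count

    def get(self, i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        return self.pairs.get(key, 0)

    def __len__(self) -> int:
        return len(self.pairs)

    def total_counts(self) -> int:
        return sum(self.pairs.values())

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, count) arrays with i < j, sorted for determinism.

        Counts are returned as float64: integer read counts in the usual
        case, but un-rounded synthetic 5C intensities are representable too.
        """
        if not self.pairs:
            z = np.zeros(0, dtype=np.int64)
            return z, z.copy(), np.zeros(0)
        keys = sorted(self.pairs)
        i = np.array([k[0] for k in keys], dtype=np.int64)
        j = np.array([k[1] for k in keys], dtype=np.int64)
        c = np.array([self.pairs[k] for k in keys], dtype=np.float64)
        return i, j, c


@dataclass
class FilterState:
    """Per-element validity mask plus the set-A distance limits."""

    valid: np.ndarray
    min_interactions: int
    min_distance: int = 0
    max_distance: int | None = None

    def pair_in_set_a(self, i: int, j: int, mids: np.ndarray,
                      chroms: np.ndarray) -> bool:
        if not (self.valid[i] and self.valid[j]):
            return False
        if chroms[i] != chroms[j]:
            return True  # trans bypasses distance limits
        d = abs(int(mids[i]) - int(mids[j]))
        if d < self.min_distance:
            return False
        if self.max_distance is not None and d > self.max_distance:
            return False
        return True


def neutral_filter(partition: Partition, min_distance: int = 0,
                   max_distance: int | None = None) -> FilterState:
    """All-valid filter state (used before phase-2 filtering)."""
    return FilterState(np.ones(partition.n_elements, dtype=bool), 0,
                       min_distance, max_distance)


def assign_read(chrom: str, pos: int, strand: str,
                partition: Partition) -> int:
    """Map a single mate to its fend (HiC) or probed fragment (5C) index.

    HiC convention: the mate is assigned to the fend of its fragment lying in
    the read's direction of travel — a "+" read extends rightward toward the
    fragment's downstream cut site, so it belongs to the right fend; a "-"
    read belongs to the left fend.  Returns ``UNASSIGNED`` when the position
    falls outside every fragment.
    """
    frag_index = partition.find_fragment(chrom, pos)
    if frag_index is None:
        return UNASSIGNED
    if partition.assay == "fivec":
        return frag_index
    left, right = partition.fends_of(frag_index)
    return right.index if strand == "+" else left.index


def filter_5c_pair(rp: ReadPair, partition: Partition) -> bool:
    """Keep a 5C pair iff its two fragments have opposite primer orientations."""
    i = partition.find_fragment(rp.chrom1, rp.pos1)
    j = partition.find_fragment(rp.chrom2, rp.pos2)
    if i is None or j is None or i == j:
        return False
    oi = partition.fragments[i].primer_orientation
    oj = partition.fragments[j].primer_orientation
    return oi != oj


def _insert_size(pos: int, strand: str, frag) -> int:
    # distance from the 5' mapped position to the cut site the read points at
    return frag.stop - pos if strand == "+" else pos - frag.start


def filter_hic_pair(rp: ReadPair, partition: Partition,
                    max_insert: int) -> bool:
    """Phase-1 HiC read-pair filter (insert size + adjacency/orientation).

    Keeps a pair iff the summed insert size (5' position to the cut site each
    mate points toward) is <= ``max_insert`` and the fragments are
    non-adjacent, or adjacent with both mates in the same orientation.
    Same-fragment pairs are always discarded.
    """
    i = partition.find_fragment(rp.chrom1, rp.pos1)
    j = partition.find_fragment(rp.chrom2, rp.pos2)
    if i is None or j is None:
        return False
    if i == j:
        return False
    insert = (_insert_size(rp.pos1, rp.strand1, partition.fragments[i])
              + _insert_size(rp.pos2, rp.strand2, partition.fragments[j]))
    if insert > max_insert:
        return False
    fi, fj = partition.fragments[i], partition.fragments[j]
    adjacent = fi.chrom == fj.chrom and abs(i - j) == 1
    if adjacent and rp.strand1 != rp.strand2:
        return False
    return True


def accumulate(reads, partition: Partition, max_insert: int = 1000,
               remove_duplicates: bool = False):
    """Stream read pairs into an :class:`InteractionSet` with a discard tally.

    Returns ``(interactions, report)`` where ``report`` maps discard reasons
    to counts and reconciles: kept + sum(discards) == total input.
    """
    ints = InteractionSet(partition)
    report = {"input": 0, "kept": 0, "unassigned": 0, "same_fragment": 0,
              "orientation": 0, "insert_size": 0, "duplicate": 0}
    seen: set[tuple] = set()
    for rp in reads:
        report["input"] += 1
        if remove_duplicates:
            key = (rp.chrom1, rp.pos1, rp.strand1,
                   rp.chrom2, rp.pos2, rp.strand2)
            if key in seen:
                report["duplicate"] += 1
                continue
            seen.add(key)
        if partition.assay == "fivec":
            i = partition.find_fragment(rp.chrom1, rp.pos1)
            j = partition.find_fragment(rp.chrom2, rp.pos2)
            if i is None or j is None:
                report["unassigned"] += 1
                continue
            if i == j:
                report["same_fragment"] += 1
                continue
            if not filter_5c_pair(rp, partition):
                report["orientation"] += 1
                continue
            ints.add(i, j)
        else:
            fi = partition.find_fragment(rp.chrom1, rp.pos1)
            fj = partition.find_fragment(rp.chrom2, rp.pos2)
            if fi is None or fj is None:
                report["unassigned"] += 1
                continue
            if fi == fj:
                report["same_fragment"] += 1
                continue
            insert = (
                _insert_size(rp.pos1, rp.strand1, partition.fragments[fi])
                + _insert_size(rp.pos2, rp.strand2, partition.fragments[fj]))
            if insert > max_insert:
                report["insert_size"] += 1
                continue
            adjacent = (partition.fragments[fi].chrom
                        == partition.fragments[fj].chrom
                        and abs(fi - fj) == 1)
            if adjacent and rp.strand1 != rp.strand2:
                report["orientation"] += 1
                continue
            i = assign_read(rp.chrom1, rp.pos1, rp.strand1, partition)
            j = assign_read(rp.chrom2, rp.pos2, rp.strand2, partition)
            ints.add(i, j)
        report["kept"] += 1
    return ints, report


def iterative_coverage_filter(ints: InteractionSet, min_interactions: int,
                              min_distance: int = 0,
                              max_distance: int | None = None,
                              count_mode: str = "partners") -> FilterState:
    """Phase-2 filter: iteratively remove low-coverage elements.

    Elements with fewer than ``min_interactions`` surviving interaction
    partners inside the distance limits are removed together with their
    interactions, repeatedly, until every survivor meets the threshold (a
    fixed point; the result is the unique maximal subset closed under the
    degree condition, independent of removal order).

    ``count_mode``: "partners" counts distinct surviving partners (default);
    "reads" thresholds on the summed read count to surviving partners.
    """
    if min_interactions < 1:
        raise ValueError("min_interactions must be >= 1")
    if count_mode not in ("partners", "reads"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    partition = ints.partition
    n = partition.n_elements
    mids = partition.element_mids()
    chroms = partition.element_chroms()
    ii, jj, cc = ints.arrays()
    # restrict to pairs usable for coverage: inside distance limits (cis)
    if len(ii):
        cis = chroms[ii] == chroms[jj]
        d = np.abs(mids[ii] - mids[jj])
        ok = ~cis | (d >= min_distance)
        if max_distance is not None:
            ok &= ~cis | (d <= max_distance)
        ii, jj, cc = ii[ok], jj[ok], cc[ok]
    valid = np.zeros(n, dtype=bool)
    touched = np.unique(np.concatenate([ii, jj])) if len(ii) else []
    valid[touched] = True
    while True:
        keep = valid[ii] & valid[jj]
        weight = np.ones(len(ii)) if count_mode == "partners" else cc
        degree = np.zeros(n)
        np.add.at(degree, ii[keep], weight[keep])
        np.add.at(degree, jj[keep], weight[keep])
        new_valid = valid & (degree >= min_interactions)
        if np.array_equal(new_valid, valid):
            break
        valid = new_valid
    state = FilterState(valid, min_interactions, min_distance, max_distance)
    return state


# -- tabular I/O ----------------------------------------------------------

def read_pairs_from_table(path):
    """Yield :class:`ReadPair` from a 6-column whitespace-delimited table."""
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            c1, p1, s1, c2, p2, s2 = line.split()[:6]
            yield ReadPair(c1, int(p1), s1, c2, int(p2), s2)


def read_pairs_from_bam(path, chrom_map=None):
    """Yield ReadPair records from a coordinate-agnostic paired BAM/SAM.

    Emits one record per proper primary pair (mate seen once, via the
    leftmost-in-pair alignment carrying both positions).  ``chrom_map``
    optionally renames references.
    """
    import pysam

    with pysam.AlignmentFile(str(path)) as bam:
        for aln in bam:
            if (aln.is_unmapped or aln.mate_is_unmapped
                    or aln.is_secondary or aln.is_supplementary
                    or not aln.is_read1):
                continue
            c1 = aln.reference_name
            c2 = aln.next_reference_name
            if chrom_map is not None:
                c1 = chrom_map.get(c1, c1)
                c2 = chrom_map.get(c2, c2)
            p1 = aln.reference_end - 1 if aln.is_reverse else aln.reference_start
            s1 = "-" if aln.is_reverse else "+"
            # mate 5' position: start if forward; for reverse mates the 5'
            # end is not in this record, approximate with start + read length
            if aln.mate_is_reverse:
                p2 = aln.next_reference_start + (aln.query_length or 0) - 1
                s2 = "-"
            else:
                p2 = aln.next_reference_start
                s2 = "+"
            yield ReadPair(c1, p1, s1, c2, p2, s2)


def read_counts_table(path, partition: Partition) -> InteractionSet:
    """Load a 3-column (index1 index2 count) table against a partition."""
    ints = InteractionSet(partition)
    n = partition.n_elements
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i, j, c = line.split()[:3]
            i, j = int(i), int(j)
            c = float(c)
            c = int(c) if c.is_integer() else c
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"element index out of range: {i}, {j}")
            ints.add(i, j, c)
    return ints


def write_counts_table(ints: InteractionSet, path) -> None:
    ii, jj, cc = ints.arrays()
    with open(path, "w") as handle:
        handle.write("# index1\tindex2\tcount\n")
        for i, j, c in zip(ii, jj, cc):
            value = int(c) if float(c).is_integer() else repr(float(c))
            handle.write(f"{i}\t{j}\t{value}\n")
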