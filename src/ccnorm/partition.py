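"""Genomic partitioning: restriction fragments, fends, and 5C regions.

All coordinates are 0-based, half-open (BED convention).  A *fend* is one
half of a restriction fragment ("fragment end") and is the atomic unit of
HiC bias correction; 5C works at the level of whole probed fragments, each
carrying the orientation of the primer that probes it.

Fend midpoints are defined as the midpoint of the fragment half the fend
represents: left fend mid = floor((start + frag_mid) / 2), right fend
mid = floor((frag_mid + stop) / 2).  All inter-element distances used
anywhere in the package are measured between these midpoints.
"""

from __future__ import annotations

import json
import re
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Fragment", "Fend", "Partition", "digest_genome", "read_fragment_bed",
    "write_partition", "read_partition", "iupac_to_regex",
]

_CONTAINER_FORMAT = "ccnorm-partition"
_CONTAINER_VERSION = 1

# IUPAC nucleotide ambiguity codes -> character classes
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class PartitionError(ValueError):
    """Raised for malformed partition inputs (BED, FASTA, sites)."""


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment or 5C probed fragment.

    ``region`` and ``primer_orientation`` are populated for 5C only;
    ``primer_orientation`` is "forward" or "reverse".
    """

    index: int
    chrom: str
    start: int
    stop: int
    region: int | None = None
    primer_orientation: str | None = None

    @property
    def mid(self) -> int:
        return (self.start + self.stop) // 2

    def __post_init__(self):
        if not self.start < self.stop:
            raise PartitionError(
                f"fragment {self.chrom}:{self.start}-{self.stop}: start >= stop")


@dataclass(frozen=True)
class Fend:
    """One half of a restriction fragment (HiC unit of correction)."""

    index: int
    fragment_index: int
    side: str  # "left" | "right"
    chrom: str
    mid: int


@dataclass
class Partition:
    """Ordered fragments (both assays), fends (HiC), and regions (5C)."""

    fragments: list[Fragment]
    assay: str  # "hic" | "fivec"
    fends: list[Fend] = field(default_factory=list)
    regions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.assay not in ("hic", "fivec"):
            raise PartitionError(f"unknown assay {self.assay!r}")
        if self.assay == "hic" and not self.fends and self.fragments:
            self.fends = _build_fends(self.fragments)
        self._index()

    def _index(self):
        self._chrom_frags: dict[str, list[Fragment]] = {}
        for frag in self.fragments:
            self._chrom_frags.setdefault(frag.chrom, []).append(frag)
        self._chrom_starts = {
            c: [f.start for f in fr] for c, fr in self._chrom_frags.items()
        }
        for chrom, frags in self._chrom_frags.items():
            prev = None
            for f in frags:
                if prev is not None and f.start < prev.stop:
                    raise PartitionError(
                        f"fragments overlap or are unsorted on {chrom}: "
                        f"{prev.start}-{prev.stop} then {f.start}-{f.stop}")
                prev = f

    # -- element accessors ------------------------------------------------

    @property
    def n_elements(self) -> int:
        """Number of correction units: fends for HiC, fragments for 5C."""
        return len(self.fends) if self.assay == "hic" else len(self.fragments)

    def element_chroms(self) -> np.ndarray:
        if self.assay == "hic":
            return np.array([f.chrom for f in self.fends])
        return np.array([f.chrom for f in self.fragments])

    def element_mids(self) -> np.ndarray:
        """Midpoint of each correction unit, in element order."""
        if self.assay == "hic":
            return np.array([f.mid for f in self.fends], dtype=np.int64)
        return np.array([f.mid for f in self.fragments], dtype=np.int64)

    def element_regions(self) -> np.ndarray:
        """5C region ordinal per fragment (-1 if unset); HiC: chrom ordinal."""
        if self.assay == "fivec":
            return np.array(
                [-1 if f.region is None else f.region for f in self.fragments],
                dtype=np.int64)
        chroms = sorted({f.chrom for f in self.fends})
        lookup = {c: k for k, c in enumerate(chroms)}
        return np.array([lookup[f.chrom] for f in self.fends], dtype=np.int64)

    def orientations(self) -> np.ndarray | None:
        if self.assay != "fivec":
            return None
        return np.array(
            [f.primer_orientation == "forward" for f in self.fragments],
            dtype=bool)

    def find_fragment(self, chrom: str, pos: int) -> int | None:
        """Index of the fragment containing ``pos`` (half-open), else None."""
        frags = self._chrom_frags.get(chrom)
        if frags is None:
            return None
        k = bisect_right(self._chrom_starts[chrom], pos) - 1
        if k < 0:
            return None
        frag = frags[k]
        if frag.start <= pos < frag.stop:
            return frag.index
        return None

    def fends_of(self, fragment_index: int) -> tuple[Fend, Fend]:
        left = self.fends[2 * fragment_index]
        right = self.fends[2 * fragment_index + 1]
        return left, right


def _build_fends(fragments: list[Fragment]) -> list[Fend]:
    fends = []
    for frag in fragments:
        mid = frag.mid
        fends.append(Fend(2 * frag.index, frag.index, "left", frag.chrom,
                          (frag.start + mid) // 2))
        fends.append(Fend(2 * frag.index + 1, frag.index, "right", frag.chrom,
                          (mid + frag.stop) // 2))
    return fends


def potential_fend_pairs(genome_size: int, site_length: int) -> float:
    """Expected number of distinct fend-pair combinations after digestion.

    A random genome of ``genome_size`` bp contains about
    genome_size / 4**site_length occurrences of a specific
    ``site_length``-bp recognition site, hence that many (+1) fragments and
    twice as many fends; the pair count is C(n_fends, 2).  This is the
    scale any fend-level analysis has to contend with: ~1e12 pairs for a
    3 Gbp genome cut with a six-base enzyme.
    """
    n_fragments = genome_size / 4 ** site_length + 1
    n_fends = 2.0 * n_fragments
    return n_fends * (n_fends - 1) / 2.0


def iupac_to_regex(site: str) -> str:
    """Expand an IUPAC recognition site into a regex character-class string."""
    out = []
    for ch in site.upper():
        try:
            out.append(_IUPAC[ch])
        except KeyError:
            raise PartitionError(f"unknown IUPAC character {ch!r} in site {site!r}")
    return "".join(out)


def digest_genome(sequences: dict[str, str], recognition_site: str,
                  cut_offset: int) -> Partition:
    """In-silico restriction digest of chromosome sequences.

    Each occurrence of ``recognition_site`` (IUPAC codes allowed; overlapping
    occurrences counted) cuts the chromosome at ``match_start + cut_offset``.
    Fragments tile each chromosome end to end; every fragment gets two fends.
    Recognition sites of type II enzymes are palindromic, so a forward-strand
    scan finds every cut.
    """
    if not recognition_site:
        raise PartitionError("empty recognition site")
    if not 0 <= cut_offset <= len(recognition_site):
        raise PartitionError(
            f"cut_offset {cut_offset} outside [0, {len(recognition_site)}]")
    pattern = re.compile("(?=" + iupac_to_regex(recognition_site) + ")")
    fragments: list[Fragment] = []
    index = 0
    for chrom in sequences:
        seq = sequences[chrom].upper()
        cuts = sorted({m.start() + cut_offset for m in pattern.finditer(seq)})
        bounds = [0] + [c for c in cuts if 0 < c < len(seq)] + [len(seq)]
        for start, stop in zip(bounds[:-1], bounds[1:]):
            fragments.append(Fragment(index, chrom, start, stop))
            index += 1
    return Partition(fragments, assay="hic")


def read_fragment_bed(path, assay: str, region_gap: int = 1_000_000) -> Partition:
    """Load a fragment partition from a BED file.

    For 5C the strand column (6th) encodes primer orientation ("+" forward,
    "-" reverse) and fragments are grouped into regions: a new region starts
    at each chromosome change or wherever the gap between consecutive
    fragments exceeds ``region_gap`` base pairs.
    """
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 3:
                raise PartitionError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, stop = cols[0], int(cols[1]), int(cols[2])
            strand = cols[5] if len(cols) >= 6 else None
            if assay == "fivec":
                if strand not in ("+", "-"):
                    raise PartitionError(
                        f"{path}:{lineno}: 5C input requires a +/- strand column")
            rows.append((chrom, start, stop, strand))
    if not rows:
        raise PartitionError(f"{path}: no fragment records")
    rows.sort(key=lambda r: (r[0], r[1]))
    fragments = []
    regions: list[tuple[str, int, int]] = []
    region = -1
    prev = None
    for index, (chrom, start, stop, strand) in enumerate(rows):
        if prev is not None and prev[0] == chrom and start < prev[2]:
            raise PartitionError(
                f"overlapping fragments on {chrom}: "
                f"{prev[1]}-{prev[2]} and {start}-{stop}")
        if assay == "fivec":
            if prev is None or prev[0] != chrom or start - prev[2] > region_gap:
                region += 1
                regions.append((chrom, start, stop))
            else:
                c, rs, _ = regions[region]
                regions[region] = (c, rs, stop)
            orientation = "forward" if strand == "+" else "reverse"
            fragments.append(Fragment(index, chrom, start, stop,
                                      region=region,
                                      primer_orientation=orientation))
        else:
            fragments.append(Fragment(index, chrom, start, stop))
        prev = (chrom, start, stop)
    return Partition(fragments, assay=assay,
                     regions=regions if assay == "fivec" else [])


def write_partition(partition: Partition, path) -> None:
    """Serialize a partition to the versioned JSON container.

    Coordinates are 0-based half-open; the container round-trips bit-exactly
    through :func:`read_partition`.
    """
    doc = {
        "format": _CONTAINER_FORMAT,
        "version": _CONTAINER_VERSION,
        "assay": partition.assay,
        "coordinates": "0-based half-open",
        "fragments": [
            [f.index, f.chrom, f.start, f.stop, f.region, f.primer_orientation]
            for f in partition.fragments
        ],
        "regions": [list(r) for r in partition.regions],
    }
    with open(path, "w") as handle:
        json.dump(doc, handle)


def read_partition(path) -> Partition:
    with open(path) as handle:
        doc = json.load(handle)
    if doc.get("format") != _CONTAINER_FORMAT:
        raise PartitionError(f"{path}: not a partition container")
    fragments = [
        Fragment(index, chrom, start, stop, region=region,
                 primer_orientation=orientation)
        for index, chrom, start, stop, region, orientation in doc["fragments"]
    ]
    regions = [tuple(r) for r in doc["regions"]]
    return Partition(fragments, assay=doc["assay"], regions=regions)
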