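"""Genomic interval data model, interval algebra, and flat-file I/O.

All coordinates are BED-convention: 0-based, half-open ``[start, end)``.
GFF3 (1-based, closed) is converted on read and write so that a single
convention holds everywhere inside the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Malformed BED/bedGraph/GFF3 line; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open, 0-based genomic region with optional strand/name/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float | None = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, rounded down (ties broken toward the smaller coordinate)."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int:
        """Bases separating two intervals on one chromosome; 0 if they touch or overlap."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def expanded(self, pad: int, chrom_len: int | None = None) -> "GenomicInterval":
        start = max(0, self.start - pad)
        end = self.end + pad
        if chrom_len is not None:
            end = min(end, chrom_len)
        return replace(self, start=start, end=end)

    def with_name(self, name: str) -> "GenomicInterval":
        return replace(self, name=name)


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus the gene/lncRNA/blacklist feature sets.

    ``tss`` maps gene name -> strand-aware 5' position (0-based): the gene
    start on the plus strand, ``end - 1`` on the minus strand.
    """

    chrom_sizes: dict[str, int]
    genes: list[GenomicInterval] = field(default_factory=list)
    lncrnas: list[GenomicInterval] = field(default_factory=list)
    blacklist: list[GenomicInterval] = field(default_factory=list)
    tes: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        for gene in self.genes:
            size = self.chrom_sizes.get(gene.chrom)
            if size is None or gene.end > size:
                raise ValueError(f"gene {gene.name} outside chromosome bounds")

    @property
    def tss(self) -> dict[str, tuple[str, int]]:
        out: dict[str, tuple[str, int]] = {}
        for gene in self.genes:
            pos = gene.start if gene.strand != "-" else gene.end - 1
            out[gene.name] = (gene.chrom, pos)
        return out

    def tss_positions(self, chrom: str) -> np.ndarray:
        """Sorted TSS coordinates on one chromosome."""
        pos = [p for c, p in self.tss.values() if c == chrom]
        return np.asarray(sorted(pos), dtype=np.int64)


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_within_gap(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Union intervals, additionally bridging separations of at most ``gap`` bases.

    Output is sorted and pairwise separated by more than ``gap`` bases;
    strand/name/score are dropped (a merged region has no single source).
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    merged: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= gap:
            last = merged[-1]
            merged[-1] = GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> tuple[float, float]:
    """``(|a∩b|/|a|, |a∩b|/|b|)`` — both in [0, 1], symmetric under swap."""
    inter = a.intersection_length(b)
    return inter / a.length, inter / b.length


class NoNeighborError(LookupError):
    """No point available on the query's chromosome."""


def distance_to_nearest(
    points: dict[str, np.ndarray] | Sequence[int],
    query: GenomicInterval,
    anchor: str = "center",
) -> int:
    """Distance from a query anchor to the nearest point.

    ``points`` is either a chrom -> sorted positions mapping or a flat
    sequence assumed to lie on the query chromosome.  ``anchor="center"``
    measures from ``floor((start+end)/2)``; ``anchor="edge"`` returns 0 for
    any point inside the interval and the gap to the closest edge otherwise.
    """
    if isinstance(points, dict):
        pos = np.asarray(points.get(query.chrom, ()), dtype=np.int64)
    else:
        pos = np.asarray(points, dtype=np.int64)
    if pos.size == 0:
        raise NoNeighborError(f"no points on {query.chrom}")
    pos = np.sort(pos)
    if anchor == "center":
        return int(np.min(np.abs(pos - query.center)))
    if anchor == "edge":
        left = np.clip(query.start - pos, 0, None)
        right = np.clip(pos - (query.end - 1), 0, None)
        return int(np.min(left + right))
    raise ValueError(f"unknown anchor {anchor!r}")


def overlaps_any(
    query: GenomicInterval, features: Sequence[GenomicInterval]
) -> bool:
    """True if the query shares at least one base with any feature."""
    return any(query.overlaps(f) for f in features)


# ---------------------------------------------------------------------------
# flat-file I/O
# ---------------------------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6; validates every record and preserves input order."""
    out: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(path, lineno, "fewer than 3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(path, lineno, f"bad coordinate: {exc}") from None
            name = fields[3] if len(fields) > 3 else ""
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand, name, score))
            except ValueError as exc:
                raise BedParseError(path, lineno, str(exc)) from None
    return out


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise BedParseError(path, lineno, "expected two columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(path, sizes: dict[str, int]) -> None:
    with open(path, "w") as handle:
        for chrom, size in sizes.items():
            handle.write(f"{chrom}\t{size}\n")


_GFF_TYPE_MAP = {
    "gene": "genes",
    "lnc_RNA": "lncrnas",
    "lncRNA": "lncrnas",
    "miRNA": "blacklist",
    "piRNA": "blacklist",
    "tRNA": "blacklist",
    "snoRNA": "blacklist",
    "snRNA": "blacklist",
    "rRNA": "blacklist",
    "repeat_region": "blacklist",
    "transposable_element": "tes",
}


def read_gff3(path, chrom_sizes: dict[str, int] | None = None) -> GenomeAnnotation:
    """Read the gene/lncRNA/blacklist/TE subset of a GFF3 file.

    Only top-level feature lines of the types in ``_GFF_TYPE_MAP`` are kept
    (exons/mRNAs are redundant for region classification).  1-based closed
    coordinates become 0-based half-open.  When ``chrom_sizes`` is not given,
    ``##sequence-region`` pragmas are required.
    """
    sizes = dict(chrom_sizes or {})
    buckets: dict[str, list[GenomicInterval]] = {
        "genes": [], "lncrnas": [], "blacklist": [], "tes": []
    }
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    sizes.setdefault(parts[1], int(parts[3]))
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise BedParseError(path, lineno, "expected 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            bucket = _GFF_TYPE_MAP.get(ftype)
            if bucket is None:
                continue
            name = ""
            for item in attrs.split(";"):
                key, _, value = item.partition("=")
                if key in ("ID", "Name") and value:
                    name = value
                    break
            try:
                iv = GenomicInterval(
                    chrom, int(start) - 1, int(end), strand if strand in STRANDS else ".", name
                )
            except ValueError as exc:
                raise BedParseError(path, lineno, str(exc)) from None
            buckets[bucket].append(iv)
    if not sizes:
        raise ValueError(f"{path}: no chromosome sizes (no ##sequence-region pragmas)")
    return GenomeAnnotation(chrom_sizes=sizes, **buckets)


def write_gff3(path, annotation: GenomeAnnotation) -> None:
    type_of = {"genes": "gene", "lncrnas": "lnc_RNA", "blacklist": "rRNA", "tes": "transposable_element"}
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for chrom, size in annotation.chrom_sizes.items():
            handle.write(f"##sequence-region {chrom} 1 {size}\n")
        for bucket, ftype in type_of.items():
            for iv in getattr(annotation, bucket):
                handle.write(
                    f"{iv.chrom}\ternascape\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={iv.name or '.'}\n"
                )


def read_bedgraph(path, chrom_sizes: dict[str, int], dtype=np.float64) -> dict[str, np.ndarray]:
    """Expand a 4-column bedGraph into dense per-base arrays, one per chromosome."""
    track = {chrom: np.zeros(size, dtype=dtype) for chrom, size in chrom_sizes.items()}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise BedParseError(path, lineno, "expected 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in track:
                raise BedParseError(path, lineno, f"unknown chromosome {chrom!r}")
            track[chrom][start:end] = value
    return track


def write_bedgraph(path, track: dict[str, np.ndarray]) -> None:
    """Write dense per-base arrays as run-length-encoded bedGraph (zeros skipped)."""
    with open(path, "w") as handle:
        for chrom in sorted(track):
            values = np.asarray(track[chrom])
            if values.size == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for start, end in zip(starts, ends):
                value = values[start]
                if value != 0:
                    handle.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def iter_chrom_arrays(track: dict[str, np.ndarray]) -> Iterator[tuple[str, np.ndarray]]:
    yield from sorted(track.items())
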