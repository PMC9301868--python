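"""W-box motif scanning and two-set enrichment.

The W-box is the WRKY transcription-factor binding core TTGAC(T/C).  The
scanner reports every exact occurrence of TTGACC/TTGACT on the forward
strand and, by default, of their reverse complements GGTCAA/AGTCAA as
minus-strand hits; overlapping occurrences are all reported and N never
matches.  Set-level enrichment is an exact two-sided Fisher test on motif
presence/absence between two region sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .config import defaults
from .intervals import GenomicInterval

_P = defaults("motif")

FORWARD_WORDS = tuple(_P["words"])                     # TTGACC, TTGACT
_RC = str.maketrans("ACGT", "TGCA")
REVERSE_WORDS = tuple(w.translate(_RC)[::-1] for w in FORWARD_WORDS)


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    matched_text: str   # always the motif word as read on the hit strand

    def __post_init__(self):
        if self.matched_text not in FORWARD_WORDS:
            raise ValueError(f"not a W-box: {self.matched_text}")


def _find_all(text: str, word: str) -> list[int]:
    hits, i = [], text.find(word)
    while i != -1:
        hits.append(i)
        i = text.find(word, i + 1)   # step 1 so overlapping matches all report
    return hits


def scan_wbox(
    sequence: str,
    chrom: str = "seq",
    offset: int = 0,
    both_strands: bool = _P["both_strands"],
) -> list[MotifHit]:
    """All W-box occurrences in a sequence, sorted by position.

    ``offset`` shifts reported coordinates so a subsequence can be scanned
    in place of its chromosome.  A reverse-complement occurrence is reported
    at its forward-strand footprint with strand '-'.
    """
    text = sequence.upper()
    hits = []
    for word in FORWARD_WORDS:
        for i in _find_all(text, word):
            hits.append(MotifHit(
                GenomicInterval(chrom, offset + i, offset + i + 6, "+"), word))
    if both_strands:
        for word, fwd in zip(REVERSE_WORDS, FORWARD_WORDS):
            for i in _find_all(text, word):
                hits.append(MotifHit(
                    GenomicInterval(chrom, offset + i, offset + i + 6, "-"), fwd))
    return sorted(hits, key=lambda h: (h.interval.start, h.interval.strand))


def region_wbox_counts(
    regions: Sequence[GenomicInterval],
    sequences,
    both_strands: bool = _P["both_strands"],
) -> list[int]:
    """Per-region W-box occurrence counts.

    ``sequences`` maps chromosome to a string, a uint8 ASCII array, or a
    pyfaidx record; a region outside the sequence bounds raises an error
    naming the region.
    """
    counts = []
    for r in regions:
        seq = sequences[r.chrom]
        length = len(seq)
        if r.end > length:
            raise ValueError(f"region {r.name or r} extends past {r.chrom} ({length} bp)")
        chunk = seq[r.start:r.end]
        if isinstance(chunk, np.ndarray):
            chunk = chunk.tobytes().decode()
        counts.append(len(scan_wbox(str(chunk), r.chrom, r.start, both_strands)))
    return counts


def wbox_count_per_set(
    sets: dict[str, Sequence[GenomicInterval]],
    sequences,
    both_strands: bool = _P["both_strands"],
) -> tuple[dict[str, float], dict[str, list[int]]]:
    """Average W-box occurrences per 100 regions, per named region set.

    Returns (per-set averages, per-set per-region count lists).  An empty
    set has no defined average and raises.
    """
    averages, tables = {}, {}
    for name, regions in sets.items():
        if not regions:
            raise ValueError(f"set {name!r} is empty")
        counts = region_wbox_counts(regions, sequences, both_strands)
        tables[name] = counts
        averages[name] = sum(counts) / (len(regions) / 100)
    return averages, tables


def motif_enrichment_fisher(
    set_a_with: int, set_a_without: int, set_b_with: int, set_b_without: int
) -> tuple[float, float]:
    """Two-sided Fisher exact test on motif presence between two sets.

    Returns (odds ratio, p-value); the odds ratio uses a 0.5 Haldane
    correction when any cell is zero (the p-value never does).
    """
    if set_a_with + set_a_without == 0 or set_b_with + set_b_without == 0:
        raise ValueError("both sets must be non-empty")
    table = [[set_a_with, set_a_without], [set_b_with, set_b_without]]
    _, pvalue = stats.fisher_exact(table, alternative="two-sided")
    a, b, c, d = set_a_with, set_a_without, set_b_with, set_b_without
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c), float(pvalue)
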