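"""Non-redundant putative distal enhancer library from two open-chromatin sources.

The ATAC-derived set (A) is taken wholesale; a DNase-derived record (D) is
added only when it has less than 50% reciprocal overlap with every A record
(reciprocal: both overlap fractions must reach the cutoff for the pair to
count as redundant).  An A record that absorbed at least one redundant D
record is labelled source A+D.  IDs are assigned by source and genome
order, zero-padded, stable under re-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import defaults
from .intervals import GenomicInterval, reciprocal_overlap, sort_intervals

_P = defaults("library")


@dataclass
class EnhancerRecord:
    """One library enhancer with everything later stages attach to it."""

    interval: GenomicInterval
    source: str                       # A / D / A+D
    id: str = ""
    transcript_region: GenomicInterval | None = None
    tpm_by_condition: dict[str, float] = field(default_factory=dict)
    counts_by_condition_strand: dict[tuple[str, str], int] = field(default_factory=dict)
    state: str = "nontranscribed"
    direction: str = "none"
    de_by_elicitor: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.source not in ("A", "D", "A+D"):
            raise ValueError(f"bad source {self.source!r}")


def merge_sources(
    enh_a: list[GenomicInterval],
    enh_d: list[GenomicInterval],
    min_reciprocal: float = _P["reciprocal_overlap"],
) -> list[EnhancerRecord]:
    """Merge A and D distal peak sets into one library.

    Every A interval is kept.  A D interval is kept iff no A interval
    reciprocally overlaps it at >= ``min_reciprocal`` of both lengths; a
    single qualifying A suffices to discard it, and that A becomes A+D.
    """
    a_records = [EnhancerRecord(iv, "A") for iv in enh_a]
    records = list(a_records)
    for d in enh_d:
        absorbed = False
        for rec in a_records:  # redundancy is judged against the A set only
            fa, fd = reciprocal_overlap(rec.interval, d)
            if fa >= min_reciprocal and fd >= min_reciprocal:
                rec.source = "A+D"
                absorbed = True
        if not absorbed:
            records.append(EnhancerRecord(d, "D"))
    order = {id(iv): k for k, iv in
             enumerate(sort_intervals([r.interval for r in records]))}
    records.sort(key=lambda r: order[id(r.interval)])
    n_a = n_d = 0
    for rec in records:
        if rec.source == "D":
            n_d += 1
            rec.id = f"EnhD{n_d:04d}"
        else:
            n_a += 1
            rec.id = f"EnhA{n_a:04d}"
        rec.interval = rec.interval.with_name(rec.id)
    return records


def library_manifest(records: list[EnhancerRecord]) -> list[dict]:
    """Flat manifest rows (id, source, coordinates, length) for TSV export."""
    return [
        {"id": r.id, "source": r.source, "chrom": r.interval.chrom,
         "start": r.interval.start, "end": r.interval.end,
         "length": r.interval.length}
        for r in records
    ]
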