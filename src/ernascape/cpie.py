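"""Nearest-gene assignment and core pattern-induced enhancer/gene sets.

Each enhancer is assigned the closest protein-coding gene (minimum gap
between intervals; ties to the smaller gene start).  The *core* induced
set across elicitors is the exact intersection of the per-elicitor
upregulated id sets — enhancers (CPIEs) or genes (CPIGs) induced by every
tested pattern; a per-elicitor membership matrix supports Venn/UpSet-style
export.
"""

from __future__ import annotations

import pandas as pd

from .intervals import GenomicInterval, GenomeAnnotation


def nearest_gene(
    enhancer: GenomicInterval, annotation: GenomeAnnotation
) -> tuple[str, int]:
    """(gene id, gap in bp) of the closest gene; ('unassigned', -1) if none.

    Distance is the gap between the two intervals (0 when they overlap);
    equidistant genes resolve to the smaller start coordinate.
    """
    best: tuple[int, int, str] | None = None
    for g in annotation.genes:
        if g.chrom != enhancer.chrom:
            continue
        key = (enhancer.gap_to(g), g.start, g.name)
        if best is None or key < best:
            best = key
    if best is None:
        return "unassigned", -1
    return best[2], best[0]


def nearest_gene_map(
    enhancers: list[GenomicInterval], annotation: GenomeAnnotation
) -> pd.DataFrame:
    rows = []
    for e in enhancers:
        gene, dist = nearest_gene(e, annotation)
        rows.append({"enhancer": e.name, "gene": gene, "distance": dist})
    return pd.DataFrame(rows, columns=["enhancer", "gene", "distance"])


def core_induced(sets: dict[str, set[str]]) -> set[str]:
    """Ids upregulated under every provided elicitor (exact intersection)."""
    if not sets:
        raise ValueError("need at least one elicitor set")
    out: set[str] | None = None
    for ids in sets.values():
        out = set(ids) if out is None else out & set(ids)
    return out


def membership_matrix(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Boolean features x elicitors membership frame, with a 'core' column."""
    universe = sorted(set().union(*sets.values())) if sets else []
    frame = pd.DataFrame(
        {cond: [fid in ids for fid in universe] for cond, ids in sets.items()},
        index=universe,
    )
    frame["core"] = frame.all(axis=1)
    return frame
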