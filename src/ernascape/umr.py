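"""Unmethylated region (UMR) calling from per-cytosine methylation counts.

The genome is tiled with non-overlapping 100-bp windows.  A window with
mean per-cytosine depth below 10x (or no cytosines) is *missing*; otherwise
it is *unmethylated* when the count-weighted methylation fraction pooled
over CG+CHG+CHH (sum meth / sum total) is below 10%, else *methylated*.
Runs of unmethylated windows are merged; neighbouring runs separated only
by missing windows are joined left-to-right, greedily and to fixpoint, as
long as the prospective merged region stays at or below 33% missing
windows.  Regions longer than 300 bp (strictly) are UMRs.  A UMR is
*proximal* when any part lies within 1500 bp of a TSS, else *genic* when it
touches a gene body, else *distal* — proximal wins when both apply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import defaults
from .intervals import GenomicInterval, GenomeAnnotation

_P = defaults("umr")

MISSING, UNMETHYLATED, METHYLATED = 0, 1, 2


@dataclass(frozen=True)
class Umr:
    interval: GenomicInterval
    missing_fraction: float
    umr_class: str = ""   # proximal / genic / distal

    def __post_init__(self):
        if self.missing_fraction > 1 / 3 + 1e-12:
            raise ValueError("UMR exceeds the missing-data bound")


def classify_windows(
    calls: pd.DataFrame,
    chrom_len: int,
    window: int = _P["window"],
    step: int = _P["step"],
    min_cov: float = _P["min_cov"],
    max_mc: float = _P["max_mc"],
) -> np.ndarray:
    """Label every ``window``-bp tile of one chromosome.

    ``calls`` holds that chromosome's cytosines (pos, meth, total).  Returns
    an int array over ceil(chrom_len / window) tiles with values MISSING,
    UNMETHYLATED or METHYLATED.  Coverage is the mean total count over the
    window's cytosines; the methylation fraction pools all contexts by
    counts.  Thresholds are strict in the stated directions: coverage
    < min_cov -> missing; fraction < max_mc -> unmethylated.
    """
    if step != window:
        raise ValueError("only non-overlapping tiling is supported")
    n_win = (chrom_len + window - 1) // window
    labels = np.full(n_win, MISSING, dtype=np.int8)
    if len(calls) == 0:
        return labels
    idx = np.minimum(calls["pos"].to_numpy() // window, n_win - 1)
    n_sites = np.bincount(idx, minlength=n_win)
    tot = np.bincount(idx, weights=calls["total"].to_numpy(), minlength=n_win)
    met = np.bincount(idx, weights=calls["meth"].to_numpy(), minlength=n_win)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = np.where(n_sites > 0, tot / np.maximum(n_sites, 1), 0.0)
        frac = np.where(tot > 0, met / np.maximum(tot, 1), 0.0)
    covered = (n_sites > 0) & (cov >= min_cov)
    labels[covered & (frac < max_mc)] = UNMETHYLATED
    labels[covered & (frac >= max_mc)] = METHYLATED
    return labels


def merge_umr_windows(
    labels: np.ndarray,
    chrom: str,
    window: int = _P["window"],
    max_missing: float = _P["max_missing"],
    min_length: int = _P["min_length"],
    chrom_len: int | None = None,
) -> list[Umr]:
    """Merge window labels of one chromosome into UMRs.

    Stage 1 joins adjacent unmethylated windows into runs.  Stage 2 bridges
    pairs of runs separated only by missing windows, scanning left to right
    and re-scanning until no merge applies; a bridge is taken iff missing
    windows / total windows of the prospective merged region <= max_missing.
    Stage 3 keeps regions strictly longer than ``min_length`` bp.
    """
    runs: list[list[int]] = []  # [first_window, last_window, n_missing_inside]
    for i, lab in enumerate(labels):
        if lab == UNMETHYLATED:
            if runs and runs[-1][1] == i - 1:
                runs[-1][1] = i
            else:
                runs.append([i, i, 0])
    changed = True
    while changed:
        changed = False
        i = 0
        while i + 1 < len(runs):
            a, b = runs[i], runs[i + 1]
            gap = labels[a[1] + 1:b[0]]
            if gap.size and np.all(gap == MISSING):
                n_missing = a[2] + b[2] + gap.size
                n_total = b[1] - a[0] + 1
                if n_missing / n_total <= max_missing:
                    runs[i] = [a[0], b[1], n_missing]
                    runs.pop(i + 1)
                    changed = True
                    continue
            i += 1
    out = []
    for first, last, n_missing in runs:
        start = first * window
        end = (last + 1) * window
        if chrom_len is not None:
            end = min(end, chrom_len)
        if end - start > min_length:
            out.append(Umr(GenomicInterval(chrom, start, end),
                           n_missing / (last - first + 1)))
    return out


def classify_umr(
    umr: Umr,
    annotation: GenomeAnnotation,
    proximal_bp: int = _P["proximal_bp"],
) -> str:
    """proximal (within 1500 bp of a TSS) > genic (touches a gene body) > distal."""
    iv = umr.interval
    tss = annotation.tss_positions(iv.chrom)
    if tss.size:
        # distance 0 when a TSS falls inside the UMR, else gap to nearest edge
        left = np.clip(iv.start - tss, 0, None)
        right = np.clip(tss - (iv.end - 1), 0, None)
        if int(np.min(left + right)) <= proximal_bp:
            return "proximal"
    if any(iv.overlaps(g) for g in annotation.genes):
        return "genic"
    return "distal"


def call_umrs(
    methylome: pd.DataFrame,
    annotation: GenomeAnnotation,
    window: int = _P["window"],
    min_cov: float = _P["min_cov"],
    max_mc: float = _P["max_mc"],
    max_missing: float = _P["max_missing"],
    min_length: int = _P["min_length"],
    proximal_bp: int = _P["proximal_bp"],
) -> list[Umr]:
    """Whole-genome UMR calls with class labels, sorted by position."""
    out: list[Umr] = []
    grouped = dict(tuple(methylome.groupby("chrom", observed=True)))
    for chrom in sorted(annotation.chrom_sizes):
        calls = grouped.get(chrom, methylome.iloc[0:0])
        labels = classify_windows(calls, annotation.chrom_sizes[chrom],
                                  window, window, min_cov, max_mc)
        for umr in merge_umr_windows(labels, chrom, window, max_missing,
                                     min_length, annotation.chrom_sizes[chrom]):
            cls = classify_umr(umr, annotation, proximal_bp)
            out.append(Umr(umr.interval, umr.missing_fraction, cls))
    return out


def enhancer_umr_overlap(
    enhancers: list[GenomicInterval],
    umrs: list[Umr],
) -> dict[str, float]:
    """Per-set overlap of enhancers with UMRs.

    ``region_fraction``: share of enhancers touching at least one UMR;
    ``base_fraction``: share of total enhancer bases covered by UMRs.
    """
    if not enhancers:
        return {"region_fraction": 0.0, "base_fraction": 0.0}
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for u in umrs:
        by_chrom.setdefault(u.interval.chrom, []).append(u.interval)
    touched = 0
    covered = 0
    total = 0
    for e in enhancers:
        total += e.length
        inter = sum(e.intersection_length(u) for u in by_chrom.get(e.chrom, ()))
        covered += inter
        if inter > 0:
            touched += 1
    return {"region_fraction": touched / len(enhancers),
            "base_fraction": covered / total}


def umr_class_summary(
    umrs: list[Umr], annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Counts, total lengths and genome fractions per UMR class.

    Both count-weighted and length-weighted proportions are reported, since
    either reading of a per-class "genome proportion" is defensible.
    """
    genome = sum(annotation.chrom_sizes.values())
    rows = []
    n_all = len(umrs) or 1
    len_all = sum(u.interval.length for u in umrs) or 1
    for cls in ("proximal", "genic", "distal"):
        members = [u for u in umrs if u.umr_class == cls]
        length = sum(u.interval.length for u in members)
        rows.append({
            "class": cls,
            "count": len(members),
            "total_bp": length,
            "count_fraction": len(members) / n_all,
            "length_fraction": length / len_all,
            "genome_fraction": length / genome,
        })
    return pd.DataFrame(rows)
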