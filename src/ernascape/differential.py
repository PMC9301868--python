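"""Differential transcription calls between elicitor-treated and mock samples.

With one pooled library per condition there is no dispersion to estimate,
so significance comes from the conditional binomial test on a feature's two
counts (Audic–Claverie style): given n = count_a + count_b, count_b is
Binomial(n, libsize_b / (libsize_a + libsize_b)) under the null of equal
relative abundance.  Fold changes use library-size-normalized counts with a
pseudocount; p-values are Benjamini–Hochberg adjusted across features.
Enhancers are called at |log2FC| >= 1, genes at twofold with FDR < 0.05;
the FDR gate on enhancers is on by default and can be disabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import defaults

_P = defaults("differential")


@dataclass(frozen=True)
class DeResult:
    feature_id: str
    log2fc: float
    pvalue: float
    fdr: float
    call: str  # up / down / ns


def log2_fold_change(
    count_a: float,
    count_b: float,
    libsize_a: float,
    libsize_b: float,
    pseudocount: float = _P["pseudocount"],
) -> float:
    """log2 of the normalized b/a ratio, pseudocounted; invariant to count+libsize scaling."""
    if libsize_a <= 0 or libsize_b <= 0:
        raise ValueError("library sizes must be positive")
    return float(np.log2(((count_b + pseudocount) / libsize_b)
                         / ((count_a + pseudocount) / libsize_a)))


def no_replicate_test(
    count_a: int, count_b: int, libsize_a: float, libsize_b: float
) -> float:
    """Two-sided conditional binomial p-value for a two-sample count contrast."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be nonnegative")
    n = count_a + count_b
    if n == 0:
        return 1.0
    p0 = libsize_b / (libsize_a + libsize_b)
    return float(stats.binomtest(count_b, n, p0, alternative="two-sided").pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR values, mapped back to input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_de(
    feature_ids,
    counts_a,
    counts_b,
    libsize_a: float | None = None,
    libsize_b: float | None = None,
    min_log2fc: float = _P["enhancer_min_log2fc"],
    max_fdr: float = _P["max_fdr"],
    fdr_gate: bool = _P["enhancer_fdr_gate"],
    pseudocount: float = _P["pseudocount"],
) -> list[DeResult]:
    """Per-feature DE calls for condition b vs condition a.

    Library sizes default to the total counts over the supplied features.
    A feature is up/down when |log2FC| >= ``min_log2fc`` and (if
    ``fdr_gate``) FDR < ``max_fdr``; otherwise ns.
    """
    counts_a = np.asarray(counts_a)
    counts_b = np.asarray(counts_b)
    if libsize_a is None:
        libsize_a = float(counts_a.sum())
    if libsize_b is None:
        libsize_b = float(counts_b.sum())
    lfc = np.array([log2_fold_change(a, b, libsize_a, libsize_b, pseudocount)
                    for a, b in zip(counts_a, counts_b)])
    pvals = np.array([no_replicate_test(int(a), int(b), libsize_a, libsize_b)
                      for a, b in zip(counts_a, counts_b)])
    fdrs = bh_adjust(pvals)
    out = []
    for fid, fc, p, q in zip(feature_ids, lfc, pvals, fdrs):
        significant = (q < max_fdr) if fdr_gate else True
        if abs(fc) >= min_log2fc and significant:
            call = "up" if fc > 0 else "down"
        else:
            call = "ns"
        out.append(DeResult(str(fid), float(fc), float(p), float(q), call))
    return out
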