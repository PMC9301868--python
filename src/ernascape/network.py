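"""Coexpression networks, the scale-free threshold criterion, and the iGRN.

Edges connect features whose expression profiles correlate at |r| at or
above a threshold.  The threshold is chosen by the scale-free criterion:
over a candidate grid, pick the smallest cutoff whose network's degree
distribution fits a power law — R² of the OLS fit of log P(k) on log k
at or above a target (default 0.95), where P(k) is the fraction of all
nodes (isolated ones included in the denominator) with exactly k links.
The integrated gene regulatory network (iGRN) restricts nodes to
upregulated enhancers carrying at least one W-box plus genes within ±1 Mb
of each, with enhancer–gene edges only.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .config import defaults
from .intervals import GenomicInterval

_P = defaults("network")


class FitUndefinedError(ValueError):
    """Too few distinct degrees to fit the degree distribution."""


def pearson_r(x, y) -> float:
    """Pearson correlation; zero variance in either vector is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of >= 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Feature-by-feature Pearson r over samples (columns)."""
    return expr.T.corr(method="pearson")


def build_network(
    expr: pd.DataFrame,
    threshold: float,
    pairs: list[tuple[str, str]] | None = None,
) -> nx.Graph:
    """Undirected graph over the matrix's features with |r| >= threshold edges.

    All features enter as nodes (so isolated nodes count toward P(k));
    zero-variance features are excluded entirely.  ``pairs`` restricts the
    edge candidates (e.g. enhancer–gene pairs only).
    """
    variable = expr.index[expr.std(axis=1) > 0]
    expr = expr.loc[variable]
    corr = correlation_matrix(expr).to_numpy()
    ids = list(expr.index)
    pos = {f: i for i, f in enumerate(ids)}
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    if pairs is None:
        iu, ju = np.triu_indices(len(ids), k=1)
        keep = np.abs(corr[iu, ju]) >= threshold
        for i, j in zip(iu[keep], ju[keep]):
            graph.add_edge(ids[i], ids[j], r=float(corr[i, j]))
    else:
        for a, b in pairs:
            if a in pos and b in pos and a != b:
                r = corr[pos[a], pos[b]]
                if abs(r) >= threshold:
                    graph.add_edge(a, b, r=float(r))
    graph.graph["threshold"] = threshold
    return graph


def degree_distribution(graph: nx.Graph) -> dict[int, float]:
    """P(k) = fraction of nodes with exactly k links; sums to 1."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    degrees = [d for _, d in graph.degree()]
    n = len(degrees)
    out: dict[int, float] = {}
    for k in degrees:
        out[k] = out.get(k, 0) + 1 / n
    return dict(sorted(out.items()))


def scale_free_fit(pk: dict[int, float]) -> tuple[float, float]:
    """OLS of log P(k) on log k over k >= 1; returns (slope, R²).

    Isolated nodes (k = 0) shape the distribution's denominator but cannot
    enter the log–log fit.  Fewer than 3 distinct positive degrees leaves
    the fit undefined.
    """
    ks = np.array([k for k in pk if k >= 1], dtype=float)
    if ks.size < 3:
        raise FitUndefinedError(f"only {ks.size} distinct positive degrees")
    ps = np.array([pk[int(k)] for k in ks])
    logk, logp = np.log(ks), np.log(ps)
    slope, intercept = np.polyfit(logk, logp, 1)
    fitted = slope * logk + intercept
    ss_res = float(np.sum((logp - fitted) ** 2))
    ss_tot = float(np.sum((logp - logp.mean()) ** 2))
    # a flat distribution (no variance in log P beyond float dust) carries
    # no power-law signal
    flat = ss_tot <= 1e-10 * ps.size * max(1.0, float(logp.mean()) ** 2)
    r2 = 0.0 if flat else max(0.0, 1 - ss_res / ss_tot)
    return float(slope), float(r2)


@dataclass
class ThresholdSelection:
    threshold: float
    r2_by_candidate: dict[float, float]
    converged: bool


def select_threshold(
    expr: pd.DataFrame,
    candidates: list[float] | None = None,
    target_r2: float = _P["target_r2"],
    pairs: list[tuple[str, str]] | None = None,
) -> ThresholdSelection:
    """Smallest candidate whose network meets the scale-free R² target.

    Candidates whose network leaves the fit undefined are recorded as NaN.
    When no candidate reaches the target, the best-R² candidate is returned
    with ``converged=False`` (callers log this as non-convergence).
    """
    candidates = sorted(candidates or _P["candidate_thresholds"])
    r2s: dict[float, float] = {}
    for cut in candidates:
        graph = build_network(expr, cut, pairs)
        try:
            _, r2 = scale_free_fit(degree_distribution(graph))
        except (FitUndefinedError, ValueError):
            r2 = float("nan")
        r2s[cut] = r2
        if r2 == r2 and r2 >= target_r2:
            return ThresholdSelection(cut, r2s, True)
    defined = {c: v for c, v in r2s.items() if v == v}
    if not defined:
        raise FitUndefinedError("no candidate threshold yields a fittable network")
    best = max(defined, key=defined.get)
    return ThresholdSelection(best, r2s, False)


def build_igrn(
    up_enhancers: list[GenomicInterval],
    wbox_counts: dict[str, int],
    genes: list[GenomicInterval],
    expr: pd.DataFrame,
    threshold: float,
    window: int = _P["igrn_window"],
    wrky_ids: set[str] | None = None,
) -> nx.Graph:
    """Integrated regulatory network of W-box upregulated enhancers and nearby genes.

    Nodes: upregulated enhancers with >= 1 W-box, plus genes whose interval
    lies within ``window`` bp (gap <= window, inclusive; 0 if overlapping)
    of such an enhancer.  Edges: enhancer–gene pairs only, at |r| >=
    ``threshold`` over the expression matrix.  Genes in ``wrky_ids`` are
    flagged kind='wrky_gene'.
    """
    wrky_ids = wrky_ids or set()
    keep = [e for e in up_enhancers if wbox_counts.get(e.name, 0) >= 1]
    pairs = []
    gene_nodes: dict[str, str] = {}
    for e in keep:
        for g in genes:
            if g.chrom == e.chrom and e.gap_to(g) <= window:
                pairs.append((e.name, g.name))
                gene_nodes[g.name] = "wrky_gene" if g.name in wrky_ids else "gene"
    graph = build_network(expr.loc[expr.index.isin(
        {e.name for e in keep} | set(gene_nodes))], threshold, pairs)
    for e in keep:
        if e.name in graph:
            graph.nodes[e.name]["kind"] = "enhancer"
    for g, kind in gene_nodes.items():
        if g in graph:
            graph.nodes[g]["kind"] = kind
    # genes only entered for proximity; drop any that ended up edgeless
    isolated_genes = [n for n, d in graph.nodes(data=True)
                      if d.get("kind") != "enhancer" and graph.degree(n) == 0]
    graph.remove_nodes_from(isolated_genes)
    return graph


def network_summary(graph: nx.Graph) -> dict:
    """Node/edge counts and per-kind breakdown of an iGRN."""
    kinds = nx.get_node_attributes(graph, "kind")
    enhancers = [n for n, k in kinds.items() if k == "enhancer"]
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_enhancers": len(enhancers),
        "n_genes": sum(1 for k in kinds.values() if k in ("gene", "wrky_gene")),
        "n_wrky": sum(1 for k in kinds.values() if k == "wrky_gene"),
        "genes_per_enhancer": {e: graph.degree(e) for e in enhancers},
    }


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [{"source": a, "target": b, "r": d.get("r", float("nan"))}
            for a, b, d in graph.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "r"]).to_csv(
        path, sep="\t", index=False)
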