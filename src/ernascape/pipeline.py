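"""End-to-end orchestration of all stages, plus truth-recovery evaluation.

``run_pipeline`` executes the stages in dependency order on an in-memory
dataset (typically from :mod:`ernascape.synth`, but any object with the
same fields works): accessibility peaks -> enhancer library -> eRNA
quantification -> differential calls -> UMRs -> W-box counts -> coexpression
network -> core pattern-induced sets.  ``evaluate`` compares the result
with a :class:`~ernascape.synth.SyntheticTruth` and reports recovery
metrics (peak recall/precision, UMR Jaccard, directionality accuracy, DE
recall and false-discovery proportion, eRNA length, bidirectional fraction,
enhancer–UMR overlap, W-box density ratio, iGRN summary, core-set overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cpie, erna, motifs, network, peaks, umr as umr_mod
from .config import merged_config
from .differential import DeResult, call_de
from .intervals import GenomicInterval, merge_within_gap, reciprocal_overlap
from .library import EnhancerRecord, merge_sources
from .synth import SyntheticDataset, SyntheticTruth


@dataclass
class PipelineResult:
    config: dict
    consensus_peaks: list[GenomicInterval] = field(default_factory=list)
    distal_peaks: list[GenomicInterval] = field(default_factory=list)
    library: list[EnhancerRecord] = field(default_factory=list)
    erna_calls: list = field(default_factory=list)
    de_enhancers: dict[str, list[DeResult]] = field(default_factory=dict)
    de_genes: dict[str, list[DeResult]] = field(default_factory=dict)
    umrs: list = field(default_factory=list)
    wbox_counts: dict[str, int] = field(default_factory=dict)
    wbox_set_averages: dict[str, float] = field(default_factory=dict)
    threshold_selection: network.ThresholdSelection | None = None
    network_cut: float | None = None
    igrn = None
    cpie_ids: set[str] = field(default_factory=set)
    cpig_ids: set[str] = field(default_factory=set)
    up_sets_enh: dict[str, set[str]] = field(default_factory=dict)
    up_sets_gene: dict[str, set[str]] = field(default_factory=dict)
    nearest_genes: pd.DataFrame | None = None


def _pooled_rna(dataset: SyntheticDataset) -> dict[str, dict[str, np.ndarray]]:
    """Sum stranded coverage over all conditions (for eRNA calling/direction)."""
    pooled = {s: {c: np.zeros(n, dtype=np.int64)
                  for c, n in dataset.annotation.chrom_sizes.items()}
              for s in "+-"}
    for cond in dataset.conditions:
        for s in "+-":
            for c, arr in dataset.rna[cond][s].items():
                pooled[s][c] += arr
    return pooled


def run_pipeline(dataset: SyntheticDataset, overrides: dict | None = None) -> PipelineResult:
    cfg = merged_config(overrides)
    result = PipelineResult(config=cfg)
    pc, ec, dc, uc, nc, cc = (cfg["peaks"], cfg["erna"], cfg["differential"],
                              cfg["umr"], cfg["network"], cfg["cpie"])

    # --- accessibility peaks: per-replicate refinement, consensus, distal set
    rep_peaks = []
    for cov in (dataset.atac_rep1, dataset.atac_rep2):
        refined = peaks.call_refined_peaks(
            cov, pc["qvalue_cutoff"], pc["freq_cutoff"],
            window=pc["refine_window"], step=pc["refine_step"],
            merge_gap=pc["merge_gap"], min_windows=pc["min_windows"],
            organellar=tuple(pc["organellar"]))
        rep_peaks.append([p.interval for p in refined])
    result.consensus_peaks = peaks.replicate_consensus(
        rep_peaks[0], rep_peaks[1], pc["consensus_min_overlap"],
        pc["consensus_reciprocal"])
    result.distal_peaks, _ = peaks.classify_distal(
        result.consensus_peaks, dataset.annotation, pc["tss_distance"],
        pc["distal_exclude_lncrna"])

    # --- library: ATAC distal peaks + DNase-style catalog
    result.library = merge_sources(result.distal_peaks, dataset.truth.d_catalog,
                                   cfg["library"]["reciprocal_overlap"])

    # --- eRNA quantification, state, directionality
    pooled = _pooled_rna(dataset)
    rna_by_cond = {cond: dataset.rna[cond] for cond in dataset.conditions}
    erna.quantify_library(result.library, rna_by_cond, dataset.annotation,
                          gene_counts=dataset.gene_counts,
                          min_count=ec["min_count"], min_tpm=ec["min_tpm"],
                          alpha=ec["direction_alpha"])
    regions = [r.transcript_region.with_name(r.id) for r in result.library
               if r.transcript_region is not None]
    result.erna_calls = erna.call_ernas(
        pooled, regions, window=ec["erna_window"], step=ec["erna_step"],
        pvalue=ec["erna_pvalue"], merge_gap=ec["erna_merge_gap"],
        min_length=ec["erna_min_length"])

    # --- differential: each elicitor vs mock, enhancers and genes
    elicitors = [c for c in dataset.conditions if c != "mock"]
    quantified = [r for r in result.library if r.transcript_region is not None]
    gene_ids = list(dataset.gene_counts.index)
    for cond in elicitors:
        enh_a = [sum(r.counts_by_condition_strand[("mock", s)] for s in "+-")
                 for r in quantified]
        enh_b = [sum(r.counts_by_condition_strand[(cond, s)] for s in "+-")
                 for r in quantified]
        gene_a = dataset.gene_counts["mock"].to_numpy()
        gene_b = dataset.gene_counts[cond].to_numpy()
        lib_a = float(gene_a.sum() + sum(enh_a))
        lib_b = float(gene_b.sum() + sum(enh_b))
        result.de_enhancers[cond] = call_de(
            [r.id for r in quantified], enh_a, enh_b, lib_a, lib_b,
            dc["enhancer_min_log2fc"], dc["max_fdr"], dc["enhancer_fdr_gate"],
            dc["pseudocount"])
        result.de_genes[cond] = call_de(
            gene_ids, gene_a, gene_b, lib_a, lib_b,
            dc["gene_min_log2fc"], dc["max_fdr"], True, dc["pseudocount"])
        for r, de in zip(quantified, result.de_enhancers[cond]):
            r.de_by_elicitor[cond] = de.call

    # --- UMRs + enhancer overlap
    result.umrs = umr_mod.call_umrs(
        dataset.methylome, dataset.annotation, uc["window"], uc["min_cov"],
        uc["max_mc"], uc["max_missing"], uc["min_length"], uc["proximal_bp"])

    # --- W-box counts on library enhancers; up-vs-down set averages
    lib_ivs = [r.interval for r in result.library]
    counts = motifs.region_wbox_counts(lib_ivs, dataset.sequences,
                                       cfg["motif"]["both_strands"])
    result.wbox_counts = {r.id: c for r, c in zip(result.library, counts)}
    up_ivs = [r.interval for r in result.library
              if r.de_by_elicitor.get("flg22") == "up"]
    down_ivs = [r.interval for r in result.library
                if r.de_by_elicitor.get("flg22") == "down"]
    sets = {}
    if up_ivs:
        sets["up"] = up_ivs
    if down_ivs:
        sets["down"] = down_ivs
    if sets:
        result.wbox_set_averages, _ = motifs.wbox_count_per_set(
            sets, dataset.sequences, cfg["motif"]["both_strands"])

    # --- up sets, core intersections, nearest genes
    for cond in elicitors:
        result.up_sets_enh[cond] = {d.feature_id for d in result.de_enhancers[cond]
                                    if d.call == "up"}
        result.up_sets_gene[cond] = {d.feature_id for d in result.de_genes[cond]
                                     if d.call == "up"}
    core_conds = [c for c in cc["core_elicitors"] if c in elicitors]
    if core_conds:
        result.cpie_ids = cpie.core_induced(
            {c: result.up_sets_enh[c] for c in core_conds})
        result.cpig_ids = cpie.core_induced(
            {c: result.up_sets_gene[c] for c in core_conds})
    result.nearest_genes = cpie.nearest_gene_map(lib_ivs, dataset.annotation)

    # --- coexpression network + iGRN over flg22-upregulated W-box enhancers
    expr = dataset.coexpression
    truth_id_of = _match_to_truth(result.library, dataset.truth)
    up_named = [r.interval.with_name(truth_id_of[r.id])
                for r in result.library
                if r.de_by_elicitor.get("flg22") == "up" and r.id in truth_id_of]
    wbox_by_truth = {truth_id_of[r.id]: result.wbox_counts[r.id]
                     for r in result.library if r.id in truth_id_of}
    if up_named and len(expr) >= 3:
        # threshold from the global coexpression network's degree distribution;
        # when the scale-free criterion never reaches the target R^2, fall
        # back to the conventional direct correlation cutoff (flag logged)
        result.threshold_selection = network.select_threshold(
            expr, nc["candidate_thresholds"], nc["target_r2"])
        if nc["direct_threshold"] is not None:
            cut = nc["direct_threshold"]
        elif result.threshold_selection.converged:
            cut = result.threshold_selection.threshold
        else:
            cut = nc["fallback_threshold"]
        result.network_cut = cut
        result.igrn = network.build_igrn(
            up_named, wbox_by_truth, dataset.annotation.genes, expr, cut,
            nc["igrn_window"], wrky_ids=set(dataset.truth.wrky_genes))
    return result


# ---------------------------------------------------------------------------
# truth recovery
# ---------------------------------------------------------------------------


def _match_to_truth(library: list[EnhancerRecord],
                    truth: SyntheticTruth) -> dict[str, str]:
    """library id -> planted enhancer id, by any-overlap interval matching."""
    out = {}
    for r in library:
        for e in truth.enhancers:
            if r.interval.overlaps(e.interval):
                out[r.id] = e.id
                break
    return out


def _interval_set_stats(called: list[GenomicInterval],
                        planted: list[GenomicInterval]) -> dict[str, float]:
    recall_hits = sum(1 for p in planted if any(p.overlaps(c) for c in called))
    precision_hits = sum(1 for c in called if any(c.overlaps(p) for p in planted))
    return {
        "recall": recall_hits / len(planted) if planted else float("nan"),
        "precision": precision_hits / len(called) if called else float("nan"),
    }


def _base_jaccard(a: list[GenomicInterval], b: list[GenomicInterval]) -> float:
    ma, mb = merge_within_gap(a, 0), merge_within_gap(b, 0)
    inter = sum(x.intersection_length(y) for x in ma for y in mb)
    union = sum(x.length for x in ma) + sum(y.length for y in mb) - inter
    return inter / union if union else float("nan")


def evaluate(result: PipelineResult, dataset: SyntheticDataset) -> dict:
    """Recovery metrics of one pipeline run against the planted truth."""
    truth = dataset.truth
    metrics: dict = {}

    planted_distal = [truth.enhancer(i).interval for i in truth.distal_peak_ids]
    metrics["distal_peaks"] = _interval_set_stats(result.distal_peaks, planted_distal)

    called_umrs = [u.interval for u in result.umrs]
    metrics["umr_jaccard"] = _base_jaccard(called_umrs, truth.umrs)
    bridged_ok = 0
    for name in truth.bridged_umr_ids:
        planted = next(u for u in truth.umrs if u.name == name)
        spanning = [u for u in called_umrs if u.overlaps(planted)]
        if len(spanning) == 1 and spanning[0].intersection_length(planted) >= 0.8 * planted.length:
            bridged_ok += 1
    metrics["bridged_recovered"] = (bridged_ok, len(truth.bridged_umr_ids))
    split_ok = 0
    for a_name, b_name in truth.split_umr_pairs:
        a = next(u for u in truth.umrs if u.name == a_name)
        b = next(u for u in truth.umrs if u.name == b_name)
        hit_a = [u for u in called_umrs if u.overlaps(a)]
        hit_b = [u for u in called_umrs if u.overlaps(b)]
        if hit_a and hit_b and not set(map(id, hit_a)) & set(map(id, hit_b)):
            split_ok += 1
    metrics["splits_kept"] = (split_ok, len(truth.split_umr_pairs))

    truth_id_of = _match_to_truth(result.library, truth)
    directed_total = directed_ok = 0
    state_total = state_ok = 0
    for r in result.library:
        e = truth.enhancer(truth_id_of[r.id]) if r.id in truth_id_of else None
        if e is None:
            continue
        if e.transcribed:
            state_total += 1
            state_ok += r.state == "transcribed"
            directed_total += 1
            directed_ok += r.direction == e.direction
    metrics["transcribed_recall"] = state_ok / state_total if state_total else float("nan")
    metrics["direction_accuracy"] = directed_ok / directed_total if directed_total else float("nan")

    # DE recovery pooled over elicitors: planted induced vs up calls
    de_tp = de_planted = de_up = de_fp = 0
    for cond, des in result.de_enhancers.items():
        for d in des:
            e = truth.enhancer(truth_id_of[d.feature_id]) if d.feature_id in truth_id_of else None
            if e is None:
                continue
            planted_up = cond in e.induced_by
            if planted_up:
                de_planted += 1
                de_tp += d.call == "up"
            if d.call == "up":
                de_up += 1
                de_fp += not planted_up
    metrics["de_recall"] = de_tp / de_planted if de_planted else float("nan")
    metrics["de_fdp"] = de_fp / de_up if de_up else 0.0

    lengths = [c.interval.length for c in result.erna_calls]
    metrics["mean_erna_length"] = float(np.mean(lengths)) if lengths else float("nan")
    metrics["bidirectional_fraction"] = erna.bidirectional_fraction(result.library)

    transcribed_ivs = [r.interval for r in result.library if r.state == "transcribed"]
    metrics["enhancer_umr_overlap"] = umr_mod.enhancer_umr_overlap(
        transcribed_ivs, result.umrs)

    if {"up", "down"} <= set(result.wbox_set_averages):
        metrics["wbox_up_down_ratio"] = (result.wbox_set_averages["up"]
                                         / result.wbox_set_averages["down"])

    planted_core = truth.core_induced_enhancers(
        [c for c in result.config["cpie"]["core_elicitors"]])
    called_core_truth = {truth_id_of[i] for i in result.cpie_ids if i in truth_id_of}
    metrics["cpie"] = {
        "called": len(result.cpie_ids),
        "planted": len(planted_core),
        "intersection": len(called_core_truth & planted_core),
    }
    planted_core_genes = truth.core_induced_genes(
        [c for c in result.config["cpie"]["core_elicitors"]])
    metrics["cpig"] = {
        "called": len(result.cpig_ids),
        "planted": len(planted_core_genes),
        "intersection": len(result.cpig_ids & planted_core_genes),
    }
    if result.igrn is not None:
        metrics["igrn"] = network.network_summary(result.igrn)
        metrics["network_threshold"] = result.network_cut
        metrics["network_converged"] = result.threshold_selection.converged
    return metrics
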