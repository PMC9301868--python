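"""Default parameter values for every pipeline stage.

Each numeric threshold of the method lives here exactly once; stage
functions take keyword arguments that default to these values, and the
CLI loads this mapping as the base layer under any user config file.
"""

from __future__ import annotations

import copy
from typing import Any

DEFAULTS: dict[str, dict[str, Any]] = {
    "peaks": {
        # candidate segmentation (internal Poisson-window replacement for
        # an external peak caller; candidates only seed the refinement)
        "segment_window": 200,
        "segment_step": 100,
        "qvalue_cutoff": 0.01,
        # window refinement
        "refine_window": 50,
        "refine_step": 25,
        "freq_cutoff": 2.0,        # normalized integration frequency, >= genome avg x2
        "merge_gap": 150,
        "min_windows": 2,          # enforces region length > 50 bp
        "organellar": ["Mt", "Pt", "ChrM", "ChrC"],
        # replicate consensus + distal classification
        "consensus_reciprocal": True,
        "consensus_min_overlap": 0.5,
        "tss_distance": 1500,      # strict >, measured from peak center
        "distal_exclude_lncrna": False,
    },
    "library": {
        "reciprocal_overlap": 0.5,  # D discarded at >= this reciprocal overlap with an A
    },
    "erna": {
        "transcript_flank": 500,    # +/- around enhancer midpoint when length < 1 kb
        "long_enhancer": 1000,      # >= this: original coordinates kept
        "blacklist_extension": 1000,  # genes/lncRNAs extended this much on both ends
        "min_count": 5,             # "detectable expression": pooled reads
        "min_tpm": 0.1,
        "erna_window": 100,
        "erna_step": 25,
        "erna_pvalue": 1e-3,
        "erna_merge_gap": 100,
        "erna_min_length": 100,
        "direction_window": 25,     # strand profile bin size
        "direction_alpha": 0.05,
        "direction_max_minority": 0.25,  # uni also needs a quiet minority strand
    },
    "differential": {
        "pseudocount": 1,
        "enhancer_min_log2fc": 1.0,
        "gene_min_log2fc": 1.0,     # "twofold"
        "max_fdr": 0.05,
        "enhancer_fdr_gate": True,
    },
    "umr": {
        "window": 100,
        "step": 100,
        "min_cov": 10,
        "max_mc": 0.10,
        "max_missing": 1 / 3,
        "min_length": 300,          # strict >
        "proximal_bp": 1500,
    },
    "motif": {
        "both_strands": True,
        "words": ["TTGACC", "TTGACT"],
    },
    "network": {
        "target_r2": 0.95,
        "candidate_thresholds": [0.5, 0.6, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 0.99],
        "igrn_window": 1_000_000,
        "direct_threshold": None,   # set to e.g. 0.95 to bypass scale-free selection
        "fallback_threshold": 0.95,  # used when the scale-free criterion fails to converge
    },
    "cpie": {
        "core_elicitors": ["flg22", "chitin", "nlp20", "pep2"],  # INA excluded from the pattern core
    },
    "simulate": {
        "n_chroms": 2,
        "chrom_len": 2_000_000,
        "n_genes": 200,
        "n_enhancers": 120,
        "elicitors": ["flg22", "chitin", "nlp20", "pep2", "ina"],
        "atac_background": 0.02,
        "atac_fold": 12.0,
        "rna_background": 0.0005,
        "erna_length": 200,
        "erna_reads": 120.0,        # expected reads per planted eRNA, mock condition
        "induction_fold": 4.0,
        "frac_transcribed": 0.7,
        "frac_bidirectional": 0.65,
        "uni_split": 0.95,
        "meth_coverage": 30.0,
        "coexpr_samples": 12,
        "coexpr_r": 0.95,
    },
}


def defaults(stage: str) -> dict[str, Any]:
    """A deep copy of the default parameter block for one stage."""
    return copy.deepcopy(DEFAULTS[stage])


def merged_config(overrides: dict | None = None) -> dict[str, dict[str, Any]]:
    """Full default config with an optional two-level override mapping."""
    cfg = copy.deepcopy(DEFAULTS)
    for stage, block in (overrides or {}).items():
        if stage not in cfg:
            raise KeyError(f"unknown config section: {stage!r}")
        for key, value in block.items():
            if key not in cfg[stage]:
                raise KeyError(f"unknown config key: {stage}.{key}")
            cfg[stage][key] = value
    return cfg
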