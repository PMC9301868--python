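"""Synthetic genomes with planted regulatory truth.

Every input the pipeline consumes — genome FASTA + GFF3 annotation,
ATAC-style per-base insertion counts, stranded RNA coverage per elicitor
condition, per-cytosine methylation calls, and a sample-by-feature
expression matrix — is generated here from a single seed, together with a
:class:`SyntheticTruth` record of what was planted (peaks, enhancers with
directionality and induction, unmethylated valleys, W-box counts,
coexpression modules).  Downstream stages are validated by recovering this
truth; no external data is required.

Coverage tracks are plain ``dict[chrom -> int32 array]`` of per-base event
counts (Tn5 insertions for accessibility, read 5' ends for RNA), so window
sums are exact event counts and Poisson statistics apply directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import defaults
from .intervals import GenomicInterval, GenomeAnnotation, write_bed, write_gff3

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
WBOX_WORDS = ("TTGACC", "TTGACT")
WBOX_RC = ("GGTCAA", "AGTCAA")

# planted per-context methylation means outside/inside unmethylated regions
METH_MEANS = {"CG": 0.8, "CHG": 0.4, "CHH": 0.1}
UMR_METH_MEAN = 0.02
BETA_CONCENTRATION = 20.0
LOW_COVERAGE = 2.0  # mean depth planted inside "missing data" stretches


# ---------------------------------------------------------------------------
# truth record
# ---------------------------------------------------------------------------


def _iv_to_json(iv: GenomicInterval) -> dict:
    return {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
            "strand": iv.strand, "name": iv.name}


def _iv_from_json(d: dict) -> GenomicInterval:
    return GenomicInterval(d["chrom"], d["start"], d["end"], d["strand"], d["name"])


@dataclass
class PlantedEnhancer:
    """One planted enhancer and everything the pipeline should recover about it."""

    id: str
    interval: GenomicInterval
    in_a: bool                      # has a planted accessibility peak (ATAC source)
    in_d: bool                      # appears in the synthetic DNase-style catalog
    transcribed: bool
    direction: str                  # uni+ / uni- / bi / none
    induced_by: list[str] = field(default_factory=list)
    repressed_by: list[str] = field(default_factory=list)
    wbox_count: int = 0
    erna: GenomicInterval | None = None   # planted transcript footprint

    def to_json(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k not in ("interval", "erna")}
        d["interval"] = _iv_to_json(self.interval)
        d["erna"] = _iv_to_json(self.erna) if self.erna else None
        return d

    @classmethod
    def from_json(cls, d: dict) -> "PlantedEnhancer":
        d = dict(d)
        d["interval"] = _iv_from_json(d["interval"])
        d["erna"] = _iv_from_json(d["erna"]) if d["erna"] else None
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Serializable ground truth for one synthetic dataset."""

    planted_peaks: list[tuple[GenomicInterval, float]] = field(default_factory=list)
    distal_peak_ids: list[str] = field(default_factory=list)
    enhancers: list[PlantedEnhancer] = field(default_factory=list)
    umrs: list[GenomicInterval] = field(default_factory=list)
    missing_regions: list[GenomicInterval] = field(default_factory=list)
    bridged_umr_ids: list[str] = field(default_factory=list)   # contain a <=33% missing gap
    split_umr_pairs: list[tuple[str, str]] = field(default_factory=list)
    induced_genes: dict[str, list[str]] = field(default_factory=dict)  # gene -> elicitors
    modules: list[dict] = field(default_factory=list)  # {enhancer, genes, r_target}
    wrky_genes: list[str] = field(default_factory=list)
    seeds: dict[str, int] = field(default_factory=dict)

    def enhancer(self, eid: str) -> PlantedEnhancer:
        return next(e for e in self.enhancers if e.id == eid)

    @property
    def d_catalog(self) -> list[GenomicInterval]:
        return [e.interval.with_name(e.id) for e in self.enhancers if e.in_d]

    def core_induced_enhancers(self, elicitors: list[str]) -> set[str]:
        return {e.id for e in self.enhancers
                if all(c in e.induced_by for c in elicitors)}

    def core_induced_genes(self, elicitors: list[str]) -> set[str]:
        return {g for g, conds in self.induced_genes.items()
                if all(c in conds for c in elicitors)}

    def to_json(self) -> dict:
        return {
            "planted_peaks": [[_iv_to_json(iv), fold] for iv, fold in self.planted_peaks],
            "distal_peak_ids": self.distal_peak_ids,
            "enhancers": [e.to_json() for e in self.enhancers],
            "umrs": [_iv_to_json(iv) for iv in self.umrs],
            "missing_regions": [_iv_to_json(iv) for iv in self.missing_regions],
            "bridged_umr_ids": self.bridged_umr_ids,
            "split_umr_pairs": [list(p) for p in self.split_umr_pairs],
            "induced_genes": self.induced_genes,
            "modules": self.modules,
            "wrky_genes": self.wrky_genes,
            "seeds": self.seeds,
        }

    @classmethod
    def from_json(cls, d: dict) -> "SyntheticTruth":
        return cls(
            planted_peaks=[(_iv_from_json(iv), fold) for iv, fold in d["planted_peaks"]],
            distal_peak_ids=list(d["distal_peak_ids"]),
            enhancers=[PlantedEnhancer.from_json(e) for e in d["enhancers"]],
            umrs=[_iv_from_json(iv) for iv in d["umrs"]],
            missing_regions=[_iv_from_json(iv) for iv in d["missing_regions"]],
            bridged_umr_ids=list(d["bridged_umr_ids"]),
            split_umr_pairs=[tuple(p) for p in d["split_umr_pairs"]],
            induced_genes={k: list(v) for k, v in d["induced_genes"].items()},
            modules=list(d["modules"]),
            wrky_genes=list(d.get("wrky_genes", [])),
            seeds=dict(d["seeds"]),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def load(cls, path) -> "SyntheticTruth":
        return cls.from_json(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------


class PlacementError(RuntimeError):
    """Requested features cannot be placed within the genome's free space."""


def _take(rng, free: list[list], chrom: str, length: int, margin: int):
    """Carve a ``length``-bp slot out of a random free segment on ``chrom``.

    Free segments are ``[chrom, start, end]`` triples; the chosen slot plus
    ``margin`` on both sides is removed so later features keep their distance.
    """
    candidates = [i for i, (c, s, e) in enumerate(free)
                  if c == chrom and e - s >= length + 2 * margin]
    if not candidates:
        raise PlacementError(f"no free segment of {length} bp (+{margin}) on {chrom}")
    i = candidates[rng.integers(len(candidates))]
    c, s, e = free[i]
    start = int(rng.integers(s + margin, e - margin - length + 1))
    free.pop(i)
    if start - margin - s > 0:
        free.append([c, s, start - margin])
    if e - (start + length + margin) > 0:
        free.append([c, start + length + margin, e])
    return start


def _snap(x: int, grid: int, up: bool) -> int:
    return ((x + grid - 1) // grid if up else x // grid) * grid


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------


def _scan_words(text: str) -> list[int]:
    hits = []
    for word in WBOX_WORDS + WBOX_RC:
        i = text.find(word)
        while i != -1:
            hits.append(i)
            i = text.find(word, i + 1)
    return sorted(set(hits))


def _plant_wbox(rng, seq: np.ndarray, start: int, end: int, count: int) -> int:
    """Scrub accidental W-boxes in seq[start:end], then plant exactly ``count``.

    Returns the number actually planted (== ``count`` unless the region is
    too short to hold that many non-overlapping 6-mers).
    """
    for _ in range(50):  # scrub accidental matches on either strand
        text = seq[start:end].tobytes().decode()
        hits = _scan_words(text)
        if not hits:
            break
        for h in hits:
            pos = start + h + 2  # break the core by flipping a middle base
            cur = seq[pos]
            options = BASES[BASES != cur]
            seq[pos] = options[rng.integers(3)]
    n_slots = (end - start) // 6
    count = min(count, n_slots)
    if count == 0:
        return 0
    for _ in range(100):
        offsets = rng.choice(n_slots, size=count, replace=False) * 6
        backup = seq[start:end].copy()
        for off in offsets:
            word = WBOX_WORDS[rng.integers(2)] if rng.random() < 0.5 else WBOX_RC[rng.integers(2)]
            seq[start + off:start + off + 6] = np.frombuffer(word.encode(), dtype=np.uint8)
        text = seq[start:end].tobytes().decode()
        if len(_scan_words(text)) == count:  # no accidental extra created at junctions
            return count
        seq[start:end] = backup
    raise PlacementError("could not plant W-boxes without accidental extras")


# ---------------------------------------------------------------------------
# genome + truth
# ---------------------------------------------------------------------------


def _child_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    names = ["genome", "atac1", "atac2", "rna", "meth", "coexpr"]
    return {n: int(v) for n, v in zip(names, rng.integers(0, 2**31 - 1, len(names)))}


def generate_genome(
    n_chroms: int = 2,
    chrom_len: int = 2_000_000,
    n_genes: int = 200,
    seed: int = 0,
    n_enhancers: int = 120,
    elicitors: list[str] | None = None,
    frac_transcribed: float = 0.7,
    frac_bidirectional: float = 0.65,
    erna_length: int = 200,
):
    """Build annotation, sequence and planted truth for a synthetic genome.

    Genes (1–3 kb) are laid out with >= 3 kb intergenic spacers; enhancers
    (200–600 bp) go into intergenic space far enough from genes that their
    ±500 bp transcript regions clear the 1-kb gene extension used by the
    blacklist filter.  W-boxes are planted inside enhancers (denser in
    upregulated ones) on an otherwise uniform-composition sequence, with
    accidental motif matches scrubbed so planted counts are exact.

    Returns ``(annotation, sequences, truth)`` where ``sequences`` maps
    chromosome -> uint8 array of ASCII bases.
    """
    elicitors = elicitors or ["flg22", "chitin", "nlp20", "pep2", "ina"]
    patterns = [c for c in elicitors if c != "ina"]
    seeds = _child_seeds(seed)
    rng = np.random.default_rng(seeds["genome"])

    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    sizes = {c: chrom_len for c in chroms}
    sequences = {c: BASES[rng.integers(0, 4, chrom_len)].copy() for c in chroms}

    # --- genes, laid end to end with randomized >=3 kb spacers
    genes: list[GenomicInterval] = []
    free: list[list] = []
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0)
                 for i in range(n_chroms)]
    gi = 0
    for chrom, n_on_chrom in zip(chroms, per_chrom):
        lengths = rng.integers(1000, 3001, n_on_chrom)
        slack = chrom_len - int(lengths.sum()) - 3000 * (n_on_chrom + 1)
        if slack < 0:
            raise PlacementError(f"{chrom}: cannot fit {n_on_chrom} genes with 3 kb spacers")
        extra = rng.multinomial(slack, np.full(n_on_chrom + 1, 1 / (n_on_chrom + 1)))
        pos = 0
        for k in range(n_on_chrom):
            gap_start = pos
            pos += 3000 + int(extra[k])
            if pos - gap_start > 3200:  # margin 1600 each side for enhancer placement
                free.append([chrom, gap_start + 1600, pos - 1600])
            strand = "+" if rng.random() < 0.5 else "-"
            gi += 1
            genes.append(GenomicInterval(chrom, pos, pos + int(lengths[k]),
                                         strand, f"gene_{gi:04d}"))
            pos += int(lengths[k])
        if chrom_len - pos > 3200:
            free.append([chrom, pos + 1600, chrom_len - 1600])

    # --- enhancers in intergenic free space
    enhancers: list[PlantedEnhancer] = []
    n_core = max(4, n_enhancers // 10)      # induced by every pattern elicitor
    n_down = max(4, n_enhancers // 8)       # repressed by flg22 (for up-vs-down contrasts)
    for k in range(n_enhancers):
        length = int(rng.integers(200, 601))
        chrom = chroms[k % n_chroms]
        start = _take(rng, free, chrom, length, margin=2000)
        iv = GenomicInterval(chrom, start, start + length, ".", f"enh_{k + 1:04d}")
        transcribed = bool(rng.random() < frac_transcribed)
        if transcribed:
            direction = ("bi" if rng.random() < frac_bidirectional
                         else ("uni+" if rng.random() < 0.5 else "uni-"))
            c = iv.center
            erna = GenomicInterval(chrom, c - erna_length // 2, c + erna_length // 2,
                                   ".", iv.name)
        else:
            direction, erna = "none", None
        induced, repressed = [], []
        if transcribed:
            if k < n_core:
                induced = list(patterns)
            elif k < n_core + n_down:
                repressed = ["flg22"]
            else:
                induced = [c for c in elicitors if rng.random() < 0.3]
        # W-box density: 3x in upregulated vs downregulated/background enhancers
        # (narrow uniform ranges keep the planted contrast tight at this n)
        want = int(rng.integers(2, 5)) if induced else int(rng.integers(0, 3))
        planted = _plant_wbox(rng, sequences[chrom], iv.start, iv.end, want)
        in_d = bool(rng.random() < 0.4)     # ~40% also in the DNase-style catalog
        in_a = bool(k % 10 != 9)            # every 10th enhancer is DNase-only
        if not in_a:
            in_d = True
        enhancers.append(PlantedEnhancer(iv.name, iv, in_a, in_d, transcribed,
                                         direction, induced, repressed, planted, erna))

    # scrub accidental W-boxes from a margin around enhancers so per-region
    # scans of slightly wider called intervals still agree with planted counts
    for e in enhancers:
        for s, t in ((e.interval.start - 200, e.interval.start),
                     (e.interval.end, e.interval.end + 200)):
            _plant_wbox(rng, sequences[e.interval.chrom], max(0, s), min(chrom_len, t), 0)

    # --- accessibility peaks: enhancers with in_a, plus proximal/genic decoys
    peaks: list[tuple[GenomicInterval, float]] = []
    distal_ids: list[str] = []
    for e in enhancers:
        if e.in_a:
            peaks.append((e.interval, 1.0))
            distal_ids.append(e.id)
    decoy_genes = rng.choice(len(genes), size=min(24, len(genes)), replace=False)
    for j, gidx in enumerate(decoy_genes):
        g = genes[gidx]
        if j % 2 == 0:  # proximal: spans the TSS flank
            tss = g.start if g.strand == "+" else g.end - 1
            lo = max(0, tss - int(rng.integers(300, 700)))
            iv = GenomicInterval(g.chrom, lo, lo + 400, ".", f"decoy_{j:03d}")
        else:           # genic: inside the gene body
            lo = g.start + int(rng.integers(0, max(1, g.length - 400)))
            iv = GenomicInterval(g.chrom, lo, lo + 400, ".", f"decoy_{j:03d}")
        peaks.append((iv, 1.0))

    # --- lncRNAs and blacklist features in remaining free space
    lncrnas, blacklist = [], []
    for j in range(4 * n_chroms):
        chrom = chroms[j % n_chroms]
        length = int(rng.integers(500, 1500))
        try:
            start = _take(rng, free, chrom, length, margin=1700)
        except PlacementError:
            break
        lncrnas.append(GenomicInterval(chrom, start, start + length,
                                       "+" if rng.random() < 0.5 else "-", f"lnc_{j:03d}"))
    for j in range(8 * n_chroms):
        chrom = chroms[j % n_chroms]
        length = int(rng.integers(80, 300))
        try:
            start = _take(rng, free, chrom, length, margin=1200)
        except PlacementError:
            break
        blacklist.append(GenomicInterval(chrom, start, start + length, ".", f"bl_{j:03d}"))

    # --- unmethylated regions: one around every transcribed enhancer, plus
    # standalone valleys exercising the missing-data bridging/splitting rules
    umrs: list[GenomicInterval] = []
    missing: list[GenomicInterval] = []
    bridged: list[str] = []
    split_pairs: list[tuple[str, str]] = []
    u = 0
    for e in enhancers:
        if not e.transcribed:
            continue
        u += 1
        lo = _snap(max(0, e.interval.start - 300), 100, up=False)
        hi = _snap(min(chrom_len, e.interval.end + 300), 100, up=True)
        umrs.append(GenomicInterval(e.interval.chrom, lo, hi, ".", f"umr_{u:04d}"))
    for j in range(6 * n_chroms):
        chrom = chroms[j % n_chroms]
        kind = j % 3
        try:
            if kind == 0:      # plain valley, 8 windows
                start = _snap(_take(rng, free, chrom, 1000, margin=600), 100, up=True)
                u += 1
                umrs.append(GenomicInterval(chrom, start, start + 800, ".", f"umr_{u:04d}"))
            elif kind == 1:    # valley with a 2/10-window low-coverage gap (<=33% -> bridged)
                start = _snap(_take(rng, free, chrom, 1200, margin=600), 100, up=True)
                u += 1
                name = f"umr_{u:04d}"
                umrs.append(GenomicInterval(chrom, start, start + 1000, ".", name))
                missing.append(GenomicInterval(chrom, start + 400, start + 600, ".", name))
                bridged.append(name)
            else:              # two 4-window valleys split by 5 missing windows (>33%)
                start = _snap(_take(rng, free, chrom, 1500, margin=600), 100, up=True)
                a_name, b_name = f"umr_{u + 1:04d}", f"umr_{u + 2:04d}"
                u += 2
                umrs.append(GenomicInterval(chrom, start, start + 400, ".", a_name))
                umrs.append(GenomicInterval(chrom, start + 900, start + 1300, ".", b_name))
                missing.append(GenomicInterval(chrom, start + 400, start + 900, ".", a_name))
                split_pairs.append((a_name, b_name))
        except PlacementError:
            break

    # --- induced genes (for DE + core-gene intersection)
    n_core_genes = max(4, len(genes) // 25)
    induced_genes: dict[str, list[str]] = {}
    order = rng.permutation(len(genes))
    for j in order[:n_core_genes]:
        induced_genes[genes[j].name] = list(patterns)
    for j in order[n_core_genes:n_core_genes + len(genes) // 5]:
        conds = [c for c in elicitors if rng.random() < 0.3]
        if conds:
            induced_genes[genes[j].name] = conds

    # --- coexpression modules: upregulated W-box enhancers + nearby genes;
    # gene-disjoint so between-module profiles stay independent, with skewed
    # module sizes emulating the hub structure of real coexpression networks
    module_sizes = [12, 8, 6, 5, 4, 3, 3, 2, 2, 2]
    modules = []
    used_genes: set[str] = set()
    for e in enhancers:
        if len(modules) >= len(module_sizes):
            break
        if not (e.induced_by and e.wbox_count >= 1):
            continue
        size = module_sizes[len(modules)]
        nearby = [g.name for g in genes
                  if g.chrom == e.interval.chrom
                  and e.interval.gap_to(g) <= 900_000
                  and g.name not in used_genes]
        if len(nearby) < size:
            continue
        pick = rng.choice(len(nearby), size=size, replace=False)
        chosen = [nearby[i] for i in pick]
        used_genes.update(chosen)
        modules.append({"enhancer": e.id, "genes": chosen, "r_target": 0.95})

    # --- a WRKY-family id list: TF genes drawn mostly from module/induced genes
    wrky_pool = sorted({g for m in modules for g in m["genes"]}
                       | set(list(induced_genes)[:10]))
    n_wrky = min(10, len(wrky_pool))
    wrky_genes = ([wrky_pool[i] for i in
                   rng.choice(len(wrky_pool), size=n_wrky, replace=False)]
                  if n_wrky else [])

    annotation = GenomeAnnotation(chrom_sizes=sizes, genes=genes, lncrnas=lncrnas,
                                  blacklist=blacklist)
    truth = SyntheticTruth(
        planted_peaks=peaks, distal_peak_ids=distal_ids, enhancers=enhancers,
        umrs=umrs, missing_regions=missing, bridged_umr_ids=bridged,
        split_umr_pairs=split_pairs, induced_genes=induced_genes,
        modules=modules, wrky_genes=wrky_genes, seeds=seeds,
    )
    return annotation, sequences, truth


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------


def generate_accessibility(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    background_rate: float = 0.02,
    fold: float = 12.0,
    seed: int | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Two pseudo-replicate Tn5 insertion-count tracks.

    Per-base counts are Poisson(background_rate) genome-wide and
    Poisson(fold x background_rate) inside planted peaks; replicates are
    independent draws from the same rate field.
    """
    seed = truth.seeds["atac1"] if seed is None else seed
    rate = {c: np.full(n, background_rate) for c, n in annotation.chrom_sizes.items()}
    for iv, peak_fold in truth.planted_peaks:
        rate[iv.chrom][iv.start:iv.end] = fold * peak_fold * background_rate
    reps = []
    for rep_seed in (seed, seed + 1):
        rng = np.random.default_rng(rep_seed)
        reps.append({c: rng.poisson(r).astype(np.int32) for c, r in rate.items()})
    return reps[0], reps[1]


def generate_stranded_rna(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    conditions: list[str] | None = None,
    background_rate: float = 0.002,
    erna_reads: float = 120.0,
    induction_fold: float = 4.0,
    uni_split: float = 0.95,
    gene_reads_mean: float = 200.0,
    seed: int | None = None,
):
    """Stranded RNA read-start coverage per condition, plus gene counts.

    Returns ``(tracks, gene_counts)`` where ``tracks[condition][strand]`` is a
    per-base count track and ``gene_counts`` is a genes x conditions frame of
    exact region read counts.  Planted eRNAs emit ``erna_reads`` expected
    reads in mock, split 50:50 (bi) or ``uni_split`` (uni) across strands and
    scaled by ``induction_fold`` in inducing conditions (divided by it in
    repressing ones); genes emit lognormal baseline counts on their own
    strand with the same induction scaling.
    """
    conditions = conditions or ["mock", "flg22", "chitin", "nlp20", "pep2", "ina"]
    seed = truth.seeds["rna"] if seed is None else seed
    rng = np.random.default_rng(seed)
    base_gene = {g.name: float(v) for g, v in
                 zip(annotation.genes,
                     rng.lognormal(np.log(gene_reads_mean), 0.6, len(annotation.genes)))}

    tracks: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    counts = pd.DataFrame(0, index=[g.name for g in annotation.genes],
                          columns=conditions, dtype=np.int64)
    for cond in conditions:
        rate = {s: {c: np.full(n, background_rate)
                    for c, n in annotation.chrom_sizes.items()}
                for s in "+-"}
        for e in truth.enhancers:
            if not e.transcribed:
                continue
            scale = 1.0
            if cond in e.induced_by:
                scale = induction_fold
            elif cond in e.repressed_by:
                scale = 1.0 / induction_fold
            total = erna_reads * scale / e.erna.length     # reads/bp over the footprint
            if e.direction == "bi":
                plus, minus = 0.5, 0.5
            elif e.direction == "uni+":
                plus, minus = uni_split, 1 - uni_split
            else:
                plus, minus = 1 - uni_split, uni_split
            sl = slice(e.erna.start, e.erna.end)
            rate["+"][e.erna.chrom][sl] += total * plus
            rate["-"][e.erna.chrom][sl] += total * minus
        for g in annotation.genes:
            scale = 1.0
            conds = truth.induced_genes.get(g.name, ())
            if cond in conds:
                scale = induction_fold
            rate[g.strand][g.chrom][g.start:g.end] += base_gene[g.name] * scale / g.length
        drawn = {s: {c: rng.poisson(r).astype(np.int32) for c, r in by_chrom.items()}
                 for s, by_chrom in rate.items()}
        tracks[cond] = drawn
        for g in annotation.genes:
            counts.loc[g.name, cond] = int(drawn[g.strand][g.chrom][g.start:g.end].sum())
    return tracks, counts


def generate_methylome(
    annotation: GenomeAnnotation,
    sequences: dict[str, np.ndarray],
    truth: SyntheticTruth,
    coverage_mean: float = 30.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-cytosine methylation calls as a (chrom, pos, context, meth, total) frame.

    Cytosines on both strands are located from the sequence; contexts are
    CG/CHG/CHH.  Depth is Poisson(coverage_mean) except inside planted
    low-coverage stretches (Poisson(2)); per-site methylation levels are Beta
    draws peaked at 0.8/0.4/0.1 by context outside planted UMRs and at 0.02
    inside, with read-level methylated counts Binomial(depth, level).
    """
    seed = truth.seeds["meth"] if seed is None else seed
    rng = np.random.default_rng(seed)
    if coverage_mean <= 0:
        return pd.DataFrame(columns=["chrom", "pos", "context", "meth", "total"])
    frames = []
    C, G = ord("C"), ord("G")
    for chrom in sorted(annotation.chrom_sizes):
        seq = sequences[chrom]
        n = seq.size
        # plus-strand cytosines: context read rightward
        plus = np.flatnonzero(seq[: n - 2] == C)
        nxt1, nxt2 = seq[plus + 1], seq[plus + 2]
        ctx_p = np.where(nxt1 == G, 0, np.where(nxt2 == G, 1, 2))
        # minus-strand cytosines (G on plus): context read leftward, complemented
        minus = np.flatnonzero(seq[2:] == G) + 2
        prv1, prv2 = seq[minus - 1], seq[minus - 2]
        ctx_m = np.where(prv1 == C, 0, np.where(prv2 == C, 1, 2))
        pos = np.concatenate([plus, minus])
        ctx = np.concatenate([ctx_p, ctx_m])
        order = np.argsort(pos, kind="stable")
        pos, ctx = pos[order], ctx[order]

        in_umr = np.zeros(n, dtype=bool)
        for iv in truth.umrs:
            if iv.chrom == chrom:
                in_umr[iv.start:iv.end] = True
        low_cov = np.zeros(n, dtype=bool)
        for iv in truth.missing_regions:
            if iv.chrom == chrom:
                low_cov[iv.start:iv.end] = True

        depth_mean = np.where(low_cov[pos], LOW_COVERAGE, coverage_mean)
        total = rng.poisson(depth_mean)
        mean = np.choose(ctx, [METH_MEANS["CG"], METH_MEANS["CHG"], METH_MEANS["CHH"]])
        mean = np.where(in_umr[pos], UMR_METH_MEAN, mean)
        level = rng.beta(BETA_CONCENTRATION * mean, BETA_CONCENTRATION * (1 - mean))
        meth = rng.binomial(total, level)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "context": pd.Categorical.from_codes(ctx, ["CG", "CHG", "CHH"]),
            "meth": meth, "total": total,
        }))
    return pd.concat(frames, ignore_index=True)


def generate_coexpression(
    truth: SyntheticTruth,
    feature_ids: list[str] | None = None,
    n_samples: int = 12,
    r_target: float = 0.95,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Features x samples expression with planted coexpression modules.

    Members of one planted module share a standard-normal latent profile plus
    independent Gaussian noise; with latent variance 1 and noise variance s²,
    the expected pairwise Pearson r is 1/(1+s²), so ``noise_sd`` defaults to
    ``sqrt(1/r_target - 1)``.  All other features are independent noise.
    """
    if not 0 < r_target < 1:
        raise ValueError("r_target must be in (0, 1)")
    seed = truth.seeds["coexpr"] if seed is None else seed
    rng = np.random.default_rng(seed)
    if noise_sd is None:
        noise_sd = float(np.sqrt(1 / r_target - 1))
    if feature_ids is None:
        feature_ids = [e.id for e in truth.enhancers if e.transcribed]
        feature_ids += [m["enhancer"] for m in truth.modules]
        feature_ids += sorted({g for m in truth.modules for g in m["genes"]})
        seen = set()
        feature_ids = [f for f in feature_ids if not (f in seen or seen.add(f))]
    data = rng.normal(0, 1, (len(feature_ids), n_samples))
    index = {f: i for i, f in enumerate(feature_ids)}
    for m in truth.modules:
        latent = rng.normal(0, 1, n_samples)
        for f in [m["enhancer"], *m["genes"]]:
            if f in index:
                data[index[f]] = latent + rng.normal(0, noise_sd, n_samples)
    return pd.DataFrame(data, index=feature_ids,
                        columns=[f"s{i + 1:02d}" for i in range(n_samples)])


# ---------------------------------------------------------------------------
# orchestration + serialization
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """Everything one simulation produced, in memory."""

    annotation: GenomeAnnotation
    sequences: dict[str, np.ndarray]
    truth: SyntheticTruth
    atac_rep1: dict[str, np.ndarray]
    atac_rep2: dict[str, np.ndarray]
    rna: dict[str, dict[str, dict[str, np.ndarray]]]   # condition -> strand -> chrom
    gene_counts: pd.DataFrame
    methylome: pd.DataFrame
    coexpression: pd.DataFrame
    conditions: list[str]


def simulate(seed: int = 0, params: dict | None = None) -> SyntheticDataset:
    """Run every generator with one master seed and the default study design."""
    p = defaults("simulate")
    p.update(params or {})
    annotation, sequences, truth = generate_genome(
        n_chroms=p["n_chroms"], chrom_len=p["chrom_len"], n_genes=p["n_genes"],
        seed=seed, n_enhancers=p["n_enhancers"], elicitors=p["elicitors"],
        frac_transcribed=p["frac_transcribed"],
        frac_bidirectional=p["frac_bidirectional"], erna_length=p["erna_length"],
    )
    rep1, rep2 = generate_accessibility(
        annotation, truth, p["atac_background"], p["atac_fold"])
    conditions = ["mock", *p["elicitors"]]
    rna, gene_counts = generate_stranded_rna(
        annotation, truth, conditions, p["rna_background"], p["erna_reads"],
        p["induction_fold"], p["uni_split"])
    methylome = generate_methylome(annotation, sequences, truth, p["meth_coverage"])
    coexpr = generate_coexpression(truth, n_samples=p["coexpr_samples"],
                                   r_target=p["coexpr_r"])
    return SyntheticDataset(annotation, sequences, truth, rep1, rep2, rna,
                            gene_counts, methylome, coexpr, conditions)


def write_fasta(path, sequences: dict[str, np.ndarray], width: int = 60) -> None:
    with open(path, "w") as handle:
        for chrom in sorted(sequences):
            handle.write(f">{chrom}\n")
            text = sequences[chrom].tobytes().decode()
            for i in range(0, len(text), width):
                handle.write(text[i:i + width] + "\n")


def write_dataset(dataset: SyntheticDataset, outdir) -> Path:
    """Serialize a dataset to plain-text files (FASTA/GFF3/BED/bedGraph/TSV/JSON)."""
    from .intervals import write_bedgraph, write_chrom_sizes

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "genome.fa", dataset.sequences)
    write_gff3(out / "annotation.gff3", dataset.annotation)
    write_chrom_sizes(out / "genome.chrom.sizes", dataset.annotation.chrom_sizes)
    dataset.truth.save(out / "truth.json")
    write_bed(out / "truth_enhancers.bed",
              [e.interval.with_name(e.id) for e in dataset.truth.enhancers])
    write_bed(out / "truth_umrs.bed", dataset.truth.umrs)
    write_bedgraph(out / "atac_rep1.bedgraph", dataset.atac_rep1)
    write_bedgraph(out / "atac_rep2.bedgraph", dataset.atac_rep2)
    for cond, by_strand in dataset.rna.items():
        write_bedgraph(out / f"rna_{cond}_plus.bedgraph", by_strand["+"])
        write_bedgraph(out / f"rna_{cond}_minus.bedgraph", by_strand["-"])
    dataset.gene_counts.to_csv(out / "gene_counts.tsv", sep="\t")
    dataset.methylome.to_csv(out / "methylome.tsv", sep="\t", index=False)
    dataset.coexpression.to_csv(out / "coexpression.tsv", sep="\t")
    return out
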