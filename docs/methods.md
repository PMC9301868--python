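# Methods

This note documents the models and procedures implemented in `ernascape`,
the parameters that matter, what the synthetic benchmark does and does not
emulate, and the choices made where the design was genuinely open.

## Coordinate and data model

All coordinates are 0-based half-open (BED convention) internally; GFF3 is
converted on read/write.  An interval "center" is `floor((start+end)/2)`,
so even-length regions anchor to the lower of the two middle bases, and
nearest-neighbor ties resolve toward the smaller coordinate.  Coverage
tracks are dense per-base event counts (Tn5 insertions; RNA read 5′ ends),
so window sums are exact event counts and Poisson tail tests apply without
fragment-length corrections.

## Accessibility peaks

Candidate regions come from a Poisson window segmentation: 200-bp windows
at 100-bp steps are tested against the genome-average rate
(upper tail, BH-adjusted, q < 0.01) and merged.  Any reasonable enrichment
seeder would do here — the result is dominated by the refinement, which is
the procedure of record: 50-bp windows at 25-bp steps, per-window
integration frequency normalized to the genome-average per-window
frequency, windows at or above the cutoff (default 2×, configurable — no
canonical value exists for this cutoff) merged across gaps ≤ 150 bp,
regions supported by a single window removed (every peak is > 50 bp), and
the summit at the per-base argmax with ties to the smaller coordinate.
Organellar chromosomes (default deny-list `Mt, Pt, ChrM, ChrC`) are
skipped.  Replicate consensus is *reciprocal* 50% overlap (both fractions
≥ 0.5); a one-sided mode is available by flag.  Distal classification uses
the peak center, strictly more than 1500 bp from every TSS, and no
gene-body overlap; whether lncRNA loci also disqualify a peak at this step
is exposed as a flag (default off — lncRNAs are only excluded later, at
the transcript-region filter).

## Enhancer library

The ATAC-derived distal set is kept wholesale.  A DNase-derived record is
added only when it has < 50% reciprocal overlap with *every* A record;
redundancy is judged against the A set only, never against already-retained
D records, and a single qualifying A both discards the D and relabels that
A as `A+D`.  IDs are assigned by source and genome order and are stable
under re-run.

## eRNA quantification and directionality

Transcript regions: midpoint ± 500 bp for enhancers under 1 kb (clamped to
chromosome bounds), the enhancer's own span otherwise.  Regions touching a
gene or lncRNA extended by 1 kb on both ends, or any blacklist feature
(miRNA, piRNA, tRNA, sno/snRNA, rRNA, repeats; no extension), are removed.
TPM is computed per condition jointly over genes and surviving enhancer
regions: `TPM_i = (c_i/l_i) / Σ_j(c_j/l_j) × 10⁶`.

"Detectable expression" requires, *within a single condition*, both the
region count ≥ 5 and TPM ≥ 0.1 (defaults, configurable).  Requiring the
pair in the same sample prevents sparse background reads spread over many
libraries from summing past the count floor.

The eRNA caller tests 100-bp windows at 25-bp steps per strand against a
Poisson null at the track's genome-average rate (p < 10⁻³), merges
enriched windows across gaps ≤ 100 bp, intersects with transcript regions,
and drops calls under 100 bp.  Two numerical details:

- **Boundary trimming.**  A 100-bp window passes on partial overlap with a
  strong transcript, so raw merged calls overhang the true footprint by up
  to a window on each side.  Calls are trimmed to the outermost 25-bp
  sub-bin that is itself enriched at the same p-value, bringing edge
  resolution down to the step size.
- **Overdispersion guard.**  The Poisson null is correct for a quiet floor
  with sparse signal.  When the genome-wide window-sum distribution has a
  nonzero median and a robust variance (quantile-spread, (q90−q50)/1.2816
  squared) above the mean — the signature of a homogeneous but heavy-tailed
  background, e.g. a permuted structured track — the tail switches to a
  Gamma–Poisson with those moments.  On genuinely Poisson tracks the robust
  variance matches the mean and nothing changes.

Directionality is an exact two-sided binomial test of summed sense vs
antisense counts (pooled over conditions) at α = 0.05.  A unidirectional
call additionally requires the minority strand to carry ≤ 25% of reads: at
high depth an α-level test rejects perfect balance on trivially small
asymmetries, and an enhancer with hundreds of reads on each strand is
bidirectional regardless of statistical imbalance.  All small-count
behaviour (50/50 → bi; 10/0 → uni; 5/2 → bi; 0/0 → none; reads confined to
one strand but short of significance → none) is unaffected by the gate.
The 25-bp strand window profile is retained for inspection; a window-level
test mode exists behind a flag but totals are the default.

## Differential transcription

One pooled library per condition leaves no dispersion to estimate, so a
dispersion-based count model is not applicable; significance comes from
the conditional binomial test: given `n = count_mock + count_elicitor`,
the elicitor count is Binomial(n, libsize_e/(libsize_m+libsize_e)) under
the null.  Fold changes are library-size-normalized with pseudocount 1.
Enhancers: |log2FC| ≥ 1 ("at least one-fold change" read as two-fold,
matching the volcano axes) with an FDR < 0.05 gate on by default (flag to
disable for strict mimicry of a fold-change-only call).  Genes: two-fold
and FDR < 0.05.  Library size defaults to the total counts over all
quantified features per sample.  BH adjustment is the standard step-up
with monotonicity enforcement, cross-checked in the tests against an
independent implementation.

## Unmethylated regions

Non-overlapping 100-bp windows.  Coverage is the *mean per-cytosine depth*
in the window — a 10× rule could also be read per-site, but mean depth is
less brittle at low site counts: < 10× (or no cytosines) → missing.  Otherwise the methylation fraction pools all
three contexts by counts (Σmeth/Σtotal over CG+CHG+CHH): < 10% →
unmethylated, else methylated — both thresholds strict in the stated
direction.  Runs of adjacent unmethylated windows are merged; runs
separated only by missing windows are bridged left-to-right, greedily and
re-scanned to fixpoint, whenever the prospective merged region stays at or
below 33% missing windows (merge order is otherwise unspecified; greedy
left-to-right is deterministic and order-independent at fixpoint for
non-adjacent gaps).  Regions strictly longer than 300 bp are UMRs.
Classification is hierarchical: proximal when any part is within 1500 bp
of a TSS, else genic on gene-body overlap, else distal.  The per-class
summary emits both count-weighted and length-weighted proportions, since
either reading of a per-class genome proportion is defensible.

## W-box scanning and enrichment

Exact-word scanning for TTGACC/TTGACT plus (default, flag to disable)
their reverse complements GGTCAA/AGTCAA reported as minus-strand hits at
their forward-strand footprint; overlapping occurrences all count and `N`
never matches.  Per-set summaries average occurrences per 100 regions;
enrichment between two sets uses presence/absence in a two-sided Fisher
exact test, with a 0.5 Haldane correction applied to the odds ratio only.
Rank-based motif-database enrichment is out of scope — the exact-word scan
plus the two-set Fisher test are what the downstream network filter and
the density comparisons require.

## Coexpression networks and the iGRN

Edges connect features with |r| at or above the threshold (sign kept on
the edge; negative correlations are not treated specially).  The
scale-free criterion fits OLS of log P(k) on log k over k ≥ 1, where P(k)
includes isolated nodes in its denominator but k = 0 cannot enter the log
fit; R² is forced to 0 when log P(k) is flat (a constant distribution
carries no power-law signal).  `select_threshold` returns the smallest
candidate reaching R² ≥ 0.95, else the best candidate with a
non-convergence flag.  The pipeline uses the selected threshold when the
criterion converges and otherwise falls back to the conventional direct
cutoff r = 0.95 — planted clique modules produce near-uniform degree
distributions that no power law fits, and an unconverged "best R²" is an
arbitrary number; the fallback and flag are both logged.  The iGRN keeps
upregulated enhancers with ≥ 1 W-box, connects them to genes whose
intervals lie within 1 Mb (gap ≤ 1,000,000 inclusive; 0 when overlapping),
builds enhancer–gene edges only (enhancer–enhancer and gene–gene pairs are
not linked), and flags WRKY-family genes from a user-supplied id list.

## Core pattern-induced sets

Per-elicitor upregulated id sets are intersected exactly over the four
pattern elicitors (flg22, chitin, nlp20, pep2); the hormone-analog
condition (INA) is carried as an ordinary condition but excluded from the
pattern core by default.  Nearest genes minimize the interval gap with
ties to the smaller gene start.

## Synthetic benchmark

Default scale: 2 chromosomes × 2 Mb, 200 genes (1–3 kb, ≥ 3 kb spacers),
120 enhancers (200–600 bp) in intergenic space far enough from genes that
their transcript regions clear the 1-kb extension filter, 5 elicitor
conditions + mock, 12 coexpression samples.  This size runs the full
pipeline in seconds while leaving every stage statistically non-trivial.

Planted structure and the signal parameters that define the study
conditions:

- **Accessibility**: per-base Poisson, background 0.02 insertions/bp, 12×
  inside planted peaks, two independent replicates.  Decoy proximal and
  genic peaks exercise the distal classifier.
- **RNA**: stranded read-start Poisson tracks; intergenic background
  5×10⁻⁴ reads/bp/strand per library (roughly one read per kb per strand —
  rRNA-depleted intergenic space is very quiet at ordinary depth); planted
  200-bp eRNAs emit 120 expected reads in mock, split 50:50 (bidirectional,
  65% of transcribed enhancers) or 95:5 (unidirectional — 95:5 rather than
  100:0 so the binomial test is exercised non-degenerately); 4-fold
  induction in eliciting conditions, 4-fold repression for a planted
  downregulated class; genes draw lognormal baselines around 200 reads.
- **Methylome**: per-cytosine depth Poisson(30×); Beta-distributed site
  levels peaked at 0.8/0.4/0.1 (CG/CHG/CHH) outside planted UMRs and 0.02
  inside; planted low-coverage stretches (2× depth) create ≤ 33% missing
  gaps inside some UMRs (must be bridged) and > 33% stretches between
  planted pairs (must stay split).
- **W-boxes**: accidental motif matches are scrubbed from enhancers and a
  200-bp margin, then exact counts are planted — 2–4 per upregulated
  enhancer, 0–2 otherwise (a 3× density contrast with low variance at this
  n).  Planted counts therefore equal scan counts exactly, which the tests
  exploit as a cross-module consistency check.
- **Coexpression**: module members share a latent standard-normal profile
  plus Gaussian noise with `sd = sqrt(1/r − 1)`, giving expected pairwise
  Pearson r = 0.95; modules are gene-disjoint (so between-module profiles
  are independent) with skewed sizes (12 down to 2 genes) emulating hub
  structure.

Every generator is a pure function of its parameters and a seed; per-track
seeds derive from one master seed and are serialized with the truth (JSON
plus BED sidecars).

**What the benchmark does not emulate** — and hence what passing tests do
not show about real data: read-level errors and mapping ambiguity, Tn5
sequence bias, fragment-length structure, splicing, genome-scale repeat
content, realistic methylation mosaicism, batch effects, and biological
dispersion beyond Poisson counting noise.  Recovery rates here measure the
correctness of the procedures under their own model assumptions, not
expected performance on sequencing data.

## Known limitations

- The no-replicate binomial test is anti-conservative under biological
  overdispersion; with replicates, a dispersion-based model should replace
  it upstream of `call_de`.
- TPM thresholds calibrated for transcriptome-scale feature sets are
  nearly vacuous on small synthetic feature sets; the per-condition
  count+TPM conjunction carries the real weight of the detectability call.
- The scale-free criterion rarely converges on clique-structured
  expression data (see above); the logged fallback keeps runs comparable.
- Interval operations are plain sorted-array scans — linear in feature
  count per query set, entirely adequate at these scales but not indexed
  for whole-mammalian-genome catalogs.
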