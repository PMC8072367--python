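# Methods

## The screening model

The screen assumes that enhancers of a target gene (i) lie within the
gene's topologically associated domain, taken as an input interval, not
computed; (ii) are deeply conserved, visible as runs of high per-base
conservation posterior; and (iii) leave epigenomic footprints (open
chromatin, promoter contact, active-enhancer histone marks, TF binding)
catalogued in interval form. None of these assumptions is enforced by
data checks — they define what the pipeline looks for.

All internal coordinates are 0-based half-open (BED-native). Printed
browser spans are converted once, at the parse boundary, under an
explicit dialect flag (`ucsc1` = 1-based inclusive, `bed0` = half-open)
because published coordinate spans do not declare their convention; no
dialect is ever assumed silently.

### Conserved element calling

A base is *good* when its score is ≥ `threshold` (inclusive — a base at
exactly the cutoff qualifies) and outside the exon mask. Elements are
maximal runs of good bases that may bridge interior stretches of
*missing* data up to `max_gap` bp. Three semantic decisions that the
run/threshold language of such screens usually leaves open are fixed
here:

* **Only missing data is bridgeable.** A sub-threshold score is
  evidence against conservation and always breaks a run; an uncovered
  base is absence of evidence. The two are distinct track states (NaN
  vs a number), never conflated with 0.0.
* **Gaps are interior-only and count toward length but not score.**
  Elements start and end on good bases; `mean_score` averages covered
  bases only; `n_gap_bases` reports the bridged span.
* **Exon bases are hard breaks applied before length filtering** — a
  3 bp exon splits a run even when `max_gap` is 10 — because excluding
  coding sequence means removing those bases from consideration
  entirely, not tolerating them.

Maximality means not contained in any longer legal run. Note that the
*number* of called elements is monotone only in `min_length` (a pure
filter). It is **not** monotone in `threshold` (raising it can split
one long element into two) nor in `max_gap` (raising it can fuse two
elements across a gap); the tests assert the true invariant only.

Defaults: `threshold` 0.98 (probability), `min_length` 50 bp,
`max_gap` 10 bp. The first two are the screen's published operating
point; the gap tolerance is a declared parameter of this
implementation — the original spelled out no number — and every
recovery property is stated relative to the declared rule.

### Prioritization

Per-track overlap is the unioned intersected length in bp (self-
overlapping peaks in one track are not double counted); an element is
priority when ≥ 1 track overlaps by ≥ `min_overlap` (default 1 bp,
since the screen's published criterion is bare "overlap"). Ranking is
by distinct-track count, descending, ties by (chrom, start) only, so
output order is deterministic. Evidence sets carrying different
declared assemblies are refused unless `assume_same_space` is set: the
tool will not guess how cross-genome evidence was projected.

### Window construction

Each priority kernel expands symmetrically about its midpoint to
`target_length` (default 1,000 bp, the floor of the screen's 1,000 to
1,500 bp window range — the least-assumption reading of "expanding" a
kernel); kernels already longer are kept as-is up to `max_length`
(1,500 bp; a longer kernel passes through with a warning). Windows
clipped at the TAD boundary push the deficit to the opposite side.
Merging unions windows sharing ≥ 1 bp, transitively; abutting windows
stay separate ("overlapping" read literally); merged unions are not
re-clipped to `max_length`. Candidate ids are ordinals in genomic
order.

## Motif scoring

PFM → PWM uses background-distributed pseudocounts with total
`pseudocount` 0.8 and uniform background by default — a common
convention in the JASPAR tool ecosystem, declared here so scores are
reproducible even where they differ in absolute value from any
database-reported number. Since databases print matrix scores on
shifting scales, the cross-species *rank order* of relative scores —
not any absolute score — is the reproducible surface, and the relative
score is invariant under affine rescaling of the raw log-odds by
construction. Windows containing N are voided rather than scored at
background. Minus-strand scores are plus-strand scores of the reverse
complement, reported at the window's query offset. A uniform
(information-free) matrix defines every site as maximal (rel = 1.0)
rather than dividing by zero.

Variant application is sequential: each edit's position refers to the
sequence as it stands, so insertion/deletion inverses compose to the
identity and recorded variant lists replay exactly.

## Assay formulas

All assay computations are closed forms over tidy tables; the
statistical wrappers delegate to scipy (`f_oneway`, `tukey_hsd` with
its single pooled variance, `ttest_ind` two-sided) and exist to fix the
contracts: technical replicates are averaged before any
biological-replicate statistic (the aggregation order such legends
leave unstated), no outlier removal anywhere, degenerate zero-variance
designs raise instead of returning NaN. Percent input may exceed 100 —
a property of 100 × 2^(ΔCt), not an error. Luciferase folds are
computed per experiment then pooled when an experiment column is
present (switchable via `per_experiment`).

## What the generator emulates — and does not

The screen fixture plants, by default, the study-scale conditions: an
880 kb TAD, 209 conserved blocks of 50–250 bp, 41 of them carrying
evidence spread over six labelled tracks with one designated element
hitting all six, plus exon-covered decoy blocks that must be excluded
and evidence decoy peaks that never touch a non-priority element.
Background scores are drawn strictly below `threshold − 0.01` so no
boundary base is ambiguous; boundary semantics (a block at exactly
0.98, a gap of exactly `max_gap`) are tested deterministically instead.
A fraction of inter-element gaps is drawn short enough that expanded
windows of neighbouring kernels must merge, so the merge stage is
always exercised. Truth manifests (expected elements, priority ids,
merged windows) are computed inside the generator by direct arithmetic
and pairwise union-find — independent of the pipeline under test.

The generator does **not** simulate phastCons autocorrelation beyond
block structure, alignment-depth-dependent missingness, peak-calling
noise, or sequence evolution along a phylogeny. Passing tests
demonstrate that the pipeline implements its declared rules exactly on
unambiguous signals; they do not certify behaviour on marginal
real-track features (scores hovering at the cutoff, ragged block
edges), which the boundary tests probe only pointwise.

The motif fixture greedily walks single-base substitutions from the
consensus until the planted site is within `tolerance` (default 0.05)
of its target relative score, erroring when a target is unreachable;
the synthetic GC-box matrix is deliberately soft (all four bases
represented in every column) so the walk has fine steps. The derived
species carries exactly 12 recorded variants — 2 single-base flank
insertions plus 10 substitutions (site edits padded with neutral flank
edits) — so haplotype-reconstruction round-trips exercise both edit
types. The assay fixture plants, by default, a 13-fold human luciferase
induction (2.6× and 1.4× over the chimpanzee and macaque orthologs), a
1.6× allelic imbalance, antibody-vs-IgG percent-input contrasts, and a
17% gland-count increase, under multiplicative log-normal noise
(`noise_sd`, default 0.05) — chosen as a realistic few-percent
coefficient of variation for replicate luminescence and qPCR ratios.
The noiseless limit recovers the continuous effects exactly; gland
counts are integers, so their planted effect is recovered only up to
rounding, which washes out at cohort scale.

## Problem sizes and numerical choices

The test suite checks segmentation against a brute-force enumerator on
200 random tracks up to 10 kb (and an exhaustive all-pairs enumerator
at ≤ 60 bp), prioritization against all-pairs overlap on 100 elements ×
6 tracks × 50 seeds, window algebra on 1,000 random sets, motif
scanning against exhaustive per-window scoring on 100 random 60-mers,
and allelic-imbalance recovery over 1,000 simulated three-replicate
experiments (tolerance ±5%, which covers the ~0.1% log-normal mean
bias at the default noise plus Monte-Carlo error). The acceptance
script reuses these sizes; the gland-count contrast is measured on 400
animals per group so integer rounding contributes < 1 percentage
point. All randomness flows from explicit seeds; fixture files
regenerate byte-identically, and a screen re-run from its archived
config snapshot reproduces outputs byte for byte (evidence tracks are
processed in sorted-label order for exactly this reason).

## Known limitations

* No liftover: all inputs must already share one coordinate space, and
  the prioritizer's refusal of mixed declared assemblies is the only
  guard.
* bigWig tracks are not read directly; convert to bedGraph/wiggle.
  The wiggle reader handles fixedStep/variableStep with span.
* The caller scales linearly in TAD length in memory (one float per
  base); chromosome-scale regions are fine, whole-genome scans are out
  of scope.
* `compare_orthologs` scores anchored, gapless sites; it does not
  align orthologs, and indel-containing sites must be resolved by the
  caller.
* The statistical wrappers cover exactly the designs used here
  (one-way ANOVA + Tukey, two-sample t); they are not a general
  modelling layer.
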