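# ece-screen

A reusable implementation of a conservation-based enhancer candidate
screen — the computational strategy used to discover distal regulatory
elements of a developmental gene (the motivating case is *EN1*, whose
ectodermal dose controls eccrine sweat gland density) — together with
the cross-species motif-affinity comparison and the closed-form assay
statistics used to validate such candidates.

It is aimed at regulatory-genomics researchers who want the screen's
rules to be explicit, parameterized, and testable rather than buried in
a one-off analysis.

## What it computes

**The screen** restricts attention to a topologically associated domain
(TAD) and proceeds in three stages:

1. **Conserved element calling.** A per-base conservation-probability
   track (phastCons-style posterior, read from bedGraph or wiggle) is
   segmented into maximal runs of bases with probability ≥ *t*
   (default 0.98, inclusive) of length ≥ *ℓ* (default 50 bp). Coding
   exon bases are hard breaks; interior stretches of *missing* data up
   to *g* bp (default 10) are bridged, but sub-threshold scores never
   are. Missing data (no track coverage) is first-class and distinct
   from a low score.
2. **Evidence prioritization.** Elements are annotated with their
   overlap (in bp) against any number of labelled evidence interval
   sets — DNase hypersensitivity, Capture-C, H3K27ac ChIP-seq peaks,
   accelerated-region catalogs, TF ChIP peaks — and an element is
   *priority* if it overlaps ≥ 1 track by ≥ 1 bp (both configurable).
   Ranking is by the number of distinct tracks hit.
3. **Window construction.** Each priority element is a kernel expanded
   symmetrically about its midpoint to a 1,000 bp test window (capped
   at 1,500 bp, clipped to the TAD with opposite-side compensation);
   transitively overlapping windows are unioned into candidate
   enhancers, named in genomic order.

**Motif affinity across species.** A JASPAR-format position frequency
matrix is converted to a log₂-odds PWM with background-distributed
pseudocounts,

    w(b, i) = log2( (n(b,i) + p·q(b)) / (N(i) + p) / q(b) ),

and windows are scored on both strands. Scores are reported on the
relative scale rel = (raw − min) / (max − min) ∈ [0, 1], where 1.0 is
the consensus site, so orthologous sites of a transcription factor
(e.g. an SP1 GC-box) can be ranked across species. In-silico
mutagenesis (`apply_variants`) rebuilds derived/ancestral haplotypes
from substitution and indel lists.

**Assay statistics.** ChIP-qPCR enrichment as percent input,
100 × 2^(Ct(input) − Ct(IP)); dual-luciferase fold induction (Firefly /
Renilla, then fold over the empty-vector control mean); allele-specific
expression as the cDNA allelic ratio normalized to the genomic-DNA
ratio; eccrine gland counts averaged over left/right forelimbs; and
one-way ANOVA + Tukey or two-tailed t contracts over scipy.

**Synthetic data.** Every input the pipeline reads can be generated
with planted ground truth (`ece_screen.synthetic_data`), so the whole
funnel is testable end-to-end without downloading any genomic dataset.
Truth manifests are computed by independent brute-force oracles, never
by the pipeline itself.

## Worked example

Generate a study-scale fixture (880 kb TAD, 209 planted conserved
blocks, 41 carrying evidence across six tracks) and run the screen:

```
$ ece-screen make-fixture screen --seed 7 --outdir fixture
planted_elements        209
planted_priority        41
expected_windows        31

$ ece-screen run --config run.yaml
elements_called         209
priority_selected       41
windows_after_merge     31
```

where `run.yaml` points at the fixture's track, exon mask and six
evidence BEDs. The run directory then contains the full funnel:

```
$ head -3 screen_out/elements.bed
chr2    118002770       118003009       CE1     990     .
chr2    118007653       118007828       CE2     991     .
chr2    118013183       118013370       CE3     990     .

$ head -2 screen_out/windows.bed
chr2    118033585       118035362       ECE1    CE7,CE8
chr2    118106624       118107624       ECE2    CE26
```

209 conserved elements were called (BED score = 1000 × mean
conservation), 41 were selected on evidence overlap, and their 1 kb
windows merged into 31 candidate enhancers — ECE1 is a 1,777 bp union
of two overlapping kernels, ECE2 a single-kernel 1,000 bp window. The
counts and every interval match the fixture's truth manifest exactly,
and re-running from `screen_out/config_snapshot.yaml` reproduces every
output byte for byte.

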