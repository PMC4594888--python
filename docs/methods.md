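# Methods

This note documents the models and conventions behind degradome-kit:
what each stage computes, the knobs that matter, what the synthetic
generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## The observable: 5′-end signal profiles

A PARE tag is the 5′ signature of an uncapped, polyadenylated RNA
fragment. The toolkit models tags as exactly 20 nt (`SimConfig.tag_length`
is configurable): the analysable object is the 5′-end coordinate, and
the read tail beyond the signature carries no extra information here.
Tags are mapped to the transcriptome on the sense strand with at most
`max_mismatch` substitutions (default 1), by pigeonhole seeding with
verification; an exhaustive all-positions scan is kept as a test
oracle. Mapping to transcripts rather than a genome is a deliberate
simplification: on intron-free synthetic data the end result is
identical, and it avoids carrying a spliced aligner.

A tag matching k loci contributes mass 1/k of its copy number at each
locus, so total profile mass equals matched tag copies exactly — an
invariant asserted in tests. Degradation level is RPM (mass × 10⁶ /
matched tag copies; with a transcriptome-wide mapping universe the
"total mapped" denominator equals the matched copies, a convention the
pipeline logs). Transcription level is FPKM = count /((length/10³) ×
(total/10⁶)). Replicates are averaged after a QC check: squared
Pearson correlation of log₂(value+1) between replicates (mean of
pairwise r² beyond two replicates).

## Two-library differential test

Both layers are tested under a random-sampling null: a gene's count is
a binomial draw from the library total with a gene-specific
proportion. The pooled two-proportion z-test is used; it agrees in
accept/reject decisions with the exact conditional binomial
(c₁ | c₁+c₂ ~ Bin(t, n₁/(n₁+n₂))) for ≥ 99% of genes once pooled
counts reach 20, which the acceptance benchmark measures. Genes with
no counts in either library carry no evidence (p = 1). Adjustment is
Benjamini–Hochberg (the step-up construction is unit-tested against
hand-computed vectors and statsmodels).

Fold changes are log₂((t+ε)/(c+ε)) on library-size-normalised counts
with pseudo-abundance ε = 0.5, keeping zero-count genes finite.
Replicate counts are pooled per condition before testing; RPM means
are what get reported. Status calls: up (log₂FC ≥ 1, adjusted
p < 0.001), down (≤ −1, p < 0.001), unchanged (|log₂FC| < 1,
p > 0.001). The threshold grid leaves cells covered by neither rule —
significant-but-small changes, large-but-unsupported changes, and
p exactly at the threshold — which are called `ambiguous` and excluded
from class assignment rather than silently folded into a category.

Limitations: this test models sampling noise only. On counts with
biological overdispersion it is anti-conservative (the variance
inflation factor is 1 + φ·m for NB dispersion φ and mean m); it is the
appropriate test for technical-replicate-level comparisons, and the
generator's defaults reflect that (below). Dispersion-aware NB tests
are out of scope.

## The nine-class grid and decay types

Genes called in both layers occupy a 3×3 grid of (D status,
R status). The letter layout is row-major — rows D up/unchanged/down,
columns R down/unchanged/up — giving A=(D↑,R↓) … I=(D↓,R↑) with E the
doubly-unchanged centre. This layout is a documented convention chosen
to satisfy all the semantic constraints of the type mapping:
concordant cells {C,G} are type I, degradation-only {B,H} type II,
discordant {A,I} type III, transcription-only {D,F} type IV, and E
maps to no type. The constraints are enforced by exhaustive
enumeration in the test suite. Genes detected in only one layer are
excluded from classification and reported separately, as are
ambiguous genes.

The uncapped/total abundance ratio (RPM/FPKM per gene) supports
comparisons of degradation load between gene sets; groups are compared
by two-sided Mann–Whitney U, and genes with FPKM = 0 are excluded and
counted.

## Sequence features

Per-transcript features: region lengths from coordinates, GC by
counting, intron counts from the annotation, and MFEI = MFE/length ×
100/GC% per region (full mRNA, 5′UTR, 3′UTR). Missing UTRs yield
missing features, never zeros. Group comparisons use the two-sided
Mann–Whitney U (the field's usual choice for these skewed length
distributions); random control sets are size-matched to the mean of
the type-group sizes and drawn without replacement from a seeded
generator.

Folding is an injectable backend. The ViennaRNA thermodynamic engine
is used when importable. The built-in fallback is a Nussinov-style
base-pair maximisation (−1 per canonical pair including G:U wobble,
hairpin loops ≥ 3 nt, vectorised O(n³) dynamic program); it is *not* a
thermodynamic energy and is labelled as such in output, but it is
exactly reproducible and is verified against an independent
exhaustive backtracking enumeration of all non-crossing pairings for
short sequences. Because both engines are cubic in length, the
pipeline folds regions up to `fold_max_len` (default 500 nt — UTRs
fold, multi-kilobase mRNAs are skipped with MFEI missing); callers
wanting full-mRNA MFEI raise the cap and pay the time.

## miRNA target identification

Candidates are gapless antiparallel duplexes between a mature miRNA
and every same-length transcript window: penalty 0 for Watson–Crick,
0.5 for G:U, 1 otherwise, doubled at miRNA positions 2–13; windows
scoring ≤ `max_score` (default 4.0) are kept. These are the standard
plant degradome-tool conventions and every threshold is configurable.
Gapless-only alignment is a documented limitation (bulged sites are
rare among validated plant targets).

RISC cleaves between the target nucleotides paired to miRNA bases 10
and 11; the 3′ fragment's first nucleotide — where a PARE tag 5′ end
lands — is the position paired with base 10, so for a site whose
window starts at s the slice coordinate is s + L − 10. A candidate
becomes a hit when profile mass at the slice coordinate
(± `offset_tolerance`, default 0) reaches `min_reads` (default 2);
categories follow the degradome convention computed on fractional
post-split mass: 4 if slice mass ≤ 1, else 0 = unique profile maximum,
1 = tied maximum, 2 = above the median of non-zero positions,
3 = at/below it. Hits are reported in a stable (miRNA, transcript,
position) order so output is independent of iteration order.

## Hairpin processing modes

A pre-miRNA is cut twice to release the miRNA/miRNA* duplex. The
first cut's 3′ remnant is polyadenylated and 5′-monophosphorylated —
visible to PARE — so the position of hairpin-mapped signal on the 3′
arm reveals cut order: loop-distal signal (position b₂+1 for a 3′-arm
duplex strand [b₁, b₂]; a cut immediately 5′ of position p leaves a
fragment starting at p) indicates classical loop-last processing;
loop-proximal signal (b₁) indicates loop-first processing. Mirror
sites on the 5′ arm are computed but feed only the arm-simultaneity
check, not the mode call, since the discriminating evidence is 3′-arm
signal.

`classify_mode` compares mass within ±`window` (default 1 nt,
reflecting common DCL end heterogeneity) of the two sites: below
`min_total` (5) → no_signal; the two sites jointly under
`dispersal_fraction` (0.5) of total mass → dispersed; otherwise
loop_last/loop_first when one site dominates by `dominance` (2.0),
else ambiguous. Raising the dominance threshold can only move calls
toward ambiguous, never away — a monotonicity property under test.
The 5′-arm mass fraction below 0.1 yields a "simultaneous-compatible"
verdict (both arms cut in one processing event leave no long-lived
5′-arm remnant). Signal strictly inside the miRNA or miRNA* locus
(≥ `margin` = 2 nt from the ends, mass ≥ 3) is flagged as mid-duplex —
a signature of small-RNA-guided self-regulation. Precursors carrying
two duplexes are represented as two hairpin records sharing a
sequence and classified independently.

## The synthetic generator

The generator emulates a two-condition (control vs drought), two-
replicate degradome study. Defaults: 500 genes of 600–2500 nt with
5′UTR/CDS/3′UTR structure (ATG start, stop end, no internal stops,
CDS length divisible by 3; Poisson(3) intron counts recorded in the
GFF3), GC 0.5, 20 mature miRNAs (20–22 nt), 50 planted
perfect-complement cleavage sites, 100 stem-loop precursors, 10⁵ PARE
tags and 5×10⁵ RNA-seq fragments per library, planted |log₂FC| = 2 on
10%/5%/10% of genes for types I/II/IV.

Key modelling choices:

* **Decay-type semantics.** Type I shifts degradation and
  transcription in the same direction, type II degradation only,
  type IV transcription only. Type III (discordant) is not planted by
  default — it is vanishingly rare in the motivating setting.
* **Composition balance.** A multiplicative effect with random
  directions systematically inflates one library's total
  (E[2^±e] > 1), which after per-million normalisation shifts *every*
  null gene — a real compositional artifact that a total-count
  normalised test then flags. The generator therefore (i) splits the
  planted effect symmetrically across conditions (2^(+e/2) vs
  2^(−e/2), per-gene ratio still exactly 2^e), and (ii) assigns
  up/down directions in expected-mass-matched pairs within each type.
  Null genes then keep condition-invariant sampling proportions up to
  a small residual that shrinks with gene count.
* **Within-transcript tag placement.** A `peak_fraction` (0.8) of a
  target transcript's tags sit exactly at its planted slice site; the
  rest follow the background model, default `exp5to3` (5′-end density
  rising toward the 3′ end, emulating the survivors of 5′→3′
  exonucleolysis; `uniform` is available for null experiments).
  Libraries are exact-depth multinomial draws, so per-library tag
  totals equal `pare_depth` exactly; replicates share gene-level
  expectations and differ only by sampling noise, which reproduces
  the high replicate correlations (r² ≈ 0.97 at default depth) seen
  in practice.
* **RNA-seq counts.** Negative binomial with mean ∝ abundance ×
  length and variance m + φm², Poisson in the φ→0 limit. The default
  φ = 0.001 models residual technical overdispersion of pooled
  samples — the regime the sampling-model test is designed for;
  larger values are available to study the test's behaviour under
  biological dispersion (a dedicated test verifies the
  overdispersion is then visible).
* **Hairpins.** Built as one stem-loop by construction: 25-nt basal
  stem, miRNA arm, 12-nt AU-rich loop, star arm (reverse complement
  of the miRNA with ≤ 2 substitutions; duplex cuts leave the
  canonical 2-nt 3′ overhangs), complementary basal stem. Hairpin
  tag sets place `hairpin_purity` (0.8) of tags at the planted mode's
  signature cut site, at most `hairpin_arm5_leak` on the 5′ arm, and
  the remainder across the 3′ side. The default leak is 0.02: small
  enough that at ~25 tags per hairpin the observed 5′-arm fraction
  stays below the 0.1 verdict threshold with high probability, which
  is what "hardly any 5′-arm signal" looks like at this sampling
  depth.
* **Determinism.** Every output is a pure function of the
  configuration; independent named substreams (transcriptome,
  abundances, miRNAs, targets, per-library PARE, RNA-seq, hairpin
  tags) hang off the master seed, so regenerating any piece is
  byte-reproducible.

What the generator does **not** emulate: sequencing errors, adapters
and quality scores; genomic (spliced) coordinates; polymorphism;
ncRNA/repeat contamination; realistic codon usage or UTR sequence
composition beyond the GC target; and any coupling between a gene's
sequence features and its decay behaviour unless explicitly planted
via `responsive_utr_boost`. Passing recovery benchmarks therefore
demonstrates the correctness of the analysis logic under the stated
sampling models, not performance on real libraries with alignment
artifacts and biological dispersion.

## Benchmark problem sizes

The planted-truth benchmarks (also run by `scripts/acceptance.py`)
use: 500 transcripts / 20 miRNAs / 50 planted sites at 10⁵ tags for
target recovery; 100 hairpins at ~25 tags each for mode recovery;
2×10⁵ null genes for test calibration; the 500-gene study-scale
defaults for decay-type recovery; and small seeded batteries for the
oracle-equivalence checks. These sizes give stable percentages (the
stochastic quantities move by well under their assertion margins
across seeds) while keeping a full run within a few tens of seconds.

## Known limitations

* The two-library test inherits DEGseq-family anti-conservativeness
  under biological overdispersion; treat calls on dispersed data as
  exploratory.
* The folding fallback ranks stability only crudely; published MFEI
  values require the thermodynamic backend.
* Gapless target alignment misses bulged sites; the category scheme
  depends on fractional mass after multi-mapper splitting, so "single
  read" boundaries (≤ 1) are conventions, not read counts.
* Transcriptome-space mapping cannot resolve tags spanning unannotated
  junctions or antisense signal.
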