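# Methods

## Problem setting

Splicing variant predictors are usually validated on variants at or near
annotated splice sites. Deep inside introns two things change: the positive
class becomes rare and mechanistically heterogeneous (pseudoexon activation,
partial intron retention, branchpoint disruption), and many tools stop
emitting scores altogether. `intronbench` implements an evaluation stack
built around those two facts — distance-aware stratification, metrics that
price in missing predictions, region-level mechanism labels, threshold
recalibration, and a quantitative grade for tools' mechanistic
explanations — together with a synthetic testbed that exercises all of it
deterministically.

## Coordinate and offset conventions

All file formats and public APIs use 1-based inclusive coordinates (the
VCF/GTF convention); the only exception is the splice-junction evidence
lookup, which stays in BED's 0-based half-open space so that a position
equal to an interval's `end` is outside it. Internally, windows are Python
slices; round-tripping through the readers and writers is bit-exact.

The **intronic offset** of a position counts the first intronic base
adjacent to an exon as 1, separately from each end of the intron, and takes
the minimum; ties between the two ends resolve to the donor side for
determinism. On the minus strand the donor is the higher-coordinate end of
the intron. Offsets 1–2 are therefore exactly the GT (donor) or AG
(acceptor) dinucleotide, which is why the first distance bin is `1-2`.

**Distance bins** default to `1-2`, `3-10`, `11-40`, `41-200`, `201-500`,
`501-1000`, `1000+`, inclusive on both edges and contiguous over all
offsets ≥ 1. Only the named anchor bins are canonical; the interior edges
(3–10, 41–200, 201–500) interpolate between them and are configurable via
`DistanceBins`.

Indels are located by the leftmost reference base of their left-normalized
representation; motif-creation detection is SNV-only.

## Multi-isoform context

A variant that is deep-intronic in a gene's reference transcript may be
exonic, or much closer to a splice site, in another isoform.
`decompose_isoform_context` labels each position `exonic` >
`smaller_offset` > `same_offset` (precedence in that order), or
`no_other_transcript` when the reference transcript is the only one
overlapping the position. The output is invariant to the order transcripts
are supplied in.

## Metrics

From confusion counts (TP, FP, FN, TN) plus the missing-prediction count:

- `Coverage = scored / total`
- `Precision = TP/(TP+FP)`, `Recall = TP/(TP+FN)`, `F1 = 2PR/(P+R)`
- `weighted F1 = Coverage · F1`
- `MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))`
- `normalized MCC = (MCC+1)/2`, `weighted normalized MCC = Coverage · normalized MCC`

Decisions are **strict** `score > threshold` (published cutoffs are printed
as “>x”); tools with scores symmetric around zero declare
`direction="absolute_value"` and are thresholded on |score|. Missing scores
never enter confusion counts or curves but always count toward the coverage
denominator — the weighted metrics exist precisely to penalize missingness.
Any 0/0 ratio is defined as 0 (logged) so rankings stay total. Balanced
datasets are ranked by weighted normalized MCC, unbalanced ones by weighted
F1.

Curves use grouped thresholds for tied scores; auROC is the trapezoidal
area (equivalently the Mann–Whitney U statistic divided by n⁺n⁻, which the
tests verify to 1e-9) and auPRC is step-wise average precision. With a
single class present the auROC is reported as undefined rather than
guessed. Per-bin evaluation computes each bin independently; the per-tool
summary is the unweighted arithmetic mean across non-empty bins, skipping
empty bins with a warning (whether empty bins should count as zero is
genuinely open; skip-and-warn keeps the mean interpretable).

The *interrogate* ranking orders candidate variants by (fraction of scoring
tools calling positive, mean min–max-normalized score), with genomic
coordinate as the final tie-break so output order is deterministic.

## Threshold recalibration

For each tool, F-beta `(1+β²)PR/(β²P+R)` is evaluated on a grid of 100
thresholds uniformly spanning the observed score range (missing scores
excluded entirely), at β ∈ {0.5, 1, 2} by default — precision-leaning,
balanced, recall-leaning. The maximizing threshold is chosen; exact ties
resolve to the **lowest** maximizing threshold, the sensitivity-favoring
choice for clinical screening (users comparing against implementations that
break ties upward should expect one-grid-step differences). Internally the
count form `(1+β²)TP / ((1+β²)TP + β²FN + FP)` is used, which is
algebraically identical but free of intermediate 0/0.

Reliability comes from a stratified bootstrap: each replicate resamples the
positive and negative scored variants separately, with replacement, at the
original class sizes — preserving the class ratio — and re-runs the grid
search. Summaries are the mean and 2.5/97.5 percentile thresholds per beta,
deterministic given the seed. The implementation uses sorted-array
searchsorted counting, so a thousand replicates on a thousand scores take
well under a second.

One caveat the test suite makes explicit: with overlapping class
distributions the empirical F-beta landscape develops near-tied maxima, so
the selected threshold can occasionally jump between near-equivalent optima
under refinement or resampling. This is sampling multimodality of an argmax
estimator, not a numerical defect; the bootstrap interval is the honest
summary of that uncertainty.

## Region classification

Positive (splicing-altering) variants are classified against their observed
cryptic splice event, with precedence splice-site categories > branchpoint
> flanking windows > exonic-like:

- **new splice acceptor** — at the acceptor AG positions or the first
  cryptic-exon base; **new splice donor** — at the donor GT positions or
  the last cryptic-exon base (the core dinucleotide belongs to the
  splice-site category, so donor-downstream starts at +3).
- **branchpoint-associated** — 18–44 bp (inclusive; counted with the
  exon-adjacent base as 1) upstream of the acceptor *and* creating or
  disrupting at least one of the adenine branchpoint consensus motifs
  YTNAY, YTNA, TNA, YNA (Y={C,T}, N={A,C,G,T}), *and* not sitting exactly
  1 bp 5′ of a candidate branchpoint adenine. Because the slot before the
  adenine is N in all four motifs, a substitution there can never change
  the motif itself; the exclusion is therefore keyed on the adenines of
  reference-window motif hits overlapping the variant.
- **acceptor upstream** — otherwise 2–18 bp upstream (polypyrimidine-tract
  territory; deeper upstream positions outside the branchpoint window also
  fall here).
- **exonic-like** — inside the cryptic exon.
- **donor downstream** — more than 2 bp past the cryptic donor (unbounded).

Negative (splicing-neutral) variants have no cryptic event; they are first
screened for splice-motif creation — an SNV forging the most common
acceptor 5-mer CAGGT or donor 6-mer GGTAAG with the variant at the core
AG/GT — and otherwise classified by annotated-site geometry: 18–44 bp
upstream of an annotated acceptor is branchpoint-associated (no motif
requirement, mirroring how neutral sets are assembled), the rest split into
acceptor-upstream / donor-downstream by the side of the nearest annotated
site; exonic controls map to exonic-like.

All motif scanning happens on the transcribed strand; windows for
minus-strand genes are reverse-complemented before matching, and a sequence
N matches nothing, not even a pattern N. Whether the branchpoint window is
measured to the acceptor AG or the first exonic base differs by 2 bp
between conventions; the exon-adjacent convention is the default and the
bounds are configurable.

Major-group assignment (pseudoexon activation vs partial intron retention)
follows the experimental outcome for positives — pseudoexon wins when both
outcomes co-occur — and geometry for negatives: within 100 bp of an
annotated acceptor or 20 bp of an annotated donor mimics intron-retention
positives, deeper positions mimic pseudoexon positives (both thresholds
configurable).

## Interpretation audit

Ground truth per variant is a mechanism (creates_new_splice_site,
activates_cryptic_acceptor/donor, branchpoint, polypyrimidine_tract,
exonic_regulatory_within_pseudoexon), an outcome group, and a region
category. Three explanation dialects are graded:

- **SPiP tags** (parsed from the third/fourth/fifth pipe-delimited fields):
  `NTR` → no interpretation; `Alter by complex event` → not informative;
  `Alter BP` correct iff branchpoint; `Alter by create new Exon` correct
  iff pseudoexon activation; `Alter by create New splice site` correct for
  any site creation/activation regardless of outcome; `Alter ESR` correct
  iff exonic-regulatory; `Alter by MES (Poly TC)` correct iff
  polypyrimidine tract; unknown tags → not informative with a warning.
  Records with multiple alternative interpretations use the first.
- **SQUIRLS** interpretations arrive pre-structured (the HTML report is
  transcribed upstream to a small enum): “new cryptic” calls are correct
  only for variants that themselves create a site on the matching side;
  “activate cryptic acceptor” additionally requires the truth not be
  branchpoint-associated; not-informative / no-interpretation pass through.
- **SpliceVault** ranked event lists (≤10): a match to the observed cryptic
  event (same kind and contig, position within a configurable tolerance,
  default exact) at rank ≤ 4 is correct, at ranks 5–10 incorrect, absent →
  no interpretation. Pseudoexon-activating variants are excluded by
  construction — the approach queries missplicing around annotated exons
  and cannot represent that outcome.

Summaries report per-tool verdict counts and fractions (summing to 1). In a
full pipeline only variants correctly predicted at the tool's recalibrated
threshold enter the audit; that gating is an upstream filter over the
calibration output.

## Synthetic testbed

The generator builds, from a single seed: random ACGT contigs with a target
GC fraction; two mirror-image genes (plus and minus strand — the minus gene
is an exact coordinate mirror of the sense-axis layout, so strand handling
is validated by construction) with four exons, GT/AG intron boundaries and
a second isoform whose extra internal exon makes deep-intronic positions of
the reference isoform exonic; a small single-transcript gene for
isoform-context edge cases.

Inside the large second intron, each of `n_slots` 300-bp slots carries one
cryptic exon (AG…GT core, 80 bp) with one planted positive per region
category — a branchpoint variant disrupting a planted YTNAY adenine 20–40 bp
upstream, an acceptor-upstream variant at offsets 4–17, splice-site
variants at the cores, an exonic-like variant inside the cryptic exon, and
a donor-downstream variant at +3 to +30 — plus two deep (offset > 500)
motif-creation negatives (CATGT→CAGGT, GCTAAG→GGTAAG). Negatives for the
geometric categories are planted relative to annotated sites (branchpoint
window 18–44, acceptor-upstream offsets outside it, donor-downstream
offsets 3–150, exonic controls inside internal exons); their alt alleles
are chosen to *not* accidentally create the splice consensus, since such a
creation would legitimately reclassify them. Stamped sequence regions are
collision-checked so plantings cannot overwrite each other.

Tool scores are class-conditional: positives ~ Beta(s, 1), negatives ~
Beta(1, s), with the shape solved from the closed form
`auROC(s) = 1 − s·B(s, s+1)` so a target auROC is hit exactly in
expectation. Missingness is a monotone function of intronic offset,
`clip(intercept + slope·log10(offset)/3, 0, 0.98)`, emulating tools whose
coverage decays with depth. The three default simulated tools (target
auROC 0.95/0.75/0.55 with increasing missingness) define the study
conditions used by the ranking checks.

What the testbed does **not** emulate: realistic human sequence
composition, linkage between variants, indels, genuine predictor behavior
(no receptive-field or context effects), or label noise. Passing the
round-trip and ranking checks therefore demonstrates that the machinery is
self-consistent and correctly strand- and distance-aware — not that any
real tool achieves any particular number on real data.

## Problem sizes

Defaults keep everything desk-scale: bundles of 2 × 25–30 event slots
(≈ 650–800 variants) for round-trip checks, 1,000-score samples for
calibration recovery, 1,000 bootstrap replicates × 100 outer datasets for
coverage, 2,000-variant cohorts × 100 seeds for ranking recovery, and
10,000 random 60-mers for the motif-scanner equivalence check. The full
test suite runs in well under a minute on one CPU.

## Known limitations

- Motif-creation detection is SNV-only; indel-driven site creation is
  logged and skipped.
- The branchpoint window convention (measured from the exon-adjacent base)
  and the unnamed interior bin edges are field conventions rather than
  universal standards; both are configurable.
- The per-bin mean skips empty bins, which slightly favors tools evaluated
  on fewer bins; the per-bin table always reports which bins contributed.
- Bootstrap percentile intervals for an argmax-type threshold estimator can
  undercover in heavily multimodal score landscapes.
- The audit grades explanation *labels*, not effect sizes; a tool that is
  mechanistically right for the wrong quantitative reason still scores
  correct.
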