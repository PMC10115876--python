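# Methods

This note documents the models, decision rules, parameter defaults and
numerical choices behind each stage, what the synthetic data do and do not
emulate, and the known limitations.

## Coordinates and strand conventions

Intervals are 0-based half-open internally; 1-based coordinates appear only
in VCF-like output and in splice-donor reporting. Protospacer positions are
1-based from the PAM-distal end, so the HbE target adenine is A5 and the
bystander A6. For minus-strand protospacers all window logic operates on
the protospacer strand: the deaminated base is always an A there, and
appears on the reference plus strand as a T→C change at the mirrored
coordinate. The editing window defaults to protospacer positions [4, 8];
the window is a required configurable because deaminase activity windows
differ between editor variants, and the defaults only assume that A5 and A6
lie inside it. The spacer sequence itself is configuration, never
hard-coded: `simulate.make_hbe_like_locus` builds a synthetic HbE-like
guide (AAG codon at protospacer positions 5–7) for testing.

## Amplicon outcome quantification

Read pairs are merged FLASH-style: the best ungapped overlap of read 1
against the reverse-complemented mate, requiring overlap ≥ `min_overlap`
(default 10) and mismatch fraction ≤ 0.25, with disagreements resolved by
the higher base quality (ties to read 1). Merge failures are counted in a
QC block and excluded rather than classified.

Merged reads are globally aligned to the amplicon with affine gap scores
(match +2, mismatch −2, gap open −10, gap extend −1). These penalties make
a gap cost more than five mismatches, so sequencing errors are not explained
away as spurious indels; terminal gaps are scored free and treated as
incomplete coverage, not indels. A gapless fast path (identical lengths,
≤ max(3, 5%) mismatches) avoids alignment for the typical
substitution-only read. Any internal gap overlapping the editing window or
the codon yields INDEL; otherwise the codon triplet maps
AAG/GAG/GGG/AGG → unedited/WT-corrected/Aubenas/AGG-variant and anything
else to OTHER_SUBSTITUTION. A read that does not cover the codon, or whose
codon bases fall below `min_base_quality` (default Q20), is UNCLASSIFIED
and excluded from frequency denominators.

**Editing efficiency** is defined as the WT_CORRECTED + AUBENAS fraction of
classified reads — the sum of the two benign corrected outcomes. Whether
the rare AGG outcome should count as "correction" is genuinely open; the
package excludes it by default and reports it separately. Per-allele
phasing (HbE vs the trans-thalassaemic allele) is supported only when a
discriminating SNV is configured; otherwise outcomes are pooled.

## Off-target nomination

`enumerate_offtargets` performs an exhaustive mismatch-only scan (no
DNA/RNA bulges — no published bulge parameters exist for this guide) of
every 20-nt window on both strands whose 3′-adjacent bases match the IUPAC
PAM pattern, up to `max_mismatches` (default 4, capped at 8). Ambiguous
reference bases count as mismatches and never satisfy a concrete PAM
symbol. The scan is vectorised over shifted array comparisons; tests prove
it identical to a naive per-position oracle.

External nuclease-assay sites enter as BED6 with the score column holding
the read count. Overlapping same-strand sites merge transitively, keeping
the representative with the fewest mismatches, the union of sources and the
maximum read count. The window-adenine filter retains exactly the sites an
ABE could edit (≥1 protospacer-strand A in the window). Ranking for the
capture panel orders by nuclease read count (descending, absent = 0), then
mismatch count, then locus — the ranking key is configurable and recorded
in the run-log, since no canonical "top N" definition exists. Capture
probes are emitted as 120 bp of plus-strand sequence centered on each
protospacer, without melting-temperature optimisation.

## Capture quantification and calling

Pileups use pysam with `min_base_quality` Q30 and `min_map_quality` 20.
Duplicates are not removed: at capture depths of tens of thousands the
library legitimately exceeds its complexity, and duplicate removal would
discard true signal (documented caveat: PCR jackpots can inflate
frequencies). Counts are reported in protospacer-strand orientation and
conserve depth exactly. Deamination frequency at a position is
count_G / depth; only window positions whose protospacer-strand reference
base is adenine are tested — at any other position a G count measures the
reference base itself, not deamination.

The call rule is this package's explicit specification of an otherwise
unpublished decision step: per adenine position a one-sided Fisher exact
test of G-vs-A counts (treated excess), computed as the hypergeometric
survival function; the site p-value is the minimum Bonferroni-adjusted
(× number of tested positions) per-position p; Benjamini–Hochberg
adjustment across the site cohort (statsmodels backend); a site is called
when q ≤ α (default 0.05) **and** its maximum deamination frequency exceeds
the control's. Zero-depth sites are flagged uncallable. Under null
simulations (both samples at error 0.001, depth 10,000, 250 sites, 200
replicates) the called fraction stays well below 1.5 α; planted 1% editing
against 0.1% background at depth 50,000 is called essentially always.

## Damage model

Candidate regulatory damage is scored by in-silico mutagenesis:
`damage = P(accessible | control) − P(accessible | edited)` per track, with
a site flagged when any track has P(accessible | control) > 0.2 and
damage > 0.1. Which bystander combinations to score is an open choice; the
default evaluates each single window adenine plus the all-adenines edit.
Gain-of-function edits (negative damage) are reported with their sign but
not flagged unless `flag_absolute` is set.

The predictor is a declared interface (`input_length`, `track_ids`,
`predict_batch`). The reference implementation is a deliberately small
convolutional classifier written in numpy: 12 filters of width 10 over
one-hot sequence, ReLU, global max pooling, and a logistic output, trained
with a seeded Adam loop (lr 5 × 10⁻³, 25 epochs, batch 128, 20% held-out
split). On the synthetic task — 200-nt sequences, positives embedding a
10-nt accessibility motif at a random offset — it reaches held-out AUROC
> 0.99 and training is bit-reproducible for a fixed seed. This model
exposes a single synthetic track; it stands in for large multi-track
accessibility CNNs only in the sense of satisfying the same interface, and
nothing about real chromatin is claimed from it. Counts of flagged sites on
real genomes would require a model trained on real accessibility data.

## Splice quantification

Junctions are extracted by walking CIGAR strings of reads overlapping the
region of interest (MAPQ ≥ 20): each skipped-region operation contributes
one count to its (donor, acceptor) key, one count per skip for multi-intron
reads. The donor is the 1-based last exonic base before the skip — matching
how the *HBB* exon-1 donor is quoted (chr11:5,248,159, hg19) — and the
acceptor the 1-based first exonic base after it; this convention differs
from pysam's 0-based half-open intron keys by +1 on the acceptor, and the
tests cross-check the two. The aberrant fraction is the count share of
junctions with a non-canonical donor; it is undefined (None) for an empty
table and invariant under read duplication.

## Expression statistics

Relative expression uses the standard 2^−ΔΔCt form with replicate Ct values
aggregated by arithmetic mean and no outlier handling (replicates are
technical triplicates in the intended use). Amplification-efficiency
correction (Pfaffl) is out of scope. The β/α ratio is the ratio of two
relative quantities and requires a positive denominator.

## Synthetic data and what passing tests show

Generators are seeded (numpy `default_rng`) and byte-reproducible; every
generator writes a JSON truth manifest sufficient for downstream
comparison. Default conditions mirror the intended experiments: the
amplicon mixture plants 78% Aubenas / 12% WT / 0.74% AGG / remainder HbE
(the outcome profile of a highly edited patient sample) at n = 50,000 reads
and a 10⁻³ substitution error rate; capture simulations use depths of
10,000–50,000 with 10⁻³ background error, matching the regime where an
average capture depth in the tens of thousands separates 0.01–1% editing
from error; the splice mixture plants a 30% cryptic fraction.

Outcome counts in the amplicon generator follow a largest-remainder exact
allocation of the planted frequencies (order shuffled), so recovered
frequencies deviate from planted values only through error-driven
misclassification, not multinomial sampling; per-read capture edits are
Bernoulli draws whose realised counts the manifest records. The error
model is substitution-only by default (an indel mode exercises the INDEL
path), with flat Q37 qualities (a degraded mode exercises quality filters).
Not emulated: PCR duplicates, GC bias, adapter read-through, correlated
errors, real chromatin tracks. Passing tests therefore demonstrate
correctness of the computations under a clean error model, not performance
on real libraries.

The off-target genome generator scrubs its random background of accidental
windows within 4 mismatches of the spacer on either strand (PAM ignored,
i.e. conservatively) before planting sites, and places planted mismatches
outside the editing window so planted sites keep their A5/A6 adenines.

## Problem sizes

The test suite and the acceptance script run on one CPU in a few minutes
total. Sizes were chosen as the smallest that still pin down each property:
10,000 reads for per-read exactness, 50,000 for frequency recovery (3
binomial SE at a 0.74% category), a 100 kb genome for the
enumeration-oracle equivalence, 250 sites × 200 replicates for the null
call rate, 200 replicates for power, 4,000 sequences for predictor
training, 30 candidate sites (5 damaging) for damage recovery.

## Known limitations

- The capture call rule is a re-specification, not a reproduction, of the
  original unpublished criteria; absolute called-site counts (e.g. how many
  of 250 sites exceed a threshold) are not comparable across rules.
- Mismatch-only off-target search misses bulge-mediated sites.
- The amplicon aligner assumes a single amplicon reference; chimeric or
  off-amplicon reads are classified OTHER/UNCLASSIFIED rather than
  filtered by mapping.
- The reference accessibility model is single-track and synthetic; damage
  scores on real genomes require substituting a real trained predictor via
  the same interface.
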