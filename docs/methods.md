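# Methods

This note documents the models, conventions and numerical choices behind
`asebias`, the assumptions they rest on, and what the synthetic experiments
do and do not demonstrate about real data.

## Read simulation model

Reads are generated exhaustively, not sampled: for each exon of length *n*
and read length *k*, one read starts at every position 0 … *n* − *k* (so
*n* − *k* + 1 reads per strand; exons shorter than *k* yield none), on both
strands, for both alleles. Reads never span exon boundaries — exons are
treated as independent transcribed units, which matches exome-style
references but ignores splice-junction reads. There is no sequencing-error
model and no expression-level variation: every read is an exact substring
(or reverse complement) of its allele. Consequently both alleles contribute
*identical* read counts at every locus, and any departure of the measured
reference proportion from 0.5 is attributable purely to the alignment
strategy. Read ids encode `allele|exon|start|strand` so every downstream
observation can be checked against the truth of origin.

## Alignment contract

Single-genome alignment is ungapped, whole-read Hamming matching: a *hit*
is a tuple (exon, start, strand) whose window is within *m* mismatches of
the read (strand “−” compares the read's reverse complement). A read is
reported only when **exactly one** hit exists over both strands of the
whole exome; two or more valid hits — regardless of whether they have
different mismatch counts — suppress the read as multimapped, and a
palindromic read matching one window on both strands counts as two hits.
`N` matches nothing, including `N` itself, so masked positions exclude
reads rather than matching them.

The production hit finder is pigeonhole-seeded: the read is cut into
*m* + 1 disjoint seeds of length ⌊*k*/(*m* + 1)⌋; any window within *m*
mismatches must contain at least one seed exactly, so gathering candidates
by hash lookup and verifying with a Hamming count is complete. The test
suite holds the finder to exact equality with an independent vectorized
brute-force scan over every window of both strands.

Dual-parental mode aligns each read to both allele-specific exomes with
*m* = 0 and calls an allele only when the read is unique in one genome and
absent from the other; reads placed in both (or multimapped in either) are
ambiguous and discarded. Zero mismatches is not an optimization but a
correctness requirement: with *m* ≥ 1 an alternative-allele read could
align to the reference parent across a single differentiating site,
destroying the assignment logic.

## Quantification

Counting is pileup-style over unique alignments only. At each
differentiating site, the base a covering read shows at the aligned offset
(complemented for minus-strand alignments) increments the reference count,
the alternative count, or an `other` count for third alleles. The
reference proportion is ref/(ref + alt); `other` reads are tracked but
excluded from the denominator, a documented choice — exhaustive simulation
produces none, and for real data only reads matching one of the two known
alleles carry assignment information. A site with zero informative
coverage has an undefined proportion, reported as missing.

In dual mode a REF-called read increments the reference count at every
site its reference-genome window covers, and symmetrically for ALT calls
using alternative-allele coordinates.

## Site diagnostics

**Neighbor density** is the maximum, over all *k*-windows that fit the
exon and cover the focal site, of the number of *other* differentiating
sites inside the window. Windows are exon-bounded, so edge sites have
fewer covering windows; if no window fits (*k* > exon length) the density
is an error rather than a value, since no read could cover the site.

**Mappability** of a position is the reciprocal of the number of locations
(both strands) that the *k*-read starting there aligns to within *m*
mismatches, computed with the same hit finder used for alignment — exact
by construction, with no approximate counting. A site's score is the
arithmetic mean over its covering positions; 1.0 means every covering read
is uniquely placeable. Scores are compared against 1 (single mode) or, as
a summed per-allele score, against 2 (dual mode) with a 1e−9 guard against
floating-point dust; true perfect scores are exact sums of ones, and any
genuine imperfection falls short by at least 1/(2*k*). One extension
beyond the reciprocal definition: a window read that aligns *nowhere*
(possible only when the window overlaps an N-masked interval) scores 0.0
rather than being undefined, which is what pushes indel-adjacent sites to
imperfect dual mappability and out of the reliable set.

Mappability in dual mode is computed on the masked exomes at *m* = 0,
matching the alignment conditions; computing it on unmasked exomes is
supported but not the default.

**Indel proximity** flags a site when an indel breakpoint lies within
*k* − 1 bases (one read can contain both) or the indel spans the site.

## Indel masking convention

Indels are intervals present in one allele but not the other, called from
global pairwise alignment of each exon pair. For dual-parental alignment
each indel is masked symmetrically in alignment-column space: the allele
carrying the extra bases gets those bases **plus the first base to their
right** replaced by `N`; the other allele gets the single junction base
masked. Both masks then occupy identical alignment columns, so the set of
surviving read windows is an exact mirror between alleles — this is what
makes the dual-genome proportion land on exactly 0.5 even at sites
adjacent to indels. Masking only the carrier's bases would leave the
junction-crossing reads of the other allele alignable and skew the counts
away from the reference allele. Sites whose base falls inside a mask are
unobservable and are dropped before counting.

Pairwise alignment uses global Needleman–Wunsch with affine gaps
(match +1, mismatch −1, a gap of length L costs 2 + L), via Biopython's
`PairwiseAligner`; among co-optimal alignments the aligner's first is
taken, which is deterministic across runs. Under this scoring an isolated
substitution is never re-called as a gap pair, and difference calling on
SNV-only exon pairs recovers the generating variants exactly at densities
up to ~2%; denser clusters of adjacent substitutions could in principle be
re-aligned as indels under other scorings, which is why the generator's
truth tables, when available, take precedence over re-derived differences.

## Statistics

For stochastic data, each site with at least `min_coverage` (default 20)
informative reads is tested with a two-sided exact binomial test of
ref ~ Binomial(*n*, 0.5), using the minimum-likelihood ordering (the sum
of probabilities of outcomes no more likely than the observed one; at
p₀ = 0.5 this equals twice the smaller tail, capped at 1). The
Benjamini–Hochberg step-up procedure controls the FDR (default 0.05)
across the tested sites of the current run only; no cross-run pooling.
The binomial p-value is delegated to `scipy.stats.binomtest` and the
step-up to `statsmodels`' `multipletests`, with the test suite holding
both to independent enumeration oracles. BH is a choice: no particular
FDR procedure is canonical here, and the choice is recorded in run
metadata. “Equal allelic abundance” means tested and not significant; for
exhaustive simulations, where coverage is deterministic, equality is
instead exact count equality.

## Synthetic data generator

The generator emulates the structure of an exome-based allele comparison:
`n_exons` random exon sequences (uniform length in `exon_length_range`,
default 300–600 bp; GC fraction 0.5), a second allele derived by i.i.d.
per-base SNVs at `snv_rate` with a uniformly random alternative base, and
optionally Poisson-distributed indels per exon (3–12 bp, insertions and
deletions equally likely) and exact-duplicate exons that break
mappability. Defaults (50 exons, `snv_rate` 0.01, no indels) describe an
intraspecific-style comparison — divergence at the high end of what
within-species panels show, which exercises the density mechanism without
swamping it; indels belong to interspecific-style runs and are kept
≥ 50 bp (`indel_margin`) from exon ends and from each other so that every
indel-adjacent site retains read windows on both sides and masked
footprints never merge. Substitution type is deliberately unmodeled (no
transition/transversion asymmetry): every diagnostic here depends only on
site *positions*. One RNG stream is keyed by the seed with per-exon
sub-streams, so outputs are byte-identical given a config.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: codon structure and selection, non-uniform
divergence along exons, expression-level differences between alleles,
sequencing errors and quality variation, paired-end structure, splice
junctions, and sampling noise (except where the statistics are explicitly
tested on simulated binomial draws). The exactness results (0.5 at clean
sites) are properties of exhaustive error-free tiling; on real data the
same sites are merely unbiased in expectation.

## Problem sizes and numerical notes

The standard experiment used throughout the tests and the acceptance
script is 50 exons × 300–600 bp (~22 kb per allele), k = 36, which tiles
~80,000 reads over both alleles and strands and yields ~200–250
differentiating sites at 1% divergence; single-reference runs at
m ∈ {1,2,3} plus a dual run complete in well under a minute on one CPU.
Hit-finder/oracle equivalence is checked on ≥ 1000 randomized instances
with m ∈ {0..3}. Proportions are exact in floating point whenever counts
are equal (ref/(ref+alt) = 0.5 has an exact binary representation), so
exactness assertions use equality, not tolerances. Coordinates are 0-based
half-open everywhere internally; only the variant TSV/VCF exports are
1-based.

## Known limitations

* Ungapped alignment only: reads spanning indels are *meant* to fail;
  gap-aware or spliced aligners are out of scope.
* Exon-local coordinates: no chromosome-scale or junction-spanning
  analysis.
* Site-level output: exon- or gene-level ASE is reported only as
  retention (fraction of exons keeping ≥ 1 reliable site), not aggregated
  into expression ratios.
* The mappability score is exact but brute-force-priced; it is intended
  for exome-scale references, not whole mammalian genomes.
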