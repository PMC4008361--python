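# Methods

## Coordinate and sequence conventions

All internal coordinates are 0-based half-open genome coordinates; GFF3's
1-based closed convention exists only at the I/O boundary. Minus-strand
features are stored in genome coordinates and reverse-complemented on
demand. Genomes are treated as linear — origin-spanning features are not
supported. ORF and CDS spans include the stop codon (the GFF3 CDS
convention), so candidate ORFs are directly comparable with gene models;
reported proteins exclude the stop. Translation uses the standard codon
table without rewriting alternative starts (GTG→V, TTG→L), which keeps
translations position-independent so peptide matching is exact substring
search. The 3′ terminus of a half-open fragment [s, e) is base e−1. The
metagene offset convention is 0 = first base of the start (or stop) codon,
negative = upstream in transcript orientation.

## The synthetic model

The generator emulates a small high-G+C actinomycete chromosome and the
omics layers measured across a six-time-point fermentation. It is the
package's test substrate: parameters are fixed once as study conditions,
not tuned per experiment.

**Genome and genes.** Background sequence is i.i.d. at the target G+C
(default 0.72). Genes are cassettes laid out with 250–1200 nt gaps: a start
codon drawn from {ATG 0.5, GTG 0.35, TTG 0.15}, a stop-free codon body
sampled base-wise at the target G+C with stop codons rejected (the
rejection mimics the stop-codon depletion that makes spurious ORFs common
in this regime), and one stop codon. Annotated genes are 120–400 aa; hidden
genes — structurally identical but omitted from the emitted GFF3 — are
40–120 aa, reproducing the observation that missed genes skew short.
A fixed SD motif (AGGAGG) sits at a configurable spacer (default 7 nt)
upstream of each start.

*Maximal-ORF guarantee.* An in-frame stop codon is written just upstream of
the SD region, and the pad/spacer are resampled until no in-frame start or
stop codon lies between that stop and the planted start. Without this, the
GC-rich background frequently contains a chance in-frame GTG/TTG upstream
of the planted start, and "exact coordinate recovery" under the 5′-most-
start expansion convention would be ill-posed rather than a property of the
method. This is a property of the *planted* genes only; the discovery code
never assumes it.

**Frameshift mis-annotation.** One annotated gene's emitted model is
shifted +1 nt relative to the true gene — the observable consequence of an
annotation derived from an assembly copy missing one base (a single GFF3
interval cannot represent a mid-gene frame change; the shifted-interval
form preserves exactly what the method can detect: peptides in-frame with
the true gene, offset ≤3 nt from the annotated model, with no new upstream
stop).

**Coverage.** Each transcribed unit (all genes plus planted non-coding
intergenic segments) draws a lognormal expression level (σ=0.6 around the
configured depth, default 30 reads/base) and a temporal profile cycled from
{constant, switch-down, switch-up, pulse}; per-base counts are Poisson.
Untranscribed background is Poisson at 0.05 reads/base. Tracks are stranded,
one pair per time point.

**Fragments.** Per expressed gene: (a) SD-protected fragments whose 5′
termini pile at the SD window start with ±1 nt jitter, count ~
Poisson(6·strength·rel. expression); (b) CDS-interior fragments whose 5′
termini follow the ribosome-step multinomial — weight w on positions in the
start's codon phase and (1−w)/2 on each other phase, with
w = (1+strength)/(3+strength) so strength 0 gives exactly uniform phases;
(c) a uniform genome-wide degradation background. Lengths are uniform in
the 15–50 nt gel window. The default protection strength (8 → w ≈ 0.82) is
a choice: no quantitative enrichment figure exists to match, so it was set
to give a clearly visible but not saturated protection peak; the negative
control (strength 0) is what the specificity tests rely on.

**Peptides.** Hidden genes receive 1–4 tryptic-style peptides (7–30 aa,
K/R-terminated) drawn from their true translation, each checked to be
unique in the six-frame translation of the genome; the first hidden gene
gets exactly one peptide to exercise the single-peptide RNA-validation
path; the frameshift gene's peptides come from the true frame. True
confidences ~ N(98, 1.5) clipped to [80, 100]; decoys are shuffled true
peptides re-checked to be absent from the six-frame translation, with
confidences ~ N(60, 15) clipped below 95. Decoys therefore test both the
mapping (zero placements) and the filter (never accepted).

**Metabolic fixture.** The domain/reaction/ortholog tables plant the
recurring situations of orphan-enzyme assignment: a duplicated-domain
requirement (PLDc×2) with a single-copy foil and an above-cutoff foil; a
two-gene tie on domains broken by synteny (one gene's ±3 neighbourhood
conserved in a reference genome); a reaction whose domain occurs nowhere
(stays unassigned); and a multi-domain ambiguity where every candidate
carries extra unrelated domains. Noise domains are sprinkled only on
non-role genes so the planted answers stay unique — the recovery statistic
measures the ranking logic, not fixture luck.

**What the generator does not model,** hence what passing tests do not
show: sequencing error and mappability, operon structure and UTRs,
overlapping genes, PWM-like SD variability (the motif is a fixed string),
nuclease sequence preferences, peptide detectability bias, and real FDR
behaviour of spectral search engines. Recovery rates on this substrate are
upper bounds on real-data performance.

## Analysis choices

**Six-frame ORFs.** Per frame, each maximal stop-to-stop interval is
scanned for its 5′-most start ∈ {ATG, GTG, TTG} (configurable); minimum
length 30 aa by default (peptide-anchored ORFs are exempt — they are
expanded, not length-filtered). Stop-free stretches hitting a region edge
are kept with a `partial` flag because broken/frameshifted genes surface
there. Verified equivalent to an independent start-anchored exhaustive
scan.

**Peptide expansion.** Only uniquely mapping peptides seed expansion
(non-unique ones may support an already-seeded ORF in-frame). The upstream
scan is bounded at 3,000 nt to contain pathological stop-free GC-rich
frames; exhausting the bound, or finding the bounding stop with no start
below it, flags the ORF partial (frameshift suspect). I/L equivalence is on
by default; "independent peptides" means distinct sequences, not spectral
counts. Confidence values are taken as given — decoy-based FDR
re-estimation is out of scope since spectra are not inputs.

**Transcription.** Normalisation is counts-per-million within each library
followed by a median-of-ratios factor across libraries of the same strand
computed over annotated genes (the two-step a practitioner would use
without spike-ins; the source protocol is not restated anywhere, so this
is the package's documented choice). Detection threshold per track is
max(k·background, floor) with k=5, background = median coverage of
intergenic positions, and an absolute floor of 5 normalized units. The
floor matters: the median background of a sparse track is 0, which would
make k·background vacuous, and isolated Poisson noise bases would otherwise
chain through the 20 nt gap-merge into spurious ≥50 nt runs. The floor is
set above the Poisson tail of the background depth. "Dynamic" means the
coefficient of variation of per-time-point means exceeds 0.5.

**RBS calling.** The protected window is searched in offsets [−20, +3]
(the SD sits 4–15 nt upstream; a few nt of slack into the codon allows
initiation-associated fragments). A call needs the in-search peak to exceed
3× the flank median (floored at 1) and an absolute peak of 5, with ≥10
weighted termini in the search range — single-read calls are worthless.
SD matching (exact or 1 mismatch) annotates calls but never gates them.
Periodicity is estimated on CDS-interior 5′ termini only (9 nt trimmed at
each end to exclude initiation/termination pile-ups) by normalized
autocorrelation over lags 2–10; the implementation's direct dot-product
route is cross-checked in tests against the spectral (Wiener–Khinchin)
route, which is the same quantity by theorem.

**Orphan assignment.** Domain requirements are multisets filtered at
E ≤ 0.001 (the conventional reporting cut-off). Synteny is the best, over
reference genomes, fraction of a gene's ±k (k=5) neighbours with orthologs
within ±k of the gene's ortholog. Ranking is lexicographic — domain
completeness, best E-value, synteny (descending), gene id — because no
principled weighting of domain vs synteny evidence exists; the order encodes
"domains first, synteny breaks ties". Verdict `ambiguous_multidomain`
requires *every* candidate to carry extra unrelated domains (one clean
candidate among ambiguous ones is still reportable).

**Integration.** Precedence for gene existence is peptide > transcription:
a transcribed region explained by an accepted ORF is not emitted twice.
RBS features attach to their target gene, or failing that to the nearest
downstream start within 25 nt. Function reassignments write the old product
name to `previous_product`; nothing is ever deleted — contradicted models
are only flagged. The merge is idempotent by construction (every add/flag
checks for its own prior effect), which the tests verify by re-integrating
the output.

## Problem sizes and determinism

Default conditions: 100 kb genome, 40 annotated + 6 hidden genes, 6 time
points, 8 non-coding transcribed segments, ~10⁴ collapsed fragments, ~40
peptides, 10 orphan reactions. Recovery statistics in the acceptance suite
aggregate 10 independent seeds (plus 10 no-protection control seeds for RBS
specificity). All generators are deterministic under a fixed seed; derived
stage seeds are small fixed offsets of the master seed.

## Known limitations

Single-chromosome assumption in the pipeline driver (the I/O layer handles
multi-record FASTA); no operon/TSS model, so RBS calls for internal genes
of real operons would be under-powered; the frameshift detector flags only
near-frame offsets ≤3 nt and partial expansions adjacent to a model, not
arbitrary broken genes; normalization assumes most genes are not
differentially expressed across libraries (median-of-ratios premise);
synteny requires a pre-computed ortholog table and inherits its errors.
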