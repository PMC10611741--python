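# Methods

This note documents the models and procedures implemented in `paraloscope`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate.

## The problem

A set of paralogs is a group of genomic regions of common duplication
origin whose pairwise identity is high enough (≥ 90%) that short reads
cannot be placed uniquely. Two consequences follow. First, reads from such
regions carry mapping quality 0 and are ignored by conventional callers, so
SNVs/indels there go undetected. Second, a homozygous ectopic gene
conversion (donor sequence copied onto an acceptor) leaves the acceptor
with no uniquely aligning reads — indistinguishable, locally, from a
homozygous deletion — while the acceptor-derived reads, now carrying donor
alleles, aggregate on the donor locus and double its apparent coverage.

## Region discovery

**Set I (annotation-driven).** Protein-coding genes are paired with their
pseudogenes by shared gene name. Each pair is globally aligned (forward and
reverse complement; the better orientation wins) and a 100 bp window slides
over the alignment columns with step 1; a column is kept when any window
containing it matches in ≥ 90% of its columns (`identity_min`, default
0.90). Kept windows are merged by union. When a gene has several
pseudogenes, only gene positions covered by **exactly one** pseudogene's
kept windows survive; maximal such runs become two-member sets with that
pseudogene. This is the package's resolution of an under-determined corner:
a position homologous to two pseudogenes cannot be assigned a single
partner for masking, so it is excluded rather than guessed.

**Set II (alignment-driven).** Positions inside the footprints of MQ < 10
reads with depth ≥ 10 are merged into regions under three gap tolerances —
250 bp, 500 bp, and 5% of the left region's length (regions < 50 bp are
dropped from the 5% list). Within each list, all pairs (including reverse
complements) are globally aligned; the score is matching columns divided by
alignment length, a normalization the upstream tooling leaves unstated.
Valid sets are the connected components of the score ≥ 0.9 graph that are
cliques: a component with an internal sub-threshold pair contains a region
scoring ≥ 0.9 against something outside any mutual group, and the whole
component is rejected. Sets with more than 5 members or no exonic overlap
are removed; the three lists merge 500 → 250 → 5%, accepting a set only if
none of its members overlaps an accepted region. Set I takes precedence
over Set II in the final merge under the same non-overlap rule.

**Masking choice.** Within each set the member with the largest CDS overlap
stays unmasked; ties break to the lowest (chrom, start). All other members
are N-filled in the masked reference.

**SUNs.** Every alignment column where members disagree yields a SUN
record; runs of columns with an identical gap pattern collapse into a
single indel-type SUN. Alleles are reported on the extracted orientation of
each member.

**Subregions.** Set I regions are cut to protein-coding exons ± 200 bp of
intron (deletion/conversion calling is exon-resolution); Set II regions are
kept whole and only for two-member sets. Each subregion carries the
projection of its interval onto the partner paralog(s).

## Masked re-alignment

Reads overlapping the extraction regions (members ± 500 bp) are extracted
once each, broken pairs are dropped (a no-op for single-end data), and
reads are re-aligned to the masked reference with an internal aligner:
exact 15-mer seeds into the non-N reference, edit-distance extension with a
banded aligner (edlib), best placement wins, placements with edit distance
above 10% of the read length are counted unplaced. Masking makes placements
unique by construction, so a production-sensitivity aligner is unnecessary;
an external hook accepts any callable producing an alignment store, and the
simulator exports FASTQ/masked FASTA for real aligners. Duplicates — same
chromosome, start, end, orientation **and sequence** — collapse to one. The
counters satisfy input = aligned + broken pairs + duplicates + unplaced on
every run.

## Variant calling and VAPs

Pileup calling on the masked alignment reports every non-reference allele
with ≥ 2 supporting reads, with exact depth and VAF and no allele-ratio
prior: with *n* pooled paralogs a heterozygous variant in one member is
expected at VAF 1/(2*n*). The raw call set keeps calls that (1) are not SUN
alterations (exact allele match at a SUN position; such calls are routed to
a `sun_site` class — the overlap-only alternative would also drop genuine
variants at SUN positions), (2) have depth ≥ 60, (3) have VAF ≥ 0.15
(inclusive; at 60× and p = 0.25 the exact binomial tail retains 97.9%), and
(4) are absent from the sample's original (unmasked) VCF after left-aligned
minimal normalization. Calls with VAF ≥ 0.85 (configurable) are classed
homozygous-in-all-paralogs and stay site-specific; the rest expand to VAPs
with one candidate per member, projected through the alignment columns.
Indels left-align within the alignment and anchor to the last non-gap
column; members lacking the column are flagged non-projectable but still
counted, so the candidate count always equals the paralog count.

The filter cascade then applies, in order: (1) cohort allele frequency
strictly > 10% (10.0% survives); (2) removal when the number of samples
with VAF > 0.05 strictly exceeds twice the number with VAF > 0.15
(systematically marginal calls); (3) homopolymer tracts ≥ 6 identical bases
computed from the reference on the fly, padded by 2 bp; (4) subregions with
5 SUNs within ≤ 10 bp (pairwise-alignment and read-alignment conventions
diverge there, inflating false calls). Filters are variant-level, so the
cascade is idempotent; each call carries a trace of all failing flags.
The CAF denominator is the whole cohort regardless of capture kit; kit
grouping applies only to the coverage model.

## Coverage model

All coverage work reads the original alignments. Per subregion, `unique`
counts MQ > 0 reads and `all` counts every read; a read overlapping two
subregions counts in both.

**KDE clustering.** One-dimensional counts are clustered by an
exponential-kernel KDE (scikit-learn), bandwidth 1.0 on raw counts and on
R × 100 (the upstream tooling's bandwidth is unstated; these are this
package's defaults, with a config override), evaluated on a 512-point grid
spanning [min − 3b, max + 3b]. Cluster boundaries are local density minima;
minima detection is plateau-aware (density underflows to exactly zero
between well-separated clusters) and a cut survives only while its density
is strictly below the highest density on both sides.

**Both-paralog deletions** use per-sample `all`-count totals over the set,
computed per capture kit. Sets with cohort-median total < 120 are skipped;
clusters with peak > 10 reads (true deletions tolerate a few stray read
ends) or holding > 10% of the cohort are excluded; remaining cluster
members are deletion_both events.

**Single-region deletion vs conversion.** For a pair (X, Y): samples with
< 30 unique reads over the pair are excluded, as are pairs with a
per-paralog unique median < 60. R = X/(X+Y) is clustered; samples in
clusters holding > 10% of the cohort are non-events. A candidate event
needs ≤ 10 unique reads on X and R ≤ 0.05. Unique counts are normalized by
a per-sample factor (cohort-median total ÷ sample total over all analysed
subregions **outside the focal set**; at genome scale any one set is a
negligible share of a sample's total, and excluding the focal set
reproduces that property in a desk-scale simulation with few sets — with a
single set the set itself is used). The acceptor's PercDPN is its inclusive
lower one-sided percentile of normalized X (ties take the max rank of the
tie block). The stringency threshold is

    T = p^(1 / (3(1 − 3p))),   p = PercDPN_X

which approaches the cube root of p for tiny p (few samples that low ⇒
conversions must be rare ⇒ demand an extreme donor) and the square root
near p = 0.1 (low acceptor coverage is common ⇒ conversions may be common ⇒
be lenient). The exponent is singular at p = 1/3; beyond a guard the
least-stringent square-root regime applies — events that common are
excluded upstream by the 10%-cluster rule anyway. Note T is **not**
monotone over all of (0, 1/3): it peaks near p ≈ 0.101 and decays to zero
at the singularity; candidates live below p ≈ 0.10, where T is increasing.

A candidate is a **conversion** when the donor side is coverage-*elevated*:
the one-sided percentile of normalized Y taken from the high end (fraction
of samples with normalized Y ≥ this sample's) falls below T, **and**
normalized Y exceeds 4/3 of the cohort median. The high-end donor
percentile is deliberate: a lower-tail percentile of an elevated donor is
necessarily near 1 and could never fall below T, which would make
conversions uncallable; the one-sided percentile must be taken toward the
tail being tested on each side. Failing either condition, X is called
deleted. Events not overlapping a protein-coding gene are discarded.

**Merging.** Same-sample, same-kind calls merge within a gene and across
neighbouring genes tolerating ≤ 3 intervening coding genes (≥ 1 bp of CDS
strictly between the event envelopes; genes overlapping either event host
the calls and do not count as intervening). The merged interval is the
envelope of its parts. Each conversion implies homozygous site-specific
variants: for every SUN in the converted interval, the donor allele at the
acceptor coordinate.

## Side statistics

* **Binomial sensitivity**: P(K ≥ k_min), K ~ Binomial(depth, p), with
  k_min the smallest integer with k/depth ≥ the VAF threshold (so
  0.15 × 60 → 9, inclusive), by exact summation. Whether the reference
  operating point used this ceil convention or an approximation is
  unstated; the exact tail reproduces 97.9% at (60, 0.25, 0.15).
* **Coding fraction of VAPs**: assuming synonymous VAPs are not under
  strong selection, half originate in the coding paralog; scaling by
  exome-wide missense:synonymous (1.19) and LoF:synonymous (0.043) ratios
  gives coding missense/LoF expectations and proportions. The LoF
  per-sample count is rounded to two decimals *before* forming its
  proportion — only that order reproduces the headline pair
  (0.14, 10.0%); the unrounded proportion (9.7%) is reported alongside.
* **Trio classification**: at sites with parental masked depth ≥ 60, a
  child call is de novo when both parental VAFs < 1%, inherited when either
  > 15%, and unresolved in between (the two extremes are the only defined
  regimes; the gap is reported, not forced).
* **Cohort allele frequency**: carriers ÷ cohort size on masked coordinates
  plus alleles; each (pos, ref, alt) is its own variant at multi-allelic
  sites.

## The simulator

`simcohort` generates paralog sets of common ancestry on one contig with
unique flanks/spacers: SUNs are substitution differences (one member
carries a private allele per SUN position), so the SUN count is
~ length × (1 − identity) and pairwise identities are ≥ the requested
value. Ancestral sequence is generated with homopolymer runs capped at 3 so
that the homopolymer filter stays neutral unless a test injects a tract
deliberately. Diploid samples place reads at their true origin; a read's
mapping quality is 0 when its sequence matches ≥ 2 members equally well,
otherwise it is placed on its best-matching member with high MQ — which
reproduces donor pile-up for conversions without an external aligner.
Homozygously deleted intervals emit no reads (reads spanning a deletion
breakpoint are dropped rather than split — events are exon-scale, so
breakpoint reads are a negligible edge). Sequencing errors are independent
per-base substitutions (default 10⁻³); read lengths vary uniformly ± 10%
around the nominal length, emulating adapter/quality trimming — with fixed
single-end lengths at 100×, position-plus-sequence duplicate collapsing
conflates distinct molecules and biases the masked VAF upward (~0.30
instead of 0.25 in direct measurement).

Default study conditions used by the tests and the acceptance script:
two-member target locus of 1500 bp at identity 0.99 (~15 SUNs), a
background locus of 3000 bp for normalization, depth 100×, read length
100 bp, 200-sample cohorts with 2% conversions, 2% single-paralog
deletions and 1% both-paralog deletions, single capture kit.

**What the simulator does not model**: exome capture and GC bias, indel
sequencing errors (injected explicitly where a test needs them),
platform-specific error profiles, paired-end fragment-size distributions
(paired mode uses a fixed 350 bp fragment), mosaicism, and reference bias
of a real aligner. Passing tests therefore demonstrate the logic of the
method under idealized read generation, not calling performance on real
exomes.

## Numerical and interface choices

* Coordinates are 0-based half-open internally, 1-based in TSV/VCF output.
* Strict inequalities exactly as specified: CAF filter removes > 10%;
  VAF-consistency removes only when strictly more than twice; depth/VAF
  raw thresholds are inclusive.
* Global alignment scoring: match +1, mismatch −1, gap open −2, extend
  −0.5; identity = matching columns / alignment length. Multi-member
  alignments are progressive, seeded by the highest-identity pair.
* Reverse-complement homologs carry a strand flag; SUN alleles are
  reported on each member's extracted orientation.
* `kde_clusters` is deterministic given bandwidth and grid; degenerate
  input (all values equal) is one cluster.
* R is undefined at X + Y = 0; such samples are excluded upstream by the
  30-read rule.
* Pipeline runs are deterministic given the cohort and config; the run log
  records stage timings, read-conservation counters, the seed and a config
  hash.

## Known limitations

* The internal aligner is seed-and-extend with exact 15-mers: a read whose
  every 15-mer spans a mismatch can go unplaced. At ≤ 10% divergence and
  0.1% error this is rare, and unplaced reads are counted, not silently
  dropped.
* Set I windowing operates on pairwise alignments per pseudogene; a gene
  region homologous to multiple pseudogenes is excluded rather than
  resolved into a multi-member set.
* The unmasked-VCF exclusion matches on normalized position + alleles
  only; complex multi-nucleotide representations of the same event could
  evade it.
* Heterozygous deletions and integer copy-number estimation are out of
  scope; the coverage model targets homozygous events.
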