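# Methods

This note documents the models, defaults and design choices behind
`poolvar`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Pooled calling model

Inference starts at the quality-filtered pileup (bases < Q20 and, when a
mapping-quality column is present, reads < MAPQ 10 are discarded and the
depth recomputed). For each non-reference allele at a site the caller
applies four gates:

1. **Coverage** — filtered depth ≥ `min_coverage` (default 50 reads).
2. **Frequency** — alt/depth ≥ `min_var_freq` (default 0.03, just below
   the 1/30 pooled frequency of a singleton carrier). The comparison is
   done in exact rational arithmetic (`alt·10⁴ ≥ 300·depth` in effect), so
   a frequency exactly at the floor is called; float edge artifacts cannot
   flip the decision.
3. **Significance** — one-sided exact binomial tail
   P(X ≥ alt | X ~ Binomial(depth, e)) ≤ `p_threshold` (default 0.01),
   with the error rate e = 10^(−Q̄/10) derived from the mean retained base
   quality of the site. The full significance machinery of pooled callers
   in this family is not published in detail; an exact, oracle-checkable
   binomial null is the simplest defensible choice, and both e and the
   threshold are exposed in `CallerConfig`.
4. **Strand** — when the strand filter is on (default), each strand must
   carry ≥ `min_strand_fraction` (default 10%) of the variant reads.

Multi-allelic sites are evaluated per allele, because cross-pool identity
is per-allele. Indels are reported anchored (VCF convention) and
left-aligned against the reference, so (contig, pos, ref, alt) keys are
comparable across pools; all coordinate conventions are 1-based inclusive,
and left-alignment lives in `io_formats` alongside the writers that need
it.

One deliberate semantic choice in pileup decoding: a read that carries an
indel token (`.+2TT`) supports the *indel allele*, not the reference —
this keeps depth equal to the sum of all allele counts at every site
(the invariant the downstream frequency computation relies on) and matches
how pooled callers count indel-supporting reads.

## Functional classification

Each variant receives exactly one category from a twelve-term vocabulary.
Precedence: CDS overlap → coding effect; otherwise membership of the
strand-aware 5′/3′ windows (default 300 bp) around genes → `upstream`,
`downstream`, or `upstream;downstream` when the variant is 5′-proximal to
one gene and 3′-proximal to another; otherwise `intergenic`. Window
membership is evaluated at the variant's anchor position.

Coding SNVs are translated codon-locally under the bacterial genetic code
(table 11; start-codon exceptions are ignored for effect calling):
same residue → synonymous; non-stop → stop → stopgain; stop → non-stop →
stoploss; otherwise nonsynonymous, reported as e.g. `A132V`. Coding indels
are classified purely by length mod 3 (frameshift vs nonframeshift) — a
frameshift that happens to recreate a stop codon is still a frameshift —
and reported in CDS coordinates (`261_262insCC`, `262_264del`), reverse
complemented for minus-strand genes.

Choices where the design was genuinely open:

* **Overlapping CDSs** — the most severe effect wins (stopgain >
  frameshift > stoploss > nonsynonymous > nonframeshift > synonymous); all
  affected gene ids are retained. `severity_resolution=False` falls back
  to first-gene order.
* **`upstream;downstream`** — read as proximity to two *different*
  flanking genes; for a point variant the two window sets of a single gene
  are disjoint, so the combined class can only arise from two genes.
* **Boundary-spanning deletions** — coding if at least one deleted base
  lies in the CDS. Insertions are coding when the insertion point falls
  between two CDS bases.
* **Strand-awareness of the windows** is the default and can be disabled
  (`strand_aware=False` / `--ignore-strand`); whether published 300-bp
  windows were strand-aware is generally not stated, so both behaviours
  are available.

The codon-local path is verified against a full-protein retranslation
oracle, and classification is checked to be invariant under mirroring the
genome (reverse complement + coordinate reflection).

## Pool comparison and summaries

Variant identity is the normalized key; matching requires the same allele,
not just the same position. Shared/specific sets are exact set operations;
the reported percentages round half-up to one decimal. Roll-ups:
amino-acid-changing = nonsynonymous + frameshift ins/del + nonframeshift
ins/del + stopgain + stoploss; near-gene = upstream + downstream +
upstream;downstream.

## Enrichment

One-sided (enrichment-only) hypergeometric upper tail per category over a
background universe of N genes, of which K carry the category; genes with
several labels count once per label, N counts genes. p-values are BH
step-up adjusted across all tested categories; the significance flag gates
on the FDR by default (`cutoff_on="p"` switches to the raw p-value, since
published pipelines report both conventions). Computation uses
`scipy.stats.hypergeom` and `statsmodels` `multipletests`; both are tested
against 10-line exact oracles.

## Pan-genome analysis

Edges with identity > 50%, coverage > 70% and passing significance are
kept; families are single-linkage connected components (the minimal
reading of threshold clustering; MCL-style methods are out of scope).
Coverage of a hit is ambiguous in the BLAST convention, so the stricter
`min(cov_query, cov_subject)` is the default (`coverage_mode` selects
query- or subject-only), preventing families chained through domain-only
hits. Ingested BLAST tabular hits are gated at E ≤ 1e-5; the built-in
Smith–Waterman aligner (BLOSUM62, BLAST-style affine gaps 11 open /
1 extend) produces no E-value, so its edges are gated on a raw-score floor
(default 50) instead — a deviation forced by desk scale, configurable.

A family present in every panel species is core, in exactly one specific,
otherwise dispensable. Per species: the expansion rate is core genes /
core families, *truncated* to two decimals (matching the convention used
when such rates are quoted beside their gene/family fractions — 3105/1980
is quoted as 1.56, not the rounded 1.57); the specific/core ratio is
rounded to three decimals. Count-vs-genome-size correlations are squared
Pearson r with two-sided p. Density profiles bin genes in fixed 400-kb
windows with bin starts expressed as percent of chromosome length;
per-class proportions sum to one.

Clade-aware "lineage-specific" sub-classification against a species tree
is not implemented; without a tree, dispensable is defined as
shared-by-≥2-but-not-all species, which is the classification the summary
statistics use. This is a known limitation.

## Genome statistics

GC content is computed over called bases (N excluded) to one decimal; GC
skew is (G−C)/(G+C) per window, with G+C-free windows flagged. The
terminal-inverted-repeat scan compares the chromosome prefix
position-by-position with the reverse complement of the suffix — ungapped,
because a TIR is a structural annotation, not an alignment product — and
reports the largest prefix length whose running mismatch fraction stays
within `max_mismatch_rate` (default 0.01); the scan stops after 100
consecutive mismatches. On random sequence the expected perfect-match TIR
length is geometric with ratio 1/4, so lengths ≥ 16 essentially never
arise by chance in megabase genomes.

## Synthetic data: what it emulates, and what it does not

The generator emulates a 30-vs-30 pooled design on a linear chromosome:

* **Genome** — i.i.d. bases at the target GC (default 0.72, the
  high-GC actinomycete regime), non-overlapping CDSs with ATG starts, stop
  ends and no internal stops, random strands, optional perfect terminal
  inverted repeats, and COG-style single-letter labels on ~64% of genes.
* **Mutagenesis** — per strain, SNV and indel counts are Poisson in the
  genome length. 70% of SNVs are G·C→A·T transitions by default (the
  dominant NTG lesion); the rest are uniform. No per-strain mutation load
  is published for designs like this; the desk-scale defaults
  (`snv_rate=1e-4`, `indel_rate=1e-5` per bp per strain) were chosen once
  so that a 100-kb demo pool carries a few hundred variants — comparable
  to what a ~10-Mb genome yields at genome scale — and are plain
  configuration, not assertions about any real mutagen dose.
* **Pooled sequencing** — per site, depth ~ Poisson(mean_depth), reads
  supporting a truth allele ~ Binomial(depth, f(1−e) + (1−f)e/3), strands
  Bernoulli(1/2), and a uniform emitted base quality consistent with e
  (Q40 when e = 0). Truth sites falling inside another indel's deleted
  footprint are dropped with a log message, avoiding normalization
  ambiguities; deletion footprints downstream of the anchor are not
  thinned in the emitted pileup.

Everything is deterministic given the seed (stage-specific child
generators from a `SeedSequence` spawn tree), to the byte across reruns.

Not emulated: read mapping and alignment artifacts (mismapping, clipped
ends, reference bias), correlated errors and quality trajectories along
reads, indel-adjacent error enrichment, GC-dependent coverage bias,
structural variants, and any phenotype model (pool labels are labels, not
simulated yields). Passing recovery tests therefore demonstrates that the
caller implements its thresholds and error model correctly — not that
those thresholds are optimal on real alignments, where mapping artifacts
dominate the false-positive budget.

The proteome simulator for the pan-genome stage descends core and
dispensable families from common ancestors by per-residue substitution
(default 10% divergence, far above the 50%-identity clustering threshold)
and adds novel random proteins as specific genes; it plants no paralog
expansions beyond the family structure given, no domain shuffling and no
partial-coverage homologs.

## Problem sizes used in the test suite

Tests run on one CPU in well under a minute per module: 10,000 random
sites for the caller-vs-oracle sweep, 1,000 random coding SNVs for the
retranslation oracle, 200 random graphs for the clustering oracle, 2,600
planted variants at 400× for the recovery band, a 5-species / 136-protein
panel for planted pan-genome recovery, and 1-Mb genomes for the TIR
probability bound. These sizes give 3σ Monte-Carlo bands tight enough to
detect threshold off-by-ones while keeping the full suite around fifteen
seconds.
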