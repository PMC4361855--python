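# poolvar

Pooled-mutant variant discovery and desk-scale pan-genome analysis for
bacterial genomes.

## The problem

A classical forward-genetics design for mapping a quantitative phenotype in
bacteria is **bulk-segregant pooled sequencing**: mutagenize a strain
library, select the n strains with the lowest and the n with the highest
phenotype (here two pools of 30), pool equimolar gDNA per group, sequence
each pool, and call variants from the pooled alignments. A variant carried
by k of the 30 strains segregates at pooled allele frequency k/30, so the
caller must be sensitive down to f = 1/30 ≈ 0.033. Variants shared by both
pools are background mutations of the parent strain or mutagen hot spots;
the **group-specific** variants are the phenotype candidates. Each candidate
is then classified by its functional consequence — coding effects through
the bacterial genetic code (translation table 11), or proximity to a gene
within a regulatory window (default 300 bp, strand-aware) — and the genes
with amino-acid-changing hits are tested for functional-category
over-representation with a one-sided Fisher/hypergeometric test under
Benjamini–Hochberg FDR control.

The package also implements the accompanying comparative-genomics toolkit
for *Streptomyces*-like genomes: all-vs-all protein similarity
(Smith–Waterman, BLOSUM62, affine gaps) or ingested BLAST tabular hits,
single-linkage protein-family clustering at identity > 50% and coverage
> 70%, core / dispensable / specific classification across a species panel,
expansion rates and specific/core ratios, 400-kb gene-density profiles,
GC content, GC skew, and terminal-inverted-repeat detection for linear
chromosomes.

## The model in brief

* **Calling.** Per pileup site, each non-reference allele is emitted iff
  depth ≥ 50, allele frequency ≥ 0.03 (compared as exact rationals),
  P(X ≥ alt | X ~ Binomial(depth, e)) ≤ 0.01 with e = 10^(−Q̄/10) from the
  mean retained base quality, and ≥ 10% of variant reads on each strand.
  Bases below Q20 and reads below MAPQ 10 are discarded upstream.
* **Pool comparison.** Variant identity is the left-aligned, anchored
  (contig, pos, ref, alt) key; the two call sets partition into shared and
  group-specific sets exactly.
* **Simulation.** The synthetic-data module generates a linear chromosome
  (configurable GC, default 72%), non-overlapping CDS gene models, optional
  terminal inverted repeats, per-strain Poisson mutation loads with an
  NTG-flavoured spectrum (70% G·C→A·T transitions), and pooled pileups with
  depth ~ Poisson(D), alt reads ~ Binomial(depth, f(1−e) + (1−f)e/3) and
  Bernoulli(1/2) strands — with the planted truth returned for recovery
  scoring.

## Worked example

```python
from poolvar.pipeline import PipelineConfig, run_end_to_end, recovery_metrics
from poolvar.synthetic_data import SimulationConfig

cfg = PipelineConfig(
    sim=SimulationConfig(genome_length=50_000, n_genes=30, seed=42,
                         snv_rate=2e-4, indel_rate=3e-5, mean_depth=200)
)
res = run_end_to_end(cfg, "demo_out")
c = res.comparison
print(f"pool L: {c.n_low} calls   pool H: {c.n_high} calls")
print(f"shared: {len(c.shared)}  L-specific: {len(c.specific_low)}  "
      f"H-specific: {len(c.specific_high)}")
print(res.summary.to_frame().to_string(index=False))
rm = recovery_metrics(res.calls["L"], res.truth["L"])
print(rm.to_string(index=False))
print(f"precision: {rm.attrs['precision']:.3f}")
```

prints

```
pool L: 200 calls   pool H: 204 calls
shared: 0  L-specific: 200  H-specific: 204
               category  low-specific  high-specific
      non-coding region            78             78
             intergenic            28             19
               upstream            26             29
             downstream            20             29
    upstream;downstream             4              1
          coding region           122            126
         synonymous SNV            33             36
      nonsynonymous SNV            80             71
    frameshift deletion             1              3
   frameshift insertion             4              3
 nonframeshift deletion             1              3
nonframeshift insertion             1              5
           stopgain SNV             2              5
           stoploss SNV             0              0
                  Total           200            204
 k  n_truth  n_recovered  sensitivity
 1      333          199     0.597598
 2        1            1     1.000000
precision: 1.000
```

The two pools draw independent mutations, so almost nothing is shared and
each pool's calls are group-specific. Every call matches a planted variant
(precision 1.0); singletons (k = 1, pooled frequency 1/30) sit right at the
0.03 frequency floor and are recovered at the rate the binomial error model
predicts (~0.60 at 200× — raising depth to 400× raises it accordingly),
while variants carried by three or more strains are recovered essentially
always. The category table mirrors the classification vocabulary used in
the TSV reports.

The same stages are scriptable from the shell:

```bash
poolvar simulate --seed 5 --out-dir run/
poolvar call --pileup run/pool_L.pileup --pool-id L --fasta run/genome.fa --out run/L.vcf
poolvar annotate --vcf run/L.vcf --gff run/models.gff3 --fasta run/genome.fa --out run/L.tsv
poolvar compare --low run/L.vcf --high run/H.vcf --out run/cmp.tsv
poolvar stats --fasta run/genome.fa --gc --tir --out run/stats.tsv
poolvar all --seed 5 --out-dir run_all/
```

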