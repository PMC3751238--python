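# asebias

Diagnosing — and removing — reference-mapping bias in allele-specific
expression (ASE) measurements from short-read sequencing.

## The problem

ASE is measured by aligning reads from a heterozygous sample to a genome and
counting, at each *differentiating site* (a position where the two alleles
carry different bases), how many reads carry each allele. When all reads are
aligned to a **single reference genome** with a mismatch allowance *m*, the
counts are systematically biased toward the reference allele: a read from
the alternative allele that covers a differentiating site carries at least
one mismatch, and if its window also covers *d* other differentiating
sites, it carries *d* + 1 — so whenever *d* ≥ *m* the read simply fails to
align and the alternative allele is undercounted. Two further properties
corrupt the counts without favoring a particular allele: *imperfect
mappability* (reads from repeated sequence cannot be placed uniquely) and
*indels* between the alleles (reads spanning them fail ungapped alignment).

`asebias` makes these mechanisms measurable. It simulates an exhaustive,
error-free allele-specific read set with known 50:50 truth — every *k*-base
read from every position of both strands of both alleles — aligns the reads
either to the single reference (unique alignment, Hamming distance ≤ *m*)
or to both parental genomes (unique, zero mismatches, indels masked), and
classifies every site by the three diagnostics:

* **neighbor density** *d* — the maximum number of other differentiating
  sites inside any *k*-base read window covering the focal site; sites with
  *d* ≥ *m* are biased by construction;
* **mappability** — the mean over covering read positions of
  1 / (number of genome locations that read aligns to within *m*
  mismatches); a site is reliable only at score 1 (single genome) or summed
  score 2 (dual genomes);
* **indel proximity** — an indel breakpoint within *k* − 1 bases.

Excluding flagged sites sequentially (density → mappability → indel)
restores unbiased counts from single-reference alignment. For stochastic
(real) data, each site with ≥ 20 informative reads is tested with a
two-sided exact binomial test of ref ~ Binomial(*n*, 0.5), with
Benjamini–Hochberg FDR control at 0.05.

## Worked example

```python
from asebias import RunConfig, run_pipeline
from asebias.synthetic import SimulationConfig

cfg = RunConfig(
    mode="single_reference", k=36, m=1,
    sim=SimulationConfig(seed=1, n_exons=50,
                         exon_length_range=(300, 600), snv_rate=0.01),
)
res = run_pipeline(cfg)
print(res.density_table.to_string(index=False))
```

```
 density  n_sites       q1   median       q3  n_equal  n_unequal
       0      120 0.500000 0.500000 0.500000      120          0
       1       74 0.600000 0.692308 0.787821        0         74
       2       24 0.727491 0.947368 1.000000        0         24
       3        4 0.809524 0.928571 1.000000        0          4
```

Reading this table: each row is a neighbor-density class; `median` is the
median reference proportion ref/(ref + alt) across its sites. With one
mismatch allowed, every site with no neighboring differentiating site sits
exactly at the unbiased value 0.5, while every site with ≥ 1 = *m*
neighbors over-counts the reference allele — the bias grows with density.
The sequential filter removes exactly those sites:

```
       step  n_excluded  n_remaining  frac_equal
       none           0          222    0.540541
    density         102          120    1.000000
mappability           0          120    1.000000
      indel           0          120    1.000000
```

After excluding the 102 density-flagged sites, 100% of the remaining sites
show exactly equal allele counts; 54% of sites and 94% of exons survive
filtering (`res.retention`). Running the same input in
`mode="dual_parental"` (with `m=0`) gives 0.5 at every
perfect-mappability site without any density filtering.

The same stages are available as CLI subcommands
(`asebias simulate | tile | align | annotate | quantify | run | report`);
`asebias run run.cfg` executes the whole pipeline from a flat
`key = value` config file and writes the site table, summary tables and a
log.

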