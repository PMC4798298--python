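# gxemap

Multi-locus dissection of genotype-by-environment interaction (GxE) in a
yeast backcross.

## The problem

In a cross of the BY lab strain and the 3S clinical isolate of
*Saccharomyces cerevisiae*, a frameshift mutation in *IRA2* (*ira2*Δ2933,
modelled here as a third allele `MUT`) lets some segregants form "rough"
colonies instead of the usual smooth ones — but only in particular genetic
backgrounds, and only at particular temperatures.  Screening rough
BY×3S *ira2*Δ2933 segregants at 21, 30 and 37 °C splits them into three
temperature-sensitivity classes:

* **HS** (highly sensitive): rough at 21 °C only,
* **MS** (moderately sensitive): rough at 21 and 30 °C,
* **NS** (non-sensitive): rough at all three temperatures.

Five predominant multi-locus genotypes over eight named loci (*END3*,
*FLO8*, *FLO11*, *IRA2*, *MGA1*, *MSS11*, *SFL1*, *TRR1*) plus an
unresolved Chromosome XII locus explain these classes.  Because two
different genotypes can produce the same class ("genotypic heterogeneity"),
naive pooled mapping misses loci that belong to only one of them; detecting
and dissecting that heterogeneity is the analytical core of this package.

## What the package does

* **`gxemap.rules`** — a genotype→phenotype rule engine: each rule maps a
  required allele combination to a permissive temperature set; a genotype
  expresses the union over its satisfied rules.  Mendelian expectations
  (`expected_frequency`) follow the product-of-½ rule over segregating
  required alleles, so a six-allele genotype occurs half as often as a
  five-allele one.
* **`gxemap.simulate`** — backcross meiosis (Haldane map function,
  r = (1 − e^(−2d))/2 at 3,300 bp/cM), phenotype screens, 0–5 replicate
  colony scores, pooled sequencing of class-selected pools, and ~1X
  individual sequencing, all against a desk-scale 16-chromosome map
  (~2,000 SNPs) with a machine-readable truth record.
* **`gxemap.phenotypes`** — median replicate score → smooth/rough/ambiguous
  state per temperature → class call.
* **`gxemap.bsa`** — bulk segregant analysis: per-SNP 3S-allele frequencies,
  25-SNP smoothing, a binned (100 bp) kernel-pooled binomial LOD scan
  against the null frequency 0.5, and locus calls at LOD ≥ 5 sustained over
  ≥ 20 kb with 2-LOD-drop support intervals
  (`BulkSegregantScan(...).fit()` → `BulkSegregantResults`).
* **`gxemap.hmm`** — two-state hidden Markov model (Viterbi +
  forward–backward, log-space) that reconstructs each low-coverage
  segregant's parental origin along the genome; individuals under 1.02X
  mean coverage are excluded.
* **`gxemap.scan`** — the heterogeneity scan: collapse identically
  inherited SNPs into segregating regions, drop regions within 20 kb of
  chromosome ends, Pearson χ² (df = 1) on every inter-chromosomal region
  pair, Storey q-values, significance at q ≤ 0.01, and dissection by
  partitioning on a focal region with <10% / >90% frequency calling
  (`HeterogeneityScan(...).fit()` → `HeterogeneityScanResults`).
* **`gxemap.pipeline` / `gxemap` CLI** — the end-to-end run
  (`gxemap run --seed 7 --out out/`), plus `simulate`, `phenotype`, `bsa`,
  `genotype` and `scan` subcommands over documented TSV/JSON formats.

## Worked example

Screen 100 segregants of the BY backcross at 37 °C (only the NS genotype is
rough there), pool them, and map the class:

```python
import numpy as np
from gxemap import (RuleSet, BulkSegregantScan, simulate_panel,
                    simulate_pool_counts, build_default_map, default_cross_design)

rules = RuleSet.default()
rng = np.random.default_rng(0)
gmap = build_default_map()
design = default_cross_design(gmap, "BY")

panel = simulate_panel(design, rules, n=100, screen_temperature=37, rng=rng)
counts = simulate_pool_counts(panel.genomes, mean_depth=150.0, rng=rng)
result = BulkSegregantScan(counts, gmap, design, n_individuals=100).fit()
print(result.summary())
```

prints

```
Bulk segregant LOD scan
================================================================
SNPs scanned:      909
Pooled depth/site: 149.7X mean
Call rule:         LOD >= 5.0 over >= 20000 bp, 2.0-LOD support interval
Loci called:       4
----------------------------------------------------------------
chromosome  peak  start   end  max_lod enriched_parent
      chrV 38751   1501 74100  37.8832              3S
   chrVIII 47251   9401 84000  38.3403              3S
     chrIX 60351  34401 84600  41.2410              3S
     chrXV 51751  20201 78500  36.0867              3S
```

The four calls sit on the chromosomes carrying *FLO8* (chrV), *TRR1*
(chrVIII), *FLO11* (chrIX) and *IRA2* (chrXV) — exactly the loci whose 3S
(or mutant) alleles the NS genotype requires among those segregating in the
BY backcross — and each 2-LOD support interval covers the true position
recorded in the panel's truth record.  The four loci fixed in the other
backcross (*END3*, *MGA1*, *MSS11*, *SFL1*) are invisible here and are
picked up by the 3S-backcross pools, giving eight distinct loci across the
six class pools.

The rule engine answers allele-swap questions directly:

```python
from gxemap import classify, expressed_temperatures
ns = {"END3": "BY", "FLO8": "3S", "FLO11": "3S", "IRA2": "MUT", "MGA1": "BY",
      "MSS11": "BY", "SFL1": "BY", "TRR1": "3S", "XII": "BY"}
expressed_temperatures(ns, rules)                  # {21, 30, 37} -> NS
expressed_temperatures(dict(ns, FLO11="BY"), rules)  # {21, 30}  -> MS
```

swapping *FLO11* to its BY allele removes trait expression at 37 °C only.

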