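# Methods

This note documents the models, parameter choices and numerical decisions
behind `gxemap`, and what the synthetic-data experiments do and do not show.

## Genotype→phenotype model

Trait expression is modelled as a deterministic rule system.  A
`GenotypeRule` names required alleles at a subset of loci and the set of
temperatures (⊆ {21, 30, 37} °C) at which that combination permits the rough
phenotype.  A genotype expresses the union of the temperature sets of all
rules it satisfies; the empty union is "smooth".  The default rule set holds
the five predominant multi-locus genotypes:

| rule | requirements (beyond FLO8^3S, IRA2^MUT) | temperatures |
|------|------------------------------------------|--------------|
| HS-a | MSS11^BY | 21 |
| HS-b | XII^3S, END3^BY, MGA1^BY, MSS11^3S, SFL1^BY | 21 |
| MS-a | END3^BY, MSS11^BY, TRR1^3S | 21, 30 |
| MS-b | END3^3S, MGA1^BY, MSS11^BY, SFL1^BY | 21, 30 |
| NS   | END3^BY, FLO11^3S, MGA1^BY, MSS11^BY, SFL1^BY, TRR1^3S | 21, 30, 37 |

Design notes:

* **Union, not precedence.**  Overlapping rules combine by union of
  temperature sets.  Because HS-a ⊂ MS-a ⊂ NS as requirement sets, this is
  equivalent to "the most permissive satisfied genotype wins", and every
  reachable union is one of {}, {21}, {21,30}, {21,30,37}; any other pattern
  raises, flagging an inconsistent custom rule set.
* **IRA2 is tri-allelic.**  The *ira2* frameshift is a third allele `MUT`
  that arose on a 3S chromosome; only `MUT` satisfies rules, and in read
  space `MUT` is indistinguishable from 3S.  One consequence: in the 3S
  backcross the IRA2 site is read-fixed, so pooled mapping can see IRA2 only
  in the BY backcross.
* **Penetrance is 1.**  Classes are deterministic functions of genotype; the
  score simulator has a separate `noise` knob (default 0) for robustness
  experiments.  No quantitative penetrance is inferred from data.
* **MS-b leaves FLO11 and MGA1-adjacent loci unconstrained** where the
  evidence does not pin them; the rule table encodes exactly the required
  alleles and nothing more.
* Temperature patterns not generated by the default rules (e.g. rough at
  37 °C only) are treated as impossible under these rules only, not as
  biological impossibilities.
* `GenotypeRule` itself only checks structural validity; the constraint that
  every rule requires the generally required pair (FLO8^3S, IRA2^MUT) is
  enforced by `RuleSet.validate_core_pair()`, which the packaged default set
  always passes.  This keeps small didactic rule sets constructible in
  tests.

Mendelian expectations: `expected_frequency(rule, design)` multiplies ½ per
segregating required locus (1 for a fixed match, 0 for a fixed mismatch).
An exhaustive 2^k enumeration backs this in the tests.

## Synthetic cross and sequencing

* **Map.**  Desk-scale default: 16 chromosomes of 50–150 kb (~1.6 Mb),
  SNPs every 800 bp (~2,000 markers), 3,300 bp/cM, yeast roman-numeral
  names.  This is a deliberately scaled-down stand-in for a ~12 Mb,
  36,756-SNP yeast map; the spacing keeps adjacent markers ~0.24 cM apart so
  linkage structure is realistic even though chromosomes are ~10× shorter.
  All sizes are constructor arguments and scale up.
* **Focal parent.**  The recombinant focal parent carries END3^BY, FLO8^3S,
  FLO11^3S, IRA2^MUT, MGA1^BY, MSS11^BY, SFL1^BY, TRR1^3S, XII^BY — an
  inference that reproduces the observed segregation pattern (FLO8, FLO11,
  IRA2, TRR1 segregate in the BY backcross; END3, MGA1, MSS11, SFL1, XII
  and IRA2 in the 3S backcross), configurable.  Each causal chromosome takes
  its locus' parental background throughout (the IRA2 chromosome is 3S with
  `MUT` at the IRA2 SNP); chromosomes without a causal locus are half BY /
  half 3S so that each backcross fixes roughly half the genome and partial
  chromosomes exercise the segregating-region subsetting.
* **Meiosis.**  A Markov walk per chromosome: first-SNP origin
  Bernoulli(½), adjacent-SNP switch probability r(d) = (1 − e^(−2·d_cM/100))/2
  (Haldane).  Backcross offspring take the focal or the recurrent parental
  allele per SNP; no crossover interference is modelled.
* **Screens.**  `simulate_panel` rejection-samples offspring until *n*
  express the trait at the screening temperature, recording how many were
  examined.  `simulate_class_mixture` additionally overrides the mixture
  proportions of genotype groups within a class (real screens showed
  non-Mendelian mixtures; the override lets power be studied at a chosen
  minority fraction instead of guessing a mechanism).
* **Scores.**  Rough temperatures draw uniformly from {4,5}, smooth from
  {0,1}, three replicates; `noise` replaces a replicate with uniform {0..5}.
* **Pools.**  Per-SNP depth ~ Poisson(150 by default, emulating ≥114X
  pools); each read comes from a uniformly random pool member and is flipped
  with error 0.005.  Uniform member assignment makes the 3S count exactly
  binomial, which is how it is drawn.  Finite-pool overdispersion beyond
  this (unequal culture representation) is not modelled; pools of ≥50 keep
  the plain-binomial approximation adequate.
* **Individuals.**  Per-SNP depth ~ Poisson(mean coverage), same error
  model.  The pipeline default is 1.2X: the screens this emulates sequenced
  individuals at "about 1X" *after* a 1.02X exclusion filter that removed
  only a few percent of individuals, so the pre-filter mean must sit above
  the threshold.

What the generator does **not** emulate: read-level artifacts (mapping
error, reference bias, telomeric repeat misalignment — the 20 kb telomere
exclusion is kept anyway, as in the real analysis), segregation distortion
(e.g. a selective-advantage locus linked to END3), crossover interference,
and non-Mendelian class mixtures unless explicitly overridden.  Passing
tests therefore certify the statistical machinery under clean Mendelian
conditions, not robustness to those real-data artifacts.

## Phenotype classing

Median of the replicate scores per temperature; medians in [0,1] are smooth,
[4,5] rough (bounds inclusive — the source protocol's "between 0 and 1 or 4
and 5" is ambiguous about closure; inclusive is chosen and frozen), anything
else ambiguous.  (rough, smooth, smooth) → HS, (rough, rough, smooth) → MS,
(rough, rough, rough) → NS; any other pattern, including any ambiguous
state, is unclassified — only individuals that clearly and consistently
score smooth or rough enter the analysis.  The classified fraction is
reported, never asserted (real screens classified 78.4%; noise-free
simulations classify 100%).

## Bulk segregant mapping

The scan statistic is a surrogate for a dynamic-Bayesian-network pooled
mapper: reads are aggregated into 100-bp bins, pooled around each bin under
a Gaussian kernel (σ = 33,000 bp = 10 cM), capped at twice the number of
pooled individuals (a finite pool of N segregants carries at most ~2N
effective observations per locus regardless of sequencing depth), and scored
as LOD = log10 of the binomial likelihood ratio of the pooled counts at the
local MLE frequency versus the null p = 0.5.  Calls require LOD ≥ 5 with a
consistent enriched parent sustained over ≥ 20 kb of contiguous bins
("span" is interpreted as the length of the LOD≥threshold run); one call per
run at the leftmost argmax bin; the support interval reaches the nearest
bins at LOD ≤ max − 2 on each side (chromosome end if never reached).
Frequency tracks for plotting are 25-SNP centered moving averages within
chromosomes, truncated at ends, with zero-depth SNPs excluded from the
denominators.

Numerical notes: LOD uses `xlogy` so empty bins contribute zero; exact
p̂ = 0.5 gives LOD 0; tiny negative values from floating point are clipped
to 0; each pool is scanned independently (no joint replicate model).

**Known limitation (desk scale).**  With the depth cap active everywhere,
the LOD surface is a monotone transform of the kernel-smoothed frequency,
and on 50–150 kb chromosomes the 33 kb kernel is comparable to the
chromosome itself.  Evaluation points near a chromosome end average only the
near flank, so panel sampling noise occasionally drags the argmax to an end
and the 2-LOD interval can miss a mid-chromosome causal SNP.  Measured over
200 replicates of the NS-pool experiment, recall is 100% and
support-interval coverage ~93%; at full genome scale the kernel is small
relative to chromosomes and the artifact vanishes.

## HMM genotyping

Two hidden states (BY, 3S origin in read space), initial distribution
(½, ½), Haldane transition probabilities from inter-SNP distances, and
per-read emissions: the true allele with probability 1 − ε (ε = 0.005 by
default; the source analysis does not state its emission parameters, so this
matches the simulator's read error).  Only read-segregating SNPs of the
backcross design are decoded; fixed regions are filled from the design with
posterior 1.  Hard calls come from the Viterbi path with ties broken toward
the previous state (preserving segments); confidences from forward–backward
posteriors, all in log space (summing over 36k-SNP chromosomes underflows
otherwise).  At isolated SNPs where the path state's marginal posterior
falls below ½, the reported call switches to the marginal-majority state so
called-state confidence is always in [½, 1].  Downstream code can mask calls
below a posterior threshold (pipeline default 0.9 → "N") and exclude
individuals whose decoded IRA2 state is wild type (possible only in the BY
backcross, where the mutation is read-visible).

## Heterogeneity scan

1. **Collapse**: greedy left-to-right grouping of SNPs whose inheritance
   patterns agree wherever both are observed ("N" matches anything — at ~1X
   many calls are missing and strict equality would shatter regions); the
   region keeps a consensus pattern with missing entries filled by any
   member that observed them.  Collapse is lossless where data were
   observed, and the region count is reported, not asserted (real data:
   1,399 and 767 regions in the two backcrosses).
2. **Telomere exclusion**: regions overlapping the first or last 20 kb of a
   chromosome are dropped.
3. **Pairwise χ²**: every inter-chromosomal region pair (intra-chromosomal
   correlation is linkage, not epistasis) forms a 2×2 table over
   individuals observed at both regions; Pearson χ² without continuity
   correction, df = 1; zero-margin pairs are skipped rather than assigned
   p = 1.  One test per region pair is the point of collapsing.
4. **FDR**: Storey q-values.  π₀ is estimated on the λ-grid 0.05…0.95 via
   a cubic smoothing spline evaluated at λ = 0.95, falling back to π₀ = 1
   (plain Benjamini–Hochberg behaviour) below 100 tests or when the
   estimate leaves (0, 1].  q_i = min over p_j ≥ p_i of π₀·m·p_j/rank(p_j),
   capped at 1 and monotone by construction.  Significance: q ≤ 0.01.
5. **Partition**: the panel splits on its allele at a focal region (in the
   pipeline, the region appearing in the most significant pairs); per
   subgroup, per-SNP 3S frequencies are smoothed over 25-SNP windows and
   loci are called where the smoothed frequency is < 10% or > 90%, merging
   adjacent called SNPs into intervals.

**Power criterion.**  On planted two-genotype mixtures, "the focal pairs are
recovered" is scored as: at least one significant pair links the region
containing the focal locus (MSS11) to a region containing another causal
locus.  This is the event the partition step is anchored on; exact pair
identities are not asserted because which specific partners reach
significance under Mendelian segregation is replicate-dependent (the
linked-region multiplicity around each causal locus shares the signal).

## Problem sizes and experiment design

The replicated validation experiments run at the conditions the analysis is
designed for: pools of 100 segregants at 150X (20 replicates for NS-class
recovery; the six-pool union uses one panel per class and backcross), 50
null panels of 100 unselected segregants for the FDR calibration, and 20
replicates of a 90-individual HS panel with a 70/30 MSS11^BY:MSS11^3S
mixture for power.  A full pipeline run at defaults (120 collected
segregants per backcross) takes a couple of seconds; the whole validation
suite a few minutes.

## Coordinates, formats, determinism

In memory, positions are 0-based and intervals half-open; on disk, 1-based
and closed (converters in `gxemap.io`, tested both ways).  All tabular
artifacts are headered TSV; rule sets, truth records and run summaries are
JSON.  Readers are strict: empty files, malformed rows (reported with line
numbers) and unknown chromosomes raise.  Every stochastic function takes an
explicit `numpy.random.Generator`; the pipeline derives everything from one
seed and a repeated run is byte-identical including `summary.json`, which
records the configuration, seed and package version.
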