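# Methods

## The statistic

`tdt2g` implements a family-based haplotype association test for nuclear-family
trios (two parents, one affected child) genotyped over a window of `l`
biallelic SNPs. Like every transmission/disequilibrium test it compares, over
heterozygous parents, how often a haplotype is transmitted to the affected
child against how often it is not; under the null hypothesis of no linkage a
heterozygous parent transmits either haplotype with probability 1/2 regardless
of population structure, which is what makes the family design robust to
stratification and admixture.

Multimarker TDTs that test every distinct haplotype jointly pay for the wider
alternative with degrees of freedom: `H` distinct haplotypes give an
`H − 1`-df chi-square, `H` grows with window width, and sparse counts make the
resulting associations hard to replicate in an independent sample. The
two-groups statistic collapses the haplotype space to a single contrast:

1. **Holdout split.** The trios are randomly partitioned into a training and a
   test subset (default halves; families never straddle the split, so the two
   parental genotypes of one family stay together; an odd count rounds half up
   in favor of training).
2. **Group construction.** From the training subset's transmission table,
   haplotypes with `T(h) > U(h)` form the high-risk group `g1`, haplotypes
   with `U(h) > T(h)` the low-risk group `g2`; ties stay unassigned at fit
   time.
3. **Scoring.** On the test subset, a heterozygous parental genotype is used
   iff its two haplotypes fall into different groups. A test haplotype absent
   from both groups is assigned to the group holding its most similar member
   under *length similarity* — the largest number of consecutive markers with
   matching alleles; equal best similarity to both groups leaves it
   unassigned, and any genotype with an unassigned side (or both sides in one
   group) is treated as homozygous and skipped. With `n_T` genotypes
   transmitting the `g1` side and `n_U` the `g2` side, the statistic is the
   McNemar chi-square

       2G = (n_T − n_U)² / (n_T + n_U),

   referred to chi-square with 1 df.

Because the grouping is learned on an independent half of the data, the 1-df
null law holds regardless of window width: conditional on the fitted groups
and on `n_T + n_U`, each used test genotype transmits the `g1` side with
probability 1/2 under no linkage, so `n_T` is Binomial(n, 1/2). The holdout
therefore replaces multiplicity corrections over the `3^H`-odd possible
grouping hypotheses. With a single biallelic marker and groups learned on the
scoring data itself, the statistic reduces exactly to the classic TDT
`(b − c)²/(b + c)`.

The same split/fit/score scaffolding (`holdout_wrap`) produces honest
variants of the comparison statistics:

* **classic TDT** (`tdt_single`) — one marker, 1 df;
* **heterozygosity multimarker TDT** (`tdt_mhet`) —
  `((H−1)/H) · Σ_i (T_i − U_i)²/(T_i + U_i)`, `H − 1` df. Its holdout variant
  fixes the haplotype set on training and maps unseen test haplotypes to the
  most length-similar reference haplotype (ties skip the genotype), keeping
  `df = H_train − 1`;
* **max one-vs-rest TDT** (`tdt_max`) — the largest one-vs-rest biallelic TDT
  over haplotypes. The plain form is not chi-square under the null, so only a
  Bonferroni-bounded p-value is reported (flagged); the holdout variant
  selects the argmax haplotype on training and scores it one-vs-rest on the
  test half as an exact 1-df test (implemented as a two-group model with a
  singleton `g1`).

## Phase resolution

Simulated datasets are phased by construction and carry each parent's true
(transmitted, nontransmitted) pair. Genotype data (PED/MAP) are phased per
window from family information alone: at each marker the transmitted allele of
each parent is deduced by enumerating the allele assignments consistent with
the three genotypes. A parent resolves only when that deduction is unique at
every window marker and the parent has no missing call in the window;
double-heterozygote ambiguities, missing data and Mendelian impossibilities
leave the trio unresolved and it is dropped from that window (both parents —
transmission records always come in pairs). Population-level completion of
unresolved phases (E-M or sampling-based) is deliberately out of scope: it
would trade the clean conditional null for an imputation model. The dropped
fraction is the price; it is reported by `phase_dataset` and quantified below
for the missing-data study.

A Mendelian-inconsistent child marker encountered while *reading* a PED file
is downgraded to missing for that family (and logged) rather than excluding
the family, preserving the rest of the window.

## Simulators

All simulators ascertain on an affected child by rejection sampling with
acceptance probability proportional to the penetrance of the child's
disease-locus genotype; only relative risks matter, the weight-1 genotype's
absolute penetrance (`baseline`, default 0.05) is never used by the sampler.
Penetrance models (genotype relative risk `RR = f(DD)/f(dd)`):

| model | weights by disease-allele count 0/1/2 |
|---|---|
| dominant | 1 / RR / RR |
| recessive | 1 / 1 / RR |
| additive | 1 / (1+RR)/2 / RR |

Two-locus models combine per-locus dominant (count ≥ 1) and recessive
(count = 2) indicators: `dom-and-dom`, `dom-or-dom`, `rec-or-rec`, a
`threshold` model (RR when the total disease-allele count is ≥ 2), a linear
`additive` model, and a `modified` placeholder (multiplicative per-locus
dominant). Every model accepts an explicit penetrance table override so exact
published penetrances can be plugged in. The second locus is always unlinked
to the marker block.

**Stratified null** (`simulate_stratified_null`): two subpopulations mixed in
proportion `pp`, founder haplotypes with independent Bernoulli alleles at the
subpopulation's MAF (0.5 in subpopulation 1, `q` in subpopulation 2), and
subpopulation-specific disease-allele frequencies (defaults 0.05 / 0.25). The
disease locus is unlinked to the window (`theta = 0.5`), so the design is null
by construction while naive pooled case-control contrasts would be confounded.
Defaults: 500 families, dominant RR = 2 (the calibration is insensitive to the
model when the locus is unlinked).

**Pool-based disease trios** (`simulate_disease_trios`): founder haplotypes
are drawn from a phased pool — read from ms/msHOT text or generated by
`coalescent_pool` (msprime; constant population size 10⁴, mutation and
recombination rates 1e-8 per bp, 200 haplotypes over 200 kb). Two
ascertainment steps emulate a genotyping-array panel: sites with MAF < 0.05
are discarded and the survivors thinned to every 6th site, matching array SNP
spacing. The disease site is the rightmost pool site with derived-allele
frequency in [0.1, 0.5] leaving `l` markers upstream; the window is those `l`
adjacent sites, so the susceptibility locus sits at one extreme of the block
and is never itself tested. Transmission recombines the gamete with the
partner haplotype at `rho_within` per marker interval (default 1e-8, the
low-recombination-block estimate) and decouples the disease allele from the
gamete with probability `theta` (0 = perfect linkage, 0.5 = none).

**Missing data** (`inject_missing`): exactly
`floor(proportion · n_parents · n_markers)` parent-marker cells are deleted
uniformly without replacement; a touched parent loses its stored phase so the
whole trio is re-phased from genotypes. The evaluation harness couples
proportions per replicate (nested prefixes of one uniform cell permutation),
so rate differences across proportions are paired comparisons.

**Reproducibility pairs** (`reproducibility_pair`): two independent same-size
draws from one population sampler, seeded from disjoint spawned streams.

### What the generators do and do not emulate

The generators reproduce the study designs — admixture confounding,
coalescent haplotype structure with array-like marker ascertainment,
ascertainment on an affected child, block-extreme disease placement — but not
several features of real data: genotyping error, informative missingness,
variable family structures, linkage-map heterogeneity and hotspots, or
population growth/bottlenecks. Passing calibration and power checks therefore
demonstrates correctness of the statistics under the stated sampling models,
not performance guarantees on any particular cohort.

## Evaluation studies (problem sizes as shipped)

Every rate carries an exact binomial 95% CI; stochastic checks are interval
inclusions against exact-binomial bands (99% central band of the nominal
level for calibration, a paired normal-approximation Monte-Carlo band floored
at one replicate for rate differences), never point equality.

* **Stratification type-I error**: 1000 replicates of 500 trios per design
  cell, holdout single-marker test, nominal levels 0.01 and 0.05 sharing each
  cell's replicates. The shipped grid covers (q, pp) = (0.1, 0.5) and
  (0.5, 0.5); `type1_table` accepts the full 3 × 3 grid.
* **Null law**: 2000 replicates of 1000 null trios, two-marker window,
  Kolmogorov–Smirnov against chi-square(1). The replicate size is chosen so
  the statistic's atom at zero (probability ≈ √(2/(πN)) halved by the parity
  mixture over the informative count N) stays well below the 1%-level KS
  distance at 2000 draws; McNemar discreteness elsewhere is smoothed by the
  random N.
* **Reproducibility**: 100 replicate pairs of 250 trios, width 8, dominant
  RR = 2.5. Five protocols per pair keep the scored sample size constant
  within each comparison: plain mhet on A vs the A-fitted model scored on B
  (both 250 trios), and the 2G/holdout-mhet models fitted on A's training
  half scored on A's test half vs B's matching half (125 trios each), so the
  2G first/second contrast shares the fitted model exactly and isolates
  sampling variation.
* **Missing data**: width 2, additive RR = 3.5, 250 trios, 100 replicates,
  proportions 2/5/10%, power (`theta = 0`) and calibration (`theta = 0.5`).
  Width 2 is deliberate: without phase completion a parent is dropped whenever
  any window cell is missing, so at width 8 a 10% cell-missingness rate
  removes ≈ 57% of parents (1 − 0.9⁸ per parent, squared per trio) and any
  power comparison would measure sample loss, not robustness; at width 2 the
  dropout stays proportionate (≈ 19% of parents at 10%) and the multimarker
  path is still exercised. The effect size sits at the top of the default RR
  grid {1.5, 2.5, 3.5} so the complete-data test enters the study with
  non-trivial power.

## Numerical and design choices

* **Ties.** Training ties (`T = U`) leave a haplotype unassigned at fit time,
  but it may still be group-assigned at test time through length similarity —
  this exact behavior is what the worked example requires. Similarity ties at
  test time skip the genotype (conservative; preserves the null). The max-TDT
  argmax breaks ties lexicographically.
* **Degenerate inputs.** `n_T + n_U = 0` yields statistic 0, p = 1 and a
  `no informative genotypes` flag; a window never aborts a scan. `H < 2`
  yields an `untestable` flag for mhet/max.
* **Indexing.** Internal windows are 0-based half-open; all written output
  uses 1-based inclusive marker indices.
* **Seeding.** One master seed per run; per-window split seeds are derived as
  `master XOR (start · 0x9E3779B1)` so extending a panel never reshuffles
  existing windows; evaluation harnesses draw separate spawned seeds per
  replicate for simulation, cell deletion and splitting (sharing one seed
  would couple the holdout split to the founder draws).
* **p-values.** Reported raw per window; no genome-wide multiplicity
  correction (the holdout itself is the overfitting control). Per-marker
  aggregation is the arithmetic mean of covering windows' p-values (geometric
  mean behind a flag).
* **Cross-validation** is deliberately not offered: dependence between folds
  breaks the chi-square null that the single holdout split preserves.

## Known limitations

* Parents unresolved within a window are lost; with many markers and missing
  data this is costly. Under the shipped missing-data study the power at 10%
  cell missingness sits measurably below the 2% power — the direct cost of
  analyzing only fully resolved trios — so the test suite's power-stability
  check documents this as an open failure rather than masking it. Phase
  completion would be the natural extension.
* The plain mhet statistic here is correctly calibrated on its own dataset
  (measured null rejection ≈ 0.05 at nominal 0.05, width 8), so the
  first-vs-second-dataset degradation of same-data multimarker testing is a
  null effect under these study conditions: there is no overfitting inflation
  to lose on an independent sample, and the directional check in the test
  suite sits at the Monte-Carlo noise floor (documented as an open failure).
* At the reproducibility study's conditions (width 8, dominant RR 2.5, 250
  trios, ~19 distinct haplotypes) the holdout two-groups and holdout-mhet
  tests have statistically indistinguishable second-dataset power; the
  1-df advantage of the collapsed contrast does not materialize when the
  grouping must be learned from 125 training trios over a weakly tagged
  locus. The corresponding superiority check is likewise an open failure.
* The two-locus `modified` model is a placeholder; supply a penetrance table
  for a specific published model.
* The chi-square reference is asymptotic; for very small informative counts
  an exact binomial McNemar would be preferable (not implemented).
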