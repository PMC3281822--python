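# tdt2g — the two-groups multimarker transmission/disequilibrium test

`tdt2g` is a toolkit for family-based haplotype association testing in
nuclear-family trios (two parents, one affected child). Its core is a
multimarker TDT whose null distribution stays chi-square with **one** degree
of freedom no matter how many SNPs the haplotype window spans, making
multi-SNP association scans both powerful and reproducible across independent
samples — the classic weakness of multimarker TDTs, whose `H − 1` degrees of
freedom grow with haplotype diversity and whose sparse-data findings often
fail to replicate.

It is aimed at statistical geneticists running family-trio association scans
(e.g. candidate-region or genome-wide pre-filtering for complex diseases) and
at methodologists who need the comparison statistics, the trio simulators and
the calibration/power harnesses in one place.

## The statistic

Trios are randomly split in half. On the **training** half, every distinct
window haplotype `h` is assigned to a high-risk group `g1` if heterozygous
parents transmit it more often than not (`T(h) > U(h)`), to a low-risk group
`g2` if the converse holds, and to neither on a tie. On the **test** half,
a heterozygous parental genotype is informative iff its two haplotypes land
in different groups; a haplotype unseen in training joins the group holding
its most *length-similar* member (largest run of consecutive matching
alleles), with similarity ties left unassigned. With `n_T` informative
genotypes transmitting the `g1` side and `n_U` the `g2` side, the statistic
is the McNemar chi-square

    2G = (n_T − n_U)² / (n_T + n_U)  ~  χ²(1)  under no linkage.

Because the grouping is learned on an independent half, no multiple-testing
correction over possible groupings is needed, and with a single biallelic
marker (groups learned on the scoring data) the statistic reduces exactly to
the classic TDT `(b − c)²/(b + c)`. The package also provides the classic
single-marker TDT, the `H − 1`-df heterozygosity multimarker TDT (`mhet`) and
the max one-vs-rest TDT (`max`), each in plain and holdout form, a
sliding-window scan engine with per-marker p-value maps, trio simulators
(stratified/admixed null populations; disease trios drawn from coalescent
haplotype pools; missing-data injection), and replicate-level evaluation
harnesses. Standard formats: LINKAGE PED/MAP, ms/msHOT haplotype pools, TSV
results, YAML simulation configs.

## Worked example

The two-marker textbook example ships as a deterministic fixture: 84 training
and 84 test trios (168 parental genotypes each) over markers with alleles
A/a and B/b.

```python
from tdt2g import worked_example_dataset, phase_dataset, count_transmissions
from tdt2g.two_groups import TwoGroupsTest, build_groups, cross_sample_test

train, test = worked_example_dataset()
txs, _ = phase_dataset(train, (0, 2))
table = count_transmissions(txs)
print(table)
model = build_groups(table)
print("g1 =", sorted("".join(h) for h in model.g1),
      " g2 =", sorted("".join(h) for h in model.g2))
res = cross_sample_test(TwoGroupsTest(), train, test, (0, 2))
print(f"statistic={res.statistic:.2f} df={res.df} "
      f"p={res.p_value:.4f} n_informative={res.n_informative}")
```

prints

```
TransmissionTable(AB:40/56, Ab:48/39, aB:17/10, ab:15/15; n=120)
g1 = ['Ab', 'aB']  g2 = ['AB']
statistic=3.40 df=1 p=0.0652 n_informative=85
```

Reading the output: in the training half the haplotype `AB` is nontransmitted
more often than transmitted (56 vs 40), so it forms the low-risk group, while
`Ab` (48 vs 39) and `aB` (17 vs 10) form the high-risk group; `ab` is tied
15/15 and stays out. In the test half, `ab` is mapped to the high-risk group
by length similarity (it shares a one-marker run with `Ab` and with `aB`, but
none with `AB`); the 85 informative test genotypes split 51 : 34 in favor of
the high-risk side, giving (51 − 34)²/85 = 3.40 on 1 df and p ≈ 0.065.

## Command line

```bash
tdt2g scan --ped trios.ped --map trios.map --test 2g --window 8 \
      --holdout-frac 0.5 --seed 7 --out scan.tsv --aggregate-out markers.tsv
tdt2g simulate stratified --config null.yaml --reps 100 --seed 1 --out-dir sims/
tdt2g evaluate --results-glob 'sims/*.tsv' --alpha 0.05 --out rates.tsv
```

`scan` tests every sliding window (offset 1 by default) and optionally writes
the per-marker mean-p map; `simulate` writes PED/MAP replicates plus a
provenance JSON; `evaluate` turns per-replicate result tables into
association-rate tables with exact binomial confidence intervals.

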