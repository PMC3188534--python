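# rohbench

Benchmarking autozygosity detection through runs of homozygosity (ROHs).

Long stretches of homozygous SNP genotypes usually mark *autozygosity*:
both homologous chromosome copies descend from a single recent common
ancestor, exposing rare partially recessive variants in homozygous form
(the mechanism behind inbreeding depression). SNP-level homozygosity,
however, also arises by chance and through linkage disequilibrium, so every
ROH-calling pipeline faces a trade-off between calling non-autozygous runs
(type-1 error) and missing truly autozygous ones (type-2 error). `rohbench` is
a self-contained simulation framework for measuring that trade-off and for
turning it into the quantity geneticists actually care about: the
statistical power of a whole-genome autozygosity-burden association.

It is aimed at statistical geneticists choosing ROH-calling parameters
(minimum SNP thresholds, heterozygote allowances, LD-pruning strength) for
burden or homozygosity-mapping studies.

## What is inside

- **`popsim`** — a forward-time Wright–Fisher diploid simulator:
  recombination concentrated in ~2 kb hotspots carrying 80% of a
  1.3 cM/Mb map, infinite-sites mutation (2.3 × 10⁻⁸/bp), a European-style
  bottleneck demography, and a terminal "mutational freeze" so recently
  coalesced tracts stay perfectly homozygous in the sequence. All
  parameters are rescaled by a factor λ that preserves θ = 4Nμ and
  ρ = 4Nr, which keeps LD and autozygosity structure while making the
  simulation run on a desk. An `ld_r2_curve` diagnostic (r² of random SNP
  pairs vs distance, with a lowess trend) verifies the LD regime.
- **`truthmap`** — true autozygosity from first principles: a segment
  inherited from an ancestor *g* generations back has exponentially
  distributed length with mean 1/(2*g*) Morgans, so capturing 80% of
  segments within 20 (50) generations needs a minimum length of 0.55 cM ≈
  423 kb (0.22 cM ≈ 169 kb) at 1.3 cM/Mb. Truth segments are maximal
  perfectly homozygous sequence runs at least that long.
- **`snparray`** — extracts an Affymetrix-6.0-like common-SNP panel
  (MAF-spectrum and density matched), injects genotyping error with the
  empirically observed ~3× excess of het→hom over hom→het miscalls, adds
  missingness, and applies standard GWAS QC (individual missingness > 5%,
  SNP missingness > 2%, MAF < 1%, HWE χ² p < 10⁻⁴).
- **`ldprune`** — PLINK-style sliding-window variance-inflation-factor
  pruning at the four conventional strengths (VIF > 10, 2, 1.33, 1.1).
- **`rohcall`** — the two window-based callers: a per-SNP sliding-window
  scan (PLINK `--homozyg` style) and a non-overlapping-block tagger
  (GERMLINE style, window sized as the expected SNPs per cM).
- **`evalmetrics`** — per-SNP confusion against truth pooled over
  individuals, and the signal-detection index
  d′ = probit(1 − β) − probit(α).
- **`powersim`** — the Monte Carlo burden-power design: 2,000 individuals,
  a 3,200 Mb genome split into equal "potential" segments, per-segment
  autozygosity at a small base rate, a phenotype in which the true
  autozygous count explains 1% of variance, detection thinned by the
  measured error rates, and OLS regression of phenotype on the called sum
  (power = fraction of 1,000 replicates with positive slope and p < 0.05).
  A closed-form normal approximation serves as an independent cross-check.
- **`io` / `cli`** — PED/MAP, VCF 4.2, BED and TSV readers/writers plus a
  `rohbench` subcommand CLI chaining the stages.

## Worked example

```console
$ rohbench truth --g 20 --capture 0.8
g=20 capture=0.8: threshold 0.55 cM (~423 kb)
```

Within 20 generations, 80% of autozygous segments are at least 0.55 cM
long — about 423 kb at the map-average 1.3 cM/Mb — so 423 kb is the
potential-segment size for the 20-generation burden design.

```console
$ rohbench power --type1 0.003 --detect 0.67 --base-rate 0.0036 \
    --segment-kb 423 --seed 1
power 0.689 (MC SE 0.015, 1000 reps, 7565 segments)
$ rohbench power --type1 0.005 --detect 0.60 --base-rate 0.0091 \
    --segment-kb 169 --seed 1
power 0.681 (MC SE 0.015, 1000 reps, 18935 segments)
```

The first call: a caller that falsely labels 0.3% of non-autozygous
segments and detects 67% of truly autozygous ones, on a genome of 7,565
potential 423 kb segments with a 0.36% base rate, detects the burden
association in ≈69% of replicate studies. The same library calls are
available programmatically:

```python
from rohbench import PowerConfig, simulate_power, d_prime
print(round(d_prime(0.003, 0.33), 2))          # 3.19
cfg = PowerConfig(type1=0.003, detect_rate=0.67, base_rate=0.0036,
                  segment_kb=423, n_reps=1000, seed=1)
print(simulate_power(cfg).power)               # ~0.69
```

An end-to-end benchmarking sweep over callers, thresholds, heterozygote
allowances and pruning levels on a freshly simulated population:

```bash
rohbench -v grid --scale mini --seed 0 --out grid.tsv
```

## Layout

```
src/rohbench/    gmap, popsim, truthmap, snparray, ldprune, rohcall,
                 evalmetrics, powersim, pipeline, io, cli
tests/           pytest suite (unit, property and acceptance tests)
docs/methods.md  model assumptions, parameter choices, limitations
```
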