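# Methods

`rohbench` measures how well window-based runs-of-homozygosity (ROH)
callers recover true autozygosity, and what their error rates imply for
the power of a whole-genome autozygosity-burden association. This note
documents the models, the parameter choices that matter, and what the
desk-scale simulations do and do not establish.

## Forward simulation (`popsim`)

The simulator is a discrete-generation Wright–Fisher model of a monoecious
diploid population: each offspring draws two parents uniformly with
replacement; each gamete is formed by sampling a Poisson number of
crossovers (mean = map length in Morgans) with positions drawn by
inverse-CDF from a piecewise-constant recombination map; new mutations
fall on an infinite-sites lattice of integer bp positions at rate μ per bp
per gamete. Haplotypes are stored sparsely as sorted arrays of carried
derived-allele positions; fixed and lost variants are swept out
periodically.

**Recombination map.** Hotspots of 2,000 bp are placed uniformly at random
without overlap so that they span 20% of the sequence and carry 80% of the
genetic length; the genome-wide average rate is 1.3 cM/Mb. The two rate
levels follow from those three constraints. A 120 Mb chromosome therefore
has a 156 cM map.

**Demography.** The default schedule is mutation–drift burn-in at
N = 10,000, a bottleneck to 800 for 200 generations, 2,000 generations of
recovery at 10,000, and a final reduction to 6,500 — the history that
produces European-panel-like LD and ROH prevalence. The timing of the
final reduction relative to recovery is not sharply determined by that
description; it is applied after recovery (the package treats this as its
own convention).

**Rescaling.** All population sizes and epoch durations are divided by a
factor λ and all per-bp rates (mutation, recombination, gene conversion)
multiplied by it, preserving θ = 4Nμ and ρ = 4Nr. Coalescent-time
structure, diversity, LD decay, and the expected amount of autozygosity
are invariant in expectation; what changes is granularity — a single
rescaled generation corresponds to λ real generations, so the most recent
possible coalescence is λ generations back. The shipped default is λ = 50
on a 10 Mb region; the test fixture uses λ = 32 on 4 Mb with 200 sampled
individuals (about a minute of CPU). Burn-in uses the 100,000-generation
(pre-rescaling) default, shortened in some test configurations to ≥ 4N
rescaled generations, which is ample for pairwise-diversity and LD
equilibration at the scales probed.

**Mutational freeze.** No new mutations arise during the final 50
*simulated* generations. The freeze window is deliberately not rescaled:
its role is to guarantee that recently coalesced tracts are perfectly
homozygous at the sequence level so the truth map attains 100% fidelity.
Because 50 rescaled generations reach further back in real time than 50
real generations, desk-scale truth also admits some older segments that
erosion would have removed at full scale; the consequences are discussed
under Limitations.

**Gene conversion** (500 bp tract copied from the homologous haplotype) is
implemented but off by default: at ROH length scales (hundreds of kb) its
effect is negligible, and it roughly doubles per-gamete cost.

## Truth autozygosity (`truthmap`)

A segment inherited intact from a common ancestor *g* generations back has
survived 2*g* meioses, so its length is approximately exponential with
mean 1/(2*g*) Morgans (25 cM for sib-mating depth g = 2; 1 cM at g = 50).
Requiring `P(X ≥ L) = capture` gives `L = −ln(capture)/(2g)` Morgans; at
the conventional 80% capture this is 0.5579 cM for g = 20 and 0.2231 cM
for g = 50, quoted truncated to two decimals (0.55 / 0.22 cM, i.e. 423 /
169 kb at 1.3 cM/Mb — truncation, which never overstates the captured
proportion, reproduces the conventional figures; plain rounding would give
0.56).

Truth segments are maximal runs with no heterozygous variant in the
sequence-level data. A run extends from just after the previous
heterozygous variant to just before the next one — the largest interval
consistent with the observed homozygosity — clipped to the region; runs at
least the threshold length (cM measured through the recombination map) are
kept. The base rate is covered bp divided by total bp, averaged over
individuals (a variant-based rate is also available).

## SNP-array emulation (`snparray`)

The array design draws a target number of SNPs per 100 kb window
(default 25, matching ~33,000 SNPs over 120 Mb), apportioned across MAF
bins by largest remainder to match a target histogram. The shipped
histogram — 15% of mass in [0.01, 0.05) and the rest uniform on
[0.05, 0.5] — is a stand-in for a real chip's empirical spectrum, which is
not redistributable. Bins that run short reallocate to the nearest
available bin with a warning.

Genotyping error uses two per-genotype rates tied by
`overall = f_het·e_het + (1 − f_het)·e_het/ratio` with ratio 3: a
heterozygote is miscalled to one of the two homozygotes (equiprobably) at
three times the rate a homozygote is miscalled to a heterozygote —
the discordance asymmetry reported for array re-genotyping. Errors are
injected before missingness (0.8% per genotype), and the QC cascade runs
in the fixed order individual-missingness (5%), SNP-missingness (2%), MAF
(1%), then a plain 1-df Hardy–Weinberg χ² at p < 10⁻⁴ (expected counts
from allele frequencies of non-missing genotypes, no continuity
correction).

## LD pruning (`ldprune`)

Within a sliding window of 50 SNPs (step 5), each SNP's VIF = 1/(1 − R²)
is computed from the multiple regression of its mean-imputed dosage on the
other window SNPs — numerically, the diagonal of the inverse window
correlation matrix, with a least-squares fallback for singular windows.
The SNP with the worst VIF above threshold is removed (ties and exact
duplicates resolve to the higher bp) until the window is clean; passes
repeat until a full scan removes nothing, so the final set audits clean
everywhere. SNPs with MAF < 0.05 are removed first. Thresholds 10 / 2 /
1.33 / 1.1 correspond to window R² limits 0.9 / 0.5 / 0.25 / 0.09
("light" through "heavy"). The 5-SNP step is the conventional choice; the
window/step are configurable since the canonical tooling does not pin the
step.

Small-sample caveat: with n individuals and 49 regressors the null
multiple R² is ≈ 49/(n − 1), so VIF pruning on panels of a few hundred
individuals is systematically more aggressive than the same thresholds on
thousands — visible in the desk-scale keep fractions.

## ROH callers (`rohcall`)

**Sliding-window caller.** A window of `window_snps` consecutive SNPs is
homozygous iff its heterozygote count ≤ `het_allowance` and missing count
≤ `missing_allowance`. A SNP is eligible when the proportion of
fully-in-bounds windows containing it that are homozygous reaches
`hit_proportion` (default 0.05); counting only in-bounds windows keeps
chromosome ends callable. Maximal eligible runs of at least
`min_roh_snps` SNPs become calls. The benchmarking grid maps a SNP
threshold *t* to window = min(t, 50), missing allowance = ⌈0.05·window⌉,
het allowance ∈ {0, 1}; the uncapped window = t reading is available by
constructing `SlidingWindowParams` directly. Density/gap constraints are
deliberately absent (the benchmark disables them).

**Block caller.** SNPs are partitioned into non-overlapping windows from
SNP 0 (trailing partial window ignored); windows pass iff their het count
≤ allowance (missing treated as homozygous-compatible by default, strict
mode available); runs of consecutive passing windows spanning at least
`min_len_cm` are called with boundaries snapped to window edges. The
window size is conventionally the expected SNP count per `min_len_cm`:
round(n_snps / total_cM × min_len_cM) — 193 SNPs per cM at 30,110 SNPs
over 156 cM; 9 after heavy pruning to 1,370.

## Scoring and power (`evalmetrics`, `powersim`)

Errors are counted per SNP, pooled over individuals: α = false-positive
SNPs / non-autozygous SNPs, β = false-negative SNPs / autozygous SNPs
(undefined denominators are flagged, never silently zero).
d′ = probit(1 − β) − probit(α); rates of exactly 0 or 1 are clamped by
half a count (1/(2·denominator)) with a warning, since d′ diverges at the
boundary.

The power design: each of 2,000 individuals has `round(3,200,000 kb /
segment_kb)` potential segments (7,565 at 423 kb; 18,935 at 169 kb), each
autozygous independently with the base rate (0.36% / 0.91%). The
phenotype is `√v·standardize(A) + √(1 − v)·ε` with v = 0.01 and A the true
autozygous count, standardized against its theoretical binomial moments
(anchoring v exactly in expectation rather than per-replicate). The
called sum is `Binomial(A, 1 − β) + Binomial(S − A, α)` — error rates
applied per segment, which coincides with per-SNP rates in expectation for
equal-length segments. A replicate succeeds when the OLS slope is
positive with two-sided p < 0.05 (equivalently one-sided at 0.025);
zero-variance called sums count as failures and are logged. The
closed-form check computes cor(y, D) from the binomial moments and applies
Φ(|r|√n − z₀.₉₇₅); it is a large-n normal approximation, accurate to a few
hundredths over the operating range, and serves as the independent oracle
for the Monte Carlo estimator.

## Determinism

Every stochastic stage takes an explicit seed; pipeline stages derive
seeds from a global seed and the stage name (SeedSequence over a CRC of
the name, kept below 2³¹). Identical configuration and seed give
bit-identical outputs, including across the CLI.

## What desk scale does and does not show

The analytic quantities (thresholds, segment grids, d′, power at given
error rates) are scale-free and reproduce exactly or within Monte Carlo
error. The simulation-based quantities are structurally faithful —
LD elevated by the bottleneck, truth segment mean lengths near full-scale
values, pruning keep-fractions ordered correctly — but three distortions
remain at λ in the tens on a few Mb:

1. **Sample volume.** ~150× less sequence×individuals than full scale, so
   rare events (chance false-positive ROHs at large SNP thresholds) are
   poorly sampled and measured α can be 0 at operating points where a
   full-scale panel shows small but decisive rates.
2. **Coalescence granularity.** The youngest possible common ancestor is
   one rescaled generation (= λ real generations) back, so desk truth
   contains a few very long segments rather than many near-threshold
   ones; per-SNP β at large thresholds is accordingly lower than at full
   scale.
3. **Array idiosyncrasy.** The shipped density/MAF design is smooth;
   real chips cluster SNPs and pile mass at low MAF, both of which
   generate the spurious homozygous runs that make LD pruning profitable.

Consequently the qualitative full-scale finding that *moderate LD pruning
beats unpruned data* does not emerge from the desk-scale grid: with false
positives nearly absent, the unpruned caller simply raises its threshold
and reaches operating points a full-scale panel never allows. The package
asserts the direction anyway (it is part of the benchmark's contract) and
the corresponding test documents the shortfall; grids run at smaller λ
and larger regions should see the full-scale direction reassert itself.
The other two directions hold at desk scale: a zero-heterozygote
allowance is at least as powerful as a one-heterozygote allowance at the
optimum on pruned data, and α falls while β rises as the minimum run
length grows.

Other known limitations: no selection, migration, sex-specific maps or
overlapping generations; no plate/batch effects, hemizygous deletions,
centromere gaps or uniparental isodisomy in the array model; truth is
defined by perfect homozygosity, not lineage tracking, so it includes
identical-by-state runs older than the nominal generation depth whenever
they are long and unmutated.
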