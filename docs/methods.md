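# Methods

This note documents the statistical model behind `erscan`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Setting

A replicated evolve-and-resequence (E&R) experiment: an outbred ancestral
population (G1) is split into replicate lines that evolve for *t*
generations under factorial combinations of a temperature regime (ambient /
hot) and a pollination regime (bumblebee / butterfly / generalised /
hand-pollinated control). Each line's demography is summarised by realised
per-generation effective sizes N<sub>e,g</sub> derived from census
contribution data — pollinator behaviour limits how many plants reproduce,
so bumblebee lines run at Ne ≈ 18 and the other regimes at Ne ≈ 35. The
ancestral pool and every evolved line are pool-sequenced (pools of ~22–30
individuals, target depth ~120×), giving allele frequencies but no
individual genotypes. At these sizes drift is large: detecting selection
requires an explicit neutral model, not just outlier ranking.

## Drift null and thresholds

The analytic variance of a neutral allele frequency after drifting through
the trajectory is

Var(p_t) = p0(1−p0)·[1 − Π<sub>g=1..t</sub>(1 − 1/(2N<sub>e,g</sub>))],

each factor describing one generation; `drift_variance` evaluates it and the
simulator reproduces it (method-of-moments tests at 10⁵ SNPs, 3 Monte-Carlo
SE). Null distributions of |ΔAF| and per-SNP Hudson F<sub>ST</sub> come from
forward simulation of 10⁵ neutral SNPs per population
(`simulate_neutral_null`); the 95th percentile (type-7 linear-interpolation
quantile, numpy's default — switching conventions moves thresholds by
< 0.01 at this sample size) is the population-specific threshold. The
effective |ΔAF| cut-off is the max of this neutral bound and the empirical
95th percentile of |ΔAF| observed in the matching-temperature
hand-pollinated control lines, which captures glasshouse adaptation shared
by all treatments.

Two null modes exist because observed pool-seq frequencies carry more than
drift:

* **drift** — propagates population frequencies only. This matches the
  analytic formula and is the mode behind the published-style classification
  thresholds (Ne = 18, uniform(0.1, 0.9) founders → |ΔAF|₉₅ ≈ 0.34); it is
  the default of `simulate_neutral_null`.
* **drift+sampling** — additionally pushes both endpoints through binomial
  sampling of the 2n pooled chromosomes and Poisson/binomial read sampling.
  `run_pipeline` calibrates with this mode by default: the three-step filter
  compares the thresholds against *observed* ΔAF and F<sub>ST</sub>, which
  include sampling noise, and a drift-only null would not control the
  empirical false-positive rate of the filter.

The founder-spectrum surrogate for calibration is Uniform(0.1, 0.9),
matching a MAF ≥ 0.1 variant filter and an ancestral expected heterozygosity
of ≈ 0.39; an empirical frequency vector can be supplied instead when real
data exist.

## SNP-level statistics

**Polarisation.** The "minor" allele is fixed per site as the less frequent
allele in the ancestral pool (ties break alphabetically) and held fixed
across pools, so ΔAF signs are comparable. Site filters follow PoPoolation2
semantics: summed minor count ≥ 12 across pools, every pool's depth within
[18, 150], strictly biallelic (any third allele, N, or deletion among the
observed alleles drops the site).

**Three-step filter** (per treatment): (1) all replicates shift the same
direction; (2) every replicate's |ΔAF| exceeds the effective threshold;
(3) every replicate's per-SNP Hudson F<sub>ST</sub> vs G1 exceeds its
neutral 95th percentile. Sample size for the pool estimators is the haploid
pool size 2n (not read depth); depth-aware pool-seq corrections are a
documented simplification — relative comparisons across pools sequenced
under one protocol are preserved.

**Drift-adjusted CMH.** Per SNP, replicate strata are 2×2 tables (evolved
vs ancestral × minor vs major read counts); the statistic is
(|Σ(a_r − E_r)| − ½)²/V on χ²(1). Classic CMH takes V = ΣV_r
(hypergeometric); that models read sampling only, so under drift it rejects
massively (~40% at α = 0.05 in the calibration experiment). The adjustment
adds, per stratum, w_r²·p̄(1−p̄)·d_r with w_r = n₁n₂/N and
d_r = 1 − (1 − 1/(2m_r))·Π(1 − 1/(2N<sub>e,g</sub>)) — drift plus one
pseudo-generation for sampling the 2m pooled individuals. Because the G1
library is one physical pool duplicated across strata, its read and
pool-sampling noise is perfectly correlated between replicates; the summed
variance therefore also gains p̄(1−p̄)·[((Σw)² − Σw²)/n_G1 + (Σw)²/(2m_G1)].
Without this cross term the neutral rejection rate sits near 0.09. With the
full adjustment the type-I error is 0.04–0.05 at α = 0.05 on simulated
neutral data (10⁴ SNPs, Ne = 100, depth 100×), and at d = 0 the statistic
reduces exactly to classic CMH (verified against statsmodels'
StratifiedTable). The continuity correction is on by default and
switchable.

**Classification.** Regime-level ΔAF (replicate mean by default; the
per-replicate minimum-magnitude variant is available) in ambient vs hot maps
each SNP to background / global adaptation / conditional (ambient or hot) /
antagonistic pleiotropy against the two regimes' effective thresholds.
Classification is attempted only for SNPs passing the concordance filter in
at least one regime; the rest are background.

## Region level

Scores are −log₁₀(q) − ξ with q the BH-adjusted CMH p-value (a flag switches
to raw p); ξ = 1 (relaxed, the default used for candidate annotation) or 2
(strict). The Lindley process accumulates them per chromosome. The null for
its maximum is built by permuting the observed scores across SNP positions
within the chromosome — preserving the score distribution while destroying
spatial clustering — tiling the chromosome into windows of a width drawn
uniformly from 10–70 kb per resample (restarting the process at window
boundaries; a fixed grid of widths is available by flag), and recording the
max windowed Lindley value of each of 5000 resamples. A method-of-moments
Gumbel fit (β = sd·√6/π, μ = mean − γβ; closed-form, deterministic under the
seed) gives the threshold μ − β·ln(−ln(1−α)) at α = 0.05. Segments are one
per excursion whose peak exceeds the threshold, reported from the first SNP
after the last zero to the peak SNP (the significant core, not the full
return-to-zero excursion). All-non-positive scores yield a degenerate fit
and an infinite threshold — nothing is callable, by design.

A consensus candidate interval is a segment containing ≥ 1 filter-passing
SNP **and** ≥ 1 CMH-significant SNP (a stricter ≥ k option exists). Genes
overlap by ≥ 1 bp under 1-based inclusive coordinates; GO enrichment is the
classic one-sided hypergeometric test per term against all annotated genes
(no term-hierarchy propagation), BH-corrected.

## Synthetic-data generator

`simulate_er_experiment` draws founder minor-allele frequencies once
(uniform or truncated-beta spectrum, bounded by maf_min = 0.1), shares them
across all populations, and evolves each line independently: deterministic
genic selection p* = p(1+s)/(1+ps) then binomial sampling of 2·Ne copies per
generation. Coefficients are regime-specific (s_ambient in ambient lines,
s_hot in hot lines, 0 in controls), so planted loci realise every class of
the ambient/hot scheme. Sequencing is binomial pool sampling of 2n
individuals, Poisson depth (default 120×), binomial reads, optional
symmetric error. G1 is sequenced once and reused by every comparison,
mirroring the duplicated ancestral library. With `select_minor` (default) a
positive coefficient favours whichever founder allele is below 0.5 — sweeps
rise from standing variation instead of nudging an allele already near
fixation; relative signs of (s_ambient, s_hot), and hence expected classes,
are unchanged.

Free recombination between SNPs is the default; `block_size > 0` switches on
block-copy mode, where SNPs within a window share one founder frequency and
one trajectory, creating the spatial clustering the local score needs.

What it does **not** emulate: linkage with realistic recombination maps
(block-copy is an idealisation with perfect within-block correlation and
none between), dominance and diploid selection, selfing-rate dynamics,
variable mapping/repeat artefacts, reference bias, or base-calling error
structure. Passing tests therefore demonstrate correct behaviour of the
statistics under the stated model, not robustness to alignment artefacts in
real data.

## Problem sizes and numerical choices

Test and demonstration runs use 10⁵-SNP nulls (thresholds stable to ~0.005),
10⁴-SNP neutral experiments for CMH calibration, and 1500-SNP two-chromosome
genomes with five planted 200-kb blocks for the end-to-end recovery
experiment (10 seeded runs; ≈ 86% of blocks recovered as consensus
intervals, < 1% of neutral SNPs passing the filter). Local-score nulls use
1000–2000 resamples in tests and 5000 by default in production runs; the
threshold shifts by < 2% between these settings. Degenerate inputs are
handled explicitly: empty trajectories mean d = 0, all-zero CMH strata are
dropped with a warning, per-SNP F<sub>ST</sub> with a zero denominator is
excluded from aggregates and nulls, windows with S < 2 flag Tajima's D as
undefined (NaN), and q = 0 scores are capped with a warning. Every
stochastic routine takes an explicit seed and fixed seeds fix all outputs
byte-for-byte.

## Known limitations

* Pool estimators use haploid pool size, not depth-aware corrections —
  absolute π/θ/D values are biased for pool-seq (negatively for D), and only
  contrasts among pools are meaningful.
* The CMH drift adjustment uses a normal-scale variance inflation, not the
  full likelihood of the published E&R variance decomposition; its contract
  is exact reduction to classic CMH at d = 0 and simulated type-I-error
  calibration, both under test.
* The local-score resampling scheme (permutation within chromosome, uniform
  window width) is one reasonable reading of "resampled trajectories over
  10–70 kb windows"; the alternative fixed-grid reading is implemented
  behind a flag and yields similar thresholds on test data.
* Ne trajectories are taken as known inputs; the package does not estimate
  Ne from the data.
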