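# erscan

Drift-calibrated selection scans for **evolve-and-resequence (E&R) pool-seq
experiments** — built for factorial designs such as a temperature ×
pollination evolution experiment in *Brassica rapa*, where replicate plant
lines evolve for a handful of generations under small, treatment-specific
effective population sizes and are then pool-sequenced against the shared
ancestral (G1) pool.

At small Ne, genetic drift alone moves allele frequencies far enough to mimic
selection; every statistic in this package is therefore calibrated against a
neutral Wright–Fisher null parameterised by the *realised* per-generation
effective sizes N<sub>e,g</sub> of each replicate line.

## Who it is for

Researchers analysing replicated E&R designs from pooled sequencing
(PoPoolation2-style sync files) who need selection candidates that survive an
explicit drift model, replicate concordance, and region-level aggregation —
and a simulator to validate the whole pipeline end to end.

## The model

**Neutral drift null.** After *t* generations of drift through effective
sizes N<sub>e,g</sub>, the allele-frequency variance is

    Var(p_t) = p0 (1 − p0) [ 1 − Π_{g=1..t} (1 − 1/(2 N_e,g)) ]

Forward simulation of 10⁵ neutral SNPs under each line's trajectory yields
null distributions of |ΔAF| = |AF<sub>final</sub> − AF<sub>G1</sub>| and
per-SNP Hudson F<sub>ST</sub>; their 95th percentiles are the
population-specific significance thresholds. The effective |ΔAF| cut-off is
the **max** of the simulated neutral bound and an empirical baseline from
hand-pollinated control lines.

**SNP-level evidence.** Three filters must agree across replicates: shared
ΔAF direction, |ΔAF| above the effective threshold in *every* replicate, and
per-replicate Hudson F<sub>ST</sub> above its neutral 95th percentile. A
replicated Cochran–Mantel–Haenszel test combines the per-replicate 2×2
allele-count tables against the (shared) ancestral pool; its stratum
variances are inflated by the drift variance the read counts cannot see, plus
a covariance term because the G1 library is duplicated across replicate
strata. SNPs are classed per pollination regime by comparing ambient and hot
ΔAF: *background*, *global adaptation* (same-signed shifts above threshold in
both regimes), *conditional* (one regime), or *antagonistic pleiotropy*
(opposite signs in both).

**Region-level evidence.** BH-adjusted CMH q-values become scores
−log₁₀(q) − ξ (ξ = 1 relaxed, ξ = 2 strict); the Lindley process
h<sub>i</sub> = max(0, h<sub>i−1</sub> + s<sub>i</sub>) accumulates runs of
moderately significant SNPs; chromosome-specific thresholds come from a
Gumbel fit to the maxima of 5000 permuted score trajectories over 10–70 kb
windows. A local-score segment becomes a **consensus candidate interval**
only if it also contains ≥ 1 filter-passing SNP and ≥ 1 CMH-significant SNP;
candidates are then intersected with gene models (GFF3) and tested for GO
enrichment (classic one-sided Fisher/hypergeometric, BH-corrected).

A forward Wright–Fisher simulator (`erscan.synthetic_data`) generates the
whole design — founder spectrum, per-generation Ne, regime-specific selection
(including sign-flipped coefficients), pool sampling of individuals and
read-depth noise — and emits sync files plus a planted-truth table.

## Worked example

Simulate one hot-regime treatment (2 replicates, Ne = 35 per generation, six
generations, 25-plant pools at ~100× depth) with one planted selected block
(s_hot = 0.6, block-copy mode), then run the full pipeline:

```python
from erscan import (PoolDesign, SelectedLocus, SimConfig, run_pipeline,
                    simulate_er_experiment, sites_to_frequencies)
from erscan.pipeline import PipelineConfig

traj = (35,) * 6
designs = (PoolDesign("G1", "ancestral", "ancestral", "-", 25, ()),
           PoolDesign("HGA", "hot", "generalised", "A", 25, traj),
           PoolDesign("HGB", "hot", "generalised", "B", 25, traj))
cfg = SimConfig(designs=designs, n_chromosomes=1, snps_per_chromosome=500,
                chromosome_length=2_500_000, block_size=200_000,
                selected_loci=(SelectedLocus(250, 0.0, 0.6),),
                depth_mean=100.0, seed=42)
sim = simulate_er_experiment(cfg)
freq = sites_to_frequencies(sim.combined_sync_records(), sim.designs)
res = run_pipeline(freq, sim.designs,
                   PipelineConfig(n_null_snps=50_000, n_resample=2000,
                                  depth_mean=100.0, seed=0))
print(res.summary.to_string(index=False))
```

prints

```
      treatment  n_fst_pass_snps  n_cmh_sig_snps  n_consensus_intervals           intervals  total_interval_bp
hot-generalised               35              34                      1 A01:1200351-1390163             189813
```

The planted block (truth table: `A01:1250449`, class `conditional_hot`) is
recovered as the single consensus interval: 35 SNPs beat the calibrated
thresholds (here |ΔAF|₉₅ ≈ 0.33 under the Ne = 35 drift+sampling null), 34
are CMH-significant at FDR < 0.05, and the local-score segment containing
both spans 190 kb around the planted 200-kb block. Neutral SNPs elsewhere on
the chromosome produce no interval.

A thin CLI wraps the same stages:

```bash
erscan simulate --seed 3 --out sim/ --selected 100:0.5:-0.5
erscan all --sync all.sync --design design.tsv --out results/ --xi 1 --seed 1
```

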