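"""Neutral expectations for allele-frequency change under realised demography.

The analytic single-locus variance after ``t`` generations of pure drift is

    Var(p_t) = p0 (1 - p0) [1 - prod_g (1 - 1/(2 N_e,g))]

with one factor per generation; forward simulation of neutral SNPs under the
same trajectories yields the full null distributions of |ΔAF| and per-SNP
Hudson FST, whose 95th percentiles are the population-specific significance
thresholds.  The effective |ΔAF| cut-off is the larger of the simulated
neutral bound and an empirical baseline measured on hand-pollinated control
populations (which experience glasshouse selection but no pollinator-mediated
selection).

Two null modes are provided: ``drift`` propagates population frequencies only
(this matches the analytic formula, and is what the study's published
thresholds correspond to), while ``drift+sampling`` additionally pushes the
initial and final frequencies through pool- and read-sampling so that the
null is commensurable with observed pool-seq estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ConfigError, PoolDesign
from .popgen_stats import hudson_fst_snp
from .synthetic_data import pool_read_counts, wf_step


@dataclass(frozen=True)
class NullDistribution:
    """Simulated neutral samples of |ΔAF| and per-SNP Hudson FST."""

    population: str
    daf: np.ndarray
    fst: np.ndarray
    mode: str
    seed: int

    def __post_init__(self):
        if (self.daf < 0).any() or (self.daf > 1).any():
            raise ValueError("|dAF| samples must lie in [0, 1]")


@dataclass(frozen=True)
class ThresholdSet:
    """Per-population calibrated thresholds; the effective |ΔAF| cut-off is
    the max of the neutral and control bounds, with a provenance flag."""

    population: str
    daf95_neutral: float
    fst95_neutral: float
    daf95_control: float
    effective_daf: float
    daf_source: str          # "neutral" | "control" | "tie"
    fst95_effective: float

    def __post_init__(self):
        if self.effective_daf + 1e-12 < max(self.daf95_neutral, self.daf95_control):
            raise ValueError("effective_daf must dominate both inputs")


def drift_variance(p0, ne_trajectory: Sequence[int]):
    """Analytic variance of the allele frequency after drifting through the
    given Ne trajectory; 0 for an empty trajectory.  Vectorised over p0."""
    p0 = np.asarray(p0, dtype=float)
    if ((p0 < 0) | (p0 > 1)).any():
        raise ValueError("p0 must lie in [0, 1]")
    prod = 1.0
    for ne in ne_trajectory:
        if ne < 1:
            raise ValueError("every N_e,g must be >= 1")
        prod *= 1 - 1 / (2 * ne)
    out = p0 * (1 - p0) * (1 - prod)
    return float(out) if out.ndim == 0 else out


def drift_factor(ne_trajectory: Sequence[int], pool_size: int | None = None) -> float:
    """The bracketed drift term d = 1 - prod(1 - 1/(2 Ne,g)), optionally with
    one extra pseudo-generation for pool sampling of 2·pool_size individuals
    (used by the CMH variance adjustment)."""
    prod = 1.0
    for ne in ne_trajectory:
        if ne < 1:
            raise ValueError("every N_e,g must be >= 1")
        prod *= 1 - 1 / (2 * ne)
    if pool_size is not None:
        prod *= 1 - 1 / (2 * pool_size)
    return 1 - prod


def simulate_neutral_null(founder_spectrum, ne_trajectory: Sequence[int],
                          n_snps: int = 100_000, mode: str = "drift",
                          n_individuals: int = 25, depth_mean: float = 120.0,
                          ancestral_individuals: int | None = None,
                          population: str = "", seed: int = 0) -> NullDistribution:
    """Simulate ``n_snps`` neutral loci through the Ne trajectory.

    ``founder_spectrum`` is either an array of founder frequencies to resample
    from, a callable ``f(n, rng) -> frequencies``, or the string
    ``"uniform"`` for the default Uniform(0.1, 0.9) surrogate of the
    MAF-filtered ancestral spectrum.  In ``drift`` mode |ΔAF| and FST are
    computed from true population frequencies (sample sizes per the design,
    n = 2·n_individuals); in ``drift+sampling`` mode both endpoints are
    additionally passed through pool- and read-sampling.
    """
    if n_snps < 1:
        raise ConfigError("n_snps must be >= 1")
    if mode not in ("drift", "drift+sampling"):
        raise ConfigError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    if callable(founder_spectrum):
        p0 = np.asarray(founder_spectrum(n_snps, rng), dtype=float)
    elif isinstance(founder_spectrum, str):
        if founder_spectrum != "uniform":
            raise ConfigError(f"unknown spectrum {founder_spectrum!r}")
        p0 = rng.uniform(0.1, 0.9, n_snps)
    else:
        pool = np.asarray(founder_spectrum, dtype=float)
        p0 = rng.choice(pool, size=n_snps, replace=True)

    pt = p0.copy()
    for ne in ne_trajectory:
        pt = wf_step(pt, ne, 0.0, rng)

    n_anc = ancestral_individuals or n_individuals
    if mode == "drift":
        f0, f1 = p0, pt
    else:
        k0, d0 = pool_read_counts(p0, n_anc, depth_mean, 0.0, rng)
        k1, d1 = pool_read_counts(pt, n_individuals, depth_mean, 0.0, rng)
        f0, f1 = k0 / d0, k1 / d1

    daf = np.abs(f1 - f0)
    _, _, fst = hudson_fst_snp(f0, f1, 2 * n_anc, 2 * n_individuals)
    return NullDistribution(population, daf, np.asarray(fst), mode, seed)


def neutral_quantile(null, q: float = 0.95) -> float:
    """Empirical q-quantile of the null |ΔAF| samples (type-7 linear
    interpolation, numpy's default)."""
    samples = null.daf if isinstance(null, NullDistribution) else np.asarray(null)
    if samples.size == 0:
        raise ValueError("empty null distribution")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    return float(np.quantile(samples, q))


def control_baseline(control_daf, q: float = 0.95) -> float:
    """Empirical q-quantile of |ΔAF| pooled over the matching-temperature
    control populations (glasshouse background change)."""
    samples = np.asarray(control_daf, dtype=float)
    if samples.size == 0:
        raise ValueError("control |dAF| samples are empty")
    return float(np.quantile(np.abs(samples), q))


def effective_threshold(neutral: float, control: float) -> tuple[float, str]:
    """Max of the neutral and control bounds, flagging which dominated."""
    if neutral < 0 or control < 0:
        raise ValueError("thresholds must be non-negative")
    if neutral > control:
        return neutral, "neutral"
    if control > neutral:
        return control, "control"
    return neutral, "tie"


def calibrate_thresholds(designs: Sequence[PoolDesign],
                         control_daf_by_temp: dict[str, np.ndarray] | None = None,
                         founder_spectrum="uniform", n_snps: int = 100_000,
                         mode: str = "drift", depth_mean: float = 120.0,
                         q: float = 0.95, seed: int = 0) -> list[ThresholdSet]:
    """Build a ThresholdSet for every evolved pool in the design.

    ``control_daf_by_temp`` maps temperature regime to the pooled observed
    |ΔAF| samples of its hand-pollinated control populations; when absent the
    control bound is 0 and the neutral bound decides.
    """
    anc = [d for d in designs if d.is_ancestral]
    n_anc = anc[0].n_individuals if anc else None
    out = []
    for i, d in enumerate(designs):
        if d.is_ancestral:
            continue
        null = simulate_neutral_null(
            founder_spectrum, d.ne_trajectory, n_snps=n_snps, mode=mode,
            n_individuals=d.n_individuals, depth_mean=depth_mean,
            ancestral_individuals=n_anc, population=d.pool_id,
            seed=np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        daf95 = neutral_quantile(null, q)
        # sites fixed identically in both endpoints have an undefined per-SNP
        # FST (zero denominator) and drop out of the null, as in the scan
        fst95 = float(np.nanquantile(null.fst, q))
        ctrl = 0.0
        if control_daf_by_temp and d.temperature in control_daf_by_temp \
                and d.pollination != "control":
            ctrl = control_baseline(control_daf_by_temp[d.temperature], q)
        eff, src = effective_threshold(daf95, ctrl)
        out.append(ThresholdSet(d.pool_id, daf95, fst95, ctrl, eff, src, fst95))
    return out


def thresholds_frame(thresholds: Sequence[ThresholdSet]) -> pd.DataFrame:
    """Threshold report table (one row per population)."""
    return pd.DataFrame([{
        "population": t.population, "daf95_neutral": t.daf95_neutral,
        "fst95_neutral": t.fst95_neutral, "daf95_control": t.daf95_control,
        "effective_daf": t.effective_daf, "daf_source": t.daf_source,
        "fst95_effective": t.fst95_effective} for t in thresholds])
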