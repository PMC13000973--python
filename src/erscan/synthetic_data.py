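"""Forward Wright–Fisher simulator for evolve-and-resequence pool-seq designs.

Generates biallelic allele-count data for a factorial temperature ×
pollination experiment: founder frequencies are drawn once and shared by all
populations (one ancestral G1 pool), each evolved replicate line then drifts
independently for ``t`` generations under its per-generation effective sizes
N_e,g, with optional genic selection whose coefficient depends on the
temperature regime (s_ambient / s_hot; control lines are always neutral).
Sequencing is modelled in two stages: binomial sampling of 2·n individuals
from the population frequency, then Poisson read depth and binomial read
counts, mirroring pool-seq.  Output is one sync file per population plus a
design table and a planted-truth table, so every downstream stage of the scan
is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (ConfigError, PoolDesign, SyncRecord, write_design,
                         write_sync)

_NUCS = np.array(["A", "T", "C", "G"])
_SYNC_IDX = {"A": 0, "T": 1, "C": 2, "G": 3}


@dataclass(frozen=True)
class SelectedLocus:
    """A planted locus: global SNP index and its regime-specific coefficients."""
    index: int
    s_ambient: float
    s_hot: float


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic E&R experiment.

    Defaults follow the study conditions: 6 generations, mean pool depth
    120x, founder minor-allele frequencies bounded away from 0/1 by
    ``maf_min`` = 0.1 (the MAF filter applied to the real data; the uniform
    spectrum then has expected heterozygosity ≈ 0.39, matching the ancestral
    pool).  ``block_size`` > 0 switches on block-copy mode: SNPs within a
    block share one founder frequency and one drift/selection trajectory,
    creating the spatial clustering that region-level scans look for.
    ``select_minor`` makes a positive coefficient favour whichever founder
    allele is below frequency 0.5 (sweeps rise from standing variation rather
    than saturating an allele already near fixation); the relative signs of
    (s_ambient, s_hot) — and hence the expected class — are preserved.
    """

    designs: tuple[PoolDesign, ...]
    n_chromosomes: int = 2
    snps_per_chromosome: int = 1000
    chromosome_length: int = 5_000_000
    founder_spectrum: str = "uniform"       # "uniform" | "beta"
    beta_params: tuple[float, float] = (0.7, 0.7)
    maf_min: float = 0.1
    generations: int = 6
    selected_loci: tuple[SelectedLocus, ...] = field(default_factory=tuple)
    depth_mean: float = 120.0
    sequencing_error_rate: float = 0.0
    block_size: int = 0                      # bp; 0 = free recombination
    select_minor: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.maf_min < 0.5:
            raise ConfigError("maf_min must lie in (0, 0.5)")
        if self.generations < 1:
            raise ConfigError("generations must be >= 1")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be > 0")
        if not 0 <= self.sequencing_error_rate < 0.5:
            raise ConfigError("sequencing_error_rate must lie in [0, 0.5)")
        for loc in self.selected_loci:
            if abs(loc.s_ambient) >= 1 or abs(loc.s_hot) >= 1:
                raise ConfigError("|s| must be < 1")
            if not 0 <= loc.index < self.n_snps:
                raise ConfigError(f"selected locus index {loc.index} out of range")
        evolved = [d for d in self.designs if not d.is_ancestral]
        if not evolved:
            raise ConfigError("design needs at least one evolved pool")
        for d in evolved:
            if len(d.ne_trajectory) != self.generations:
                raise ConfigError(
                    f"pool {d.pool_id}: ne_trajectory length "
                    f"{len(d.ne_trajectory)} != generations {self.generations}")

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome


def default_design(generations: int = 6, n_individuals: int = 25,
                   ne_bumblebee: int = 18, ne_other: int = 35,
                   pollinations: Sequence[str] = ("bumblebee", "butterfly",
                                                  "generalised", "control"),
                   temperatures: Sequence[str] = ("ambient", "hot"),
                   replicates: Sequence[str] = ("A", "B")) -> tuple[PoolDesign, ...]:
    """The study layout: 2 temperatures × 4 pollination regimes × 2
    replicates plus the ancestral G1 pool.  Bumblebee lines get the small
    realised Ne (≈18) imposed by the restricted-visitation protocol; the
    other regimes get Ne ≈ 35.  Trajectories are constant at those means."""
    pools = [PoolDesign("G1", "ancestral", "ancestral", "-", n_individuals, ())]
    code = {"ambient": "C", "hot": "H"}
    pcode = {"bumblebee": "B", "butterfly": "P", "generalised": "G", "control": "H"}
    for temp in temperatures:
        for poll in pollinations:
            ne = ne_bumblebee if poll == "bumblebee" else ne_other
            for rep in replicates:
                pid = f"{code[temp]}{pcode[poll]}{rep}"
                pools.append(PoolDesign(pid, temp, poll, rep, n_individuals,
                                        (ne,) * generations))
    return tuple(pools)


# ---------------------------------------------------------------------------
# primitive draws
# ---------------------------------------------------------------------------

def draw_founder_spectrum(n_snps: int, config: SimConfig,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw founder minor-allele frequencies from the configured surrogate
    spectrum, truncated to [maf_min, 1 - maf_min]."""
    if n_snps < 1:
        raise ConfigError("n_snps must be >= 1")
    lo, hi = config.maf_min, 1 - config.maf_min
    if config.founder_spectrum == "uniform":
        return rng.uniform(lo, hi, n_snps)
    if config.founder_spectrum == "beta":
        a, b = config.beta_params
        out = np.empty(n_snps)
        need = np.ones(n_snps, dtype=bool)
        while need.any():  # rejection sampling keeps the shape within bounds
            draw = rng.beta(a, b, int(need.sum()))
            ok = (draw >= lo) & (draw <= hi)
            idx = np.nonzero(need)[0][ok]
            out[idx] = draw[ok]
            need[idx] = False
        return out
    raise ConfigError(f"unknown founder spectrum {config.founder_spectrum!r}")


def wf_step(p, ne: int, s, rng: np.random.Generator):
    """One Wright–Fisher generation: deterministic genic selection
    p* = p(1+s)/(1+ps), then binomial sampling of 2·ne allele copies.
    Vectorised over loci; 0 and 1 are absorbing."""
    p = np.asarray(p, dtype=float)
    if ne < 1:
        raise ConfigError("ne must be >= 1")
    s = np.asarray(s, dtype=float)
    pstar = p * (1 + s) / (1 + p * s)
    return rng.binomial(2 * ne, pstar) / (2 * ne)


def pool_read_counts(p, n_individuals: int, depth_mean: float, err: float,
                     rng: np.random.Generator):
    """Two-stage pool-seq sampling.

    2·n_individuals chromosomes are drawn binomially at frequency ``p``
    giving the pool frequency p̂; read depth is Poisson(depth_mean) (floored
    at 1 read) and the minor-read count binomial at p̂ pushed toward 0.5 by a
    symmetric sequencing-error rate.  Returns (minor_count, depth) arrays.
    """
    p = np.asarray(p, dtype=float)
    if n_individuals < 1:
        raise ConfigError("n_individuals must be >= 1")
    if not 0 <= err < 0.5:
        raise ConfigError("err must lie in [0, 0.5)")
    phat = rng.binomial(2 * n_individuals, p) / (2 * n_individuals)
    pread = phat * (1 - err) + (1 - phat) * err
    depth = np.maximum(rng.poisson(depth_mean, size=p.shape), 1)
    minor = rng.binomial(depth, pread)
    return minor, depth


# ---------------------------------------------------------------------------
# whole-experiment simulation
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """In-memory result of one simulated experiment.

    ``freqs`` are true minor-allele population frequencies per pool
    (ancestral pool = founder frequencies); ``counts``/``depths`` the
    sequenced pool read counts.  ``truth`` is the planted-truth table with
    the class label each selected locus is expected to earn.
    """

    config: SimConfig
    chrom: np.ndarray       # per SNP
    pos: np.ndarray
    ref: np.ndarray         # major/reference base per SNP
    alt: np.ndarray         # minor base per SNP
    founder: np.ndarray     # founder minor-allele frequency per SNP
    freqs: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]
    depths: dict[str, np.ndarray]
    truth: pd.DataFrame
    block_id: np.ndarray | None = None

    @property
    def designs(self) -> tuple[PoolDesign, ...]:
        return self.config.designs

    def sync_records(self, pool_id: str) -> list[SyncRecord]:
        k = self.counts[pool_id]
        d = self.depths[pool_id]
        recs = []
        for i in range(len(self.pos)):
            counts = np.zeros(6, dtype=np.int64)
            counts[_SYNC_IDX[self.alt[i]]] = k[i]
            counts[_SYNC_IDX[self.ref[i]]] = d[i] - k[i]
            recs.append(SyncRecord(str(self.chrom[i]), int(self.pos[i]),
                                   str(self.ref[i]), counts))
        return recs

    def combined_sync_records(self) -> list[SyncRecord]:
        """All pools side by side, in design order (read_sync compatible)."""
        ids = [d.pool_id for d in self.designs]
        ks = np.stack([self.counts[i] for i in ids], axis=1)
        ds = np.stack([self.depths[i] for i in ids], axis=1)
        recs = []
        for i in range(len(self.pos)):
            counts = np.zeros((len(ids), 6), dtype=np.int64)
            counts[:, _SYNC_IDX[self.alt[i]]] = ks[i]
            counts[:, _SYNC_IDX[self.ref[i]]] = ds[i] - ks[i]
            recs.append(SyncRecord(str(self.chrom[i]), int(self.pos[i]),
                                   str(self.ref[i]), counts))
        return recs

    def write(self, outdir) -> dict[str, Path]:
        """Emit one sync file per population, the design TSV and truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for d in self.designs:
            p = outdir / f"{d.pool_id}.sync"
            write_sync(self.sync_records(d.pool_id), p)
            paths[d.pool_id] = p
        write_design(self.designs, outdir / "design.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        paths["design"] = outdir / "design.tsv"
        paths["truth"] = outdir / "truth.tsv"
        return paths


def _expected_class(s_a: float, s_h: float) -> str:
    if s_a == 0 and s_h == 0:
        return "background"
    if s_a != 0 and s_h == 0:
        return "conditional_ambient"
    if s_a == 0 and s_h != 0:
        return "conditional_hot"
    return "global_adaptation" if np.sign(s_a) == np.sign(s_h) \
        else "antagonistic_pleiotropy"


def simulate_er_experiment(config: SimConfig) -> SimResult:
    """Run the full forward simulation for every pool in the design.

    Founder frequencies are drawn once; the ancestral pool is sequenced once
    from them and shared by all downstream comparisons.  Replicates of a
    treatment share founders but drift independently.  Selection at planted
    loci uses s_ambient in ambient lines and s_hot in hot lines; control
    (hand-pollinated) lines are neutral at every locus.
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_snps

    # coordinates: evenly spaced with jitter, sorted per chromosome
    chroms = np.repeat([f"A{c + 1:02d}" for c in range(config.n_chromosomes)],
                       config.snps_per_chromosome)
    spacing = config.chromosome_length / config.snps_per_chromosome
    pos = np.empty(L, dtype=np.int64)
    for c in range(config.n_chromosomes):
        sl = slice(c * config.snps_per_chromosome, (c + 1) * config.snps_per_chromosome)
        base = (np.arange(config.snps_per_chromosome) * spacing).astype(np.int64)
        jitter = rng.integers(0, max(int(spacing * 0.5), 1), config.snps_per_chromosome)
        pos[sl] = np.sort(base + jitter) + 1

    ref_i = rng.integers(0, 4, L)
    alt_i = (ref_i + rng.integers(1, 4, L)) % 4
    ref, alt = _NUCS[ref_i], _NUCS[alt_i]

    # block structure: share founder frequency and trajectory within blocks
    if config.block_size > 0:
        block_id = np.empty(L, dtype=np.int64)
        offset = 0
        for c in range(config.n_chromosomes):
            sl = slice(c * config.snps_per_chromosome,
                       (c + 1) * config.snps_per_chromosome)
            block_id[sl] = offset + pos[sl] // config.block_size
            offset = block_id[sl].max() + 1
        uniq, inverse = np.unique(block_id, return_inverse=True)
        n_units = len(uniq)
    else:
        block_id, inverse, n_units = None, np.arange(L), L

    founder_u = draw_founder_spectrum(n_units, config, rng)
    founder = founder_u[inverse]

    # per-unit selection coefficients
    s_amb_u = np.zeros(n_units)
    s_hot_u = np.zeros(n_units)
    for loc in config.selected_loci:
        u = inverse[loc.index]
        flip = -1.0 if (config.select_minor and founder_u[u] > 0.5) else 1.0
        s_amb_u[u] = flip * loc.s_ambient
        s_hot_u[u] = flip * loc.s_hot

    freqs: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    depths: dict[str, np.ndarray] = {}
    for d in config.designs:
        if d.is_ancestral:
            freqs[d.pool_id] = founder.copy()
        else:
            if d.pollination == "control":
                s = np.zeros(n_units)
            elif d.temperature == "ambient":
                s = s_amb_u
            else:
                s = s_hot_u
            p = founder_u.copy()
            for ne in d.ne_trajectory:
                p = wf_step(p, ne, s, rng)
            freqs[d.pool_id] = p[inverse]
        k, dp = pool_read_counts(freqs[d.pool_id], d.n_individuals,
                                 config.depth_mean,
                                 config.sequencing_error_rate, rng)
        counts[d.pool_id], depths[d.pool_id] = k, dp

    truth = pd.DataFrame(
        [{"chrom": chroms[loc.index], "pos": int(pos[loc.index]),
          "index": loc.index, "s_ambient": loc.s_ambient, "s_hot": loc.s_hot,
          "expected_class": _expected_class(loc.s_ambient, loc.s_hot)}
         for loc in config.selected_loci],
        columns=["chrom", "pos", "index", "s_ambient", "s_hot", "expected_class"])

    return SimResult(config, chroms, pos, ref, alt, founder, freqs, counts,
                     depths, truth, block_id)
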