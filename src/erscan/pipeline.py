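"""End-to-end orchestration: calibration → diversity → scan → local score →
consensus → annotation.

The pipeline consumes a frequency table (from sync files + design, or
directly from a simulation), calibrates per-population thresholds under the
realised demography, runs the treatment-level scans and region calling, and
emits per-stage tables plus a per-treatment summary (counts of filter-passing
SNPs, CMH-significant SNPs and consensus intervals with coordinates).

Threshold calibration here defaults to the drift+sampling null: observed
pool-seq ΔAF and FST contain pool- and read-sampling noise on top of drift,
so a commensurable null must contain it too.  (The drift-only null, which
matches the analytic variance formula, remains the default of
``drift_calibration.simulate_neutral_null`` for analytic work.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (CandidateInterval, consensus_intervals,
                         genes_in_intervals, go_enrichment, intervals_frame)
from .drift_calibration import ThresholdSet, calibrate_thresholds, thresholds_frame
from .io_formats import (ConfigError, GeneModel, PoolDesign, read_design,
                         read_gff, read_sync, sites_to_frequencies, write_bed)
from .local_score import chromosome_scan
from .popgen_stats import pairwise_fst, windowed_diversity
from .selection_scan import TreatmentScan, classify_regime_pair, scan_treatment

log = logging.getLogger("erscan")


@dataclass
class PipelineConfig:
    """Tunable parameters of a full run (defaults = study settings)."""
    min_count: int = 12
    min_cov: int = 18
    max_cov: int = 150
    null_mode: str = "drift+sampling"
    n_null_snps: int = 100_000
    depth_mean: float = 120.0
    fdr: float = 0.05
    xi: float = 1.0
    n_resample: int = 5000
    window_range: tuple[int, int] = (10_000, 70_000)
    alpha: float = 0.05
    window_width: int = 50_000
    drift_adjust: bool = True
    seed: int = 0


@dataclass
class PipelineResult:
    """All per-stage outputs of one run."""
    design: tuple[PoolDesign, ...]
    freq: pd.DataFrame
    thresholds: list[ThresholdSet]
    scans: dict[str, TreatmentScan]
    classes: dict[str, pd.DataFrame]
    segments: dict[str, pd.DataFrame]
    intervals: dict[str, list[CandidateInterval]]
    diversity: pd.DataFrame
    fst_matrix: pd.DataFrame
    go: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: pd.DataFrame | None = None

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        thresholds_frame(self.thresholds).to_csv(
            outdir / "thresholds.tsv", sep="\t", index=False)
        for name, scan in self.scans.items():
            scan.table.to_csv(outdir / f"scan_{name}.tsv", sep="\t", index=False)
        for name, cls in self.classes.items():
            cls.to_csv(outdir / f"classes_{name}.tsv", sep="\t", index=False)
        for name, seg in self.segments.items():
            seg.to_csv(outdir / f"segments_{name}.tsv", sep="\t", index=False)
        all_iv = [iv for ivs in self.intervals.values() for iv in ivs]
        intervals_frame(all_iv).to_csv(outdir / "intervals.tsv", sep="\t",
                                       index=False)
        write_bed([{"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                    "name": iv.label} for iv in all_iv],
                  outdir / "intervals.bed")
        self.diversity.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
        self.fst_matrix.to_csv(outdir / "fst_matrix.tsv", sep="\t")
        for name, go in self.go.items():
            go.to_csv(outdir / f"go_{name}.tsv", sep="\t", index=False)
        if self.summary is not None:
            self.summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)


def _treatment_groups(design: Sequence[PoolDesign]) -> dict[str, list[PoolDesign]]:
    groups: dict[str, list[PoolDesign]] = {}
    for d in design:
        if not d.is_ancestral:
            groups.setdefault(d.treatment, []).append(d)
    return groups


def run_pipeline(freq: pd.DataFrame, design: Sequence[PoolDesign],
                 config: PipelineConfig | None = None,
                 gene_models: Sequence[GeneModel] | None = None,
                 go_map: dict[str, set[str]] | None = None) -> PipelineResult:
    """Run every stage on an already-filtered frequency table."""
    cfg = config or PipelineConfig()
    design = tuple(design)
    anc = [d for d in design if d.is_ancestral]
    if not anc:
        raise ConfigError("design must contain an ancestral pool")
    ancestral = anc[0]
    groups = _treatment_groups(design)
    log.info("erscan %s: %d pools, %d treatments, %d SNPs, seed %d",
             __version__, len(design), len(groups), len(freq), cfg.seed)

    # --- stage: control baseline (observed |dAF| of hand-pollinated lines)
    g1_f = freq[f"freq_{ancestral.pool_id}"].to_numpy()
    control_daf: dict[str, np.ndarray] = {}
    for temp in ("ambient", "hot"):
        samples = [np.abs(freq[f"freq_{d.pool_id}"].to_numpy() - g1_f)
                   for d in design
                   if d.pollination == "control" and d.temperature == temp]
        if samples:
            control_daf[temp] = np.concatenate(samples)

    # --- stage: calibration
    try:
        thresholds = calibrate_thresholds(
            design, control_daf_by_temp=control_daf or None,
            n_snps=cfg.n_null_snps, mode=cfg.null_mode,
            depth_mean=cfg.depth_mean, seed=cfg.seed)
    except Exception as exc:  # pragma: no cover - stage naming contract
        raise RuntimeError(f"calibration stage failed: {exc}") from exc
    thr = {t.population: t for t in thresholds}

    # --- stage: diversity statistics
    try:
        div = []
        for d in design:
            w = windowed_diversity(freq, d.pool_id, 2 * d.n_individuals,
                                   cfg.window_width)
            w.insert(0, "population", d.pool_id)
            div.append(w)
        diversity = pd.concat(div, ignore_index=True) if div else pd.DataFrame()
        n_by_pool = {d.pool_id: 2 * d.n_individuals for d in design}
        fst_matrix = pairwise_fst(freq, [d.pool_id for d in design], n_by_pool)
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"diversity stage failed: {exc}") from exc

    # --- stage: per-treatment scan
    scans: dict[str, TreatmentScan] = {}
    for name, reps in groups.items():
        try:
            scans[name] = scan_treatment(
                freq, ancestral.pool_id, reps, thr,
                ancestral_pool_size=ancestral.n_individuals,
                drift_adjust=cfg.drift_adjust, use_q_lt=cfg.fdr)
        except Exception as exc:
            raise RuntimeError(f"scan stage failed for {name}: {exc}") from exc

    # --- stage: classification per pollination regime
    classes: dict[str, pd.DataFrame] = {}
    pollinations = {d.pollination for d in design if not d.is_ancestral}
    for poll in sorted(pollinations):
        amb, hot = f"ambient-{poll}", f"hot-{poll}"
        if amb in scans and hot in scans:
            thr_a = float(np.mean([thr[d.pool_id].effective_daf
                                   for d in groups[amb]]))
            thr_h = float(np.mean([thr[d.pool_id].effective_daf
                                   for d in groups[hot]]))
            classes[poll] = classify_regime_pair(scans[amb], scans[hot],
                                                 thr_a, thr_h)

    # --- stage: local score + consensus
    segments: dict[str, pd.DataFrame] = {}
    intervals: dict[str, list[CandidateInterval]] = {}
    rng = np.random.default_rng(cfg.seed)
    for name, scan in scans.items():
        try:
            segs = []
            t = scan.table
            for chrom, grp in t.groupby("chrom", sort=True):
                _, _, seg = chromosome_scan(
                    str(chrom), grp["pos"].to_numpy(), grp["q"].to_numpy(),
                    xi=cfg.xi, n_resample=cfg.n_resample,
                    window_range=cfg.window_range, alpha=cfg.alpha,
                    seed=int(rng.integers(2**31)))
                segs.append(seg)
            segs = [s for s in segs if len(s)]
            seg_cols = ["chrom", "start", "end", "peak", "n_snps",
                        "threshold", "xi"]
            seg_df = pd.concat(segs, ignore_index=True) if segs \
                else pd.DataFrame(columns=seg_cols)
            segments[name] = seg_df
            fst_pass = t.loc[t["filter_pass"], ["chrom", "pos"]]
            cmh_sig = t.loc[t["cmh_sig"], ["chrom", "pos"]]
            intervals[name] = consensus_intervals(seg_df, fst_pass, cmh_sig,
                                                  treatment=name)
        except Exception as exc:
            raise RuntimeError(f"local-score stage failed for {name}: {exc}") from exc

    # --- stage: annotation
    go: dict[str, pd.DataFrame] = {}
    if gene_models is not None:
        for name in intervals:
            intervals[name] = genes_in_intervals(intervals[name], gene_models)
        if go_map:
            universe = [g.gene_id for g in gene_models if go_map.get(g.gene_id)]
            for name, ivs in intervals.items():
                genes = sorted({gid for iv in ivs for gid in iv.gene_ids
                                if go_map.get(gid)})
                if genes:
                    go[name] = go_enrichment(genes, universe, go_map)

    # --- summary (Table-2 shape)
    rows = []
    for name, scan in scans.items():
        t = scan.table
        ivs = intervals.get(name, [])
        rows.append({
            "treatment": name,
            "n_fst_pass_snps": int(t["filter_pass"].sum()),
            "n_cmh_sig_snps": int(t["cmh_sig"].sum()),
            "n_consensus_intervals": len(ivs),
            "intervals": ";".join(f"{iv.chrom}:{iv.start}-{iv.end}"
                                  for iv in ivs),
            "total_interval_bp": sum(iv.length for iv in ivs)})
    summary = pd.DataFrame(rows).sort_values("treatment").reset_index(drop=True)

    return PipelineResult(design, freq, thresholds, scans, classes, segments,
                          intervals, diversity, fst_matrix, go, summary)


def run_pipeline_from_files(sync_path, design_path,
                            config: PipelineConfig | None = None,
                            gff_path=None, go_table=None,
                            outdir=None) -> PipelineResult:
    """File-based entry point: combined sync + design TSV (+ optional GFF3
    and gene→GO table); writes all per-stage TSVs when ``outdir`` is given."""
    cfg = config or PipelineConfig()
    design = read_design(design_path)
    records = read_sync(sync_path, design=design)
    freq = sites_to_frequencies(records, design, min_count=cfg.min_count,
                                min_cov=cfg.min_cov, max_cov=cfg.max_cov)
    genes = read_gff(gff_path, go_table) if gff_path else None
    gmap = None
    if genes is not None:
        gmap = {g.gene_id: set(g.go_terms) for g in genes if g.go_terms}
    result = run_pipeline(freq, design, cfg, genes, gmap)
    if outdir is not None:
        result.write(outdir)
    return result
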