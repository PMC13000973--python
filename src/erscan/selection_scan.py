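"""SNP-level selection statistics for replicated E&R designs.

Three layers are implemented on the polarised minor-allele frequencies:

* signed allele-frequency change ΔAF = AF_final − AF_G1 and the four-class
  temperature × pollinator scheme (background / global adaptation /
  conditional / antagonistic pleiotropy) against calibrated thresholds;
* the three-step replicate-concordance filter (shared direction, |ΔAF| above
  the effective threshold in every replicate, per-replicate Hudson FST above
  its neutral 95th percentile);
* a replicated Cochran–Mantel–Haenszel test of the per-replicate 2×2
  allele-count tables (evolved vs ancestral × minor vs major allele), with an
  optional drift adjustment that inflates each stratum's conditional variance
  by the demographic variance the read counts cannot see, plus a covariance
  term for the ancestral pool being one physical library duplicated across
  replicate strata.  With the adjustment off the statistic is the classic
  continuity-corrected CMH.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ConfigError
from .drift_calibration import ThresholdSet, drift_factor

CLASS_LABELS = ("background", "global_adaptation", "conditional_ambient",
                "conditional_hot", "antagonistic_pleiotropy")


def delta_af(final_freq, g1_freq):
    """Signed change of the polarised minor allele, in [-1, 1]."""
    f = np.asarray(final_freq, dtype=float)
    g = np.asarray(g1_freq, dtype=float)
    if ((f < 0) | (f > 1) | (g < 0) | (g > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    out = f - g
    return float(out) if out.ndim == 0 else out


def classify_snp(daf_ambient, daf_hot, thr_ambient: float, thr_hot: float):
    """Assign the four-class label from regime-level ΔAF.

    background: |ΔAF| below threshold in both regimes; global_adaptation:
    above in both with the same sign; conditional_ambient / conditional_hot:
    above in exactly one regime; antagonistic_pleiotropy: above in both with
    opposite signs.  Vectorised; scalar in, scalar out.
    """
    if not (0 <= thr_ambient <= 1 and 0 <= thr_hot <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    da = np.atleast_1d(np.asarray(daf_ambient, dtype=float))
    dh = np.atleast_1d(np.asarray(daf_hot, dtype=float))
    above_a = np.abs(da) >= thr_ambient
    above_h = np.abs(dh) >= thr_hot
    out = np.full(da.shape, "background", dtype=object)
    out[above_a & ~above_h] = "conditional_ambient"
    out[~above_a & above_h] = "conditional_hot"
    both = above_a & above_h
    same = np.sign(da) == np.sign(dh)
    out[both & same] = "global_adaptation"
    out[both & ~same] = "antagonistic_pleiotropy"
    if np.ndim(daf_ambient) == 0 and np.ndim(daf_hot) == 0:
        return str(out[0])
    return out


def concordance_filter(rep_dafs, rep_fsts, daf_thresholds, fst_thresholds):
    """Three-step replicate-concordance filter for one treatment.

    ``rep_dafs`` / ``rep_fsts``: arrays of shape (n_snps, n_replicates);
    ``daf_thresholds`` / ``fst_thresholds``: per-replicate effective |ΔAF|
    and neutral FST 95th-percentile cut-offs (scalars broadcast).

    Returns (passed, reason): ``reason`` is "pass", or the first failing step
    ("direction", "daf", "fst").
    """
    daf = np.atleast_2d(np.asarray(rep_dafs, dtype=float))
    fst = np.atleast_2d(np.asarray(rep_fsts, dtype=float))
    if daf.shape[1] < 2:
        raise ConfigError("concordance filter needs >= 2 replicates")
    if daf.shape != fst.shape:
        raise ConfigError("rep_dafs and rep_fsts must have matching shapes")
    thr_d = np.broadcast_to(np.asarray(daf_thresholds, dtype=float), (daf.shape[1],))
    thr_f = np.broadcast_to(np.asarray(fst_thresholds, dtype=float), (daf.shape[1],))

    same_dir = (np.all(daf > 0, axis=1)) | (np.all(daf < 0, axis=1))
    above_daf = np.all(np.abs(daf) >= thr_d, axis=1)
    above_fst = np.all(fst > thr_f, axis=1)

    passed = same_dir & above_daf & above_fst
    reason = np.full(daf.shape[0], "pass", dtype=object)
    reason[~above_fst] = "fst"
    reason[~above_daf] = "daf"
    reason[~same_dir] = "direction"
    return passed, reason


# ---------------------------------------------------------------------------
# CMH
# ---------------------------------------------------------------------------

def _stack_tables(tables):
    """Accept (n_rep, 2, 2), (n_snps, n_rep, 2, 2) or a list of 2x2 arrays;
    return float array of shape (n_snps, n_rep, 2, 2)."""
    arr = np.asarray(tables, dtype=float)
    if arr.ndim == 3:
        arr = arr[None, ...]
    elif arr.ndim == 2:
        arr = arr[None, None, ...]
    if arr.ndim != 4 or arr.shape[-2:] != (2, 2):
        raise ConfigError("tables must be (..., n_rep, 2, 2)")
    if (arr < 0).any():
        raise ConfigError("counts must be non-negative")
    return arr


def cmh_test(tables, ne_trajectories=None, pool_sizes=None,
             ancestral_pool_size: int | None = None,
             drift_adjust: bool = False, shared_ancestral: bool = True,
             continuity: bool = True):
    """Replicated (E&R) Cochran–Mantel–Haenszel test.

    Each stratum is a 2×2 table with rows (evolved, ancestral) and columns
    (minor, major) read counts; ``a_r`` is the evolved minor count.  The
    statistic is ``(|Σ(a_r − E_r)| − ½)² / V`` referred to χ²(1), with
    ``E_r``/``V_r`` the hypergeometric stratum mean/variance.

    With ``drift_adjust`` each stratum's variance is inflated by the extra
    variance drift (and pool sampling of individuals, when ``pool_sizes`` is
    given) adds to the evolved allele frequency:
    ``w_r²·p̄(1−p̄)·d_r`` with ``w_r = n1·n2/N`` and
    ``d_r = 1 − (1 − 1/(2m_r))·Π_g(1 − 1/(2Ne,g))``.  When the ancestral pool
    is one physical library duplicated across strata (``shared_ancestral``),
    its read and pool-sampling noise is common to all strata and the summed
    variance gains ``p̄(1−p̄)·[((Σw)²−Σw²)/n_anc + (Σw)²/(2·m_anc)]``.
    At ``d = 0`` (no adjustment) the statistic is the classic CMH.

    ``ne_trajectories`` is one trajectory shared by all replicates or a
    sequence of per-replicate trajectories.  Returns (statistic, p); arrays
    for stacked per-SNP input, scalars for a single SNP.
    """
    arr = _stack_tables(tables)
    n_snps, n_rep = arr.shape[:2]

    a = arr[:, :, 0, 0]
    n1 = arr[:, :, 0, 0] + arr[:, :, 0, 1]   # evolved depth
    n2 = arr[:, :, 1, 0] + arr[:, :, 1, 1]   # ancestral depth
    col1 = arr[:, :, 0, 0] + arr[:, :, 1, 0]
    N = n1 + n2
    usable = N > 0
    if not usable.any(axis=1).all():
        raise ConfigError("some SNP has no usable stratum")
    with np.errstate(divide="ignore", invalid="ignore"):
        E = np.where(usable, n1 * col1 / np.where(usable, N, 1), 0.0)
        col2 = N - col1
        denom = N**2 * np.maximum(N - 1, 1)
        V = np.where(usable & (N > 1), n1 * n2 * col1 * col2 / denom, 0.0)
        w = np.where(usable, n1 * n2 / np.where(usable, N, 1), 0.0)

    sum_aE = (a - E).sum(axis=1)
    V_tot = V.sum(axis=1)

    if drift_adjust:
        if ne_trajectories is None:
            raise ConfigError("drift_adjust requires ne_trajectories")
        if len(ne_trajectories) == 0 or np.ndim(ne_trajectories[0]) == 0:
            ne_trajectories = [ne_trajectories] * n_rep
        if len(ne_trajectories) != n_rep:
            raise ConfigError("one Ne trajectory per replicate required")
        if pool_sizes is None:
            pool_sizes = [None] * n_rep
        elif np.ndim(pool_sizes) == 0:
            pool_sizes = [int(pool_sizes)] * n_rep
        d = np.array([drift_factor(traj, m)
                      for traj, m in zip(ne_trajectories, pool_sizes)])
        pbar = col1.sum(axis=1) / N.sum(axis=1)
        pq = pbar * (1 - pbar)
        V_tot = V_tot + pq * (w**2 * d[None, :]).sum(axis=1)
        if shared_ancestral and n_rep > 1:
            sw = w.sum(axis=1)
            sw2 = (w**2).sum(axis=1)
            n_anc = np.where(usable, n2, np.inf).min(axis=1)  # duplicated depth
            g_read = (sw**2 - sw2) / n_anc
            g_pool = sw**2 / (2 * ancestral_pool_size) if ancestral_pool_size \
                else 0.0
            V_tot = V_tot + pq * (g_read + g_pool)

    num = np.abs(sum_aE)
    if continuity:
        num = np.clip(num - 0.5, 0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(V_tot > 0, num**2 / np.where(V_tot > 0, V_tot, 1), 0.0)
    p = stats.chi2.sf(stat, df=1)
    p = np.where(V_tot > 0, p, 1.0)
    if n_snps == 1:
        return float(stat[0]), float(p[0])
    return stat, p


def bh_fdr(p_values):
    """Benjamini–Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# treatment-level scan
# ---------------------------------------------------------------------------

@dataclass
class TreatmentScan:
    """Scan results of one temperature × pollination treatment."""
    treatment: str
    table: pd.DataFrame  # per-SNP record


def scan_treatment(freq_df: pd.DataFrame, ancestral_id: str,
                   replicate_designs: Sequence, thresholds: dict[str, ThresholdSet],
                   ancestral_pool_size: int | None = None,
                   drift_adjust: bool = True,
                   use_q_lt: float = 0.05) -> TreatmentScan:
    """Run ΔAF, per-replicate FST, the concordance filter and the CMH test
    for the replicates of one treatment against the shared ancestral pool."""
    from .popgen_stats import hudson_fst_snp

    reps = list(replicate_designs)
    if len(reps) < 2:
        raise ConfigError("a treatment needs >= 2 replicates")
    g1_f = freq_df[f"freq_{ancestral_id}"].to_numpy()
    g1_d = freq_df[f"depth_{ancestral_id}"].to_numpy()
    g1_minor = np.rint(g1_f * g1_d)

    dafs, fsts, tables = [], [], []
    for d in reps:
        f = freq_df[f"freq_{d.pool_id}"].to_numpy()
        dp = freq_df[f"depth_{d.pool_id}"].to_numpy()
        dafs.append(delta_af(f, g1_f))
        _, _, r = hudson_fst_snp(f, g1_f, 2 * d.n_individuals,
                                 2 * (ancestral_pool_size or d.n_individuals))
        fsts.append(r)
        minor = np.rint(f * dp)
        tables.append(np.stack([
            np.stack([minor, dp - minor], axis=-1),
            np.stack([g1_minor, g1_d - g1_minor], axis=-1)], axis=-2))
    daf = np.stack(dafs, axis=1)
    fst = np.stack(fsts, axis=1)
    tab = np.stack(tables, axis=1)  # (n_snps, n_rep, 2, 2)

    thr_d = np.array([thresholds[d.pool_id].effective_daf for d in reps])
    thr_f = np.array([thresholds[d.pool_id].fst95_effective for d in reps])
    passed, reason = concordance_filter(daf, fst, thr_d, thr_f)

    stat, p = cmh_test(tab, ne_trajectories=[d.ne_trajectory for d in reps],
                       pool_sizes=[d.n_individuals for d in reps],
                       ancestral_pool_size=ancestral_pool_size,
                       drift_adjust=drift_adjust)
    q = bh_fdr(p)

    out = freq_df[["chrom", "pos"]].copy()
    for j, d in enumerate(reps):
        out[f"daf_{d.pool_id}"] = daf[:, j]
        out[f"fst_{d.pool_id}"] = fst[:, j]
    out["daf_mean"] = daf.mean(axis=1)
    out["cmh_stat"] = np.atleast_1d(stat)
    out["p"] = np.atleast_1d(p)
    out["q"] = q
    out["cmh_sig"] = out["q"] < use_q_lt
    out["filter_pass"] = passed
    out["filter_reason"] = reason
    treatment = reps[0].treatment
    return TreatmentScan(treatment, out)


def classify_regime_pair(scan_ambient: TreatmentScan, scan_hot: TreatmentScan,
                         thr_ambient: float, thr_hot: float,
                         statistic: str = "mean") -> pd.DataFrame:
    """Four-class labels for one pollination regime from its ambient and hot
    treatment scans.

    ``statistic``: "mean" uses the replicate-mean ΔAF per regime, "min" the
    signed ΔAF of smallest magnitude (stricter).  Classification is only
    attempted for SNPs passing the per-replicate concordance filter in at
    least one regime; all others are background.
    """
    ta, th = scan_ambient.table, scan_hot.table
    merged = ta[["chrom", "pos", "daf_mean", "filter_pass"]].merge(
        th[["chrom", "pos", "daf_mean", "filter_pass"]],
        on=["chrom", "pos"], suffixes=("_ambient", "_hot"))
    if statistic == "min":
        def _minmag(t):
            cols = [c for c in t.columns if c.startswith("daf_") and c != "daf_mean"]
            d = t[cols].to_numpy()
            idx = np.argmin(np.abs(d), axis=1)
            return d[np.arange(len(d)), idx]
        da = _minmag(ta)
        dh = _minmag(th)
    elif statistic == "mean":
        da = merged["daf_mean_ambient"].to_numpy()
        dh = merged["daf_mean_hot"].to_numpy()
    else:
        raise ConfigError(f"unknown statistic {statistic!r}")
    labels = classify_snp(da, dh, thr_ambient, thr_hot)
    eligible = merged["filter_pass_ambient"] | merged["filter_pass_hot"]
    labels = np.where(eligible, labels, "background")
    out = merged[["chrom", "pos"]].copy()
    out["daf_ambient"] = da
    out["daf_hot"] = dh
    out["class"] = labels
    return out
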