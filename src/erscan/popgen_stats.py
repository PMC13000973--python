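"""Pool-aware diversity and differentiation statistics.

Sample size for the pool estimators is the haploid pool size n = 2 × number
of pooled individuals, not the read depth; this keeps the estimators simple
and preserves relative comparisons across pools sequenced under one protocol
(absolute pool-seq values would need depth-aware corrections).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def site_pi(p, n: int):
    """Per-site nucleotide diversity for a biallelic site: 2p(1-p)·n/(n-1)
    (the small-sample-unbiased heterozygosity)."""
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    p = np.asarray(p, dtype=float)
    out = 2 * p * (1 - p) * n / (n - 1)
    return float(out) if out.ndim == 0 else out


def expected_het(frequencies, n: int) -> float:
    """Expected heterozygosity He = 1 - Q1 (probability of identity in
    state), averaged over SNPs, with the n/(n-1) small-sample correction —
    identical in form to :func:`site_pi` at biallelic sites."""
    p = np.asarray(frequencies, dtype=float)
    if p.size == 0:
        raise ValueError("empty SNP set")
    return float(np.mean(site_pi(p, n)))


def _harmonic(n: int, power: int = 1) -> float:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i**power))


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator S / a1 with a1 the (n-1)-th harmonic number."""
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    if S < 0:
        raise ValueError("S must be >= 0")
    return S / _harmonic(n)


def tajimas_d(pi_sum: float, S: int, n: int) -> float:
    """Tajima's D from the window's summed pairwise diversity and number of
    segregating sites, using the standard normalising constants.  Returns NaN
    (undefined) when S < 2."""
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    if S < 2:
        return float("nan")
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_sum - S / a1) / np.sqrt(var))


def hudson_fst_snp(p1, p2, n1: int, n2: int):
    """Hudson's per-SNP FST components.

    numerator = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    denominator = p1(1-p2) + p2(1-p1)

    Returns (numerator, denominator, ratio); the ratio is NaN where the
    denominator is 0 (both pools fixed for the same allele) — such SNPs are
    excluded from genome-wide aggregates.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("sample sizes must be >= 2")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    if np.ndim(num) == 0:
        return float(num), float(den), float(ratio)
    return num, den, ratio


def hudson_fst_genome(p1, p2, n1: int, n2: int) -> float:
    """Genome-wide Hudson FST as a ratio of averages Σnum/Σden over SNPs
    with a positive denominator (negative per-SNP ratios are retained)."""
    num, den, _ = hudson_fst_snp(p1, p2, n1, n2)
    num, den = np.atleast_1d(num), np.atleast_1d(den)
    keep = den > 0
    if not keep.any():
        return float("nan")
    return float(num[keep].sum() / den[keep].sum())


def pairwise_fst(freq_df: pd.DataFrame, pool_ids: Sequence[str],
                 n_by_pool: dict[str, int]) -> pd.DataFrame:
    """Genome-wide pairwise Hudson FST matrix over the frequency table."""
    mat = pd.DataFrame(0.0, index=list(pool_ids), columns=list(pool_ids))
    for i, a in enumerate(pool_ids):
        for b in pool_ids[i + 1:]:
            f = hudson_fst_genome(freq_df[f"freq_{a}"].to_numpy(),
                                  freq_df[f"freq_{b}"].to_numpy(),
                                  n_by_pool[a], n_by_pool[b])
            mat.loc[a, b] = mat.loc[b, a] = f
    return mat


def windowed_diversity(freq_df: pd.DataFrame, pool_id: str, n: int,
                       window: int = 50_000) -> pd.DataFrame:
    """Windowed π, Watterson's θ and Tajima's D for one pool.

    Windows are fixed 1-based intervals of ``window`` bp; per-window means
    follow the valid-SNPs policy (divide by the number of retained SNPs in
    the window, not the window width).  D is NaN where S < 2.
    """
    p = freq_df[f"freq_{pool_id}"].to_numpy()
    pis = site_pi(p, n)
    seg = (p > 0) & (p < 1)
    df = pd.DataFrame({"chrom": freq_df["chrom"], "pos": freq_df["pos"],
                       "pi": pis, "seg": seg})
    df["win"] = (df["pos"] - 1) // window
    rows = []
    for (chrom, w), grp in df.groupby(["chrom", "win"], sort=True):
        S = int(grp["seg"].sum())
        pi_sum = float(grp.loc[grp["seg"], "pi"].sum())
        n_valid = len(grp)
        rows.append({"chrom": chrom, "start": int(w) * window + 1,
                     "end": (int(w) + 1) * window, "n_valid_snps": n_valid,
                     "S": S, "pi": pi_sum / n_valid if n_valid else np.nan,
                     "theta_w": watterson_theta(S, n) / n_valid if n_valid else np.nan,
                     "tajimas_d": tajimas_d(pi_sum, S, n), "n": n})
    return pd.DataFrame(rows)


def allele_freq_pca(freq_matrix):
    """PCA of a pools × SNPs frequency matrix via SVD of the column-centred
    matrix.  Returns (scores, explained_variance_fraction); a constant matrix
    yields all-zero scores and fractions."""
    X = np.asarray(freq_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a pools x SNPs matrix with >= 2 of each")
    if np.isnan(X).any():
        raise ValueError("missing values must be dropped before PCA")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, sv, _ = np.linalg.svd(Xc, full_matrices=False)
    # zero out numerically-null axes (constant matrices decompose to noise)
    tol = np.finfo(float).eps * X.size * max(1.0, float(np.abs(X).max()))
    sv = np.where(sv > tol, sv, 0.0)
    scores = U * sv
    total = np.sum(sv**2)
    frac = sv**2 / total if total > 0 else np.zeros_like(sv)
    return scores, frac


def bootstrap_ci(values, n_boot: int = 1000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of per-window values."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 windows")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return float(lo), float(hi)
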