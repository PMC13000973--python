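"""Local-score region calling via the Lindley process.

Per-SNP significance is converted to scores s_i = −log10(q_i) − ξ (ξ = 1
relaxed, ξ = 2 strict; q is the BH-adjusted CMH p-value by default).  The
Lindley process h_i = max(0, h_{i−1} + s_i) accumulates runs of moderately
significant SNPs; chromosome-specific significance thresholds for its maxima
come from resampling: scores are permuted across SNP positions (destroying
spatial clustering while preserving the score distribution), the chromosome
is tiled into windows of a width drawn uniformly from 10–70 kb, and the
maximum within-window Lindley value of each of the resampled trajectories is
recorded; a Gumbel distribution fitted to those maxima gives the threshold at
the chosen significance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_EULER_GAMMA = float(np.euler_gamma)


@dataclass(frozen=True)
class LindleyTrack:
    """Per-chromosome score and cumulative Lindley trajectories."""
    chrom: str
    positions: np.ndarray
    scores: np.ndarray
    h: np.ndarray

    def __post_init__(self):
        if (np.diff(self.positions) < 0).any():
            raise ValueError("positions must be ascending")


@dataclass(frozen=True)
class GumbelFit:
    """Gumbel fit to resampled Lindley maxima and the derived threshold."""
    chrom: str
    mu: float
    beta: float
    n_resamples: int
    window_range: tuple[int, int]
    alpha: float
    threshold: float
    degenerate: bool = False


def scores_from_q(q_values, xi: float, max_score: float = 50.0):
    """Scores s_i = −log10(q_i) − ξ; q = 0 is capped at ``max_score``."""
    if xi <= 0:
        raise ValueError("xi must be > 0")
    q = np.asarray(q_values, dtype=float)
    if ((q < 0) | (q > 1)).any():
        raise ValueError("q-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        s = -np.log10(q) - xi
    capped = np.minimum(s, max_score)
    if (s > max_score).any():
        import warnings
        warnings.warn("q-values of 0 capped at max score")
    return float(capped) if capped.ndim == 0 else capped


def lindley(scores) -> np.ndarray:
    """Cumulative Lindley process h_i = max(0, h_{i-1} + s_i), h_0 = 0."""
    s = np.asarray(scores, dtype=float)
    h = np.empty_like(s)
    acc = 0.0
    for i, si in enumerate(s):
        acc = max(0.0, acc + si)
        h[i] = acc
    return h


def _windowed_lindley_max(scores_mat: np.ndarray, restart: np.ndarray) -> np.ndarray:
    """Max Lindley value per row, restarting at True entries of ``restart``
    (vectorised across rows; loop over the SNP axis)."""
    n_rows, n = scores_mat.shape
    h = np.zeros(n_rows)
    best = np.zeros(n_rows)
    for i in range(n):
        h = np.where(restart[:, i], 0.0, h)
        h = np.maximum(0.0, h + scores_mat[:, i])
        np.maximum(best, h, out=best)
    return best


def gumbel_threshold(scores, positions, n_resample: int = 5000,
                     window_range: tuple[int, int] = (10_000, 70_000),
                     alpha: float = 0.05, seed: int = 0,
                     chrom: str = "") -> GumbelFit:
    """Chromosome-specific significance threshold for the Lindley maximum.

    Method-of-moments Gumbel fit (β = sd·√6/π, μ = mean − γ·β) to the maxima
    of ``n_resample`` permuted trajectories; threshold = μ − β·ln(−ln(1−α)).
    All-non-positive scores give a degenerate fit with an infinite threshold
    (nothing is callable).
    """
    s = np.asarray(scores, dtype=float)
    pos = np.asarray(positions)
    if s.size < 2:
        raise ValueError("need >= 2 SNPs per chromosome")
    if (s <= 0).all():
        return GumbelFit(chrom, 0.0, 0.0, n_resample, tuple(window_range),
                         alpha, np.inf, degenerate=True)
    rng = np.random.default_rng(seed)
    n = s.size
    perm = np.argsort(rng.random((n_resample, n)), axis=1)
    mat = s[perm]
    widths = rng.integers(window_range[0], window_range[1] + 1, n_resample)
    # restart the process at every window boundary (tiling from the first SNP)
    win_idx = (pos - pos[0])[None, :] // widths[:, None]
    restart = np.zeros((n_resample, n), dtype=bool)
    restart[:, 1:] = win_idx[:, 1:] != win_idx[:, :-1]
    maxima = _windowed_lindley_max(mat, restart)

    sd = float(maxima.std(ddof=1))
    if sd == 0:
        return GumbelFit(chrom, float(maxima.mean()), 0.0, n_resample,
                         tuple(window_range), alpha, np.inf, degenerate=True)
    beta = sd * np.sqrt(6) / np.pi
    mu = float(maxima.mean()) - _EULER_GAMMA * beta
    threshold = mu - beta * np.log(-np.log(1 - alpha))
    return GumbelFit(chrom, mu, float(beta), n_resample, tuple(window_range),
                     alpha, float(threshold))


def call_segments(track: LindleyTrack, threshold: float) -> pd.DataFrame:
    """Call one interval per excursion of the Lindley process above the
    threshold.

    An excursion is a maximal run with h > 0; if its peak exceeds the
    threshold, the interval runs from the first SNP after the excursion's
    last zero to the SNP where h attains the excursion maximum (the
    significant core), 1-based inclusive.  Returned columns: chrom, start,
    end, peak, n_snps.
    """
    if not np.isfinite(threshold) or threshold <= 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "peak", "n_snps"])
    h = track.h
    pos = np.asarray(track.positions)
    rows = []
    i = 0
    n = len(h)
    while i < n:
        if h[i] <= 0:
            i += 1
            continue
        j = i
        while j < n and h[j] > 0:
            j += 1
        seg = slice(i, j)
        peak_rel = int(np.argmax(h[seg]))
        peak = float(h[seg][peak_rel])
        if peak > threshold:
            end_idx = i + peak_rel
            rows.append({"chrom": track.chrom, "start": int(pos[i]),
                         "end": int(pos[end_idx]), "peak": peak,
                         "n_snps": end_idx - i + 1})
        i = j
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "peak", "n_snps"])


def chromosome_scan(chrom: str, positions, q_values, xi: float = 1.0,
                    n_resample: int = 5000,
                    window_range: tuple[int, int] = (10_000, 70_000),
                    alpha: float = 0.05, seed: int = 0):
    """Scores → Lindley track → Gumbel threshold → called segments for one
    chromosome.  Returns (track, fit, segments)."""
    order = np.argsort(positions)
    pos = np.asarray(positions)[order]
    s = scores_from_q(np.asarray(q_values)[order], xi)
    track = LindleyTrack(chrom, pos, s, lindley(s))
    fit = gumbel_threshold(s, pos, n_resample, window_range, alpha, seed, chrom)
    segments = call_segments(track, fit.threshold)
    segments["threshold"] = fit.threshold
    segments["xi"] = xi
    return track, fit, segments
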