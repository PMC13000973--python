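"""Consensus candidate intervals, gene intersection and GO enrichment.

A local-score segment graduates to a candidate interval only when it is
independently supported by the other two evidence layers: it must contain at
least one SNP passing the three-step FST/concordance filter and at least one
CMH-significant SNP (BH q < 0.05).  Genes overlap an interval by >= 1 bp
under 1-based inclusive coordinates; GO enrichment is the classic one-sided
Fisher/hypergeometric test against all annotated genes, BH-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneModel
from .selection_scan import bh_fdr


@dataclass(frozen=True)
class CandidateInterval:
    """A consensus selection region supported by all three evidence layers."""
    chrom: str
    start: int
    end: int
    n_fst_pass_snps: int
    n_cmh_sig_snps: int
    segment_peak: float
    treatment: str = ""
    gene_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def label(self) -> str:
        return f"{self.treatment}:{self.chrom}:{self.start}-{self.end}"


def _positions_in(df_or_none, chrom, start, end) -> int:
    if df_or_none is None or len(df_or_none) == 0:
        return 0
    d = df_or_none
    return int(((d["chrom"] == chrom) & (d["pos"] >= start) & (d["pos"] <= end)).sum())


def consensus_intervals(segments: pd.DataFrame, fst_pass: pd.DataFrame,
                        cmh_sig: pd.DataFrame, treatment: str = "",
                        min_fst_snps: int = 1, min_cmh_snps: int = 1
                        ) -> list[CandidateInterval]:
    """Keep each local-score segment containing >= ``min_fst_snps`` filter-
    passing SNPs and >= ``min_cmh_snps`` CMH-significant SNPs.

    ``segments``: DataFrame with chrom/start/end/peak; ``fst_pass`` and
    ``cmh_sig``: DataFrames with chrom/pos of the supporting SNPs.
    """
    out = []
    if segments is None or len(segments) == 0:
        return out
    for _, seg in segments.iterrows():
        nf = _positions_in(fst_pass, seg["chrom"], seg["start"], seg["end"])
        nc = _positions_in(cmh_sig, seg["chrom"], seg["start"], seg["end"])
        if nf >= min_fst_snps and nc >= min_cmh_snps:
            out.append(CandidateInterval(seg["chrom"], int(seg["start"]),
                                         int(seg["end"]), nf, nc,
                                         float(seg.get("peak", np.nan)),
                                         treatment))
    return out


def genes_in_intervals(intervals: Sequence[CandidateInterval],
                       gene_models: Sequence[GeneModel]
                       ) -> list[CandidateInterval]:
    """Attach overlapping genes (>= 1 bp overlap, 1-based inclusive on both
    sides) to each interval; warns on chromosomes absent from the models."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for iv in intervals:
        genes = by_chrom.get(iv.chrom)
        if genes is None:
            warnings.warn(f"no gene models on chromosome {iv.chrom}")
            hits: tuple[str, ...] = ()
        else:
            hits = tuple(sorted(g.gene_id for g in genes
                                if g.start <= iv.end and g.end >= iv.start))
        out.append(CandidateInterval(iv.chrom, iv.start, iv.end,
                                     iv.n_fst_pass_snps, iv.n_cmh_sig_snps,
                                     iv.segment_peak, iv.treatment, hits))
    return out


def go_enrichment(candidate_genes: Sequence[str], universe_genes: Sequence[str],
                  go_map: dict[str, set[str]]) -> pd.DataFrame:
    """One-sided hypergeometric GO term enrichment.

    ``go_map`` maps gene_id → set of GO ids; the universe is restricted to
    genes with >= 1 annotation.  Terms with zero candidate overlap get p = 1.
    Returns a DataFrame with go_id, n_universe, n_candidate, p, q (BH).
    """
    cand = set(candidate_genes)
    if not cand:
        raise ValueError("empty candidate set")
    universe = {g for g in universe_genes if go_map.get(g)}
    if not cand <= universe:
        missing = sorted(cand - universe)[:5]
        raise ValueError(f"candidates not in annotated universe: {missing}")
    by_term: dict[str, set[str]] = {}
    for gene in universe:
        for term in go_map.get(gene, ()):
            by_term.setdefault(term, set()).add(gene)
    M, n_draw = len(universe), len(cand)
    rows = []
    for term, members in sorted(by_term.items()):
        K = len(members)
        k = len(members & cand)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, M, K, n_draw))
        rows.append({"go_id": term, "n_universe": K, "n_candidate": k, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    return df


def intervals_frame(intervals: Sequence[CandidateInterval]) -> pd.DataFrame:
    """Tabular (Table-2-like) view of candidate intervals."""
    return pd.DataFrame([{
        "treatment": iv.treatment, "chrom": iv.chrom, "start": iv.start,
        "end": iv.end, "length_bp": iv.length,
        "n_fst_pass_snps": iv.n_fst_pass_snps,
        "n_cmh_sig_snps": iv.n_cmh_sig_snps, "peak": iv.segment_peak,
        "genes": ";".join(iv.gene_ids)} for iv in intervals],
        columns=["treatment", "chrom", "start", "end", "length_bp",
                 "n_fst_pass_snps", "n_cmh_sig_snps", "peak", "genes"])
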