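"""Basic diagnostic plots: Manhattan of the CMH scan and the ambient-vs-hot
classification scatter."""

from __future__ import annotations

import numpy as np
import pandas as pd

_CLASS_COLORS = {
    "background": "0.7",
    "global_adaptation": "tab:green",
    "conditional_ambient": "tab:blue",
    "conditional_hot": "tab:red",
    "antagonistic_pleiotropy": "tab:purple",
}


def manhattan(scan_table: pd.DataFrame, fdr: float = 0.05, ax=None):
    """-log10(p) per SNP, chromosomes alternating shade, BH-significant SNPs
    highlighted; returns the axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(scan_table.groupby("chrom", sort=True)):
        x = grp["pos"].to_numpy() + offset
        y = -np.log10(np.clip(grp["p"].to_numpy(), 1e-300, 1))
        ax.scatter(x, y, s=4, color="k" if i % 2 == 0 else "0.6", linewidths=0)
        sig = grp["q"].to_numpy() < fdr
        ax.scatter(x[sig], y[sig], s=6, color="tab:red", linewidths=0)
        ticks.append(offset + grp["pos"].max() / 2)
        labels.append(str(chrom))
        offset += grp["pos"].max()
    ax.set_xticks(ticks, labels)
    ax.set_ylabel(r"$-\log_{10}(p)$")
    return ax


def classification_scatter(classes: pd.DataFrame, thr_ambient: float,
                           thr_hot: float, ax=None):
    """ΔAF(ambient) vs ΔAF(hot) coloured by the four-class label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for label, color in _CLASS_COLORS.items():
        sub = classes[classes["class"] == label]
        if len(sub):
            ax.scatter(sub["daf_ambient"], sub["daf_hot"], s=5, color=color,
                       label=label, linewidths=0)
    ax.axhline(0, color="k", ls="--", lw=0.5)
    ax.axvline(0, color="k", ls="--", lw=0.5)
    for s in (1, -1):
        ax.axvline(s * thr_ambient, color="0.4", lw=0.5)
        ax.axhline(s * thr_hot, color="0.4", lw=0.5)
    ax.set_xlabel(r"$\Delta$AF ambient")
    ax.set_ylabel(r"$\Delta$AF hot")
    ax.legend(fontsize=6, frameon=False)
    return ax
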