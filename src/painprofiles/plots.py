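"""Plot exports: Manhattan-style battery views and concordance heatmaps."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .was import AssociationResult, bonferroni_threshold
from .concordance import ConcordanceMatrix


def manhattan(result: AssociationResult, ax=None):
    """-log10 p by clinical column, grouped and coloured by category, with
    the FDR and Bonferroni threshold lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    table = result.table.dropna(subset=["p_value"]).copy()
    table["category"] = table["category"].fillna("unknown")
    table = table.sort_values("category", kind="stable")
    x = np.arange(len(table))
    for cat, grp in table.groupby("category", sort=False):
        pos = [table.index.get_loc(i) for i in grp.index]
        ax.scatter(x[pos], -np.log10(grp["p_value"]), s=8, label=str(cat))
    bon = bonferroni_threshold(result.alpha, result.m_tests)
    ax.axhline(-np.log10(bon), color="k", ls="--", lw=0.8)
    ax.text(0, -np.log10(bon), "BON", va="bottom", fontsize=7)
    flagged = table.loc[table["fdr_sig"], "p_value"]
    if len(flagged):
        fdr_line = flagged.max()
        ax.axhline(-np.log10(fdr_line), color="grey", ls=":", lw=0.8)
        ax.text(0, -np.log10(fdr_line), "FDR", va="bottom", fontsize=7, color="grey")
    ax.set_xlabel(f"{result.battery} columns (by category)")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(f"{result.battery} associations, {result.profile}")
    return ax


def concordance_heatmap(matrix: ConcordanceMatrix, battery: str, ax=None):
    """Profile x profile concordance for one battery."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.5))
    mat = matrix.matrices[battery]
    im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(mat)), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(mat)), mat.index)
    for i in range(len(mat)):
        for j in range(len(mat)):
            ax.text(j, i, f"{mat.iloc[i, j]:.2f}", ha="center", va="center", fontsize=8)
    ax.figure.colorbar(im, ax=ax, label="Pearson r of Fisher-z vectors")
    ax.set_title(f"profile concordance: {battery}")
    return ax
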