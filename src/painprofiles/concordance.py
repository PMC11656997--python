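"""Concordance of pain profiles across association batteries.

For each battery (medication, diagnosis, phenotype), the Fisher-z vectors of
two profiles' association results are correlated over their shared testable
clinical columns; a profile pair with similar clinical signatures has high
concordance. A per-battery mean off-diagonal summary ranks the batteries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .was import AssociationResult


@dataclass
class ConcordanceMatrix:
    """Per-battery profile x profile Pearson correlations of Fisher-z vectors."""

    matrices: dict[str, pd.DataFrame]  # battery -> symmetric corr matrix
    n_shared: dict[str, pd.DataFrame]  # battery -> per-cell shared column count
    p_values: dict[str, pd.DataFrame]

    def to_tsv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for battery, mat in self.matrices.items():
            mat.to_csv(out / f"concordance_{battery}.tsv", sep="\t", index_label="profile")


def profile_concordance(
    results: dict[str, dict[str, AssociationResult]],
) -> ConcordanceMatrix:
    """``results[battery][profile]`` -> concordance matrices.

    Columns with undefined rho in either profile are dropped pairwise; fewer
    than 3 shared columns is an error. Flipping one profile's score
    orientation flips the sign of its z-vector and hence of its concordances.
    """
    matrices, n_shared, p_values = {}, {}, {}
    for battery, per_profile in results.items():
        profiles = list(per_profile)
        K = len(profiles)
        corr = pd.DataFrame(np.eye(K), index=profiles, columns=profiles)
        nmat = pd.DataFrame(0, index=profiles, columns=profiles, dtype=int)
        pmat = pd.DataFrame(np.nan, index=profiles, columns=profiles)
        for i in range(K):
            zi = per_profile[profiles[i]].table["fisher_z"]
            nmat.iloc[i, i] = int(zi.notna().sum())
            for j in range(i + 1, K):
                zj = per_profile[profiles[j]].table["fisher_z"]
                pair = pd.concat([zi, zj], axis=1, join="inner").dropna()
                if len(pair) < 3:
                    raise ValueError(
                        f"battery {battery!r}: fewer than 3 shared columns for "
                        f"{profiles[i]!r} vs {profiles[j]!r}"
                    )
                rho, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
                corr.iloc[i, j] = corr.iloc[j, i] = float(rho)
                nmat.iloc[i, j] = nmat.iloc[j, i] = len(pair)
                pmat.iloc[i, j] = pmat.iloc[j, i] = float(p)
        matrices[battery] = corr
        n_shared[battery] = nmat
        p_values[battery] = pmat
    return ConcordanceMatrix(matrices=matrices, n_shared=n_shared, p_values=p_values)


def battery_similarity_summary(matrix: ConcordanceMatrix) -> pd.Series:
    """Mean off-diagonal concordance per battery (for ranking batteries)."""
    out = {}
    for battery, mat in matrix.matrices.items():
        K = mat.shape[0]
        if K < 2:
            raise ValueError("similarity summary needs at least two profiles")
        vals = mat.to_numpy()
        off = vals[~np.eye(K, dtype=bool)]
        out[battery] = float(off.mean())
    return pd.Series(out, name="mean_offdiag_concordance")
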