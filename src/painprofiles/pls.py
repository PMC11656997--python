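"""Two-view PLS canonical decomposition with permutation inference.

The decomposition alternates between the two views: per mode, the dominant
singular pair of the current cross-covariance X'Y is found by power iteration
(NIPALS-equivalent, tolerance 1e-6, at most 500 inner iterations), the paired
latent scores are formed, and both views are symmetrically deflated by
regressing out their own score. Mode significance uses a non-parametric
permutation null in which the brain matrix stays fixed while the pain matrix
rows are shuffled and the model is refit; per-feature loading significance
compares each observed weight against the tail of its own permuted-weight
null. Individual "pain scores" are projections of the centered pain matrix
onto the retained pain-side vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import FeatureTable

_POWER_TOL = 1e-6
_POWER_MAXIT = 500


def _as_matrix(x) -> tuple[np.ndarray, list, list]:
    """Accept a FeatureTable, DataFrame or ndarray; return (values, ids, names)."""
    if isinstance(x, FeatureTable):
        return x.values, list(x.participant_ids), list(x.features)
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.index), list(x.columns)
    arr = np.asarray(x, dtype=float)
    return arr, list(range(arr.shape[0])), list(range(arr.shape[1]))


@dataclass
class PLSModel:
    """Fitted canonical vectors and per-mode latent correlations.

    ``V`` (p x K) projects the brain view, ``U`` (q x K) the pain view; both
    have unit-norm columns. ``R[l]`` is the correlation of the paired latent
    scores of mode l. R is not assumed non-increasing across modes.
    """

    V: np.ndarray
    U: np.ndarray
    R: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    K: int
    x_names: list
    y_names: list

    def save(self, out_dir) -> None:
        from pathlib import Path
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.V, index=self.x_names).to_csv(out / "V.tsv", sep="\t")
        pd.DataFrame(self.U, index=self.y_names).to_csv(out / "U.tsv", sep="\t")
        pd.DataFrame({"R": self.R}).to_csv(out / "R.tsv", sep="\t", index_label="mode")
        means = pd.concat(
            [
                pd.Series(self.x_mean, index=self.x_names, name="mean"),
                pd.Series(self.y_mean, index=self.y_names, name="mean"),
            ]
        )
        means.to_csv(out / "means.tsv", sep="\t", index_label="feature")
        (out / "model.json").write_text(json.dumps({"K": self.K}))


@dataclass
class PermutationNull:
    """Null draws from refits on row-shuffled pain matrices (brain fixed)."""

    null_R: np.ndarray  # n_perms x K
    null_U: np.ndarray  # n_perms x q x K
    null_V: np.ndarray  # n_perms x p x K
    n_perms: int
    perm_seed: int


@dataclass
class PainScoreMatrix:
    """Per-participant expression of each retained mode (L_Y columns)."""

    scores: pd.DataFrame  # n x K_sig, columns = mode labels
    mode_labels: list
    orientation: np.ndarray  # per-mode sign flag (+1 / -1)

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy()


def _dominant_pair(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leading left/right singular vectors of C by power iteration."""
    q = C.shape[1]
    v = C[np.argmax(np.linalg.norm(C, axis=1))]
    nrm = np.linalg.norm(v)
    v = v / nrm if nrm > 0 else np.full(q, 1.0 / np.sqrt(q))
    for _ in range(_POWER_MAXIT):
        a = C @ v
        a_nrm = np.linalg.norm(a)
        if a_nrm < 1e-300:
            break
        a /= a_nrm
        v_new = C.T @ a
        v_nrm = np.linalg.norm(v_new)
        if v_nrm < 1e-300:
            break
        v_new /= v_nrm
        if np.linalg.norm(v_new - v) < _POWER_TOL:
            v = v_new
            break
        v = v_new
    a = C @ v
    a_nrm = np.linalg.norm(a)
    if a_nrm > 0:
        a /= a_nrm
    return a, v


def fit_pls(X, Y, K: int = 10) -> PLSModel:
    """Fit K canonical modes linking brain view X (n x p) to pain view Y (n x q).

    Views are centered (not scaled). Per mode, the dominant singular pair of
    the residual cross-covariance is extracted and both views are deflated by
    their own latent score. Weight signs are fixed so each pain-side vector's
    largest-magnitude entry is positive; flipping u and v jointly leaves R
    unchanged.
    """
    Xv, x_ids, x_names = _as_matrix(X)
    Yv, y_ids, y_names = _as_matrix(Y)
    if Xv.shape[0] != Yv.shape[0]:
        raise ValueError("X and Y must have the same participants")
    if isinstance(X, (FeatureTable, pd.DataFrame)) and isinstance(
        Y, (FeatureTable, pd.DataFrame)
    ):
        if list(x_ids) != list(y_ids):
            raise ValueError("X and Y participant IDs do not match")
    if np.isnan(Xv).any() or np.isnan(Yv).any():
        raise ValueError("fit_pls requires complete data; impute first")
    n, p = Xv.shape
    q = Yv.shape[1]
    if K > min(p, q):
        raise ValueError(f"K={K} exceeds min(p, q)={min(p, q)}")
    for name, M, labels in (("X", Xv, x_names), ("Y", Yv, y_names)):
        sd = M.std(axis=0)
        if np.any(sd < 1e-12):
            cols = [labels[j] for j in np.flatnonzero(sd < 1e-12)]
            raise ValueError(f"zero-variance column(s) in {name}: {cols[:5]}")

    x_mean = Xv.mean(axis=0)
    y_mean = Yv.mean(axis=0)
    Xr = Xv - x_mean
    Yr = Yv - y_mean

    V = np.zeros((p, K))
    U = np.zeros((q, K))
    R = np.zeros(K)
    for l in range(K):
        C = Xr.T @ Yr
        a, b = _dominant_pair(C)
        # sign convention on the pain side
        j = int(np.argmax(np.abs(b)))
        if b[j] < 0:
            a, b = -a, -b
        t = Xr @ a
        s = Yr @ b
        tt = t @ t
        ss = s @ s
        if tt > 0 and ss > 0:
            R[l] = float((t @ s) / np.sqrt(tt * ss))
        V[:, l] = a
        U[:, l] = b
        # symmetric rank-one deflation: regress each view on its own score
        if tt > 0:
            Xr = Xr - np.outer(t, (t @ Xr) / tt)
        if ss > 0:
            Yr = Yr - np.outer(s, (s @ Yr) / ss)
    return PLSModel(V=V, U=U, R=R, x_mean=x_mean, y_mean=y_mean, K=K,
                    x_names=x_names, y_names=y_names)


def permutation_null(
    X, Y, model: PLSModel, n_perms: int = 1000, seed: int = 0
) -> PermutationNull:
    """Refit on row-shuffled Y (X fixed) ``n_perms`` times, recording all
    per-mode R values and both weight matrices per permutation.

    Null values are recorded per mode *index*; no alignment to the observed
    modes is performed.
    """
    if n_perms < 100:
        warnings.warn(
            f"n_perms={n_perms} < 100: tail quantiles will be unstable", stacklevel=2
        )
    Xv, _, _ = _as_matrix(X)
    Yv, _, _ = _as_matrix(Y)
    rng = np.random.default_rng(seed)
    K = model.K
    null_R = np.zeros((n_perms, K))
    null_U = np.zeros((n_perms, Yv.shape[1], K))
    null_V = np.zeros((n_perms, Xv.shape[1], K))
    for i in range(n_perms):
        perm = rng.permutation(Yv.shape[0])
        m = fit_pls(Xv, Yv[perm], K=K)
        null_R[i] = m.R
        null_U[i] = m.U
        null_V[i] = m.V
    return PermutationNull(null_R=null_R, null_U=null_U, null_V=null_V,
                           n_perms=n_perms, perm_seed=seed)


def mode_pvalues(
    observed_R: np.ndarray, null: PermutationNull, alpha: float = 0.001
) -> pd.DataFrame:
    """Permutation-inclusive (add-one) p-value per mode.

    p_l = (1 + #{null R_l >= observed R_l}) / (1 + n_perms); the smallest
    attainable p at 1000 permutations is 1/1001 < 0.001.
    """
    observed_R = np.asarray(observed_R, dtype=float)
    if observed_R.shape[0] != null.null_R.shape[1]:
        raise ValueError("observed_R length does not match null mode count")
    exceed = (null.null_R >= observed_R[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + null.n_perms)
    return pd.DataFrame(
        {
            "mode": np.arange(len(p)),
            "R": observed_R,
            "p_value": p,
            "significant": p < alpha,
        }
    ).set_index("mode")


def significant_loadings(
    model: PLSModel,
    null: PermutationNull,
    mode: int,
    tail: float = 0.05,
    side: str = "pain",
) -> pd.DataFrame:
    """Flag features whose |observed weight| exceeds the (1 - tail) quantile
    of that feature's own permuted-|weight| null for the given mode."""
    if side == "pain":
        weights = model.U[:, mode]
        null_w = np.abs(null.null_U[:, :, mode])
        names = model.y_names
    elif side == "brain":
        weights = model.V[:, mode]
        null_w = np.abs(null.null_V[:, :, mode])
        names = model.x_names
    else:
        raise ValueError("side must be 'pain' or 'brain'")
    thresholds = np.quantile(null_w, 1.0 - tail, axis=0)
    return pd.DataFrame(
        {
            "weight": weights,
            "threshold": thresholds,
            "significant": np.abs(weights) > thresholds,
        },
        index=pd.Index(names, name="feature"),
    )


def domain_summary(loadings: pd.DataFrame, domain_assignment: pd.Series) -> pd.DataFrame:
    """Per-domain count and signed sum of the significant loadings; the
    dominant domain is the one with the largest |summed weight|."""
    df = loadings.join(domain_assignment.rename("domain"))
    sig = df[df["significant"]]
    summary = pd.DataFrame(
        {
            "n_significant": sig.groupby("domain")["weight"].size(),
            "summed_weight": sig.groupby("domain")["weight"].sum(),
        }
    )
    summary = summary.reindex(sorted(df["domain"].unique())).fillna(0.0)
    summary["n_significant"] = summary["n_significant"].astype(int)
    summary.attrs["dominant_domain"] = (
        summary["summed_weight"].abs().idxmax() if len(summary) else None
    )
    return summary


def align_modes(U_ref: np.ndarray, U_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy maximal-|correlation| matching of ``U_new`` columns to
    ``U_ref`` columns, with sign fixing. Returns (order, signs) such that
    U_new[:, order] * signs best matches U_ref column-for-column."""
    K = U_ref.shape[1]
    corr = np.corrcoef(U_ref.T, U_new.T)[:K, K:]
    order = np.full(K, -1, dtype=int)
    signs = np.ones(K)
    remaining = set(range(K))
    for _ in range(K):
        masked = np.abs(corr.copy())
        masked[order >= 0, :] = -1
        masked[:, [j for j in range(K) if j not in remaining]] = -1
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        order[i] = j
        signs[i] = np.sign(corr[i, j]) or 1.0
        remaining.discard(j)
    return order, signs


def split_half_stability(
    X, Y, K: int, n_iters: int = 1000, seed: int = 0
) -> np.ndarray:
    """Cross-half stability of the pain-side vectors.

    Per iteration, participants are split into random disjoint halves, each
    half is fit independently, half-B modes are aligned to half-A modes
    (greedy |corr| matching), and the per-mode |correlation| between the two
    halves' pain-side vectors is recorded. Returns (n_iters, K).
    """
    Xv, _, _ = _as_matrix(X)
    Yv, _, _ = _as_matrix(Y)
    n = Xv.shape[0]
    if n < 2 * (K + 1):
        raise ValueError("too few participants for a split-half analysis")
    rng = np.random.default_rng(seed)
    out = np.zeros((n_iters, K))
    for it in range(n_iters):
        perm = rng.permutation(n)
        a, b = perm[: n // 2], perm[n // 2 :]
        ma = fit_pls(Xv[a], Yv[a], K=K)
        mb = fit_pls(Xv[b], Yv[b], K=K)
        order, _ = align_modes(ma.U, mb.U)
        for l in range(K):
            out[it, l] = abs(np.corrcoef(ma.U[:, l], mb.U[:, order[l]])[0, 1])
    return out


def pain_scores(Y, model: PLSModel, retained_modes) -> PainScoreMatrix:
    """Project centered Y onto the retained pain-side vectors (L_Y columns)."""
    Yv, y_ids, y_names = _as_matrix(Y)
    if list(y_names) != list(model.y_names):
        raise ValueError("Y features do not match the fitted model")
    retained = list(retained_modes)
    scores = (Yv - model.y_mean) @ model.U[:, retained]
    labels = [f"mode_{l + 1}" for l in retained]
    return PainScoreMatrix(
        scores=pd.DataFrame(scores, index=y_ids, columns=labels),
        mode_labels=labels,
        orientation=np.ones(len(retained)),
    )
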