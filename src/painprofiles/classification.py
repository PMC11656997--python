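"""Body-part versus dominant-pain-profile class labels and their
predictability from behavioural/lifestyle features.

Two labelings of the same cohort are compared: (1) a body-region label from
the pain-location questionnaire (region codes with 900 for "more than three
major sites" and a no-pain code), and (2) a dominant-pain-profile label from
pain-agnostic, sign-oriented profile scores with the lowest-scoring fraction
assigned to a "no pain" class. A linear discriminant classifier is evaluated
under stratified five-fold cross-validation with class-balancing resampling
of the training folds, reporting accuracy and micro-averaged AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .pls import PLSModel, PainScoreMatrix, pain_scores
from .tables import FeatureTable

log = logging.getLogger(__name__)

NO_PAIN_LABEL = "no-pain"
PROFILE_NAMES = ("pain-interference", "depression", "medical-pain", "anxiety")
IASP_MULTISITE = 900
IASP_NO_PAIN = 0


# ---------------------------------------------------------------------------
# body-part labels


def assign_body_part(
    location_fields: pd.DataFrame, mapping_table: pd.DataFrame
) -> pd.DataFrame:
    """One body-region label per participant, with rule provenance.

    Precedence: (1) the "area most bothered" answer when present; (2) the
    all-over-body flag -> 900; (3) more than two listed sites -> 900, exactly
    two -> the first listed site; (4) a single site -> its mapped region;
    (5) no sites -> no-pain.
    """
    site_map = dict(zip(mapping_table["site"].astype(str), mapping_table["iasp_code"]))
    site_cols = [c for c in location_fields.columns if c.startswith("site_")]
    site_names = [c[len("site_"):] for c in site_cols]
    unmapped = [s for s in site_names if s not in site_map]
    if unmapped:
        raise ValueError(f"unmapped location value(s): {unmapped}")

    labels = np.empty(len(location_fields), dtype=int)
    provenance = np.empty(len(location_fields), dtype=object)
    most = location_fields.get("most_bothered")
    all_over = location_fields.get("all_over")
    sites = location_fields[site_cols].to_numpy() > 0
    for i in range(len(location_fields)):
        mb = None if most is None else most.iloc[i]
        if isinstance(mb, str) and mb:
            if mb not in site_map:
                raise ValueError(f"unmapped location value: {mb!r}")
            labels[i] = site_map[mb]
            provenance[i] = "most_bothered"
            continue
        if all_over is not None and all_over.iloc[i]:
            labels[i] = IASP_MULTISITE
            provenance[i] = "all_over"
            continue
        listed = np.flatnonzero(sites[i])
        if len(listed) > 2:
            labels[i] = IASP_MULTISITE
            provenance[i] = "multi_site"
        elif len(listed) == 2:
            labels[i] = site_map[site_names[listed[0]]]
            provenance[i] = "first_of_two"
        elif len(listed) == 1:
            labels[i] = site_map[site_names[listed[0]]]
            provenance[i] = "single_site"
        else:
            labels[i] = IASP_NO_PAIN
            provenance[i] = "no_pain"
    return pd.DataFrame(
        {"iasp_code": labels, "provenance": provenance}, index=location_fields.index
    )


# ---------------------------------------------------------------------------
# profile labels


def pain_agnostic_scores(Y, model: PLSModel, retained_modes) -> PainScoreMatrix:
    """Profile scores with all pain-location fields zeroed out first.

    The pain-side vectors U are left untouched; only the participant data
    loses its location information before projection.
    """
    if isinstance(Y, FeatureTable):
        data = Y.data.copy()
        loc_cols = Y.location_features()
    else:
        raise TypeError("pain_agnostic_scores expects a FeatureTable with location flags")
    data[loc_cols] = 0.0
    return pain_scores(FeatureTable(data, Y.meta.copy()), model, retained_modes)


def orient_profiles(
    scores: PainScoreMatrix, pain_burden: pd.Series
) -> PainScoreMatrix:
    """Flip each score column's sign so it correlates positively with the
    per-participant pain burden (count of reported painful sites).

    Magnitudes are untouched; the operation is idempotent.
    """
    burden = pain_burden.loc[scores.scores.index].to_numpy(dtype=float)
    if np.std(burden) < 1e-12:
        raise ValueError("pain burden has zero variance; cannot orient profiles")
    values = scores.values
    signs = np.ones(values.shape[1])
    for k in range(values.shape[1]):
        r = np.corrcoef(values[:, k], burden)[0, 1]
        if r < 0:
            signs[k] = -1.0
    oriented = values * signs
    return PainScoreMatrix(
        scores=pd.DataFrame(oriented, index=scores.scores.index, columns=scores.scores.columns),
        mode_labels=scores.mode_labels,
        orientation=scores.orientation * signs,
    )


def assign_dominant_profile(
    oriented: PainScoreMatrix,
    no_pain_fraction: float = 0.34,
    profile_names=PROFILE_NAMES,
) -> pd.Series:
    """Largest oriented score wins; the floor(no_pain_fraction * n)
    participants with the smallest maximum score become the no-pain class.

    Score columns are standardised (z-scored) before comparison: the modes'
    raw score scales are not commensurate, and zeroing location fields shifts
    each column by a different constant. Argmax ties break by fixed profile
    order (first column wins).
    """
    values = oriented.values
    values = (values - values.mean(axis=0)) / values.std(axis=0)
    if values.shape[1] != len(profile_names):
        raise ValueError(
            f"expected {len(profile_names)} score columns, got {values.shape[1]}"
        )
    best = np.argmax(values, axis=1)  # first occurrence wins ties
    max_score = values[np.arange(len(values)), best]
    labels = np.array([profile_names[b] for b in best], dtype=object)
    k = int(np.floor(no_pain_fraction * len(values)))
    if k > 0:
        lowest = np.argsort(max_score, kind="stable")[:k]
        labels[lowest] = NO_PAIN_LABEL
    return pd.Series(labels, index=oriented.scores.index, name="profile_label")


# ---------------------------------------------------------------------------
# classifier


def fit_lda(features: np.ndarray, labels: np.ndarray) -> LinearDiscriminantAnalysis:
    """Gaussian linear discriminant with shared covariance; posteriors via
    predict_proba. A singular pooled covariance falls back to a small ridge
    (shrinkage), logged."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes")
    if np.isnan(np.asarray(features, dtype=float)).any():
        raise ValueError("features must be complete")
    try:
        model = LinearDiscriminantAnalysis(solver="svd")
        model.fit(features, labels)
    except np.linalg.LinAlgError:
        eps = 1e-4
        log.warning("singular pooled covariance; ridge-regularizing with eps=%g", eps)
        model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=eps)
        model.fit(features, labels)
    return model


def micro_auc(scores_per_class: np.ndarray, labels: np.ndarray, classes) -> float:
    """Micro-averaged one-vs-rest ROC AUC.

    Labels are binarized one-vs-rest, all (score, indicator) pairs are pooled
    across classes, and a single ROC AUC is computed on the pooled vectors.
    """
    classes = list(classes)
    if len(classes) < 2:
        raise ValueError("micro-averaged AUC is undefined for a single class")
    labels = np.asarray(labels)
    scores_per_class = np.asarray(scores_per_class, dtype=float)
    indicator = np.column_stack([(labels == c).astype(int) for c in classes])
    y = indicator.ravel()
    x = scores_per_class.ravel()
    # rank-based (Mann-Whitney) AUC on the pooled pairs, ties averaged
    order = pd.Series(x).rank(method="average").to_numpy()
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("pooled indicator is degenerate")
    return float((order[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class CVResult:
    """Cross-validated performance: folds x resamples iterations."""

    accuracies: np.ndarray  # per iteration
    micro_aucs: np.ndarray  # per iteration
    per_class_auc: pd.DataFrame  # iterations x classes (one-vs-rest)
    chance_level: float
    folds: int
    resamples: int

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1))

    @property
    def mean_micro_auc(self) -> float:
        return float(self.micro_aucs.mean())

    @property
    def sd_micro_auc(self) -> float:
        return float(self.micro_aucs.std(ddof=1))

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "mean_accuracy": self.mean_accuracy,
                "sd_accuracy": self.sd_accuracy,
                "mean_micro_auc": self.mean_micro_auc,
                "sd_micro_auc": self.sd_micro_auc,
                "chance_level": self.chance_level,
                "iterations": len(self.accuracies),
            }
        )


def _balance_classes(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample minority classes with replacement to the majority size."""
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    idx_parts = []
    for c, cnt in zip(classes, counts):
        idx = np.flatnonzero(y == c)
        if cnt < target:
            extra = rng.choice(idx, size=target - cnt, replace=True)
            idx = np.concatenate([idx, extra])
        idx_parts.append(idx)
    sel = np.concatenate(idx_parts)
    return X[sel], y[sel]


def crossvalidate(
    features,
    labels,
    folds: int = 5,
    resamples: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation with class-balancing resampling.

    Per fold, the training data are rebalanced by oversampling before each of
    ``resamples`` LDA fits; evaluation is always on the untouched held-out
    fold. Accuracy and micro-averaged AUC are recorded per iteration
    (folds x resamples total).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` members for stratification")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
    accs, aucs, per_class_rows = [], [], []
    for train_idx, test_idx in skf.split(X, y):
        if len(np.unique(y[test_idx])) < len(classes):
            raise RuntimeError("a class is absent from a held-out fold")
        for _ in range(resamples):
            Xb, yb = _balance_classes(X[train_idx], y[train_idx], rng)
            model = fit_lda(Xb, yb)
            proba = model.predict_proba(X[test_idx])
            # column order follows model.classes_; realign to global order
            col = {c: i for i, c in enumerate(model.classes_)}
            proba = proba[:, [col[c] for c in classes]]
            pred = classes[np.argmax(proba, axis=1)]
            accs.append(float(np.mean(pred == y[test_idx])))
            aucs.append(micro_auc(proba, y[test_idx], classes))
            row = {}
            for i, c in enumerate(classes):
                ind = (y[test_idx] == c).astype(int)
                row[c] = _binary_auc(proba[:, i], ind)
            per_class_rows.append(row)
    return CVResult(
        accuracies=np.array(accs),
        micro_aucs=np.array(aucs),
        per_class_auc=pd.DataFrame(per_class_rows),
        chance_level=1.0 / len(classes),
        folds=folds,
        resamples=resamples,
    )


def _binary_auc(score: np.ndarray, indicator: np.ndarray) -> float:
    ranks = pd.Series(score).rank(method="average").to_numpy()
    n_pos = int(indicator.sum())
    n_neg = len(indicator) - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    return float((ranks[indicator == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
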