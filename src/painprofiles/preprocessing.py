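"""Cohort-definition filters, 0-10 recoding, resampling imputation, and
linear deconfounding.

The fixed pipeline order is: participant filter -> field filter -> recode ->
impute -> deconfound (brain features only). Pain features are recoded and
imputed but deliberately not deconfounded of age/sex/BMI, since that
interindividual variation is part of the signal of interest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .tables import FeatureTable, RecodingRule

log = logging.getLogger(__name__)


class EmptyCohortError(ValueError):
    """All participants (or all fields) were removed by a filter."""


def filter_participants(table: FeatureTable, max_missing_frac: float = 0.90) -> FeatureTable:
    """Drop participants whose missing fraction across all features is
    >= ``max_missing_frac`` (the threshold itself is excluded, per the
    inclusive >= rule). Survivor order is preserved."""
    if not (0.0 < max_missing_frac <= 1.0):
        raise ValueError("max_missing_frac must be in (0, 1]")
    frac = table.participant_missing_frac()
    keep = frac < max_missing_frac
    if not keep.any():
        raise EmptyCohortError("participant filter removed every participant")
    out = table.select_participants(table.participant_ids[keep])
    log.info("participant filter: kept %d of %d", out.n, table.n)
    return out


def filter_fields(table: FeatureTable, max_missing_frac: float = 0.75) -> FeatureTable:
    """Drop fields missing in >= ``max_missing_frac`` of (retained)
    participants; metadata follows the surviving columns."""
    if not (0.0 < max_missing_frac <= 1.0):
        raise ValueError("max_missing_frac must be in (0, 1]")
    frac = table.feature_missing_frac()
    keep = frac < max_missing_frac
    if not keep.any():
        raise EmptyCohortError("field filter removed every field")
    out = table.select_features(table.features[keep])
    log.info("field filter: kept %d of %d fields", len(out.features), len(table.features))
    return out


@dataclass
class RecodeReport:
    """Per-cell recoding failures: raw values outside a rule's domain."""

    bad_cells: list = field(default_factory=list)  # (participant_id, feature, raw)

    @property
    def n_bad(self) -> int:
        return len(self.bad_cells)


def recode(
    table: FeatureTable, rules: dict[str, RecodingRule]
) -> tuple[FeatureTable, RecodeReport]:
    """Map every feature onto the common 0-10 scale via its recoding rule.

    Missing stays missing. A raw value outside the rule's source levels is
    reported, set missing, and a warning is emitted.
    """
    out = table.copy()
    report = RecodeReport()
    for feat in out.features:
        rule_id = str(out.meta.loc[feat, "rule_id"])
        if rule_id not in rules:
            raise KeyError(f"feature {feat!r}: no recoding rule {rule_id!r}")
        recoded, bad = rules[rule_id].apply(out.data[feat].to_numpy())
        if bad.any():
            for i in np.flatnonzero(bad):
                report.bad_cells.append(
                    (out.participant_ids[i], feat, out.data[feat].iloc[i])
                )
            recoded[bad] = np.nan
        out.data[feat] = recoded
    if report.n_bad:
        warnings.warn(
            f"recode: {report.n_bad} cell(s) outside their rule's domain were set missing",
            stacklevel=2,
        )
    return out, report


def impute(table: FeatureTable, seed: int) -> FeatureTable:
    """Fill each missing cell with a uniform draw (with replacement) from the
    same feature's observed values.

    Deterministic under ``seed``: features are processed in column order and
    missing cells in row order.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    for feat in out.features:
        col = out.data[feat].to_numpy()
        missing = np.isnan(col)
        if not missing.any():
            continue
        donors = col[~missing]
        if donors.size == 0:
            raise ValueError(
                f"feature {feat!r} is fully missing; run filter_fields first"
            )
        col[missing] = rng.choice(donors, size=int(missing.sum()), replace=True)
        out.data[feat] = col
    return out


def deconfound(table: FeatureTable, confounds: FeatureTable) -> FeatureTable:
    """Replace each feature by its residual after ordinary least squares on an
    intercept plus the confound columns.

    Residuals have zero sample correlation with every confound. Requires the
    same participants in both tables and complete confounds.
    """
    if not table.participant_ids.equals(confounds.participant_ids):
        raise ValueError("table and confounds must share the same participants")
    C = confounds.values
    if np.isnan(C).any():
        raise ValueError("confounds must be complete (no missing values)")
    if np.isnan(table.values).any():
        raise ValueError("deconfound requires a complete table; impute first")
    design = np.column_stack([np.ones(len(C)), C])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the collinear columns via the rank-revealing QR pivot order
        _, _, piv = scipy.linalg.qr(design, pivoting=True, mode="economic")
        bad = [
            ("intercept" if j == 0 else str(confounds.features[j - 1]))
            for j in piv[rank:]
        ]
        raise ValueError(f"rank-deficient confound matrix; collinear columns: {bad}")
    Y = table.values
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta
    out = table.copy()
    out.data = pd.DataFrame(resid, index=table.participant_ids, columns=table.features)
    return out


def preprocess_pipeline(
    pain: FeatureTable,
    brain: FeatureTable,
    confounds: FeatureTable,
    rules: dict[str, RecodingRule],
    seed: int,
    participant_thresh: float = 0.90,
    field_thresh: float = 0.75,
) -> tuple[FeatureTable, FeatureTable, RecodeReport]:
    """The full fixed-order pipeline.

    Missingness filters apply to the pain table (the candidate pain
    variables); the brain and confound tables are subset to the surviving
    participants. Only the brain features are deconfounded.
    """
    pain = filter_participants(pain, participant_thresh)
    pain = filter_fields(pain, field_thresh)
    pain, report = recode(pain, rules)
    pain = impute(pain, seed)
    survivors = pain.participant_ids
    brain = brain.select_participants(survivors)
    confounds = confounds.select_participants(survivors)
    brain = deconfound(brain, confounds)
    log.info(
        "pipeline: %d participants, %d pain features, %d brain features",
        pain.n,
        len(pain.features),
        len(brain.features),
    )
    return pain, brain, report
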