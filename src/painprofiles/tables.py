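"""Participant-by-feature tables and recoding rules.

The whole pipeline moves participant-level data around as :class:`FeatureTable`
objects: a numeric participant x feature matrix (``NaN`` marks missing) paired
with per-feature metadata (symptom domain, whether the feature records pain
location, and which recoding rule maps its raw coding onto the common 0-10
health-to-disease scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns every FeatureTable carries
META_COLUMNS = ("domain", "is_location", "rule_id")

#: recognised symptom domains for pain features
DOMAINS = (
    "pain-interference",
    "depression",
    "medical-pain",
    "anxiety",
    "location",
    "other",
)


@dataclass(frozen=True)
class RecodingRule:
    """Maps one raw coding onto the common 0-10 scale (0 best, 10 worst).

    Discrete rules enumerate ``source_levels`` and their ``target_values``;
    the two continuous rules (``identity`` and ``reverse``) are registered
    with empty level tuples and applied functionally.
    """

    rule_id: str
    source_levels: tuple = ()
    target_values: tuple = ()
    direction: str = "standard"  # "reversed" when raw high = healthy

    def __post_init__(self):
        if len(self.source_levels) != len(self.target_values):
            raise ValueError(f"rule {self.rule_id}: levels/targets length mismatch")
        for t in self.target_values:
            if not (0.0 <= float(t) <= 10.0):
                raise ValueError(f"rule {self.rule_id}: target {t} outside [0, 10]")

    @property
    def continuous(self) -> bool:
        return self.rule_id in ("identity", "reverse")

    def apply(self, raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Recode ``raw`` values; returns (recoded, bad_mask).

        Missing (NaN) input stays missing. Values outside the rule's domain
        are flagged in ``bad_mask`` and set missing by the caller.
        """
        raw = np.asarray(raw, dtype=float)
        out = np.full(raw.shape, np.nan)
        observed = ~np.isnan(raw)
        bad = np.zeros(raw.shape, dtype=bool)
        if self.rule_id == "identity":
            ok = observed & (raw >= 0) & (raw <= 10)
            out[ok] = raw[ok]
            bad = observed & ~ok
        elif self.rule_id == "reverse":
            ok = observed & (raw >= 0) & (raw <= 10)
            out[ok] = 10.0 - raw[ok]
            bad = observed & ~ok
        else:
            levels = np.asarray(self.source_levels, dtype=float)
            targets = np.asarray(self.target_values, dtype=float)
            for lev, tgt in zip(levels, targets):
                out[observed & (raw == lev)] = tgt
            bad = observed & np.isnan(out)
        return out, bad


def default_rules() -> dict[str, RecodingRule]:
    """The shipped rule registry: the raw codings the generator emits."""
    return {
        "identity": RecodingRule("identity"),
        "reverse": RecodingRule("reverse", direction="reversed"),
        "ordinal4": RecodingRule(
            "ordinal4", (1, 2, 3, 4), (0.0, 10.0 / 3.0, 20.0 / 3.0, 10.0)
        ),
        "binary": RecodingRule("binary", (0, 1), (0.0, 10.0)),
    }


def rules_to_frame(rules: dict[str, RecodingRule]) -> pd.DataFrame:
    rows = []
    for rule in rules.values():
        if rule.continuous:
            rows.append((rule.rule_id, "", "", rule.direction))
        else:
            for lev, tgt in zip(rule.source_levels, rule.target_values):
                rows.append((rule.rule_id, lev, tgt, rule.direction))
    return pd.DataFrame(rows, columns=["rule_id", "raw_level", "target_value", "direction"])


def rules_from_frame(frame: pd.DataFrame) -> dict[str, RecodingRule]:
    rules: dict[str, RecodingRule] = {}
    for rule_id, grp in frame.groupby("rule_id", sort=False):
        direction = str(grp["direction"].iloc[0])
        if rule_id in ("identity", "reverse"):
            rules[rule_id] = RecodingRule(rule_id, direction=direction)
        else:
            levels = tuple(float(x) for x in grp["raw_level"])
            targets = tuple(float(x) for x in grp["target_value"])
            rules[rule_id] = RecodingRule(rule_id, levels, targets, direction)
    return rules


@dataclass
class FeatureTable:
    """Numeric participant x feature matrix plus per-feature metadata.

    ``data`` is indexed by participant ID (unique, order-preserving) with one
    float column per feature; ``NaN`` is the missing marker. ``meta`` is
    indexed by feature name with columns ``domain``, ``is_location`` and
    ``rule_id``.
    """

    data: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate participant IDs: {dupes[:5]}")
        if self.meta is None:
            self.meta = pd.DataFrame(
                {"domain": "other", "is_location": False, "rule_id": "identity"},
                index=self.data.columns,
            )
        if not self.meta.index.equals(self.data.columns.astype(self.meta.index.dtype)):
            if set(self.meta.index) != set(self.data.columns):
                raise ValueError("feature metadata does not match data columns")
            self.meta = self.meta.loc[self.data.columns]
        self.data = self.data.astype(float)

    # -- basic views ------------------------------------------------------
    @property
    def participant_ids(self) -> pd.Index:
        return self.data.index

    @property
    def features(self) -> pd.Index:
        return self.data.columns

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def participant_missing_frac(self) -> pd.Series:
        """Per-participant fraction of missing cells across all features."""
        return self.data.isna().mean(axis=1)

    def feature_missing_frac(self) -> pd.Series:
        """Per-feature fraction of missing cells across all participants."""
        return self.data.isna().mean(axis=0)

    def location_features(self) -> list[str]:
        return list(self.meta.index[self.meta["is_location"].astype(bool)])

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.meta.copy())

    def select_participants(self, ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[ids], self.meta.copy())

    def select_features(self, names) -> "FeatureTable":
        names = list(names)
        return FeatureTable(self.data[names], self.meta.loc[names])

    # -- I/O: tab-separated dialect shared across the package -------------
    def to_tsv(self, values_path, meta_path=None) -> None:
        self.data.to_csv(values_path, sep="\t", index_label="participant_id")
        if meta_path is not None:
            self.meta.to_csv(meta_path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, values_path, meta_path=None) -> "FeatureTable":
        data = pd.read_csv(values_path, sep="\t", index_col="participant_id")
        meta = None
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t", index_col="feature")
            meta.index = meta.index.astype(data.columns.dtype)
        return cls(data, meta)
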