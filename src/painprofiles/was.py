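"""Clinical feature matrices and mass-univariate association batteries.

Three batteries run against the individual pain scores: a phenome-wide scan
(curated phenotypes), a diagnosis-wide scan (binary phecode columns built
from ICD records, with control-exclusion masks to avoid case contamination),
and a medication-wide scan (per-category ATC level-3 prescription counts).
Each battery computes a Pearson correlation, two-sided p-value and Fisher z
per column, with Bonferroni and Benjamini-Hochberg (5% FDR) multiplicity
flags over the testable columns.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable
from .pls import PainScoreMatrix

log = logging.getLogger(__name__)

_ATC5_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")
#: code prefix length per ATC level
_ATC_LEVEL_LEN = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}


@dataclass
class ClinicalMatrix:
    """Participant x clinical-feature matrix with per-column metadata.

    ``exclusion_mask`` (diagnosis source only) is True where a participant
    must be dropped from a column's control group (related disease but not
    the disease of study).
    """

    data: pd.DataFrame
    meta: pd.DataFrame  # index = columns; columns: category, source
    exclusion_mask: pd.DataFrame | None = None

    def __post_init__(self):
        if self.data.columns.has_duplicates:
            raise ValueError("clinical matrix column names must be unique")
        if self.exclusion_mask is not None:
            if set(self.meta["source"]) - {"diagnosis"}:
                if (self.meta.loc[self.meta["source"] != "diagnosis"].index
                        .intersection(self.exclusion_mask.columns[self.exclusion_mask.any()])
                        .size):
                    raise ValueError("exclusion mask is only valid for diagnosis columns")


@dataclass
class AssociationResult:
    """One battery x one profile: per-column rho, p, Fisher z and flags."""

    table: pd.DataFrame  # rho, p_value, fisher_z, n_used, bonferroni_sig, fdr_sig
    profile: str
    battery: str
    m_tests: int
    alpha: float = 0.05
    fdr_q: float = 0.05


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up flags at level ``q``.

    NaN p-values (untestable columns) are never flagged and do not count
    toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    flags = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.any():
        flags[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return flags


def fisher_z(rho) -> np.ndarray:
    """atanh of a correlation, clipped at |rho| = 1 - 1e-12."""
    r = np.clip(np.asarray(rho, dtype=float), -1 + 1e-12, 1 - 1e-12)
    return np.arctanh(r)


def run_was(
    scores: PainScoreMatrix | pd.DataFrame,
    clinical: ClinicalMatrix,
    profile: str,
    alpha: float = 0.05,
    fdr_q: float = 0.05,
    battery: str = "clinical",
) -> AssociationResult:
    """Pearson association of one profile's scores with every clinical column.

    Participants are matched on the intersection of IDs; each column uses
    pairwise-complete observations minus its control-exclusion mask. Columns
    that end up constant (or with < 3 observations) are recorded with missing
    statistics and excluded from the multiplicity count m.
    """
    score_df = scores.scores if isinstance(scores, PainScoreMatrix) else scores
    if profile not in score_df.columns:
        raise KeyError(f"profile {profile!r} not among score columns")
    shared = score_df.index.intersection(clinical.data.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared participants")
    s = score_df.loc[shared, profile].to_numpy(dtype=float)
    rows = []
    for col in clinical.data.columns:
        y = clinical.data.loc[shared, col].to_numpy(dtype=float)
        keep = ~np.isnan(y) & ~np.isnan(s)
        if clinical.exclusion_mask is not None and col in clinical.exclusion_mask.columns:
            excl = clinical.exclusion_mask.loc[shared, col].to_numpy(dtype=bool)
            keep &= ~excl
        n_used = int(keep.sum())
        if n_used < 3 or np.std(y[keep]) < 1e-12 or np.std(s[keep]) < 1e-12:
            warnings.warn(f"column {col!r}: untestable (constant or n<3)", stacklevel=2)
            rows.append((col, np.nan, np.nan, np.nan, n_used))
            continue
        rho, p = stats.pearsonr(s[keep], y[keep])
        rows.append((col, float(rho), float(p), float(fisher_z(rho)), n_used))
    table = pd.DataFrame(
        rows, columns=["column", "rho", "p_value", "fisher_z", "n_used"]
    ).set_index("column")
    testable = ~table["p_value"].isna()
    m = int(testable.sum())
    if m == 0:
        raise ValueError("no testable clinical columns")
    thr = bonferroni_threshold(alpha, m)
    table["bonferroni_sig"] = testable & (table["p_value"] < thr)
    table["fdr_sig"] = bh_fdr(table["p_value"].to_numpy(), q=fdr_q)
    table = table.join(clinical.meta[["category"]], how="left")
    log.info("%s/%s: m=%d testable columns, Bonferroni threshold %.3g",
             battery, profile, m, thr)
    return AssociationResult(
        table=table, profile=profile, battery=battery, m_tests=m,
        alpha=alpha, fdr_q=fdr_q,
    )


# ---------------------------------------------------------------------------
# phecode matrix


@dataclass
class PhecodeMap:
    """ICD -> phecode mapping with control-exclusion ranges.

    ICD codes map by the longest matching code prefix within their coding
    version, emulating the hierarchical grouping of the source map.
    """

    mapping: pd.DataFrame  # icd_version, icd_code (prefix), phecode, category
    exclusions: pd.DataFrame  # phecode, range_start, range_end

    def __post_init__(self):
        known = set(self.mapping["phecode"].astype(float))
        missing = set(self.exclusions["phecode"].astype(float)) - known
        if missing:
            raise ValueError(f"exclusion ranges reference undefined phecodes: {missing}")

    @classmethod
    def from_tsv(cls, map_path, exclusions_path) -> "PhecodeMap":
        return cls(
            pd.read_csv(map_path, sep="\t", dtype={"icd_code": str}),
            pd.read_csv(exclusions_path, sep="\t"),
        )

    def lookup(self, icd_version: str, icd_code: str) -> float | None:
        """Longest-prefix match of one ICD code; None if unmapped."""
        cand = self.mapping[self.mapping["icd_version"] == icd_version]
        best, best_len = None, -1
        for prefix, phecode in zip(cand["icd_code"], cand["phecode"]):
            if icd_code.startswith(str(prefix)) and len(str(prefix)) > best_len:
                best, best_len = float(phecode), len(str(prefix))
        return best


def build_phecode_matrix(
    diagnoses: pd.DataFrame, phemap: PhecodeMap, cohort_ids
) -> ClinicalMatrix:
    """Binary phecode columns over the cohort, with control-exclusion masks.

    Only phecodes actually represented in the cohort get a column
    (unrepresented codes are dropped). For each phecode, participants whose
    records fall inside its exclusion range without carrying the phecode
    itself are masked out of the control group; a participant with no
    diagnoses at all is an unmasked control everywhere.
    """
    cohort_ids = pd.Index(cohort_ids)
    carried: dict[str, set] = {}
    n_unmapped = 0
    for pid, ver, code in zip(
        diagnoses["participant_id"], diagnoses["icd_version"], diagnoses["icd_code"]
    ):
        if pid not in cohort_ids:
            continue
        phe = phemap.lookup(str(ver), str(code))
        if phe is None:
            n_unmapped += 1
            continue
        carried.setdefault(pid, set()).add(phe)
    if n_unmapped:
        log.info("build_phecode_matrix: %d unmapped ICD records skipped", n_unmapped)

    present = sorted({phe for s in carried.values() for phe in s})
    cols = {f"phecode_{phe:g}": phe for phe in present}
    data = pd.DataFrame(0.0, index=cohort_ids, columns=list(cols))
    mask = pd.DataFrame(False, index=cohort_ids, columns=list(cols))
    excl_ranges = {
        float(r.phecode): (float(r.range_start), float(r.range_end))
        for r in phemap.exclusions.itertuples()
    }
    for pid, phes in carried.items():
        for name, phe in cols.items():
            if phe in phes:
                data.loc[pid, name] = 1.0
            elif phe in excl_ranges:
                lo, hi = excl_ranges[phe]
                if any(lo <= other <= hi for other in phes):
                    mask.loc[pid, name] = True
    cat = phemap.mapping.drop_duplicates("phecode").set_index("phecode")["category"]
    meta = pd.DataFrame(
        {
            "category": [cat.get(phe, "unknown") for phe in cols.values()],
            "source": "diagnosis",
        },
        index=pd.Index(cols, name="column"),
    )
    return ClinicalMatrix(data=data, meta=meta, exclusion_mask=mask)


# ---------------------------------------------------------------------------
# ATC medication matrix


@dataclass
class ATCMap:
    """Medication-name -> ATC code(s) map with a combination flag.

    ``codes`` maps a lower-cased medication name to its ATC level-5 codes
    sorted alpha-numerically; when a medication has several codes the first
    in that order is used. Combination products are excluded.
    """

    codes: dict[str, list[str]] = field(default_factory=dict)
    combinations: set = field(default_factory=set)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ATCMap":
        codes: dict[str, list[str]] = {}
        combos = set()
        for row in frame.itertuples():
            name = str(row.medication_name).lower()
            parsed = sorted(str(row.atc_codes).split(";"))
            for c in parsed:
                if not _ATC5_RE.match(c):
                    raise ValueError(f"invalid ATC level-5 code {c!r} for {name!r}")
            codes[name] = parsed
            if int(row.is_combination):
                combos.add(name)
        return cls(codes=codes, combinations=combos)

    @classmethod
    def from_tsv(cls, path) -> "ATCMap":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def truncate_atc(code: str, level: int = 3) -> str:
    return code[: _ATC_LEVEL_LEN[level]]


def build_atc_matrix(
    medications: pd.DataFrame,
    atc_map: ATCMap,
    level: int = 3,
    cohort_ids=None,
) -> ClinicalMatrix:
    """Per-participant prescription counts over ATC categories at ``level``.

    Rules: multi-code medications take the first code in alpha-numeric order;
    combination products are dropped; codeine is never counted under N02A
    (the shipped map assigns it the cough-suppressant code); unmapped names
    are logged and skipped.
    """
    if cohort_ids is None:
        cohort_ids = pd.Index(medications["participant_id"].unique())
    else:
        cohort_ids = pd.Index(cohort_ids)
    counts: dict[str, dict[str, int]] = {}
    n_skipped = 0
    for pid, name in zip(medications["participant_id"], medications["medication_name"]):
        if pid not in cohort_ids:
            continue
        key = str(name).lower()
        if key not in atc_map.codes:
            n_skipped += 1
            continue
        if key in atc_map.combinations:
            continue
        code = atc_map.codes[key][0]
        cat = truncate_atc(code, level)
        if key == "codeine" and cat == "N02A":
            # codeine is a weak opioid most often used as a cough suppressant;
            # it must never inflate the opioid category
            continue
        counts.setdefault(cat, {}).setdefault(pid, 0)
        counts[cat][pid] += 1
    if n_skipped:
        log.info("build_atc_matrix: %d records without an ATC code skipped", n_skipped)
    cats = sorted(counts)
    data = pd.DataFrame(0.0, index=cohort_ids, columns=cats)
    for cat, per_pid in counts.items():
        for pid, c in per_pid.items():
            data.loc[pid, cat] = float(c)
    meta = pd.DataFrame(
        {"category": [c[0] for c in cats], "source": "medication"},
        index=pd.Index(cats, name="column"),
    )
    return ClinicalMatrix(data=data, meta=meta)


# ---------------------------------------------------------------------------
# phenotype curation


def curate_phenotypes(
    raw: FeatureTable,
    min_n: int = 500,
    dedup_rho: float = 0.99,
    drop_categories: tuple = ("mental health",),
) -> ClinicalMatrix:
    """Curation rules for the phenome battery.

    Drops listed categories, one-hot expands categorical-unordered columns,
    drops columns observed for fewer than ``min_n`` participants, and keeps
    only the first column (in file order) of any group correlated above
    ``dedup_rho``.
    """
    meta = raw.meta
    cats = meta["category"] if "category" in meta else pd.Series("unknown", index=meta.index)
    dtypes = meta["datatype"] if "datatype" in meta else pd.Series("numerical", index=meta.index)

    keep = [f for f in raw.features if cats.get(f, "unknown") not in set(drop_categories)]
    frames = {}
    out_meta_rows = []
    for f in keep:
        col = raw.data[f]
        if dtypes.get(f, "numerical") == "categorical_unordered":
            observed = col.dropna().unique()
            for lev in sorted(observed):
                name = f"{f}={lev:g}" if isinstance(lev, float) else f"{f}={lev}"
                frames[name] = (col == lev).astype(float).mask(col.isna())
                out_meta_rows.append((name, cats.get(f, "unknown")))
        else:
            frames[f] = col
            out_meta_rows.append((f, cats.get(f, "unknown")))
    data = pd.DataFrame(frames, index=raw.participant_ids)

    enough = data.notna().sum(axis=0) >= min_n
    data = data.loc[:, enough]
    out_meta_rows = [r for r in out_meta_rows if r[0] in data.columns]

    # dedup: first column in order wins its correlated group
    kept_cols: list[str] = []
    for col in data.columns:
        duplicate = False
        for prior in kept_cols:
            pair = data[[prior, col]].dropna()
            if len(pair) >= 3:
                sd = pair.std(ddof=0)
                if (sd > 1e-12).all():
                    rho = pair[prior].corr(pair[col])
                    if abs(rho) > dedup_rho:
                        duplicate = True
                        break
        if not duplicate:
            kept_cols.append(col)
    data = data[kept_cols]
    meta_out = pd.DataFrame(
        [r for r in out_meta_rows if r[0] in kept_cols],
        columns=["column", "category"],
    ).set_index("column")
    meta_out["source"] = "phenotype"
    return ClinicalMatrix(data=data, meta=meta_out)
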