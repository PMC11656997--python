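"""Synthetic cohorts with a planted two-view low-rank pain-brain structure.

Every downstream stage of the pipeline is testable without restricted data:
this module generates a participant cohort whose pain-experience matrix and
regional brain-volume matrix share a planted rank-K cross-covariance, applies
heterogeneous raw codings and structured missingness to the pain features, and
derives clinical annotation tables (medications, diagnoses, phenotypes, pain
locations) whose event probabilities are logistic in the latent mode scores.

The construction: latent scores Z ~ N(0, I) of shape (n, K); pain signal
Z diag(s) U' and brain signal Z diag(s) V' with orthonormal-column U (q x K)
and V (p x K) and strictly decreasing mode strengths s. Independent Gaussian
noise of scale ``noise_sd`` is added per view, each feature is affinely
standardised onto the 0-10 scale, and the per-feature raw coding (identity,
reversed, 1-4 ordinal, binary) is applied. A "null" variant redraws the latent
scores independently per view so the true cross-view association is zero while
all marginals are preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import FeatureTable, default_rules, rules_to_frame

# ---------------------------------------------------------------------------
# configuration

#: pain-location sites and their body-region codes (three-digit region axis;
#: 900 is reserved for "more than three major sites", 0 for no pain)
SITES = {
    "head": 100,
    "face": 100,
    "neck": 200,
    "shoulder": 300,
    "arm": 300,
    "chest": 400,
    "abdomen": 500,
    "back": 600,
    "hip": 800,
    "knee": 700,
}

IASP_MULTISITE = 900
IASP_NO_PAIN = 0


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the cohort generator; one master seed drives everything."""

    n_participants: int = 2000
    n_pain_features: int = 154
    n_brain_features: int = 100
    n_modes: int = 4
    mode_strengths: tuple = (1.0, 0.85, 0.7, 0.55)
    noise_sd: float = 0.5
    private_rank: int = 30
    frac_participants_heavy_missing: float = 0.02
    frac_fields_heavy_missing: float = 0.03
    frac_cell_missing: float = 0.05
    no_pain_fraction: float = 0.34
    clinical_log_odds: float = 0.5
    discrete_coding: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in (
            "frac_participants_heavy_missing",
            "frac_fields_heavy_missing",
            "frac_cell_missing",
            "no_pain_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_modes > min(self.n_pain_features, self.n_brain_features):
            raise ValueError(
                f"n_modes={self.n_modes} exceeds min(p, q)="
                f"{min(self.n_pain_features, self.n_brain_features)}"
            )
        if len(self.mode_strengths) != self.n_modes:
            raise ValueError("mode_strengths length must equal n_modes")
        s = np.asarray(self.mode_strengths, dtype=float)
        if np.any(s <= 0) or np.any(s > 1):
            raise ValueError("mode_strengths must lie in (0, 1]")
        if np.any(np.diff(s) >= 0):
            raise ValueError("mode_strengths must be strictly decreasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Planted structure kept aside for recovery testing."""

    true_U: np.ndarray  # q x K, orthonormal columns (pain side)
    true_V: np.ndarray  # p x K, orthonormal columns (brain side)
    latent_scores: np.ndarray  # n x K (the scores driving the PAIN view)
    domain_assignment: pd.Series  # feature name -> domain tag


@dataclass
class CohortBundle:
    """Everything the pipeline consumes, plus ground truth."""

    pain_table: FeatureTable
    brain_table: FeatureTable
    confound_table: FeatureTable
    medications: pd.DataFrame  # participant_id, medication_name
    diagnoses: pd.DataFrame  # participant_id, icd_version, icd_code
    phenotypes: FeatureTable
    location_fields: pd.DataFrame  # most_bothered, all_over, site indicators
    ground_truth: GroundTruth
    config: GeneratorConfig = field(default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# planted structure helpers

MODE_DOMAINS = ("pain-interference", "depression", "medical-pain", "anxiety")


def _assign_domains(q: int, rng: np.random.Generator) -> pd.Series:
    """Split q pain features into symptom domains with a small location block."""
    n_loc = min(len(SITES), max(q // 15, 0))
    remaining = q - n_loc
    per_domain = int(remaining * 0.8) // 4
    n_other = remaining - 4 * per_domain
    tags = []
    for d in MODE_DOMAINS:
        tags += [d] * per_domain
    tags += ["other"] * n_other
    tags += ["location"] * n_loc
    names = []
    counters: dict[str, int] = {}
    for t in tags:
        counters[t] = counters.get(t, 0) + 1
        names.append(f"{t.replace('-', '_')}_{counters[t]:03d}")
    return pd.Series(tags, index=names, name="domain")


def _build_true_u(domains: pd.Series, K: int, rng: np.random.Generator) -> np.ndarray:
    """Pain-side vectors: mode k loads dominantly on its own symptom domain.

    Mode 1 additionally carries a moderate positive loading on the location
    block, tying reported pain sites to the leading mode.
    """
    q = len(domains)
    U = rng.normal(size=(q, K)) * 0.05
    for k in range(K):
        dom = MODE_DOMAINS[k % len(MODE_DOMAINS)]
        block = np.flatnonzero(domains.to_numpy() == dom)
        U[block, k] = rng.uniform(0.8, 1.2, size=len(block))
    loc = np.flatnonzero(domains.to_numpy() == "location")
    if len(loc) and K >= 1:
        U[loc, 0] = rng.uniform(0.3, 0.5, size=len(loc))
    # modified Gram-Schmidt; dominant blocks are disjoint so the columns are
    # already near-orthogonal and dominance is preserved
    for k in range(K):
        for j in range(k):
            U[:, k] -= (U[:, j] @ U[:, k]) * U[:, j]
        U[:, k] /= np.linalg.norm(U[:, k])
    return U


def _build_true_v(p: int, K: int, rng: np.random.Generator) -> np.ndarray:
    V, _ = np.linalg.qr(rng.normal(size=(p, K)))
    # deterministic sign convention: largest-|entry| positive
    for k in range(K):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    return V


def _structured_noise(
    n: int, m: int, rank: int, rng: np.random.Generator
) -> np.ndarray:
    """Unit-scale noise with private low-rank structure plus isotropic floor."""
    iso = rng.normal(size=(n, m))
    rank = min(rank, m)
    if rank == 0:
        return iso
    P, _ = np.linalg.qr(rng.normal(size=(m, rank)))
    d = np.linspace(1.5, 0.3, rank) * np.sqrt(m / rank)
    G = rng.normal(size=(n, rank))
    return iso + G @ np.diag(d) @ P.T / np.sqrt(2.0)


def _standardise_to_scale(raw: np.ndarray) -> np.ndarray:
    """Affine map of each feature onto the 0-10 scale centred at 5.

    Unit-sd standardisation keeps the low-rank structure intact (the map is
    affine); values land outside [0, 10] only beyond five standard deviations
    and are clipped there.
    """
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return np.clip(5.0 + (raw - mu) / sd, 0.0, 10.0)


# ---------------------------------------------------------------------------
# clinical catalogues (toy, synthetic stand-ins for licensed tables)


def toy_atc_map() -> pd.DataFrame:
    """Small synthetic medication -> ATC level-5 code map shipped for tests.

    ``atc_codes`` holds all codes for a medication, semicolon-separated;
    combination medications are flagged and excluded downstream. Codeine is
    assigned its cough-suppressant code so it is never counted under N02A.
    """
    rows = [
        ("oxycodone", "N02AA05", 0),
        ("morphine", "N02AA01", 0),
        ("tramadol", "N02AX02", 0),
        ("escitalopram", "N06AB10", 0),
        ("sertraline", "N06AB06", 0),
        ("bupropion", "N06AX12", 0),
        ("amitriptyline", "N06AA09", 0),
        ("paracetamol", "N02BE01", 0),
        ("ibuprofen", "M01AE01", 0),
        ("naproxen", "M01AE02", 0),
        ("allopurinol", "M04AA01", 0),
        ("metformin", "A10BA02", 0),
        ("atorvastatin", "C10AA05", 0),
        ("amlodipine", "C08CA01", 0),
        ("lisinopril", "C09AA03", 0),
        ("omeprazole", "A02BC01", 0),
        ("levothyroxine", "H03AA01", 0),
        ("cetirizine", "R06AE07", 0),
        ("codeine", "R05DA04", 0),
        # multi-code medications: first alpha-numeric code wins downstream
        ("aspirin", "N02BA01;B01AC06", 0),
        ("finasteride", "G04CB01;D11AX10", 0),
        # combination product: excluded downstream
        ("budesonide/formoterol", "R03AK07", 1),
    ]
    return pd.DataFrame(rows, columns=["medication_name", "atc_codes", "is_combination"])


def toy_phecode_map() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Small synthetic ICD -> phecode map with exclusion ranges.

    Returns (map, exclusions): the map rows are (icd_version, icd_prefix,
    phecode, category); exclusion rows are (phecode, range_start, range_end)
    marking related-disease phecodes whose carriers leave the control group.
    """
    rows = [
        ("icd10", "E11", 250.2, "endocrine/metabolic"),
        ("icd9", "250.0", 250.2, "endocrine/metabolic"),
        ("icd10", "E10", 250.1, "endocrine/metabolic"),
        ("icd10", "I10", 401.1, "circulatory system"),
        ("icd9", "401", 401.1, "circulatory system"),
        ("icd10", "F32", 296.2, "mental disorders"),
        ("icd10", "F33", 296.2, "mental disorders"),
        ("icd10", "G43", 340.0, "neurological"),
        ("icd10", "M10", 274.1, "endocrine/metabolic"),
        ("icd10", "M19", 740.1, "musculoskeletal"),
        ("icd10", "K21", 530.1, "digestive"),
        ("icd10", "J45", 495.0, "respiratory"),
    ]
    excl = [
        (250.2, 249.0, 250.99),
        (250.1, 249.0, 250.99),
        (401.1, 401.0, 405.99),
        (296.2, 295.0, 299.99),
    ]
    return (
        pd.DataFrame(rows, columns=["icd_version", "icd_code", "phecode", "category"]),
        pd.DataFrame(excl, columns=["phecode", "range_start", "range_end"]),
    )


def iasp_site_map() -> pd.DataFrame:
    """Pain-site name -> body-region code mapping table."""
    return pd.DataFrame(
        [(site, code) for site, code in SITES.items()],
        columns=["site", "iasp_code"],
    )


# medication event model: (medication, base prevalence, {mode index: log-odds weight})
_MED_EFFECTS = [
    ("oxycodone", 0.06, {0: 1.0}),
    ("morphine", 0.04, {0: 1.0}),
    ("tramadol", 0.06, {0: 1.0}),
    ("escitalopram", 0.07, {1: 1.0, 3: 0.6}),
    ("sertraline", 0.06, {1: 1.0, 3: 0.6}),
    ("bupropion", 0.04, {1: 0.8, 2: 0.5}),
    ("amitriptyline", 0.05, {1: 0.6, 2: 0.6, 3: 0.6}),
    ("paracetamol", 0.15, {2: 0.8}),
    ("ibuprofen", 0.12, {2: 0.6}),
    ("naproxen", 0.06, {2: 0.6}),
    ("allopurinol", 0.05, {2: 0.8}),
    ("metformin", 0.07, {0: 0.6, 2: 0.4}),
    ("atorvastatin", 0.10, {0: 0.6}),
    ("amlodipine", 0.08, {0: 0.6}),
    ("lisinopril", 0.08, {0: 0.6}),
    ("omeprazole", 0.10, {0: 0.4}),
    ("levothyroxine", 0.06, {}),
    ("cetirizine", 0.08, {}),
    ("codeine", 0.05, {0: 0.5}),
    ("aspirin", 0.09, {0: 0.4}),
    ("finasteride", 0.03, {}),
    ("budesonide/formoterol", 0.04, {}),
]

# diagnosis event model: (icd_version, icd_code, base prevalence, {mode: weight})
_DX_EFFECTS = [
    ("icd10", "E11.9", 0.06, {2: 1.0, 0: 0.4}),
    ("icd10", "E10.9", 0.02, {}),
    ("icd10", "I10", 0.12, {0: 0.8}),
    ("icd10", "F32.1", 0.05, {1: 1.0}),
    ("icd10", "G43.0", 0.04, {0: 0.6}),
    ("icd10", "M10.9", 0.04, {2: 0.8}),
    ("icd10", "M19.9", 0.08, {0: 0.6, 2: 0.6}),
    ("icd10", "K21.9", 0.07, {0: 0.4}),
    ("icd10", "J45.9", 0.06, {}),
    ("icd9", "250.00", 0.02, {2: 1.0}),
    ("icd9", "401.1", 0.03, {0: 0.8}),
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


# ---------------------------------------------------------------------------
# generation


def generate_cohort(config: GeneratorConfig) -> CohortBundle:
    """Generate a cohort with a planted rank-K pain-brain cross-covariance."""
    return _generate(config, null=False)


def generate_null_cohort(config: GeneratorConfig) -> CohortBundle:
    """Identical marginals, but latent scores redrawn independently per view.

    The brain view gets its own latent draw, so the true cross-view
    association is exactly zero; clinical tables and locations remain driven
    by the pain-side latent scores.
    """
    return _generate(config, null=True)


def _generate(config: GeneratorConfig, null: bool) -> CohortBundle:
    n, q, p, K = (
        config.n_participants,
        config.n_pain_features,
        config.n_brain_features,
        config.n_modes,
    )
    ss = np.random.SeedSequence(config.seed)
    (
        r_struct,
        r_latent,
        r_noise,
        r_coding,
        r_missing,
        r_clinical,
        r_location,
        r_confound,
    ) = [np.random.default_rng(s) for s in ss.spawn(8)]

    ids = pd.Index([f"P{i:06d}" for i in range(n)], name="participant_id")
    strengths = np.asarray(config.mode_strengths, dtype=float)

    domains = _assign_domains(q, r_struct)
    U = _build_true_u(domains, K, r_struct)
    V = _build_true_v(p, K, r_struct)

    Z = r_latent.normal(size=(n, K))
    Z_brain = r_latent.normal(size=(n, K)) if null else Z

    pain_raw = Z @ np.diag(strengths) @ U.T
    brain_raw = Z_brain @ np.diag(strengths) @ V.T
    if config.noise_sd > 0:
        # each view's "noise" mixes private (non-shared) low-rank structure
        # with an isotropic floor, emulating the strong within-view
        # autocorrelation of real cohort data; both scale with noise_sd so
        # the noiseless construction stays exactly rank K across views
        pain_raw = pain_raw + config.noise_sd * _structured_noise(
            n, q, config.private_rank, r_noise
        )
        brain_raw = brain_raw + config.noise_sd * _structured_noise(
            n, p, config.private_rank, r_noise
        )

    # confounds: head-size and motion proxies leaking into brain volumes;
    # the leak scales with noise_sd so the noiseless construction stays rank-K
    confounds = pd.DataFrame(
        {
            "head_size": r_confound.normal(size=n),
            "motion": r_confound.normal(size=n),
        },
        index=ids,
    )
    leak = 0.3 * config.noise_sd * r_confound.normal(size=(2, p))
    brain = brain_raw + confounds.to_numpy() @ leak

    # --- pain coding -------------------------------------------------------
    pain10 = _standardise_to_scale(pain_raw)
    rules = default_rules()
    feature_names = list(domains.index)
    is_location = (domains == "location").to_numpy()

    if config.discrete_coding:
        rule_pool = np.array(["identity", "reverse", "ordinal4", "binary"])
        rule_ids = r_coding.choice(rule_pool, size=q, p=[0.55, 0.2, 0.15, 0.1])
        rule_ids[is_location] = "binary"
    else:
        rule_ids = r_coding.choice(np.array(["identity", "reverse"]), size=q, p=[0.75, 0.25])

    # location sites: Bernoulli with log-odds mildly increasing in the leading
    # latent score; base prevalences are calibrated so the marginal no-site
    # fraction is close to no_pain_fraction (for ~10 sites at prevalence
    # ~0.10 each, prod(1 - p) is ~0.34). Which site hurts is idiosyncratic.
    n_loc = int(is_location.sum())
    site_base = r_location.uniform(0.09, 0.17, size=n_loc)
    site_draws = r_location.random((n, n_loc))

    raw = np.empty_like(pain10)
    ordinal_targets = np.array([0.0, 10.0 / 3.0, 20.0 / 3.0, 10.0])
    loc_counter = 0
    for j in range(q):
        col = pain10[:, j]
        rid = rule_ids[j]
        if is_location[j]:
            eta = _logit(site_base[loc_counter]) + 0.4 * Z[:, 0]
            present = site_draws[:, loc_counter] < _sigmoid(eta)
            raw[:, j] = present.astype(float)
            loc_counter += 1
        elif rid == "identity":
            raw[:, j] = col
        elif rid == "reverse":
            raw[:, j] = 10.0 - col
        elif rid == "ordinal4":
            snapped = np.argmin(np.abs(col[:, None] - ordinal_targets[None, :]), axis=1)
            raw[:, j] = snapped + 1.0
        else:  # binary
            raw[:, j] = (col >= 5.0).astype(float)

    # --- structured missingness (pain table only) --------------------------
    miss = np.zeros((n, q), dtype=bool)
    n_heavy_p = int(round(config.frac_participants_heavy_missing * n))
    n_heavy_f = int(round(config.frac_fields_heavy_missing * q))
    heavy_rows = r_missing.choice(n, size=n_heavy_p, replace=False) if n_heavy_p else []
    heavy_cols = r_missing.choice(q, size=n_heavy_f, replace=False) if n_heavy_f else []
    for i in heavy_rows:
        k_miss = int(np.ceil(0.95 * q))
        cols = r_missing.choice(q, size=k_miss, replace=False)
        miss[i, cols] = True
    for j in heavy_cols:
        k_miss = int(np.ceil(0.80 * n))
        rows = r_missing.choice(n, size=k_miss, replace=False)
        miss[rows, j] = True
    if config.frac_cell_missing > 0:
        miss |= r_missing.random((n, q)) < config.frac_cell_missing
    raw = raw.copy()
    raw[miss] = np.nan

    pain_meta = pd.DataFrame(
        {
            "domain": domains.to_numpy(),
            "is_location": is_location,
            "rule_id": rule_ids,
            "heavy_missing": [j in set(np.atleast_1d(heavy_cols).tolist()) for j in range(q)],
        },
        index=pd.Index(feature_names, name="feature"),
    )
    pain_table = FeatureTable(pd.DataFrame(raw, index=ids, columns=feature_names), pain_meta)
    # record which participants were planted heavy-missing for count tests
    pain_table.meta.attrs["heavy_missing_participants"] = [ids[i] for i in np.sort(np.atleast_1d(heavy_rows)).tolist()]

    brain_names = [f"region_{j:03d}" for j in range(p)]
    brain_table = FeatureTable(
        pd.DataFrame(brain, index=ids, columns=brain_names),
        pd.DataFrame(
            {"domain": "brain", "is_location": False, "rule_id": "identity"},
            index=pd.Index(brain_names, name="feature"),
        ),
    )
    confound_table = FeatureTable(confounds)

    # --- clinical tables ----------------------------------------------------
    beta = config.clinical_log_odds
    med_rows = []
    for name, prev, effects in _MED_EFFECTS:
        eta = np.full(n, _logit(prev))
        for mode, w in effects.items():
            if mode < K:
                eta = eta + beta * w * Z[:, mode]
        taking = r_clinical.random(n) < _sigmoid(eta)
        for i in np.flatnonzero(taking):
            med_rows.append((ids[i], name))
    medications = pd.DataFrame(med_rows, columns=["participant_id", "medication_name"])

    dx_rows = []
    for ver, code, prev, effects in _DX_EFFECTS:
        eta = np.full(n, _logit(prev))
        for mode, w in effects.items():
            if mode < K:
                eta = eta + beta * w * Z[:, mode]
        has = r_clinical.random(n) < _sigmoid(eta)
        for i in np.flatnonzero(has):
            dx_rows.append((ids[i], ver, code))
    diagnoses = pd.DataFrame(dx_rows, columns=["participant_id", "icd_version", "icd_code"])

    phenotypes = _generate_phenotypes(ids, Z, K, r_clinical)

    location_fields = _generate_location_fields(ids, pain_table, domains, r_location)

    ground_truth = GroundTruth(
        true_U=U, true_V=V, latent_scores=Z, domain_assignment=domains
    )
    return CohortBundle(
        pain_table=pain_table,
        brain_table=brain_table,
        confound_table=confound_table,
        medications=medications,
        diagnoses=diagnoses,
        phenotypes=phenotypes,
        location_fields=location_fields,
        ground_truth=ground_truth,
        config=config,
    )


def _generate_phenotypes(
    ids: pd.Index, Z: np.ndarray, K: int, rng: np.random.Generator
) -> FeatureTable:
    """Curated-phenotype stand-in: planted, null, duplicated, categorical and
    instrument (BPI / PHQ-9 total) columns."""
    n = len(ids)
    cols: dict[str, np.ndarray] = {}
    meta_rows = []

    for k in range(min(K, 4)):
        cols[f"pheno_mode{k + 1}"] = 0.5 * Z[:, k] + rng.normal(size=n)
        meta_rows.append((f"pheno_mode{k + 1}", "lifestyle", "numerical"))
    for j in range(6):
        cols[f"blood_assay_{j + 1}"] = rng.normal(size=n)
        meta_rows.append((f"blood_assay_{j + 1}", "blood assays", "numerical"))
    base = 30 + 5 * rng.normal(size=n)
    cols["leg_fat_right"] = base
    cols["leg_fat_left"] = base + 0.05 * rng.normal(size=n)
    meta_rows.append(("leg_fat_right", "physical measures", "numerical"))
    meta_rows.append(("leg_fat_left", "physical measures", "numerical"))
    emp = 1.0 + (Z[:, 0] > 0.5) + (rng.random(n) < 0.2)
    cols["employment_status"] = emp
    meta_rows.append(("employment_status", "sociodemographics", "categorical_unordered"))
    for j in range(2):
        cols[f"mh_item_{j + 1}"] = rng.normal(size=n)
        meta_rows.append((f"mh_item_{j + 1}", "mental health", "numerical"))

    bpi = np.clip(np.round(4 + 2 * Z[:, 0] + rng.normal(scale=1.5, size=n)), 0, 10)
    phq = np.clip(
        np.round(8 + 5 * Z[:, min(1, K - 1)] + rng.normal(scale=3.0, size=n)), 0, 27
    )
    cols["bpi_total"] = bpi
    cols["phq9_total"] = phq
    meta_rows.append(("bpi_total", "instrument", "numerical"))
    meta_rows.append(("phq9_total", "instrument", "numerical"))

    data = pd.DataFrame(cols, index=ids)
    # sparse missingness so association batteries exercise pairwise handling
    mask = rng.random(data.shape) < 0.02
    data = data.mask(mask)
    meta = pd.DataFrame(
        meta_rows, columns=["feature", "category", "datatype"]
    ).set_index("feature")
    meta["domain"] = "phenotype"
    meta["is_location"] = False
    meta["rule_id"] = "identity"
    return FeatureTable(data, meta)


def _generate_location_fields(
    ids: pd.Index,
    pain_table: FeatureTable,
    domains: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Body-location questionnaire: site indicators consistent with the pain
    table's location features, an all-over-body flag, and an 'area most
    bothered' answer present for a subset of participants."""
    loc_features = [f for f, d in domains.items() if d == "location"]
    site_names = list(SITES.keys())[: len(loc_features)]
    out = pd.DataFrame(index=ids)
    site_values = {}
    for feat, site in zip(loc_features, site_names):
        v = pain_table.data[feat].fillna(0.0).to_numpy()
        site_values[site] = (v > 0).astype(int)
        out[f"site_{site}"] = site_values[site]
    n_sites = out.filter(like="site_").sum(axis=1).to_numpy()
    all_over = (n_sites >= 6) & (rng.random(len(ids)) < 0.7)
    out["all_over"] = all_over.astype(int)
    most = np.full(len(ids), "", dtype=object)
    ask = (rng.random(len(ids)) < 0.4) & (n_sites > 0)
    for i in np.flatnonzero(ask):
        present = [s for s in site_names if site_values[s][i]]
        most[i] = rng.choice(present)
    out["most_bothered"] = most
    return out


# ---------------------------------------------------------------------------
# bundle I/O: a directory of tab-separated text files plus a manifest


def write_bundle(bundle: CohortBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.pain_table.to_tsv(out / "pain.tsv", out / "pain_meta.tsv")
    bundle.brain_table.to_tsv(out / "brain.tsv", out / "brain_meta.tsv")
    bundle.confound_table.to_tsv(out / "confounds.tsv")
    bundle.phenotypes.to_tsv(out / "phenotypes.tsv", out / "phenotypes_meta.tsv")
    bundle.medications.to_csv(out / "medications.tsv", sep="\t", index=False)
    bundle.diagnoses.to_csv(out / "diagnoses.tsv", sep="\t", index=False)
    bundle.location_fields.to_csv(out / "locations.tsv", sep="\t", index_label="participant_id")

    gt = bundle.ground_truth
    pd.DataFrame(gt.true_U, index=bundle.pain_table.features).to_csv(
        out / "true_U.tsv", sep="\t", index_label="feature"
    )
    pd.DataFrame(gt.true_V, index=bundle.brain_table.features).to_csv(
        out / "true_V.tsv", sep="\t", index_label="feature"
    )
    pd.DataFrame(gt.latent_scores, index=bundle.pain_table.participant_ids).to_csv(
        out / "latent_scores.tsv", sep="\t", index_label="participant_id"
    )
    rules_to_frame(default_rules()).to_csv(out / "recoding_rules.tsv", sep="\t", index=False)
    toy_atc_map().to_csv(out / "atc_map.tsv", sep="\t", index=False)
    pmap, pexcl = toy_phecode_map()
    pmap.to_csv(out / "phecode_map.tsv", sep="\t", index=False)
    pexcl.to_csv(out / "phecode_exclusions.tsv", sep="\t", index=False)
    iasp_site_map().to_csv(out / "iasp_map.tsv", sep="\t", index=False)

    manifest = {
        "pain.tsv": "pain feature table (raw codings)",
        "pain_meta.tsv": "pain feature metadata",
        "brain.tsv": "regional brain volumes",
        "brain_meta.tsv": "brain feature metadata",
        "confounds.tsv": "head-size and motion confounds",
        "phenotypes.tsv": "curated-phenotype stand-in table",
        "phenotypes_meta.tsv": "phenotype metadata (category, datatype)",
        "medications.tsv": "long medication table",
        "diagnoses.tsv": "long ICD diagnosis table",
        "locations.tsv": "pain-location questionnaire fields",
        "true_U.tsv": "ground truth pain-side canonical vectors",
        "true_V.tsv": "ground truth brain-side canonical vectors",
        "latent_scores.tsv": "ground truth latent mode scores",
        "recoding_rules.tsv": "raw-coding to 0-10 recoding rules",
        "atc_map.tsv": "toy medication -> ATC map (synthetic)",
        "phecode_map.tsv": "toy ICD -> phecode map (synthetic)",
        "phecode_exclusions.tsv": "phecode control-exclusion ranges (synthetic)",
        "iasp_map.tsv": "pain site -> body-region code map",
        "config": asdict(bundle.config) if bundle.config else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
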