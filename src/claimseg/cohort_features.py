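"""Analytic cohort construction and feature assembly.

Turns raw claim lines and a demographics table into one row per
patient-year (demographics, condition-category flags, utilization counts,
annual spend), applies the cost-threshold eligibility rule, and encodes
the clustering inputs as a purely numeric matrix.

Categorical variables enter the Euclidean feature space through a
polar-coordinate transform: each level of an L-level variable is mapped
to an equally spaced point on the unit circle, contributing a (cos, sin)
column pair.  Binary variables use orthogonal unit vectors (a quarter
turn apart), so a disagreement contributes squared distance 2.
Continuous variables are z-scored.  Utilization and spend never enter
the feature matrix: they are held out so that between-cluster comparisons
of utilization are not circular.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Closed vocabularies for the Medicaid patient-year record.
ELIGIBILITY_LEVELS = ["TANF", "SSI", "Expansion", "Medicare-eligible"]
RACE_LEVELS = ["White", "Black", "Hispanic", "Asian", "Other", "Missing"]
SETTINGS = ["IP", "ED", "OP"]

UTILIZATION_COLUMNS = [
    "admissions",
    "hospital_days",
    "ed_visits",
    "preventable_admissions",
    "preventable_ed_visits",
]

#: columns that must never appear in the clustering feature matrix
EXCLUDED_FEATURE_COLUMNS = UTILIZATION_COLUMNS + ["annual_spend"]

CONDITION_PREFIX = "cond_"


class ValidationError(ValueError):
    """Raised when an input table or config violates its contract."""


def condition_column(name: str) -> str:
    """Column name for a condition-category flag in the patient-year table."""
    slug = name.strip().lower().replace("/", "_").replace(" ", "_")
    return CONDITION_PREFIX + slug


# ---------------------------------------------------------------------------
# Crosswalk
# ---------------------------------------------------------------------------


@dataclass
class ConditionCrosswalk:
    """ICD-9-CM prefix -> condition-category mapping.

    Mirrors the shape of a multi-level diagnosis grouper (e.g. the AHRQ
    CCS distribution): each row maps a code prefix to a category id at a
    given level.  Trailing-wildcard semantics: a code matches an entry
    when it starts with the entry's prefix; the longest matching prefix
    wins.
    """

    table: pd.DataFrame  # columns: code_prefix, category_id, category_name, level

    REQUIRED = ("code_prefix", "category_id", "category_name", "level")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"crosswalk missing columns: {missing}")
        t = self.table
        dup = t.duplicated(subset=["code_prefix", "level"])
        if dup.any():
            bad = t.loc[dup, "code_prefix"].tolist()
            raise ValidationError(
                f"crosswalk: code prefixes mapped to two categories at the same level: {bad}"
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConditionCrosswalk":
        return cls(pd.read_csv(path, dtype={"code_prefix": str, "category_id": str}))

    def categories(self, level: int = 2) -> list[str]:
        """Category names at *level*, in first-appearance order."""
        sub = self.table[self.table["level"] == level]
        return list(dict.fromkeys(sub["category_name"]))

    def lookup(self, code: str, level: int = 2) -> str | None:
        """Category name for *code* at *level*; None when unmapped."""
        sub = self.table[self.table["level"] == level]
        best = None
        best_len = -1
        for prefix, name in zip(sub["code_prefix"], sub["category_name"]):
            if code.startswith(prefix) and len(prefix) > best_len:
                best, best_len = name, len(prefix)
        return best


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------


def read_claims(path: str | Path) -> pd.DataFrame:
    """Read a claim-line table (patient_id, service_date, setting, icd9, paid_amount)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "icd9": str})
    required = {"patient_id", "service_date", "setting", "icd9", "paid_amount"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"claims table missing columns: {sorted(missing)}")
    bad = set(df["setting"]) - set(SETTINGS)
    if bad:
        raise ValidationError(f"claims table: unknown settings {sorted(bad)}")
    if (df["paid_amount"] < 0).any():
        raise ValidationError("claims table: negative paid_amount")
    return df


def read_demographics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "age", "female", "eligibility", "race_ethnicity"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"demographics table missing columns: {sorted(missing)}")
    return df


def read_preventable_flags(path: str | Path) -> pd.DataFrame:
    """Read the pluggable preventable-utilization flag table (code, setting)."""
    df = pd.read_csv(path, dtype={"code": str})
    if not {"code", "setting"} <= set(df.columns):
        raise ValidationError("preventable flag table needs columns: code, setting")
    bad = set(df["setting"]) - {"IP", "ED", "any"}
    if bad:
        raise ValidationError(f"preventable flag table: unknown settings {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# Claims -> patient-year aggregation
# ---------------------------------------------------------------------------


def group_conditions(
    claims: pd.DataFrame,
    crosswalk: ConditionCrosswalk,
    level: int = 2,
    patient_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, Counter]:
    """Binary condition-category flags per patient.

    A patient's flag for category c is 1 iff at least one claim carries a
    code mapping to c at the chosen crosswalk level.  Unmapped codes are
    tallied and logged, never fatal.

    Returns (flags DataFrame indexed by patient_id, Counter of unmapped codes).
    """
    cats = crosswalk.categories(level)
    if patient_ids is None:
        patient_ids = list(dict.fromkeys(claims["patient_id"]))
    unmapped: Counter = Counter()
    code_to_cat: dict[str, str | None] = {}
    for code in claims["icd9"].unique() if len(claims) else []:
        code_to_cat[code] = crosswalk.lookup(code, level)
    flags = pd.DataFrame(0, index=pd.Index(patient_ids, name="patient_id"),
                         columns=[condition_column(c) for c in cats], dtype=int)
    for pid, code in zip(claims["patient_id"], claims["icd9"]):
        cat = code_to_cat.get(code)
        if cat is None:
            unmapped[code] += 1
        elif pid in flags.index:
            flags.loc[pid, condition_column(cat)] = 1
    if unmapped:
        logger.warning(
            "group_conditions: %d claim lines with unmapped codes (%d distinct)",
            sum(unmapped.values()), len(unmapped),
        )
    return flags, unmapped


def count_utilization(claims: pd.DataFrame, patient_ids: list[str]) -> pd.DataFrame:
    """Admissions, hospital days, ED visits and spend per patient.

    Encounter conventions for the delimited claim-line format:
    an inpatient admission is a distinct (patient, service_date) pair among
    IP lines, each IP line is one hospital day, and each ED line is one visit.
    """
    idx = pd.Index(patient_ids, name="patient_id")
    out = pd.DataFrame(
        {"admissions": 0, "hospital_days": 0, "ed_visits": 0, "annual_spend": 0.0},
        index=idx,
    )
    if len(claims):
        ip = claims[claims["setting"] == "IP"]
        adm = ip.groupby("patient_id")["service_date"].nunique()
        days = ip.groupby("patient_id").size()
        ed = claims[claims["setting"] == "ED"].groupby("patient_id").size()
        spend = claims.groupby("patient_id")["paid_amount"].sum()
        for col, series in [("admissions", adm), ("hospital_days", days),
                            ("ed_visits", ed), ("annual_spend", spend)]:
            out[col] = series.reindex(idx).fillna(0).to_numpy()
    out[["admissions", "hospital_days", "ed_visits"]] = (
        out[["admissions", "hospital_days", "ed_visits"]].astype(int)
    )
    out["annual_spend"] = out["annual_spend"].round(2)
    return out


def flag_preventable(
    claims: pd.DataFrame,
    flag_table: pd.DataFrame,
    patient_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Possibly-preventable admission and ED-visit counts per patient.

    The flag table is a pluggable stand-in for licensed preventable-
    utilization classifications (inpatient prevention quality indicators,
    ED-visit avoidability algorithms): a plain list of ICD codes with the
    setting each applies to.  An inpatient encounter (distinct IP service
    date) is preventable when any of its lines carries an IP-flagged code;
    each ED line with an ED-flagged code is one preventable visit.
    """
    if patient_ids is None:
        patient_ids = list(dict.fromkeys(claims["patient_id"]))
    idx = pd.Index(patient_ids, name="patient_id")
    out = pd.DataFrame({"preventable_admissions": 0, "preventable_ed_visits": 0}, index=idx)
    if not len(claims):
        return out
    ip_codes = set(flag_table.loc[flag_table["setting"].isin(["IP", "any"]), "code"])
    ed_codes = set(flag_table.loc[flag_table["setting"].isin(["ED", "any"]), "code"])
    ip = claims[claims["setting"] == "IP"]
    if len(ip):
        flagged = ip[ip["icd9"].isin(ip_codes)]
        prev_adm = flagged.groupby("patient_id")["service_date"].nunique()
        out["preventable_admissions"] = prev_adm.reindex(idx).fillna(0).astype(int).to_numpy()
    ed = claims[claims["setting"] == "ED"]
    if len(ed):
        prev_ed = ed[ed["icd9"].isin(ed_codes)].groupby("patient_id").size()
        out["preventable_ed_visits"] = prev_ed.reindex(idx).fillna(0).astype(int).to_numpy()
    return out


def build_patient_years(
    demographics: pd.DataFrame,
    claims: pd.DataFrame,
    crosswalk: ConditionCrosswalk,
    preventable_flags: pd.DataFrame | None = None,
    level: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the patient-year table from raw inputs.

    Every patient in the demographics table appears in the output, with
    all-zero condition flags and utilization when they have no claims.
    Returns (patient_year DataFrame, warnings dict).
    """
    pids = list(demographics["patient_id"])
    if len(set(pids)) != len(pids):
        raise ValidationError("demographics: duplicate patient_id")
    flags, unmapped = group_conditions(claims, crosswalk, level, patient_ids=pids)
    util = count_utilization(claims, pids)
    if preventable_flags is not None:
        prev = flag_preventable(claims, preventable_flags, patient_ids=pids)
    else:
        prev = pd.DataFrame(
            {"preventable_admissions": 0, "preventable_ed_visits": 0},
            index=pd.Index(pids, name="patient_id"),
        )
    py = demographics.set_index("patient_id").join([flags, util, prev])
    py = py.reset_index()
    # order: demographics, conditions, utilization, spend
    cond_cols = [c for c in flags.columns]
    ordered = (["patient_id", "age", "female", "eligibility", "race_ethnicity"]
               + cond_cols + UTILIZATION_COLUMNS + ["annual_spend"])
    py = py[[c for c in ordered if c in py.columns]]
    bad_prev = (py["preventable_admissions"] > py["admissions"]) | (
        py["preventable_ed_visits"] > py["ed_visits"])
    if bad_prev.any():
        raise ValidationError(
            "preventable counts exceed parent counts for patients: "
            f"{py.loc[bad_prev, 'patient_id'].tolist()[:5]}"
        )
    warnings = {"unmapped_codes": dict(unmapped)}
    return py, warnings


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------


def select_eligible(
    patient_years: pd.DataFrame,
    quantile: float = 0.05,
    min_age: int = 21,
) -> pd.DataFrame:
    """Cost-threshold cohort selection: adults in the top spending tail.

    Keeps patients aged ``min_age`` and above whose annual spend falls in
    the top ``quantile`` of the age-filtered cohort.  The threshold is the
    ``ceil(quantile * n)``-th largest spend; all patients tied at the
    threshold value are included (deterministic, conservative tie rule).
    """
    if not 0 < quantile < 1:
        raise ValidationError(f"quantile must be in (0,1), got {quantile}")
    if len(patient_years) == 0:
        raise ValidationError("select_eligible: empty patient-year table")
    adults = patient_years[patient_years["age"] >= min_age]
    if len(adults) == 0:
        raise ValidationError(f"select_eligible: no patients aged {min_age}+")
    spend = adults["annual_spend"].to_numpy(dtype=float)
    if np.ptp(spend) == 0:
        raise ValidationError(
            "select_eligible: all spends equal — the top-quantile rule is "
            "degenerate; supply an explicit tie policy or pre-filtered cohort"
        )
    m = math.ceil(quantile * len(adults))
    threshold = np.sort(spend)[::-1][m - 1]
    return adults[adults["annual_spend"] >= threshold].copy()


# ---------------------------------------------------------------------------
# Polar encoding
# ---------------------------------------------------------------------------


@dataclass
class EncodingScheme:
    """Which patient-year columns enter clustering, and how.

    ``categorical`` maps a variable to its ordered level list (the order
    fixes the polar angle of each level).  ``binary`` variables are 0/1
    flags.  ``continuous`` variables are z-scored.  Utilization and spend
    columns are rejected outright.
    """

    categorical: dict[str, list[str]] = field(default_factory=dict)
    binary: list[str] = field(default_factory=list)
    continuous: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        banned = set(EXCLUDED_FEATURE_COLUMNS)
        used = set(self.categorical) | set(self.binary) | set(self.continuous)
        bad = used & banned
        if bad:
            raise ValidationError(
                f"utilization/spend variables may not be clustering features: {sorted(bad)}"
            )
        for var, levels in self.categorical.items():
            if len(levels) != len(set(levels)):
                raise ValidationError(f"duplicate levels for {var}")

    @classmethod
    def default(cls, condition_names: list[str]) -> "EncodingScheme":
        return cls(
            categorical={"eligibility": list(ELIGIBILITY_LEVELS),
                         "race_ethnicity": list(RACE_LEVELS)},
            binary=["female"] + [condition_column(c) for c in condition_names],
            continuous=["age"],
        )


@dataclass
class FeatureMatrix:
    """Numeric clustering inputs with per-column provenance.

    ``column_meta`` records, for every column, the source variable and its
    encoding role (polar-cos / polar-sin / scaled-continuous), so the
    no-utilization contract can be audited after the fact.
    """

    values: np.ndarray
    column_meta: list[dict]
    row_ids: list[str]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [m["name"] for m in self.column_meta]

    def to_files(self, features_csv: str | Path, meta_json: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "patient_id", self.row_ids)
        df.to_csv(features_csv, index=False, float_format="%.10g")
        Path(meta_json).write_text(json.dumps(self.column_meta, indent=1))

    @classmethod
    def from_files(cls, features_csv: str | Path, meta_json: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(features_csv, dtype={"patient_id": str})
        meta = json.loads(Path(meta_json).read_text())
        row_ids = df["patient_id"].tolist()
        values = df[[m["name"] for m in meta]].to_numpy(dtype=float)
        return cls(values=values, column_meta=meta, row_ids=row_ids)


def polar_angle(level_index: int, n_levels: int) -> float:
    """Angle for 1-based level ``level_index`` of an ``n_levels``-level variable."""
    return 2.0 * math.pi * (level_index - 1) / n_levels


def polar_encode(patient_years: pd.DataFrame, scheme: EncodingScheme) -> FeatureMatrix:
    """Encode the patient-year table as the numeric clustering matrix.

    Categorical levels sit at equally spaced angles on the unit circle
    (level 1 at angle 0).  Binary flags use the quarter-circle convention
    0 -> (1, 0), 1 -> (0, 1).  Continuous variables are z-scored against
    this cohort.  Raises on a categorical value absent from the scheme's
    level list, naming the variable and level.
    """
    n = len(patient_years)
    cols: list[np.ndarray] = []
    meta: list[dict] = []

    for var, levels in scheme.categorical.items():
        vals = patient_years[var].astype(str).to_numpy()
        lut = {lev: i + 1 for i, lev in enumerate(levels)}
        unseen = sorted(set(vals) - set(levels))
        if unseen:
            raise ValidationError(
                f"polar_encode: variable {var!r} has level(s) {unseen} "
                "not present in the encoding scheme"
            )
        idx = np.array([lut[v] for v in vals])
        theta = 2.0 * np.pi * (idx - 1) / len(levels)
        cols.append(np.cos(theta))
        meta.append({"name": f"{var}__cos", "source": var, "role": "polar-cos",
                     "levels": levels})
        cols.append(np.sin(theta))
        meta.append({"name": f"{var}__sin", "source": var, "role": "polar-sin",
                     "levels": levels})

    for var in scheme.binary:
        vals = patient_years[var].to_numpy()
        bad = set(np.unique(vals)) - {0, 1}
        if bad:
            raise ValidationError(f"polar_encode: binary variable {var!r} has values {bad}")
        # quarter-circle: 0 -> (1,0), 1 -> (0,1)
        cols.append(1.0 - vals.astype(float))
        meta.append({"name": f"{var}__cos", "source": var, "role": "polar-cos",
                     "levels": [0, 1]})
        cols.append(vals.astype(float))
        meta.append({"name": f"{var}__sin", "source": var, "role": "polar-sin",
                     "levels": [0, 1]})

    for var in scheme.continuous:
        vals = patient_years[var].to_numpy(dtype=float)
        sd = vals.std()
        if sd == 0:
            logger.warning("polar_encode: continuous variable %r is constant; "
                           "emitting zeros", var)
            z = np.zeros(n)
        else:
            z = (vals - vals.mean()) / sd
        cols.append(z)
        meta.append({"name": f"{var}__z", "source": var, "role": "scaled-continuous"})

    values = np.column_stack(cols) if cols else np.empty((n, 0))
    return FeatureMatrix(values=values, column_meta=meta,
                         row_ids=patient_years["patient_id"].tolist())
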