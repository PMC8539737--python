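"""Synthetic Medicaid patient-year cohorts with planted cluster structure.

Generates cohorts that mimic the structure of a high-cost high-need
claims population: each patient belongs to a planted cluster that drives
their condition-category flags (independent Bernoulli draws given the
cluster), demographics (age, gender, eligibility program, race/ethnicity),
overdispersed utilization counts, and a heavy-tailed annual spend tied to
utilization.  Preventable counts are a binomial thinning of their parent
counts, so the per-record invariant preventable <= parent holds exactly.

A ``separation`` knob scales each cluster's deviation from the population
prevalence on the logit scale: 0 collapses every cluster onto the
population mean, 1 reproduces the specified prevalences, >1 pushes the
clusters further apart while keeping probabilities inside (0, 1).

The generator can also materialise a long-format claim-line table that is
exactly consistent with the patient-year aggregates, for exercising the
ingestion path end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort_features import (
    ELIGIBILITY_LEVELS,
    RACE_LEVELS,
    ValidationError,
    condition_column,
)

logger = logging.getLogger(__name__)

_CLAIMS_YEAR = 2014  # observation year for synthetic claim dates (ICD-9 era)

# fallback codes for encounters of patients with no coded conditions;
# deliberately absent from the bundled crosswalk
GENERIC_CODE = "780.9"
GENERIC_PREVENTABLE_CODE = "799.1"


@dataclass
class ClusterDemographics:
    """Demographic distribution for one planted cluster."""

    age_mean: float
    age_sd: float
    p_female: float
    eligibility: dict[str, float]  # over ELIGIBILITY_LEVELS
    race_ethnicity: dict[str, float]  # over RACE_LEVELS incl. "Missing"


@dataclass
class ClusterUtilization:
    """Cluster-conditional count-model parameters (annual means)."""

    admissions_mean: float
    hospital_days_mean: float
    ed_visits_mean: float
    preventable_admissions_mean: float
    preventable_ed_visits_mean: float
    admissions_dispersion: float = 0.15  # negative-binomial size parameter
    ed_dispersion: float = 0.3
    count_model: str = "negbin"  # or "poisson"


@dataclass
class CostSpec:
    """Annual spend = lognormal noise around a linear index of utilization."""

    base: float = 2000.0
    per_admission: float = 9000.0
    per_hospital_day: float = 1800.0
    per_ed_visit: float = 600.0
    sigma: float = 0.6  # lognormal log-scale SD


@dataclass
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    n_patients: int
    condition_names: list[str]
    mixing_weights: list[float]
    condition_prevalence: list[list[float]]  # [cluster][condition]
    demographics: list[ClusterDemographics]
    utilization: list[ClusterUtilization]
    cost: CostSpec = field(default_factory=CostSpec)
    separation: float = 1.0
    seed: int = 0

    @property
    def n_clusters_true(self) -> int:
        return len(self.mixing_weights)

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValidationError(f"n_patients must be >= 0, got {self.n_patients}")
        k = self.n_clusters_true
        if k < 1:
            raise ValidationError("mixing_weights: need at least one cluster")
        w = np.asarray(self.mixing_weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
            raise ValidationError(
                f"mixing_weights must be nonnegative and sum to 1, got sum={w.sum()!r}"
            )
        prev = np.asarray(self.condition_prevalence, dtype=float)
        if prev.shape != (k, len(self.condition_names)):
            raise ValidationError(
                "condition_prevalence: expected shape "
                f"({k}, {len(self.condition_names)}), got {prev.shape}"
            )
        if ((prev < 0) | (prev > 1)).any():
            raise ValidationError("condition_prevalence: values outside [0,1]")
        if len(self.demographics) != k or len(self.utilization) != k:
            raise ValidationError("demographics/utilization: need one entry per cluster")
        for c, d in enumerate(self.demographics):
            if not 0 <= d.p_female <= 1:
                raise ValidationError(f"demographics[{c}].p_female outside [0,1]")
            for name, dist, levels in [
                ("eligibility", d.eligibility, ELIGIBILITY_LEVELS),
                ("race_ethnicity", d.race_ethnicity, RACE_LEVELS),
            ]:
                if set(dist) - set(levels):
                    raise ValidationError(
                        f"demographics[{c}].{name}: unknown levels {set(dist) - set(levels)}"
                    )
                p = np.array([dist.get(l, 0.0) for l in levels])
                if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                    raise ValidationError(
                        f"demographics[{c}].{name}: probabilities must sum to 1"
                    )
        for c, u in enumerate(self.utilization):
            if u.preventable_ed_visits_mean > u.ed_visits_mean + 1e-12:
                raise ValidationError(
                    f"utilization[{c}]: preventable_ed_visits_mean exceeds ed_visits_mean"
                )
            if u.preventable_admissions_mean > u.admissions_mean + 1e-12:
                raise ValidationError(
                    f"utilization[{c}]: preventable_admissions_mean exceeds admissions_mean"
                )
            if u.count_model not in ("negbin", "poisson"):
                raise ValidationError(f"utilization[{c}].count_model: {u.count_model!r}")
        if self.separation < 0:
            raise ValidationError(f"separation must be >= 0, got {self.separation}")

    def effective_prevalence(self) -> np.ndarray:
        """Cluster prevalences after applying the separation knob.

        The deviation of each cluster's logit-prevalence from the
        mixing-weighted population logit is scaled by ``separation``.
        """
        prev = np.clip(np.asarray(self.condition_prevalence, dtype=float), 1e-6, 1 - 1e-6)
        w = np.asarray(self.mixing_weights, dtype=float)
        pop = np.clip(w @ prev, 1e-6, 1 - 1e-6)
        logit = np.log(prev / (1 - prev))
        logit_pop = np.log(pop / (1 - pop))
        eff = logit_pop + self.separation * (logit - logit_pop)
        return 1.0 / (1.0 + np.exp(-eff))

    # --- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["demographics"] = [ClusterDemographics(**x) for x in d["demographics"]]
        d["utilization"] = [ClusterUtilization(**x) for x in d["utilization"]]
        d["cost"] = CostSpec(**d["cost"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SyntheticCohort:
    """A generated cohort: patient-year table, planted labels, and the spec."""

    patient_years: pd.DataFrame
    true_labels: np.ndarray  # 1-based planted cluster ids
    spec: CohortSpec
    claims: pd.DataFrame | None = None


def _draw_counts(rng: np.random.Generator, mean: float, dispersion: float,
                 size: int, model: str) -> np.ndarray:
    if size == 0 or mean <= 0:
        return np.zeros(size, dtype=int)
    if model == "poisson":
        return rng.poisson(mean, size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort from *spec*; deterministic given ``spec.seed``."""
    spec.validate()
    n = spec.n_patients
    k = spec.n_clusters_true
    cond_cols = [condition_column(c) for c in spec.condition_names]
    rng = np.random.default_rng(spec.seed)

    labels = rng.choice(k, size=n, p=np.asarray(spec.mixing_weights, dtype=float)) + 1
    prev = spec.effective_prevalence()
    flags = (rng.random((n, len(cond_cols))) < prev[labels - 1]).astype(int)

    age = np.zeros(n, dtype=int)
    female = np.zeros(n, dtype=int)
    elig = np.empty(n, dtype=object)
    race = np.empty(n, dtype=object)
    adm = np.zeros(n, dtype=int)
    days = np.zeros(n, dtype=int)
    ed = np.zeros(n, dtype=int)
    prev_adm = np.zeros(n, dtype=int)
    prev_ed = np.zeros(n, dtype=int)

    for c in range(1, k + 1):
        mask = labels == c
        m = int(mask.sum())
        if m == 0:
            continue
        d = spec.demographics[c - 1]
        u = spec.utilization[c - 1]
        age[mask] = np.clip(np.round(rng.normal(d.age_mean, d.age_sd, m)), 21, 95).astype(int)
        female[mask] = rng.random(m) < d.p_female
        elig[mask] = rng.choice(
            ELIGIBILITY_LEVELS, size=m,
            p=np.array([d.eligibility.get(l, 0.0) for l in ELIGIBILITY_LEVELS]))
        race[mask] = rng.choice(
            RACE_LEVELS, size=m,
            p=np.array([d.race_ethnicity.get(l, 0.0) for l in RACE_LEVELS]))

        a = np.minimum(
            _draw_counts(rng, u.admissions_mean, u.admissions_dispersion, m, u.count_model),
            365)
        # per-admission length of stay: 1 + Poisson extra days, additive over admissions
        if u.admissions_mean > 0 and u.hospital_days_mean > u.admissions_mean:
            los_extra = u.hospital_days_mean / u.admissions_mean - 1.0
        else:
            los_extra = 0.0
        extra = np.where(a > 0, rng.poisson(np.maximum(a * los_extra, 0.0)), 0)
        e = _draw_counts(rng, u.ed_visits_mean, u.ed_dispersion, m, u.count_model)
        q_adm = (u.preventable_admissions_mean / u.admissions_mean
                 if u.admissions_mean > 0 else 0.0)
        q_ed = (u.preventable_ed_visits_mean / u.ed_visits_mean
                if u.ed_visits_mean > 0 else 0.0)
        adm[mask] = a
        days[mask] = np.where(a > 0, a + extra, 0)
        ed[mask] = e
        prev_adm[mask] = rng.binomial(a, min(q_adm, 1.0))
        prev_ed[mask] = rng.binomial(e, min(q_ed, 1.0))

    cost = spec.cost
    index = (cost.base + cost.per_admission * adm + cost.per_hospital_day * days
             + cost.per_ed_visit * ed)
    noise = rng.lognormal(-cost.sigma ** 2 / 2.0, cost.sigma, n) if n else np.empty(0)
    spend = np.round(index * noise, 2)

    width = max(len(str(n)), 1)
    pids = [f"P{i:0{width}d}" for i in range(1, n + 1)]
    py = pd.DataFrame({"patient_id": pids, "age": age, "female": female,
                       "eligibility": elig, "race_ethnicity": race})
    for j, col in enumerate(cond_cols):
        py[col] = flags[:, j]
    py["admissions"] = adm
    py["hospital_days"] = days
    py["ed_visits"] = ed
    py["preventable_admissions"] = prev_adm
    py["preventable_ed_visits"] = prev_ed
    py["annual_spend"] = spend
    return SyntheticCohort(patient_years=py, true_labels=labels, spec=spec)


# ---------------------------------------------------------------------------
# Claim-line materialisation
# ---------------------------------------------------------------------------


def build_claims(cohort: SyntheticCohort, code_table: dict[str, tuple[str, str]]) -> pd.DataFrame:
    """Long-format claim lines exactly consistent with the patient-year table.

    ``code_table`` maps each condition-category name to a (base_code,
    preventable_code) pair; the preventable code is expected to appear in
    the companion preventable-flag table.  Conventions match the ingestion
    rules in :mod:`claimseg.cohort_features`: one IP line per hospital day
    (all lines of an admission share its service date), one ED line per
    visit, one OP line per coded condition, and paid amounts that sum to
    the patient's annual spend to the cent.

    Deterministic given the cohort spec seed.
    """
    spec = cohort.spec
    rng = np.random.default_rng(spec.seed + 777_001)
    cond_cols = [condition_column(c) for c in spec.condition_names]
    base_code = {c: code_table[c][0] for c in spec.condition_names}
    prevent_code = {c: code_table[c][1] for c in spec.condition_names}

    dates = pd.date_range(f"{_CLAIMS_YEAR}-01-01", periods=365).strftime("%Y-%m-%d")
    rows: list[tuple] = []
    py = cohort.patient_years
    flag_arr = py[cond_cols].to_numpy() if cond_cols else np.zeros((len(py), 0), int)

    for i, rec in enumerate(py.itertuples(index=False)):
        pid = rec.patient_id
        active = [spec.condition_names[j] for j in range(len(cond_cols)) if flag_arr[i, j]]

        def pick_code(preventable: bool) -> str:
            if active:
                cat = active[rng.integers(len(active))]
                return prevent_code[cat] if preventable else base_code[cat]
            return GENERIC_PREVENTABLE_CODE if preventable else GENERIC_CODE

        lines: list[tuple[str, str, str]] = []  # (date, setting, code)
        n_adm = int(rec.admissions)
        if n_adm:
            adm_dates = rng.choice(365, size=n_adm, replace=False)
            extra_days = int(rec.hospital_days) - n_adm
            split = rng.multinomial(extra_days, np.full(n_adm, 1.0 / n_adm))
            preventable_ix = set(
                rng.choice(n_adm, size=int(rec.preventable_admissions), replace=False))
            for a_ix in range(n_adm):
                date = dates[adm_dates[a_ix]]
                los = 1 + int(split[a_ix])
                for day in range(los):
                    flagged = day == 0 and a_ix in preventable_ix
                    lines.append((date, "IP", pick_code(flagged)))
        n_ed = int(rec.ed_visits)
        if n_ed:
            ed_dates = rng.integers(0, 365, size=n_ed)
            for v_ix in range(n_ed):
                flagged = v_ix < int(rec.preventable_ed_visits)
                lines.append((dates[ed_dates[v_ix]], "ED", pick_code(flagged)))
        for cat in active:
            lines.append((dates[rng.integers(365)], "OP", base_code[cat]))
        total_cents = int(round(float(rec.annual_spend) * 100))
        if not lines:
            if total_cents > 0:
                lines.append((dates[rng.integers(365)], "OP", GENERIC_CODE))
            else:
                continue
        per_line = total_cents // len(lines)
        amounts = [per_line] * len(lines)
        amounts[0] += total_cents - per_line * len(lines)
        for (date, setting, code), cents in zip(lines, amounts):
            rows.append((pid, date, setting, code, cents / 100.0))

    return pd.DataFrame(rows, columns=["patient_id", "service_date", "setting",
                                       "icd9", "paid_amount"])


def emit_claims_tables(
    cohort: SyntheticCohort,
    directory: str | Path,
    code_table: dict[str, tuple[str, str]] | None = None,
) -> dict[str, Path]:
    """Write demographics.csv, claims.csv, truth.csv and a spec echo.

    Emitting then re-ingesting through :func:`build_patient_years`
    reproduces every patient-year aggregate exactly.
    """
    if code_table is None:
        from .fixtures import condition_code_table
        code_table = condition_code_table(cohort.spec.condition_names)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    claims = cohort.claims if cohort.claims is not None else build_claims(cohort, code_table)

    demo = cohort.patient_years[
        ["patient_id", "age", "female", "eligibility", "race_ethnicity"]]
    paths = {
        "demographics": directory / "demographics.csv",
        "claims": directory / "claims.csv",
        "truth": directory / "truth.csv",
        "spec": directory / "cohort_spec.yaml",
    }
    demo.to_csv(paths["demographics"], index=False)
    claims.to_csv(paths["claims"], index=False, float_format="%.2f")
    pd.DataFrame({"patient_id": cohort.patient_years["patient_id"],
                  "true_label": cohort.true_labels}).to_csv(paths["truth"], index=False)
    cohort.spec.to_yaml(paths["spec"])
    return paths
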