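"""Per-cluster descriptive profiles, deviation ranking, and labeling.

For every cluster: size and cohort share, demographic summary, condition
prevalences, and utilization means/SDs.  Utilization is summarised here
even though it is excluded from the clustering features, so clusters can
be compared on outcomes they were not built from.

Cluster naming follows the published workflow: find the features of a
cluster that deviate most from the overall mean, then attach a clinical
label.  The deviation score is (cluster mean - grand mean) / grand SD,
computed on the clustering inputs (demographics and condition flags);
a small editable rule table turns the top deviations into a suggested
label, and any user-supplied label always wins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_features import (
    CONDITION_PREFIX,
    ELIGIBILITY_LEVELS,
    RACE_LEVELS,
    UTILIZATION_COLUMNS,
)

logger = logging.getLogger(__name__)


def _input_feature_frame(patient_years: pd.DataFrame) -> pd.DataFrame:
    """Numeric view of the clustering inputs (demographics + condition flags)."""
    cond_cols = [c for c in patient_years.columns if c.startswith(CONDITION_PREFIX)]
    out = pd.DataFrame(index=patient_years.index)
    out["age"] = patient_years["age"].astype(float)
    out["female"] = patient_years["female"].astype(float)
    for lev in ELIGIBILITY_LEVELS:
        out[f"eligibility={lev}"] = (patient_years["eligibility"] == lev).astype(float)
    for lev in RACE_LEVELS:
        out[f"race={lev}"] = (patient_years["race_ethnicity"] == lev).astype(float)
    for c in cond_cols:
        out[c] = patient_years[c].astype(float)
    return out


@dataclass
class ClusterProfiles:
    """Cluster-by-feature summary tables plus grand (cohort) statistics."""

    summary: pd.DataFrame           # one row per cluster + "overall" row
    input_means: pd.DataFrame       # cluster x input-feature means (fractions, years)
    grand_means: pd.Series
    grand_sds: pd.Series            # patient-level SDs of the input features
    condition_columns: list[str]
    labels: dict[int, str] = field(default_factory=dict)

    @property
    def cluster_ids(self) -> list[int]:
        return [int(c) for c in self.input_means.index]

    def to_csv(self, path: str | Path) -> None:
        self.summary.to_csv(path, index=False, float_format="%.6g")


def profile_clusters(patient_years: pd.DataFrame, assignments: np.ndarray
                     ) -> ClusterProfiles:
    """Descriptive statistics per cluster and for the whole cohort.

    ``assignments`` is a 1-based label vector aligned with the rows of
    ``patient_years``.  Empty clusters (a label in 1..k with no members)
    do not occur under partitional assignment and are not represented.
    """
    assignments = np.asarray(assignments)
    if len(assignments) != len(patient_years):
        raise ValueError("every patient must be assigned to a cluster")
    feats = _input_feature_frame(patient_years)
    n = len(patient_years)

    cluster_ids = sorted(int(c) for c in np.unique(assignments))
    util_cols = UTILIZATION_COLUMNS

    rows = []
    input_rows = {}
    groups = list(cluster_ids) + ["overall"]
    for cid in groups:
        mask = np.ones(n, bool) if cid == "overall" else assignments == cid
        sub = patient_years[mask]
        fsub = feats[mask]
        row = {"cluster": cid, "size": int(mask.sum()),
               "share_pct": 100.0 * mask.sum() / n}
        row["age_mean"] = float(sub["age"].mean())
        row["female_pct"] = 100.0 * float(sub["female"].mean())
        for lev in ELIGIBILITY_LEVELS:
            row[f"elig_{lev}_pct"] = 100.0 * float((sub["eligibility"] == lev).mean())
        for lev in RACE_LEVELS:
            row[f"race_{lev}_pct"] = 100.0 * float((sub["race_ethnicity"] == lev).mean())
        for c in feats.columns:
            if c.startswith(CONDITION_PREFIX):
                row[f"{c}_pct"] = 100.0 * float(fsub[c].mean())
        for c in util_cols + ["annual_spend"]:
            row[f"{c}_mean"] = float(sub[c].mean())
            row[f"{c}_sd"] = float(sub[c].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append(row)
        if cid != "overall":
            input_rows[cid] = fsub.mean()

    summary = pd.DataFrame(rows)
    input_means = pd.DataFrame(input_rows).T
    input_means.index.name = "cluster"
    grand_means = feats.mean()
    grand_sds = feats.std(ddof=0)
    cond_cols = [c for c in feats.columns if c.startswith(CONDITION_PREFIX)]
    return ClusterProfiles(summary=summary, input_means=input_means,
                           grand_means=grand_means, grand_sds=grand_sds,
                           condition_columns=cond_cols)


def rank_deviations(profiles: ClusterProfiles, top_m: int = 5
                    ) -> dict[int, pd.DataFrame]:
    """Features of each cluster that most deviate from the overall mean.

    Score = (cluster mean - grand mean) / grand SD, ranked by absolute
    value; the sign records the direction.  Zero-variance features are
    excluded from ranking (their score is undefined) and logged.
    """
    sds = profiles.grand_sds
    zero_var = list(sds.index[sds == 0])
    if zero_var:
        logger.info("rank_deviations: excluding zero-variance features %s", zero_var)
    usable = [f for f in sds.index if f not in zero_var]
    out = {}
    for cid in profiles.cluster_ids:
        scores = ((profiles.input_means.loc[cid, usable]
                   - profiles.grand_means[usable]) / sds[usable])
        top = scores.reindex(scores.abs().sort_values(ascending=False).index)[:top_m]
        out[cid] = pd.DataFrame({"feature": top.index, "score": top.to_numpy()})
    return out


@dataclass
class LabelRule:
    """One row of the editable naming-rule table.

    ``kind="positive_features"``: the rule matches when every feature in
    ``features`` appears among the cluster's top deviations with score
    >= ``min_score``.  ``kind="positive_count"``: matches when at least
    ``min_count`` condition-category features appear among the top
    deviations with score >= ``min_score`` (broad multimorbidity).
    ``kind="negative_majority"``: matches when more than half of the top
    deviations are condition-category features with negative scores (the
    'relatively few conditions' pattern).
    """

    label: str
    features: list[str] = field(default_factory=list)
    min_score: float = 0.5
    min_count: int = 3
    kind: str = "positive_features"


def default_label_rules() -> list[LabelRule]:
    """Naming rules for the bundled condition vocabulary.

    Order matters: the multimorbidity (Complex Illness) rule precedes the
    cardio-metabolic one because multimorbid clusters are typically also
    elevated on the endocrine/cardiovascular categories.
    """
    c = CONDITION_PREFIX
    return [
        LabelRule("Pregnancy Complications", [f"{c}pregnancy_complications"]),
        LabelRule("Behavioral Health",
                  [f"{c}mental_illness", f"{c}neurologic_disorders"]),
        LabelRule("Complex Illness", kind="positive_count", min_count=3),
        LabelRule("Cardio-metabolic",
                  [f"{c}endocrine_disorders", f"{c}cardiovascular_disorders"]),
        LabelRule("Relatively Healthy", kind="negative_majority"),
    ]


def suggest_label(top_deviations: pd.DataFrame, naming_rules: list[LabelRule],
                  cluster_id: int, user_label: str | None = None) -> str:
    """First matching rule wins; a user-supplied label always overrides.

    Falls back to ``"Cluster <id>: <top feature>"`` when no rule matches,
    or to the bare cluster id when there are no ranked deviations.
    """
    if user_label:
        return user_label
    feats = dict(zip(top_deviations["feature"], top_deviations["score"]))
    for rule in naming_rules:
        if rule.kind == "positive_features":
            if rule.features and all(
                    feats.get(f, 0.0) >= rule.min_score for f in rule.features):
                return rule.label
        elif rule.kind == "positive_count":
            hits = sum(1 for f, s in feats.items()
                       if f.startswith(CONDITION_PREFIX) and s >= rule.min_score)
            if hits >= rule.min_count:
                return rule.label
        elif rule.kind == "negative_majority":
            cond_scores = [s for f, s in feats.items()
                           if f.startswith(CONDITION_PREFIX)]
            if cond_scores and len(feats) > 0:
                negative = sum(1 for s in cond_scores if s < 0)
                if negative > len(feats) / 2:
                    return rule.label
        else:
            raise ValueError(f"unknown rule kind {rule.kind!r}")
    if len(top_deviations) == 0:
        return f"Cluster {cluster_id}"
    return f"Cluster {cluster_id}: {top_deviations.iloc[0]['feature']}"


def label_clusters(profiles: ClusterProfiles,
                   naming_rules: list[LabelRule] | None = None,
                   user_labels: dict[int, str] | None = None,
                   top_m: int = 5) -> dict[int, dict]:
    """Suggested label per cluster with provenance (rule vs user)."""
    rules = naming_rules if naming_rules is not None else default_label_rules()
    user_labels = user_labels or {}
    devs = rank_deviations(profiles, top_m=top_m)
    out = {}
    for cid in profiles.cluster_ids:
        user = user_labels.get(cid)
        label = suggest_label(devs[cid], rules, cid, user_label=user)
        out[cid] = {"label": label, "provenance": "user" if user else "rule",
                    "top_deviations": devs[cid].to_dict(orient="records")}
    profiles.labels = {cid: d["label"] for cid, d in out.items()}
    return out


def export_heatmap_table(profiles: ClusterProfiles) -> pd.DataFrame:
    """Condition-category x cluster matrix of prevalences (%).

    The tabular twin of a condition-by-cluster heat map; rows are
    condition categories, columns are cluster ids.
    """
    if not profiles.cluster_ids:
        raise ValueError("export_heatmap_table: no clusters to export")
    mat = (profiles.input_means[profiles.condition_columns] * 100.0).T
    mat.columns = [str(c) for c in mat.columns]
    mat.index.name = "condition"
    return mat


def labels_to_json(labels: dict[int, dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {str(cid): d for cid, d in labels.items()}, indent=1))
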