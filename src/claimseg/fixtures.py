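"""Bundled synthetic study fixtures.

A small ICD-9-CM-style condition crosswalk (one prefix family per
condition category, standing in for a licensed multi-level diagnosis
grouper), a matching preventable-utilization flag table, and two cohort
recipes:

* :func:`fixture6_spec` — six planted clusters whose demographic,
  condition-prevalence and utilization profiles echo the published
  segmentation of a high-cost high-need Medicaid population (a
  pregnancy-complications cluster at 98% prevalence, a behavioral-health
  cluster, a cardio-metabolic cluster, a relatively healthy cluster, and
  two multimorbid clusters with low vs high resource use).
* :func:`gradient_spec` — two well-separated plus two heavily overlapping
  clusters, for exercising the stability gradient.
"""

from __future__ import annotations

import copy

import pandas as pd

from .cohort_features import ConditionCrosswalk
from .synthetic_claims import (
    GENERIC_PREVENTABLE_CODE,
    ClusterDemographics,
    ClusterUtilization,
    CohortSpec,
    CostSpec,
)

# (category name, ICD-9 prefix family)
CONDITIONS: list[tuple[str, str]] = [
    ("Pregnancy complications", "646"),
    ("Mental illness", "296"),
    ("Substance use", "304"),
    ("Neurologic disorders", "345"),
    ("Endocrine disorders", "250"),
    ("Cardiovascular disorders", "401"),
    ("Respiratory disorders", "493"),
    ("Gastrointestinal disorders", "571"),
    ("Renal disorders", "585"),
    ("Musculoskeletal disorders", "724"),
    ("Injury", "959"),
    ("Infection", "038"),
]

CONDITION_NAMES = [name for name, _ in CONDITIONS]


def default_crosswalk() -> ConditionCrosswalk:
    """Level-2 condition crosswalk covering the fixture code families."""
    rows = [
        {"code_prefix": prefix, "category_id": f"C{i + 1:02d}",
         "category_name": name, "level": 2}
        for i, (name, prefix) in enumerate(CONDITIONS)
    ]
    return ConditionCrosswalk(pd.DataFrame(rows))


def condition_code_table(condition_names: list[str] | None = None) -> dict[str, tuple[str, str]]:
    """(base_code, preventable_code) per category; codes share the category prefix."""
    prefix_of = dict(CONDITIONS)
    names = condition_names if condition_names is not None else CONDITION_NAMES
    table = {}
    for name in names:
        prefix = prefix_of.get(name)
        if prefix is None:
            raise KeyError(f"no bundled code family for condition {name!r}")
        table[name] = (f"{prefix}.0", f"{prefix}.1")
    return table


def default_preventable_flags() -> pd.DataFrame:
    """Flag table marking each category's '.1' code as possibly preventable."""
    rows = [{"code": f"{prefix}.1", "setting": "any"} for _, prefix in CONDITIONS]
    rows.append({"code": GENERIC_PREVENTABLE_CODE, "setting": "any"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Six-cluster fixture
# ---------------------------------------------------------------------------

# prevalence rows ordered as CONDITIONS; clusters: relatively healthy,
# pregnancy complications, behavioral health, cardio-metabolic,
# complex illness lower / higher resource use
_PREVALENCE6 = [
    [0.02, 0.08, 0.04, 0.04, 0.10, 0.12, 0.08, 0.06, 0.03, 0.10, 0.08, 0.04],
    [0.98, 0.05, 0.03, 0.02, 0.04, 0.04, 0.03, 0.03, 0.01, 0.03, 0.02, 0.04],
    [0.03, 0.90, 0.60, 0.86, 0.12, 0.15, 0.12, 0.10, 0.04, 0.12, 0.20, 0.06],
    [0.01, 0.12, 0.04, 0.08, 0.96, 0.93, 0.20, 0.15, 0.30, 0.15, 0.08, 0.08],
    [0.02, 0.30, 0.10, 0.15, 0.70, 0.65, 0.75, 0.80, 0.10, 0.80, 0.15, 0.10],
    [0.02, 0.35, 0.15, 0.20, 0.75, 0.70, 0.30, 0.25, 0.80, 0.20, 0.70, 0.75],
]

_DEMOGRAPHICS6 = [
    ClusterDemographics(42, 13, 0.61,
                        {"TANF": 0.58, "SSI": 0.34, "Expansion": 0.06, "Medicare-eligible": 0.02},
                        {"White": 0.50, "Black": 0.23, "Hispanic": 0.06, "Asian": 0.03,
                         "Other": 0.02, "Missing": 0.16}),
    ClusterDemographics(28, 6, 1.0,
                        {"TANF": 0.95, "SSI": 0.04, "Expansion": 0.008, "Medicare-eligible": 0.002},
                        {"White": 0.48, "Black": 0.27, "Hispanic": 0.09, "Asian": 0.04,
                         "Other": 0.01, "Missing": 0.11}),
    ClusterDemographics(40, 12, 0.84,
                        {"TANF": 0.58, "SSI": 0.35, "Expansion": 0.06, "Medicare-eligible": 0.01},
                        {"White": 0.62, "Black": 0.17, "Hispanic": 0.05, "Asian": 0.01,
                         "Other": 0.02, "Missing": 0.13}),
    ClusterDemographics(51, 12, 0.45,
                        {"TANF": 0.34, "SSI": 0.54, "Expansion": 0.06, "Medicare-eligible": 0.06},
                        {"White": 0.50, "Black": 0.21, "Hispanic": 0.05, "Asian": 0.04,
                         "Other": 0.01, "Missing": 0.19}),
    ClusterDemographics(54, 11, 0.68,
                        {"TANF": 0.40, "SSI": 0.47, "Expansion": 0.06, "Medicare-eligible": 0.07},
                        {"White": 0.38, "Black": 0.21, "Hispanic": 0.10, "Asian": 0.08,
                         "Other": 0.02, "Missing": 0.21}),
    ClusterDemographics(52, 12, 0.65,
                        {"TANF": 0.26, "SSI": 0.61, "Expansion": 0.06, "Medicare-eligible": 0.07},
                        {"White": 0.49, "Black": 0.18, "Hispanic": 0.05, "Asian": 0.02,
                         "Other": 0.01, "Missing": 0.25}),
]

_UTILIZATION6 = [
    ClusterUtilization(0.3, 4.3, 2.9, 0.01, 1.1),
    ClusterUtilization(0.8, 2.5, 4.7, 0.02, 1.9),
    ClusterUtilization(0.4, 2.1, 7.9, 0.04, 2.9),
    ClusterUtilization(0.4, 2.8, 4.8, 0.06, 1.9),
    ClusterUtilization(0.5, 3.2, 4.9, 0.10, 2.4),
    ClusterUtilization(2.0, 16.0, 14.6, 0.33, 6.3),
]

# cluster shares of the analytic cohort (six clusters, 13-21% each)
_WEIGHTS6 = [0.20699, 0.13075, 0.16675, 0.19436, 0.16078, 0.14037]

CLUSTER6_NAMES = [
    "Relatively Healthy",
    "Pregnancy Complications",
    "Behavioral Health",
    "Cardio-metabolic",
    "Complex Illness Lower Resource Use",
    "Complex Illness Higher Resource Use",
]


def fixture6_spec(n_patients: int = 3000, seed: int = 0,
                  separation: float = 2.0) -> CohortSpec:
    """The bundled six-cluster cohort recipe.

    The default ``separation`` of 2 doubles each cluster's logit-scale
    deviation from the population prevalence, yielding a high-separation
    cohort whose planted structure is recoverable at moderate n.
    ``separation=1`` reproduces the tabulated prevalences as written.
    """
    w = [x / sum(_WEIGHTS6) for x in _WEIGHTS6]
    return CohortSpec(
        n_patients=n_patients,
        condition_names=list(CONDITION_NAMES),
        mixing_weights=w,
        condition_prevalence=[list(r) for r in _PREVALENCE6],
        demographics=copy.deepcopy(_DEMOGRAPHICS6),
        utilization=copy.deepcopy(_UTILIZATION6),
        cost=CostSpec(),
        separation=separation,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Stability-gradient fixture
# ---------------------------------------------------------------------------

_PREV_GRAD = [
    # two well-separated clusters: pregnancy-like and cardio-metabolic-like
    [0.97, 0.03, 0.02, 0.02, 0.03, 0.03, 0.02, 0.02, 0.01, 0.02, 0.02, 0.03],
    [0.01, 0.10, 0.05, 0.08, 0.95, 0.95, 0.10, 0.10, 0.15, 0.10, 0.05, 0.05],
    # two heavily overlapping multimorbid clusters
    [0.02, 0.55, 0.35, 0.45, 0.40, 0.45, 0.50, 0.55, 0.35, 0.50, 0.45, 0.40],
    [0.02, 0.63, 0.30, 0.50, 0.45, 0.40, 0.55, 0.48, 0.42, 0.45, 0.50, 0.46],
]

_UTIL_GRAD = ClusterUtilization(0.5, 3.0, 4.0, 0.05, 1.5)


def gradient_spec(n_patients: int = 2000, seed: int = 0) -> CohortSpec:
    """Two well-separated plus two overlapping planted clusters.

    The overlapping pair shares demographics and differs only slightly in
    condition prevalences, so a k=4 partition splits their union along an
    unstable boundary; the separated pair should reproduce under
    resampling far more faithfully.
    """
    demo_sep1 = ClusterDemographics(27, 5, 1.0,
                                    {"TANF": 0.9, "SSI": 0.08, "Expansion": 0.02,
                                     "Medicare-eligible": 0.0},
                                    {"White": 0.5, "Black": 0.25, "Hispanic": 0.1,
                                     "Asian": 0.03, "Other": 0.02, "Missing": 0.1})
    demo_sep2 = ClusterDemographics(55, 10, 0.45,
                                    {"TANF": 0.3, "SSI": 0.6, "Expansion": 0.05,
                                     "Medicare-eligible": 0.05},
                                    {"White": 0.5, "Black": 0.2, "Hispanic": 0.06,
                                     "Asian": 0.04, "Other": 0.02, "Missing": 0.18})
    demo_overlap = ClusterDemographics(48, 12, 0.6,
                                       {"TANF": 0.45, "SSI": 0.45, "Expansion": 0.06,
                                        "Medicare-eligible": 0.04},
                                       {"White": 0.45, "Black": 0.22, "Hispanic": 0.08,
                                        "Asian": 0.04, "Other": 0.02, "Missing": 0.19})
    return CohortSpec(
        n_patients=n_patients,
        condition_names=list(CONDITION_NAMES),
        mixing_weights=[0.25, 0.25, 0.25, 0.25],
        condition_prevalence=[list(r) for r in _PREV_GRAD],
        demographics=[demo_sep1, demo_sep2, demo_overlap, demo_overlap],
        utilization=[_UTIL_GRAD] * 4,
        cost=CostSpec(),
        separation=1.0,
        seed=seed,
    )
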