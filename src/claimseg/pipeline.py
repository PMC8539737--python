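"""End-to-end orchestration: data -> features -> select-k -> fit -> stability -> profile.

A single :class:`RunConfig` (loadable from YAML) drives the whole
analysis.  One master seed fans out to per-stage seeds by fixed offsets,
so a single integer reproduces every numeric output byte for byte.  Each
stage writes its artifact into the output directory and contributes to a
run manifest (config echo, seeds, row counts, warnings).

Synthetic runs materialise the claim-line tables and then re-ingest them
through the same reader path used for external data, so the full
ingestion contract is exercised on every run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixtures
from .cohort_features import (
    ConditionCrosswalk,
    EncodingScheme,
    build_patient_years,
    polar_encode,
    read_claims,
    read_demographics,
    read_preventable_flags,
    select_eligible,
)
from .profiling import export_heatmap_table, label_clusters, labels_to_json, profile_clusters
from .segmentation import fit_kmeans, select_k
from .stability import run_stability
from .synthetic_claims import CohortSpec, emit_claims_tables, generate_cohort

logger = logging.getLogger(__name__)

# master-seed fan-out offsets per stage
SEED_OFFSETS = {"simulate": 0, "select_k": 10_000, "fit": 20_000, "stability": 30_000}


@dataclass
class RunConfig:
    """Everything needed for one reproducible pipeline run.

    Exactly one of ``synthetic`` / ``inputs`` must be set.  ``synthetic``
    is ``{"fixture": "fixture6"|"gradient", "n_patients": int, ...}`` or
    ``{"spec_yaml": path}``.  ``inputs`` maps table names (demographics,
    claims, crosswalk, preventable_flags) to file paths.

    ``eligibility_quantile`` applies the top-spending cohort rule before
    clustering; ``None`` skips it (synthetic cohorts already emulate the
    post-threshold population).  The remaining defaults mirror the study
    settings: a 5% spending threshold, k searched over 2..20, and 500
    bootstrap replicates.
    """

    outdir: str
    seed: int = 0
    synthetic: dict | None = None
    inputs: dict | None = None
    eligibility_quantile: float | None = 0.05
    min_age: int = 21
    k_grid: list[int] = field(default_factory=lambda: list(range(2, 21)))
    fixed_k: int | None = None
    n_restarts: int = 10
    selection_criterion: str = "partial_f_jump"
    n_replicates: int = 500
    stability_restarts: int = 5
    stability_population: str = "unique"
    top_m_deviations: int = 5

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("RunConfig: set exactly one of synthetic / inputs")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _resolve_spec(synthetic: dict, seed: int) -> CohortSpec:
    synthetic = dict(synthetic)
    if "spec_yaml" in synthetic:
        spec = CohortSpec.from_yaml(synthetic["spec_yaml"])
        spec.seed = seed
        return spec
    name = synthetic.pop("fixture", "fixture6")
    if name == "fixture6":
        return fixtures.fixture6_spec(seed=seed, **synthetic)
    if name == "gradient":
        return fixtures.gradient_spec(seed=seed, **synthetic)
    raise ValueError(f"unknown fixture {name!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest: dict = {"claimseg_version": __version__,
                      "config": config.to_dict(), "stages": [], "warnings": {},
                      "seeds": {s: config.seed + off for s, off in SEED_OFFSETS.items()}}

    # --- stage 1: data -----------------------------------------------------
    if config.synthetic is not None:
        spec = _resolve_spec(config.synthetic, config.seed + SEED_OFFSETS["simulate"])
        cohort = generate_cohort(spec)
        data_dir = out / "data"
        paths = emit_claims_tables(cohort, data_dir)
        crosswalk = fixtures.default_crosswalk()
        prevent = fixtures.default_preventable_flags()
        demo = read_demographics(paths["demographics"])
        claims = read_claims(paths["claims"])
        truth = pd.read_csv(paths["truth"], dtype={"patient_id": str})
        manifest["stages"].append({"stage": "simulate", "n_patients": spec.n_patients,
                                   "n_claim_lines": int(len(claims))})
    else:
        demo = read_demographics(config.inputs["demographics"])
        claims = read_claims(config.inputs["claims"])
        crosswalk = ConditionCrosswalk.from_csv(config.inputs["crosswalk"])
        prevent = (read_preventable_flags(config.inputs["preventable_flags"])
                   if "preventable_flags" in config.inputs else None)
        truth = None
        manifest["stages"].append({"stage": "load", "n_patients": int(len(demo)),
                                   "n_claim_lines": int(len(claims))})

    # --- stage 2: features -------------------------------------------------
    patient_years, warn = build_patient_years(demo, claims, crosswalk, prevent)
    manifest["warnings"]["unmapped_code_lines"] = int(sum(warn["unmapped_codes"].values()))
    if config.eligibility_quantile is not None:
        before = len(patient_years)
        patient_years = select_eligible(patient_years, config.eligibility_quantile,
                                        config.min_age)
        manifest["stages"].append({"stage": "eligibility",
                                   "quantile": config.eligibility_quantile,
                                   "n_before": before, "n_after": len(patient_years)})
    patient_years = patient_years.reset_index(drop=True)
    scheme = EncodingScheme.default(crosswalk.categories())
    features = polar_encode(patient_years, scheme)
    patient_years.to_csv(out / "patient_year.csv", index=False, float_format="%.2f")
    features.to_files(out / "features.csv", out / "features_meta.json")
    manifest["stages"].append({"stage": "features", "n": features.n, "p": features.p})

    # --- stage 3: select-k -------------------------------------------------
    if config.fixed_k is not None or len(config.k_grid) == 1:
        k = config.fixed_k if config.fixed_k is not None else config.k_grid[0]
        manifest["stages"].append({"stage": "select_k", "skipped": True, "k": k,
                                   "reason": "k fixed by config"})
    else:
        curve = select_k(features, config.k_grid,
                         seed=config.seed + SEED_OFFSETS["select_k"],
                         n_restarts=config.n_restarts,
                         criterion=config.selection_criterion)
        curve.to_csv(out / "kcurve.csv")
        k = curve.selected_k
        manifest["stages"].append({"stage": "select_k", "skipped": False,
                                   "selected_k": k, "criterion": curve.criterion})

    # --- stage 4: fit ------------------------------------------------------
    model = fit_kmeans(features, k, seed=config.seed + SEED_OFFSETS["fit"],
                       n_restarts=config.n_restarts)
    model.to_json(out / "model.json")
    pd.DataFrame({"patient_id": features.row_ids,
                  "cluster": model.assignments}).to_csv(
        out / "assignments.csv", index=False)
    fit_info = {"stage": "fit", "k": k, "within_sse": model.within_sse,
                "n_iter": model.n_iter}
    if truth is not None:
        from sklearn.metrics import adjusted_rand_score
        truth_map = dict(zip(truth["patient_id"], truth["true_label"]))
        planted = np.array([truth_map[pid] for pid in features.row_ids])
        fit_info["ari_vs_truth"] = float(adjusted_rand_score(planted, model.assignments))
    manifest["stages"].append(fit_info)

    # --- stage 5: stability ------------------------------------------------
    report = run_stability(features, model, n_replicates=config.n_replicates,
                           seed=config.seed + SEED_OFFSETS["stability"],
                           n_restarts=config.stability_restarts,
                           population=config.stability_population)
    report.to_csv(out / "stability.csv", out / "replicates.csv")
    manifest["warnings"]["skipped_replicates"] = report.n_skipped
    manifest["stages"].append({"stage": "stability", "n_replicates": config.n_replicates,
                               "overall": report.overall})

    # --- stage 6: profile --------------------------------------------------
    profiles = profile_clusters(patient_years, model.assignments)
    labels = label_clusters(profiles, top_m=config.top_m_deviations)
    profiles.to_csv(out / "profiles.csv")
    export_heatmap_table(profiles).to_csv(out / "heatmap.csv", float_format="%.6g")
    labels_to_json(labels, out / "labels.json")
    manifest["stages"].append({"stage": "profile",
                               "labels": {cid: d["label"] for cid, d in labels.items()}})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
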