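# claimseg

Segmentation of **high-cost high-need (HCHN)** patient populations from
claims data. A small share of insured patients — commonly defined as the
top 5% of annual spending — accounts for roughly half of expenditure,
but that threshold lumps together clinically very different people:
women with pregnancy complications, patients driven by behavioral-health
needs, multimorbid patients, and relatively healthy outliers. Programs
aimed at "the top 5%" as a single group tend to underperform; `claimseg`
disaggregates the thresholded cohort into clinically distinct subgroups
so interventions can be targeted, and quantifies how reproducible each
subgroup is.

Intended users: health-services researchers and population-health
analysts working with Medicaid/commercial claims extracts (or anyone who
needs tested mixed-data k-means with bootstrap cluster stability).

## Method

Given patient-year records (demographics, ICD-9-CM diagnoses grouped to
condition categories through a crosswalk, utilization counts, annual
spend):

1. **Cohort** — keep adults (≥ 21) in the top spending quantile
   (default 5%), ties at the threshold included.
2. **Features** — demographics and binary condition flags only
   (utilization is held out of clustering so outcome comparisons are
   unbiased). Categorical variables are embedded by **polar encoding**:
   level ℓ of an L-level variable ↦ (cos θ, sin θ), θ = 2π(ℓ−1)/L;
   binary flags use 0 ↦ (1,0), 1 ↦ (0,1); age is z-scored.
3. **Clustering** — Lloyd's k-means (random-partition initialisation,
   best of 10 restarts), minimising within-cluster SSE
   W(C) = Σ_k Σ_{i∈C_k} ‖x_i − μ_k‖².
4. **Choice of k** — fit k = 2..20 and compute the partial-F statistic
   per transition, F(k) = ((W_{k−1} − W_k)/p) / (W_k/(n − k·p));
   the selected k is the elbow of the F curve (largest relative collapse
   F(k)/F(k+1) above the noise floor).
5. **Stability** — 500 bootstrap resamples; each refit is aligned to the
   reference partition by maximising total Cohen's kappa over label
   permutations (Hungarian algorithm), then every cluster gets a
   per-replicate **Rand-style observed agreement** (% of patients whose
   binary membership matches) and **Jaccard overlap**
   (|∩|/|∪| of the membership sets, the stricter index).
6. **Profiling & labels** — per-cluster demographics, condition
   prevalences and utilization; features ranked by standardized
   deviation (cluster mean − grand mean)/grand SD; an editable rule
   table suggests clinical labels ("Pregnancy Complications",
   "Behavioral Health", …) which a user can always override.

A bundled synthetic claims generator plants known cluster structure
(mixing weights, per-cluster condition prevalences, demographics,
overdispersed utilization, heavy-tailed spend), so the entire pipeline
is testable without proprietary data. See `docs/methods.md` for
conventions and limitations.

## Worked example

Run the whole pipeline on a synthetic 1,000-patient cohort drawn from
the bundled six-cluster recipe:

```bash
claimseg run-all --n-patients 1000 --seed 7 --out demo_run
```

which prints the stage summaries:

```
{'stage': 'simulate', 'n_patients': 1000, 'n_claim_lines': 15624}
{'stage': 'features', 'n': 1000, 'p': 31}
{'stage': 'select_k', 'skipped': False, 'selected_k': 6, 'criterion': 'partial_f_jump'}
{'stage': 'fit', 'k': 6, 'within_sse': 3364.6896645980096, 'n_iter': 16, 'ari_vs_truth': 0.877806455840552}
{'stage': 'stability', 'n_replicates': 500, 'overall': {'rand_mean': 99.73058620620003, 'jaccard_mean': 98.52449570318254}}
{'stage': 'profile', 'labels': {1: 'Complex Illness', 2: 'Complex Illness', 3: 'Cardio-metabolic', 4: 'Relatively Healthy', 5: 'Behavioral Health', 6: 'Pregnancy Complications'}}
```

Reading this: the jump criterion recovered the six planted clusters
(`selected_k: 6`); the fitted partition agrees with the planted one at
adjusted Rand index 0.88; all six clusters are highly reproducible under
resampling on this well-separated cohort (per-cluster Jaccard means
97.1–100.0 in `demo_run/stability.csv`); and the rule table named the
pregnancy, behavioral-health, cardio-metabolic, relatively-healthy and
two multimorbid clusters from their deviation patterns. `demo_run/`
also contains the patient-year table, feature matrix with column
provenance, the k-selection curve, per-cluster profiles, the
condition-by-cluster heat-map table, and a manifest with every seed.

The library surface mirrors the stages: `generate_cohort`,
`build_patient_years` / `select_eligible` / `polar_encode`,
`fit_kmeans` / `select_k`, `run_stability`, `profile_clusters` /
`label_clusters`, and `run_pipeline` for the whole chain (CLI verbs:
`simulate`, `select-k`, `fit`, `stability`, `run-all`).

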