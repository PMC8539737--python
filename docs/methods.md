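# Methods

`claimseg` implements a segmentation analysis for high-cost high-need
(HCHN) patient populations defined by a spending threshold: disaggregate
the thresholded cohort into clinically distinct subgroups with k-means on
mixed categorical/continuous inputs, choose the number of clusters with a
jump criterion on the partial-F statistic, quantify per-cluster stability
under bootstrap resampling, and profile each cluster's conditions and
utilization. This note records the model, the conventions chosen where
the underlying procedure is commonly left informal, and what the bundled
synthetic cohorts do and do not establish.

## Cohort and features

The unit of analysis is the patient-year: demographics (age, gender,
Medicaid eligibility pathway, race/ethnicity including an explicit
Missing level), binary condition-category flags derived by mapping ICD-9-CM
diagnosis codes through a level-2 condition crosswalk (a pluggable
stand-in for a multi-level diagnosis grouper such as the AHRQ CCS), and
utilization counts (admissions, hospital days, ED visits, and possibly
preventable admissions/ED visits via a pluggable code-flag table standing
in for the licensed PQI and NYU/Billings classifications).

Eligibility uses the spending-quantile rule only: adults (age ≥ 21) whose
annual spend reaches the top `q` (default 0.05) of the age-filtered
cohort. The threshold is the `ceil(q·n)`-th largest spend and all
patients tied at the threshold are kept — deterministic and conservative.
A cohort with all-equal spends makes the rule degenerate and is rejected
with an explicit error rather than silently returning everything.

Clustering inputs are demographics and condition flags only. Utilization
and spend never enter the feature matrix (enforced against the per-column
metadata), so between-cluster utilization comparisons are not circular.

**Polar encoding.** Each categorical variable with L ordered levels maps
level ℓ to the unit-circle point (cos θ, sin θ) with θ = 2π(ℓ−1)/L; the
level order is part of the encoding config, since it determines which
levels sit adjacent. Binary flags use the quarter-circle convention
0 → (1, 0), 1 → (0, 1), so one disagreement contributes squared distance
2 and every variable's influence is bounded (squared distance ≤ 4 for any
pair of patients on any polar pair). Age is z-scored against the cohort
so years do not dominate unit-circle coordinates. The encoding is
injective per variable and keeps all levels equidistant from the origin.

## k-means

Lloyd's algorithm with random-partition initialisation: every
observation is first assigned to one of k clusters at random, centroids
are those groups' means, and assignment/update steps alternate until
assignments are stable or the relative SSE change falls below `tol`
(default 1e-6; `max_iter` 300). Within-cluster SSE is recorded per
iteration and asserted non-increasing — both steps of Lloyd's are
monotone, so any increase is a bug, and the fitted history makes that
checkable. Empty clusters are repaired by reseeding the empty centroid
at the point farthest from its current centroid (which cannot increase
SSE). The default 10 restarts keep the best solution; restart streams
are nested, so more restarts can never do worse for a fixed seed.
k-means++ initialisation is available by config as a robustness option.

## Choosing k: the partial-F jump

For each k in the grid (default 2..20, plus a baseline fit at k−1 of the
grid minimum so the first grid point is selectable), the transition
statistic is

    F(k) = ((SSE_{k−1} − SSE_k) / p) / (SSE_k / (n − k·p))

with p the feature dimension: the per-coordinate mean-square improvement
from adding the k-th cluster over the residual mean square. Monotone
non-increase of SSE in k is guaranteed by warm-starting each k from the
previous best centroids plus the farthest point, in addition to the
random restarts.

**Elbow definition.** Past the true number of clusters, F hovers around
a noise floor; through it, F stays well above. The selected k maximises
the relative collapse F(k)/F(k+1) among transitions whose F is at least
twice the median F over the grid (the median estimates the noise floor,
because for a wide grid most transitions lie beyond the true k). An
absolute-drop rule (argmax of F(k) − F(k+1)) was evaluated first and
rejected: on hierarchy-shaped mixed data the F curve is convexly
decreasing, so the largest absolute drop always lands at the front of
the grid regardless of the true structure. The relative rule is
scale-free and formalises the by-eye plot read; the noise-floor factor 2
is a design constant, and the floor restriction exists only to keep
small-F tail fluctuations (ratios of two near-zero numbers) from
producing spurious elbows. The last grid point is never selectable;
widen the grid if the curve has not flattened. A Sugar–James-style
distortion-jump criterion (argmax of d_k^(−p/2) − d_{k−1}^(−p/2), d the
mean per-point distortion) is available by config; note that with
p ≈ 30 effective dimensions it is fragile on non-Gaussian binary data.

## Cluster stability

Each of `n_replicates` (default 500) bootstrap replicates resamples n
patients with replacement and refits k-means at the reference k
(replicate r uses seed `seed + r`; 5 restarts by default). Because
k-means labels are arbitrary, the replicate partition is aligned to the
reference by Cohen's kappa: the k×k matrix of kappas between binary
membership indicators is built and the one-to-one relabeling maximising
total kappa found by the Hungarian algorithm (optimal, deterministic,
order-independent — a greedy match is not). Degenerate kappa tables
(both indicators constant) are defined as 1 when identical and 0
otherwise, avoiding 0/0.

Per original cluster c, two indices are computed per replicate over the
comparison universe (default: the distinct patients drawn in the
replicate; optionally all patients, with out-of-sample patients assigned
to the nearest replicate centroid):

- observed agreement (Rand-style): % of the universe on which the two
  binary membership indicators for c agree;
- Jaccard overlap: |intersection| / |union| of the two membership sets.

Jaccard ≤ agreement is an algebraic identity for binary membership (the
agreement numerator adds the both-out cell to the intersection while its
denominator adds the both-out cell to the union), and is asserted on
every replicate. Both-empty membership sets yield Jaccard 100 (vacuous
agreement) with a logged warning. These are per-cluster binary-membership
indices; the global pair-counting Rand index over whole partitions is a
different statistic and is deliberately not implemented.

Refit failures skip the replicate and are counted in the report, never
silently absorbed.

## Profiling and labeling

Per-cluster profiles report size and share, mean age, % female, %
eligibility pathway, % race/ethnicity, condition prevalences, and
utilization means/SDs; weighted cluster means recompose the cohort grand
mean exactly (asserted to 1e-9). Labeling mechanises the "maximally
deviated features" read: per feature, score = (cluster mean − grand
mean) / grand patient-level SD, ranked by absolute value (top 5 by
default). Standardisation makes scores invariant to affine rescaling of
continuous features; zero-variance features have undefined scores and
are excluded with a log line. A small editable rule table maps top-
deviation patterns to candidate names (first match wins; a
negative-majority rule catches the relatively-healthy pattern); an
unmatched cluster falls back to "Cluster <id>: <top feature>", and a
user-supplied label always overrides — final naming is a human decision.

## Synthetic cohorts

The generator plants cluster structure so every downstream stage is
testable without proprietary claims data. Per patient: a planted cluster
from the mixing weights; condition flags as independent Bernoulli draws
given the cluster; demographics from cluster-conditional distributions;
admissions and ED visits negative-binomial (claims counts are
overdispersed; Poisson by config), hospital days as admissions plus
Poisson per-admission extra days; preventable counts as binomial
thinning of their parents (so preventable ≤ parent holds per record);
and spend as lognormal noise around a linear index of utilization — only
the rank tail of spend matters to the quantile rule, so the exact form
is non-critical. The marginal spend distribution and count
overdispersion of real HCHN cohorts are not publicly tabulated; the
defaults here are stated choices, not estimates.

A `separation` knob scales each cluster's deviation from the population
prevalence on the logit scale (0 collapses all clusters to the
population mean; 1 reproduces the specified prevalences; >1 pushes
clusters apart while keeping probabilities inside (0,1)).

The bundled six-cluster recipe mirrors a published Medicaid HCHN
segmentation: cluster shares 13–21%; a pregnancy-complications cluster
(98% prevalence, all female, young), a behavioral-health cluster (90%
mental illness, 86% neurologic), a cardio-metabolic cluster (96%
endocrine, 93% cardiovascular), a relatively healthy cluster, and two
multimorbid clusters with low vs high resource use (admissions 0.3–2.0,
ED visits 2.9–14.6, preventable admissions 0.01–0.33, preventable ED
1.1–6.3 across clusters). The prevalence matrix is blocky by design —
signature categories extreme, the multimorbid pair differing on six
categories in opposite directions — because the recipe's role is a
recoverable high-separation ground truth (default separation 2.0); at
separation 1.0 it reproduces the tabulated prevalences as written. A
second recipe plants 2 well-separated plus 2 heavily overlapping
clusters to exercise the stability gradient.

The generator can materialise claim lines exactly consistent with the
patient-year aggregates. Conventions for the delimited format: one IP
line per hospital day, all lines of an admission stamped with its
admission date (admissions = distinct patient-IP-date pairs); one ED
line per visit; one OP line per coded condition; line codes drawn from
the patient's own condition-code families, with preventable encounters
carrying that family's flagged code; paid amounts split across lines to
the cent. Emit-then-ingest reproduces every aggregate exactly and is
tested as such.

**What passing tests do not show.** Real claims have correlated
conditions within patients (not independent Bernoulli), coding intensity
that varies by plan and provider, longitudinal dynamics
(regression-to-the-mean in the spending tail), and cluster structure far
less separable than planted fixtures. Recovery and stability results on
synthetic cohorts validate the machinery, not the clinical claim that a
particular real population has six clusters.

## Problem sizes and determinism

Default analysis sizes used throughout the package's own checks:
n = 3,000 patients for recovery and k-selection sweeps (20 generator
seeds), n = 2,000 for the stability gradient (50 replicates), and the
full 500-replicate bootstrap in the reproduction script. A single master
seed fans out to stage seeds by fixed offsets (simulate +0, select-k
+10000, fit +20000, stability +30000; replicate r adds r), and reruns
with one config are byte-identical across all numeric artifacts.

## Known limitations

- ICD-9-CM only; no ICD-10 crosswalk dialect.
- The licensed groupers (multi-level CCS, PQI, NYU/Billings) are
  represented by user-supplied tables; the bundled fixture crosswalk is
  a 12-category miniature for testing and documentation, not clinical
  content.
- The partial-F elbow and the polar level-ordering are conventions;
  both are config-visible so alternatives can be evaluated.
- Per-cluster stability is computed on the unique patients drawn per
  replicate by default; scoring all patients via nearest-centroid
  assignment is available but changes the universe and typically raises
  agreement.
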