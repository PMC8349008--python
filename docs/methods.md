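# Methods

`psnet` reconstructs, as a reusable pipeline, the empirical identification of
healthcare-provider networks for adults with mental illness from
administrative claims: a patient-sharing graph over individual providers,
nested modularity-based communities, the Bice–Boxerman continuity-of-care
index, and random-intercept models linking network structure to continuity.
This note records the model, its assumptions, the parameters that matter,
and the design choices made where the design was genuinely open.

## Cohort and claim model

A claim is one paid service line: patient, individual provider (empty for
facility-only lines), service date, claim type (inpatient / outpatient /
pharmacy), ICD-10 diagnosis codes (principal first), a procedure code, and a
payer. Patients qualify in a calendar year when all three hold in that year:

* **Age.** At least 18 at the start of the year and under 65 at its end.
  Claims schemas rarely carry full birth dates, so age is year arithmetic:
  `year − birth_year`, evaluated once per year. A patient qualifying in
  either study year (default 2016, 2017) is retained.
* **Diagnosis.** At least one qualifying behavioral-health code (F01–F99)
  on any claim of that year, any diagnosis position, all claim types
  (facility lines included). Nicotine dependence (F17), neonatal abstinence
  (P96.1) and fetal alcohol (Q86.0) codes never qualify.
* **Provider type.** At least one claim that year with a provider of one of
  the four analytic specialties (PCP, psychiatrist, psychologist, behavioral
  health specialist).

Diagnoses are assigned hierarchically to six mutually exclusive categories —
psychotic disorders, bipolar, depression/mood, anxiety/stress, other mental,
substance use — taking the highest applicable category over all of a
patient-year's codes. The shipped taxonomy-to-specialty mapping (~20 NUCC
codes) and 3-character-prefix diagnosis hierarchy are compact stand-ins for
the licensed NUCC and CCSR code sets; both are plain CSV and user-replaceable.

Insurance is classified over the whole window from the payers observed on a
patient's claims: dual when both Medicaid and Medicare appear, commercial +
public when commercial appears with either public payer, otherwise the single
observed class.

## Patient-sharing network

Two providers are connected when at least `min_shared` (default 3) distinct
patients have claims with both, anywhere in the window. By default all claim
types linking a patient to an individual provider count (a switch restricts
edges to deduplicated outpatient visits). After thresholding the graph is
undirected and unweighted — community detection consumes presence/absence of
ties — with the shared-patient count retained as edge metadata only.
Analysis proceeds on the largest connected component; when components tie in
size, the one containing the lexicographically smallest provider id is taken
so runs are reproducible. Retained fractions of providers and of patients
are reported.

## Community detection

Communities maximize Newman modularity

    Q = Σ_c [ e_c/m − (d_c / 2m)² ]

via greedy agglomeration (Clauset–Newman–Moore): start from singletons,
repeatedly merge the connected pair of communities with maximal gain
ΔQ = e_ij/m − 2 a_i a_j, and return the partition at the peak of the Q
trajectory. The implementation is in-package because downstream contracts
need what library routines do not expose: the full merge history, and a
deterministic tie rule (equal gains resolve toward the lexicographically
smallest pair of community identifiers, a community being identified by its
smallest member provider id). Correctness is tested against definitional
modularity recomputation, exhaustive per-step gain scans on small graphs,
and planted-partition recovery.

Sub-communities re-run the same algorithm on each community's induced
subgraph, using that subgraph's own edge count. Communities and
sub-communities under 10 providers are excluded from further analysis.

## Continuity of care and provider metrics

For a patient-year with `n ≥ 4` deduplicated outpatient visits (one visit
per patient–provider–day, procedure code in the Evaluation & Management
range 99201–99499) the Bice–Boxerman index is

    CoC = (Σ_i n_i² − n) / (n (n − 1)),

1 when all visits are with one provider, 0 when all providers differ.
Equivalently it is the fraction of visit pairs sharing a provider, which is
the brute-force oracle used in tests. A provider's mean CoC averages,
unweighted, over all eligible patient-years in which the provider had at
least one visit, pooling both years; alter CoC averages the mean CoC of a
provider's direct neighbours, skipping missing values.

Local transitivity is the fraction of a provider's neighbour pairs that are
themselves connected; it is undefined (missing, not zero) below degree 2,
and such providers are excluded from transitivity averages and model fits,
with counts logged — silent zeros would bias averages downward. The
"% of PCP connections within sub-community" uses each provider's own PCP
connections as denominator; providers without PCP connections contribute
nothing to the sub-community mean.

## Association models

Across retained sub-communities, Pearson and Spearman correlations relate
size to each characteristic (pairwise-complete; zero-variance columns are
reported as undefined). At provider level, the random-intercept model

    CoC_j = I + β_T T_j + β_P P_j + β_S S_j [+ β_A A_j] + u_c(j) + e_j

is estimated by REML (statsmodels MixedLM), with u a Gaussian intercept on
the provider's level-1 community (a switch allows sub-community grouping),
specialty contrasts against the PCP reference, and Wald 1-df normal
p-values, with no small-sample degrees-of-freedom correction. Model 1 omits
and Model 2 includes the alter-CoC term. The standardized transitivity
effect (SDs of CoC per SD of transitivity) is a derived report from the raw
slope, not a refit. With fewer than two groups the random intercept is
unidentifiable and the fit falls back to OLS, which is also available
explicitly by pinning the intercept variance at zero; a variance component
estimated at the boundary is flagged as singular, not an error.

## Synthetic data generator

The generator emulates the structure of a two-year all-payer extract: a
planted hierarchy of 5 communities × 5 sub-communities × 80 providers
(2,000 providers) and 20,000 patients by default, with specialty mix,
diagnosis-category and insurance marginals set to the published cohort
composition. Each patient has a home sub-community and a personal set of
m = 4 providers with Zipf-like weights tempered by the `concentration`
parameter (mean CoC rises monotonically with it; the default 1.5 places mean
provider CoC near 0.23, inside the 0.16–0.39 range reported for real
sub-communities). Per year, a patient draws a negative-binomial visit count
(mean 6, shape 2 — chosen so a realistic share of patient-years clears the
4-visit continuity filter); each visit goes to the personal set with
probability `p_within_sub` (0.8), else to the home community with
probability `p_within_com` (0.9), else anywhere. Within every pool,
providers are sampled with Zipf-like popularity weights (exponent 0.8).
The popularity skew is deliberate: at the desk-scale 10:1 patient:provider
ratio, uniform choice would leave almost no pair sharing three patients,
whereas skewed volume — as in real claims — produces a connected hub core
and a sparse periphery. Background pharmacy and facility claims (the latter
carrying diagnoses but no individual provider) exercise the
facility/diagnosis rules, and small fractions of out-of-age-range and
nicotine-only patients exercise the cohort filters.

What the generator does **not** emulate: ICD-10 comorbidity co-occurrence,
geographic structure, payment amounts, realistic utilization tails, or the
~58:1 patient:provider ratio of the real statewide data. Consequently the
pipeline's absolute outputs on synthetic data (e.g. near-total provider
retention in the largest component, transitivity around 0.8) are properties
of the planted world, not forecasts for real claims; passing tests
demonstrate that each computation is correct and that planted structure and
planted model coefficients are recovered, not that real-data values are
reproduced.

For estimator testing, provider-level profiles can also be simulated
directly and a continuity outcome planted from the linear model above
(`plant_coc_outcome`). Planted outcomes are clipped to [0, 1] by default,
with the clipped fraction logged; recovery studies disable clipping, since
censoring is not part of the estimator's model and, at roughly 1% censored,
is already enough to distort Wald coverage measurably.

## Numerical and procedural choices

* Modularity bookkeeping is validated to 1e-12 against definitional
  recomputation; the greedy peak is found by replaying the merge prefix with
  a union–find, avoiding per-step partition copies.
* All outputs are written deterministically (sorted rows, fixed 6-decimal
  float format, config hash and seed stamped in a header comment); the same
  inputs, configuration and seed give byte-identical artifacts.
* Edgeless graphs make modularity undefined — signalled explicitly, not
  returned as zero. Degraded runs (e.g. a threshold that empties the graph)
  complete with empty tables, warnings, and skipped model fits rather than
  aborting.
* Every record dropped anywhere is counted in a machine-readable audit
  (exclusions per cohort criterion, providers without transitivity, rows
  lost to listwise deletion).

## Problem sizes

Default test and reproduction scales: the end-to-end study runs at 2,000
providers / 20,000 patients (≈300k claims, ~25 s); estimator-recovery
studies use 50 communities × 40 providers with 200 replicates; greedy-step
exhaustive verification runs on graphs up to 60 vertices, and component
extraction is cross-checked on random graphs up to 500 vertices.

## Known limitations

Shared-patient counting is quadratic in providers-per-patient (fine for
realistic personal-set sizes); the CNM implementation targets graphs up to
tens of thousands of edges, not millions; Wald inference ignores
variance-component uncertainty, as in the original analysis; and the
compact code mappings are illustrative subsets, so real-data use requires
supplying full NUCC/CCSR-derived mapping files.
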