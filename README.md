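# symptomnet

Network analysis and second-order patient clustering for ordinal
symptom-severity cohorts.

Oncology patients report dozens of concurrent symptoms whose severities are
scored on 0–4 checklists (0 = not reported … 4 = very severe). Two
questions matter clinically: *which symptoms drive the overall burden* —
so they can be prioritized for treatment — and *which subgroups of
patients share a symptom pattern* — so management can be tailored.
`symptomnet` answers both from a single patient × symptom severity matrix
plus a covariate table, and ships a synthetic-cohort generator with planted
ground truth so that every stage of the pipeline has a recovery test.

## The model

**Symptom network.** Severities are treated as thresholded views of latent
continuous intensities. Each column is mapped through the nonparanormal
transform (average ranks → normal quantiles), near-duplicate symptom pairs
are first detected by weighted topological overlap and consolidated by an
equal-loading one-factor model, and a Gaussian graphical model is estimated
by the graphical lasso with EBIC (γ = 0.5) model selection. Edges are
partial correlations ρ_ij = −K_ij/√(K_ii·K_jj): association between two
symptoms after controlling for all others. Symptom clusters come from
walktrap community detection; symptom importance from strength, closeness
and betweenness centrality plus their *bridge* variants restricted to
cross-cluster structure; and edge/cluster stability from re-estimating the
network on bootstrap resamples of the patients.

**Patient subgroups.** Each patient's severity vector x is summarized by
the concordance matrix xx<sup>T</sup>/100 (co-severity of every symptom
pair). Patient similarity is the Adjusted Rand Index between the discrete
cell labelings of two concordance matrices, and walktrap on the similarity
graph yields subgroups — grouping patients by the *structure* of their
symptom experience, not by total burden. Subgroup membership is then
modeled by multinomial logistic regression on covariates (odds ratios,
Bonferroni-corrected p-values, AIC, Cragg–Uhler pseudo-R², likelihood-ratio
test), with the most cohort-representative subgroup as reference.

## Worked example

`analysis/` contains the numbered walk-through. It simulates a
demonstration cohort — 1000 patients × 31 symptoms sharing a general
burden factor, three equal patient subgroups each elevating an interleaved
third of the symptoms by 0.9 σ, covariates with planted log-odds
(treatment OR 3.32 for subgroup 2, an age effect for subgroup 3), and one
planted near-duplicate symptom — then runs every stage:

```text
$ python analysis/01_simulate_cohort.py
wrote 1000 patients x 31 symptoms (43% zero cells) to results/cohort

$ python analysis/02_preprocess.py
all 31 symptoms non-normal (max Shapiro p = 3.1e-30)
1 redundant pair(s) at wTO >= 0.25; 30 symptoms enter the network stage

$ python analysis/03_estimate_network.py
selected lambda = 0.08649: 149 of 435 possible edges nonzero; min/max edge weight 0.002/0.154

$ python analysis/04_network_metrics.py
cluster ARI vs planted co-elevation sets: 1.00
3 symptom clusters; highest strength centrality: symptom_16 (z = 2.24)
highest bridge strength: symptom_24 (z = 2.45)

$ python analysis/05_stability.py
88/149 edges significant at 95%; exactly 3 clusters in 100.0% of 200 resamples; min per-symptom same-cluster proportion 1.00

$ python analysis/06_patient_subgroups.py
3 subgroups {1: 268, 2: 336, 3: 396}; ARI vs planted truth 0.55; min consistency across 11 runs 1.00

$ python analysis/07_subgroup_regression.py
reference subgroup 3; AIC 2040, Cragg-Uhler pseudo-R2 0.160, LR chi2 152.6 (p = 5.5e-29)
  subgroup 1: age OR 0.95 (corrected p = 1.93e-10)
  subgroup 2: on_treatment OR 3.49 (corrected p = 8.62e-15)
```

Reading the output: the redundancy screen flags exactly the planted
duplicate — its overlap (0.37) tops the matrix, and every other
above-threshold pair shares a symptom with it, so the greedy rule merges
only the duplicate; the selected network's three walktrap clusters match the
planted co-elevation sets perfectly; patient clustering finds three
subgroups whose agreement with the planted labels is moderate at this
realistic 0.9 σ effect size (the recovery experiments in
`analysis/08_recovery_experiments.py` show ARI ≥ 0.8 in ≥ 90% of cohorts
once subgroups are separated by 2 σ); and the regression recovers the
planted treatment odds ratio (3.49 estimated vs 3.32 planted) and the age
effect, with the expected fit-statistic ordering against the null model.
The bootstrap (B = 200) confirms the three clusters are rock-stable on
this cohort: every symptom stays in its cluster in every resample, and 88
of the 149 edges are significant at 95%.

The same stages are scriptable (`symptomnet simulate|preprocess|network|
metrics|stability|subgroups|regress|run`) and callable as a library
(`symptomnet.run_pipeline` writes every artifact plus a manifest that
makes the run byte-for-byte reproducible from its seed).

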