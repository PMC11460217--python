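# Methods

`symptomnet` analyzes patient-by-symptom severity matrices on the 0–4
ordinal scale used by multi-symptom checklists such as the Memorial Symptom
Assessment Scale (0 = symptom not reported, 4 = very severe). The pipeline
has six stages; this note records the model behind each stage, the defaults
and why they were chosen, and what the synthetic-data experiments do and do
not demonstrate.

## Severity model and preprocessing

The analysis treats each observed severity as a thresholded view of a
continuous latent symptom intensity. Severity data are therefore mapped
through the **nonparanormal transform** before any Gaussian modeling: per
column, average ranks r_i (ties share the mean rank, which matters because
0–4 data are almost all ties) are mapped to Φ⁻¹(r_i/(n+1)) and rescaled to
unit sample variance. The transform depends only on within-column ranks, so
it is invariant to monotone recoding of the scale. The simple n+1 rank
denominator is the default rather than the Winsorized/truncated variant
(available as `npn_variant="winsorized"`, clamping rank probabilities at
δ = 1/(4·n^¼·√(π·log n))); with n in the hundreds or thousands and only
five distinct input values the two differ negligibly, and the simpler form
is easier to reason about in the idempotence and equivariance tests.

Before transformation, near-duplicate symptom pairs are screened by
**weighted topological overlap** on the zero-diagonal Pearson association
matrix w:

    wTO_ij = |Σ_k w_ik w_jk + w_ij| / (min(s_i, s_j) + 1 − |w_ij|),
    s_i = Σ_k |w_ik|.

Two symptoms overlap highly when they share both a direct association and
the same neighbourhood of associations — the signature of two items
measuring one construct. Pairs at or above the threshold (default 0.25, the
conventional cutoff in the unique-variable-analysis literature; the right
value for a given instrument is a judgment call and the parameter is
exposed) are consolidated greedily, highest overlap first, each symptom in
at most one merge. A flagged pair is replaced by the regression-method
factor score of a **tau-equivalent (equal-loading) one-factor model** fit
to the standardized pair — the minimal identified two-indicator maximum
likelihood model; an unconstrained one-factor model on two indicators is
not identified. Under equal loadings the score is a monotone function of
z_a + z_b; it is affinely rescaled to [0, 4] so downstream stages see the
familiar severity range. Consolidation refuses non-positively correlated
pairs. Shapiro–Wilk statistics are reported per column for transparency but
never gate the transform: ordinal severity data always fail normality
screening, and the transform is applied unconditionally.

## Partial-correlation network

The symptom network is a Gaussian graphical model: an edge between symptoms
i and j means their transformed severities are conditionally dependent
given all other symptoms, with weight equal to the partial correlation
ρ_ij = −K_ij/√(K_ii K_jj) where K is the precision matrix. K is estimated
by the **graphical lasso** (L1-penalized Gaussian maximum likelihood,
sklearn's coordinate-descent solver) over a 100-point penalty grid,
log-spaced from λ_max — the largest absolute off-diagonal sample
correlation, the smallest penalty producing an empty graph — down to
0.01·λ_max. The model minimizing the **extended Bayesian information
criterion**

    EBIC(λ) = −n(log det K − tr(SK)) + |E| log n + 4 |E| γ log p

is selected, with |E| the number of nonzero upper-triangle precision
entries. γ defaults to 0.5, the standard compromise between discovery and
false-edge control in EBIC-glasso practice; γ = 0 recovers plain BIC.
The solver's duality-gap tolerance defaults to 1e-4 (the solver's own
convention). At this tolerance a full penalty path on a p = 12, n = 1000
problem costs ~0.6 s, which is what makes the resampling stage affordable;
a tighter tolerance can be passed where single-fit precision matters, and
the λ = 0 case bypasses the solver entirely (direct inversion). Patients
with any missing severity are dropped listwise before estimation.

## Symptom clusters and centralities

Communities are found by the **walktrap** algorithm (igraph, 4-step random
walks — the library default) on the graph weighted by absolute partial
correlations, cutting the merge dendrogram at maximal modularity. Isolated
nodes become singleton communities.

Node importance uses three standard centralities, with shortest-path
lengths defined by the 1/|w| distance transform (the convention of the
network-psychometrics software family; strong partial correlations = short
distances; a −log|w| transform is available behind the `distance`
parameter):

- **strength** — Σ_j |w_ij|;
- **closeness** — inverse of the summed shortest-path distances to the
  other nodes of the same connected component (unreachable pairs are
  excluded rather than counted as infinite, keeping z-scores finite on
  disconnected graphs);
- **betweenness** — number of shortest paths passing through the node,
  fractional credit for ties (Brandes counting), each unordered pair
  counted once.

**Bridge** variants restrict each quantity to cross-community structure:
bridge strength sums |w_ij| over neighbours in other communities, bridge
closeness sums distances to all nodes outside the node's community, and
bridge betweenness counts only shortest paths whose two endpoints lie in
different communities (a dedicated Brandes accumulation with an
endpoint-community filter, validated against exhaustive path enumeration).
Absolute weights are used throughout; on networks whose edges are all
positive this is equivalent to using signed weights. All six measures are
reported raw and z-scored across nodes.

## Stability by case resampling

Accuracy and stability are assessed by re-running the entire estimation
(transform input → glasso path → EBIC selection → walktrap) on B case
resamples of the patient rows. The default is the nonparametric bootstrap
(n rows drawn with replacement); drawing a fraction without replacement
(`mode="subsample"`, default fraction 0.9) is available, since permuting
whole patient rows of a patient-wise dataset would change nothing. B
defaults to 1000 for reports and 200 in the bundled experiments, which is
enough for the proportion estimates used here (half-width ∝ 1/√B); a
resample that leaves a column constant is redrawn (at most 10 times).

- **Edge significance**: percentile interval per edge across resamples; an
  edge is significant when its interval excludes zero and the reference
  weight is nonzero.
- **Cluster stability**: each resample's walktrap solution is matched to
  the reference solution by greedy maximal Jaccard overlap (largest overlap
  first, ties broken by cluster id); a symptom scores 1 when its resample
  cluster maps onto its reference cluster. Also reported: the distribution
  of cluster counts across resamples (an empty resample network counts as a
  0-cluster outcome) and, per reference cluster, the proportion of
  resamples reproducing it exactly as a set. The matching rule is this
  package's own; no canonical rule exists for matching resampled
  partitions.

## Second-order patient clustering

Patients are grouped not by raw severity but by the *structure* of their
co-severity. Each patient's severity vector x yields a concordance matrix
xx^T/100 whose (i,j) cell encodes the joint severity of symptoms i and j.
Because severity products take at most 17 distinct integer values, the
upper triangle (diagonal included, symmetric cells not double-counted) of a
concordance matrix is read as a *discrete labeling* of the p(p+1)/2 cell
positions, and the similarity of two patients is the **Adjusted Rand
Index** between their two labelings, computed by the standard
contingency-table formula. This is the implementable reading of "ARI
between two matrices" for this data type — it generalizes the binary
co-occurrence concordance-network approach to graded severities — and it
makes the similarity exactly invariant to the /100 scaling. Degenerate case
(both labelings constant, the raw formula 0/0): defined as 1 when the
partitions coincide, 0 otherwise, so two all-zero patients count as
identical. The implementation is validated cell-for-cell against
brute-force pair counting and against a generic partition-ARI routine.

The n×n similarity matrix (negative values floored at zero, as walktrap
needs nonnegative weights) is the weighted adjacency of a complete graph on
patients; walktrap with default parameters yields the subgroups. The merge
procedure is deterministic given a node order, so "repeated runs" randomize
the node ordering: the assignment is taken from the first (identity-order)
run and the pairwise ARI between all runs' labelings is reported as a
consistency check. Per-subgroup severity profiles report mean severity per
symptom with normal-approximation 95% CIs (mean ± 1.96·sd/√n_g; a
singleton subgroup gets missing CIs), alongside the cohort mean.

Per-subgroup networks are only estimated for subgroups whose EBIC-selected
model has at least p/2 edges (configurable); a subgroup with minimal
symptom burden produces a sparse, unstable network that is skipped with a
logged reason rather than reported.

## Subgroup membership regression

Subgroup membership is modeled by reference-coded multinomial logistic
regression (statsmodels MNLogit, Newton optimization) on the covariate
table, complete cases only, categorical covariates expanded to indicators
against their first sorted level and continuous covariates entered
linearly. The reference subgroup defaults to the one most demographically
similar to the whole cohort: the subgroup minimizing the sum over
covariates of |mean difference|/cohort-sd (continuous) plus total variation
distance of level frequencies (categorical); a flag overrides the choice.
Reported per coefficient: odds ratio, Wald p-value, and Bonferroni-corrected
p-value with multiplicity m = number of non-intercept coefficients across
all non-reference equations (configurable, since the appropriate family is
a modeling decision). Reported per model: AIC, the likelihood-ratio χ²
against the intercept-only model, and Cragg–Uhler (Nagelkerke) pseudo-R²
(1 − (L₀/L₁)^{2/n}) / (1 − L₀^{2/n}). Changing the reference group
reparameterizes the coefficients but leaves fitted class probabilities
unchanged, which is asserted in the tests.

## Synthetic cohorts

The generator draws cohorts from exactly the model the pipeline assumes, so
every stage has a well-posed ground-truth recovery test.

- **Latent structure**: a block-exchangeable correlation matrix — planted
  symptom clusters with within-block correlation (default 0.4) and
  between-block correlation (default 0); requests that are not positive
  definite fail loudly with the offending eigenvalue. When the between
  correlation is zero the precision matrix is inverted block-wise so
  off-block entries are exactly zero.
- **Ordinal severities**: Gaussian copula — each patient's latent vector is
  multivariate normal with the planted correlation and a subgroup-specific
  mean shift, cut at fixed thresholds into 0–4. Default thresholds
  (0.1, 0.9, 1.6, 2.3) give ≈54% zeros per symptom and a long right tail,
  the zero-inflated shape of real severity checklists.
- **Subgroups and covariates**: one age-like continuous covariate, one
  treatment-like binary, one diagnosis-like categorical. When covariate
  effects are planted, covariates are drawn first and subgroup membership
  follows a multinomial logit with intercepts log(subgroup proportions) and
  slopes equal to the requested log-odds. This factorization makes the
  planted coefficients exactly the population quantities the regression
  stage estimates — the point of the recovery test — while matching the
  requested subgroup proportions through the intercepts (approximately,
  since slopes on centered covariates perturb the margins slightly).
  Without covariate effects, subgroups are drawn directly from the
  proportions.

Fixed seed and spec give byte-identical cohorts; all randomness flows from
one root seed split per stage.

### What the experiments show — problem sizes

The bundled experiments (analysis/08, scripts/acceptance.py) use desk-scale
sizes chosen to make the Monte-Carlo answers stable: symptom-cluster
recovery on p = 12, n = 1000 cohorts with three planted 4-symptom blocks
over 20 cohorts; patient-subgroup recovery on n = 300, p = 20 with three
subgroups elevated ±2σ on disjoint symptom thirds; stability at B = 200
resamples; regression recovery at n = 2000 with a planted treatment
log-odds of 1.2 (OR 3.32); and an end-to-end determinism check on an
n = 400, p = 12 cohort combining all three structures (B = 200, 20-point
penalty grid — grid resolution does not affect determinism).

Because generation and analysis share the nonparanormal model, passing
recovery tests demonstrate internal consistency and correct implementation,
not robustness to real-data violations: the generator does not emulate
instrument missingness, informative non-response, floor effects beyond the
planted thresholds, heterogeneous threshold use across patients, or
covariate measurement error. Recovery rates on real severity data will be
lower than on these planted cohorts.

## Numerical choices and degenerate inputs

- Edge presence threshold 1e-10 on precision/partial-correlation entries.
- Dendrogram/partition tie-breaks are deterministic by node index;
  community ids are renumbered contiguously from 1 in order of first
  appearance.
- Constant columns fail loudly everywhere (correlation, transform, wTO)
  with the offending column named.
- An empty selected network is returned with a warning from estimation but
  is a hard error for community detection; in resampling it is tallied as a
  0-cluster outcome.
- Quasi-separation in the regression (|coef| > 15) warns with the covariate
  name; a singular design is an error.
- JSON/CSV artifacts are written with sorted keys and fixed float formats
  so a rerun with the same seed is byte-identical.

## Known limitations

- The ARI-between-matrices reading of patient similarity is one defensible
  interpretation of comparing concordance matrices; alternatives (e.g.
  correlating vectorized matrices) would weight severity magnitude
  differently.
- Centralities on disconnected graphs exclude unreachable pairs, which
  favours nodes in small dense components; interpret closeness across
  components with care.
- The pipeline estimates a single network per (sub)cohort; temporal or
  directed structure is out of scope.
- O(n²) patient similarity with per-pair contingency tables is fine to a
  few thousand patients but would need blocking or sparsification well
  beyond that.
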