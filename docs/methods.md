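# Methods

`groomnet` re-implements, as a tested pipeline, a multi-group social-network
analysis of grooming in zoo-housed bonobos: scan-sampling observations are
turned into directed weighted grooming networks, five node-level network
metrics are computed per individual and standardized for group size,
dominance hierarchies are tested by randomization, and linear mixed models
relate the metrics to individual traits (sex, age, rearing history) and
group traits (group size, sex ratio).

## Observation model and network construction

The observational unit is the instantaneous group scan.  A grooming record
is an ordered (actor, receiver) pair within one scan; mutual grooming is two
records.  Edge weights use the *index of interactions*:

    w_ij = (number of scans in which i groomed j)
           / (number of scans in which the dyad was jointly observable)

A scan leaves the denominator of dyad (i, j) only when **both** i and j were
out of sight — if one member is visible, its grooming state is knowable.
The denominator is therefore per-dyad; a shared group-level denominator
(total scans) is available via `shared_denominator=True` because the
original description does not fully pin this down.  A dyad that was never
jointly observable yields weight 0 with a logged warning; a grooming count
for such a dyad is an inconsistency and is rejected.

## Node metrics

Per individual-in-group, on the weighted network:

* **out-/in-strength** — row/column sums of W (grooming given/received).
* **disparity** Y_i = Σ_j (w_ij / s_i)² over out-going edges; 1/k for k
  equally strong partners, 1 for a single partner.  Undefined (missing,
  never zero) when the individual gave no grooming.  A switch computes it
  on symmetrized edges instead; out-going is the default since the measure
  describes how an individual divides *its* grooming.
* **affinity** — the edge-weight-weighted mean strength of a node's
  partners on M = W + Wᵀ (an unweighted-mean variant is available; the
  weighted form is the default because the measure targets the rate at
  which one actually grooms with high-strength partners).
* **eigenvector centrality** — leading eigenvector of M, scaled to maximum
  1 within the group.  Computed by power iteration (tolerance 1e-10, with a
  diagonal shift by the maximum row sum so the dominant eigenvalue is
  strictly largest in modulus and bipartite-like structures cannot make the
  iteration oscillate; the shift leaves eigenvectors unchanged).  Tests
  verify agreement with a dense eigendecomposition to < 1e-8 on random
  networks.  Disconnected networks are flagged and solved per component,
  each non-trivial component scaled to its own maximum; isolated nodes get
  missing values.

Affinity and eigenvector centrality are reported as missing for groups with
fewer than 5 adults, where indirect connectivity is not biologically
meaningful.

Group-size standardizations: strengths are divided by the number of
available partners (N−1); disparity becomes the deviation from edge-weight
disparity, Y − 1/k (observed minus the equal-weights expectation for the
observed number of partners — the unique parameter-free deviation with the
uniform baseline); affinity and centrality are scaled to the maximum value
within the individual's network.

A Pearson screen over all 10 metric pairs flags |r| > 0.70 as the a-priori
redundancy criterion before any modeling.

## Dominance

From a flee-upon-aggression win matrix X: win proportions P_ij = X_ij/n_ij
and the chance-corrected dyadic index D_ij = P_ij − (P_ij − 0.5)/(n_ij + 1).
David's scores DS = w + w₂ − l − l₂ (unknown dyads contribute 0) are
normalized to normDS = (DS + N(N−1)/2)/N, which always sums to N(N−1)/2 and
is mean-centered within groups for cross-group comparability.  The
chance-corrected index is the default (it shrinks sparse dyads toward 0.5);
the raw-proportion variant is selectable — which of the two the original
analysis used is not stated.

**Steepness** is the absolute slope of descending-sorted normDS on ranks
1..N.  Its null keeps each dyad's interaction count and redraws the win
split as Binomial(n_ij, ½).  **Linearity** uses V_i (dominated partners,
ties/unknowns ½): h = 12/(N³−N)·Σ(V_i − (N−1)/2)², with the unknown-dyad
correction h′ = h + 6u/(N³−N).  Its null is the h of random complete
dominance matrices (each dyad a fair coin); an alternative two-step variant
(Monte Carlo filling of unknown/tied dyads) sits behind
`fill_unknowns=True`, because the exact procedure of the original software
is not documented.  All randomization p-values use the +1 small-sample
correction, so p ∈ [1/(n_rand+1), 1]; the default is 10,000 draws, seeded.
A group's hierarchy counts as resolved when both p-values are ≤ 0.10.

Two small-N facts matter when interpreting these tests.  With 5 or fewer
individuals, fully linear random tournaments are so common (120/1024 at
N = 5) that even a perfect order cannot reach p ≤ 0.10.  And the
calibration study for the linearity test uses groups of 8: at N = 6 the
support of h is so coarse that the achievable rejection rates cannot
straddle 0.10, which is a discreteness artifact rather than a
miscalibration (the steepness calibration uses N = 6, where its continuous
statistic has no such problem).

## Mixed models

For each metric, the full model has fixed effects sex, age (mean-centered
over the analysis rows; centering before squaring removes the collinearity
between age and age²), age², rearing history, group size, sex ratio, and
the two-way interactions of sex with each other term; random intercepts for
individual identity (repeated observations across group compositions) and
group identity.  Reference levels: female, mother-reared.

Workflow per response: drop missing-response rows (and, for indirect
metrics, groups below 5); Rosner's generalized-ESD outlier screen
(α = 0.05, up to 5 candidates) on the response; VIF collinearity check
(threshold 5); backward single-term elimination under ML, dropping at each
step the removable term whose removal lowers AIC most (marginality is
respected: interactions before their main effects, age² before age, and
the quadratic ordering extends inside the sex interaction; ties break
alphabetically); REML refit of the final structure for inference;
Shapiro–Wilk and residual/QQ diagnostics (report-only); Tukey-adjusted
pairwise contrasts of sex-by-rearing cell means at mean covariates when
that interaction survives.  ML is used for AIC comparison and REML for
final estimates — the standard convention for fixed-effect selection.

The solver is statsmodels MixedLM.  Crossed random intercepts are expressed
as variance components within a single stratum; when no individual repeats
(as in the simulation studies) the individual intercept is unidentifiable
from the residual and is dropped with a log note.  When every variance
component sits on the boundary the model degenerates to ordinary least
squares, which then supplies the standard errors (the components are
reported as 0).  Reported df are residual df (n − p); Satterthwaite-style
fractional df are solver-specific and deliberately not imitated, so t and
p values are comparable only approximately across solvers.  An lme4 fit via
Rscript serves as an independent cross-check in the test suite.

## Synthetic data generator

The generator emulates the study conditions: 22 groups (3–15 adults,
male-to-female ratios 0.20–2.00, ages 7–71 drawn from a shifted gamma),
274–1103 scans per group, 5% per-individual per-scan invisibility, rearing
atypical with probability 0.26.  Grooming is logistic-additive: giver
propensity (intercept −4.05, calibrated so male mean out-strength sits near
0.08, the scale of the real data; quadratic age effect −6.5e−4 per year² on
the logit with a peak near age 28; atypical-rearing deficit −0.35),
receiver attractiveness (+0.25 for females, −0.50 for atypically reared
males), female–female assortment +0.30 (and the mirror penalty for
male–male dyads), dyad and individual noise.  A finite-time-budget dilution
scales per-dyad giving by 1/(N−1) so that total giving is group-size-free,
matching the empirical pattern in this system — without it, strength grows
mechanically with group size.  Each actor grooms at most one receiver per
scan (instantaneous sampling); among candidate receivers the highest draw
wins.  Agonistic events are Poisson per dyad and the higher latent
dominance value wins with logistic probability; latent dominance follows
sex-specific age curves (female advantage 1.5, female peak at 35, male
trough at 25).

What the generator does **not** emulate: kinship (mother–son bonds),
temporal bout structure, female transfer dynamics, observer effects, and —
importantly — whatever generative process produced the real data's negative
out-strength/affinity correlation (−0.63 in the original sample).  In the
simulated networks that correlation comes out positive: dense small
networks with shared group-level rate variation make strong individuals sit
next to strong partners.  Passing tests on synthetic data therefore
demonstrate the correctness of the computations and the recoverability of
planted effects, not the reproduction of every empirical pattern.

## Synthetic reference dataset

The published supplementary workbook (composition, metadata, raw adjacency
matrices) is not redistributable here, so `groomnet.reference` constructs a
synthetic stand-in whose *composition* reproduces every printed descriptor
exactly: 22 groups with sizes 3–15 (median 6), 136 individual-in-group
records from 84 unique individuals (48/25/6/5 observed 1/2/3/4 times,
always in different groups), 51 male records (33 unique; 39 mother-reared /
12 atypically reared), 85 female records (51 unique; 62/23), sex ratios
0.20–2.00 with 14 female-biased groups, male ages 7–45 averaging ~19 and
female ages 7–71 averaging ~24.  Two printed counts require care: the
published tally of female-/male-biased/even groups sums to 21, so the
composition uses 5 even-ratio groups; and an indirect-measure subset of 126
records from 20 groups cannot arise from the <5-member group filter alone
(the two small groups hold only 7 records), so three records in large
groups belong to individuals never observed grooming, whose indirect
metrics are missing — yielding exactly 126 records from 20 groups.  The
grooming scans, matrices and metric values on top of this composition are
simulated and depend on the seed; only the composition is fixed.

## Problem sizes and numerical choices

Property checks use 200 random networks/win matrices; calibration studies
use 500 replicates with 199 randomizations each; recovery studies use 100
simulated datasets of ~300 records (34 groups).  Backward elimination in
the recovery study operates on the main-effects model, whose terms match
the planted structure.  Elimination stops when no removal lowers ML-AIC by
any amount; note that for a true-null single-df term the removal
probability is asymptotically P(χ²₁ < 2) ≈ 0.843, so per-run elimination
rates near 85–90% are the expected behavior of AIC itself, not a defect of
the search.  Power iteration uses tolerance 1e-10 with a cap of 10⁵
iterations.  Pearson screens use pairwise-complete records and report
missing correlations for constant columns.

## Known limitations

* The crossed random-intercept approximation and residual-df p-values mean
  coefficient tables agree with lmerTest-style output in estimates and SEs
  but not in fractional df.
* REML log-likelihoods are not comparable across fixed structures; AIC is
  always taken from ML fits during selection.
* Eigenvector centrality on disconnected networks is a convention (per
  component, component-wise max scaling), flagged in logs.
* The workbook reader implements this package's documented S1-style layout
  (groups sheet, individuals sheet, per-group matrix sheets, tolerant of
  decimal commas); the original file's internal layout may differ and
  would need a thin adapter.
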