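# groomnet

Multi-group social-network analysis of grooming in zoo-housed bonobos
(*Pan paniscus*) — from scan-sampling observations to directed weighted
grooming networks, node-level network metrics, randomization-tested
dominance hierarchies, and mixed-model inference of individual- and
group-level predictors.

Grooming is the affiliative currency of bonobo societies.  An individual's
position in the grooming network — how much it gives and receives, how it
divides grooming among partners, and how well-connected its partners are —
varies with sex, age, rearing history, and the demography of the group.
Single-group studies confound these levels; this package implements the
multi-group workflow that separates them, for behavioral ecologists who
collect scan-sampling data on several groups and want one reproducible
pipeline from raw scans to coefficient tables.

## What it computes

**Networks.** Per group, a directed weighted matrix with
*index-of-interactions* weights: w_ij = (scans where i groomed j) / (scans
where i and j were jointly observable); only scans with *both* members out
of sight leave a dyad's denominator.

**Node metrics** (per individual-in-group): out-strength and in-strength
(row/column sums of W); disparity Y_i = Σ_j (w_ij/s_i)², the concentration
of an individual's given grooming (1/k when k partners are groomed evenly,
1 for a single partner); affinity, the edge-weighted mean strength of a
node's partners on W + Wᵀ; and eigenvector centrality, the leading
eigenvector of W + Wᵀ scaled to max 1 per group (power iteration, verified
against dense eigendecomposition).  Group-size standardizations: s/(N−1),
the deviation from edge-weight disparity Y − 1/k, and within-group max
scaling.  A Pearson screen flags metric pairs with |r| > 0.70.

**Dominance.** From flee-upon-aggression win matrices: normalized David's
scores (chance-corrected D_ij by default), hierarchy steepness (|slope| of
sorted scores on ranks, binomial-null randomization test) and Landau's
linearity h with the unknown-dyad correction h′ (random-tournament null);
a hierarchy counts as resolved when both p ≤ 0.10.

**Models.** Per metric, a linear mixed model with fixed effects sex,
mean-centered age and its square, rearing history, group size and sex
ratio plus sex interactions, and random intercepts for individual and
group; Rosner outlier screen, VIF check, marginality-respecting backward
AIC reduction under ML, REML refit, Tukey-adjusted cell contrasts, and
residual diagnostics.

**Synthetic data.** A generator with planted, recoverable effects
(quadratic age, rearing deficit, receiver and assortment structure, latent
dominance) emulating the study conditions (22 groups of 3–15 adults,
274–1103 scans each), used for end-to-end validation; `groomnet.reference`
builds a synthetic stand-in for the study's supplementary workbook whose
composition matches every published descriptor exactly.

## Worked example

```sh
python analysis/01_build_reference_dataset.py --seed 1
python analysis/02_networks_and_metrics.py
python analysis/03_dominance.py
python analysis/04_mixed_models.py
python analysis/05_validation_studies.py --seed 1
```

The first script prints the sample descriptors of the generated reference
dataset:

```
groups: 22, records: 136, unique individuals: 84
median group size 6, 14 female-biased groups, sex ratios 0.20-2.00
indirect-measure subset: 126 records from 20 groups
```

The second builds the 22 networks and reports `mean male out-strength:
0.080` — i.e. an average male spends about 8% of scan time grooming.  The
third tests each hierarchy (`21 groups tested; 5 pass both randomization
tests at alpha = 0.10`) and draws the rank-vs-age visual aid from the
passing groups.  The fourth fits the model battery; for disparity it
retains group size with a negative coefficient,

```
group_size   estimate -0.0176   se 0.0023   t -7.78   p < 0.001
```

meaning each additional adult lowers an individual's grooming
concentration by ~0.018 on the disparity scale — in denser, larger groups
individuals spread their grooming more evenly.  The fifth script reruns
the validation battery (metric invariants, null calibrations at α = 0.10,
and planted-effect recovery across 100 simulated datasets; the planted
quadratic-age and rearing effects are recovered with the correct sign in
100% of fits).

All numbers downstream of the seed are reproducible; rerunning with the
same seed gives byte-identical tables.

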