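# Methods

## Model

Intelligibility scores are proportions in (0, 1): the fraction of a
child's spoken words transcribed correctly, averaged over two listeners.
Each group (TD, NSMI, SMI) is modelled independently with a
distributional beta regression in age,

    y | a ~ Beta(mu(a) phi(a), (1 - mu(a)) phi(a)),
    logit mu(a)  = b0 + b' N3(a)     (3-df natural cubic spline),
    log   phi(a) = g0 + g' N2(a)     (2-df natural cubic spline),

so both the central tendency and the spread of scores move with age;
variance at fixed mean is mu(1 - mu)/(1 + phi). This is the
mean-precision parameterization; a mean-sigma beta (GAMLSS-style) is the
same family under phi = (1 - sigma^2)/sigma^2, an identity the test
suite verifies numerically.

Observations are treated as independent at the point-estimation stage.
Longitudinal cohorts violate that (children contribute repeated visits);
within-child correlation is handled entirely by the cluster bootstrap,
not by random effects — point estimates are consistent under the
working-independence assumption, and only the uncertainty statements
need the clustering.

### Spline basis

Natural cubic splines (truncated-power natural basis) with boundary
knots at the minimum/maximum observed age and interior knots at the
empirical quantiles splitting the group's observations into equal-count
bins: tertile boundaries for the 3-df mean spline, the median for the
2-df precision spline. Each group's knots come from its own ages; the
three groups' bases are not shared. Beyond the boundary knots the
functions are linear (zero second derivative), but prediction outside
the observed range is refused rather than linearly extended — reference
curves are only defended where data exist. Internally the basis maps
ages affinely onto [0, 1] before the cubic terms; this spans the same
function space while keeping design columns O(1), which matters for
optimizer conditioning (below).

### Estimation

Maximum likelihood via L-BFGS-B with an analytic gradient. The start is
deterministic — intercepts from the logit of the sample mean and the log
of the method-of-moments precision, spline weights zero — so refits are
bit-reproducible. Function tolerance is effectively disabled (1e-15) so
the gradient criterion (max |grad| < 1e-6) binds; early experiments
showed that a loose function tolerance can halt L-BFGS-B far from the
optimum on these likelihoods. Line-search stalls that terminate
"abnormally" at a stationary point are accepted when the mean
per-observation gradient is below 1e-4. Scores of exactly 0 or 1 (which
the beta likelihood cannot absorb) are squeezed to the interior via
y' = (y(n-1) + 0.5)/n before fitting; interior scores are untouched.

## Derived statistics

**Percentile curves.** The p-th percentile curve is the pointwise
p-quantile of the fitted beta at each grid age. Curves at different p
cannot cross (quantiles of a common distribution are monotone in p).

**Density ROC.** With the case group fixed as the lower-scoring group
and "positive" meaning a score below threshold t: sensitivity is
F_case(t), specificity is 1 - F_ref(t), and the AUC is
P(Y_case < Y_ref) computed as the integral of F_case f_ref over (0, 1)
by adaptive quadrature on (1e-9, 1 - 1e-9) — beta densities can be
unbounded at the endpoints, and the excluded mass is below 1e-8 for all
realistic shape parameters; the quadrature's reported error is checked
against 1e-6. ROC curves trace a uniform threshold grid (default step
0.005). A computed AUC more than 0.10 below 1/2 raises an orientation
error (ref/case likely swapped); smaller dips are sampling noise when
groups genuinely overlap.

**Cut-points.** The fixed-specificity threshold at level s is the
reference model's (1 - s)-quantile; the fixed-sensitivity threshold is
the case model's s-quantile. PPV uses Bayes' rule,
Se pi / (Se pi + (1 - Sp)(1 - pi)), with prevalence pi computed from
child counts (not visit counts) and held constant across ages. Tables
report ages at exact year marks (36...96 months), thresholds both at
full precision and rounded to the nearest half percentage point.

Note: the source analyses that motivated this pipeline print a
prevalence of .677 (= 44/65) in their tables while the running text
says .667; the tabled PPVs are consistent only with .677, which is what
the worked examples here use.

**Developmental lag.** For percentile level p and grid age a, the lag
d(a) solves case_quantile(a + d, p) = ref_quantile(a, p), found by
scanning for sign changes over d in [-36, +36] months (intersected with
the case model's range) and Brent root-finding to 1e-3 months. Fitted
spline percentile curves can be locally non-monotone, so multiple roots
are possible; the smallest-magnitude root is taken and the occurrence
logged. The headline lag is the mean over solvable grid ages (default
grid: monthly, 36-90); fewer than three solvable ages refuses the
estimate rather than reporting an average of almost nothing.

**Bootstrap.** Cross-sectional cohorts are resampled within five fixed
age strata (30-41, 42-53, 54-65, 66-77, 78-96 months), preserving each
stratum's size, so every replicate has the original age composition.
Longitudinal cohorts are resampled by whole child: a drawn child
contributes every visit, duplicates get distinct synthetic ids. Each
replicate reruns the entire derivation (refit, re-derive). Intervals
are percentile intervals — the simplest defensible reading of an
unadorned "bootstrap CI" — at level 0.95 by default, B = 2000 by
default (tests and examples use 100-200 for desk-scale runtime).
Replicates whose refit fails are excluded with a logged count; more
than 10% failures aborts rather than silently reporting a biased
interval. Replicate streams are spawned deterministically from
(seed, replicate index), so results are independent of execution order.

**Listener reliability.** One-way random-effects, average-measures,
consistency ICC over child-visit units with k = 2 ratings:
(MSB - MSW)/MSB from the one-way ANOVA decomposition. Negative
estimates are returned as computed (flooring at zero would bias
aggregate summaries). The confidence interval is the standard
F-distribution interval for one-way average measures. The companion
descriptive is the mean (and SD of the) absolute within-pair difference
in percentage points.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with
closed-form ground truth for recovery testing. Group truth is a
four-parameter logistic mean curve (floor, asymptote, midpoint age,
scale) with log-linear precision phi0 exp(slope (a - 30)). Defaults are
fixtures, not estimates:

| group | asymptote | midpoint (mo) | scale | floor | phi0 | phi slope | child SD shift | child SD asym |
|-------|-----------|---------------|-------|-------|------|-----------|----------------|----------------|
| TD    | 0.97      | 32            | 12    | 0.10  | 6    | +0.035    | 0              | 0              |
| NSMI  | 0.965     | 39            | 12    | 0.10  | 6    | +0.035    | 4              | 0.25           |
| SMI   | 0.80      | 50            | 16    | 0.05  | 8    | -0.025    | 6              | 1.0            |

These put group medians in the order TD > NSMI > SMI through the
preschool years, make NSMI lag TD by roughly half a year (the midpoint
offset), shrink TD/NSMI spread with age (positive precision slope plus
ceiling approach) and widen SMI spread with age (negative slope plus a
large per-child asymptote wobble). The SMI parameters were chosen so
the widening-spread pattern holds in the population, not just at lucky
seeds; the associated tests allow a 0.02 slack between adjacent age
bins for sampling noise.

TD cohorts are cross-sectional: integer ages uniform on [30, 96], one
beta draw per child. Clinical cohorts are longitudinal: visit start
ages on the study's 6-month grid anchored at 30 months (uniform over
{30, 36, ..., 60}), a uniform visit count in {2..11} truncated at 96
months, and child-level random effects entering on the age axis
(normal midpoint shift) and the logit scale (normal asymptote wobble) —
never additively on proportions, so support stays in (0, 1). When a
group has at least two children, one child starts at 30 months and one
is followed from 60 to 96 months, guaranteeing each group spans the
full design range the way the real cohorts did; without this, small
groups can fail to cover the year marks at which tables are reported.
Listener pairs split each score symmetrically (pair mean is exactly the
stored score) with the half-gap SD set by the folded-normal identity to
target a mean absolute difference of 3.7 points (TD-like) or 5.0 points
(CP-like); the gap is shrunk where needed to keep both scores in [0, 1],
which pulls the realized mean difference slightly below target when
scores sit near the boundaries.

A single integer seed drives everything through named, deterministically
spawned substreams (one per child), so any child's trajectory is
reproducible in isolation and cohorts are byte-identical across reruns.

What the generator does **not** emulate: utterance-length structure and
missing-item imputation/weighting upstream of the scores, listener
selection effects, visit-attrition patterns correlated with severity,
and any misclassification of group labels. Passing recovery tests
therefore show that the pipeline recovers the distributions it assumes,
not that those assumptions hold in clinical data.

## Test-scale choices

Recovery tests fit n = 2000 cross-sectional draws per group (percentile
curves within 0.03-0.05 of truth over ages 36-90) and 50 replicates at
n = 500 for the aggregate 10th-percentile error. The bootstrap coverage
study uses 200 simulated datasets of n = 250 children with B = 200
replicates each, asserting at least 88% coverage of the generator truth
by the nominal 95% interval — percentile intervals are expected to
undercover slightly at moderate n, and the Monte-Carlo SE of the
coverage estimate itself is about 2 points. AUC quadrature is checked
against 10^6-draw sampling oracles within 0.003, and the maximum
likelihood fit against an independent beta-regression implementation
polished from our optimum.

## Known limitations

* No random-effects beta regression: longitudinal point estimates lean
  on working independence, and per-child trajectories are not produced.
* No model selection over spline degrees of freedom; 3 (mean) and 2
  (precision) are fixed by design.
* Extrapolation refusal means year-mark tables require data reaching
  the year marks; cohorts that stop short produce fewer table rows.
* The density ROC inherits any misfit of the beta model, particularly
  in the far tails where thresholds at extreme levels live.
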