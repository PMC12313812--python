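# Methods

## The law and the modelling strategy

The Menzerath-Altmann law relates constituent size to construct size as
`y = a x^b e^{cx}`: here `y` is the duration of one call (seconds) and
`x` the number of calls in its sequence.  `fit_menzerath_nonlinear`
estimates all three parameters by least squares on the log scale, where
the law is linear in `(ln a, b, c)`; noiseless data is therefore
recovered exactly.  All regression modelling uses the linearised form
(`c = 0`), the convention in comparative work on vocal sequences, with
natural logarithms throughout.

Rather than regressing mean call duration per sequence on sequence
length, every call contributes a response row and a sequence-level
random intercept absorbs within-sequence correlation.  This avoids the
regression-to-the-mean artifact of sequence averaging and propagates the
within-sequence sample size into the uncertainty of the slope.

Two model families are fitted, both Gaussian on `ln(duration)`:

* **simple** — `ln(duration) ~ ln(length) + (1 | individual/sequence)`,
  fitted separately per subspecies.  This asks only whether the law is
  present (`b < 0`).
* **complex** — three nested specifications on carrion-crow calls, with
  nested random intercepts for population / group / individual /
  sequence: main effects of sex, group size, age, Elo and CSI (form A);
  plus their interactions with `ln(length)` (form B); plus a nested
  random slope on `ln(length)` per individual with no intercept at that
  level (form C).  Interactions measure whether a covariate modulates
  the *strength* of the law; the random slope admits idiosyncratic
  individual departures beyond the covariates.

All fits are maximum likelihood (not REML) so that AIC differences and
likelihood-ratio tests between the nested forms are valid; the
estimation method is recorded on every fit and REML is deliberately not
offered until someone needs it.  Uncertainty is reported as 95% Wald
intervals (estimate ± 1.96 SE); an interval excluding zero is flagged a
"strong effect", and no p-values are attached to coefficients.

### Estimation

Both model families are estimated by a profiled-likelihood algorithm
written for exactly these designs.  Since every random term is either a
nested intercept or an individual-level slope, the marginal covariance
`V = sigma^2 (I + sum_k lambda_k Z_k Z_k')` can be inverted by applying
Woodbury identities level by level — a rank-one update per sequence, a
2x2 block per individual (intercept + slope), then rank-one updates per
group and population — so one likelihood evaluation costs O(n).  Fixed
effects and `sigma^2` have closed-form profiles; only the variance
ratios `lambda_k = tau_k^2 / sigma^2` are optimised (L-BFGS-B, bounded
at zero, three starting points, ftol 1e-12, max 500 iterations).  A fit
is reported non-converged when no start both succeeds and attains the
best objective; non-convergence is a recorded state, never an exception.
The test suite verifies exact agreement (estimates, standard errors,
log-likelihood) with statsmodels MixedLM and with lme4 via Rscript on
small datasets.  Variances pinned at the zero boundary (e.g. a single
individual) produce a warning, not a failure, and with all variance
ratios forced to zero the fit reduces to ordinary least squares to
1e-8 — an identity the tests assert.

AIC counts one parameter per fixed effect, per variance component and
for the residual variance.  LRTs are only computed for the documented
nesting chain (complex A ⊂ B ⊂ C) on identical rows; requesting one for
a non-nested pair is an error, not a silent chi-square.

### Covariate construction

Continuous covariates (group size, age, Elo, CSI) are z-scored before
fitting, so coefficients are per-SD and comparable in magnitude; the
(mean, sd) pairs are stored on the fit for back-transformation, and
prediction profiles are supplied on the original scale.  Sex is coded
with female as reference.  Age at recording is recording year minus
hatch year; birds with unknown hatch year get the mean age of the known
birds.  Group membership and group size are resolved from the
membership interval covering the recording date.  A covariate with zero
variance in the data at hand is dropped with an explicit warning.

## Segmentation and exclusions

The silent interval between calls is next onset minus previous offset.
A new sequence starts when that interval strictly exceeds the threshold
(default 1.0 s): an interval of exactly 1.000 s does **not** split.
Sequences never span recordings or individuals.  Overlapping
same-individual calls are flagged, never merged, and the flag later
removes the whole sequence.  Exclusions run in a fixed order — unknown
caller, overlap, incomplete, single-call — and each dropped sequence is
counted against the first rule that removes it, so the audit tally is
reproducible.  Sequence completeness cannot be inferred from time
stamps alone; it is honoured as an explicit flag set at annotation time,
standing in for the manual validation a field annotator would do.

## Social indices

**Elo.** Ratings update sequentially over agonistic interactions in
date order (ties in date keep input order; the loser is the bird that
retreated).  With expected win probability
`p = 1 / (1 + exp(-(r_w - r_l)/s))`, the winner gains `k (1 - p)` and
the loser loses the same, so the rating sum is conserved exactly.
Defaults: initial rating 0, `k = 100`, steepness `s = 400/ln 10 ≈
173.7`, which reproduces the classical Elo convention that a 200-point
gap implies a ~76% expected win; all three are configurable because
published analyses rarely state them.

**CSI.** For each co-housed dyad and each affiliative category
(allopreening, contact sitting), the interaction rate is events per
unit of dyadic observation time, approximated as the smaller of the two
individuals' focal totals (focal observations are five minutes each).
The dyadic CSI averages rate / population-mean-rate over categories, so
the population mean of dyadic values is 1 by construction and uniform
scaling of observation times cancels.  An individual's CSI is the mean
over its dyads.  A category with no events anywhere is dropped with a
warning instead of dividing by zero.  This is the standard two-category
form of the index; variants with more categories or dyad-inclusion
rules exist, and the choice is an assumption of this implementation.

**Effort correction.** Both indices are replaced by their residuals
from an OLS regression on the per-individual number of focal
observations, removing sampling-effort bias; by OLS orthogonality the
corrected index has exactly zero sample correlation with effort.  With
constant effort or fewer than three individuals the regression is
degenerate and the mean-centred index is returned with a warning.  Raw
and corrected values are both reported, since published tables do not
always say which convention they print.

## Synthetic data: what it emulates and what it does not

The generator draws a nested population/group/individual structure
(default 2 populations x 3 groups, group sizes uniform between 3 and 7,
~30 birds), per-individual covariates (sex Bernoulli(0.5), integer ages
1-10, standard-normal Elo, CSI), and sequences whose log call durations
follow the law plus Gaussian deviates at every nesting level, optional
covariate effects on level and slope, and residual noise.  Defaults:
`a = 0.25` (a ~0.25 s call at length 1), `b = -0.5`, `c = 0`, SDs
(population, group, individual, sequence, residual) = (0.05, 0.05, 0.2,
0.1, 0.3) on the log scale.  Sequence lengths mix a settable singleton
fraction (default 0.2) with a shifted geometric calibrated so the mean
is ~3.3 calls per sequence, matching the scale of published corvid
call-sequence corpora.  Calls are laid on a timeline with 0.3 s
within-sequence gaps and 3 s between sequences — safely on either side
of the 1 s rule, so segmentation is exactly invertible and the
round-trip through Audacity label files is lossless (times written with
nine decimals).  Durations are floored at 1 ms to keep logs finite
under extreme noise draws.

One integer seed drives a single numpy Generator; all draws happen in a
fixed order, so equal seeds give byte-identical outputs.

The generator does *not* emulate: acoustic content of any kind, call
types, temporal autocorrelation of durations beyond the sequence
intercept, observer biases in annotation, time-varying group
composition within a run, or non-Gaussian duration tails.  Passing
recovery tests on this generator therefore demonstrates correctness of
the estimation machinery under the model's own assumptions — not that
real crow data satisfies those assumptions.

Interaction logs are drawn from a latent dominance scale with logistic
win probabilities and per-dyad Poisson affiliation counts, supporting
rank-order recovery and CSI normalisation checks.

## Problem sizes used in tests and the acceptance script

Parameter-recovery and null-control experiments run 100 replicates at
study-like scale (~30 individuals, ~14,000 calls in ~4,300 sequences,
~3,500 of them multi-call), which the profiled fitter completes in well
under a minute per experiment.  Complex-model checks use ~4,000-call
datasets, enough for every variance component to be identified while
keeping a three-model comparison in a few seconds.  The lme4 and
MixedLM cross-checks use a few hundred calls, where all three
implementations agree to at least four decimals.

## Known limitations

- Dyadic observation time is an approximation (minimum of the two focal
  totals), not a true joint-presence log.
- The canonical call-table column layout is this package's own; data
  deposited by other groups needs a one-off import step.
- No formal cross-subspecies comparison is offered: with severely
  unbalanced subspecies samples, per-subspecies simple fits are
  reported instead of a pooled interaction model.
- Wald intervals are first-order; near variance boundaries their
  coverage can dip slightly below nominal (the recovery experiment
  measures ~0.93-0.96 at study scale).
- The random-slope form C places no intercept at the slope's grouping
  level and assumes slope deviates independent of intercept deviates;
  correlated random effects are not implemented.
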