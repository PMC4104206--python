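# Methods

This note documents the models implemented in `dyadrecip`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about real field data.

## Data model and observation window

The unit of observation is the *risk day*: an ordered (host family i, guest
family j, day t) cell that was potentially observable because at least one
of the two families completed an interview covering day t.  Interviews
cover exactly the two days preceding the interview day (the interview day
itself is excluded, avoiding partial-day ambiguity).  The panel carries
three binary tensors: hosting `h`, observability `o` (with `h ≤ o` enforced
everywhere), and a `guest_only` flag for cells covered only by the guest's
interview — the stratum where under-reporting acts.

Report reconciliation favors positive reports: a dyad-day is an event if
either party reported it.  When a host-side and a guest-side report of the
same ordered pair carry different dates within a two-day window and neither
has an exactly matching counterpart, they are treated as one event and one
of the two dates is kept uniformly at random under a caller-supplied seed.
The two-day matching window mirrors the recall window; no principled rule
exists for these rare collisions, so the choice is randomized rather than
biased toward either role.

## Kinship and space

Pairwise relatedness uses the standard recursive kinship coefficient
(founders unrelated, φ(a,a) = ½(1+φ(father, mother)), recursion on the
deeper individual), with r = 2φ.  Family-level relatedness is the mean r
over all cross-family member pairs; missing ancestors are treated as
founders.  Dyads are classed as close kin (r ≥ 0.25), distant kin
(0 < r < 0.25) or unrelated; the dynamical analysis uses the binary split
at 0.25.  Household distances use the spherical law of cosines with
R = 6371 km and the cosine clamped to [−1, 1]; distances are floored at
50 m before taking logs.

## Stationary model

A logistic regression on risk days with crossed random intercepts for host,
guest and host-guest dyad partitions unexplained variance across those
levels.  Fixed-effect builds follow a nested suite (A: week dummies +
guest-only flag; B: + head ages, quadratic for hosts; C/D/E: + log distance
and/or relatedness; F: + reciprocal hosting rate and its interaction with
relatedness).  The reciprocal rate for row (i, j) is j's hosting rate of i
over the whole sample (events / risk days) — no leave-one-out correction,
so its endogeneity is a property of the design, not a bug.  Week dummies
use week 0 as reference; ages enter on the raw scale.

The fitter is a Laplace-approximation GLMM: penalized IRLS jointly solves
for fixed effects and random-effect modes; a derivative-free outer search
optimizes the Laplace deviance over log variance components (bounded in
[e⁻⁸, e⁴]).  AIC = deviance + 2(p + k) is comparable across fixed-effect
builds fitted on identical rows.  Outer tolerances are loose (log-variance
to ~0.05) because component sampling noise at 35 families dwarfs that
precision.  Degenerate outcomes (all 0 or all 1) and optimizer failures are
flagged on the result, never silent.  Inference is by outcome-shuffling
permutation (unrestricted shuffle across rows, statistic |β| for fixed
effects and the variance itself for components, add-one p-estimator);
asymptotic standard errors are deliberately not the primary inference.

## Conditional-action reciprocity

For each ordered pair and lag Δt ≥ 1 (same-day mutual hosting is
ill-ordered and excluded), four windowed sums over day pairs (t, t+Δt) —
N_hh, N_oo, N_ho, N_oh — yield the estimator R̂ = N_hh·N_oo/(N_ho·N_oh),
the maximum-likelihood plug-in for the ratio of the conditional to the base
hosting probability.  Undefined ratios (zero N_ho or N_oh) propagate as
missing, never coerced to 0 or ∞.  The rapid-timescale statistic pools the
four counts over lags 1–3 *before* forming the ratio: per-lag ratios are
frequently undefined at realistic sparsity, and count-pooling is the ML
estimator of the pooled conditional probability (an open reading; the
alternative — averaging per-lag ratios — is noted but not used).

Class averages (all / close kin / not close kin) include ordered pairs with
events in both directions and joint observability at some lag (membership
is global, not per-lag).  Each pair's observed R̂ is renormalized by that
pair's null-ensemble mean; pairs whose null mean is undefined are dropped
with a logged count.  Bands are 1σ/2σ quantile envelopes of the same
class statistic computed on each null realization; p-values are one-sided
upper-tail with the add-one estimator.  Defaults: lag grid 1–60 for curves,
ensembles of 200 for bands and up to 1000 for p-values.

## The null hierarchy

All three nulls are i.i.d. across days.  The sampled mechanism is: host i
is *active* on day t with probability α_i·m_w(t); given activity, each
potential guest j joins independently with probability θ_ij; a simulated
event on a guest-only-covered cell is retained with probability γ.
Independent Bernoulli guest inclusion makes party sizes binomial
(Poisson-binomial when θ varies), which is exactly the sufficient-statistic
sense in which the size distribution is preserved, and it makes every
declared margin linear in the parameters — so margins can be preserved
*exactly* in expectation, which weighted sampling without replacement
cannot do for party sizes above one.

Fitting proceeds by count ratios restricted to observable cells.  The
seasonal multiplier m_w is the weekly hosting-pair fraction normalized to
mean 1; the reporting factor γ is the ratio of event rates on guest-only
vs host-covered cells.  Per-pair underlying rates λ_ij = events /
(seasonally- and γ-weighted exposure) are computed at the level's
resolution: free per pair (full-heterogeneous), pooled within kin strata
per host (kin-heterogeneous; strata group guests by mean r rounded to 3
decimals, since literal equality of continuous r would create singleton
strata), or pooled across all guests (homogeneous).  θ_ij = λ_ij/α_i, and
α_i is calibrated by bisection so the *expected number of observed party
days* matches the data (the remaining degree of freedom the margins do not
pin down).  Simulated panels are windowed by the true observation mask.

The hierarchy nests: per-pair margins aggregate to stratum margins
aggregate to host margins, verified directly on fitted parameters in the
test suite, and all three levels preserve their declared margins within
Monte-Carlo tolerance over 500-realization ensembles.

## Synthetic-data generator

The generator emulates the study system rather than any specific dataset:

- **Village** (35 families, ~195 individuals by default): founder couples,
  two further generations of marriages (60% of spouses are in-migrating
  founders, which keeps mean family relatedness near 0.03 and close-kin
  dyads rare, as in real villages of this size), households placed near the
  husband's natal compound inside a ~5 km village so that relatedness
  explains on the order of 20% of log-distance variance.
- **Events**: each family throws a party per day with probability
  base_rate × an age multiplier (log-quadratic, peaking in the 50s) × a
  weekly seasonal profile (active early season, mid-study lull, second
  active period; mean 1).  Guest counts are geometric (mean 2); guests are
  drawn without replacement with weights exp(β_dist·log d + β_kin·r + ε),
  ε ~ N(0, σ²_dyad).  Defaults (base 0.30, β_dist = −1.2, β_kin = 8,
  σ_dyad = 1.0) give an overall hosting rate near 0.93% per risk day and a
  stationary structure in which distance and kinship each explain roughly
  half-to-three-quarters of dyad-level variance — the regime the stationary
  analysis is designed for.
- **Reciprocity kernel**: with strength ρ > 1 and window w, the selection
  weight of guest j for host i is multiplied by ρ whenever j hosted i
  within the past w days and (i, j) is in the eligible kin classes; the
  host's party probability gets a proportional additive boost, so both the
  hosting and the guest-choice margins respond.  ρ = 1 gives an exactly
  i.i.d. process given preferences.
- **Observer**: interviews twice per family-week on random weekdays, each
  covering the two preceding days; hosts always report their own parties;
  a guest *either* discloses an attended event in every covering interview
  or never does, with disclosure probability 0.38.  The per-event (rather
  than per-interview) disposition is what makes the recovered-event
  fraction track the disclosure probability.

All randomness flows from one master seed through named substreams
(village / preferences / events / margins / interviews), so every fixture
is reproducible byte-for-byte.

What the generator does **not** emulate: real interview attrition (its
coverage, ~76% of dyad-days, is denser than sparse field campaigns),
host-rate heterogeneity beyond age (its hosting/attendance variance ratio
is ~2–3 rather than ~5), event dyad concentration (~30% of directed dyads
see an event vs ~17% in sparse field data), and any non-stationarity other
than the weekly activity profile.  Passing tests therefore establish the
estimators' correctness and calibration under a realistic generative class,
not the reproduction of any particular field dataset.

## Calibration and power, as tested

- Analyzing pseudo-data drawn from a fitted null's own mechanism against
  that null's ensemble yields class-averaged renormalized statistics within
  3 ensemble-SD of 1, for each of the three levels.  (Analyzing *preference-
  heterogeneous* data against the *homogeneous* null is expected to elevate
  the statistic — that mismatch is the diagnostic signal of the hierarchy,
  not a calibration failure.)
- An injected ρ = 3, w = 3 kernel among not-close-kin dyads at study scale
  is detected against the full-heterogeneous null (one-sided p ≤ 0.05,
  200-realization ensembles) in ≥ 80% of 20 seeds, with no systematic
  elevation among close kin.
- Injected dyad-level variance of 2.5 is recovered by the GLMM within 40%
  relative error (mean over 10 seeds) at study scale — Laplace
  approximations shrink binary-outcome variance components somewhat, which
  is inside that band at these cluster sizes.
- Permutation p-values are uniform under the null (KS over 50 replicates).

Problem sizes used in the test suite (ensembles of 200–500, lag grids to
10, reduced villages for unit tests) were chosen to make the full suite run
in about two minutes on one core while keeping every statistical tolerance
at its stated level.

## Known limitations

- The Laplace approximation biases variance components downward for sparse
  binary clusters; permutation inference is unaffected, but absolute
  variance levels should be read with that in mind.
- The guest-only reporting correction is a single multiplicative factor;
  heterogeneous reporting by family would require a per-family factor.
- The seasonal correction is weekly piecewise-constant by construction.
- α_i calibration can saturate (θ = 1 bound) for hosts whose observed
  party days exceed what any Bernoulli mechanism with their margins can
  produce; the margin tests tolerate the resulting clipping.
- `reciprocal_rate` in model F uses the full-sample reverse rate; its
  coefficient is descriptive of stationary contingency, not causal.
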