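# dyadrecip

Stationary and dynamical reciprocity analysis of temporal, directed
social-event networks sampled by interviews.

## The problem

In small-scale societies, families host each other at social events (the
motivating system is manioc-beer drinking parties in an Amazonian village of
~35 nuclear families observed for 16 weeks).  Two questions drive the
analysis:

1. **Stationary structure** — how heterogeneous are dyadic hosting rates,
   and how much of that heterogeneity is explained by kinship, spatial
   proximity, and the partner's reciprocal hosting rate?
2. **Dynamical (conditional-action) reciprocity** — does "i hosts j" raise
   the probability of "j hosts i" within days, beyond what stationary
   preferences predict?

Observation is incomplete: each family is interviewed roughly twice a week
about the two preceding days, and guests under-report.  Every estimator in
the package is corrected for this observation window.

## The core statistics

**Windowing-corrected conditional-action reciprocity.**  With hosting
indicators h\_ij(t) and observability indicators o\_ij(t), the pair-level
statistic at lag Δt is

    R̂_ij(Δt) = N_hh · N_oo / (N_ho · N_oh)

where the four counts sum h/o products over day pairs (t, t+Δt).  Under any
process that is i.i.d. across days, E[R̂] → 1.  Class-averaged curves
renormalize each pair by its expectation under a fitted stationary null
model (Monte-Carlo ensemble), and significance is the one-sided upper-tail
fraction of null realizations (add-one estimator).

**The null hierarchy.**  Three stationary mechanisms of increasing
strictness are fitted to the observed panel and sampled i.i.d. day by day:
*homogeneous* (per-host party rate and party-size distribution),
*kin-heterogeneous* (per-host guest preferences constant within kin strata),
and *full-heterogeneous* (all per-pair probabilities).  Each includes a
weekly seasonal multiplier and a guest-only reporting correction, and is
windowed by the true observation mask.

**Stationary model.**  A crossed random-effects logistic regression on risk
days,

    logit P(i hosts j on day t) = α_i + α_j + α_ij + Xβ,

with host/guest/dyad random intercepts (fitted by a Laplace-approximation
penalized-IRLS GLMM), AIC-based fixed-effect selection, outcome-shuffling
permutation p-values, and variance accounting 1 − Var(α_ij|model)/
Var(α_ij|baseline).

Because the original field data are not public, the package ships a
synthetic village-and-events generator (`dyadrecip.synthetic_data`) with
pedigree, kin-clustered geography, heterogeneous preferences, an interview
observer with guest under-reporting, and an injectable conditional
reciprocity kernel (strength ρ, window w) so every stage is testable with
known ground truth.

## Worked example

```python
from dyadrecip import SimParams, panel_summaries
from dyadrecip.workflows import simulate_and_build, reciprocity_analysis

params = SimParams(seed=7, recip_strength=3.0, recip_window=3,
                   recip_classes=("distant_kin", "non_kin"))
village, truth, panel, relmat, distmat = simulate_and_build(params)

s = panel_summaries(panel)
print(f"hosting rate {100 * s['hosting_rate']:.3f}% "
      f"({s['n_events']}/{s['risk_days']} risk days)")

_, _, curves = reciprocity_analysis(panel, relmat, "full_heterogeneous",
                                    n_null=200, seed=1)
for cls in ("close_kin", "not_close_kin"):
    c = curves[cls]
    print(f"{cls}: pooled <=3d R = {c.pooled_observed:.2f}, p = {c.pooled_p:.3f}")
```

prints (seed 7):

```
hosting rate 1.751% (1775/101348 risk days)
close_kin: pooled <=3d R = 1.09, p = 0.239
not_close_kin: pooled <=3d R = 2.80, p = 0.005
```

i.e. the injected 3-fold kernel among not-close-kin dyads is recovered as a
2.8-fold pooled elevation with p = 0.005, while close kin stay at their
null expectation — the qualitative contrast the method is designed to
detect.  (The overall hosting rate is above the ρ=1 baseline of ~0.93%
because the kernel also boosts party probabilities.)

There is also a CLI: `dyadrecip simulate|build|summarize|regress|
reciprocity|report --config cfg.yaml --seed 1`.

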