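"""Stationary (time-averaged) analysis: crossed random-effects logistic
regression of daily hosting on dyadic covariates.

One observation per *risk day* — a (host, guest, day) cell that was
observable.  The outcome is whether the host in fact hosted the guest that
day; random intercepts for host, guest and host-guest dyad partition the
unexplained variance across those levels, and fixed effects (week of study,
reporting flag, head ages, family sizes, log household distance, mean
relatedness, the reciprocal hosting rate, and a kinship x reciprocity
interaction) quantify how much of the dyad-level heterogeneity the measured
covariates absorb.  Inference is by outcome-shuffling permutation, not
asymptotic standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glmm import LaplaceFit, fit_laplace
from .io_model import EventPanel, Village
from .kinship_space import DistanceMatrix, RelatednessMatrix

FIXED_TERM_CATALOG = (
    "intercept", "week", "guest_only", "host_age", "host_age2", "guest_age",
    "host_size", "guest_size", "log_distance", "relatedness",
    "reciprocal_rate", "relatedness_x_reciprocal_rate",
)

RANDOM_TERM_CATALOG = ("host", "guest", "dyad")


@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effect build plus a set of crossed random intercepts."""

    fixed_terms: tuple[str, ...] = ("intercept",)
    random_terms: frozenset[str] = frozenset()
    name: str = ""

    def __post_init__(self) -> None:
        if "intercept" not in self.fixed_terms:
            raise ValueError("intercept is always present")
        unknown = set(self.fixed_terms) - set(FIXED_TERM_CATALOG)
        if unknown:
            raise ValueError(f"unknown fixed terms {sorted(unknown)}")
        unknown = set(self.random_terms) - set(RANDOM_TERM_CATALOG)
        if unknown:
            raise ValueError(f"unknown random terms {sorted(unknown)}")


@dataclass
class HierFitResult:
    """Estimates of one hierarchical logistic fit."""

    spec: ModelSpec
    beta: pd.Series  # log-odds
    var_components: dict[str, float]
    aic: float
    converged: bool
    message: str = ""
    n_obs: int = 0
    perm_p: pd.Series | None = None

    @property
    def exp_beta(self) -> pd.Series:
        return np.exp(self.beta)


def assemble_design(panel: EventPanel, village: Village,
                    relmat: RelatednessMatrix, distmat: DistanceMatrix
                    ) -> pd.DataFrame:
    """Long observation table: one row per risk day, outcome plus features.

    ``reciprocal_rate`` for row (i, j) is the mean daily rate at which j
    hosted i over the sample (events / risk days of the reverse dyad).
    """
    ids = panel.family_ids
    if list(village.family_ids) != ids or relmat.family_ids != ids \
            or distmat.family_ids != ids:
        raise ValueError("panel, village and matrices must share family ids")
    for f in village.families:
        if any(np.isnan(a) for a in f.head_ages):
            raise ValueError(f"family {f.family_id} has missing head ages")
        if any(np.isnan(c) for c in f.location):
            raise ValueError(f"family {f.family_id} has missing coordinates")

    i, j, t = np.nonzero(panel.o)
    events = panel.h.sum(axis=2).astype(float)
    risk = panel.o.sum(axis=2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(risk > 0, events / risk, 0.0)
    recip = rate.T  # recip[i, j] = rate at which j hosts i

    ages = np.array([f.head_age for f in village.families])
    sizes = np.array([f.size for f in village.families], dtype=float)
    d = np.maximum(distmat.d, 0.05)  # 50 m floor for the log

    df = pd.DataFrame(
        {
            "host": np.asarray(ids)[i],
            "guest": np.asarray(ids)[j],
            "host_idx": i,
            "guest_idx": j,
            "day": t,
            "week": t // 7,
            "y": panel.h[i, j, t].astype(float),
            "guest_only": panel.guest_only[i, j, t].astype(float),
            "host_age": ages[i],
            "guest_age": ages[j],
            "host_size": sizes[i],
            "guest_size": sizes[j],
            "log_distance": np.log(d[i, j]),
            "relatedness": relmat.r[i, j],
            "reciprocal_rate": recip[i, j],
        }
    )
    df["host_age2"] = df["host_age"] ** 2
    df["relatedness_x_reciprocal_rate"] = df["relatedness"] * df["reciprocal_rate"]
    df["dyad_idx"] = df["host_idx"] * len(ids) + df["guest_idx"]
    return df


def _design_matrix(table: pd.DataFrame, spec: ModelSpec):
    cols, names = [], []
    cols.append(np.ones(len(table)))
    names.append("intercept")
    for term in spec.fixed_terms:
        if term == "intercept":
            continue
        if term == "week":
            weeks = np.sort(table["week"].unique())
            for wk in weeks[1:]:  # week 0 is the reference
                cols.append((table["week"] == wk).to_numpy(float))
                names.append(f"week_{wk}")
        else:
            cols.append(table[term].to_numpy(float))
            names.append(term)
    return np.column_stack(cols), names


def _groups(table: pd.DataFrame, spec: ModelSpec) -> dict[str, np.ndarray]:
    groups = {}
    for term in ("host", "guest", "dyad"):
        if term in spec.random_terms:
            codes = pd.factorize(table[f"{term}_idx"])[0]
            groups[term] = codes
    return groups


def fit_hier_logistic(table: pd.DataFrame, spec: ModelSpec,
                      y: np.ndarray | None = None) -> HierFitResult:
    """Fit the crossed random-effects logistic model for one spec.

    Non-convergence is flagged on the result, never silent.  AICs are
    comparable across specs fitted on identical rows.
    """
    X, names = _design_matrix(table, spec)
    groups = _groups(table, spec)
    yv = table["y"].to_numpy(float) if y is None else np.asarray(y, float)
    fit = fit_laplace(yv, X, groups)
    return HierFitResult(
        spec=spec,
        beta=pd.Series(fit.beta, index=names),
        var_components=fit.var_components,
        aic=fit.aic,
        converged=fit.converged,
        message=fit.message,
        n_obs=fit.n_obs,
    )


def variance_explained(baseline: HierFitResult, model: HierFitResult,
                       component: str = "dyad") -> int:
    """Proportional reduction in a random-effect variance, as a rounded
    percentage: 100 * (1 - Var_model / Var_baseline)."""
    if baseline.n_obs != model.n_obs:
        raise ValueError("fits must share the same observation rows")
    return variance_reduction_percent(
        baseline.var_components[component], model.var_components[component]
    )


def variance_reduction_percent(var_baseline: float, var_model: float) -> int:
    if var_baseline <= 0:
        raise ValueError("baseline variance must be positive")
    return int(round(100.0 * (1.0 - var_model / var_baseline)))


def aic_select(table: pd.DataFrame, candidate_specs: list[ModelSpec]
               ) -> tuple[ModelSpec, pd.DataFrame]:
    """Fit all candidates and return the AIC-minimal spec plus the AIC table.

    Ties break toward fewer parameters; non-convergent candidates are
    excluded with a warning.
    """
    if not candidate_specs:
        raise ValueError("need at least one candidate spec")
    rows = []
    fits: list[tuple[ModelSpec, HierFitResult]] = []
    for spec in candidate_specs:
        fit = fit_hier_logistic(table, spec)
        n_par = len(fit.beta) + len(fit.var_components)
        rows.append(
            {"name": spec.name or ",".join(spec.fixed_terms), "aic": fit.aic,
             "n_parameters": n_par, "converged": fit.converged}
        )
        if fit.converged:
            fits.append((spec, fit))
        else:
            warnings.warn(
                f"candidate {spec.name or spec.fixed_terms} excluded: "
                f"{fit.message or 'did not converge'}", stacklevel=2,
            )
    aic_table = pd.DataFrame(rows)
    if not fits:
        raise RuntimeError("no candidate converged")
    best = min(
        fits,
        key=lambda sf: (round(sf[1].aic, 6),
                        len(sf[1].beta) + len(sf[1].var_components)),
    )
    return best[0], aic_table


def permutation_significance(table: pd.DataFrame, spec: ModelSpec,
                             n_perm: int = 199, seed: int = 0,
                             observed: HierFitResult | None = None
                             ) -> pd.Series:
    """Outcome-shuffling permutation p-values for every estimate.

    The hosting outcomes are shuffled across all observation rows; the model
    is refitted; for each fixed effect the statistic is |beta| and for each
    variance component the variance itself; p uses the add-one estimator
    (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    obs = observed if observed is not None else fit_hier_logistic(table, spec)
    obs_stats = np.concatenate(
        [np.abs(obs.beta.to_numpy()),
         np.array([obs.var_components[k] for k in sorted(obs.var_components)])]
    )
    names = list(obs.beta.index) + [f"var_{k}" for k in sorted(obs.var_components)]

    y = table["y"].to_numpy(float)
    exceed = np.zeros(len(obs_stats))
    n_used = 0
    for _ in range(n_perm):
        fit = fit_hier_logistic(table, spec, y=rng.permutation(y))
        if not fit.converged:
            continue
        stats = np.concatenate(
            [np.abs(fit.beta.to_numpy()),
             np.array([fit.var_components[k] for k in sorted(fit.var_components)])]
        )
        exceed += stats >= obs_stats
        n_used += 1
    p = (1.0 + exceed) / (n_used + 1.0)
    return pd.Series(p, index=names)


# ---------------------------------------------------------------------------
# The standard model suite (analogues of builds A..F)
# ---------------------------------------------------------------------------

def standard_model_suite() -> dict[str, ModelSpec]:
    """The fixed-effect builds of the stationary analysis, A through F."""
    re_all = frozenset({"host", "guest", "dyad"})
    base = ("intercept", "week", "guest_only")
    ages = base + ("host_age", "host_age2", "guest_age")
    return {
        "A": ModelSpec(base, re_all, name="A"),
        "B": ModelSpec(ages, re_all, name="B"),
        "C": ModelSpec(ages + ("log_distance",), re_all, name="C"),
        "D": ModelSpec(ages + ("relatedness",), re_all, name="D"),
        "E": ModelSpec(ages + ("log_distance", "relatedness"), re_all, name="E"),
        "F": ModelSpec(
            ages + ("log_distance", "relatedness", "reciprocal_rate",
                    "relatedness_x_reciprocal_rate"),
            re_all, name="F",
        ),
    }


def format_results_table(fits: dict[str, HierFitResult]) -> pd.DataFrame:
    """Human-readable layout: variance block then beta / exp(beta) / p block."""
    rows = []
    for name, fit in fits.items():
        for comp, var in fit.var_components.items():
            p = fit.perm_p.get(f"var_{comp}") if fit.perm_p is not None else np.nan
            rows.append({"model": name, "term": f"Var({comp})", "estimate": var,
                         "exp": np.nan, "p": p})
        for term, b in fit.beta.items():
            p = fit.perm_p.get(term) if fit.perm_p is not None else np.nan
            rows.append({"model": name, "term": term, "estimate": b,
                         "exp": float(np.exp(b)), "p": p})
        rows.append({"model": name, "term": "AIC", "estimate": fit.aic,
                     "exp": np.nan, "p": np.nan})
    return pd.DataFrame(rows)
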