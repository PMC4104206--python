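"""Conditional-action reciprocity estimation and the null-model hierarchy.

The estimator asks: by what factor does "i hosts j at time t" raise the
probability of "j hosts i at time t + dt", relative to the base rate?  For an
ordered pair (i, j) and lag dt it is the windowing-corrected ratio

    R_ij(dt) = N_hh * N_oo / (N_ho * N_oh)

built from four sums over day pairs (t, t + dt): joint hosting (N_hh), joint
observability (N_oo), and the two cross terms (N_ho, N_oh).  Under any
stationary (i.i.d.-across-days) process the pair-level expectation is one.

Significance comes from a three-level hierarchy of stationary null models of
increasing strictness — homogeneous (per-host party rate and size
distribution), kin-heterogeneous (per-host guest preferences constant within
kin strata), full-heterogeneous (all per-pair probabilities) — each fitted to
the observed panel, sampled i.i.d. day by day, windowed by the true
observation mask, and pushed through the identical estimator.  Class-averaged
statistics renormalize each pair by its own null-ensemble mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_model import EventPanel
from .kinship_space import KIN_THRESHOLD, RelatednessMatrix

logger = logging.getLogger(__name__)

NULL_LEVELS = ("homogeneous", "kin_heterogeneous", "full_heterogeneous")

DEFAULT_LAGS = tuple(range(1, 61))
POOLED_LAGS = (1, 2, 3)


# ---------------------------------------------------------------------------
# Windowed pair counts and the estimator
# ---------------------------------------------------------------------------

@dataclass
class PairCounts:
    """The four windowed sums for one ordered pair, per lag."""

    lags: tuple[int, ...]
    n_hh: np.ndarray
    n_oo: np.ndarray
    n_ho: np.ndarray
    n_oh: np.ndarray

    def __post_init__(self) -> None:
        for name in ("n_hh", "n_oo", "n_ho", "n_oh"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        if np.any(self.n_hh > np.minimum(self.n_ho, self.n_oh)) or \
                np.any(np.maximum(self.n_ho, self.n_oh) > self.n_oo):
            raise ValueError("pair counts violate N_hh <= min(N_ho, N_oh) <= N_oo")

    def pooled(self, lags: tuple[int, ...] = POOLED_LAGS) -> "PairCounts":
        """Counts summed over a set of lags (count pooling)."""
        sel = np.isin(self.lags, lags)
        return PairCounts(
            lags=(tuple(lags)),
            n_hh=self.n_hh[sel].sum(keepdims=True),
            n_oo=self.n_oo[sel].sum(keepdims=True),
            n_ho=self.n_ho[sel].sum(keepdims=True),
            n_oh=self.n_oh[sel].sum(keepdims=True),
        )


def _lagged_counts(a: np.ndarray, b: np.ndarray, lags) -> np.ndarray:
    """sum_t a[..., t] * b[..., t + lag] for each lag; a, b (..., T)."""
    out = np.empty(a.shape[:-1] + (len(lags),), dtype=np.int64)
    T = a.shape[-1]
    for k, lag in enumerate(lags):
        if lag >= T:
            out[..., k] = 0
        else:
            out[..., k] = np.einsum("...t,...t->...",
                                    a[..., : T - lag], b[..., lag:])
    return out


def pair_counts(panel: EventPanel, i: int | str, j: int | str,
                lags=DEFAULT_LAGS) -> PairCounts:
    """Exact windowed sums for ordered pair (i, j) at each lag (days)."""
    if isinstance(i, str):
        i = panel.family_ids.index(i)
    if isinstance(j, str):
        j = panel.family_ids.index(j)
    if i == j:
        raise ValueError("pair must be two distinct families")
    if min(lags) < 1:
        raise ValueError("lags must be >= 1")
    hij = panel.h[i, j].astype(np.int64)
    hji = panel.h[j, i].astype(np.int64)
    oij = panel.o[i, j].astype(np.int64)
    oji = panel.o[j, i].astype(np.int64)
    return PairCounts(
        lags=tuple(lags),
        n_hh=_lagged_counts(hij, hji, lags),
        n_oo=_lagged_counts(oij, oji, lags),
        n_ho=_lagged_counts(hij, oji, lags),
        n_oh=_lagged_counts(oij, hji, lags),
    )


def rhat(counts: PairCounts) -> np.ndarray:
    """Windowing-corrected conditional-probability ratio per lag.

    Undefined values (N_ho = 0 or N_oh = 0) propagate as NaN.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        num = counts.n_hh.astype(float) * counts.n_oo.astype(float)
        den = counts.n_ho.astype(float) * counts.n_oh.astype(float)
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return r


def pooled_rhat(counts: PairCounts, lags: tuple[int, ...] = POOLED_LAGS) -> float:
    """R-hat with counts pooled over the given lags before forming the ratio."""
    return float(rhat(counts.pooled(lags))[0])


def _stacked_counts(h: np.ndarray, o: np.ndarray, lags) -> dict[str, np.ndarray]:
    """Counts for all ordered pairs at once.

    h, o: (F, F, T).  Returns arrays (F, F, L) for the four count types of
    pair (i, j): forward direction i->j then j->i at t + lag.
    """
    hT = np.swapaxes(h, 0, 1)  # hT[i, j] = h[j, i]
    oT = np.swapaxes(o, 0, 1)
    return {
        "hh": _lagged_counts(h, hT, lags),
        "oo": _lagged_counts(o, oT, lags),
        "ho": _lagged_counts(h, oT, lags),
        "oh": _lagged_counts(o, hT, lags),
    }


def _rhat_from_stacks(c: dict[str, np.ndarray]) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        den = c["ho"].astype(float) * c["oh"].astype(float)
        return np.where(den > 0,
                        c["hh"].astype(float) * c["oo"].astype(float)
                        / np.where(den > 0, den, 1.0),
                        np.nan)


# ---------------------------------------------------------------------------
# Null models
# ---------------------------------------------------------------------------

@dataclass
class NullParams:
    """Fitted stationary mechanism of one null level.

    The sampled process is: host *i* is active on day *t* with probability
    ``alpha[i] * season[t]``; given activity, each potential guest *j* joins
    independently with probability ``theta[i, j]`` (binomial party sizes —
    the sufficient statistic matched is the mean); a simulated event on a
    cell covered only by the guest's interview is retained with probability
    ``guest_factor``.  ``alpha`` is calibrated so the expected number of
    observed party days per host matches the panel; ``theta`` is set so each
    per-pair observed probability is preserved exactly in expectation, with
    theta constant across guests (homogeneous), across kin strata
    (kin-heterogeneous), or free (full-heterogeneous).
    """

    level: str
    family_ids: list[str]
    alpha: np.ndarray  # (F,) per-host daily activity probability
    theta: np.ndarray  # (F, F) per-guest inclusion probability
    season: np.ndarray  # (T,) weekly piecewise-constant multiplier, mean 1
    guest_factor: float
    #: expected observed event count per cell (diagnostic / margin checks)
    lam: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.level not in NULL_LEVELS:
            raise ValueError(f"unknown null level {self.level!r}")
        if np.any(self.theta < 0) or np.any(self.theta > 1):
            raise ValueError("theta outside [0, 1]")
        if np.any(self.alpha < 0):
            raise ValueError("alpha must be >= 0")


def _weekly_multipliers(panel: EventPanel) -> np.ndarray:
    """Weekly hosting-pair fraction, normalized to a mean-1 daily multiplier."""
    T = panel.n_days
    weeks = np.arange(T) // 7
    h_week = np.zeros(weeks.max() + 1)
    o_week = np.zeros(weeks.max() + 1)
    for wk in range(weeks.max() + 1):
        sel = weeks == wk
        h_week[wk] = panel.h[:, :, sel].sum()
        o_week[wk] = panel.o[:, :, sel].sum()
    overall = panel.h.sum() / max(panel.o.sum(), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(o_week > 0, h_week / o_week, overall)
    m_week = rate / overall if overall > 0 else np.ones_like(rate)
    m = m_week[weeks]
    return m / m.mean() if m.mean() > 0 else np.ones(T)


def guest_report_factor(panel: EventPanel) -> float:
    """Ratio of event rates on guest-only-covered vs host-covered cells."""
    go = panel.guest_only.astype(bool)
    hc = panel.o.astype(bool) & ~go
    n_go, n_hc = go.sum(), hc.sum()
    if n_go == 0 or n_hc == 0:
        return 1.0
    rate_go = panel.h[go].sum() / n_go
    rate_hc = panel.h[hc].sum() / n_hc
    if rate_hc == 0:
        return 1.0
    return float(np.clip(rate_go / rate_hc, 0.0, 1.0))


def fit_null(panel: EventPanel, relmat: RelatednessMatrix | None, level: str,
             kin_round: int = 3) -> NullParams:
    """Maximum-likelihood (count-ratio) fit of a null level to the panel.

    Kin strata for the kin-heterogeneous level group guests by mean
    relatedness rounded to ``kin_round`` decimals.
    """
    if level not in NULL_LEVELS:
        raise ValueError(f"unknown null level {level!r}; expected one of {NULL_LEVELS}")
    if level == "kin_heterogeneous" and relmat is None:
        raise ValueError("kin_heterogeneous level requires a relatedness matrix")

    F, T = panel.n_families, panel.n_days
    season = _weekly_multipliers(panel)
    gamma = guest_report_factor(panel)

    o = panel.o.astype(bool)
    go = panel.guest_only.astype(bool)
    # seasonal/reporting-weighted exposure per cell: expected events given a
    # unit underlying rate
    cell_weight = season[None, None, :] * np.where(go, gamma, 1.0) * o
    exposure = cell_weight.sum(axis=2)  # (F, F)
    events = panel.h.sum(axis=2).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        lam_pair = np.where(exposure > 0, events / exposure, 0.0)

    if level == "full_heterogeneous":
        lam = lam_pair
    elif level == "kin_heterogeneous":
        r_round = np.round(relmat.r, kin_round)
        lam = np.zeros((F, F))
        for i in range(F):
            for stratum in np.unique(r_round[i]):
                sel = (r_round[i] == stratum)
                sel[i] = False
                ev, ex = events[i, sel].sum(), exposure[i, sel].sum()
                lam[i, sel] = ev / ex if ex > 0 else 0.0
    else:  # homogeneous
        lam = np.zeros((F, F))
        for i in range(F):
            sel = np.ones(F, bool)
            sel[i] = False
            ev, ex = events[i, sel].sum(), exposure[i, sel].sum()
            lam[i, sel] = ev / ex if ex > 0 else 0.0
    np.fill_diagonal(lam, 0.0)

    # calibrate per-host activity rate alpha so the expected number of
    # observed party days matches the data; theta = lam / alpha
    party_days = (panel.h.sum(axis=1) > 0).sum(axis=1).astype(float)  # (F,)
    alpha = np.zeros(F)
    max_season = season.max()
    for i in range(F):
        if party_days[i] == 0 or lam[i].max() <= 0:
            continue
        lo = max(lam[i].max(), 1e-9)  # theta <= 1
        hi = min(1.0 / max_season, 1.0)
        if lo >= hi:
            alpha[i] = lo
            continue

        obs_w = np.where(go[i], gamma, 1.0) * o[i]  # (F, T)

        def expected_party_days(a: float) -> float:
            theta_i = np.minimum(lam[i] / a, 1.0)
            # P(no observed guest on day t)
            p_cell = np.minimum(theta_i[:, None] * obs_w, 1.0)
            log_none = np.log1p(-np.minimum(p_cell, 1 - 1e-12)).sum(axis=0)
            p_active = np.minimum(a * season, 1.0)
            return float((p_active * (1.0 - np.exp(log_none))).sum())

        f_lo, f_hi = expected_party_days(lo), expected_party_days(hi)
        if party_days[i] <= f_lo:
            alpha[i] = lo
        elif party_days[i] >= f_hi:
            alpha[i] = hi
        else:
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if expected_party_days(mid) < party_days[i]:
                    lo = mid
                else:
                    hi = mid
            alpha[i] = 0.5 * (lo + hi)

    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(alpha[:, None] > 0,
                         np.minimum(lam / np.maximum(alpha[:, None], 1e-12), 1.0),
                         0.0)
    np.fill_diagonal(theta, 0.0)
    return NullParams(level=level, family_ids=list(panel.family_ids),
                      alpha=alpha, theta=theta, season=season,
                      guest_factor=gamma, lam=lam)


def sample_null(params: NullParams, o_mask: np.ndarray,
                guest_only: np.ndarray, n_realizations: int,
                seed: int = 0, batch: int = 100) -> np.ndarray:
    """Draw an ensemble of simulated hosting panels under the null.

    Each realization samples days i.i.d. (activity x independent guest
    inclusion), thins events on guest-only cells by the reporting factor, and
    windows by the true observation mask.  Returns uint8 (R, F, F, T).
    """
    rng = np.random.default_rng(seed)
    F, _, T = o_mask.shape
    o = o_mask.astype(bool)
    go = guest_only.astype(bool)
    p_active = np.minimum(params.alpha[:, None] * params.season[None, :], 1.0)
    keep_prob = np.where(go, params.guest_factor, 1.0) * o

    out = np.empty((n_realizations, F, F, T), dtype=np.uint8)
    done = 0
    while done < n_realizations:
        nb = min(batch, n_realizations - done)
        active = rng.random((nb, F, 1, T)) < p_active[None, :, None, :]
        join = rng.random((nb, F, F, T)) < params.theta[None, :, :, None]
        keep = rng.random((nb, F, F, T)) < keep_prob[None, :, :, :]
        out[done:done + nb] = (active & join & keep).astype(np.uint8)
        done += nb
    return out


def null_margins(params: NullParams, o_mask: np.ndarray,
                 guest_only: np.ndarray) -> dict:
    """Expected preserved margins under the fitted null (for moment checks)."""
    o = o_mask.astype(bool)
    go = guest_only.astype(bool)
    keep = np.where(go, params.guest_factor, 1.0) * o
    p_active = np.minimum(params.alpha[:, None] * params.season[None, :], 1.0)
    # expected observed events per cell
    p_cell = p_active[:, None, :] * params.theta[:, :, None] * keep
    # expected observed party days per host
    log_none = np.log1p(-np.minimum(params.theta[:, :, None] * keep, 1 - 1e-12)
                        ).sum(axis=1)
    party_days = (p_active * (1.0 - np.exp(log_none))).sum(axis=1)
    return {
        "events_per_pair": p_cell.sum(axis=2),
        "party_days_per_host": party_days,
        "events_per_host": p_cell.sum(axis=(1, 2)),
    }


# ---------------------------------------------------------------------------
# Class-averaged curves
# ---------------------------------------------------------------------------

@dataclass
class ReciprocityCurve:
    """Class-averaged, null-renormalized reciprocity versus lag."""

    class_label: str
    null_level: str
    lags: tuple[int, ...]
    observed: np.ndarray  # renormalized class average per lag
    null_mean: np.ndarray
    lo1: np.ndarray
    hi1: np.ndarray
    lo2: np.ndarray
    hi2: np.ndarray
    p_per_lag: np.ndarray
    pooled_observed: float  # <= 3-day pooled statistic
    pooled_p: float
    n_pairs: int
    n_dropped: int = 0
    #: distribution of the pooled statistic over the null ensemble
    null_pooled_mean: float = np.nan
    null_pooled_sd: float = np.nan
    null_pooled_stats: np.ndarray | None = None


def class_members(panel: EventPanel, relmat: RelatednessMatrix,
                  class_label: str, lags=DEFAULT_LAGS,
                  kin_threshold: float = KIN_THRESHOLD) -> np.ndarray:
    """Ordered pairs with observed reciprocity in the given class.

    Membership requires events in both directions over the sample and joint
    observability at some lag.
    """
    counts = _stacked_counts(panel.h, panel.o, lags)
    ev = panel.h.sum(axis=2)
    both = (ev > 0) & (ev.T > 0)
    observable = counts["oo"].sum(axis=2) > 0
    member = both & observable
    np.fill_diagonal(member, False)
    close = relmat.r >= kin_threshold
    if class_label == "close_kin":
        member &= close
    elif class_label == "not_close_kin":
        member &= ~close
    elif class_label != "all":
        raise ValueError(f"unknown class {class_label!r}")
    return member


def class_curve(panel: EventPanel, ensemble: np.ndarray,
                relmat: RelatednessMatrix, class_label: str,
                lags=DEFAULT_LAGS, null_level: str = "full_heterogeneous",
                kin_threshold: float = KIN_THRESHOLD,
                pooled_lags: tuple[int, ...] = POOLED_LAGS) -> ReciprocityCurve:
    """Class-averaged reciprocity with null-ensemble renormalization.

    Every pair's observed R-hat is divided by that pair's null-ensemble mean
    before averaging over the class; the same statistic computed on each null
    realization yields the 1 and 2 sigma bands and one-sided upper-tail
    p-values (add-one estimator).
    """
    lags = tuple(lags)
    member = class_members(panel, relmat, class_label, lags, kin_threshold)
    if not member.any():
        raise ValueError(f"class {class_label!r} has no member pairs")
    ii, jj = np.nonzero(member)
    R = ensemble.shape[0]

    obs_counts = _stacked_counts(panel.h, panel.o, lags)
    obs_r = _rhat_from_stacks(obs_counts)[ii, jj]  # (P, L)

    # pooled observed per pair
    pool_sel = np.isin(np.array(lags), pooled_lags)

    def pooled_from(c: dict[str, np.ndarray], i_idx, j_idx) -> np.ndarray:
        out = {}
        for k, v in c.items():
            out[k] = v[i_idx, j_idx][:, pool_sel].sum(axis=1, keepdims=True)
        return _rhat_from_stacks(out)[:, 0]

    obs_pooled = pooled_from(obs_counts, ii, jj)

    null_r = np.empty((R, len(ii), len(lags)))
    null_pooled = np.empty((R, len(ii)))
    for r_idx in range(R):
        c = _stacked_counts(ensemble[r_idx], panel.o, lags)
        null_r[r_idx] = _rhat_from_stacks(c)[ii, jj]
        null_pooled[r_idx] = pooled_from(c, ii, jj)

    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="Mean of empty slice")
        null_mean_pair = np.nanmean(null_r, axis=0)  # (P, L)
        null_mean_pooled = np.nanmean(null_pooled, axis=0)  # (P,)

    # drop pairs whose pooled null mean is undefined or zero
    valid = np.isfinite(null_mean_pooled) & (null_mean_pooled > 0) \
        & np.isfinite(obs_pooled)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("class %s: dropped %d/%d pairs with undefined null mean",
                    class_label, n_dropped, len(ii))
    if not valid.any():
        raise ValueError(f"class {class_label!r}: no pair has a defined null mean")

    with np.errstate(invalid="ignore", divide="ignore"), \
            _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="Mean of empty slice")
        renorm_obs = obs_r / null_mean_pair
        renorm_null = null_r / null_mean_pair[None, :, :]
        observed_curve = np.nanmean(renorm_obs, axis=0)
        null_curves = np.nanmean(renorm_null, axis=1)  # (R, L)

        pooled_obs_stat = float(np.mean(obs_pooled[valid] / null_mean_pooled[valid]))
        pooled_null_stat = np.nanmean(
            null_pooled[:, valid] / null_mean_pooled[None, valid], axis=1
        )

    with _warnings.catch_warnings():
        # lags with no jointly-observable day pairs are legitimately all-NaN
        _warnings.filterwarnings("ignore", message="All-NaN slice")
        _warnings.filterwarnings("ignore", message="Mean of empty slice")
        q = np.nanquantile
        lo1 = q(null_curves, 0.1587, axis=0)
        hi1 = q(null_curves, 0.8413, axis=0)
        lo2 = q(null_curves, 0.0228, axis=0)
        hi2 = q(null_curves, 0.9772, axis=0)
        null_mean_curve = np.nanmean(null_curves, axis=0)

    with np.errstate(invalid="ignore"):
        p_per_lag = (
            1 + np.nansum(null_curves >= observed_curve[None, :], axis=0)
        ) / (R + 1)
    pooled_p = float(
        (1 + np.sum(pooled_null_stat[np.isfinite(pooled_null_stat)]
                    >= pooled_obs_stat)) / (R + 1)
    )

    return ReciprocityCurve(
        class_label=class_label, null_level=null_level, lags=lags,
        observed=observed_curve, null_mean=null_mean_curve,
        lo1=lo1, hi1=hi1, lo2=lo2, hi2=hi2, p_per_lag=p_per_lag,
        pooled_observed=pooled_obs_stat, pooled_p=pooled_p,
        n_pairs=int(valid.sum()), n_dropped=n_dropped,
        null_pooled_mean=float(np.nanmean(pooled_null_stat)),
        null_pooled_sd=float(np.nanstd(pooled_null_stat)),
        null_pooled_stats=pooled_null_stat,
    )


def curve_to_frame(curve: ReciprocityCurve):
    """Tidy export of a curve (one row per lag)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "class": curve.class_label,
            "null_level": curve.null_level,
            "lag": list(curve.lags),
            "observed": curve.observed,
            "null_mean": curve.null_mean,
            "lo1": curve.lo1,
            "hi1": curve.hi1,
            "lo2": curve.lo2,
            "hi2": curve.hi2,
            "p": curve.p_per_lag,
        }
    )
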