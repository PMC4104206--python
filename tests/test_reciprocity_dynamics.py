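"""The conditional-action reciprocity estimator, its brute-force oracle,
and the stationary null hierarchy."""

import itertools

import numpy as np
import pytest

from dyadrecip.io_model import EventPanel
from dyadrecip.kinship_space import RelatednessMatrix
from dyadrecip.reciprocity_dynamics import (
    NULL_LEVELS,
    PairCounts,
    class_curve,
    class_members,
    fit_null,
    guest_report_factor,
    null_margins,
    pair_counts,
    pooled_rhat,
    rhat,
    sample_null,
)

from conftest import random_small_panel


def panel_from_bits(h01, o01, h10, o10):
    """Two-family panel from explicit bit strings."""
    T = len(h01)
    h = np.zeros((2, 2, T), np.uint8)
    o = np.zeros((2, 2, T), np.uint8)
    h[0, 1] = list(h01)
    o[0, 1] = list(o01)
    h[1, 0] = list(h10)
    o[1, 0] = list(o10)
    return EventPanel(["A", "B"], h=h, o=o, guest_only=np.zeros_like(o))


class TestPairCounts:
    def test_full_observation_adjacent_day_pairs(self):
        T = 10
        ones = [1] * T
        panel = panel_from_bits([0] * T, ones, [0] * T, ones)
        c = pair_counts(panel, 0, 1, lags=[1])
        assert c.n_oo[0] == 9

    def test_hand_enumerated_toy_panel(self):
        # 4 days: A hosts B on days 0, 2; B hosts A on day 1; partial windows
        panel = panel_from_bits(
            h01=[1, 0, 1, 0], o01=[1, 1, 1, 0],
            h10=[0, 1, 0, 0], o10=[1, 1, 1, 1],
        )
        c = pair_counts(panel, 0, 1, lags=[1, 2])
        # lag 1 pairs (t, t+1): hh: (0,1) -> 1; oo: (0,1),(1,2),(2,3) -> 3
        # ho: h01 at 0,2 with o10 at 1,3 -> 2; oh: o01 at 0 with h10 at 1 -> 1
        assert (c.n_hh[0], c.n_oo[0], c.n_ho[0], c.n_oh[0]) == (1, 3, 2, 1)
        # lag 2: hh: none; oo: (0,2),(1,3) -> 2; ho: (0,2),(2,... ) h at 0 o at 2,
        # h at 2 o at 4(x) -> 1; oh: o01 at 0.. h10 at 1 matches lag 2 from t=-1(x) -> 0
        assert (c.n_hh[1], c.n_oo[1], c.n_ho[1], c.n_oh[1]) == (0, 2, 1, 0)

    def test_saturated_panel_counts_equal(self):
        T = 7
        ones = [1] * T
        panel = panel_from_bits(ones, ones, ones, ones)
        c = pair_counts(panel, 0, 1, lags=[1, 2, 3])
        assert np.all(c.n_hh == c.n_oo)
        assert np.all(c.n_ho == c.n_oo)
        assert np.all(c.n_oh == c.n_oo)

    def test_invalid_count_ordering_rejected(self):
        with pytest.raises(ValueError, match="N_hh"):
            PairCounts(lags=(1,), n_hh=[3], n_oo=[5], n_ho=[2], n_oh=[2])

    def test_same_pair_rejected(self):
        panel = panel_from_bits([0], [1], [0], [1])
        with pytest.raises(ValueError):
            pair_counts(panel, 0, 0, lags=[1])


class TestRhat:
    def test_direct_arithmetic(self):
        c = PairCounts(lags=(1,), n_hh=[2], n_oo=[100], n_ho=[10], n_oh=[10])
        assert rhat(c)[0] == pytest.approx(2.0)

    def test_undefined_denominator_is_missing(self):
        c = PairCounts(lags=(1,), n_hh=[0], n_oo=[50], n_ho=[0], n_oh=[5])
        assert np.isnan(rhat(c)[0])

    def test_independent_coin_flips_converge_to_one(self):
        rng = np.random.default_rng(0)
        T = 40_000
        h01 = (rng.random(T) < 0.3).astype(np.uint8)
        h10 = (rng.random(T) < 0.2).astype(np.uint8)
        panel = panel_from_bits(h01, [1] * T, h10, [1] * T)
        c = pair_counts(panel, 0, 1, lags=[1, 2])
        assert np.allclose(rhat(c), 1.0, atol=0.05)

    def test_brute_force_conditional_probability_oracle(self):
        """On fully-observed panels R-hat must equal the directly counted
        P(j hosts i at t+lag | i hosts j at t) / P(j hosts i), exhaustively
        over all short binary histories."""
        for T in (4, 5):
            for bits in itertools.product([0, 1], repeat=2 * T):
                h01 = np.array(bits[:T], np.uint8)
                h10 = np.array(bits[T:], np.uint8)
                panel = panel_from_bits(h01, [1] * T, h10, [1] * T)
                c = pair_counts(panel, 0, 1, lags=[1])
                est = rhat(c)[0]
                # oracle: direct conditional frequency over day pairs
                n_cond = h01[:-1].sum()  # windows where "A hosts B" at t
                n_joint = int((h01[:-1] * h10[1:]).sum())
                n_base = h10[1:].sum()  # "B hosts A" events in lagged window
                if n_cond == 0 or n_base == 0:
                    assert np.isnan(est)
                else:
                    oracle = (n_joint / n_cond) / (n_base / (T - 1))
                    assert est == pytest.approx(oracle)

    def test_windowed_counts_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            T = 6
            o01 = rng.integers(0, 2, T)
            o10 = rng.integers(0, 2, T)
            h01 = rng.integers(0, 2, T) & o01
            h10 = rng.integers(0, 2, T) & o10
            panel = panel_from_bits(h01, o01, h10, o10)
            for lag in (1, 2, 3):
                c = pair_counts(panel, 0, 1, lags=[lag])
                pairs = [(t, t + lag) for t in range(T - lag)]
                assert c.n_hh[0] == sum(h01[a] * h10[b] for a, b in pairs)
                assert c.n_oo[0] == sum(o01[a] * o10[b] for a, b in pairs)
                assert c.n_ho[0] == sum(h01[a] * o10[b] for a, b in pairs)
                assert c.n_oh[0] == sum(o01[a] * h10[b] for a, b in pairs)


class TestPooledRhat:
    def test_identical_per_lag_counts_equal_pooled(self):
        c = PairCounts(lags=(1, 2, 3), n_hh=[2] * 3, n_oo=[100] * 3,
                       n_ho=[10] * 3, n_oh=[10] * 3)
        assert pooled_rhat(c) == pytest.approx(rhat(c)[0])

    def test_pooled_matches_brute_force_summed_counts(self):
        rng = np.random.default_rng(9)
        o = np.ones(9, np.uint8)
        h01 = rng.integers(0, 2, 9).astype(np.uint8)
        h10 = rng.integers(0, 2, 9).astype(np.uint8)
        panel = panel_from_bits(h01, o, h10, o)
        c = pair_counts(panel, 0, 1, lags=[1, 2, 3])
        manual = {k: 0 for k in ("hh", "oo", "ho", "oh")}
        for lag in (1, 2, 3):
            for t in range(9 - lag):
                manual["hh"] += h01[t] * h10[t + lag]
                manual["oo"] += 1
                manual["ho"] += h01[t]
                manual["oh"] += h10[t + lag]
        expected = (manual["hh"] * manual["oo"]) / (manual["ho"] * manual["oh"])
        assert pooled_rhat(c) == pytest.approx(expected)

    def test_zero_joint_hosting_gives_zero(self):
        c = PairCounts(lags=(1, 2, 3), n_hh=[0] * 3, n_oo=[30] * 3,
                       n_ho=[3] * 3, n_oh=[2] * 3)
        assert pooled_rhat(c) == 0.0


@pytest.fixture(scope="module")
def fitted_panel():
    """A small simulated panel plus relatedness, for null-model tests."""
    from dyadrecip.io_model import build_panel, reconcile_reports
    from dyadrecip.kinship_space import Pedigree, family_relatedness
    from dyadrecip.synthetic_data import SimParams, simulate_study

    params = SimParams(n_families=12, n_days=56, seed=21)
    village, gt, true_events, records = simulate_study(params)
    events = reconcile_reports(records, seed=21)
    panel = build_panel(village, records, events)
    relmat = family_relatedness(Pedigree(village.individuals), village)
    return panel, relmat


class TestFitNull:
    def test_unknown_level_rejected(self, fitted_panel):
        panel, relmat = fitted_panel
        with pytest.raises(ValueError, match="unknown null level"):
            fit_null(panel, relmat, "bogus")

    def test_full_heterogeneous_preserves_pair_margins_exactly(self, fitted_panel):
        panel, relmat = fitted_panel
        params = fit_null(panel, relmat, "full_heterogeneous")
        margins = null_margins(params, panel.o, panel.guest_only)
        assert np.allclose(margins["events_per_pair"], panel.h.sum(axis=2),
                           atol=1e-8)

    def test_homogeneous_daily_host_of_size_two(self):
        # family A hosts a party of exactly 2 guests every day, all observed
        F, T = 4, 8
        h = np.zeros((F, F, T), np.uint8)
        o = np.ones((F, F, T), np.uint8)
        idx = np.arange(F)
        o[idx, idx] = 0
        h[0, 1, :] = 1
        h[0, 2, :] = 1
        panel = EventPanel([f"F{k}" for k in range(F)], h=h, o=o,
                           guest_only=np.zeros_like(o))
        params = fit_null(panel, None, "homogeneous")
        assert params.alpha[0] == pytest.approx(1.0, abs=1e-6)
        # mean party size preserved: 2 guests across 3 eligible
        assert params.theta[0, 1:].sum() == pytest.approx(2.0, rel=1e-6)

    def test_kin_single_stratum_collapses_to_homogeneous(self, fitted_panel):
        panel, _ = fitted_panel
        F = panel.n_families
        flat = RelatednessMatrix(panel.family_ids, np.zeros((F, F)))
        kin = fit_null(panel, flat, "kin_heterogeneous")
        hom = fit_null(panel, flat, "homogeneous")
        assert np.allclose(kin.theta, hom.theta)
        assert np.allclose(kin.alpha, hom.alpha)

    def test_null_hierarchy_margin_nesting(self, fitted_panel):
        """Each stricter level reproduces every margin of the weaker ones:
        per-pair margins aggregate to per-stratum margins aggregate to
        per-host margins."""
        panel, relmat = fitted_panel
        fits = {lv: fit_null(panel, relmat, lv) for lv in NULL_LEVELS}
        m = {lv: null_margins(fits[lv], panel.o, panel.guest_only)
             for lv in NULL_LEVELS}
        obs_host = panel.h.sum(axis=(1, 2))
        for lv in NULL_LEVELS:
            assert np.allclose(m[lv]["events_per_host"], obs_host, atol=1e-6)
        r_round = np.round(relmat.r, 3)
        full, kin = m["full_heterogeneous"], m["kin_heterogeneous"]
        for i in range(panel.n_families):
            for stratum in np.unique(r_round[i]):
                sel = r_round[i] == stratum
                sel[i] = False
                assert full["events_per_pair"][i, sel].sum() == pytest.approx(
                    kin["events_per_pair"][i, sel].sum(), abs=1e-6)


class TestSampleNull:
    def test_empty_mask_empty_panels(self, fitted_panel):
        panel, relmat = fitted_panel
        params = fit_null(panel, relmat, "homogeneous")
        ens = sample_null(params, np.zeros_like(panel.o),
                          np.zeros_like(panel.guest_only), 5, seed=0)
        assert ens.sum() == 0

    def test_seed_reproducibility(self, fitted_panel):
        panel, relmat = fitted_panel
        params = fit_null(panel, relmat, "full_heterogeneous")
        e1 = sample_null(params, panel.o, panel.guest_only, 3, seed=11)
        e2 = sample_null(params, panel.o, panel.guest_only, 3, seed=11)
        assert np.array_equal(e1, e2)

    @pytest.mark.parametrize("level", NULL_LEVELS)
    def test_moments_match_small_ensemble(self, fitted_panel, level):
        """Simulated totals track the fitted expectations (light version of
        the moment-preservation acceptance check)."""
        panel, relmat = fitted_panel
        params = fit_null(panel, relmat, level)
        n_real = 150
        ens = sample_null(params, panel.o, panel.guest_only, n_real, seed=3)
        m = null_margins(params, panel.o, panel.guest_only)
        exp_total = m["events_per_pair"].sum()
        sim_total = ens.sum() / n_real
        sd = np.sqrt(exp_total / n_real)
        assert abs(sim_total - exp_total) < 4 * sd


class TestClassCurve:
    def test_empty_class_errors(self, fitted_panel):
        panel, relmat = fitted_panel
        F = panel.n_families
        # force an empty close-kin class
        flat = RelatednessMatrix(panel.family_ids, np.zeros((F, F)))
        params = fit_null(panel, flat, "homogeneous")
        ens = sample_null(params, panel.o, panel.guest_only, 20, seed=0)
        with pytest.raises(ValueError, match="close_kin"):
            class_curve(panel, ens, flat, "close_kin", lags=range(1, 5))

    def test_membership_requires_bidirectional_events(self, fitted_panel):
        panel, relmat = fitted_panel
        member = class_members(panel, relmat, "all")
        ev = panel.h.sum(axis=2)
        ii, jj = np.nonzero(member)
        assert len(ii) > 0
        assert np.all(ev[ii, jj] > 0)
        assert np.all(ev[jj, ii] > 0)

    def test_single_pair_with_missing_lag_no_crash(self):
        # one pair, observable only at lag 1; events both directions
        panel = panel_from_bits(
            h01=[1, 0, 0, 0], o01=[1, 1, 0, 0],
            h10=[0, 1, 0, 0], o10=[1, 1, 0, 0],
        )
        flat = RelatednessMatrix(["A", "B"], np.zeros((2, 2)))
        params = fit_null(panel, flat, "full_heterogeneous")
        ens = sample_null(params, panel.o, panel.guest_only, 50, seed=1)
        curve = class_curve(panel, ens, flat, "all", lags=range(1, 4))
        assert np.isnan(curve.observed[2])  # lag 3 unobservable -> missing
        assert 0 < curve.pooled_p <= 1.0

    def test_bands_nested_and_p_in_range(self, fitted_panel):
        panel, relmat = fitted_panel
        params = fit_null(panel, relmat, "full_heterogeneous")
        ens = sample_null(params, panel.o, panel.guest_only, 60, seed=5)
        curve = class_curve(panel, ens, relmat, "all", lags=range(1, 8))
        ok = np.isfinite(curve.lo1)
        assert np.all(curve.lo2[ok] <= curve.lo1[ok])
        assert np.all(curve.hi1[ok] <= curve.hi2[ok])
        assert 0 < curve.pooled_p <= 1
        assert np.all((curve.p_per_lag > 0) & (curve.p_per_lag <= 1))


class TestGuestReportFactor:
    def test_unbiased_reporting_gives_one(self):
        rng = np.random.default_rng(2)
        panel = random_small_panel(rng, n_families=4, n_days=30)
        # force equal rates on both strata: h everywhere o is
        panel.h = panel.o.copy()
        assert guest_report_factor(panel) == 1.0
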