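"""Robust IRLS fits, group t-maps, FDR, peaks, effect sizes, scoring."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from trialwise import (
    BetaMap,
    DataError,
    DesignError,
    ParameterError,
    build_design,
    fdr_bh,
    find_peak,
    fit_subject_maps,
    group_onesample_map,
    hedges_g,
    irls_fit,
    read_betamap,
    score_questionnaire,
    write_betamap,
)

from conftest import make_epochs


def brute_force_bh(p, alpha):
    """Independent oracle: literal step-up definition of Benjamini-Hochberg."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    sorted_p = p[order]
    below = sorted_p <= alpha * (np.arange(1, m + 1) / m)
    reject = np.zeros(m, bool)
    if below.any():
        k = np.nonzero(below)[0].max()
        reject[order[: k + 1]] = True
    crit = sorted_p[below].max() if below.any() else 0.0
    return reject, float(crit)


class TestIRLS:
    def test_clean_gaussian_matches_ols(self, rng):
        # bisquare trimming of Gaussian tails makes the robust and OLS
        # estimators differ by O(sqrt(1/efficiency - 1)) ~ 0.23 standard
        # errors; equivalence means the difference stays within the
        # coefficient's own statistical uncertainty
        X = np.column_stack([np.ones(100), rng.normal(size=100), rng.normal(size=100)])
        y = X @ [1.0, 2.0, -0.5] + rng.normal(size=100)
        b, diag = irls_fit(y, X)
        b_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ b_ols
        se = np.sqrt(resid @ resid / 97 * np.diag(np.linalg.inv(X.T @ X)))
        assert np.all(np.abs(b - b_ols) < se)
        assert diag["converged"]

    def test_matches_statsmodels_rlm_oracle(self, rng):
        X = np.column_stack([np.ones(80), rng.normal(size=80), rng.normal(size=80)])
        y = X @ [1.0, 2.0, -0.5] + rng.standard_t(3, 80)
        b, _ = irls_fit(y, X)
        oracle = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(4.685)).fit().params
        assert np.abs(b - oracle).max() < 1e-4

    def test_unit_weights_reproduce_ols_exactly(self, rng):
        # with an effectively infinite tuning constant every weight is 1,
        # and the weighted solve must reproduce OLS to machine precision
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        y = X @ [1.0, 2.0] + rng.normal(size=50)
        b, diag = irls_fit(y, X, tuning=1e9)
        b_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(b, b_ols, atol=1e-10)
        assert np.allclose(diag["weights"], 1.0)

    def test_exact_linear_data_interpolated(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = X @ [2.0, -3.0]
        b, diag = irls_fit(y, X)
        np.testing.assert_allclose(b, [2.0, -3.0], atol=1e-10)
        assert diag["converged"]

    def test_outliers_downweighted_to_zero(self, rng):
        X = np.column_stack([np.ones(60), rng.normal(size=60)])
        y = X @ [1.0, 1.0] + 0.5 * rng.normal(size=60)
        y[:3] += 100
        b, diag = irls_fit(y, X)
        assert np.all(diag["weights"][:3] == 0.0)
        assert np.abs(b - [1.0, 1.0]).max() < 0.3

    def test_rank_deficient_names_columns(self, rng):
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, 2 * x])
        with pytest.raises(DesignError, match="rank deficient"):
            irls_fit(rng.normal(size=50), X)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(DesignError, match="rows"):
            irls_fit(np.zeros(6), np.column_stack([np.ones(6), np.arange(6)]))


class TestSubjectMaps:
    def test_trial_shuffle_exchangeable(self, rng):
        from trialwise import simulate_gonogo_events
        from trialwise.cohort import ComponentSpec, NoiseModel, synthesize_epochs

        ev = simulate_gonogo_events(40, seed=0)
        ep = synthesize_epochs(ev, 1.0, 2.0, ComponentSpec("Cz", 360.0),
                               NoiseModel(sd=2.0, outlier_rate=0.0), seed=1)
        d = build_design(ep.trial_table, "gonogo")
        bmap = fit_subject_maps(ep, d)
        perm = rng.permutation(ep.n_trials)
        ep2 = make_epochs(ep.data[perm], fs=ep.fs, channels=ep.channels,
                          table=ep.trial_table.iloc[perm].reset_index(drop=True))
        bmap2 = fit_subject_maps(ep2, build_design(ep2.trial_table, "gonogo"))
        np.testing.assert_allclose(bmap.b, bmap2.b, atol=1e-8)

    def test_betamap_bundle_round_trip(self, tmp_path, rng):
        bmap = BetaMap(rng.normal(size=(3, 5, 2)).astype("<f4"), ["a", "b", "c"],
                       np.arange(5.0), ["intercept", "x"], subject="s1", task="gonogo")
        write_betamap(bmap, tmp_path / "bm")
        back = read_betamap(tmp_path / "bm")
        np.testing.assert_array_equal(back.b, bmap.b)
        assert back.regressors == ["intercept", "x"] and back.subject == "s1"


def null_maps(rng, n_subj=8, n_ch=2, n_t=10, effect=None, cell=None):
    maps = []
    for s in range(n_subj):
        b = rng.normal(size=(n_ch, n_t, 1))
        if effect is not None:
            b[cell[0], cell[1], 0] += effect
        maps.append(BetaMap(b, [f"c{i}" for i in range(n_ch)],
                            np.arange(n_t, dtype=float), ["x"], subject=f"s{s}"))
    return maps


class TestGroupMap:
    def test_df_is_subjects_minus_one(self, rng):
        g = group_onesample_map(null_maps(rng, n_subj=205), "x")
        assert g.df == 204

    def test_zero_variance_constant_beta_certain(self, rng):
        maps = [BetaMap(np.full((2, 3, 1), 0.7), ["a", "b"], np.arange(3.0), ["x"])
                for _ in range(6)]
        g = group_onesample_map(maps, "x", alpha=0.025)
        # identical b across subjects: certainty (t may be astronomically
        # large but finite when float cancellation leaves a ~1e-17 SD)
        assert (np.abs(g.t) > 1e10).all() and (g.p < 1e-60).all() and g.significant.all()

    def test_grid_mismatch_rejected(self, rng):
        maps = null_maps(rng)
        maps[3] = BetaMap(rng.normal(size=(3, 10, 1)), ["a", "b", "c"],
                          np.arange(10.0), ["x"])
        with pytest.raises(DataError, match="grids"):
            group_onesample_map(maps, "x")

    def test_significance_flag_consistent_with_critical_p(self, rng):
        maps = null_maps(rng, n_subj=12, n_ch=4, n_t=30, effect=3.0, cell=(1, 7))
        g = group_onesample_map(maps, "x", alpha=0.025)
        np.testing.assert_array_equal(g.significant, g.p <= max(g.critical_p, 0))
        assert g.critical_p <= g.alpha


class TestFDR:
    def test_spec_example(self):
        reject, crit = fdr_bh([0.001, 0.02, 0.8], alpha=0.025)
        np.testing.assert_array_equal(reject, [True, False, False])
        assert crit == 0.001

    def test_all_ones_no_rejection(self):
        reject, crit = fdr_bh(np.ones(50), alpha=0.025)
        assert not reject.any() and crit == 0.0

    def test_monotone_in_alpha(self, rng):
        p = rng.random(200)
        r1, _ = fdr_bh(p, 0.01)
        r2, _ = fdr_bh(p, 0.05)
        assert np.all(r2 | ~r1)  # rejections grow with alpha

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60),
           st.floats(0.001, 0.2))
    def test_matches_bruteforce_oracle(self, pvals, alpha):
        reject, crit = fdr_bh(pvals, alpha)
        exp_reject, exp_crit = brute_force_bh(pvals, alpha)
        np.testing.assert_array_equal(reject, exp_reject)
        assert np.isclose(crit, exp_crit)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            fdr_bh([], 0.025)


class TestPeaks:
    def test_planted_peak_located(self, rng):
        maps = null_maps(rng, n_subj=20, n_ch=4, n_t=30, effect=4.0, cell=(2, 11))
        g = group_onesample_map(maps, "x")
        pk = find_peak(g, ["c0", "c1", "c2", "c3"], (0.0, 29.0), "positive")
        assert pk.found and pk.electrode == "c2" and pk.time_ms == 11.0
        for field in ("beta", "t", "p", "critical_p", "ci_low", "ci_high", "ci_level", "g"):
            assert getattr(pk, field) is not None
        assert pk.ci_low < pk.beta < pk.ci_high
        assert np.isclose(pk.ci_level, 100 * (1 - g.critical_p))

    def test_no_significant_cell_gives_no_peak(self, rng):
        maps = null_maps(rng, n_subj=5, n_ch=2, n_t=5)
        g = group_onesample_map(maps, "x", alpha=0.025)
        if g.significant.any():  # pure null: nearly always empty
            pytest.skip("null draw produced rejections")
        pk = find_peak(g, ["c0", "c1"], (0.0, 4.0))
        assert not pk.found and pk.electrode is None

    def test_polarity_restricts_sign(self, rng):
        maps = null_maps(rng, n_subj=20, n_ch=2, n_t=10, effect=-4.0, cell=(0, 3))
        g = group_onesample_map(maps, "x")
        assert not find_peak(g, ["c0", "c1"], (0.0, 9.0), "positive").found
        pk = find_peak(g, ["c0", "c1"], (0.0, 9.0), "negative")
        assert pk.found and pk.t < 0


class TestHedgesG:
    @pytest.mark.parametrize("t,n,expected", [(27.74, 205, 1.93), (23.49, 205, 1.63)])
    def test_reference_values(self, t, n, expected):
        assert round(hedges_g(t, n), 2) == expected

    def test_zero_t_zero_g(self):
        assert hedges_g(0.0, 50) == 0.0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(0.01, 50), st.integers(3, 500))
    def test_odd_and_increasing_in_t(self, t, n):
        assert hedges_g(-t, n) == -hedges_g(t, n)
        assert hedges_g(t + 0.5, n) > hedges_g(t, n)

    def test_small_n_rejected(self):
        with pytest.raises(ParameterError):
            hedges_g(1.0, 1)


class TestQuestionnaires:
    @pytest.mark.parametrize("items,scale,expected", [
        ([4] * 12, "nu", 48),
        ([0] * 18, "ocir", 0),
        ([4] * 18, "ocir", 72),
    ])
    def test_sum_scores(self, items, scale, expected):
        assert score_questionnaire(items, scale) == expected

    def test_out_of_range_item_named(self):
        items = [2] * 12
        items[7] = 5
        with pytest.raises(DataError, match="item 7"):
            score_questionnaire(items, "nu")

    def test_wrong_length_rejected(self):
        with pytest.raises(DataError):
            score_questionnaire([1] * 11, "nu")
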