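"""Moderated brain-brain regression, Johnson-Neyman, residualisation."""

import numpy as np
import pytest
from scipy import stats

from trialwise import (
    BetaMap,
    DataError,
    DesignError,
    ParameterError,
    fit_moderated_map,
    jn_points,
    mask_map,
    residualize,
    window_score,
)


def beta_map_from_values(values, times=None, channel="Pz", subject=None):
    """1-channel BetaMap whose single regressor holds the given time course."""
    values = np.asarray(values, float)
    times = np.asarray(times if times is not None else np.arange(values.size), float)
    return BetaMap(values.reshape(1, -1, 1), [channel], times, ["valence"], subject=subject)


class TestWindowScore:
    def test_constant_returns_constant(self):
        bm = beta_map_from_values(np.full(20, 2.5))
        assert window_score(bm, "Pz", (5, 10), "valence").value == 2.5

    def test_pz_window_averages_eleven_samples_at_500hz(self):
        times = -100 + 2.0 * np.arange(401)
        vals = np.zeros(401)
        in_win = (times >= 500) & (times <= 520)
        assert in_win.sum() == 11
        vals[in_win] = np.arange(11)
        bm = beta_map_from_values(vals, times)
        assert np.isclose(window_score(bm, "Pz", (500, 520), "valence").value, np.mean(np.arange(11)))

    def test_twostep_component_window_accepted(self):
        times = -100 + 10.0 * np.arange(81)
        bm = beta_map_from_values(np.ones(81), times, channel="CP1")
        ws = window_score(bm, "CP1", (440, 460), "valence", component="p3_twostep")
        assert ws.value == 1.0 and ws.component == "p3_twostep"

    def test_missing_electrode_rejected(self):
        bm = beta_map_from_values(np.ones(10))
        with pytest.raises(DataError):
            window_score(bm, "Oz", (0, 5), "valence")


def synthetic_second_level(rng, n=60, coupling=0.5, moderation=-0.02, noise=0.05,
                           n_ch=2, n_t=6, cell=(0, 2)):
    """y maps whose planted cell follows b0 + c*x_c + g*x_c*m_c + noise."""
    x = rng.normal(4.0, 2.0, size=n)
    m = rng.normal(13.0, 9.0, size=n)
    x_c, m_c = x - x.mean(), m - m.mean()
    maps = []
    for i in range(n):
        b = rng.normal(0, noise, size=(n_ch, n_t, 1))
        b[cell] += 1.0 + coupling * x_c[i] + moderation * x_c[i] * m_c[i]
        maps.append(BetaMap(b, [f"c{j}" for j in range(n_ch)],
                            np.arange(n_t, dtype=float), ["trial_type"], subject=f"s{i}"))
    return maps, x, m


class TestModeratedFit:
    def test_recovers_planted_coefficients(self, rng):
        maps, x, m = synthetic_second_level(rng)
        fit = fit_moderated_map(maps, x, m, moderator="oci_r")
        assert fit.df == 60 - 3
        assert abs(fit.b1[0, 2] - 0.5) < 0.01
        assert abs(fit.b2[0, 2] + 0.02) < 0.002
        assert fit.p2[0, 2] < 1e-6

    def test_constant_moderator_degenerate(self, rng):
        maps, x, m = synthetic_second_level(rng, n=20)
        with pytest.raises(DesignError, match="moderator"):
            fit_moderated_map(maps, x, np.full(20, 13.0))

    def test_too_few_subjects_rejected(self, rng):
        maps, x, m = synthetic_second_level(rng, n=9)
        with pytest.raises(DataError):
            fit_moderated_map(maps, x, m)

    def test_moderator_main_effect_optional_column(self, rng):
        maps, x, m = synthetic_second_level(rng)
        fit = fit_moderated_map(maps, x, m, include_moderator_main=True)
        assert fit.df == 60 - 4
        assert abs(fit.b2[0, 2] + 0.02) < 0.002

    def test_reported_df_conventions(self, rng):
        maps, x, m = synthetic_second_level(rng, n=20)
        fit = fit_moderated_map(maps, x, m)
        assert fit.reported_df() == 17  # n - 3, used for inference
        assert fit.reported_df("n_minus_1") == 19  # echo convention only

    def test_main_effect_t_equals_jn_slope_at_mean(self, rng):
        # with centred predictors beta1 is the simple slope at the moderator
        # mean; the JN t there must reproduce the main-effect t exactly
        maps, x, m = synthetic_second_level(rng)
        fit = fit_moderated_map(maps, x, m)
        from trialwise.moderation import _slope_t

        c, t = 0, 2
        t_at_mean = _slope_t(0.0, fit.b1[c, t], fit.b2[c, t],
                             fit.cov11[c, t], fit.cov12[c, t], fit.cov22[c, t])
        assert np.isclose(t_at_mean, fit.t1[c, t], rtol=1e-12)


class TestMask:
    def test_unit_threshold_is_identity(self, rng):
        maps, x, m = synthetic_second_level(rng, n=20)
        fit = fit_moderated_map(maps, x, m)
        assert mask_map(fit, 1.0)["n_unmasked"] == fit.p2.size

    def test_all_masked_when_no_cell_passes(self, rng):
        maps, x, m = synthetic_second_level(rng, n=20, coupling=0.0, moderation=0.0,
                                            noise=1.0)
        fit = fit_moderated_map(maps, x, m)
        masked = mask_map(fit, 1e-12)
        assert masked["n_unmasked"] == 0 and np.isnan(masked["beta"]).all()

    def test_monotone_in_threshold(self, rng):
        maps, x, m = synthetic_second_level(rng)
        fit = fit_moderated_map(maps, x, m)
        counts = [mask_map(fit, p)["n_unmasked"] for p in (0.2, 0.05, 0.01, 0.001)]
        assert counts == sorted(counts, reverse=True)


def grid_scan_boundaries(b1, b2, v11, v12, v22, df, threshold, lo, hi, n=10_001):
    """Independent oracle: dense scan of the simple-slope p-value."""
    grid = np.linspace(lo, hi, n)
    slope = b1 + b2 * grid
    se = np.sqrt(v11 + 2 * grid * v12 + grid**2 * v22)
    p = 2 * stats.t.sf(np.abs(slope / se), df)
    sig = p < threshold
    flips = np.nonzero(np.diff(sig.astype(int)))[0]
    return grid[flips], sig


class TestJohnsonNeyman:
    def test_spec_constructed_case_matches_grid_scan(self):
        kw = dict(b1=1.0, b2=-0.05, cov11=0.01, cov12=0.0, cov22=0.0004, df=202)
        res = jn_points(**kw, m_mean=0.0, moderator_range=(-60, 60), threshold=0.01)
        scan, sig = grid_scan_boundaries(1.0, -0.05, 0.01, 0.0, 0.0004, 202,
                                         0.01, -60, 60, n=120_001)  # 0.001 resolution
        assert len(res.boundaries) == len(scan)
        np.testing.assert_allclose(res.boundaries, scan, atol=1.5e-3)
        # significance labels agree with the scan at a probe point
        assert res.significant_at(0.0) == sig[60_000]

    def test_zero_interaction_significant_everywhere(self):
        res = jn_points(b1=1.0, b2=0.0, cov11=0.0001, cov12=0.0, cov22=1e-12,
                        df=100, moderator_range=(0, 40), threshold=0.01)
        assert res.boundaries == []
        assert res.significant_intervals == [(0.0, 40.0)]

    def test_boundaries_reported_in_raw_units(self):
        centred = jn_points(b1=1.0, b2=-0.05, cov11=0.01, cov12=0.0, cov22=0.0004,
                            df=202, m_mean=0.0, moderator_range=(-60, 60))
        shifted = jn_points(b1=1.0, b2=-0.05, cov11=0.01, cov12=0.0, cov22=0.0004,
                            df=202, m_mean=12.6, moderator_range=(-47.4, 72.6))
        np.testing.assert_allclose(
            [b + 12.6 for b in centred.boundaries], shifted.boundaries
        )

    def test_degenerate_range_rejected(self):
        with pytest.raises(ParameterError):
            jn_points(1, 0, 1e-4, 0, 1e-4, 10, moderator_range=(5, 5))


class TestResidualize:
    def test_orthogonal_to_regressor_and_zero_mean(self, rng):
        a, b = rng.normal(size=80), rng.normal(size=80)
        r = residualize(a, b)
        assert abs(r.mean()) < 1e-14
        assert abs(r @ (b - b.mean())) < 1e-9

    def test_perfect_collinearity_gives_zeros(self):
        b = np.arange(20.0)
        np.testing.assert_allclose(residualize(2 * b, b), 0.0, atol=1e-12)

    def test_uncorrelated_traits_recover_centred_values(self, rng):
        a = rng.normal(size=500)
        b = rng.normal(size=500)
        b -= (b @ (a - a.mean())) / ((a - a.mean()) @ (a - a.mean())) * (a - a.mean())
        r = residualize(a, b)
        np.testing.assert_allclose(r, a - a.mean(), atol=1e-9)

    def test_constant_regressor_rejected(self):
        with pytest.raises(DesignError):
            residualize(np.arange(5.0), np.ones(5))

    def test_residualised_moderator_leaves_fit_unchanged_when_orthogonal(self, rng):
        # exactly uncorrelated traits: residualising m on the other trait only
        # recentres it, so the whole moderated fit is unchanged
        maps, x, m = synthetic_second_level(rng)
        other = rng.normal(size=60)
        other -= (other @ (m - m.mean())) / ((m - m.mean()) @ (m - m.mean())) * (m - m.mean())
        fit_raw = fit_moderated_map(maps, x, m)
        fit_res = fit_moderated_map(maps, x, residualize(m, other))
        np.testing.assert_allclose(fit_raw.b1, fit_res.b1, atol=1e-10)
        np.testing.assert_allclose(fit_raw.b2, fit_res.b2, atol=1e-10)
        np.testing.assert_allclose(fit_raw.t2, fit_res.t2, atol=1e-8)
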