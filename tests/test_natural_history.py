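import numpy as np
import pytest
from scipy import stats

from bcscreen import (
    GrowthModel,
    MvkRates,
    OnsetModel,
    SymptomaticModel,
    TumorGeometry,
    diameter_from_volume,
    doubling_time,
    reparameterize_mvk,
    sample_symptomatic,
    tumor_volume,
    volume_from_diameter,
)


class TestMvkReparameterization:
    def test_collapsed_roots(self):
        # no second events and death rate equal to division rate: bracket is 0 +/- 0
        A, B, d = reparameterize_mvk(MvkRates(1.0, 0.5, 1.0, 0.0))
        assert A == 0.0 and B == 0.0

    def test_delta_ratio_identity(self):
        _, _, d = reparameterize_mvk(MvkRates(2.0, 2.0, 0.3, 0.1))
        assert d == pytest.approx(1.0)

    def test_against_quadratic_root_oracle(self):
        """A and B are the roots of x^2 - (beta+mu-alpha) x - alpha mu."""
        alpha, nu, beta, mu = 1.0, 0.1, 0.9, 0.01
        A, B, d = reparameterize_mvk(MvkRates(alpha, nu, beta, mu))
        roots = sorted(np.roots([1.0, -(beta + mu - alpha), -alpha * mu]))
        assert B == pytest.approx(roots[0], abs=1e-12)
        assert A == pytest.approx(roots[1], abs=1e-12)
        assert d == pytest.approx(nu / alpha)

    def test_zero_division_rate_rejected(self):
        with pytest.raises(ValueError):
            reparameterize_mvk(MvkRates(0.0, 0.1, 0.1, 0.1))


class TestOnsetSurvival:
    def test_survival_at_zero_is_one(self):
        m = OnsetModel()
        assert m.survival(0.0) == pytest.approx(1.0)

    def test_value_at_50_unscaled(self):
        # direct high-precision evaluation of the published parameters
        m = OnsetModel(age_scale=1.0)
        assert m.survival(50.0) == pytest.approx(0.96080331, abs=1e-6)

    def test_monotone_decreasing_on_dense_grid(self):
        m = OnsetModel()
        ages = np.linspace(0, 92, 500)
        s = m.survival(ages)
        assert np.all(np.diff(s) <= 0)
        assert s[-1] > 0

    def test_log_space_stable_at_extreme_age(self):
        m = OnsetModel()
        assert np.isfinite(m.survival(5000.0))


class TestOnsetSampling:
    def test_degenerate_grid_normalizes(self):
        m = OnsetModel(grid=(50,))
        w, never = m.onset_probabilities()
        assert w.sum() + never == pytest.approx(1.0)

    def test_onset_fraction_matches_closed_form(self):
        """Empirical onset fraction matches the grid's total survival mass."""
        m = OnsetModel()
        w, never = m.onset_probabilities()
        rng = np.random.default_rng(0)
        ages = m.sample(1_000_000, rng)
        frac = np.mean(~np.isnan(ages))
        se = np.sqrt(w.sum() * never / 1_000_000)
        assert abs(frac - w.sum()) < 3 * se

    def test_sampled_distribution_matches_weights(self):
        """Chi-squared goodness of fit of samples against constructed weights."""
        m = OnsetModel()
        w, never = m.onset_probabilities()
        rng = np.random.default_rng(1)
        n = 100_000
        ages = m.sample(n, rng)
        support = np.concatenate([[np.nan], m.age_scale * np.asarray(m.grid, float)])
        probs = np.concatenate([[never], w])
        counts = np.array(
            [np.isnan(ages).sum()]
            + [(ages == a).sum() for a in support[1:]]
        )
        chi2, p = stats.chisquare(counts, n * probs)
        assert p > 0.01

    def test_onset_age_scaling_convention(self):
        """Default: weights from the unscaled survival, ages scaled by 0.48."""
        m = OnsetModel()
        rng = np.random.default_rng(2)
        ages = m.sample(50_000, rng)
        onset = ages[~np.isnan(ages)]
        assert onset.min() >= 0.48 * 38 - 1e-9
        assert onset.max() <= 0.48 * 92 + 1e-9
        # under the alternative convention ages stay on the reference grid
        m2 = OnsetModel(scale_applies_to="evaluation")
        ages2 = m2.sample(50_000, rng)
        onset2 = ages2[~np.isnan(ages2)]
        assert onset2.min() >= 38.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            OnsetModel(grid=())


class TestGrowthModel:
    def test_identity_link(self):
        m = GrowthModel(lambda0=0.0, lambda1=0.0)
        assert m.mean_from_bmi(27.0) == pytest.approx(1.0)

    def test_published_link_value(self):
        m = GrowthModel()
        assert m.mean_from_bmi(28.81) == pytest.approx(np.exp(-0.015 + 0.009 * 28.81))

    def test_mean_monotone_in_bmi(self):
        m = GrowthModel()
        bmis = np.linspace(15, 45, 50)
        assert np.all(np.diff(m.mean_from_bmi(bmis)) > 0)

    def test_gamma_moments(self):
        """Sample mean -> exp(l0 + l1 b); sample CV^2 -> phi (3-SE check)."""
        m = GrowthModel()
        rng = np.random.default_rng(3)
        n = 1_000_000
        r = m.sample(np.full(n, 21.5), rng)
        mu = float(m.mean_from_bmi(21.5))
        se_mean = np.sqrt(m.phi) * mu / np.sqrt(n)
        assert abs(r.mean() - mu) < 3 * se_mean
        cv2 = r.var() / r.mean() ** 2
        # gamma kurtosis-based SE for the CV^2 estimate
        se_cv2 = m.phi * np.sqrt((8 * m.phi + 2 * 3 * m.phi ** 2 + 4) / n)
        assert abs(cv2 - m.phi) < 3 * se_cv2

    def test_degenerate_gamma_limit(self):
        m = GrowthModel(phi=1e-6)
        rng = np.random.default_rng(4)
        r = m.sample(np.full(10_000, 25.0), rng)
        assert r.std() / r.mean() < 0.01

    def test_invalid_phi_rejected(self):
        with pytest.raises(ValueError):
            GrowthModel(phi=0.0)


class TestGeometry:
    def test_onset_volume_from_diameter(self):
        g = TumorGeometry()
        assert g.onset_volume == pytest.approx(np.pi * 0.125 / 6, rel=1e-12)
        assert g.onset_volume == pytest.approx(0.065, abs=5e-4)  # published rounding

    def test_sphere_volume_of_2mm(self):
        assert volume_from_diameter(2.0) == pytest.approx(np.pi * 8 / 6)

    @pytest.mark.parametrize("d", [0.5, 9.0, 50.0, 128.0])
    def test_round_trip(self, d):
        assert diameter_from_volume(volume_from_diameter(d)) == pytest.approx(d, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            volume_from_diameter(0.0)
        with pytest.raises(ValueError):
            diameter_from_volume(-1.0)


class TestTumorVolume:
    def test_volume_at_onset_is_v0(self):
        g = TumorGeometry()
        for conv in ("inverse_rate", "direct_rate"):
            assert tumor_volume(g, 1.3, 40.0, 40.0, conv) == pytest.approx(g.onset_volume)

    def test_doubling_definition(self):
        g = TumorGeometry()
        r = 0.8
        z = r * np.log(2)
        v = tumor_volume(g, r, 0.0, z, "inverse_rate")
        assert v == pytest.approx(2 * g.onset_volume)

    def test_direct_evaluation(self):
        g = TumorGeometry()
        v = tumor_volume(g, 1.0, 0.0, 10.0, "inverse_rate")
        assert v == pytest.approx(g.onset_volume * np.exp(10.0), rel=1e-12)

    def test_age_before_onset_rejected(self):
        with pytest.raises(ValueError):
            tumor_volume(TumorGeometry(), 1.0, 50.0, 49.0)


class TestDoublingTime:
    def test_inverse_rate_unit(self):
        assert doubling_time(1.0, "inverse_rate") == pytest.approx(np.log(2) * 365.25)

    def test_linearity(self):
        assert doubling_time(2.0, "inverse_rate") == pytest.approx(2 * doubling_time(1.0, "inverse_rate"))

    def test_direct_rate_unit(self):
        assert doubling_time(np.log(2), "direct_rate") == pytest.approx(365.25)


class TestSymptomaticSampler:
    def test_zero_cumulative_hazard(self):
        g, s = TumorGeometry(), SymptomaticModel()
        v, d, up, u_age = sample_symptomatic(g, s, 1.0, 45.0, 0.0)
        assert v == pytest.approx(g.onset_volume)
        assert up == pytest.approx(0.0)
        assert u_age == pytest.approx(45.0)

    def test_direct_evaluation_median_draw(self):
        g, s = TumorGeometry(), SymptomaticModel()
        v, d, up, _ = sample_symptomatic(g, s, 1.0, 0.0, 0.5)
        expected_v = g.onset_volume + np.log(2) / 6.418e-5
        assert v == pytest.approx(expected_v, rel=1e-9)
        assert d == pytest.approx((6 * expected_v / np.pi) ** (1 / 3), rel=1e-9)
        assert up == pytest.approx(np.log(expected_v / g.onset_volume), rel=1e-9)

    def test_invalid_u_rejected(self):
        g, s = TumorGeometry(), SymptomaticModel()
        with pytest.raises(ValueError):
            sample_symptomatic(g, s, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            sample_symptomatic(g, s, 1.0, 0.0, -0.1)

    def test_inverse_cdf_matches_brute_force_hazard(self):
        """KS test: closed-form U' vs discrete-time simulation of eta*V(s)."""
        g, s = TumorGeometry(), SymptomaticModel()
        r = 0.6
        rng = np.random.default_rng(8)
        n = 100_000
        _, _, up_closed, _ = sample_symptomatic(g, s, np.full(n, r), 0.0, rng.uniform(size=n))

        # brute force: cumulative hazard on a fine grid, invert per draw
        dt = 1e-3
        tmax = 60.0
        grid = np.arange(0.0, tmax, dt)
        haz = s.eta * g.onset_volume * np.exp(grid / r)
        cumhaz = np.concatenate([[0.0], np.cumsum(haz * dt)])
        e = rng.exponential(size=n)
        idx = np.searchsorted(cumhaz, e)
        up_brute = np.minimum(idx, len(grid)) * dt
        ks = stats.ks_2samp(up_closed[up_closed < tmax], up_brute[up_brute < tmax - dt])
        assert ks.pvalue > 0.01

    def test_larger_eta_gives_smaller_volumes_coupled(self):
        """First-order dominance over matched uniform draws."""
        g = TumorGeometry()
        u = np.random.default_rng(9).uniform(size=1000)
        v_lo, *_ = sample_symptomatic(g, SymptomaticModel(eta=1e-5), 1.0, 0.0, u)
        v_hi, *_ = sample_symptomatic(g, SymptomaticModel(eta=1e-4), 1.0, 0.0, u)
        assert np.all(v_hi <= v_lo)


class TestLifeHistories:
    def test_no_onset_rows_have_empty_disease_fields(self, small_histories):
        no = small_histories[small_histories.onset_age.isna()]
        assert no.growth_rate.isna().all()
        assert no.sympt_age.isna().all()

    def test_life_history_invariants(self, small_histories):
        h = small_histories.dropna(subset=["onset_age"])
        g = TumorGeometry()
        assert (h.sympt_age >= h.onset_age - 1e-9).all()
        assert (h.sojourn >= 0).all()
        assert (h.sympt_volume >= g.onset_volume - 1e-12).all()
        assert (h.sympt_diameter >= g.onset_diameter - 1e-12).all()
        assert (h.doubling_time_days > 0).all()

    def test_onset_fraction_matches_closed_form(self, small_histories, nh_model):
        w, never = nh_model.onset.onset_probabilities()
        n = len(small_histories)
        frac = small_histories.onset_age.notna().mean()
        se = np.sqrt(w.sum() * never / n)
        assert abs(frac - w.sum()) < 3.5 * se

    def test_unscreened_symptomatic_sizes_dominated_by_20_50_band(self, small_histories):
        """The 20-50 mm band is the largest among unscreened symptomatic cases."""
        h = small_histories.dropna(subset=["onset_age"])
        cohort = h[(h.onset_age >= 30) & (h.onset_age <= 65) & (h.sympt_age <= 65)]
        d = cohort.sympt_diameter
        bands = [
            (d < 10).mean(),
            ((d >= 10) & (d < 20)).mean(),
            ((d >= 20) & (d < 50)).mean(),
            (d >= 50).mean(),
        ]
        assert np.argmax(bands) == 2
        assert bands[2] > 0.45
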