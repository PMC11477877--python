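import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lectinquench.binding import (
    KsvEstimate,
    QuenchPoint,
    classify_mechanism,
    hill_fit,
    modified_sv_fit,
    quench_points,
    stern_volmer_fit,
)
from lectinquench.spectra import EmissionSpectrum, TitrationSeries
from lectinquench.synthetic_data import GeneratorConfig, gen_titration
from conftest import gaussian_spectrum


def series_from_scales(scales, qs, temperature=298.0):
    """Titration series whose F values are ``scales`` times F0."""
    f0 = gaussian_spectrum(amplitude=100.0)
    pts = tuple(
        (q, gaussian_spectrum(amplitude=100.0 * s)) for q, s in zip(qs, scales)
    )
    return TitrationSeries(f0, pts, temperature)


def points_from_fracs(qs, fracs):
    """QuenchPoints built directly from fractional quench values."""
    out = []
    for q, y in zip(qs, fracs):
        ratio = 1.0 / (1.0 - y)
        logterm = math.log10(y / (1.0 - y)) if y > 0 else None
        out.append(QuenchPoint(q, ratio, y, math.log10(q), logterm))
    return out


def ols_oracle(x, y):
    """Closed-form two-parameter OLS."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xb, yb = x.mean(), y.mean()
    slope = np.sum((x - xb) * (y - yb)) / np.sum((x - xb) ** 2)
    return slope, yb - slope * xb


class TestQuenchPoints:
    def test_arithmetic_of_single_step(self):
        s = series_from_scales([0.8], [0.01])
        (p,) = quench_points(s)
        assert p.ratio == pytest.approx(1.25, rel=1e-9)
        assert p.frac == pytest.approx(0.2, rel=1e-9)
        assert p.logterm == pytest.approx(math.log10(0.25), rel=1e-9)

    def test_no_quench_flags_logterm_undefined(self):
        s = series_from_scales([1.0], [0.01])
        (p,) = quench_points(s)
        assert p.ratio == pytest.approx(1.0)
        assert p.frac == pytest.approx(0.0)
        assert p.logterm is None and not p.usable

    def test_noise_free_static_ratios_match_generator_truth(self):
        cfg = GeneratorConfig(noise_rel=0.0, temps_K=(298.0,))
        pts = quench_points(gen_titration(cfg)[0])
        for p in pts:
            assert p.ratio == pytest.approx(1 + cfg.ksv_at(298.0) * p.q_M, rel=1e-12)

    def test_nonpositive_intensity_rejected(self):
        f0 = gaussian_spectrum(amplitude=100.0)
        neg = EmissionSpectrum(f0.wavelengths, -f0.intensities)
        s = TitrationSeries(f0, ((0.01, neg),), 298.0)
        with pytest.raises(ValueError):
            quench_points(s)


class TestSternVolmer:
    def test_exact_line_recovers_constant(self):
        qs = np.linspace(2e-3, 11e-3, 12)
        scales = 1.0 / (1.0 + 28.47 * qs)
        est = stern_volmer_fit(quench_points(series_from_scales(scales, qs)))
        assert est.ksv_per_M == pytest.approx(28.47, rel=1e-9)
        assert est.r2 == pytest.approx(1.0, abs=1e-12)
        assert est.intercept == pytest.approx(1.0, abs=1e-9)

    def test_constant_ratio_gives_zero_slope(self):
        qs = np.linspace(2e-3, 11e-3, 12)
        est = stern_volmer_fit(quench_points(series_from_scales(np.ones(12), qs)))
        assert est.ksv_per_M == pytest.approx(0.0, abs=1e-12)

    def test_noisy_fit_equals_closed_form_oracle(self):
        cfg = GeneratorConfig(noise_rel=0.01, seed=1, temps_K=(298.0,))
        pts = quench_points(gen_titration(cfg)[0])
        est = stern_volmer_fit(pts)
        slope, intercept = ols_oracle([p.q_M for p in pts], [p.ratio for p in pts])
        assert est.ksv_per_M == pytest.approx(slope, abs=1e-10 * abs(slope))
        assert est.intercept == pytest.approx(intercept, rel=1e-10)

    def test_degenerate_design_rejected(self):
        pts = [QuenchPoint(0.01, r, 0.1, -2.0, -1.0) for r in (1.1, 1.2, 1.3)]
        with pytest.raises(ValueError):
            stern_volmer_fit(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            stern_volmer_fit([QuenchPoint(0.01, 1.1, 0.1, -2, -1)] * 2)

    @given(
        st.lists(
            st.tuples(st.floats(1e-4, 1e-1), st.floats(0.5, 3.0)),
            min_size=3, max_size=12, unique_by=lambda t: t[0],
        )
    )
    def test_property_fit_equals_ols_oracle(self, data):
        data = sorted(data)
        pts = [QuenchPoint(q, r, 0.0, math.log10(q), None) for q, r in data]
        slope, intercept = ols_oracle([q for q, _ in data], [r for _, r in data])
        est = stern_volmer_fit(pts)
        assert est.ksv_per_M == pytest.approx(slope, rel=1e-9, abs=1e-10)
        assert est.intercept == pytest.approx(intercept, rel=1e-9, abs=1e-10)


class TestMechanism:
    GLUCOSE = [(298.0, 28.47, 0.20), (303.0, 17.01, 0.14), (308.0, 15.42, 0.13)]
    GALACTOSE = [(298.0, 97.68, 0.07), (303.0, 96.10, 0.09), (308.0, 95.84, 0.80)]

    @staticmethod
    def _est(rows):
        return [KsvEstimate(k, 1.0, se, 1.0, t, 12) for t, k, se in rows]

    @pytest.mark.parametrize("rows", [GLUCOSE, GALACTOSE], ids=["glucose", "galactose"])
    def test_decreasing_ksv_called_static(self, rows):
        call = classify_mechanism(self._est(rows))
        assert call.verdict == "static"
        assert call.z_score < -2

    def test_increasing_ksv_called_dynamic(self):
        rows = [(298.0, 10.0, 0.01), (303.0, 20.0, 0.01), (308.0, 30.0, 0.01)]
        assert classify_mechanism(self._est(rows)).verdict == "dynamic"

    def test_flat_trend_ambiguous(self):
        rows = [(298.0, 20.0, 5.0), (303.0, 20.5, 5.0), (308.0, 19.8, 5.0)]
        assert classify_mechanism(self._est(rows)).verdict == "ambiguous"

    def test_sign_only_call_with_zero_threshold(self):
        rows = [(298.0, 20.0, 5.0), (303.0, 19.9, 5.0), (308.0, 19.8, 5.0)]
        assert classify_mechanism(self._est(rows), z_threshold=0.0).verdict == "static"

    def test_order_invariance(self):
        fwd = classify_mechanism(self._est(self.GLUCOSE))
        rev = classify_mechanism(self._est(self.GLUCOSE[::-1]))
        assert fwd.verdict == rev.verdict
        assert fwd.z_score == pytest.approx(rev.z_score, rel=1e-12)

    def test_single_temperature_rejected(self):
        with pytest.raises(ValueError):
            classify_mechanism(self._est(self.GLUCOSE[:1]))


class TestModifiedSternVolmer:
    def test_recovers_known_association_constant(self):
        # (F0-F)/F = Ka [Q] with Ka = 29.785 1/M -> intercept log10 Ka, slope 1
        qs = np.linspace(2e-3, 11e-3, 12)
        scales = 1.0 / (1.0 + 29.785 * qs)
        fit = modified_sv_fit(quench_points(series_from_scales(scales, qs)))
        assert fit.ka_per_M == pytest.approx(29.785, rel=1e-9)
        assert fit.n_sites == pytest.approx(1.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_squared_isotherm_gives_two_sites(self):
        qs = np.linspace(2e-3, 11e-3, 12)
        ka = 50.0
        scales = 1.0 / (1.0 + (ka * qs) ** 2)  # (F0-F)/F = (Ka q)^2
        fit = modified_sv_fit(quench_points(series_from_scales(scales, qs)))
        assert fit.n_sites == pytest.approx(2.0, abs=1e-9)

    def test_noisy_fit_equals_closed_form_oracle(self):
        cfg = GeneratorConfig(noise_rel=0.01, seed=3, temps_K=(298.0,))
        pts = [p for p in quench_points(gen_titration(cfg)[0]) if p.usable]
        fit = modified_sv_fit(pts)
        slope, intercept = ols_oracle([p.logq for p in pts], [p.logterm for p in pts])
        assert fit.n_sites == pytest.approx(slope, rel=1e-10)
        assert math.log10(fit.ka_per_M) == pytest.approx(intercept, rel=1e-10)

    def test_unusable_points_filtered_and_counted(self):
        qs = np.linspace(2e-3, 11e-3, 12)
        scales = 1.0 / (1.0 + 29.785 * qs)
        scales[0] = 1.0  # F = F0: no signal at the first step
        fit = modified_sv_fit(quench_points(series_from_scales(scales, qs)))
        assert fit.n_points == 11

    def test_too_few_usable_points_rejected(self):
        qs = [1e-3, 2e-3, 3e-3]
        with pytest.raises(ValueError):
            modified_sv_fit(quench_points(series_from_scales([1.0, 1.0, 0.9], qs)))


class TestHill:
    @pytest.mark.parametrize("h_true", [0.5, 1.0, 2.0, 3.0])
    def test_exact_recovery_on_model_data(self, h_true):
        qs = np.linspace(2e-3, 11e-3, 12)
        kd, bmax = 6e-3, 0.9
        y = bmax * qs**h_true / (kd**h_true + qs**h_true)
        fit = hill_fit(points_from_fracs(qs, y))
        assert fit.converged
        assert fit.h == pytest.approx(h_true, abs=1e-6)
        assert fit.kd_M == pytest.approx(kd, rel=1e-6)
        assert fit.bmax == pytest.approx(bmax, rel=1e-6)

    def test_concerted_two_site_isotherm_gives_h_two(self):
        # all-or-none two-ligand binding, K = 6 mM, 12 points over 2-11 mM
        qs = np.linspace(2e-3, 11e-3, 12)
        K = 6e-3
        y = qs**2 / (K**2 + qs**2)
        fit = hill_fit(points_from_fracs(qs, y))
        assert fit.converged
        assert fit.h == pytest.approx(2.0, abs=0.01)

    def test_single_site_isotherm_gives_h_one(self):
        qs = np.linspace(2e-3, 11e-3, 12)
        K = 6e-3
        y = qs / (K + qs)
        fit = hill_fit(points_from_fracs(qs, y))
        assert fit.h == pytest.approx(1.0, abs=1e-6)

    def test_independent_two_site_hill_slope_matches_analytic_oracle(self):
        # y = theta^2 with theta = q/(K+q): the Hill slope at half-saturation
        # is 2/(1+sqrt(1/2)) analytically; a fit over a symmetric log-range
        # around the half-saturation point must land there.
        K = 6e-3
        q_half = K * math.sqrt(0.5) / (1.0 - math.sqrt(0.5))
        qs = q_half * np.logspace(-0.3, 0.3, 11)
        theta = qs / (K + qs)
        fit = hill_fit(points_from_fracs(qs, theta**2), fix_bmax=1.0)
        oracle = 2.0 / (1.0 + math.sqrt(0.5))
        assert fit.h == pytest.approx(oracle, abs=0.05)

    def test_too_few_points_rejected(self):
        qs = np.linspace(2e-3, 5e-3, 4)
        with pytest.raises(ValueError):
            hill_fit(points_from_fracs(qs, [0.1, 0.2, 0.3, 0.4]))

    def test_response_convention_switch(self):
        qs = np.linspace(2e-3, 11e-3, 12)
        K = 6e-3
        y = 0.5 * qs**2 / (K**2 + qs**2)
        pts = points_from_fracs(qs, y)
        # (F0-F)/F = y/(1-y) differs from y; both must converge
        assert hill_fit(pts, response="f0").converged
        assert hill_fit(pts, response="f").converged
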