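"""Estimators: tangent-correlation persistence length, Hill isotherm,
aspiration moduli, spike geometry, and the aspiration tension relation."""

import math

import numpy as np
import pytest

from septcurve import EstimationError, ValidationError, estimators as est, synth
from septcurve.estimators import (
    AspirationSeries,
    BindingCurve,
    FilamentTrackSet,
    TangentCorrelation,
)


def make_corr(L, mean_cos, count=1000):
    L = np.asarray(L, dtype=float)
    return TangentCorrelation(
        L_nm=L,
        mean_cos=np.asarray(mean_cos, dtype=float),
        count=np.full(L.shape, count),
    )


class TestTangentCorrelation:
    def test_straight_track_fully_correlated(self):
        pts = np.stack([np.linspace(0, 5000, 60), np.zeros(60)], axis=1)
        corr = est.tangent_correlation(FilamentTrackSet([pts]), bin_width_nm=200.0)
        assert np.allclose(corr.mean_cos, 1.0, atol=1e-12)

    def test_circular_arc_matches_cosine_oracle(self):
        """On a perfect arc of radius rho, tangents separated by arclength L
        enclose angle L/rho, so <cos theta>(L) = cos(L/rho)."""
        rho = 4000.0
        s = np.linspace(0, 6000, 400)
        pts = rho * np.stack([np.cos(s / rho), np.sin(s / rho)], axis=1)
        corr = est.tangent_correlation(
            FilamentTrackSet([pts]), bin_width_nm=100.0, smoothing_window=1
        )
        # the sparsely populated tail bins sit off their bin centers
        keep = corr.count >= 20
        expected = np.cos(corr.L_nm[keep] / rho)
        assert np.allclose(corr.mean_cos[keep], expected, atol=5e-3)

    def test_zero_separation_bin_is_one(self):
        tracks = synth.generate_wlc(8000.0, 5000.0, n_chains=3, seed=0)
        corr = est.tangent_correlation(tracks, bin_width_nm=300.0)
        assert corr.L_nm[0] == 0.0
        assert corr.mean_cos[0] == pytest.approx(1.0, abs=1e-9)

    def test_wlc_ensemble_matches_exponential_decay(self):
        tracks = synth.generate_wlc(8000.0, 10000.0, n_chains=400, seed=3)
        corr = est.tangent_correlation(tracks, bin_width_nm=500.0, smoothing_window=1)
        keep = corr.L_nm <= 6000.0
        expected = np.exp(-corr.L_nm[keep] / 16000.0)
        # pairs within a chain are correlated: the statistical scale is
        # set by the number of chains, ~0.5/sqrt(400) at the longest lags
        assert np.allclose(corr.mean_cos[keep], expected, atol=0.05)

    def test_all_short_tracks_error(self):
        with pytest.raises(ValidationError):
            FilamentTrackSet([np.zeros((2, 2))])


class TestPersistenceLengthFit:
    def test_noiseless_exponential_inverts_exactly(self):
        L = np.arange(0, 5000, 250.0)
        corr = make_corr(L, np.exp(-L / (2 * 8000.0)))
        fit = est.fit_persistence_length(corr)
        assert fit.Lp_nm == pytest.approx(8000.0, rel=1e-9)

    def test_straight_input_fails(self):
        corr = make_corr(np.arange(0, 3000, 250.0), np.ones(12))
        with pytest.raises(EstimationError):
            est.fit_persistence_length(corr)

    def test_scale_equivariance(self):
        tracks = synth.generate_wlc(8000.0, 10000.0, n_chains=50, seed=5)
        corr = est.tangent_correlation(tracks, bin_width_nm=400.0)
        fit = est.fit_persistence_length(corr)
        scaled = FilamentTrackSet([np.asarray(t) * 3.0 for t in tracks.tracks])
        corr3 = est.tangent_correlation(scaled, bin_width_nm=1200.0)
        fit3 = est.fit_persistence_length(corr3)
        assert fit3.Lp_nm == pytest.approx(3.0 * fit.Lp_nm, rel=1e-9)

    def test_recovery_from_simulated_ensemble(self):
        """300 chains of 10 µm contour at Lp = 8 µm recover 7.2-8.8 µm."""
        tracks = synth.generate_wlc(8000.0, 10000.0, n_chains=300, seed=11)
        corr = est.tangent_correlation(tracks, bin_width_nm=250.0)
        fit = est.fit_persistence_length(corr)
        assert 7200.0 < fit.Lp_nm < 8800.0


class TestHillFit:
    def test_noiseless_langmuir_recovers_exactly(self):
        conc = np.geomspace(5, 1000, 12)
        curve = synth.generate_binding_curve(1.0, 88.0, conc, hill_n=1.0, cv_noise=0.0)
        fit = est.fit_hill(curve)
        assert fit.S_sat == pytest.approx(1.0, rel=1e-6)
        assert fit.Kd_nM == pytest.approx(88.0, rel=1e-6)
        assert fit.hill_n == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("hill_n", [0.5, 1.0, 2.0])
    def test_half_saturation_at_kd(self, hill_n):
        curve = synth.generate_binding_curve(
            2.0, 88.0, np.array([44.0, 88.0, 176.0]), hill_n=hill_n, cv_noise=0.0
        )
        assert curve.bound_per_um2[1] == pytest.approx(1.0, rel=1e-12)

    def test_fixed_n_matches_free_fit_on_clean_data(self):
        conc = np.geomspace(5, 1000, 12)
        curve = synth.generate_binding_curve(1.0, 88.0, conc, hill_n=1.0, cv_noise=0.0)
        fixed = est.fit_hill(curve, fix_hill_n=1.0)
        assert fixed.Kd_nM == pytest.approx(88.0, rel=1e-9)
        assert fixed.se_hill_n == 0.0

    def test_noisy_recovery_within_ten_percent(self):
        conc = np.geomspace(10, 250, 8)
        kds = [
            est.fit_hill(
                synth.generate_binding_curve(4000.0, 88.0, conc, seed=7, replicate=i),
                fix_hill_n=1.0,
            ).Kd_nM
            for i in range(60)
        ]
        assert np.mean(kds) == pytest.approx(88.0, rel=0.10)


class TestAspirationModuli:
    def test_exact_bending_line(self):
        sigma = np.geomspace(1e-6, 4e-4, 8)
        area = np.log(sigma / sigma[0]) / (8 * math.pi * 10.5)
        fit = est.fit_bending_modulus(AspirationSeries(sigma, area))
        assert fit.value == pytest.approx(10.5, rel=1e-9)

    def test_sigma0_invariance(self):
        sigma = np.geomspace(1e-6, 4e-4, 8)
        area = np.log(sigma / sigma[0]) / (8 * math.pi * 10.5)
        a = est.fit_bending_modulus(AspirationSeries(sigma, area, sigma0_N_per_m=1e-6))
        b = est.fit_bending_modulus(AspirationSeries(sigma, area, sigma0_N_per_m=3e-5))
        assert a.value == pytest.approx(b.value, rel=1e-9)

    def test_too_few_low_tension_points(self):
        sigma = np.geomspace(1e-3, 5e-3, 6)
        with pytest.raises(EstimationError):
            est.fit_bending_modulus(AspirationSeries(sigma, np.linspace(0, 0.05, 6)))

    def test_exact_stretching_line(self):
        sigma = np.linspace(1e-3, 6e-3, 6)
        area = sigma / 0.065 + 0.004
        fit = est.fit_stretching_modulus(AspirationSeries(sigma, area))
        assert fit.value == pytest.approx(65.0, rel=1e-9)

    def test_flat_stretching_input_fails(self):
        sigma = np.linspace(1e-3, 6e-3, 6)
        with pytest.raises(EstimationError):
            est.fit_stretching_modulus(AspirationSeries(sigma, np.full(6, 0.01)))

    def test_noisy_bending_recovery(self):
        vals = [
            est.fit_bending_modulus(
                synth.generate_aspiration_series(
                    np.geomspace(2e-6, 4.5e-4, 10),
                    kappa_kT=10.5,
                    Ka_mN_per_m=None,
                    seed=13,
                    replicate=i,
                )
            ).value
            for i in range(40)
        ]
        assert np.mean(vals) == pytest.approx(10.5, rel=0.10)

    def test_noisy_stretching_recovery(self):
        vals = [
            est.fit_stretching_modulus(
                synth.generate_aspiration_series(
                    np.geomspace(1e-3, 5e-3, 10),
                    kappa_kT=None,
                    Ka_mN_per_m=65.0,
                    seed=13,
                    replicate=i,
                )
            ).value
            for i in range(40)
        ]
        assert np.mean(vals) == pytest.approx(65.0, rel=0.15)


class TestTensionFromAspiration:
    def test_zero_pressure(self):
        assert est.tension_from_aspiration(0.0, 3.0, 15.0) == 0.0

    def test_wide_vesicle_limit(self):
        sigma = est.tension_from_aspiration(100.0, 3.0, 3e6)
        assert sigma == pytest.approx(100.0 * 3e-6 / 2.0, rel=1e-5)

    def test_worked_value(self):
        assert est.tension_from_aspiration(100.0, 3.0, 15.0) == pytest.approx(
            1.875e-4, rel=1e-12
        )

    def test_pipette_wider_than_vesicle_rejected(self):
        from septcurve import DomainError

        with pytest.raises(DomainError):
            est.tension_from_aspiration(100.0, 15.0, 3.0)


class TestMeasureSpikes:
    def test_circle_has_no_spikes(self):
        phi = np.linspace(0, 2 * math.pi, 256, endpoint=False)
        contour = 10.0 * np.stack([np.cos(phi), np.sin(phi)], axis=1)
        stats = est.measure_spikes(contour)
        assert stats.n_spikes == 0
        assert math.isnan(stats.amplitude_um)

    def test_analytic_star_amplitude_and_spacing(self):
        """r(phi) = 10 + 0.9 max(0, cos 8 phi)^4: eight spikes of height
        0.9 over a circular baseline of radius 10."""
        phi = np.linspace(0, 2 * math.pi, 2048, endpoint=False)
        r = 10.0 + 0.9 * np.clip(np.cos(8 * phi), 0, None) ** 4
        contour = np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)
        stats = est.measure_spikes(contour)
        assert stats.n_spikes == 8
        assert stats.amplitude_um == pytest.approx(0.9, rel=0.05)
        assert stats.period_um == pytest.approx(2 * math.pi * 10.0 / 8, rel=0.10)

    def test_rigid_motion_and_cyclic_shift_invariance(self):
        contour = synth.generate_spiky_contour(seed=2, jitter_sd_um=0.0)
        ref = est.measure_spikes(contour)
        ang = 0.83
        R = np.array(
            [[math.cos(ang), math.sin(ang)], [-math.sin(ang), math.cos(ang)]]
        )
        moved = np.roll(contour @ R + np.array([5.0, -2.0]), 101, axis=0)
        out = est.measure_spikes(moved)
        assert out.n_spikes == ref.n_spikes
        assert out.amplitude_um == pytest.approx(ref.amplitude_um, rel=1e-6)
        assert out.period_um == pytest.approx(ref.period_um, rel=1e-6)
        assert out.concave_radius_um == pytest.approx(ref.concave_radius_um, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            est.measure_spikes(np.zeros((10, 2)))

    def test_constructed_contour_round_trip_noiseless(self):
        contour = synth.generate_spiky_contour(seed=4, jitter_sd_um=0.0)
        stats = est.measure_spikes(contour)
        assert stats.n_spikes == 16
        assert stats.amplitude_um == pytest.approx(0.9, rel=0.05)
        assert stats.period_um == pytest.approx(2 * math.pi * 10.0 / 16, rel=0.05)
        assert stats.concave_radius_um == pytest.approx(1.0 / 1.1, rel=0.05)
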