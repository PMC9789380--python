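import numpy as np
import pytest
from scipy import stats as sps

from ciliaxis.photophysics import (
    DoseResponse,
    LifetimeModel,
    Trace,
    alpha_mode,
    delta_f_over_f,
    disk_roi_mean,
    exp_kinetics_fit,
    flim_cilium_mode,
    flim_fraction_fit,
    fret_ratio_series,
    hill_fit,
    lowpass_fourier,
    response_metrics,
)
from ciliaxis.volumes import FlimVolume


class TestDeltaFOverF:
    def test_constant_trace_gives_zero(self):
        tr = delta_f_over_f(Trace(np.arange(10.0), np.full(10, 50.0)), (0, 5))
        np.testing.assert_allclose(tr.dff, 0.0)

    def test_step_with_background_subtraction(self):
        F = np.array([10.0] * 5 + [12.0] * 5)
        tr = delta_f_over_f(Trace(np.arange(10.0), F), (0, 5), background=2.0)
        assert tr.F0 == pytest.approx(8.0)
        np.testing.assert_allclose(tr.dff[5:], 0.25)

    def test_invariant_under_joint_intensity_scaling(self):
        rng = np.random.default_rng(0)
        F = 50 + rng.random(30) * 10
        a = delta_f_over_f(Trace(np.arange(30.0), F), (0, 10), background=5.0)
        b = delta_f_over_f(Trace(np.arange(30.0), 3 * F), (0, 10), background=15.0)
        np.testing.assert_allclose(a.dff, b.dff, atol=1e-12)

    def test_nonpositive_baseline_raises(self):
        with pytest.raises(ValueError):
            delta_f_over_f(Trace(np.arange(5.0), np.full(5, 1.0)), (0, 3), background=2.0)


class TestLowpassFourier:
    def test_constant_trace_unchanged(self):
        tr = Trace(np.arange(40) / 4.0, np.full(40, 7.0))
        np.testing.assert_allclose(lowpass_fourier(tr, 0.2).F, 7.0)

    def test_suppresses_above_cutoff_keeps_below(self):
        t = np.arange(80) / 4.0  # 20 s at 4 Hz: 0.5 and 0.05 Hz land on bins
        hi = lowpass_fourier(Trace(t, np.sin(2 * np.pi * 0.5 * t)), 0.2)
        lo = lowpass_fourier(Trace(t, np.sin(2 * np.pi * 0.05 * t)), 0.2)
        assert np.abs(hi.F).max() < 1e-6
        assert np.abs(lo.F).max() == pytest.approx(1.0, rel=0.01)

    def test_mean_preserved_and_idempotent(self):
        rng = np.random.default_rng(1)
        tr = Trace(np.arange(64) / 4.0, rng.random(64))
        once = lowpass_fourier(tr, 0.3)
        twice = lowpass_fourier(once, 0.3)
        assert once.F.mean() == pytest.approx(tr.F.mean(), abs=1e-12)
        np.testing.assert_allclose(once.F, twice.F, atol=1e-12)

    def test_nonuniform_time_base_rejected(self):
        tr = Trace(np.array([0.0, 1.0, 3.0]), np.zeros(3))
        with pytest.raises(ValueError):
            lowpass_fourier(tr, 0.1)


class TestResponseMetrics:
    def test_zero_trace(self):
        tr = Trace(np.arange(10.0), np.ones(10), dff=np.zeros(10))
        m = response_metrics(tr, (2, 8))
        assert m == {"peak_dff": 0.0, "mean_dff": 0.0}

    def test_peak_and_mean_extraction(self):
        dff = np.zeros(30)
        dff[10:20] = np.linspace(0, 0.15, 10)  # ramp peaking at 0.15
        tr = Trace(np.arange(30.0), np.ones(30), dff=dff)
        assert response_metrics(tr, (10, 20))["peak_dff"] == pytest.approx(0.15)
        boxcar = np.zeros(30)
        boxcar[5:25] = 0.08
        tr2 = Trace(np.arange(30.0), np.ones(30), dff=boxcar)
        assert response_metrics(tr2, (5, 25))["mean_dff"] == pytest.approx(0.08)


class TestHillFit:
    def _noiseless(self, ec50, top=0.8, hill=1.0):
        conc = np.geomspace(1e-9, 1e-5, 9)
        resp = top / (1 + (ec50 / conc) ** hill)
        return DoseResponse(conc, resp)

    @pytest.mark.parametrize("ec50_nm", [84.0, 28.0])
    def test_noiseless_ec50_recovery(self, ec50_nm):
        fit = hill_fit(self._noiseless(ec50_nm * 1e-9))
        assert fit.fit["EC50"] == pytest.approx(ec50_nm * 1e-9, rel=1e-3)
        assert fit.fit["hill"] == pytest.approx(1.0, rel=1e-3)

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            hill_fit(DoseResponse(np.array([1e-9, 1e-8, 1e-7]), np.zeros(3)))


class TestKinetics:
    @pytest.mark.parametrize("tau,direction,t_end,dt", [
        (0.19, "on", 1.5, 0.01),
        (8.46, "off", 45.0, 0.25),
    ])
    def test_noiseless_tau_recovery(self, tau, direction, t_end, dt):
        t = np.arange(0, t_end, dt)
        if direction == "on":
            F = 1.0 + 0.15 * (1 - np.exp(-t / tau))
        else:
            F = 1.0 + 0.15 * np.exp(-t / tau)
        fit = exp_kinetics_fit(Trace(t, F), direction)
        assert fit.tau == pytest.approx(tau, rel=0.01)

    def test_short_trace_warns(self, caplog):
        t = np.arange(0, 1.0, 0.05)
        F = np.exp(-t / 5.0)
        with caplog.at_level("WARNING"):
            exp_kinetics_fit(Trace(t, F), "off")
        assert any("3 tau" in r.message for r in caplog.records)


class TestFretRatio:
    def _stacks(self, n_frames=30, step_frame=None, step_gain=1.2, background=0.0):
        y = x = 48
        yy, xx = np.mgrid[0:y, 0:x]
        mask = (yy - 24) ** 2 + (xx - 24) ** 2 < 40
        donor = np.full((n_frames, y, x), background)
        sens = np.full((n_frames, y, x), background)
        donor[:, mask] += 100.0
        sens[:, mask] += 50.0
        if step_frame is not None:
            sens[step_frame:, mask] *= step_gain
        return donor, sens

    def test_uniform_structure_gives_constant_ratio(self):
        donor, sens = self._stacks()
        res = fret_ratio_series(donor, sens, (slice(0, 8), slice(0, 8)),
                                rolling_radius=10, baseline_frames=10)
        np.testing.assert_allclose(res["ratio"], 0.5, atol=1e-9)

    def test_planted_background_subtracted(self):
        donor, sens = self._stacks(background=10.0)
        res = fret_ratio_series(donor, sens, (slice(0, 8), slice(0, 8)),
                                rolling_radius=10, baseline_frames=10)
        np.testing.assert_allclose(res["ratio"], 0.5, atol=1e-6)

    def test_sensitized_step_appears_in_drr(self):
        donor, sens = self._stacks(step_frame=15)
        res = fret_ratio_series(donor, sens, (slice(0, 8), slice(0, 8)),
                                rolling_radius=10, baseline_frames=10)
        np.testing.assert_allclose(res["dRR"][15:], 0.2, atol=1e-9)

    def test_invariant_under_joint_channel_rescaling(self):
        donor, sens = self._stacks(step_frame=20)
        r1 = fret_ratio_series(donor, sens, (slice(0, 8), slice(0, 8)),
                               rolling_radius=10, baseline_frames=10)
        r2 = fret_ratio_series(donor * 5, sens * 5, (slice(0, 8), slice(0, 8)),
                               rolling_radius=10, baseline_frames=10)
        np.testing.assert_allclose(r1["ratio"], r2["ratio"], rtol=1e-9)

    def test_disk_roi_mean_reads_circle(self):
        frames = np.zeros((3, 20, 20))
        frames[:, 10, 10] = 9.0
        roi = disk_roi_mean(frames, (10, 10), radius_um=0.5, pixel_um=0.5)
        assert roi.shape == (3,)
        assert roi[0] > 0


class TestFlimFractionFit:
    def _decay(self, f, n=60):
        t = np.linspace(0, 12, n)
        return t, f * np.exp(-t / 1.3) + (1 - f) * np.exp(-t / 2.7)

    @pytest.mark.parametrize("f,tau_expected", [(0.0, 2.7), (1.0, 1.3)])
    def test_pure_components(self, f, tau_expected):
        t, y = self._decay(f)
        model = flim_fraction_fit(t, y)
        assert model.quenched_fraction == pytest.approx(f, abs=1e-9)
        assert model.mean_lifetime == pytest.approx(tau_expected)

    def test_even_mixture_recovered(self):
        t, y = self._decay(0.5)
        model = flim_fraction_fit(t, y)
        assert model.quenched_fraction == pytest.approx(0.5, abs=1e-6)

    def test_mean_lifetime_decreases_with_quenched_fraction(self):
        taus = []
        for f in (0.1, 0.4, 0.7, 0.95):
            t, y = self._decay(f)
            taus.append(flim_fraction_fit(t, y).mean_lifetime)
        assert taus == sorted(taus, reverse=True)

    def test_degenerate_decay_rejected(self):
        t = np.linspace(0, 12, 20)
        y = np.zeros(20)
        y[0] = 100
        with pytest.raises(ValueError):
            flim_fraction_fit(t, y)


class TestFlimCiliumMode:
    def test_alpha_sample_mode_matches_closed_form(self):
        a, loc, scale = 3.0, 0.5, 2.0
        x = sps.alpha.rvs(a, loc, scale, size=100_000,
                          random_state=np.random.default_rng(0))
        side = int(round(len(x) ** (1 / 3))) + 1
        vals = np.resize(x, (side,) * 3)
        counts = np.full((side,) * 3, 100)
        summary = flim_cilium_mode(FlimVolume(counts, vals), np.ones((side,) * 3, bool))
        expected = alpha_mode(a, loc, scale)
        assert summary.mode == pytest.approx(expected, rel=0.02)
        # cross-check the closed form against a numeric density maximizer
        from scipy.optimize import minimize_scalar

        num = minimize_scalar(lambda v: -sps.alpha.pdf(v, a, loc, scale),
                              bounds=(loc + 1e-6, loc + 5 * scale), method="bounded")
        assert expected == pytest.approx(num.x, rel=1e-4)

    def test_degenerate_field_returns_that_value(self):
        counts = np.full((4, 4, 4), 100)
        vals = np.full((4, 4, 4), 2.0)
        summary = flim_cilium_mode(FlimVolume(counts, vals), np.ones((4, 4, 4), bool))
        assert summary.mode == 2.0

    def test_low_count_voxels_cannot_move_the_mode(self, flim_scene):
        fv, truth = flim_scene
        mask = np.ones(fv.counts.shape, bool)
        base = flim_cilium_mode(fv, mask)
        # perturb all sub-threshold voxels adversarially
        arrival = fv.arrival.copy()
        arrival[truth.low_count_mask] = 123.0
        perturbed = flim_cilium_mode(FlimVolume(fv.counts, arrival, fv.spacing), mask)
        assert perturbed.mode == base.mode

    def test_two_population_mode_inside_lifetime_range(self):
        from ciliaxis.synth import FlimSceneParams, make_flim_scene

        fv, _ = make_flim_scene(FlimSceneParams(field="two_state", seed=2))
        summary = flim_cilium_mode(fv, np.ones(fv.counts.shape, bool))
        assert 1.3 - 0.2 <= summary.mode <= 2.7 + 0.2

    def test_too_few_voxels_refused(self):
        counts = np.full((2, 2, 2), 100)
        vals = np.linspace(1, 3, 8).reshape(2, 2, 2)
        with pytest.raises(ValueError, match="usable voxels"):
            flim_cilium_mode(FlimVolume(counts, vals), np.ones((2, 2, 2), bool))

    def test_lifetime_model_validation(self):
        with pytest.raises(ValueError):
            LifetimeModel(tau_quenched=3.0, tau_unquenched=2.7)
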