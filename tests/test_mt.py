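"""Magnetic-tweezer trace pipeline: smoothing, baselines, event calling,
lifetimes, hat slopes, and compaction screening."""

import numpy as np
import pytest

from pscloop import (EventDetectionConfig, GroundTruth, HatCurve,
                     HatCurveModel, Trace, TraceGenConfig, baseline_stats,
                     detect_events, fit_lifetimes, gen_hat_curve, gen_mt_trace,
                     hat_extension, hat_slope, screen_compaction, smooth)


def make_trace(ext, rate=10.0, **kw):
    ext = np.asarray(ext, dtype=float)
    return Trace(time=np.arange(ext.size) / rate, extension=ext, **kw)


class TestSmooth:
    def test_constant_unchanged(self):
        tr = make_trace(np.full(200, 3.0))
        assert np.allclose(smooth(tr, 2.0).extension, 3.0)

    def test_noise_variance_reduction(self):
        rng = np.random.default_rng(0)
        tr = make_trace(rng.normal(0, 0.1, 100_000), rate=50.0)
        sm = smooth(tr, 5.0)
        interior = sm.extension[500:-500]
        expected = 0.1 / np.sqrt(5.0 * 50.0)
        assert interior.std() == pytest.approx(expected, rel=0.10)

    def test_impulse_response(self):
        ext = np.zeros(400)
        ext[200] = 1.0
        sm = smooth(make_trace(ext, rate=10.0), 2.0)
        assert sm.extension[200] == pytest.approx(1.0 / 20.0)

    def test_invalid_window_rejected(self):
        tr = make_trace(np.zeros(100))
        with pytest.raises(ValueError):
            smooth(tr, -1.0)
        with pytest.raises(ValueError):
            smooth(tr, 1e6)


class TestBaselineStats:
    def test_recovers_gaussian_moments(self):
        rng = np.random.default_rng(1)
        tr = make_trace(rng.normal(4.0, 0.05, 20_000), rate=50.0)
        mean, sd = baseline_stats(tr)
        assert mean == pytest.approx(4.0, rel=0.02)
        assert sd == pytest.approx(0.05, rel=0.02)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError):
            baseline_stats(make_trace(np.full(500, 4.0)))

    def test_bimodal_trace_flagged(self):
        rng = np.random.default_rng(2)
        ext = np.r_[rng.normal(3.0, 0.03, 5000), rng.normal(4.0, 0.03, 5000)]
        with pytest.warns(UserWarning, match="poor Gaussian|multimodal"):
            baseline_stats(make_trace(ext, rate=50.0))


class TestDetectEvents:
    def test_single_event_recovered(self, baseline):
        # seed chosen so the drawn dwell (14.8 s) is comfortably above the
        # 2 x min_duration regime the recovery guarantee applies to
        cfg = TraceGenConfig(duration=200, sample_rate=20, event_count=1,
                             event_amplitude_sd=0.0, event_rise_rate=0.5,
                             seed=2)
        tr, truth = gen_mt_trace(cfg)
        events = [e for e in detect_events(tr, baseline) if not e.censored]
        assert len(events) == 1
        ev = events[0]
        s, amp, rise, dwell = truth.events[0]
        assert ev.peak_amplitude == pytest.approx(amp, rel=0.05)
        expected = GroundTruth.threshold_dwell(truth.events[0], 3 * baseline[1])
        assert abs(ev.lifetime - expected) < 5.0  # one smoothing window
        assert ev.positive_rate >= 0

    def test_short_excursion_excluded(self):
        # 1.5 s above threshold at the >2.5 s rule: no call
        t = np.arange(0, 60, 0.1)
        ext = np.where((t >= 30) & (t < 31.5), 1.0, 0.0)
        tr = Trace(time=t, extension=ext, smoothed=True)
        assert detect_events(tr, (0.0, 0.05)) == []
        # but a 4 s excursion is called
        ext2 = np.where((t >= 30) & (t < 34), 1.0, 0.0)
        tr2 = Trace(time=t, extension=ext2, smoothed=True)
        assert len(detect_events(tr2, (0.0, 0.05))) == 1

    def test_translation_invariance(self, baseline):
        tr, _ = gen_mt_trace(TraceGenConfig(duration=200, sample_rate=20,
                                            seed=3))
        ev0 = detect_events(tr, baseline)
        shifted = Trace(time=tr.time, extension=tr.extension + 2.5)
        ev1 = detect_events(shifted, (baseline[0] + 2.5, baseline[1]))
        assert [e.start for e in ev1] == [e.start for e in ev0]
        assert [e.peak_amplitude for e in ev1] == pytest.approx(
            [e.peak_amplitude for e in ev0])

    def test_event_at_record_end_censored(self):
        t = np.arange(0, 60, 0.1)
        ext = np.where(t >= 50, 1.0, 0.0)
        tr = Trace(time=t, extension=ext, smoothed=True)
        events = detect_events(tr, (0.0, 0.05))
        assert len(events) == 1 and events[0].censored

    def test_zero_baseline_sd_rejected(self):
        tr = make_trace(np.zeros(100))
        with pytest.raises(ValueError):
            detect_events(tr, (0.0, 0.0))


class TestFitLifetimes:
    def test_recovers_programmed_half_life(self):
        rng = np.random.default_rng(7)
        dwells = rng.exponential(20 / np.log(2), 300)
        fit = fit_lifetimes(dwells)
        assert fit.ci95[0] <= 20.0 <= fit.ci95[1]
        assert fit.half_life == pytest.approx(20.0, rel=0.2)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        dwells = rng.exponential(10.0, 100)
        assert fit_lifetimes(2 * dwells).half_life == pytest.approx(
            2 * fit_lifetimes(dwells).half_life)

    def test_survival_method_agrees(self):
        rng = np.random.default_rng(9)
        dwells = rng.exponential(20 / np.log(2), 500)
        mle = fit_lifetimes(dwells, method="mle")
        surv = fit_lifetimes(dwells, method="survival")
        assert surv.half_life == pytest.approx(mle.half_life, rel=0.15)

    def test_degenerate_dwells_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_lifetimes(np.full(20, 5.0))
        assert fit.degenerate

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="9"):
            fit_lifetimes(np.ones(9))


class TestHatSlope:
    def test_noiseless_arm_slope_exact(self):
        m = HatCurveModel()
        hat = gen_hat_curve(m, noise_sd=0.0, n_points=281)
        fit = hat_slope(hat, -70, -20)
        assert fit.slope == pytest.approx(m.slope_neg, abs=1e-12)
        assert not fit.mixed_regime

    def test_flat_melted_arm_distinguished(self):
        # a melting (non-buckling) negative arm stays flat; at SNR 10 its
        # fitted slope separates cleanly from a buckling arm's
        turns = np.linspace(-70, -20, 100)
        rng = np.random.default_rng(3)
        m = HatCurveModel()
        noise = abs(m.slope_neg) * 50 / 10
        flat = HatCurve(turns=turns,
                        extension=4.0 + rng.normal(0, noise, turns.size))
        arm = HatCurve(turns=turns,
                       extension=hat_extension(m, turns)
                       + rng.normal(0, noise, turns.size))
        s_flat = hat_slope(flat, -70, -20).slope
        s_arm = hat_slope(arm, -70, -20).slope
        assert abs(s_flat) < 0.015 < abs(s_arm)

    def test_window_spanning_apex_flagged(self):
        m = HatCurveModel()
        hat = gen_hat_curve(m, noise_sd=0.0, n_points=281)
        fit = hat_slope(hat, -40, 40)
        assert fit.mixed_regime
        assert abs(fit.slope) < abs(m.slope_neg)

    def test_empty_window_rejected(self):
        hat = gen_hat_curve(HatCurveModel(), n_points=10)
        with pytest.raises(ValueError):
            hat_slope(hat, 200, 300)


class TestScreenCompaction:
    def test_clean_trace_kept_whole(self):
        tr = make_trace(np.linspace(3.0, 3.5, 600), rate=10.0)
        kept, censored = screen_compaction(tr, (3.0, 0.01))
        assert not censored
        assert kept.time.size == tr.time.size

    def test_truncated_at_first_dip(self):
        t = np.arange(0, 300, 0.1)
        ext = np.where(t < 120, 3.0, 2.0)
        tr = Trace(time=t, extension=ext, smoothed=True)
        kept, censored = screen_compaction(tr, (3.0, 0.01))
        assert censored
        assert kept.time[-1] == pytest.approx(120.0, abs=0.2)

    def test_recovery_after_dip_still_truncated(self):
        t = np.arange(0, 300, 0.1)
        ext = np.where((t >= 120) & (t < 150), 2.0, 3.0)  # dips then recovers
        tr = Trace(time=t, extension=ext, smoothed=True)
        kept, censored = screen_compaction(tr, (3.0, 0.01))
        assert censored
        assert kept.time[-1] < 121.0
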