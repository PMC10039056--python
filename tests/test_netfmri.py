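"""Event-triggered BOLD averaging, contrasts, synergy and pre-transition stats."""

import numpy as np
import pandas as pd
import pytest

from sleepscape.dynamics import TransitionEpochSet
from sleepscape.glm import make_hrf
from sleepscape.io import BoldSeries, EventTable, EVENT_COLUMNS
from sleepscape.netfmri import (DataError, NetResponse, compare_conditions,
                                event_frames, event_triggered_response,
                                pre_transition_event_probability,
                                pre_transition_spectrogram_contrast,
                                response_power_correlation,
                                sample_control_epochs, session_synergy,
                                synergy_analysis)


def _events(rows):
    return EventTable(pd.DataFrame(rows, columns=EVENT_COLUMNS))


def _bold(series_matrix, TR=2.0):
    """(t, v) matrix -> BoldSeries on a small grid with v brain voxels."""
    t, v = series_matrix.shape
    grid = (v, 1, 2)
    vol = np.zeros(grid + (t,))
    brain = np.zeros(grid, bool)
    brain[:, 0, 0] = True
    nonbrain = np.zeros(grid, bool)
    nonbrain[:, 0, 1] = True
    vol[brain] = series_matrix.T
    vol[nonbrain] = 100.0
    return BoldSeries(vol, TR, brain, nonbrain, np.zeros((t, 6)))


class TestEventFrames:
    def test_binning_collapses_duplicates(self):
        ev = _events([("SWR", "c", 10.1, 10.0, 10.2, 1.0, "NA", "NREM"),
                      ("SWR", "c", 10.9, 10.8, 11.0, 1.0, "NA", "NREM")])
        np.testing.assert_array_equal(event_frames(ev, 2.0), [5])

    def test_state_filter(self):
        ev = _events([("SWR", "c", 4.0, 3.9, 4.1, 1.0, "NA", "AW"),
                      ("SWR", "c", 8.0, 7.9, 8.1, 1.0, "NA", "NREM")])
        np.testing.assert_array_equal(
            event_frames(ev, 2.0, state="NREM"), [4])

    def test_coupling_filter(self):
        ev = _events([("SWR", "c", 4.0, 3.9, 4.1, 1.0, "coupled", "NREM"),
                      ("SWR", "c", 8.0, 7.9, 8.1, 1.0, "uncoupled", "NREM")])
        np.testing.assert_array_equal(
            event_frames(ev, 2.0, coupling="uncoupled"), [4])


class TestTriggeredResponse:
    def test_impulse_recovers_hrf_shape(self):
        hrf = make_hrf(TR=2.0).samples_tr
        t = 400
        frames = np.arange(20, 380, 20)
        sig = np.zeros(t)
        for f in frames:
            sig[f:f + hrf.size] += hrf[:min(hrf.size, t - f)]
        b = _bold(100.0 + np.tile(sig[:, None], (1, 3)))
        resp = event_triggered_response(b, frames, window=(-5, 10),
                                        baseline_frames=(-5, -2))
        tc = resp.roi_mean()
        expect = 100.0 * np.concatenate([np.zeros(5), hrf[:11]]) / 100.0
        np.testing.assert_allclose(tc, expect, atol=1e-6 * max(hrf))

    def test_constant_series_zero_response(self):
        b = _bold(np.full((100, 2), 100.0))
        resp = event_triggered_response(b, np.arange(20, 80, 10))
        np.testing.assert_allclose(resp.response, 0.0, atol=1e-12)

    def test_sem_halves_per_quadrupling(self, rng):
        sems = []
        for n_ep in (25, 100, 400):
            t = 20 * (n_ep + 2)
            b = _bold(100.0 + rng.standard_normal((t, 1)))
            frames = np.arange(10, 20 * n_ep, 20)[:n_ep]
            snips = []
            for f in frames:
                series = b.masked()[:, 0]
                base = series[f - 5:f - 1].mean()
                snips.append(100 * (series[f:f + 5] - base) / base)
            sems.append(np.std(snips, axis=0).mean() / np.sqrt(n_ep))
        assert sems[0] / sems[1] == pytest.approx(2.0, rel=0.25)
        assert sems[1] / sems[2] == pytest.approx(2.0, rel=0.25)

    def test_out_of_bounds_epochs_dropped(self):
        b = _bold(np.full((50, 2), 100.0))
        resp = event_triggered_response(b, [2, 25, 48])
        assert resp.n_epochs == 1
        with pytest.raises(DataError):
            event_triggered_response(b, [2])


def _resp(scalar, rng, v=4, w=(-5, 10)):
    n = w[1] - w[0] + 1
    r = rng.standard_normal((n, v)) * 0.05
    r[5:11] += scalar
    return NetResponse(w, r, 30, (-5, -2))


class TestCompareConditions:
    def test_single_session_missing_p(self, rng):
        out = compare_conditions([_resp(1.0, rng)], [_resp(0.5, rng)])
        assert out["p"] is None
        assert out["difference"] > 0

    def test_paired_detection(self, rng):
        a = [_resp(1.0 + 0.1 * rng.standard_normal(), rng) for _ in range(8)]
        b = [_resp(0.4 + 0.1 * rng.standard_normal(), rng) for _ in range(8)]
        out = compare_conditions(a, b)
        assert out["p"] < 0.01 and out["difference"] > 0.3

    def test_identical_conditions_calibrated(self):
        # p under the null is uniform: check rejection rate over seeds
        rejections = 0
        n_seeds = 60
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            a = [_resp(0.5 + 0.2 * r.standard_normal(), r) for _ in range(6)]
            b = [_resp(0.5 + 0.2 * r.standard_normal(), r) for _ in range(6)]
            out = compare_conditions(a, b, paired=False)
            rejections += out["p"] < 0.05
        assert rejections <= 9                  # binomial 95% upper at p=0.05


class TestSynergy:
    def _session(self, rng, surplus=0.0, t=600):
        # events spaced past the HRF tail so baselines stay clean
        hrf = make_hrf(TR=2.0).samples_tr
        frames = {"sp": np.arange(10, 190, 15),
                  "swr": np.arange(210, 390, 15),
                  "cp": np.arange(410, 590, 15)}
        sig = np.zeros(t)
        amp = {"sp": 1.0, "swr": 0.8, "cp": 1.8 + surplus}
        rows = []
        for key, fr in frames.items():
            for f in fr:
                sig[f:f + hrf.size] += amp[key] * hrf[:min(hrf.size, t - f)]
                c = f * 2.0 + 0.5
                if key == "sp":
                    rows.append(("spindle", "i", c, c - 0.5, c + 0.5, 1.0,
                                 "uncoupled", "NREM"))
                elif key == "swr":
                    rows.append(("SWR", "l", c, c - 0.03, c + 0.03, 1.0,
                                 "uncoupled", "NREM"))
                else:
                    rows.append(("SWR", "l", c, c - 0.03, c + 0.03, 1.0,
                                 "coupled", "NREM"))
        noise = 0.05 * rng.standard_normal((t, 3))
        b = _bold(100.0 + sig[:, None] + noise)
        return b, _events(rows)

    def test_summed_of_zero_responses_is_zero(self):
        b = _bold(np.full((600, 2), 100.0))
        rng = np.random.default_rng(0)
        _, ev = self._session(rng)
        out = session_synergy(b, ev, 2.0)
        np.testing.assert_allclose(out["summed"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["diff"], 0.0, atol=1e-12)

    def test_additive_sessions_null(self):
        rng = np.random.default_rng(1)
        sessions = [self._session(rng, surplus=0.0) for _ in range(10)]
        out = synergy_analysis([session_synergy(b, e, 2.0)
                                for b, e in sessions])
        assert out["p"] > 0.01
        assert abs(out["diff"].mean()) < 0.1

    def test_supralinear_detected(self):
        rng = np.random.default_rng(2)
        sessions = [self._session(rng, surplus=0.8) for _ in range(10)]
        out = synergy_analysis([session_synergy(b, e, 2.0)
                                for b, e in sessions])
        assert out["p"] < 0.05
        assert out["diff"].mean() > 0

    def test_insufficient_epochs_skipped(self):
        rng = np.random.default_rng(3)
        b, ev = self._session(rng)
        few = EventTable(ev.df.iloc[:5])
        assert session_synergy(b, few, 2.0) is None


def _tset(times, ttype="NREM_to_AW"):
    return TransitionEpochSet([{"type": ttype, "t_trans": float(t),
                                "pre_dur": 100, "post_dur": 100}
                               for t in times])


class TestPreTransition:
    def _uniform_events(self, rate, dur, rng):
        n = rng.poisson(rate * dur)
        centers = np.sort(rng.uniform(0, dur, n))
        rows = [("SWR", "l", c, c - 0.03, c + 0.03, 1.0, "NA", "NREM")
                for c in centers]
        return _events(rows)

    def test_rate_decline_found_early(self, rng):
        dur = 20000
        trans = np.arange(300, dur - 300, 400.0)
        ctrl = np.arange(500, dur - 300, 400.0)
        centers = []
        t = 0.0
        while t < dur:
            t += rng.exponential(1 / 0.5)
            near = np.abs(trans - t)
            d = t - trans[np.argmin(near)]
            # rate collapses to zero over the 10 s before each transition
            keep_p = 1.0 if not (-10 <= d < 0) else max(0.0, (-d - 7) / 3.0)
            if rng.random() < keep_p:
                centers.append(t)
        rows = [("SWR", "l", c, c - 0.03, c + 0.03, 1.0, "NA", "NREM")
                for c in centers]
        out = pre_transition_event_probability(_events(rows), _tset(trans),
                                               ctrl)
        assert out["earliest_sig_s"] is not None
        assert out["earliest_sig_s"] <= -6.0
        assert np.all((out["p_transition"] >= 0)
                      & (out["p_transition"] <= 1))

    def test_constant_rate_rarely_significant(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            dur = 8000
            ev = self._uniform_events(0.4, dur, rng)
            trans = np.arange(200, dur - 200, 300.0)
            ctrl = np.arange(350, dur - 200, 300.0)
            out = pre_transition_event_probability(ev, _tset(trans), ctrl)
            # single pre-chosen second for the calibration count
            hits += out["pvals"][10] < 0.05
        assert hits <= 5

    def test_too_few_transitions_rejected(self):
        ev = self._uniform_events(0.5, 1000, np.random.default_rng(0))
        with pytest.raises(DataError):
            pre_transition_event_probability(ev, _tset([100.0]),
                                             np.arange(10))


class TestSpectrogramContrast:
    def _spec(self, dur, rng, boost_times=None):
        freqs = np.arange(1.0, 31.0)
        power = rng.standard_normal((dur, freqs.size)) * 0.2 + 1.0
        if boost_times is not None:
            for t0 in boost_times:
                power[int(t0) - 10:int(t0), 5:9] += 2.0   # theta rows
        return np.arange(dur, dtype=float), freqs, power

    def test_theta_boost_cluster(self, rng):
        dur = 8000
        trans = np.arange(200, dur - 200, 300.0)
        ctrl = trans + 140.0
        times, freqs, power = self._spec(dur, rng, boost_times=trans)
        out = pre_transition_spectrogram_contrast(times, freqs, power,
                                                  _tset(trans), ctrl)
        sig_theta = out["sig"][-10:, 5:9]
        assert sig_theta.mean() > 0.8
        assert out["sig"][:15, 15:].mean() < 0.15

    def test_identical_distributions_calibrated(self, rng):
        dur = 6000
        trans = np.arange(200, dur - 200, 300.0)
        ctrl = trans + 140.0
        times, freqs, power = self._spec(dur, rng)
        out = pre_transition_spectrogram_contrast(times, freqs, power,
                                                  _tset(trans), ctrl)
        assert 0.005 < out["sig"].mean() < 0.15

    def test_empty_control_rejected(self, rng):
        times, freqs, power = self._spec(1000, rng)
        with pytest.raises(DataError):
            pre_transition_spectrogram_contrast(times, freqs, power,
                                                _tset([500.0]),
                                                np.empty(0))


class TestResponsePowerCorrelation:
    def test_identical_vectors_r_one(self):
        x = np.arange(8.0)
        r = response_power_correlation(x, np.tile(x[:, None], (1, 5)))
        np.testing.assert_allclose(r, 1.0, atol=1e-12)

    def test_band_limited_coupling(self, rng):
        n, nf = 20, 50
        bold = rng.standard_normal(n)
        power = rng.standard_normal((n, nf)) * 0.2
        power[:, 3:25] += bold[:, None]          # couple 3-25 Hz rows
        r = response_power_correlation(bold, power)
        assert r[3:25].min() > 0.7
        assert np.abs(r[30:]).mean() < 0.4

    def test_too_few_sessions(self):
        with pytest.raises(DataError):
            response_power_correlation(np.ones(3), np.ones((3, 5)))


class TestControlSampling:
    def test_anchors_inside_long_epochs(self, rng):
        epochs = [(0.0, 50.0), (100.0, 300.0), (400.0, 420.0)]
        anchors = sample_control_epochs(epochs, 30, 30.0, rng)
        assert anchors.size == 30
        # the 20 s epoch cannot hold a 30 s window; the others can, with
        # the window fitting fully inside
        in_first = (anchors >= 30.0) & (anchors <= 49.0)
        in_second = (anchors >= 130.0) & (anchors <= 299.0)
        assert np.all(in_first | in_second)
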