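"""Group PCA, phase profiles, transition averages, manifold, asymmetry."""

import numpy as np
import pytest

from sleepscape.dynamics import (GroupPCA, TransitionEpochSet,
                                 electrophysiological_state_space,
                                 extract_transitions, group_pca,
                                 manifold_trajectories, state_phase_profiles,
                                 transition_asymmetry,
                                 transition_triggered_average)
from conftest import make_hypnogram


class TestGroupPCA:
    def test_single_scan_matches_one_step_pca(self, rng):
        S = rng.standard_normal((80, 50))
        g = GroupPCA(p_scan=50, p0=20).fit([S])
        Sc = S - S.mean(axis=0)
        _, _, vt = np.linalg.svd(Sc, full_matrices=False)
        scores = Sc @ vt[:20].T
        # align per-component signs before comparison
        for j in range(20):
            if np.dot(g.components_[j], vt[j]) < 0:
                scores[:, j] *= -1
        assert np.abs(g.scan_tpcs_[0] - scores).max() < 1e-8

    def test_rows_orthonormal(self, rng):
        scans = [rng.standard_normal((60, 40)) for _ in range(3)]
        g = group_pca(scans, p_scan=30, p0=15)
        gram = g.components_ @ g.components_.T
        assert np.abs(gram - np.eye(15)).max() < 1e-10

    def test_three_component_data_concentrates_variance(self, rng):
        maps = np.linalg.qr(rng.standard_normal((40, 3)))[0].T
        scans = []
        for _ in range(4):
            tc = rng.standard_normal((70, 3)) * [5, 3, 2]
            scans.append(tc @ maps + 0.01 * rng.standard_normal((70, 40)))
        g = group_pca(scans, p_scan=20, p0=10)
        assert g.explained_variance_ratio_[:3].sum() >= 0.95

    def test_explained_variance_non_increasing(self, rng):
        g = group_pca([rng.standard_normal((50, 30))], p_scan=30, p0=10)
        assert np.all(np.diff(g.explained_variance_ratio_) <= 1e-12)

    def test_p0_capped_at_rank_with_warning(self, rng):
        g = GroupPCA(p_scan=10, p0=50).fit([rng.standard_normal((20, 30))])
        assert g.n_components_ <= 10

    def test_transform_matches_fit_tpcs(self, rng):
        scans = [rng.standard_normal((40, 25)) for _ in range(2)]
        g = group_pca(scans, p_scan=20, p0=8)
        out = g.transform(scans)
        for a, b in zip(out, g.scan_tpcs_):
            np.testing.assert_allclose(a, b, atol=1e-10)

    def test_sklearn_params_roundtrip(self):
        g = GroupPCA(p_scan=12, p0=6)
        assert GroupPCA(**g.get_params()).p0 == 6


class TestTransitions:
    def test_flank_filter(self):
        hyp = make_hypnogram([("AW", 100), ("NREM", 30), ("AW", 100),
                              ("NREM", 80), ("REM", 120), ("AW", 70)])
        tset = extract_transitions(hyp, min_flank=60)
        types = [t["type"] for t in tset.transitions]
        # AW->NREM(30s) fails post-flank; NREM(30)->AW fails pre-flank
        assert types == ["AW_to_NREM", "NREM_to_REM", "REM_to_AW"]

    def test_observed_types_only(self):
        hyp = make_hypnogram([("AW", 100), ("NREM", 100), ("AW", 100)])
        tset = extract_transitions(hyp)
        assert all(t["type"] in ("AW_to_NREM", "NREM_to_AW")
                   for t in tset.transitions)


class TestPhaseProfiles:
    def test_constant_tpc_flat_inside_null(self, rng):
        hyp = make_hypnogram([("AW", 100), ("NREM", 100)] * 4)
        tpcs = np.ones((400, 2)) + 0.01 * rng.standard_normal((400, 2))
        out = state_phase_profiles(tpcs, hyp, dt=2.0, n_bins=30,
                                   n_shuffle=200, rng=rng)
        prof = out["NREM"]["profile"]
        inside = ((prof >= out["NREM"]["null_lo"])
                  & (prof <= out["NREM"]["null_hi"]))
        assert inside.mean() > 0.9

    def test_ramp_escapes_null(self, rng):
        hyp = make_hypnogram([("AW", 100), ("NREM", 100)] * 6)
        n_sec = 1200
        x = np.zeros(n_sec)
        for a, b in hyp.epochs_of("NREM"):
            x[int(a):int(b)] = np.linspace(-1, 1, int(b - a))
        x += 0.05 * rng.standard_normal(n_sec)
        out = state_phase_profiles(x[:, None], hyp, dt=1.0, n_bins=30,
                                   n_shuffle=300, rng=rng)
        prof = out["NREM"]["profile"][:, 0]
        escapes = ((prof < out["NREM"]["null_lo"][:, 0])
                   | (prof > out["NREM"]["null_hi"][:, 0]))
        assert escapes.mean() > 0.5
        assert np.all(np.diff(prof) > -0.05)     # monotone ramp recovered

    def test_identity_resampling(self):
        hyp = make_hypnogram([("NREM", 60), ("AW", 60)])
        x = np.arange(120.0)
        out = state_phase_profiles(x[:, None], hyp, dt=1.0, n_bins=60,
                                   n_shuffle=10, min_dur=60)
        np.testing.assert_allclose(out["NREM"]["profile"][:, 0],
                                   np.arange(60.0), atol=1e-9)


class TestTransitionAverage:
    def _tset(self, times, ttype="AW_to_NREM"):
        return TransitionEpochSet([{"type": ttype, "t_trans": t,
                                    "pre_dur": 100, "post_dur": 100}
                                   for t in times])

    def test_step_centred_at_zero(self):
        n = 2000
        times = np.arange(100, 1900, 200.0)
        x = np.zeros(n)
        for t in times:
            x[int(t):] += 1.0
        x -= x.mean()
        out = transition_triggered_average(x, 1.0, self._tset(times),
                                           window_s=30, n_shuffle=50)
        m = out["AW_to_NREM"]["mean"][:, 0]
        t_ax = out["AW_to_NREM"]["t"]
        step = np.diff(m)
        assert t_ax[np.argmax(step) + 1] == 0.0

    def test_white_noise_within_null(self, rng):
        x = rng.standard_normal(3000)
        times = np.arange(200, 2800, 100.0)
        out = transition_triggered_average(x, 1.0, self._tset(times),
                                           window_s=30, n_shuffle=500,
                                           rng=rng)
        r = out["AW_to_NREM"]
        inside = (r["mean"][:, 0] >= r["null_lo"][:, 0]) \
            & (r["mean"][:, 0] <= r["null_hi"][:, 0])
        assert inside.mean() >= 0.9

    def test_sem_scales_inverse_sqrt_n(self, rng):
        sems = []
        for n_tr in (10, 40, 160):
            x = rng.standard_normal(200 * (n_tr + 2))
            times = np.arange(100, 200 * (n_tr + 1), 200.0)[:n_tr]
            out = transition_triggered_average(x, 1.0, self._tset(times),
                                               window_s=10, n_shuffle=10,
                                               rng=rng)
            sems.append(out["AW_to_NREM"]["sem"].mean())
        assert sems[0] / sems[1] == pytest.approx(2.0, rel=0.35)
        assert sems[1] / sems[2] == pytest.approx(2.0, rel=0.35)


class TestManifold:
    def test_separated_clusters(self, rng):
        hyp = make_hypnogram([("AW", 300), ("NREM", 300)])
        pts = np.zeros((300, 3))
        pts[:150] = [0, 0, 0]
        pts[150:] = [20, 20, 0]
        pts += 0.5 * rng.standard_normal((300, 3))
        out = manifold_trajectories(pts, hyp, dt=2.0)
        lab = out["labels"]
        aw = out["points"][lab == "AW"]
        nr = out["points"][lab == "NREM"]
        sep = np.linalg.norm(aw.mean(0) - nr.mean(0))
        within = max(aw.std(0).max(), nr.std(0).max())
        assert sep > 5 * within

    def test_flow_zero_at_fixed_point(self):
        hyp = make_hypnogram([("AW", 100)])
        pts = np.tile([1.0, 2.0, 3.0], (50, 1))
        out = manifold_trajectories(pts, hyp, dt=2.0)
        finite = out["flow"][~np.isnan(out["flow"])]
        np.testing.assert_allclose(finite, 0.0, atol=1e-12)

    def test_step_bookkeeping(self, rng):
        hyp = make_hypnogram([("AW", 100)])
        pts = rng.standard_normal((50, 3))
        out = manifold_trajectories(pts, hyp, dt=2.0)
        lens = np.linalg.norm(np.diff(out["points"], axis=0), axis=1)
        np.testing.assert_allclose(
            np.linalg.norm(out["step"], axis=1), lens, atol=1e-12)


class TestAsymmetry:
    def _sets(self, n_each, traj, rng, noise=0.0, reverse_back=True):
        """Build a series containing n_each transitions of both directions."""
        w = traj.shape[0] // 2
        span = 200
        n_t = span * (2 * n_each + 2)
        x = np.zeros((n_t, traj.shape[1]))
        trs = []
        for k in range(2 * n_each):
            c = span * (k + 1)
            ttype = "AW_to_NREM" if k % 2 == 0 else "NREM_to_AW"
            shape = traj if ttype == "AW_to_NREM" else (
                traj[::-1] if reverse_back else traj * [1.0, -1.0, 1.0])
            x[c - w:c + w + 1] += shape
            trs.append({"type": ttype, "t_trans": float(c),
                        "pre_dur": span, "post_dur": span})
        if noise:
            x += noise * rng.standard_normal(x.shape)
        return x, TransitionEpochSet(trs)

    def test_time_reversed_pairs_give_zero_distance(self, rng):
        t = np.linspace(-1, 1, 61)
        traj = np.column_stack([np.tanh(3 * t), t ** 2, np.sin(t)])
        x, tset = self._sets(6, traj, rng, noise=0.0)
        out = transition_asymmetry(x, 1.0, tset, window_s=30, rng=rng)
        np.testing.assert_allclose(out["distance"], 0.0, atol=1e-9)

    def test_distinct_paths_significant_near_zero(self, rng):
        t = np.linspace(-1, 1, 61)
        traj = np.column_stack([np.tanh(3 * t), 4 * t ** 2, np.sin(t)])
        x, tset = self._sets(8, traj, rng, noise=0.05, reverse_back=False)
        out = transition_asymmetry(x, 1.0, tset, window_s=30, rng=rng)
        centre = np.abs(out["t"]) <= 5
        assert (out["p"][centre] < 0.05).any()

    def test_symmetric_noisy_mostly_non_significant(self, rng):
        t = np.linspace(-1, 1, 61)
        traj = np.column_stack([np.tanh(3 * t), t ** 2, np.sin(t)])
        x, tset = self._sets(10, traj, rng, noise=0.3)
        out = transition_asymmetry(x, 1.0, tset, window_s=30, rng=rng)
        assert (out["p"] > 0.05).mean() >= 0.9

    def test_too_few_transitions_missing(self, rng):
        t = np.linspace(-1, 1, 61)
        traj = np.column_stack([t, t, t])
        x, tset = self._sets(2, traj, rng)
        out = transition_asymmetry(x, 1.0, tset, window_s=30, rng=rng)
        assert out["distance"] is None


class TestStateSpace:
    def test_pure_delta_x_near_one(self):
        from sleepscape.staging import StagingFeatures
        n = 50
        ones = np.ones(n)
        f = StagingFeatures(np.arange(n) + 0.5, 10 * ones, 0.01 * ones,
                            ones, 10.1 * ones, 0.001 * ones, 10 * ones,
                            0.01 * ones, 0.001 * ones, ones, {})
        out = electrophysiological_state_space(f)
        assert np.all(out["x"] > 0.95)

    def test_rem_like_high_ratio_low_delta(self):
        from sleepscape.staging import StagingFeatures
        n = 50
        ones = np.ones(n)
        f = StagingFeatures(np.arange(n) + 0.5, 0.5 * ones, 5 * ones, ones,
                            10 * ones, 10 * ones, 0.5 * ones, 5 * ones,
                            10 * ones, ones, {})
        out = electrophysiological_state_space(f)
        assert np.all(out["y"] > 5) and np.all(out["x"] < 0.2)

    def test_session_states_linearly_separable(self, default_session):
        from sleepscape.staging import compute_staging_features
        from sklearn.linear_model import LogisticRegression
        _, bundle, truth = default_session
        f = compute_staging_features(bundle.ephys, "ecog01", "emg1")
        out = electrophysiological_state_space(f)
        labels = np.array(truth.hypnogram.labels)[:f.n_seconds]
        X = np.column_stack([out["x"], np.log(out["y"])])
        clf = LogisticRegression(max_iter=2000).fit(X, labels)
        assert clf.score(X, labels) >= 0.9
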