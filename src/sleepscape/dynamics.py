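"""Group PCA of BOLD dynamics and state-trajectory analyses.

The two-step group decomposition reduces each scan to ``p_scan`` spatial
components, stacks the reduced matrices across scans, and extracts
``p0`` group spatial weights W (rows orthonormal). Back-projecting a scan
onto W yields its temporal component series (tPCs), the substrate for
phase profiles, transition-triggered averages, the low-dimensional
manifold, and the transition-asymmetry test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import Hypnogram
from .staging import StagingFeatures

logger = logging.getLogger("sleepscape")

TRANSITION_TYPES = ("AW_to_NREM", "NREM_to_AW", "NREM_to_REM", "REM_to_AW")


class GroupPCA(TransformerMixin, BaseEstimator):
    """Two-step group PCA with temporal back-projection.

    Parameters
    ----------
    p_scan : int
        Scan-level reduction dimension (capped at each scan's rank).
    p0 : int
        Group dimension; rows of ``components_`` are orthonormal spatial
        weights with a deterministic sign (largest-|loading| voxel positive).

    Attributes (after fit)
    ----------------------
    components_ : (p0, v) group spatial weights W
    explained_variance_ratio_ : (p0,) fractions, non-increasing
    scan_tpcs_ : list of (t, p0) temporal weight matrices, one per scan
    scan_means_ : list of per-scan voxel means used for centering
    """

    def __init__(self, p_scan: int = 200, p0: int = 100):
        self.p_scan = p_scan
        self.p0 = p0

    def fit(self, X: Sequence[np.ndarray], y=None) -> "GroupPCA":
        scans = [np.asarray(s, float) for s in X]
        if not scans:
            raise ValueError("need at least one scan")
        v = scans[0].shape[1]
        if any(s.shape[1] != v for s in scans):
            raise ValueError("all scans must share the voxel space")
        reduced = []
        self.scan_means_ = []
        for s in scans:
            mu = s.mean(axis=0)
            self.scan_means_.append(mu)
            sc = s - mu
            u, sv, vt = np.linalg.svd(sc, full_matrices=False)
            k = min(self.p_scan, int((sv > sv[0] * 1e-12).sum()))
            reduced.append(sv[:k, None] * vt[:k])          # (k, v)
        stacked = np.vstack(reduced)
        u2, s2, vt2 = np.linalg.svd(stacked, full_matrices=False)
        rank = int((s2 > s2[0] * 1e-12).sum())
        p0 = min(self.p0, rank)
        if p0 < self.p0:
            logger.warning("p0 reduced from %d to available rank %d",
                           self.p0, p0)
        W = vt2[:p0]
        for j in range(p0):                                # sign convention
            k = int(np.argmax(np.abs(W[j])))
            if W[j, k] < 0:
                W[j] = -W[j]
        self.components_ = W
        var = s2[:p0] ** 2
        self.explained_variance_ratio_ = var / (s2 ** 2).sum()
        self.n_components_ = p0
        self.scan_tpcs_ = [ (s - m) @ W.T
                            for s, m in zip(scans, self.scan_means_) ]
        return self

    def transform(self, X: Sequence[np.ndarray]) -> list:
        """Back-project scans (centered per scan) onto the group weights."""
        W = self.components_
        out = []
        for s in X:
            s = np.asarray(s, float)
            out.append((s - s.mean(axis=0)) @ W.T)
        return out

    def fit_transform(self, X, y=None) -> list:
        return self.fit(X).scan_tpcs_


def group_pca(scans: Sequence[np.ndarray], p_scan: int = 200,
              p0: int = 100) -> GroupPCA:
    """Functional wrapper over the :class:`GroupPCA` estimator."""
    return GroupPCA(p_scan=p_scan, p0=p0).fit(scans)


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

@dataclass
class TransitionEpochSet:
    """Transitions with both flanking epochs at least ``min_flank`` s long."""

    transitions: list = field(default_factory=list)
    min_flank: float = 60.0

    def of_type(self, ttype: str) -> list:
        return [tr for tr in self.transitions if tr["type"] == ttype]


def extract_transitions(hyp: Hypnogram, min_flank: float = 60.0
                        ) -> TransitionEpochSet:
    """List state transitions whose flanking epochs are both >= min_flank."""
    out = []
    eps = hyp.epochs
    for (s0, a0, b0), (s1, a1, b1) in zip(eps, eps[1:]):
        ttype = f"{s0}_to_{s1}"
        if ttype not in TRANSITION_TYPES:
            continue
        pre, post = b0 - a0, b1 - a1
        if pre >= min_flank and post >= min_flank:
            out.append({"type": ttype, "t_trans": b0,
                        "pre_dur": pre, "post_dur": post})
    return TransitionEpochSet(out, min_flank)


def _resample_to_1hz(series: np.ndarray, dt: float) -> np.ndarray:
    """Linear resampling of a regularly sampled series to a 1 Hz grid."""
    series = np.asarray(series, float)
    n = series.shape[0]
    t_in = np.arange(n) * dt
    t_out = np.arange(0.0, t_in[-1] + 1e-9, 1.0)
    if series.ndim == 1:
        return np.interp(t_out, t_in, series)
    return np.column_stack([np.interp(t_out, t_in, series[:, j])
                            for j in range(series.shape[1])])


def state_phase_profiles(tpcs: np.ndarray, hyp: Hypnogram, dt: float,
                         n_bins: int = 60, n_shuffle: int = 1000,
                         min_dur: float = 60.0,
                         rng: Optional[np.random.Generator] = None) -> dict:
    """Within-state phase profiles (epoch onset -> offset) with a circular-
    shift null.

    Each qualifying epoch's tPC series is linearly resampled to ``n_bins``
    phase bins and averaged across epochs; the null re-averages after
    circularly shifting each epoch's resampled series by a uniform random
    offset. Returns per state: ``{profile (n_bins, p), null_lo, null_hi,
    n_epochs}``; states without qualifying epochs are absent.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    tpcs = np.asarray(tpcs, float)
    if tpcs.ndim == 1:
        tpcs = tpcs[:, None]
    n_t, p = tpcs.shape
    out = {}
    for state in ("AW", "NREM", "REM"):
        mats = []
        for a, b in hyp.epochs_of(state):
            if b - a < min_dur:
                continue
            i0, i1 = int(np.floor(a / dt)), int(np.ceil(b / dt))
            seg = tpcs[max(i0, 0):min(i1, n_t)]
            if seg.shape[0] < 2:
                continue
            src = np.linspace(0, 1, seg.shape[0])
            dst = np.linspace(0, 1, n_bins)
            mats.append(np.column_stack(
                [np.interp(dst, src, seg[:, j]) for j in range(p)]))
        if not mats:
            continue
        stack = np.stack(mats)                       # (n_ep, n_bins, p)
        profile = stack.mean(axis=0)
        null = np.empty((n_shuffle, n_bins, p))
        for k in range(n_shuffle):
            shifts = rng.integers(0, n_bins, size=stack.shape[0])
            null[k] = np.stack([np.roll(m, sh, axis=0)
                                for m, sh in zip(stack, shifts)]).mean(axis=0)
        out[state] = {
            "profile": profile,
            "null_lo": np.percentile(null, 2.5, axis=0),
            "null_hi": np.percentile(null, 97.5, axis=0),
            "n_epochs": stack.shape[0],
        }
    return out


def transition_triggered_average(series: np.ndarray, dt: float,
                                 tset: TransitionEpochSet,
                                 window_s: float = 30.0,
                                 n_shuffle: int = 1000,
                                 rng: Optional[np.random.Generator] = None
                                 ) -> dict:
    """Mean +- SEM of a series aligned to transitions, with a random-trigger
    null, on a common 1 Hz grid over ``+-window_s``.

    ``series`` is (t,) or (t, p) sampled every ``dt`` s. Returns per
    transition type ``{t, mean, sem, null_lo, null_hi, n}``.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    x = _resample_to_1hz(series, dt)
    x2 = x if x.ndim == 2 else x[:, None]
    n_t = x2.shape[0]
    w = int(round(window_s))
    rel = np.arange(-w, w + 1)
    out = {}
    for ttype in TRANSITION_TYPES:
        trs = tset.of_type(ttype)
        snips = []
        for tr in trs:
            c = int(round(tr["t_trans"]))
            if c - w < 0 or c + w >= n_t:
                continue
            snips.append(x2[c + rel])
        if not snips:
            continue
        stack = np.stack(snips)                      # (n, 2w+1, p)
        n = stack.shape[0]
        valid_lo, valid_hi = w, n_t - w - 1
        null_means = np.empty((n_shuffle,) + stack.shape[1:])
        for k in range(n_shuffle):
            cs = rng.integers(valid_lo, valid_hi, size=n)
            null_means[k] = np.stack([x2[c + rel] for c in cs]).mean(axis=0)
        out[ttype] = {
            "t": rel.astype(float),
            "mean": stack.mean(axis=0),
            "sem": stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else
                   np.zeros(stack.shape[1:]),
            "null_lo": np.percentile(null_means, 2.5, axis=0),
            "null_hi": np.percentile(null_means, 97.5, axis=0),
            "n": n,
        }
    return out


def manifold_trajectories(tpcs: np.ndarray, hyp: Hypnogram, dt: float,
                          dims: int = 3, flow_bins: int = 12) -> dict:
    """Per-second manifold points in the first ``dims`` PCs, labelled by
    state, plus the mean one-step flow field binned over the first two dims."""
    x = _resample_to_1hz(np.asarray(tpcs, float)[:, :dims], dt)
    n = x.shape[0]
    labels = (hyp.labels + [hyp.labels[-1]] * n)[:n]
    step = np.diff(x, axis=0)                        # displacement per second
    lo = x[:, :2].min(axis=0)
    hi = x[:, :2].max(axis=0)
    edges0 = np.linspace(lo[0], hi[0], flow_bins + 1)
    edges1 = np.linspace(lo[1], hi[1], flow_bins + 1)
    i0 = np.clip(np.digitize(x[:-1, 0], edges0) - 1, 0, flow_bins - 1)
    i1 = np.clip(np.digitize(x[:-1, 1], edges1) - 1, 0, flow_bins - 1)
    flow = np.zeros((flow_bins, flow_bins, 2))
    count = np.zeros((flow_bins, flow_bins))
    for k in range(step.shape[0]):
        flow[i0[k], i1[k]] += step[k, :2]
        count[i0[k], i1[k]] += 1
    with np.errstate(invalid="ignore"):
        flow = np.where(count[..., None] > 0, flow / count[..., None], np.nan)
    return {"points": x, "labels": np.array(labels), "step": step,
            "flow": flow, "flow_count": count,
            "edges": (edges0, edges1)}


def transition_asymmetry(series: np.ndarray, dt: float,
                         tset: TransitionEpochSet, window_s: float = 30.0,
                         dims: int = 3, n_null: int = 200,
                         rng: Optional[np.random.Generator] = None) -> dict:
    """Compare the mean AW->NREM trajectory with the time-reversed mean
    NREM->AW trajectory, pointwise, in the low-dimensional space.

    The null splits same-type transitions into random halves and measures
    the distance between half-means; the one-tailed p per time point is a
    prediction-interval t-test of the empirical distance against the null
    sample. Requires >= 5 transitions of each direction.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    x = _resample_to_1hz(np.asarray(series, float)[:, :dims], dt)
    n_t = x.shape[0]
    w = int(round(window_s))
    rel = np.arange(-w, w + 1)

    def snippets(ttype):
        snips = []
        for tr in tset.of_type(ttype):
            c = int(round(tr["t_trans"]))
            if c - w >= 0 and c + w < n_t:
                snips.append(x[c + rel])
        return snips

    fwd = snippets("AW_to_NREM")
    bwd = snippets("NREM_to_AW")
    if len(fwd) < 5 or len(bwd) < 5:
        return {"distance": None, "p": None, "n_fwd": len(fwd),
                "n_bwd": len(bwd)}
    A = np.stack(fwd)
    B = np.stack(bwd)
    mean_a = A.mean(axis=0)
    mean_b_rev = B.mean(axis=0)[::-1]
    dist = np.linalg.norm(mean_a - mean_b_rev, axis=1)

    null = np.empty((n_null, rel.size))
    for k in range(n_null):
        pool = A if k % 2 == 0 else B
        idx = rng.permutation(pool.shape[0])
        half = pool.shape[0] // 2
        m1 = pool[idx[:half]].mean(axis=0)
        m2 = pool[idx[half:]].mean(axis=0)
        null[k] = np.linalg.norm(m1 - m2, axis=1)
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    tstat = (dist - mu) / (sd * np.sqrt(1.0 + 1.0 / n_null) + 1e-30)
    p = stats.t.sf(tstat, df=n_null - 1)
    return {"t": rel.astype(float), "distance": dist, "null_mean": mu,
            "null_sd": sd, "p": p, "n_fwd": A.shape[0], "n_bwd": B.shape[0]}


def electrophysiological_state_space(f: StagingFeatures) -> dict:
    """Per-second 2D embedding: x = delta / total (1-100 Hz) power,
    y = theta/delta ratio."""
    x = f.delta_power / np.maximum(f.total_power, 1e-30)
    y = f.ratio
    return {"x": x, "y": y}
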