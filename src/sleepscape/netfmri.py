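"""Neural-event-triggered (NET) fMRI statistics.

BOLD responses are averaged time-locked to detected electrophysiological
events counted at the fMRI frame rate (0.5 Hz), expressed as % change from
a pre-event baseline, and compared across states / coupling classes with
t-tests; the synergy analysis asks whether the response to spindle-coupled
SWRs exceeds the sum of the solitary spindle and solitary SWR responses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .glm import bh_fdr
from .io import BoldSeries, EventTable
from .dynamics import TransitionEpochSet

logger = logging.getLogger("sleepscape")


class DataError(ValueError):
    pass


DEFAULT_WINDOW = (-5, 10)          # frames: -10..+20 s at TR 2 s
DEFAULT_BASELINE = (-5, -2)        # frames: -10..-4 s
POST_FRAMES = (0, 5)               # scalarization window, 0..+10 s


@dataclass
class NetResponse:
    """Mean event-triggered voxel response in % change from baseline."""

    window: tuple                  # (first, last) frame offsets, inclusive
    response: np.ndarray           # (n_window_frames, n_voxels)
    n_epochs: int
    baseline: tuple

    @property
    def rel_frames(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1] + 1)

    def roi_mean(self, roi_index: Optional[np.ndarray] = None) -> np.ndarray:
        """Time course averaged over a voxel subset (all voxels if None)."""
        r = self.response if roi_index is None else self.response[:, roi_index]
        return r.mean(axis=1)

    def scalar(self, roi_index: Optional[np.ndarray] = None,
               post: tuple = POST_FRAMES) -> float:
        """Session-level scalar: mean over post-event frames of the ROI mean."""
        tc = self.roi_mean(roi_index)
        sel = (self.rel_frames >= post[0]) & (self.rel_frames <= post[1])
        return float(tc[sel].mean())


def event_frames(events: EventTable, TR: float,
                 type: Optional[str] = None, state: Optional[str] = None,
                 coupling: Optional[str] = None) -> np.ndarray:
    """Frames containing >= 1 matching event center (duplicates collapsed)."""
    sub = events.select(type=type, state=state, coupled=coupling)
    if len(sub) == 0:
        return np.empty(0, int)
    frames = np.floor(sub.df["center_s"].to_numpy(float) / TR).astype(int)
    return np.unique(frames)


def event_triggered_response(b: BoldSeries, frames: np.ndarray,
                             window: tuple = DEFAULT_WINDOW,
                             baseline_frames: tuple = DEFAULT_BASELINE,
                             mask: Optional[np.ndarray] = None) -> NetResponse:
    """Average the voxel series around event frames, as % change from the
    per-epoch baseline mean; epochs overrunning the scan are dropped."""
    if len(frames) == 0:
        raise DataError("no event frames")
    series = b.masked(b.brain_mask if mask is None else mask)   # t x v
    t_n = series.shape[0]
    w0, w1 = window
    rel = np.arange(w0, w1 + 1)
    b0, b1 = baseline_frames
    epochs = []
    for f in np.asarray(frames, int):
        if f + w0 < 0 or f + w1 >= t_n:
            continue
        snip = series[f + rel]                                  # (w, v)
        base = series[f + np.arange(b0, b1 + 1)].mean(axis=0)
        base = np.where(np.abs(base) > 1e-12, base, np.nan)
        epochs.append(100.0 * (snip - base) / base)
    if not epochs:
        raise DataError("all event epochs overran the scan bounds")
    resp = np.nanmean(np.stack(epochs), axis=0)
    return NetResponse(window, resp, len(epochs), baseline_frames)


def compare_conditions(resp_a: Sequence[NetResponse],
                       resp_b: Sequence[NetResponse],
                       roi_index: Optional[np.ndarray] = None,
                       paired: bool = True,
                       voxelwise: bool = False, q: float = 0.05) -> dict:
    """Two-tailed t-test of per-session response scalars between conditions.

    With fewer than 3 sessions the difference is still reported but the p
    value is missing. ``voxelwise=True`` adds a BH-FDR-corrected per-voxel
    map (paired designs only).
    """
    a = np.array([r.scalar(roi_index) for r in resp_a])
    bvals = np.array([r.scalar(roi_index) for r in resp_b])
    diff = float(a.mean() - bvals.mean())
    out = {"difference": diff, "p": None, "n_a": a.size, "n_b": bvals.size}
    if min(a.size, bvals.size) >= 3:
        if paired and a.size == bvals.size:
            out["p"] = float(stats.ttest_rel(a, bvals).pvalue)
        else:
            out["p"] = float(stats.ttest_ind(a, bvals).pvalue)
    if voxelwise and paired and a.size == bvals.size and a.size >= 3:
        A = np.stack([_post_mean(r) for r in resp_a])
        B = np.stack([_post_mean(r) for r in resp_b])
        res = stats.ttest_rel(A, B, axis=0)
        out["voxel_t"] = res.statistic
        out["voxel_p"] = res.pvalue
        out["voxel_sig"] = bh_fdr(res.pvalue, q)
    return out


def _post_mean(r: NetResponse, post: tuple = POST_FRAMES) -> np.ndarray:
    sel = (r.rel_frames >= post[0]) & (r.rel_frames <= post[1])
    return r.response[sel].mean(axis=0)


def session_synergy(b: BoldSeries, events: EventTable, TR: float,
                    window: tuple = DEFAULT_WINDOW,
                    baseline_frames: tuple = DEFAULT_BASELINE,
                    min_epochs: int = 10) -> Optional[dict]:
    """Per-session coupled vs summed solitary responses, or None if any of
    the three event classes has fewer than ``min_epochs`` usable frames."""
    classes = {
        "solitary_spindle": dict(type="spindle", coupling="uncoupled"),
        "solitary_swr": dict(type="SWR", coupling="uncoupled"),
        "coupled_swr": dict(type="SWR", coupling="coupled"),
    }
    resp = {}
    for name, sel in classes.items():
        frames = event_frames(events, TR, **sel)
        if frames.size < min_epochs:
            logger.info("synergy: %s has %d epochs (< %d), session skipped",
                        name, frames.size, min_epochs)
            return None
        resp[name] = event_triggered_response(b, frames, window,
                                              baseline_frames)
    summed = resp["solitary_spindle"].response + resp["solitary_swr"].response
    coupled = resp["coupled_swr"].response
    return {"responses": resp, "summed": summed, "coupled": coupled,
            "diff": coupled - summed}


def synergy_analysis(sessions: Sequence[dict],
                     roi_index: Optional[np.ndarray] = None,
                     post: tuple = POST_FRAMES, q: float = 0.05) -> dict:
    """Paired t-test of coupled vs summed scalars across sessions, plus a
    voxelwise paired-t map. ``sessions`` are outputs of
    :func:`session_synergy` (None entries are excluded)."""
    usable = [s for s in sessions if s is not None]
    if not usable:
        raise DataError("no sessions with enough epochs in all classes")
    w = usable[0]["responses"]["coupled_swr"]
    sel = (w.rel_frames >= post[0]) & (w.rel_frames <= post[1])

    def scal(resp):
        r = resp[sel] if roi_index is None else resp[sel][:, roi_index]
        return float(r.mean())

    coupled = np.array([scal(s["coupled"]) for s in usable])
    summed = np.array([scal(s["summed"]) for s in usable])
    out = {"coupled": coupled, "summed": summed,
           "diff": coupled - summed, "n_sessions": len(usable), "p": None}
    if len(usable) >= 3:
        out["p"] = float(stats.ttest_rel(coupled, summed).pvalue)
        C = np.stack([s["coupled"][sel].mean(axis=0) for s in usable])
        S = np.stack([s["summed"][sel].mean(axis=0) for s in usable])
        res = stats.ttest_rel(C, S, axis=0)
        out["voxel_t"] = res.statistic
        out["voxel_p"] = res.pvalue
        out["voxel_sig"] = bh_fdr(res.pvalue, q)
    return out


# ---------------------------------------------------------------------------
# pre-transition statistics
# ---------------------------------------------------------------------------

def sample_control_epochs(hyp_epochs: Sequence[tuple], n: int,
                          window_s: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Anchor times inside NREM-only epochs long enough to hold the window."""
    eligible = [(a, b) for a, b in hyp_epochs if b - a >= window_s + 2]
    if not eligible:
        return np.empty(0)
    anchors = []
    for _ in range(n):
        a, b = eligible[rng.integers(len(eligible))]
        anchors.append(rng.uniform(a + window_s, b - 1))
    return np.asarray(anchors)


def pre_transition_event_probability(events: EventTable,
                                     tset: TransitionEpochSet,
                                     control_anchors: np.ndarray,
                                     ttype: str = "NREM_to_AW",
                                     event_type: str = "SWR",
                                     window: tuple = (-30, 0),
                                     alpha: float = 0.05) -> dict:
    """Per-second event probability before transitions vs matched control
    offsets, with a left-tailed two-sample t-test per second.

    Returns probability curves, per-second p values, and the earliest
    (most negative) second from which the transition probability is
    significantly lower contiguously to 0.
    """
    trs = tset.of_type(ttype)
    if len(trs) < 10 or control_anchors.size < 10:
        raise DataError("need >= 10 transitions and >= 10 control epochs")
    centers = events.select(type=event_type).df["center_s"].to_numpy(float)
    secs = np.arange(window[0], window[1])

    def indicator(anchors):
        mat = np.zeros((len(anchors), secs.size))
        for i, t0 in enumerate(anchors):
            for j, s in enumerate(secs):
                lo, hi = t0 + s, t0 + s + 1
                mat[i, j] = np.any((centers >= lo) & (centers < hi))
        return mat

    trans_mat = indicator([tr["t_trans"] for tr in trs])
    ctrl_mat = indicator(control_anchors)
    p_curve = trans_mat.mean(axis=0)
    c_curve = ctrl_mat.mean(axis=0)
    pvals = np.ones(secs.size)
    for j in range(secs.size):
        t_res = stats.ttest_ind(trans_mat[:, j], ctrl_mat[:, j],
                                alternative="less")
        pvals[j] = t_res.pvalue if np.isfinite(t_res.pvalue) else 1.0
    sig = pvals < alpha
    # earliest = start of the contiguous significant tail ending at 0
    j = secs.size - 1
    while j >= 0 and sig[j]:
        j -= 1
    earliest = float(secs[j + 1]) if j + 1 < secs.size else None
    return {"t": secs.astype(float), "p_transition": p_curve,
            "p_control": c_curve, "pvals": pvals, "sig": sig,
            "earliest_sig_s": earliest,
            "n_transitions": trans_mat.shape[0],
            "n_controls": ctrl_mat.shape[0]}


def pre_transition_spectrogram_contrast(spec_times: np.ndarray,
                                        spec_freqs: np.ndarray,
                                        spec_power: np.ndarray,
                                        tset: TransitionEpochSet,
                                        control_anchors: np.ndarray,
                                        ttype: str = "NREM_to_AW",
                                        window: tuple = (-30, 0),
                                        alpha: float = 0.05) -> dict:
    """Two-tailed two-sample t-map (time x frequency) between
    transition-aligned and control-aligned spectrogram power; the p < 0.05
    mask is uncorrected by design."""
    if control_anchors.size == 0:
        raise DataError("empty control set")
    secs = np.arange(window[0], window[1])
    dt = float(np.median(np.diff(spec_times)))

    def cube(anchors):
        snips = []
        for t0 in anchors:
            idx = np.round((t0 + secs - spec_times[0]) / dt).astype(int)
            if idx.min() < 0 or idx.max() >= spec_power.shape[0]:
                continue
            snips.append(spec_power[idx])
        return np.stack(snips) if snips else None

    A = cube([tr["t_trans"] for tr in tset.of_type(ttype)])
    B = cube(control_anchors)
    if A is None or B is None:
        raise DataError("no usable aligned spectrogram snippets")
    res = stats.ttest_ind(A, B, axis=0)
    return {"t": secs.astype(float), "freqs": spec_freqs,
            "tmap": res.statistic, "pmap": res.pvalue,
            "sig": res.pvalue < alpha, "n_trans": A.shape[0],
            "n_ctrl": B.shape[0]}


def response_power_correlation(bold_diff: np.ndarray,
                               power_diff: np.ndarray) -> np.ndarray:
    """Across-session Pearson r between a BOLD response difference (n,) and
    the event-locked power difference (n, n_freq), per frequency."""
    bold_diff = np.asarray(bold_diff, float)
    power_diff = np.asarray(power_diff, float)
    if bold_diff.size < 5:
        raise DataError("need >= 5 sessions")
    b = bold_diff - bold_diff.mean()
    P = power_diff - power_diff.mean(axis=0)
    num = (b[:, None] * P).sum(axis=0)
    den = np.sqrt((b ** 2).sum() * (P ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)
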