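"""Semi-automated AW / NREM / REM scoring from ECoG + EMG band power.

Features are multitaper band powers (3 s window, 1 s step): delta 1-4 Hz,
theta 6-12 Hz, their ratio, and EMG 160-250 Hz, median-smoothed with a
20-point kernel. A time point is tentatively REM if the smoothed
theta/delta ratio exceeds its mean by 2 SD while EMG is 1 SD below its
mean; otherwise NREM if smoothed delta exceeds its mean; otherwise AW.
Boundaries are then refined to the steepest delta/theta slopes, reconciled
with the EMG-derived boundary, and epochs shorter than 5 s merged — a
deterministic surrogate for the manual adjustment step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .io import EphysRecording, Hypnogram

logger = logging.getLogger("sleepscape")


class ParameterError(ValueError):
    pass


class DataError(ValueError):
    pass


DELTA_BAND = (1.0, 4.0)
THETA_BAND = (6.0, 12.0)
EMG_BAND = (160.0, 250.0)
TOTAL_BAND = (1.0, 100.0)


def multitaper_spectrogram(x: np.ndarray, fs: float, win: float = 3.0,
                           step: float = 1.0, nw: float = 3.0,
                           k_tapers: int = 5):
    """Sliding-window multitaper PSD.

    Returns ``(times, freqs, power)`` with ``times`` at window centers and
    ``power`` shaped (n_windows, n_freqs).
    """
    x = np.asarray(x, float)
    n_win = int(round(win * fs))
    n_step = int(round(step * fs))
    if x.size < n_win:
        raise ParameterError("signal shorter than one window")
    if n_win < 2 * nw + 1:
        raise ParameterError("window too short for the requested bandwidth")
    tapers = windows.dpss(n_win, nw, Kmax=k_tapers)      # (k, n_win), unit norm
    starts = np.arange(0, x.size - n_win + 1, n_step)
    frames = np.stack([x[s:s + n_win] for s in starts])  # (n_t, n_win)
    spec = np.fft.rfft(frames[:, None, :] * tapers[None, :, :], axis=-1)
    power = (np.abs(spec) ** 2).mean(axis=1) / fs
    power[:, 1:-1] *= 2.0                                # one-sided
    freqs = np.fft.rfftfreq(n_win, 1.0 / fs)
    times = (starts + n_win / 2) / fs
    return times, freqs, power


def band_power(freqs: np.ndarray, power: np.ndarray, band) -> np.ndarray:
    """Integrate the PSD over a frequency band (per time bin)."""
    sel = (freqs >= band[0]) & (freqs <= band[1])
    df = freqs[1] - freqs[0]
    return power[:, sel].sum(axis=1) * df


def medfilt20(x: np.ndarray, kernel: int = 20) -> np.ndarray:
    """Running median with an even kernel, zero-padded edges.

    ``y[k] = median(x[k - n/2 : k + n/2])`` (half-open), the even-kernel
    median being the mean of the two middle order statistics; edges see the
    zero padding, matching the reference running-median implementation.
    """
    x = np.asarray(x, float)
    half = kernel // 2
    padded = np.concatenate([np.zeros(half), x, np.zeros(kernel - half)])
    sw = np.lib.stride_tricks.sliding_window_view(padded, kernel)[:x.size]
    return np.median(sw, axis=1)


@dataclass
class StagingFeatures:
    """Per-second spectral features and session-level thresholds."""

    t: np.ndarray
    delta_power: np.ndarray
    theta_power: np.ndarray
    emg_power: np.ndarray
    total_power: np.ndarray
    ratio: np.ndarray
    delta_s: np.ndarray
    theta_s: np.ndarray
    ratio_s: np.ndarray
    emg_s: np.ndarray
    thresholds: dict

    @property
    def n_seconds(self) -> int:
        return self.t.size


def _per_second(times: np.ndarray, values: np.ndarray, n_sec: int) -> np.ndarray:
    """Map window-center values onto the 1 Hz second grid, edge-padded."""
    out = np.empty(n_sec)
    sec = np.floor(times).astype(int)
    filled = np.zeros(n_sec, bool)
    for s, v in zip(sec, values):
        if 0 <= s < n_sec:
            out[s] = v
            filled[s] = True
    idx = np.where(filled)[0]
    if idx.size == 0:
        raise DataError("no spectral estimates inside the recording")
    out[:idx[0]] = out[idx[0]]
    out[idx[-1] + 1:] = out[idx[-1]]
    return out


def compute_staging_features(rec: EphysRecording, stage_channel: str,
                             emg_channel: str, win: float = 3.0,
                             step: float = 1.0) -> StagingFeatures:
    """Band powers, smoothed series and session thresholds at 1 Hz."""
    if rec.duration < 60:
        raise DataError("recording shorter than 60 s cannot be staged")
    n_sec = int(np.floor(rec.duration))
    t_grid = np.arange(n_sec) + 0.5

    times, freqs, pxx = multitaper_spectrogram(rec.get(stage_channel), rec.fs,
                                               win=win, step=step)
    delta = _per_second(times, band_power(freqs, pxx, DELTA_BAND), n_sec)
    theta = _per_second(times, band_power(freqs, pxx, THETA_BAND), n_sec)
    total = _per_second(times, band_power(freqs, pxx, TOTAL_BAND), n_sec)

    times_e, freqs_e, pxx_e = multitaper_spectrogram(rec.get(emg_channel),
                                                     rec.fs, win=win, step=step)
    emg = _per_second(times_e, band_power(freqs_e, pxx_e, EMG_BAND), n_sec)

    ratio = theta / np.maximum(delta, 1e-30)
    delta_s = medfilt20(delta)
    theta_s = medfilt20(theta)
    ratio_s = medfilt20(ratio)
    # EMG is thresholded on the RMS-amplitude scale: band power is bimodal
    # (high AW, low sleep), and with AW under half the session the power-scale
    # mean - 1 SD falls below every sample; amplitude compresses the split
    emg_s = medfilt20(np.sqrt(emg))
    thresholds = {
        "delta_mean": float(delta_s.mean()),
        "ratio_mean": float(ratio_s.mean()),
        "ratio_sd": float(ratio_s.std()),
        "emg_mean": float(emg_s.mean()),
        "emg_sd": float(emg_s.std()),
    }
    return StagingFeatures(t_grid, delta, theta, emg, total, ratio,
                           delta_s, theta_s, ratio_s, emg_s, thresholds)


def tentative_score(f: StagingFeatures) -> Hypnogram:
    """Per-second threshold scoring; the (stricter) REM rule wins first."""
    th = f.thresholds
    rem = ((f.ratio_s > th["ratio_mean"] + 2 * th["ratio_sd"])
           & (f.emg_s < th["emg_mean"] - th["emg_sd"]))
    nrem = f.delta_s > th["delta_mean"]
    labels = np.where(rem, "REM", np.where(nrem, "NREM", "AW"))
    return Hypnogram.from_labels(list(labels))


def _steepest(series: np.ndarray, center: int, radius: int, mode: str) -> int:
    """Index of the max ascent / descent / absolute step of ``series``
    within ``center +- radius`` (first difference, boundary between k-1, k)."""
    d = np.diff(series)
    lo = max(1, center - radius)
    hi = min(d.size, center + radius)
    if lo >= hi:
        return center
    seg = d[lo - 1:hi]
    if mode == "ascent":
        k = int(np.argmax(seg))
    elif mode == "descent":
        k = int(np.argmin(seg))
    else:
        k = int(np.argmax(np.abs(seg)))
    return lo + k


def _rem_hysteresis(h: Hypnogram, f: StagingFeatures) -> Hypnogram:
    """Extend each REM epoch while the ratio stays above mean + 1 SD with
    EMG below its mean: the strict 2 SD entry criterion drops out mid-bout,
    fragmenting real REM episodes."""
    th = f.thresholds
    sustain = ((f.ratio_s > th["ratio_mean"] + th["ratio_sd"])
               & (f.emg_s < th["emg_mean"]))
    labels = np.array(h.labels)
    n = min(labels.size, sustain.size)
    labels, sustain = labels[:n], sustain[:n]
    rem = labels == "REM"
    for start in np.flatnonzero(rem[1:] & ~rem[:-1]) + 1:
        i = start - 1
        while i >= 0 and sustain[i]:
            labels[i] = "REM"
            i -= 1
    for end in np.flatnonzero(rem[:-1] & ~rem[1:]):
        i = end + 1
        while i < n and sustain[i]:
            labels[i] = "REM"
            i += 1
    return Hypnogram.from_labels(list(labels), t0=h.start)


def refine_boundaries(h: Hypnogram, f: StagingFeatures,
                      search_radius: int = 10,
                      emg_tolerance_s: float = 2.0,
                      min_epoch_s: float = 5.0) -> Hypnogram:
    """Deterministic surrogate for manual boundary adjustment.

    REM epochs are first extended by hysteresis; NREM starts/ends then snap
    to the steepest ascent/descent of smoothed delta, REM starts to the
    preceding NREM end and REM ends to the steepest theta descent; where an
    informative EMG-derived boundary disagrees by more than
    ``emg_tolerance_s`` the (floored) midpoint is used; epochs shorter than
    ``min_epoch_s`` are merged into the longer flanking epoch until stable;
    finally any REM epoch still directly following AW is legalised (REM is
    only entered from NREM).
    """
    h = _rem_hysteresis(h, f)
    states = [s for s, _, _ in h.epochs]
    bounds = [a for _, a, _ in h.epochs] + [h.epochs[-1][2]]
    n_sec = f.n_seconds
    d_emg = np.abs(np.diff(f.emg_s))
    emg_informative_thr = d_emg.mean() + d_emg.std()

    def snap(i: int, series: np.ndarray, mode: str) -> float:
        b = int(round(bounds[i]))
        ecog_b = _steepest(series, b, search_radius, mode)
        emg_b = _steepest(f.emg_s, b, search_radius, "abs")
        new = ecog_b
        if (abs(emg_b - ecog_b) > emg_tolerance_s
                and d_emg[emg_b - 1] > emg_informative_thr):
            new = int(np.floor((ecog_b + emg_b) / 2))
        lo = bounds[i - 1] + 1 if i > 0 else 0
        hi = bounds[i + 1] - 1 if i + 1 < len(bounds) else n_sec
        return float(np.clip(new, lo, min(hi, n_sec)))

    for i in range(1, len(bounds) - 1):
        prev_s, next_s = states[i - 1], states[i]
        if next_s == "NREM":                       # NREM start
            bounds[i] = snap(i, f.delta_s, "ascent")
        elif prev_s == "NREM":                     # NREM end; REM start = NREM end
            bounds[i] = snap(i, f.delta_s, "descent")
        elif prev_s == "REM":                      # REM end
            bounds[i] = snap(i, f.theta_s, "descent")

    epochs = [(states[i], bounds[i], bounds[i + 1])
              for i in range(len(states)) if bounds[i + 1] > bounds[i]]

    # merge short epochs into the longer flanking epoch (tie -> preceding)
    changed = True
    while changed:
        changed = False
        for i, (s, a, b) in enumerate(epochs):
            if b - a >= min_epoch_s or len(epochs) == 1:
                continue
            left = epochs[i - 1] if i > 0 else None
            right = epochs[i + 1] if i + 1 < len(epochs) else None
            if left is None:
                target = i + 1
            elif right is None:
                target = i - 1
            else:
                l_dur = left[2] - left[1]
                r_dur = right[2] - right[1]
                target = i - 1 if l_dur >= r_dur else i + 1
            if target < i:
                epochs[target] = (epochs[target][0], epochs[target][1], b)
            else:
                epochs[target] = (epochs[target][0], a, epochs[target][2])
            epochs.pop(i)
            changed = True
            break
        # collapse adjacent same-state epochs created by merging
        j = 0
        while j + 1 < len(epochs):
            if epochs[j][0] == epochs[j + 1][0]:
                epochs[j] = (epochs[j][0], epochs[j][1], epochs[j + 1][2])
                epochs.pop(j + 1)
                changed = True
            else:
                j += 1

    # legality: REM is only entered from NREM. A short REM epoch after AW is
    # a spurious detection (absorbed into AW); a long one implies the
    # preceding low-delta stretch was in fact NREM
    changed = True
    while changed:
        changed = False
        for i in range(1, len(epochs)):
            if epochs[i][0] == "REM" and epochs[i - 1][0] == "AW":
                s, a, b = epochs[i]
                if b - a < 15.0:
                    epochs[i] = ("AW", a, b)
                else:
                    ps, pa, pb = epochs[i - 1]
                    epochs[i - 1] = ("NREM", pa, pb)
                changed = True
                break
        j = 0
        while j + 1 < len(epochs):
            if epochs[j][0] == epochs[j + 1][0]:
                epochs[j] = (epochs[j][0], epochs[j][1], epochs[j + 1][2])
                epochs.pop(j + 1)
            else:
                j += 1
    return Hypnogram(epochs)


def score_session(rec: EphysRecording, stage_channel: str, emg_channel: str,
                  search_radius: int = 10) -> Hypnogram:
    """Full deterministic scoring: features -> tentative -> refined."""
    f = compute_staging_features(rec, stage_channel, emg_channel)
    tentative = tentative_score(f)
    return refine_boundaries(tentative, f, search_radius=search_radius)
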