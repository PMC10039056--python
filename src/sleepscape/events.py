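"""Spindle, sharp-wave-ripple and slow-wave detection plus coupling.

All thresholds are relative (mean + k*SD of the band envelope, or per-session
percentiles), so detection is invariant to global amplitude rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from .io import EventTable, Hypnogram, EVENT_COLUMNS

logger = logging.getLogger("sleepscape")


class ParameterError(ValueError):
    pass


@dataclass
class DetectorConfig:
    """Bands, filter orders and thresholds for the three detectors."""

    spindle_band: tuple = (10.0, 16.0)
    swr_band: tuple = (120.0, 250.0)
    sw_band: tuple = (0.3, 4.5)
    order: int = 4
    sw_order: int = 2
    spindle_k: float = 1.5
    swr_k: float = 3.0
    spindle_dur: tuple = (0.4, 3.0)
    sw_interval: tuple = (0.4, 2.0)
    sw_neg_pct: float = 35.0          # keep top 35% negative amplitudes
    sw_p2p_pct: float = 45.0          # keep top 45% peak-to-peak amplitudes
    spindle_smooth_ms: float = 50.0
    swr_smooth_ms: float = 20.0
    swr_power_window_ms: float = 20.0
    swr_min_dur_ms: float = 20.0
    merge_gap_ms: float = 30.0


def band_envelope(x: np.ndarray, fs: float, band: tuple, order: int = 4,
                  smooth_ms: float = 50.0) -> np.ndarray:
    """Zero-phase Butterworth bandpass -> analytic-signal magnitude ->
    moving-average smoothing over ``smooth_ms``."""
    lo, hi = band
    if hi >= fs / 2:
        raise ParameterError(f"band {band} exceeds Nyquist ({fs / 2} Hz)")
    sos = signal.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, np.asarray(x, float))
    env = np.abs(signal.hilbert(filt))
    n_sm = max(1, int(round(smooth_ms / 1000 * fs)))
    if n_sm > 1:
        env = np.convolve(env, np.ones(n_sm) / n_sm, mode="same")
    return env


def event_bounds(envelope: np.ndarray, peak_idx: int,
                 mean: Optional[float] = None) -> tuple[int, int, bool]:
    """Walk left/right from the peak until the envelope drops below its mean.

    Returns ``(start, end, clamped)`` with half-open ``[start, end)``;
    ``clamped`` flags an edge that never crossed the mean.
    """
    if mean is None:
        mean = float(envelope.mean())
    if envelope[peak_idx] <= mean:
        raise ParameterError("peak must exceed the envelope mean")
    clamped = False
    i = peak_idx
    while i > 0 and envelope[i - 1] >= mean:
        i -= 1
    if i == 0 and envelope[0] >= mean:
        clamped = True
    j = peak_idx
    while j < envelope.size - 1 and envelope[j + 1] >= mean:
        j += 1
    if j == envelope.size - 1 and envelope[j] >= mean:
        clamped = True
    return i, j + 1, clamped


def _supra_runs(mask: np.ndarray, fs: float, merge_gap_ms: float) -> list:
    """Contiguous True runs, merging runs separated by < merge_gap_ms."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    gap = int(round(merge_gap_ms / 1000 * fs))
    splits = np.flatnonzero(np.diff(idx) > max(gap, 1))
    runs = []
    start = 0
    for s in list(splits) + [idx.size - 1]:
        runs.append((idx[start], idx[s] + 1))
        start = s + 1
    return runs


def _second_mask(hyp: Optional[Hypnogram], state: str, n: int, fs: float
                 ) -> np.ndarray:
    if hyp is None:
        return np.ones(n, bool)
    sec = hyp.state_mask(state, n_seconds=int(np.ceil(n / fs)))
    return np.repeat(sec, int(round(fs)))[:n]


def _merge_overlapping(rows: list) -> list:
    """Drop the weaker of any two same-type overlapping events."""
    rows = sorted(rows, key=lambda r: r["start_s"])
    out: list = []
    for r in rows:
        if out and r["start_s"] < out[-1]["end_s"]:
            if r["peak_amp"] > out[-1]["peak_amp"]:
                out[-1] = r
        else:
            out.append(r)
    return out


def _state_of(hyp: Optional[Hypnogram], t: float) -> str:
    if hyp is None:
        return "NA"
    try:
        return hyp.state_at(t)
    except Exception:
        return "NA"


def detect_spindles(x: np.ndarray, fs: float, hyp: Hypnogram,
                    cfg: Optional[DetectorConfig] = None,
                    channel: str = "ieeg_mpfc") -> EventTable:
    """Spindles: envelope > mean + 1.5 SD within NREM, duration 0.4-3 s.

    Mean/SD (and the bounds mean) are computed over NREM samples only. The
    duration window is applied to the supra-threshold run (the mean-crossing
    walk pads every event with background-envelope excursions, regardless of
    SNR); bounds come from the walk, capped at the duration ceiling.
    """
    cfg = cfg or DetectorConfig()
    x = np.asarray(x, float)
    nrem = _second_mask(hyp, "NREM", x.size, fs)
    if not nrem.any():
        return EventTable()
    env = band_envelope(x, fs, cfg.spindle_band, cfg.order,
                        cfg.spindle_smooth_ms)
    mu = float(env[nrem].mean())
    sd = float(env[nrem].std())
    thr = mu + cfg.spindle_k * sd
    rows = []
    for a, b in _supra_runs((env > thr) & nrem, fs, cfg.merge_gap_ms):
        if not (cfg.spindle_dur[0] <= (b - a) / fs <= cfg.spindle_dur[1]):
            continue
        peak = a + int(np.argmax(env[a:b]))
        s, e, _ = event_bounds(env, peak, mean=mu)
        cap = int(cfg.spindle_dur[1] * fs)
        if e - s > cap:                        # shrink around the peak
            over = (e - s) - cap
            s = min(s + (over + 1) // 2, peak)
            e = s + cap
        rows.append(dict(type="spindle", channel=channel, center_s=peak / fs,
                         start_s=s / fs, end_s=e / fs,
                         peak_amp=float(env[peak]),
                         coupled="NA", state=_state_of(hyp, peak / fs)))
    rows = _merge_overlapping(rows)
    return EventTable(pd.DataFrame(rows, columns=EVENT_COLUMNS))


def detect_swrs(x: np.ndarray, fs: float,
                cfg: Optional[DetectorConfig] = None,
                hyp: Optional[Hypnogram] = None,
                channel: str = "lfp_ca1") -> EventTable:
    """SWRs: (1) ripple-band envelope > mean + 3 SD and (2) ripple-band
    power (smoothed squared signal) above its temporal mean; any state.

    The mean/SD threshold is taken from the raw analytic-signal magnitude
    (the envelope proper); candidates are found on a lightly smoothed copy,
    which suppresses isolated noise excursions without moving the
    threshold.
    """
    cfg = cfg or DetectorConfig()
    if fs < 512:
        raise ParameterError("need fs >= 512 Hz for the ripple band")
    band = (cfg.swr_band[0], min(cfg.swr_band[1], 0.999 * fs / 2))
    x = np.asarray(x, float)
    sos = signal.butter(cfg.order, band, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, x)
    env_raw = np.abs(signal.hilbert(filt))
    n_sm = max(1, int(round(cfg.swr_smooth_ms / 1000 * fs)))
    env = np.convolve(env_raw, np.ones(n_sm) / n_sm, mode="same")
    n_pw = max(1, int(round(cfg.swr_power_window_ms / 1000 * fs)))
    power = np.convolve(filt ** 2, np.ones(n_pw) / n_pw, mode="same")
    mu, sd = float(env_raw.mean()), float(env_raw.std())
    cand = (env > mu + cfg.swr_k * sd) & (power > power.mean())
    rows = []
    for a, b in _supra_runs(cand, fs, cfg.merge_gap_ms):
        peak = a + int(np.argmax(env[a:b]))
        s, e, _ = event_bounds(env, peak, mean=mu)
        if (e - s) / fs * 1000 < cfg.swr_min_dur_ms:
            continue
        rows.append(dict(type="SWR", channel=channel, center_s=peak / fs,
                         start_s=s / fs, end_s=e / fs,
                         peak_amp=float(env[peak]),
                         coupled="NA", state=_state_of(hyp, peak / fs)))
    rows = _merge_overlapping(rows)
    return EventTable(pd.DataFrame(rows, columns=EVENT_COLUMNS))


def detect_slow_waves(x: np.ndarray, fs: float, hyp: Hypnogram,
                      cfg: Optional[DetectorConfig] = None,
                      channel: str = "ieeg_mpfc") -> EventTable:
    """Slow waves: NREM negative half-waves with interval T in [0.4, 2] s,
    kept only if in both the top-35% negative-amplitude and top-45%
    peak-to-peak sets (per-session percentiles over candidates)."""
    cfg = cfg or DetectorConfig()
    x = np.asarray(x, float)
    sos = signal.butter(cfg.sw_order, cfg.sw_band, btype="bandpass", fs=fs,
                        output="sos")
    filt = signal.sosfiltfilt(sos, x)
    nrem = _second_mask(hyp, "NREM", x.size, fs)

    sign = filt >= 0
    down = np.flatnonzero(sign[:-1] & ~sign[1:]) + 1   # negative-going zc
    up = np.flatnonzero(~sign[:-1] & sign[1:]) + 1     # positive-going zc
    cands = []
    for zc1 in down:
        nxt_up = up[up > zc1]
        if nxt_up.size == 0:
            continue
        zc2 = nxt_up[0]                                # end of negative wave
        T = (zc2 - zc1) / fs
        if not (cfg.sw_interval[0] <= T <= cfg.sw_interval[1]):
            continue
        nxt_down = down[down > zc2]
        if nxt_down.size == 0:
            continue
        zc3 = nxt_down[0]                              # third zero crossing
        if (zc3 - zc1) / fs > cfg.sw_interval[1]:
            continue                                   # full wave too long
        if not nrem[zc1:zc3].all():
            continue
        trough = zc1 + int(np.argmin(filt[zc1:zc2]))
        N = float(-filt[trough])
        M = N + float(filt[zc2:zc3].max(initial=0.0))
        cands.append((zc1, zc2, zc3, trough, N, M))
    if len(cands) < 10:
        if cands:
            logger.warning("only %d slow-wave candidates: percentile "
                           "thresholds unstable, returning empty table",
                           len(cands))
        return EventTable()

    Ns = np.array([c[4] for c in cands])
    Ms = np.array([c[5] for c in cands])
    n = len(cands)
    k_n = max(1, int(np.floor(cfg.sw_neg_pct / 100 * n + 1e-9)))
    k_m = max(1, int(np.floor(cfg.sw_p2p_pct / 100 * n + 1e-9)))
    thr_n = np.sort(Ns)[::-1][k_n - 1]
    thr_m = np.sort(Ms)[::-1][k_m - 1]
    rows = []
    for zc1, zc2, zc3, trough, N, M in cands:
        if N < thr_n or M < thr_m:
            continue
        rows.append(dict(type="slow_wave", channel=channel,
                         center_s=trough / fs, start_s=zc1 / fs,
                         end_s=zc3 / fs, peak_amp=N, coupled="NA",
                         state=_state_of(hyp, trough / fs)))
    return EventTable(pd.DataFrame(rows, columns=EVENT_COLUMNS))


def classify_coupling(swrs: EventTable, spindles: EventTable) -> EventTable:
    """Flag SWRs whose center falls inside a spindle ``[start, end)`` as
    coupled, and spindles containing >= 1 SWR center; returns the merged
    table sorted by center time."""
    swr_df = swrs.df.copy()
    sp_df = spindles.df.copy()
    sp_iv = sp_df[["start_s", "end_s"]].to_numpy(float) if len(sp_df) else \
        np.empty((0, 2))
    coupled_swr = []
    for c in swr_df["center_s"]:
        coupled_swr.append(bool(np.any((sp_iv[:, 0] <= c) & (c < sp_iv[:, 1]))))
    swr_df["coupled"] = ["coupled" if f else "uncoupled" for f in coupled_swr]
    centers = swr_df["center_s"].to_numpy(float)
    flags = []
    for _, row in sp_df.iterrows():
        inside = (centers >= row["start_s"]) & (centers < row["end_s"])
        flags.append("coupled" if inside.any() else "uncoupled")
    sp_df["coupled"] = flags
    merged = pd.concat([swr_df, sp_df], ignore_index=True)
    merged = merged.sort_values("center_s").reset_index(drop=True)
    return EventTable(merged)
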