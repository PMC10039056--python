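"""Ground-truthed synthetic sessions: ephys + BOLD with known structure.

The generator emulates the statistical features the pipeline assumes:
state-dependent band power (delta up in NREM, theta up in REM, EMG down in
sleep), embedded spindle / SWR / slow-wave events, slice-trigger-locked
gradient artifacts, and HRF-convolved state- and event-dependent BOLD with
motion / drift / physiological nuisance shared with non-brain voxels.

Sleep architecture is a semi-Markov chain: an embedded jump chain over
{AW, NREM, REM} with lognormal dwell times whose medians default to the
fragmented mouse values (AW 46.0 s, NREM 41.0 s, REM 121.5 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal, ndimage

from .io import (BoldSeries, Channel, EphysRecording, EventTable, Hypnogram,
                 SessionBundle, STATES, EVENT_COLUMNS)

import pandas as pd


class ConfigError(ValueError):
    """Raised for an inconsistent or degenerate simulation configuration."""


def _default_transitions() -> np.ndarray:
    # rows/cols ordered AW, NREM, REM; zero diagonal (embedded jump chain);
    # REM entered only from NREM, matching the observed transition set
    return np.array([[0.0, 1.0, 0.0],
                     [0.94, 0.0, 0.06],
                     [1.0, 0.0, 0.0]])


@dataclass
class SimConfig:
    """All knobs of the session generator.

    ``band_gains`` are per-state *power* multipliers relative to AW.
    Event rates are Poisson rates (events/s) active only in the listed state.
    """

    total_duration: float = 2400.0
    TR: float = 2.0
    fs_ephys: float = 1024.0
    state_transition_matrix: np.ndarray = field(default_factory=_default_transitions)
    duration_medians: dict = field(default_factory=lambda: {
        "AW": 46.0, "NREM": 41.0, "REM": 121.5})
    duration_sigma: float = 0.6
    duration_sigmas: dict = field(default_factory=lambda: {"REM": 0.25})
    min_dwell_s: float = 5.0
    band_gains: dict = field(default_factory=lambda: {
        "delta": {"AW": 1.0, "NREM": 3.5, "REM": 0.4},
        "theta": {"AW": 1.0, "NREM": 0.6, "REM": 4.0},
        "emg": {"AW": 1.0, "NREM": 0.15, "REM": 0.05}})
    event_rates: dict = field(default_factory=lambda: {
        "spindle": {"NREM": 0.08},
        "SWR": {"AW": 0.04, "NREM": 0.08},
        "slow_wave": {"NREM": 0.2}})
    coupling_prob: float = 0.5
    artifact_amp: float = 0.0
    n_slices: int = 22
    hrf_params: dict = field(default_factory=lambda: {
        "peak_time_s": 1.75, "fwhm_s": 1.5, "undershoot_ratio": 0.0})
    # ephys amplitudes (microvolt std of the unit-gain oscillator / background)
    bg_amp: float = 5.0
    delta_amp: float = 30.0
    theta_amp: float = 20.0
    emg_amp: float = 30.0
    spindle_amp: float = 50.0
    swr_amp: float = 40.0
    sw_amp: float = 150.0
    n_ecog: int = 14
    # BOLD
    grid: tuple = (16, 16, 8)
    voxel_size_mm: tuple = (0.2, 0.2, 0.5)
    baseline: float = 100.0
    bold_noise_sd: float = 0.5
    drift_amp: float = 1.0
    nuisance_amp: float = 1.5
    state_bold_amp: dict = field(default_factory=lambda: {"NREM": 2.0, "REM": 1.5})
    event_bold_amp: dict = field(default_factory=lambda: {
        "spindle": 1.0, "SWR": 1.0, "slow_wave": 0.5})
    seed: int = 0

    def validate(self) -> None:
        P = np.asarray(self.state_transition_matrix, float)
        if P.shape != (3, 3):
            raise ConfigError("transition matrix must be 3x3")
        if np.any(np.abs(np.diag(P)) > 1e-12):
            raise ConfigError("embedded jump chain requires a zero diagonal")
        if not np.allclose(P.sum(axis=1), 1.0):
            raise ConfigError("transition matrix rows must sum to 1")
        if np.any((P.sum(axis=1) - np.diag(P)) <= 0):
            raise ConfigError("transition matrix admits an absorbing state")
        if np.any(P < 0):
            raise ConfigError("transition probabilities must be non-negative")
        for t, per_state in self.event_rates.items():
            for s, r in per_state.items():
                if r < 0:
                    raise ConfigError(f"negative {t} rate in {s}")
        if not 0.0 <= self.coupling_prob <= 1.0:
            raise ConfigError("coupling_prob must lie in [0, 1]")
        if self.total_duration <= 0 or self.TR <= 0 or self.fs_ephys <= 0:
            raise ConfigError("durations and rates must be positive")


@dataclass
class GroundTruth:
    """Everything the generator injected, for exact downstream checks."""

    hypnogram: Hypnogram
    events: EventTable
    activation_maps: dict
    component_maps: dict
    artifact_template: Optional[np.ndarray] = None
    hrf_kernel: Optional[np.ndarray] = None
    drivers: Optional[dict] = None
    nuisance_series: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# state sequence
# ---------------------------------------------------------------------------

def simulate_state_sequence(cfg: SimConfig,
                            rng: Optional[np.random.Generator] = None) -> Hypnogram:
    """Semi-Markov AW/NREM/REM sequence with lognormal dwell times.

    Dwells are rounded to integer seconds and clipped below at
    ``cfg.min_dwell_s``; the final epoch is truncated to ``total_duration``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    P = np.asarray(cfg.state_transition_matrix, float)
    state = 0  # start awake
    t = 0.0
    epochs = []
    while t < cfg.total_duration:
        name = STATES[state]
        mu = np.log(cfg.duration_medians[name])
        sigma = cfg.duration_sigmas.get(name, cfg.duration_sigma)
        dwell = float(np.round(rng.lognormal(mu, sigma)))
        dwell = max(dwell, cfg.min_dwell_s)
        end = min(t + dwell, cfg.total_duration)
        epochs.append((name, t, end))
        t = end
        state = int(rng.choice(3, p=P[state]))
    # a truncated trailing sliver shorter than min_dwell is merged backwards
    if len(epochs) > 1 and epochs[-1][2] - epochs[-1][1] < cfg.min_dwell_s:
        name, a, _ = epochs[-2]
        epochs[-2] = (name, a, epochs[-1][2])
        epochs.pop()
    return Hypnogram(epochs)


# ---------------------------------------------------------------------------
# ephys
# ---------------------------------------------------------------------------

def _pink_noise(n: int, fs: float, rng: np.random.Generator,
                f_knee: float = 1.0) -> np.ndarray:
    """1/f-shaped noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec /= np.sqrt(np.maximum(f, f_knee))
    x = np.fft.irfft(spec, n)
    return x / x.std()

def _band_noise(n: int, fs: float, band: tuple, rng: np.random.Generator) -> np.ndarray:
    """Bandpass-filtered white noise, unit variance."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()

def _theta_oscillator(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Rhythmic theta: slowly wandering frequency and amplitude, unit RMS.

    REM theta is a sustained oscillation, not band noise: its bin-to-bin
    band power is nearly constant, which the ratio-based REM criterion
    relies on.
    """
    # slow (seconds-scale) frequency / amplitude wander, built at 1 Hz
    n_sec = max(int(np.ceil(n / fs)) + 2, 4)
    t_sec = np.arange(n_sec, dtype=float)
    t_all = np.arange(n) / fs
    drift = ndimage.gaussian_filter1d(rng.standard_normal(n_sec), 2.0)
    drift = np.interp(t_all, t_sec, drift)
    f_inst = 7.0 + 0.8 * drift / max(drift.std(), 1e-12)
    phase = 2 * np.pi * np.cumsum(f_inst) / fs
    am = ndimage.gaussian_filter1d(rng.standard_normal(n_sec), 1.0)
    am = np.interp(t_all, t_sec, am)
    am = 1.0 + 0.15 * am / max(am.std(), 1e-12)
    x = am * np.sin(phase + rng.uniform(0, 2 * np.pi))
    return x / x.std()

def _gain_series(hyp: Hypnogram, gains: dict, n: int, fs: float) -> np.ndarray:
    """Per-sample sqrt(power-gain) series from per-second state labels."""
    labels = hyp.labels
    per_sec = np.array([gains[l] for l in labels])
    per_sample = np.repeat(np.sqrt(per_sec), int(round(fs)))
    if per_sample.size < n:
        per_sample = np.concatenate(
            [per_sample, np.full(n - per_sample.size, per_sample[-1])])
    return per_sample[:n]


def _place_events(epochs, rate_map, durations, rng, occupied, margin=0.25,
                  max_tries=50):
    """Poisson placement of events inside state epochs, avoiding overlap.

    ``occupied`` is a list of (start, end) intervals updated in place.
    Returns a list of (center, half_dur) tuples.
    """
    placed = []
    for state, a, b in epochs:
        rate = rate_map.get(state, 0.0)
        if rate <= 0:
            continue
        span = b - a
        if rate * (np.mean(durations) + 2 * margin) > 0.6:
            raise ConfigError(
                f"event rate {rate}/s in {state} too high to place without "
                "overlap")
        n_ev = rng.poisson(rate * span)
        for _ in range(n_ev):
            dur = float(rng.uniform(*durations))
            for _ in range(max_tries):
                c = rng.uniform(a + dur / 2 + margin, b - dur / 2 - margin)
                lo, hi = c - dur / 2 - margin, c + dur / 2 + margin
                if all(hi <= s or lo >= e for s, e in occupied):
                    occupied.append((lo, hi))
                    placed.append((c, dur / 2))
                    break
    return placed


def _artifact_template(cfg: SimConfig, n_per: int) -> np.ndarray:
    """One slice-period gradient-artifact waveform (fixed harmonic stack)."""
    ph = np.linspace(0, 2 * np.pi, n_per, endpoint=False)
    tmpl = np.zeros(n_per)
    for h in range(1, 9):
        tmpl += np.sin(h * ph + 0.7 * h) / h
    return cfg.artifact_amp * tmpl / np.abs(tmpl).max()


def simulate_ephys(hyp: Hypnogram, cfg: SimConfig,
                   rng: Optional[np.random.Generator] = None
                   ) -> tuple[EphysRecording, EventTable]:
    """Generate the multichannel recording plus the true event table.

    Channels: ``cfg.n_ecog`` ECoG surface channels on a planar grid (shared
    state-gated delta/theta oscillators + independent 1/f background), one
    mPFC iEEG channel carrying spindles and slow waves, one CA1 LFP channel
    carrying SWRs, and one EMG channel.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    fs = cfg.fs_ephys
    n = int(round(hyp.duration * fs))
    tvec = np.arange(n) / fs

    g_delta = _gain_series(hyp, cfg.band_gains["delta"], n, fs)
    g_theta = _gain_series(hyp, cfg.band_gains["theta"], n, fs)
    g_emg = _gain_series(hyp, cfg.band_gains["emg"], n, fs)

    common_delta = _band_noise(n, fs, (1.0, 4.0), rng)
    common_theta = _theta_oscillator(n, fs, rng)

    channels: list[Channel] = []
    rows = []
    n_cols = max(1, cfg.n_ecog // 2)
    for i in range(cfg.n_ecog):
        xy = (float(i % n_cols), float(i // n_cols))  # 1 mm grid spacing
        channels.append(Channel(f"ecog{i + 1:02d}", "ECoG", xy))
        x = (cfg.delta_amp * g_delta * common_delta
             + cfg.theta_amp * g_theta * common_theta
             + cfg.bg_amp * _pink_noise(n, fs, rng))
        rows.append(x)

    # --- events -----------------------------------------------------------
    ev_rows = []
    occupied_ieeg: list = []
    spindles = _place_events(hyp.epochs, cfg.event_rates.get("spindle", {}),
                             (0.5, 2.5), rng, occupied_ieeg)
    slow_waves = _place_events(hyp.epochs, cfg.event_rates.get("slow_wave", {}),
                               (0.5, 1.1), rng, occupied_ieeg)

    ieeg = (cfg.bg_amp * _pink_noise(n, fs, rng)
            + 0.4 * cfg.delta_amp * g_delta * _band_noise(n, fs, (1, 4), rng))
    spindle_ivals = []
    for c, half in spindles:
        i0, i1 = int((c - half) * fs), int((c + half) * fs)
        seg = np.arange(i1 - i0) / fs
        f0 = rng.uniform(11.0, 15.0)
        burst = cfg.spindle_amp * np.hanning(i1 - i0) * np.sin(
            2 * np.pi * f0 * seg + rng.uniform(0, 2 * np.pi))
        ieeg[i0:i1] += burst
        spindle_ivals.append((c - half, c + half))
        ev_rows.append(("spindle", "ieeg_mpfc", c, c - half, c + half,
                        cfg.spindle_amp, "uncoupled", hyp.state_at(c)))

    for c, half in slow_waves:
        T = 2 * half                     # negative-phase interval
        pos = 0.6 * T
        amp = cfg.sw_amp * rng.uniform(0.8, 1.2)
        i0 = int((c - half) * fs)
        n_neg = int(T * fs)
        n_pos = int(pos * fs)
        wave = np.concatenate([
            -amp * np.sin(np.pi * np.arange(n_neg) / n_neg),
            0.5 * amp * np.sin(np.pi * np.arange(n_pos) / n_pos)])
        i1 = min(i0 + wave.size, n)
        ieeg[i0:i1] += wave[:i1 - i0]
        ev_rows.append(("slow_wave", "ieeg_mpfc", c, c - half, c - half + 1.6 * T,
                        amp, "NA", hyp.state_at(c)))

    # SWRs on the LFP channel, optionally coupled into spindle intervals
    lfp = (cfg.bg_amp * _pink_noise(n, fs, rng)
           + 0.3 * cfg.theta_amp * g_theta * _band_noise(n, fs, (6, 12), rng))
    swr_times = []
    occupied_lfp: list = []
    raw_swrs = _place_events(hyp.epochs, cfg.event_rates.get("SWR", {}),
                             (0.05, 0.05), rng, occupied_lfp, margin=0.15)
    nrem_spindles = [(a, b) for (a, b) in spindle_ivals]
    for c, half in raw_swrs:
        coupled = False
        if nrem_spindles and rng.random() < cfg.coupling_prob:
            a, b = nrem_spindles[rng.integers(len(nrem_spindles))]
            c = float(rng.uniform(a + 0.1, b - 0.1))
            coupled = True
        elif any(a <= c < b for a, b in nrem_spindles):
            # keep truly uncoupled SWRs out of spindle intervals
            continue
        swr_times.append((c, coupled))
    for c, coupled in swr_times:
        i0 = max(int((c - 0.06) * fs), 0)
        i1 = min(int((c + 0.06) * fs), n)
        seg = (np.arange(i1 - i0) / fs) - (c - i0 / fs)
        env = np.exp(-0.5 * (seg / 0.012) ** 2)
        ripple = cfg.swr_amp * env * np.sin(2 * np.pi * rng.uniform(150, 200) * seg)
        sharp = -1.5 * cfg.swr_amp * np.exp(-0.5 * (seg / 0.03) ** 2)
        lfp[i0:i1] += ripple + sharp
        ev_rows.append(("SWR", "lfp_ca1", c, c - 0.035, c + 0.035, cfg.swr_amp,
                        "coupled" if coupled else "uncoupled", hyp.state_at(c)))

    # flag spindles that contain >= 1 SWR center
    ev_df = pd.DataFrame(ev_rows, columns=EVENT_COLUMNS)
    if len(ev_df):
        swr_centers = ev_df.loc[ev_df["type"] == "SWR", "center_s"].to_numpy()
        for i in ev_df.index[ev_df["type"] == "spindle"]:
            a, b = ev_df.at[i, "start_s"], ev_df.at[i, "end_s"]
            if np.any((swr_centers >= a) & (swr_centers < b)):
                ev_df.at[i, "coupled"] = "coupled"
        ev_df = ev_df.sort_values("center_s").reset_index(drop=True)
    events = EventTable(ev_df)

    channels.append(Channel("ieeg_mpfc", "iEEG"))
    rows.append(ieeg)
    channels.append(Channel("lfp_ca1", "LFP"))
    rows.append(lfp)
    emg = (cfg.emg_amp * g_emg * _band_noise(n, fs, (160.0, 250.0), rng)
           + 0.5 * cfg.bg_amp * _pink_noise(n, fs, rng))
    channels.append(Channel("emg1", "EMG"))
    rows.append(emg)

    data = np.vstack(rows)

    # slice triggers on the scanner clock, one per slice period
    period = cfg.TR / cfg.n_slices
    n_trig = int(np.floor(hyp.duration / period))
    triggers = np.arange(n_trig) * period
    if cfg.artifact_amp > 0:
        n_per = int(round(period * fs))
        tmpl = _artifact_template(cfg, n_per)
        mod = 1.0 + 0.05 * np.sin(2 * np.pi * tvec / 600.0)
        for k in range(n_trig):
            i0 = int(round(triggers[k] * fs))
            i1 = min(i0 + n_per, n)
            data[:, i0:i1] += tmpl[:i1 - i0] * mod[i0:i1]

    rec = EphysRecording(data, fs, channels, triggers, session_id="sim")
    return rec, events


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------

def hrf_kernel_1hz(params: dict, length_s: float = 20.0) -> np.ndarray:
    """Sampled unit-area HRF at 1 Hz (delegates to the GLM module)."""
    from .glm import make_hrf
    return make_hrf(params, dt=1.0, length_s=length_s).samples_1hz


def _blob(grid, center, sigma, mask=None) -> np.ndarray:
    zz = np.zeros(grid)
    idx = tuple(int(round(c)) for c in center)
    zz[idx] = 1.0
    out = ndimage.gaussian_filter(zz, sigma)
    out /= out.max()
    if mask is not None:
        out = out * mask
    return out


def default_masks(grid) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoidal brain mask plus a non-brain rim (muscle surrogate)."""
    nx, ny, nz = grid
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    r = (((x - cx) / (0.36 * nx)) ** 2 + ((y - cy) / (0.36 * ny)) ** 2
         + ((z - cz) / (0.42 * nz)) ** 2)
    brain = r <= 1.0
    rim = (x < 2) | (x >= nx - 2) | (y < 2) | (y >= ny - 2)
    nonbrain = rim & ~brain
    return brain, nonbrain


def simulate_bold(hyp: Hypnogram, events: EventTable, cfg: SimConfig,
                  rng: Optional[np.random.Generator] = None
                  ) -> tuple[BoldSeries, GroundTruth]:
    """HRF-convolved state- and event-driven BOLD plus shared nuisance.

    Voxel series = sum_c map_c * (HRF (*) driver_c) + drift + motion-coupled
    nuisance (shared with non-brain voxels) + white noise, on a baseline of
    ``cfg.baseline``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    dur = hyp.duration
    if abs(dur / cfg.TR - round(dur / cfg.TR)) > 1e-9:
        raise ConfigError("TR must divide the hypnogram duration")
    n_sec = int(round(dur))
    n_fr = int(round(dur / cfg.TR))
    grid = cfg.grid
    brain, nonbrain = default_masks(grid)
    if not brain.any():
        raise ConfigError("brain mask is empty")

    hrf = hrf_kernel_1hz(cfg.hrf_params)

    # 1 Hz drivers
    labels = hyp.labels[:n_sec]
    drivers = {}
    for st in ("NREM", "REM"):
        drivers[st] = np.array([1.0 if l == st else 0.0 for l in labels])
    for etype in ("spindle", "SWR", "slow_wave"):
        tr = np.zeros(n_sec)
        if len(events):
            for c in events.select(type=etype).df["center_s"]:
                k = int(c)
                if 0 <= k < n_sec:
                    tr[k] += 1.0
        drivers[etype] = tr

    # spatial patterns (zero outside the brain mask)
    nx, ny, nz = grid
    maps = {
        "NREM": (cfg.state_bold_amp["NREM"] * _blob(grid, (nx * 0.5, ny * 0.5, nz * 0.72), 2.0, brain)
                 - 0.5 * cfg.state_bold_amp["NREM"] * _blob(grid, (nx * 0.5, ny * 0.5, nz * 0.3), 1.6, brain)),
        "REM": cfg.state_bold_amp["REM"] * _blob(grid, (nx * 0.3, ny * 0.62, nz * 0.5), 2.0, brain),
        "spindle": cfg.event_bold_amp["spindle"] * _blob(grid, (nx * 0.68, ny * 0.35, nz * 0.62), 1.8, brain),
        "SWR": cfg.event_bold_amp["SWR"] * _blob(grid, (nx * 0.38, ny * 0.38, nz * 0.42), 1.8, brain),
        "slow_wave": cfg.event_bold_amp["slow_wave"] * _blob(grid, (nx * 0.55, ny * 0.6, nz * 0.75), 2.4, brain),
    }

    frame_sec = (np.arange(n_fr) * cfg.TR).astype(int)
    vol = np.full(grid + (n_fr,), cfg.baseline, dtype=np.float64)
    conv = {}
    for name, drv in drivers.items():
        c = np.convolve(drv, hrf)[:n_sec]
        conv[name] = c[frame_sec]
        vol += maps[name][..., None] * conv[name]

    # motion parameters: smoothed random walks
    steps = rng.standard_normal((n_fr, 6))
    rp = ndimage.gaussian_filter1d(np.cumsum(steps, axis=0), 3.0, axis=0)
    rp[:, :3] *= 0.01
    rp[:, 3:] *= 0.002
    rp -= rp[0]

    # shared nuisance: motion-coupled + slow physiological oscillation
    rp_z = (rp - rp.mean(0)) / (rp.std(0) + 1e-12)
    physio = np.sin(2 * np.pi * np.arange(n_fr) * cfg.TR / 63.0
                    + rng.uniform(0, 2 * np.pi))
    nuis = rp_z @ rng.normal(0, 0.5, 6) + physio
    nuis = (nuis - nuis.mean()) / (nuis.std() + 1e-12)

    load = ndimage.gaussian_filter(rng.standard_normal(grid), 2.0)
    load = cfg.nuisance_amp * load / np.abs(load).max()
    vol += load[..., None] * nuis

    # slow polynomial drift, random per voxel
    tt = np.linspace(-1, 1, n_fr)
    basis = np.vstack([tt, tt ** 2 - np.mean(tt ** 2)])
    coef = rng.normal(0, cfg.drift_amp, grid + (2,))
    vol += np.tensordot(coef, basis, axes=([3], [0]))

    if cfg.bold_noise_sd > 0:
        vol += rng.normal(0, cfg.bold_noise_sd, vol.shape)

    series = BoldSeries(vol, cfg.TR, brain, nonbrain, rp, cfg.voxel_size_mm)
    truth = GroundTruth(
        hypnogram=hyp, events=events,
        activation_maps={k: maps[k] for k in ("NREM", "REM")},
        component_maps=maps, hrf_kernel=hrf,
        drivers={k: conv[k] for k in conv}, nuisance_series=nuis)
    return series, truth


def simulate_session(cfg: SimConfig) -> tuple[SessionBundle, GroundTruth]:
    """Full session: hypnogram -> ephys + events -> BOLD, one seed."""
    rng = np.random.default_rng(cfg.seed)
    hyp = simulate_state_sequence(cfg, rng)
    rec, events = simulate_ephys(hyp, cfg, rng)
    bold, truth = simulate_bold(hyp, events, cfg, rng)
    truth.artifact_template = (
        _artifact_template(cfg, int(round(cfg.TR / cfg.n_slices * cfg.fs_ephys)))
        if cfg.artifact_amp > 0 else None)
    bundle = SessionBundle(rec, bold, hyp, events)
    return bundle, truth
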