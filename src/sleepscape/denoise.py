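"""MRI gradient-artifact removal, bad-channel interpolation and downsampling.

Artifact removal follows the slice-template approach: the signal is
segmented at slice triggers, each segment's artifact is estimated as a
sliding local average of neighbouring segments and subtracted, iteratively.

Bad-channel repair replaces a noisy channel by a distance-weighted average
of the good channels, with weights ``Dis**lambda`` (lambda < 0) normalised
to sum to one, so that nearer channels contribute more and the lambda -> 0
limit is the plain mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal, ndimage

from .io import EphysRecording

logger = logging.getLogger("sleepscape")


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# gradient artifact
# ---------------------------------------------------------------------------

def remove_gradient_artifact(rec: EphysRecording, template_window: int = 30,
                             n_iter: int = 2) -> EphysRecording:
    """Subtract the slice-locked gradient artifact from every channel.

    Each inter-trigger segment's artifact template is the moving average of
    the surrounding ``template_window`` segments; subtraction is repeated
    ``n_iter`` times. Samples before the first / after the last full segment
    are left untouched; trigger times are preserved.
    """
    trig = rec.triggers
    if trig.size == 0:
        raise ParameterError("no slice triggers: cannot segment the artifact")
    if trig.size < template_window:
        raise ParameterError(
            f"only {trig.size} triggers for a {template_window}-segment window; "
            "reduce template_window")
    iti = np.diff(trig)
    if iti.size and iti.std() / iti.mean() > 0.10:
        raise ParameterError("inter-trigger interval varies by more than 10%")

    fs = rec.fs
    seg_len = int(round(np.median(iti) * fs)) if iti.size else rec.n_samples
    starts = np.round(trig * fs).astype(int)
    starts = starts[starts + seg_len <= rec.n_samples]
    n_seg = starts.size
    if n_seg < template_window:
        raise ParameterError("too few complete segments for the template window")

    out = rec.data.copy()
    gather = starts[:, None] + np.arange(seg_len)[None, :]
    for ci in range(out.shape[0]):
        x = out[ci]
        for _ in range(n_iter):
            segs = x[gather]                              # (n_seg, seg_len)
            tmpl = ndimage.uniform_filter1d(segs, size=template_window,
                                            axis=0, mode="nearest")
            x[gather.ravel()] = (segs - tmpl).ravel()
        out[ci] = x
    return EphysRecording(out, fs, list(rec.channels), rec.triggers.copy(),
                          rec.session_id)


# ---------------------------------------------------------------------------
# bad-channel interpolation
# ---------------------------------------------------------------------------

@dataclass
class InterpolationModel:
    """Distance-weighted interpolation model for repairing bad channels."""

    lam: float
    good_channels: Sequence[int]
    distances: np.ndarray  # full pairwise channel distance matrix (mm)

    def __post_init__(self) -> None:
        if self.lam >= 0:
            raise ParameterError("lambda must be negative")
        D = np.asarray(self.distances, float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ParameterError("distances must be a square matrix")
        if not np.allclose(D, D.T) or np.any(np.abs(np.diag(D)) > 1e-12):
            raise ParameterError("distances must be symmetric with zero diagonal")
        self.distances = D

    @classmethod
    def from_layout(cls, rec: EphysRecording, lam: float,
                    good_channels: Optional[Sequence[int]] = None
                    ) -> "InterpolationModel":
        xy = np.array([ch.layout_xy if ch.layout_xy is not None else (np.nan,) * 2
                       for ch in rec.channels], float)
        D = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
        np.fill_diagonal(D, 0.0)
        if good_channels is None:
            good_channels = [i for i, ch in enumerate(rec.channels)
                             if ch.kind == "ECoG"]
        return cls(lam, list(good_channels), np.nan_to_num(D, nan=np.inf))


def interpolation_weights(distances: np.ndarray, lam: float) -> np.ndarray:
    """Normalised powered-distance weights; a zero distance degenerates to a
    nearest-channel copy (weight 1 on that channel)."""
    d = np.asarray(distances, float)
    if np.any(d <= 0):
        logger.warning("coincident channel (zero distance): using nearest copy")
        w = np.zeros_like(d)
        w[np.argmin(d)] = 1.0
        return w
    w = d ** lam
    return w / w.sum()


def interpolate_bad_channels(rec: EphysRecording, bad: Sequence[int],
                             model: InterpolationModel) -> EphysRecording:
    """Replace each bad channel by the weighted average of good channels."""
    good = [g for g in model.good_channels if g not in set(bad)]
    if len(bad) >= len(good):
        raise ParameterError("need more good channels than bad ones")
    out = rec.data.copy()
    for b in bad:
        w = interpolation_weights(model.distances[b, good], model.lam)
        out[b] = w @ rec.data[good]
    return EphysRecording(out, rec.fs, list(rec.channels), rec.triggers.copy(),
                          rec.session_id)


def estimate_lambda(rec: EphysRecording, good: Sequence[int],
                    grid: Sequence[float],
                    distances: Optional[np.ndarray] = None) -> float:
    """Pick lambda by leave-one-out least squares over the good channels.

    Ties (within numerical tolerance) resolve to the smallest ``|lambda|``.
    """
    grid = list(grid)
    if not grid:
        raise ParameterError("empty lambda grid")
    if len(good) < 3:
        raise ParameterError("need at least 3 good channels")
    if distances is None:
        distances = InterpolationModel.from_layout(rec, -1.0, good).distances
    losses = []
    for lam in grid:
        sse = 0.0
        for b in good:
            others = [g for g in good if g != b]
            w = interpolation_weights(distances[b, others], lam)
            pred = w @ rec.data[others]
            sse += float(np.sum((rec.data[b] - pred) ** 2))
        losses.append(sse)
    losses = np.asarray(losses)
    best = losses.min()
    tied = [lam for lam, l in zip(grid, losses)
            if l <= best * (1 + 1e-9) + 1e-12]
    return min(tied, key=abs)


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------

def downsample(rec: EphysRecording, fs_out: float = 1024.0) -> EphysRecording:
    """Zero-phase anti-alias low-pass at 0.45*fs_out, then resample.

    Trigger times are in seconds and therefore unchanged.
    """
    if fs_out > rec.fs:
        raise ParameterError(f"fs_out {fs_out} exceeds input rate {rec.fs}")
    # elliptic low-pass: ~flat passband, >= 45 dB stopband, squared by filtfilt
    wp = 0.45 * fs_out
    ws = min(0.5 * fs_out, 0.499 * rec.fs)
    if ws > wp:
        n_ord, wn = signal.ellipord(wp, ws, 0.002, 45, fs=rec.fs)
        sos = signal.ellip(n_ord, 0.002, 45, wn, btype="low", fs=rec.fs,
                           output="sos")
        data = signal.sosfiltfilt(sos, rec.data, axis=1)
    else:
        data = rec.data
    if np.isclose(fs_out, rec.fs):
        out = data
    else:
        n_out = int(round(rec.n_samples * fs_out / rec.fs))
        t_in = np.arange(rec.n_samples) / rec.fs
        t_out = np.arange(n_out) / fs_out
        out = np.empty((rec.n_channels, n_out))
        for i in range(rec.n_channels):
            out[i] = np.interp(t_out, t_in, data[i])
    return EphysRecording(out, fs_out, list(rec.channels), rec.triggers.copy(),
                          rec.session_id)
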