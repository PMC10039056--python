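"""Mouse-HRF state GLM and band-power-to-BOLD correlation.

NREM and REM boxcars (AW is the implicit baseline) are convolved with a
single-gamma mouse HRF (peak 1.75 s, FWHM 1.5 s — inside the 1.5-2 s
hemodynamic delay reported for mice), fit voxelwise by OLS, and thresholded
with Benjamini-Hochberg FDR at q = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .io import BoldSeries, Hypnogram

DEFAULT_HRF = {"peak_time_s": 1.75, "fwhm_s": 1.5, "undershoot_ratio": 0.0}


class ParameterError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class BandDefs:
    """Non-overlapping, ordered frequency bands (Hz)."""

    bands: dict = field(default_factory=lambda: {
        "delta": (1.0, 4.0), "theta": (5.0, 10.0), "alpha": (11.0, 20.0),
        "beta": (21.0, 40.0), "gamma": (41.0, 100.0)})

    def __post_init__(self) -> None:
        edges = list(self.bands.values())
        for (a0, b0), (a1, b1) in zip(edges, edges[1:]):
            if b0 > a1:
                raise ParameterError("bands must be ordered and non-overlapping")


@dataclass
class HrfKernel:
    """Unit-area HRF sampled at 1 Hz and at the TR grid; zero before t=0."""

    samples_1hz: np.ndarray
    samples_tr: np.ndarray
    TR: float
    params: dict


def _gamma_fwhm(a: float, b: float) -> float:
    """FWHM of the gamma-shaped kernel t^(a-1) exp(-t/b) (fine grid)."""
    t = np.linspace(1e-6, 40.0, 40000)
    logy = (a - 1) * np.log(t) - t / b       # log-space avoids overflow
    logy -= logy.max()
    above = t[logy >= np.log(0.5)]
    return float(above[-1] - above[0])


def make_hrf(params: dict | None = None, dt: float = 1.0, TR: float = 2.0,
             length_s: float = 20.0) -> HrfKernel:
    """Single-gamma HRF with the requested peak time and FWHM, unit area.

    The gamma shape/scale are solved so the mode equals ``peak_time_s`` and
    the full width at half maximum matches ``fwhm_s``.
    """
    p = dict(DEFAULT_HRF, **(params or {}))
    peak, fwhm = p["peak_time_s"], p["fwhm_s"]
    if peak <= 0 or fwhm <= 0:
        raise ParameterError("HRF peak time and FWHM must be positive")

    def err(log_a):
        a = 1.0 + np.exp(log_a)
        return _gamma_fwhm(a, peak / (a - 1.0)) - fwhm

    log_a = optimize.brentq(err, np.log(0.1), np.log(500.0))
    a = 1.0 + np.exp(log_a)
    b = peak / (a - 1.0)

    def sample(step: float) -> np.ndarray:
        t = np.arange(0.0, length_s + 1e-9, step)
        with np.errstate(divide="ignore"):
            logh = (a - 1) * np.log(t) - t / b
        h = np.exp(logh - np.nanmax(logh[np.isfinite(logh)]))
        h[~np.isfinite(h)] = 0.0
        if p.get("undershoot_ratio", 0.0) > 0:
            u_peak = peak + 2.0 * fwhm
            au = 1.0 + (u_peak / b)
            h = h - p["undershoot_ratio"] * (t ** (au - 1) * np.exp(-t / b)
                                             / special.gamma(au))
        s = h.sum() * step
        return h / s

    return HrfKernel(sample(dt), sample(TR), TR, p)


def build_design(hyp: Hypnogram, hrf: HrfKernel, TR: float,
                 n_frames: int) -> np.ndarray:
    """t x 2 design: HRF-convolved NREM and REM boxcars at the TR grid,
    mean-centered (AW implicit baseline)."""
    n_sec = int(np.ceil(n_frames * TR))
    labels = (hyp.labels + ["AW"] * n_sec)[:n_sec]
    X = np.zeros((n_frames, 2))
    frame_sec = np.minimum((np.arange(n_frames) * TR).astype(int), n_sec - 1)
    for j, st in enumerate(("NREM", "REM")):
        box = np.array([1.0 if l == st else 0.0 for l in labels])
        conv = np.convolve(box, hrf.samples_1hz)[:n_sec]
        X[:, j] = conv[frame_sec]
    return X - X.mean(axis=0)


def fit_state_glm(b: BoldSeries, X: np.ndarray, q: float = 0.05) -> dict:
    """Voxelwise OLS with intercept; per-predictor t maps and BH-FDR masks.

    Returns dict with 'beta', 'tmap', 'p', 'fdr_mask' arrays of shape
    (n_predictors, n_brain_voxels) plus the brain mask for unflattening.
    """
    if b.n_frames < 10:
        raise DataError("need at least 10 volumes")
    Y = b.masked(b.brain_mask)                        # t x v
    t_n, v = Y.shape
    Xd = np.column_stack([np.ones(t_n), X])
    beta, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
    resid = Y - Xd @ beta
    dof = t_n - Xd.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    # pinv tolerates a degenerate predictor (e.g. a state absent from the
    # hypnogram gives an all-zero column); its t values come out 0
    XtX_inv = np.linalg.pinv(Xd.T @ Xd)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tmap = np.where(se > 0, beta / se, 0.0)
    p = 2 * stats.t.sf(np.abs(tmap), dof)
    fdr = np.zeros_like(p, bool)
    for j in range(1, Xd.shape[1]):
        fdr[j] = multipletests(p[j], alpha=q, method="fdr_bh")[0]
    return {"beta": beta[1:], "tmap": tmap[1:], "p": p[1:],
            "fdr_mask": fdr[1:], "mask": b.brain_mask, "dof": dof}


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg rejection mask (thin wrapper, shared convention)."""
    return multipletests(np.asarray(pvals, float).ravel(), alpha=q,
                         method="fdr_bh")[0].reshape(np.shape(pvals))


def band_power_bold_correlation(band_powers: dict, hyp: Hypnogram,
                                roi_series: np.ndarray, hrf: HrfKernel,
                                TR: float, state: str = "NREM") -> dict:
    """Epoch-wise Pearson correlation between relative band power and
    relative BOLD, both expressed vs the session AW mean (value/AW - 1).

    ``band_powers`` maps band name -> 1 Hz power series; ``roi_series`` is
    the ROI BOLD series at the TR grid. Returns per band
    ``{r, p, rel_power, rel_bold}`` with per-epoch pairs; fewer than 3
    epochs of ``state`` yields ``r = nan``.
    """
    n_frames = len(roi_series)
    frame_sec = (np.arange(n_frames) * TR).astype(int)
    n_sec = int(np.ceil(n_frames * TR))
    labels = (hyp.labels + ["AW"] * n_sec)[:n_sec]
    frame_state = np.array(labels)[np.minimum(frame_sec, n_sec - 1)]
    aw_frames = frame_state == "AW"
    epochs = [(a, b) for a, b in hyp.epochs_of(state)]
    out = {}
    for name, series in band_powers.items():
        conv = np.convolve(np.asarray(series, float), hrf.samples_1hz)[:n_sec]
        conv_fr = conv[np.minimum(frame_sec, n_sec - 1)]
        aw_pow = conv_fr[aw_frames].mean() if aw_frames.any() else np.nan
        aw_bold = roi_series[aw_frames].mean() if aw_frames.any() else np.nan
        rel_p, rel_b = [], []
        for a, b in epochs:
            sel = (frame_sec >= a) & (frame_sec < b)
            if sel.sum() == 0:
                continue
            rel_p.append(conv_fr[sel].mean() / aw_pow - 1.0)
            rel_b.append(roi_series[sel].mean() / aw_bold - 1.0)
        rel_p, rel_b = np.asarray(rel_p), np.asarray(rel_b)
        if rel_p.size < 3:
            out[name] = {"r": np.nan, "p": np.nan,
                         "rel_power": rel_p, "rel_bold": rel_b}
            continue
        r, pv = stats.pearsonr(rel_p, rel_b)
        out[name] = {"r": float(r), "p": float(pv),
                     "rel_power": rel_p, "rel_bold": rel_b}
    return out
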