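"""Spatial smoothing, the 6 rp + 6 drp + 40 PCs nuisance model, and FD/DVARS QC.

The nuisance design combines the six rigid-body motion parameters, their
first-order backward differences, and the leading temporal principal
components of the non-brain (muscle) voxel series; regression is ordinary
least squares per brain voxel, with the voxel mean restored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import BoldSeries

logger = logging.getLogger("sleepscape")


class DataError(ValueError):
    pass


@dataclass
class NuisanceModel:
    """t x (12 + n_pc) regressor matrix with column labels."""

    regressors: np.ndarray
    column_labels: list

    def __post_init__(self) -> None:
        if self.regressors.shape[1] != len(self.column_labels):
            raise DataError("label count does not match regressor columns")


def smooth_spatial(b: BoldSeries, fwhm_mm: float = 0.4) -> BoldSeries:
    """Per-volume isotropic 3D Gaussian smoothing with the stated FWHM (mm)."""
    vox = np.asarray(b.voxel_size_mm, float)
    if fwhm_mm < vox.min() / 4:
        logger.warning("FWHM %.3f mm below voxel size / 4: pass-through",
                       fwhm_mm)
        return b
    sigma_vox = (fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / vox
    out = ndimage.gaussian_filter(b.volume, sigma=tuple(sigma_vox) + (0.0,))
    return b.with_volume(out)


def compute_motion_metrics(rp: np.ndarray, radius_mm: float = 5.0
                           ) -> tuple[np.ndarray, float]:
    """Framewise displacement: sum |dtranslation| + radius * sum |drotation|.

    The rotation radius approximates the mouse head; FD[0] = 0.
    """
    rp = np.asarray(rp, float)
    if not np.all(np.isfinite(rp)):
        raise DataError("non-finite motion parameters")
    d = np.diff(rp, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd]), radius_mm


def dvars(b: BoldSeries) -> np.ndarray:
    """RMS over brain voxels of the frame-to-frame change of the
    global-mean-normalised series; DVARS[0] = 0."""
    series = b.masked(b.brain_mask)                     # t x v
    norm = series / series.mean()
    d = np.diff(norm, axis=0)
    out = np.sqrt((d ** 2).mean(axis=1))
    return np.concatenate([[0.0], out])


def build_nuisance(b: BoldSeries, n_pc: int = 40) -> NuisanceModel:
    """Assemble 6 rp + 6 backward-difference drp (leading zero row) + the
    top ``n_pc`` unit-variance temporal PCs of variance-normalised
    non-brain voxels (capped at the available rank, with a log message)."""
    if not b.nonbrain_mask.any():
        raise DataError("non-brain mask is empty")
    rp = b.rp
    drp = np.vstack([np.zeros((1, 6)), np.diff(rp, axis=0)])
    cols = [rp, drp]
    labels = [f"rp{i + 1}" for i in range(6)] + [f"drp{i + 1}" for i in range(6)]
    if n_pc > 0:
        series = b.masked(b.nonbrain_mask)              # t x v
        series = series - series.mean(axis=0)
        sd = series.std(axis=0)
        keep = sd > 0
        series = series[:, keep] / sd[keep]
        u, s, vt = np.linalg.svd(series, full_matrices=False)
        rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
        if rank < n_pc:
            logger.info("non-brain rank %d < requested %d PCs", rank, n_pc)
        n_use = min(n_pc, rank)
        pcs = u[:, :n_use]
        # deterministic sign: largest-|loading| voxel of each component positive
        for j in range(n_use):
            k = int(np.argmax(np.abs(vt[j])))
            if vt[j, k] < 0:
                pcs[:, j] = -pcs[:, j]
        pcs = pcs / pcs.std(axis=0)
        cols.append(pcs)
        labels += [f"pc{j + 1}" for j in range(n_use)]
    X = np.hstack(cols)
    return NuisanceModel(X, labels)


def regress_nuisance(b: BoldSeries, m: NuisanceModel) -> BoldSeries:
    """OLS removal of the nuisance design from every brain voxel.

    The residual plus the voxel mean is returned; non-brain voxels and the
    masks pass through untouched. Collinear columns are dropped with a
    warning.
    """
    if m.regressors.shape[0] != b.n_frames:
        raise DataError("regressor rows do not match frame count")
    t = b.n_frames
    X = np.column_stack([np.ones(t), m.regressors])
    # drop collinear columns via pivoted QR (intercept always kept)
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    if (diag < diag.max() * 1e-10).any():
        from scipy.linalg import qr as sqr
        _, r2, piv = sqr(X, mode="economic", pivoting=True)
        d2 = np.abs(np.diag(r2))
        rank = int((d2 > d2[0] * 1e-10).sum())
        keep = sorted(piv[:rank])
        if 0 not in keep:
            keep = [0] + keep[:-1]
        logger.warning("dropping %d collinear nuisance columns",
                       X.shape[1] - len(keep))
        X = X[:, keep]
    Y = b.volume[b.brain_mask].T                        # t x v
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    resid += Y.mean(axis=0)
    out = b.volume.copy()
    out[b.brain_mask] = resid.T
    return b.with_volume(out)
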