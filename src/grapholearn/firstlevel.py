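"""Voxelwise ordinary-least-squares fit of a BOLD run against a design.

``FirstLevelGLM`` is the model object; ``fit()`` returns a
``FirstLevelResults`` carrying one beta volume per named regressor plus a
residual-variance map.  The temporal smoothing recorded in the design is
applied to the data here, so data and regressors pass through matched filters.
Spatial smoothing (``smooth_volume``) is kept separate: pattern analyses use
unsmoothed betas while univariate group maps use spatially smoothed inputs.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import BoldRun
from .design import FWHM_TO_SIGMA, DesignMatrix, temporal_smooth


class FirstLevelResults:
    """Betas, residual variance and bookkeeping from one first-level fit."""

    def __init__(
        self,
        betas: np.ndarray,
        names: list[str],
        resid_var: np.ndarray,
        mask: np.ndarray,
        shape: tuple[int, int, int],
        affine: np.ndarray,
        design: DesignMatrix,
        flagged: np.ndarray,
    ):
        self._betas = betas  # (p, n_mask_voxels)
        self.names = list(names)
        self._resid_var = resid_var
        self.mask = mask
        self.shape = shape
        self.affine = affine
        self.design = design
        self._flagged = flagged

    def _unmask(self, flat: np.ndarray) -> np.ndarray:
        vol = np.zeros(self.shape, dtype=float)
        vol[self.mask] = flat
        return vol

    def beta_map(self, name: str) -> np.ndarray:
        """3D beta volume for one named regressor."""
        return self._unmask(self._betas[self.names.index(name)])

    def beta_matrix(self, names: list[str], roi_mask: np.ndarray | None = None) -> np.ndarray:
        """(len(names), n_voxels) beta matrix, optionally restricted to an ROI."""
        idx = [self.names.index(n) for n in names]
        if roi_mask is None:
            return self._betas[idx]
        sel = roi_mask[self.mask]
        return self._betas[np.ix_(idx, np.flatnonzero(sel))]

    def t_map(self, name: str) -> tuple[np.ndarray, int]:
        """(3D t-statistic volume, error dof) for one regressor's beta.

        Standard OLS inference: se = sqrt(resid_var * (X'X)^-1_jj); voxels
        with zero residual variance (flagged or perfectly fitted) get t = 0.
        """
        j = self.names.index(name)
        x = self.design.values
        xtx_inv = np.linalg.pinv(x.T @ x)
        dof = max(x.shape[0] - x.shape[1], 1)
        se = np.sqrt(self._resid_var * xtx_inv[j, j])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, self._betas[j] / se, 0.0)
        return self._unmask(t), dof

    @property
    def residual_variance(self) -> np.ndarray:
        """3D unbiased residual variance map; 0 at flagged (all-zero) voxels."""
        return self._unmask(self._resid_var)

    @property
    def flagged_voxels(self) -> np.ndarray:
        """Mask of voxels whose time series was identically zero."""
        return self._unmask(self._flagged.astype(float)) > 0.5


class FirstLevelGLM:
    """OLS of every in-mask voxel time series on the design matrix."""

    def __init__(self, run: BoldRun, design: DesignMatrix, mask: np.ndarray | None = None):
        if design.values.shape[0] != run.n_volumes:
            raise ValueError("design rows must match the number of volumes")
        self.run = run
        self.design = design
        self.mask = (
            np.ones(run.data.shape[:3], dtype=bool) if mask is None else mask.astype(bool)
        )

    def fit(self) -> FirstLevelResults:
        data = self.run.data[self.mask].T.astype(float)  # (t, v)
        if self.design.temporal_smooth_s > 0:
            data = temporal_smooth(data, self.design.temporal_smooth_s, self.design.tr_seconds)
        x = self.design.values
        betas, _, _, _ = np.linalg.lstsq(x, data, rcond=None)
        resid = data - x @ betas
        dof = max(x.shape[0] - x.shape[1], 1)
        resid_var = np.sum(resid**2, axis=0) / dof
        flagged = np.all(self.run.data[self.mask].T == 0, axis=0)
        resid_var[flagged] = 0.0
        return FirstLevelResults(
            betas=betas,
            names=self.design.columns,
            resid_var=resid_var,
            mask=self.mask,
            shape=self.run.data.shape[:3],
            affine=np.asarray(self.run.affine),
            design=self.design,
            flagged=flagged,
        )


def fit_glm(
    run: BoldRun, design: DesignMatrix, mask: np.ndarray | None = None
) -> FirstLevelResults:
    """Functional wrapper around ``FirstLevelGLM(run, design, mask).fit()``."""
    return FirstLevelGLM(run, design, mask).fit()


def voxel_sizes_mm(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel size in mm; rejects shear/oblique affines."""
    lin = np.asarray(affine, dtype=float)[:3, :3]
    gram = lin.T @ lin
    off = gram - np.diag(np.diag(gram))
    if np.max(np.abs(off)) > 1e-6 * np.max(np.abs(gram)):
        raise ValueError("affine has shear or oblique axes; unsupported geometry")
    return np.sqrt(np.diag(gram))


def smooth_volume(volume: np.ndarray, affine: np.ndarray, fwhm_mm: float) -> np.ndarray:
    """Separable spatial Gaussian smoothing with FWHM given in millimetres."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=float).copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_sizes_mm(affine)
    return gaussian_filter(np.asarray(volume, dtype=float), sigma=sigma_vox, mode="constant")
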