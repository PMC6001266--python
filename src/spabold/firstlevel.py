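"""Voxelwise OLS estimation of FIR responses and the SPA summary.

The summed positive area (SPA) collapses the five freely estimated FIR
coefficients of a condition into a single non-negative response magnitude
per voxel: the sum of the non-negative coefficients.  It makes no
assumption about response shape or latency, which is why it suits a sparse
acquisition where the hemodynamic response is sampled at only five lags.
Temporal whitening is deliberately absent: with a discontinuous series the
usual AR(1) model does not apply.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import linalg, ndimage

from .design import DesignMatrix
from .errors import ConditionAbsent, InputError, RankDeficiencyError
from .synth import VolumeSeries

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def smooth_volumes(series: VolumeSeries, fwhm_mm: float,
                   voxel_size_mm: float) -> VolumeSeries:
    """Volume-wise Gaussian smoothing with the given FWHM in mm.

    Kernel sigma per axis is ``fwhm / (2 sqrt(2 ln 2))``; boundaries are
    zero-padded (constant mode), so per-volume mass is preserved up to the
    kernel tails clipped at the grid edge.  ``fwhm_mm=0`` returns the data
    unchanged.
    """
    if fwhm_mm < 0:
        raise InputError(f"fwhm_mm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return series
    sigma_vox = fwhm_mm / _FWHM_TO_SIGMA / voxel_size_mm
    out = ndimage.gaussian_filter(
        series.data.astype(np.float32, copy=True),
        sigma=(sigma_vox, sigma_vox, sigma_vox, 0.0), mode="constant")
    return _dc_replace(series, data=out)


@dataclass
class BetaMaps:
    """Per-regressor coefficient maps restricted to the brain mask."""

    betas: np.ndarray           # (n_columns, n_mask_voxels)
    columns: list[str]
    residuals: np.ndarray       # (n_volumes, n_mask_voxels), float32
    df_resid: int
    mask: np.ndarray            # 3D boolean
    affine: np.ndarray
    fir_events: dict[str, int]
    omitted_events: list[str]
    volumes_per_trial: int

    def map3d(self, label: str, fill: float = np.nan) -> np.ndarray:
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.mask] = self.betas[self.columns.index(label)]
        return out

    def fir_profile_matrix(self, event_type: str) -> np.ndarray:
        """(volumes_per_trial, n_mask_voxels) FIR coefficients of one event type."""
        if event_type not in self.fir_events:
            raise ConditionAbsent(
                f"event type {event_type!r} was not estimable "
                f"(omitted: {self.omitted_events})")
        idx = [self.columns.index(f"{event_type}:fir{k + 1}")
               for k in range(self.volumes_per_trial)]
        return self.betas[idx]

    def residuals_4d(self) -> np.ndarray:
        out = np.zeros(self.mask.shape + (self.residuals.shape[0],), dtype=np.float32)
        out[self.mask] = self.residuals.T
        return out


def fit_glm(series: VolumeSeries, dm: DesignMatrix,
            keep_residuals: bool = True) -> BetaMaps:
    """Ordinary least squares fit at every brain-mask voxel.

    Raises :class:`RankDeficiencyError` naming collinear columns when the
    design is rank deficient.  Residuals (kept by default) feed the
    smoothness estimation used for random-field inference.
    """
    X = np.asarray(dm.matrix, dtype=float)
    if X.shape[0] != series.n_volumes:
        raise InputError(
            f"design has {X.shape[0]} rows but series has {series.n_volumes} volumes")
    n, p = X.shape
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = diag <= tol
    if bad.any():
        names = [dm.columns[i] for i in np.flatnonzero(bad)]
        raise RankDeficiencyError(f"design matrix is rank deficient; collinear columns: {names}")

    # volume-major view so masking stays cheap regardless of storage order
    vol_first = np.moveaxis(series.data, -1, 0)
    Y = np.ascontiguousarray(vol_first[:, series.brain_mask], dtype=float)
    coef = linalg.solve_triangular(R, Q.T @ Y)
    resid = (Y - X @ coef).astype(np.float32) if keep_residuals else np.empty((0, Y.shape[1]), np.float32)
    return BetaMaps(
        betas=coef, columns=list(dm.columns),
        residuals=resid, df_resid=n - p,
        mask=series.brain_mask, affine=series.affine,
        fir_events=dict(dm.fir_events), omitted_events=list(dm.omitted_events),
        volumes_per_trial=len(dm.fir_columns(next(iter(dm.fir_events)))) if dm.fir_events else 0,
    )


@dataclass
class SpaMap:
    """Per-subject, per-condition summed-positive-area map (in-mask vector)."""

    values: np.ndarray          # (n_mask_voxels,), all >= 0
    condition: str
    subject_id: str | None
    mask: np.ndarray
    affine: np.ndarray

    def map3d(self, fill: float = np.nan) -> np.ndarray:
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.mask] = self.values
        return out


def compute_spa(betas: BetaMaps, condition: str,
                subject_id: str | None = None) -> SpaMap:
    """Sum the non-negative FIR coefficients of ``condition`` voxelwise.

    Raises :class:`ConditionAbsent` when the condition had no trials (its
    columns were omitted from the design): an absent condition is an
    explicit outcome, never a zero map.
    """
    profile = betas.fir_profile_matrix(condition)
    values = np.clip(profile, 0.0, None).sum(axis=0)
    return SpaMap(values=values, condition=condition, subject_id=subject_id,
                  mask=betas.mask, affine=betas.affine)


def spa_group_average(betas: BetaMaps, conditions, label: str,
                      subject_id: str | None = None) -> SpaMap:
    """Average the SPA maps of the listed conditions that were estimable.

    Used to form composite responses such as "all correct sentences" from
    the per-cell event types.  Raises :class:`ConditionAbsent` if none of
    the conditions had trials.
    """
    present = [c for c in conditions if c in betas.fir_events]
    if not present:
        raise ConditionAbsent(f"no estimable condition among {list(conditions)}")
    stacked = np.stack([compute_spa(betas, c).values for c in present])
    return SpaMap(values=stacked.mean(axis=0), condition=label,
                  subject_id=subject_id, mask=betas.mask, affine=betas.affine)


def reconstruct_timecourse(betas: BetaMaps, location, condition: str) -> np.ndarray:
    """FIR coefficients at a voxel (index triple) or averaged over a mask.

    This is the shape-free reconstruction of the hemodynamic response at
    the five acquired lags; aggregating over a one-voxel mask equals
    indexing that voxel directly.
    """
    profile = betas.fir_profile_matrix(condition)
    if isinstance(location, np.ndarray) and location.dtype == bool:
        if location.shape != betas.mask.shape:
            raise InputError("location mask shape does not match the brain grid")
        sel = location & betas.mask
        if not sel.any():
            raise InputError("location mask has no voxels inside the brain mask")
        flat = np.zeros(betas.mask.shape, dtype=bool)
        flat[sel] = True
        idx = flat[betas.mask]
        return profile[:, idx].mean(axis=1)
    loc = tuple(int(v) for v in location)
    if len(loc) != 3 or not betas.mask[loc]:
        raise InputError(f"voxel {loc} is outside the brain mask")
    vox_index = np.zeros(betas.mask.shape, dtype=bool)
    vox_index[loc] = True
    return profile[:, vox_index[betas.mask]][:, 0]
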