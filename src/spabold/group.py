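"""Second-level inference across subjects on SPA maps.

The second level is deliberately simple summary-statistic OLS: paired t
tests for condition contrasts and voxelwise simple linear regressions for
subject covariates (PTA, age, working memory, accuracy), each converted to
a Z map for random-field cluster inference.  The residualization scheme
regresses the covariate of interest on nuisance covariates and enters the
residual into the same voxelwise regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .errors import InputError
from .firstlevel import SpaMap

_Z_CLIP = 38.0  # largest |Z| representable without underflow games


def t_to_z(t, df: int):
    """Map t statistics to standard-normal quantiles of equal tail mass.

    Computed through log tail probabilities so that extreme t values do not
    underflow; strictly increasing in t at fixed df.
    """
    t = np.asarray(t, dtype=float)
    logsf = stats.t.logsf(np.abs(t), df)
    z = -special.ndtri_exp(logsf)
    z = np.clip(z, None, _Z_CLIP)
    return np.where(t < 0, -z, z)


@dataclass
class StatMap:
    """Voxelwise t map with its Z transform (in-mask vectors)."""

    t: np.ndarray
    z: np.ndarray
    df: int
    label: str
    mask: np.ndarray
    affine: np.ndarray
    residuals: np.ndarray | None = None   # (n_subjects, n_mask), for smoothness
    effect: np.ndarray | None = None      # mean difference or regression slope

    def z3d(self, fill: float = np.nan) -> np.ndarray:
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.mask] = self.z
        return out


def _stack_maps(maps) -> tuple[np.ndarray, list, np.ndarray, np.ndarray]:
    if isinstance(maps, np.ndarray):
        raise InputError("pass a sequence of SpaMap objects")
    arr = np.stack([m.values for m in maps])
    ids = [m.subject_id for m in maps]
    return arr, ids, maps[0].mask, maps[0].affine


def paired_t(maps_a, maps_b, label: str = "paired") -> StatMap:
    """Voxelwise paired t test on (a - b); df = n - 1.

    The two map lists must contain the same subjects in the same order.
    """
    a, ids_a, mask, affine = _stack_maps(maps_a)
    b, ids_b, _, _ = _stack_maps(maps_b)
    if ids_a != ids_b:
        raise InputError("paired_t requires identical subjects in identical order")
    if a.shape != b.shape or a.shape[0] < 2:
        raise InputError("paired_t needs at least two matched subject pairs")
    d = a - b
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[np.isnan(t)] = 0.0          # 0/0: constant zero difference
    df = n - 1
    resid = d - mean
    return StatMap(t=t, z=t_to_z(t, df), df=df, label=label,
                   mask=mask, affine=affine, residuals=resid.astype(np.float32),
                   effect=mean)


def regress_covariate(maps, covariate, label: str = "regression") -> StatMap:
    """Voxelwise simple linear regression ``map ~ intercept + covariate``.

    The covariate is mean-centered; the t statistic (df = n - 2) of the
    slope is returned with the convention that positive Z means larger SPA
    with larger covariate.
    """
    y, _, mask, affine = _stack_maps(maps)
    x = np.asarray(covariate, dtype=float)
    if x.ndim != 1 or len(x) != y.shape[0]:
        raise InputError("covariate length must match the number of maps")
    if len(x) < 3:
        raise InputError("regression needs at least 3 subjects")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise InputError("covariate has zero variance")
    yc = y - y.mean(axis=0)
    slope = (xc @ yc) / sxx
    fitted = np.outer(xc, slope)
    resid = yc - fitted
    df = len(x) - 2
    sigma2 = (resid ** 2).sum(axis=0) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / sxx)
        t = slope / se            # exact fits give +/-inf, Z-clipped downstream
    t[np.isnan(t)] = 0.0          # 0/0: constant map with zero slope
    return StatMap(t=t, z=t_to_z(t, df), df=df, label=label,
                   mask=mask, affine=affine, residuals=resid.astype(np.float32),
                   effect=slope)


def residualize(target, others) -> np.ndarray:
    """OLS residual of ``target`` on an intercept plus one or more covariates.

    The residual has zero mean and zero sample correlation with each
    regressor; an (almost) exactly collinear target is flagged by raising
    :class:`InputError`, since a zero residual cannot carry information
    into a regression.
    """
    y = np.asarray(target, dtype=float)
    X = np.column_stack([np.ones(len(y))] + [np.asarray(o, float) for o in np.atleast_2d(others)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InputError("nuisance covariates are rank deficient with the intercept")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    scale = np.linalg.norm(y - y.mean())
    if scale > 0 and np.linalg.norm(resid) < 1e-10 * scale:
        raise InputError("target is an exact linear function of the nuisance covariates")
    return resid


def partial_regression(maps, covariate, nuisance, label: str = "partial") -> StatMap:
    """Voxelwise multiple regression, reporting the covariate's partial t.

    The alternative to the residualization scheme: nuisance covariates are
    modeled jointly with the covariate of interest and the partial t of
    that covariate (df = n - 2 - #nuisance) is Z-transformed.  For a single
    nuisance variable this differs from regression on the residualized
    covariate only through the error degrees of freedom.
    """
    y, _, mask, affine = _stack_maps(maps)
    x = np.asarray(covariate, dtype=float)
    Z = np.column_stack([np.ones(len(x)), x]
                        + [np.asarray(o, float) for o in np.atleast_2d(nuisance)])
    n, p = Z.shape
    if n != y.shape[0]:
        raise InputError("covariate length must match the number of maps")
    if n <= p:
        raise InputError("more regressors than subjects")
    if np.linalg.matrix_rank(Z) < p:
        raise InputError("covariates are rank deficient with the intercept")
    pinv = np.linalg.pinv(Z)
    coef = pinv @ y
    resid = y - Z @ coef
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    var_b = float((pinv @ pinv.T)[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef[1] / np.sqrt(sigma2 * var_b)
    t[np.isnan(t)] = 0.0
    return StatMap(t=t, z=t_to_z(t, df), df=df, label=label,
                   mask=mask, affine=affine, residuals=resid.astype(np.float32),
                   effect=coef[1])


def condition_restricted_regression(maps_by_condition: dict, covariate,
                                    label_prefix: str = "") -> dict[str, StatMap]:
    """Run :func:`regress_covariate` separately per condition's map list."""
    return {
        cond: regress_covariate(maps, covariate, label=f"{label_prefix}{cond}")
        for cond, maps in maps_by_condition.items()
    }
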