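"""Cluster-level family-wise-error inference by Gaussian random field theory.

Group Z maps are thresholded voxelwise (default p < 0.001, i.e. Z > 3.09),
suprathreshold voxels are grouped with 26-connectivity, and each cluster
receives an FWE-corrected p-value from the standard random-field
approximation: the expected number of clusters comes from the expected
Euler characteristic (resel counts x EC densities), and the probability
that a cluster exceeds the observed extent uses the classic
``exp(-beta k^(2/3))`` extent distribution.  A permutation oracle
(max-cluster-extent null) is provided for validation; the analytic path is
the one mirroring the analysis this package reimplements.

Smoothness (FWHM per axis) is estimated from normalized residual spatial
derivatives; resel counts use Worsley's box-counting over the search mask,
so edge effects of small masks enter the expected Euler characteristic
through the lower-dimensional resel terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, special
from scipy.special import gammaln

from .errors import InputError
from .group import StatMap, t_to_z

_4LN2 = 4.0 * np.log(2.0)


# ---------------------------------------------------------------------------
# smoothness
# ---------------------------------------------------------------------------

@dataclass
class SmoothnessEstimate:
    fwhm_mm: np.ndarray         # per axis
    fwhm_vox: np.ndarray        # per axis, voxel units
    resels: np.ndarray          # R_0..R_3 box-counting resel counts
    n_voxels: int               # voxels in the search mask
    voxel_size_mm: float
    df: int


def _resel_counts(mask: np.ndarray, fwhm_vox: np.ndarray) -> np.ndarray:
    """Worsley box-counting resel counts R_0..R_3 of a 3D mask."""
    m = mask.astype(bool)
    P = int(m.sum())
    Ex = int((m[:-1] & m[1:]).sum())
    Ey = int((m[:, :-1] & m[:, 1:]).sum())
    Ez = int((m[:, :, :-1] & m[:, :, 1:]).sum())
    Fxy = int((m[:-1, :-1] & m[1:, :-1] & m[:-1, 1:] & m[1:, 1:]).sum())
    Fxz = int((m[:-1, :, :-1] & m[1:, :, :-1] & m[:-1, :, 1:] & m[1:, :, 1:]).sum())
    Fyz = int((m[:, :-1, :-1] & m[:, 1:, :-1] & m[:, :-1, 1:] & m[:, 1:, 1:]).sum())
    C = int((m[:-1, :-1, :-1] & m[1:, :-1, :-1] & m[:-1, 1:, :-1] & m[:-1, :-1, 1:]
             & m[1:, 1:, :-1] & m[1:, :-1, 1:] & m[:-1, 1:, 1:] & m[1:, 1:, 1:]).sum())
    rx, ry, rz = 1.0 / np.asarray(fwhm_vox, dtype=float)
    r0 = P - (Ex + Ey + Ez) + (Fxy + Fxz + Fyz) - C
    r1 = (Ex - Fxy - Fxz + C) * rx + (Ey - Fxy - Fyz + C) * ry + (Ez - Fxz - Fyz + C) * rz
    r2 = (Fxy - C) * rx * ry + (Fxz - C) * rx * rz + (Fyz - C) * ry * rz
    r3 = C * rx * ry * rz
    return np.array([r0, r1, r2, r3], dtype=float)


def estimate_smoothness(residuals: np.ndarray, mask: np.ndarray, df: int,
                        voxel_size_mm: float) -> SmoothnessEstimate:
    """Per-axis FWHM and resel counts from a 4D residual array (x, y, z, n).

    Residuals are variance-normalized per voxel; the variance of their
    spatial finite differences estimates the derivative variance
    ``lambda`` of the unit-variance field, giving
    ``FWHM = sqrt(4 ln 2 / lambda)`` per axis (the FWHM of the Gaussian
    kernel that would produce the observed smoothness from white noise).
    """
    if residuals.shape[-1] < 2:
        raise InputError("smoothness estimation needs at least 2 residual volumes")
    mask = mask.astype(bool)
    if not mask.any():
        raise InputError("empty search mask")
    r = np.asarray(residuals, dtype=float)
    ssq = np.sum(r ** 2, axis=-1)
    u = np.zeros_like(r)
    ok = (ssq > 0) & mask
    u[ok] = r[ok] / np.sqrt(ssq[ok])[:, None]

    lam = np.empty(3)
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        pair = ok[tuple(sl_lo)] & ok[tuple(sl_hi)]
        if not pair.any():
            raise InputError("mask too thin to estimate smoothness along an axis")
        d = u[tuple(sl_hi)] - u[tuple(sl_lo)]
        lam[ax] = float(np.mean(np.sum(d[pair] ** 2, axis=-1)))
    if np.any(lam <= 0):
        raise InputError("degenerate residuals: zero spatial derivative variance")
    fwhm_vox = np.sqrt(_4LN2 / lam)
    return SmoothnessEstimate(
        fwhm_mm=fwhm_vox * voxel_size_mm,
        fwhm_vox=fwhm_vox,
        resels=_resel_counts(mask, fwhm_vox),
        n_voxels=int(mask.sum()),
        voxel_size_mm=voxel_size_mm,
        df=df,
    )


# ---------------------------------------------------------------------------
# RFT cluster p-values
# ---------------------------------------------------------------------------

def _ec_densities(u: float) -> np.ndarray:
    """Euler characteristic densities rho_0..rho_3 of a unit Gaussian field."""
    e = np.exp(-u * u / 2.0)
    return np.array([
        special.ndtr(-u),
        np.sqrt(_4LN2) / (2.0 * np.pi) * e,
        _4LN2 / (2.0 * np.pi) ** 1.5 * u * e,
        _4LN2 ** 1.5 / (2.0 * np.pi) ** 2 * (u * u - 1.0) * e,
    ])


def expected_clusters(smoothness: SmoothnessEstimate, z_threshold: float) -> float:
    """Expected number of suprathreshold clusters (expected EC)."""
    return float(np.clip(smoothness.resels @ _ec_densities(z_threshold), 1e-12, None))


def rft_cluster_p(extent_voxels: int, smoothness: SmoothnessEstimate,
                  z_threshold: float) -> float:
    """Cluster-level FWE p for a cluster of ``extent_voxels`` voxels.

    ``p = 1 - exp(-E[m] * P(n >= k))`` where ``E[m]`` is the expected
    cluster count and ``P(n >= k) = exp(-beta k^(2/3))`` with
    ``beta = (Gamma(5/2) E[m] / E[N])^(2/3)``, ``E[N]`` the expected
    suprathreshold voxel count.
    """
    if z_threshold <= 0:
        raise InputError("z_threshold must be positive")
    if extent_voxels < 1:
        raise InputError("extent must be at least one voxel")
    if np.any(smoothness.fwhm_vox <= 0):
        raise InputError("nonpositive smoothness")
    em = expected_clusters(smoothness, z_threshold)
    en = smoothness.n_voxels * float(special.ndtr(-z_threshold))
    if en <= 0:
        return 0.0
    beta = (np.exp(gammaln(2.5)) * em / en) ** (2.0 / 3.0)
    p_extent = np.exp(-beta * float(extent_voxels) ** (2.0 / 3.0))
    return float(-np.expm1(-em * p_extent))


def rft_critical_extent(smoothness: SmoothnessEstimate, z_threshold: float,
                        alpha: float = 0.05, max_extent: int = 100000) -> int:
    """Smallest cluster extent (voxels) significant at FWE ``alpha``."""
    lo, hi = 1, max_extent
    if rft_cluster_p(hi, smoothness, z_threshold) > alpha:
        return max_extent
    while lo < hi:
        mid = (lo + hi) // 2
        if rft_cluster_p(mid, smoothness, z_threshold) <= alpha:
            hi = mid
        else:
            lo = mid + 1
    return lo


# ---------------------------------------------------------------------------
# thresholding and cluster extraction
# ---------------------------------------------------------------------------

@dataclass
class Peak:
    z: float
    voxel: tuple[int, int, int]
    mni_mm: tuple[float, float, float]


@dataclass
class Cluster:
    extent_voxels: int
    volume_ul: float
    peaks: list[Peak]
    voxels: np.ndarray              # boolean 3D membership
    p_fwe: float | None = None

    @property
    def peak(self) -> Peak:
        return self.peaks[0]


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise InputError(f"connectivity must be 6, 18, or 26, got {connectivity}")


def threshold_and_cluster(statmap: StatMap, p_voxel: float = 0.001,
                          connectivity: int = 26,
                          smoothness: SmoothnessEstimate | None = None,
                          negative: bool = False) -> list["Cluster"]:
    """Extract suprathreshold clusters from a Z map.

    The cluster-forming threshold is the standard-normal quantile of
    ``1 - p_voxel`` applied to the Z map (positive tail by default; set
    ``negative=True`` to test decreases).  Peaks are local maxima under
    26-connectivity, at most three per cluster, sorted by descending Z with
    lexicographic voxel order breaking ties.  Cluster volume is
    ``extent x voxel_volume`` in microliters.  When ``smoothness`` is
    given, each cluster carries its RFT FWE p-value.
    """
    if not 0.0 < p_voxel < 1.0:
        raise InputError("p_voxel must lie in (0, 1)")
    u = float(special.ndtri(1.0 - p_voxel))
    z = statmap.z3d(fill=0.0)
    if negative:
        z = -z
    z[~statmap.mask] = -np.inf
    above = z > u
    structure = _connectivity_structure(connectivity)
    labels, n_lab = ndimage.label(above, structure=structure)
    if n_lab == 0:
        return []

    voxel_mm = np.abs(np.linalg.det(statmap.affine[:3, :3]))
    footprint = np.ones((3, 3, 3), dtype=bool)
    zmax = ndimage.maximum_filter(np.where(above, z, -np.inf), footprint=footprint,
                                  mode="constant", cval=-np.inf)
    clusters = []
    for lab in range(1, n_lab + 1):
        member = labels == lab
        extent = int(member.sum())
        peak_mask = member & (z >= zmax)
        coords = np.argwhere(peak_mask)
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0],
                            -z[tuple(coords.T)]))
        peaks = []
        for i in order[:3]:
            vox = tuple(int(v) for v in coords[i])
            mm = statmap.affine @ np.array([*vox, 1.0])
            zv = float(z[vox])
            peaks.append(Peak(z=-zv if negative else zv, voxel=vox,
                              mni_mm=tuple(float(v) for v in mm[:3])))
        p = rft_cluster_p(extent, smoothness, u) if smoothness is not None else None
        clusters.append(Cluster(extent_voxels=extent, volume_ul=extent * voxel_mm,
                                peaks=peaks, voxels=member, p_fwe=p))
    clusters.sort(key=lambda c: -c.extent_voxels)
    return clusters


@dataclass
class ClusterTable:
    """Reporting table for one contrast, mirroring cluster-report conventions."""

    contrast: str
    p_voxel: float
    fwe_alpha: float
    clusters: list[Cluster] = field(default_factory=list)
    marginal_limit: float = 0.1

    COLUMNS = ("cluster", "peak", "z", "x_mm", "y_mm", "z_mm",
               "volume_ul", "extent_voxels", "p_fwe", "marginal")

    def to_frame(self):
        import pandas as pd
        rows = []
        for ci, c in enumerate(self.clusters, start=1):
            for pi, pk in enumerate(c.peaks, start=1):
                rows.append({
                    "cluster": ci,
                    "peak": pi,
                    "z": pk.z,
                    "x_mm": pk.mni_mm[0], "y_mm": pk.mni_mm[1], "z_mm": pk.mni_mm[2],
                    "volume_ul": c.volume_ul if pi == 1 else np.nan,
                    "extent_voxels": c.extent_voxels if pi == 1 else np.nan,
                    "p_fwe": c.p_fwe if pi == 1 else np.nan,
                    "marginal": (c.p_fwe is not None and
                                 self.fwe_alpha <= c.p_fwe < self.marginal_limit)
                                if pi == 1 else False,
                })
        return pd.DataFrame(rows, columns=list(self.COLUMNS))


def cluster_table(statmap: StatMap, smoothness: SmoothnessEstimate,
                  p_voxel: float = 0.001, fwe_alpha: float = 0.05,
                  connectivity: int = 26, negative: bool = False,
                  marginal_limit: float = 0.1) -> ClusterTable:
    """Threshold, cluster, and keep clusters passing FWE or flagged marginal.

    A cluster with ``fwe_alpha <= p < marginal_limit`` is retained with a
    marginal flag rather than dropped, so near-threshold findings remain
    visible in reports.
    """
    all_clusters = threshold_and_cluster(statmap, p_voxel=p_voxel,
                                         connectivity=connectivity,
                                         smoothness=smoothness, negative=negative)
    kept = [c for c in all_clusters if c.p_fwe is not None and c.p_fwe < marginal_limit]
    return ClusterTable(contrast=statmap.label, p_voxel=p_voxel,
                        fwe_alpha=fwe_alpha, clusters=kept,
                        marginal_limit=marginal_limit)


# ---------------------------------------------------------------------------
# permutation oracle
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    null_max_extents: np.ndarray
    p_values: np.ndarray
    n_permutations: int
    low_precision: bool          # flagged when n_permutations < 100

    def critical_extent(self, alpha: float = 0.05) -> float:
        return float(np.quantile(self.null_max_extents, 1.0 - alpha))


def permutation_cluster_p(maps: np.ndarray, mask: np.ndarray,
                          observed_extents, *, covariate=None,
                          n_permutations: int = 999, seed=None,
                          p_voxel: float = 0.001,
                          connectivity: int = 26) -> PermutationResult:
    """Max-cluster-extent permutation null for FWE p-values.

    ``maps`` is (n_subjects, n_mask_voxels).  With ``covariate=None`` the
    exchangeability scheme is sign-flipping of the subject maps (suitable
    for paired/one-sample contrasts on difference maps); with a covariate
    it is random reassignment (shuffling) of covariate values to subjects.
    ``p = (1 + #{null max-extent >= observed}) / (1 + n_permutations)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    u = float(special.ndtri(1.0 - p_voxel))
    structure = _connectivity_structure(connectivity)
    shape = mask.shape

    null_max = np.empty(n_permutations)
    if covariate is None:
        df = n - 1
        ssq = (maps ** 2).sum(axis=0)
        for i in range(n_permutations):
            signs = rng.choice([-1.0, 1.0], size=n)
            mean = (signs @ maps) / n
            var = (ssq - n * mean ** 2) / (n - 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(var > 0, mean / np.sqrt(var / n), 0.0)
            null_max[i] = _max_extent(t_to_z(t, df), mask, u, structure, shape)
    else:
        x = np.asarray(covariate, dtype=float)
        df = n - 2
        yc = maps - maps.mean(axis=0)
        ynorm = np.sqrt((yc ** 2).sum(axis=0))
        for i in range(n_permutations):
            xp = rng.permutation(x)
            xc = xp - xp.mean()
            xnorm = np.linalg.norm(xc)
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(ynorm > 0, (xc @ yc) / (xnorm * ynorm), 0.0)
                r = np.clip(r, -0.999999999, 0.999999999)
                t = r * np.sqrt(df / (1.0 - r ** 2))
            null_max[i] = _max_extent(t_to_z(t, df), mask, u, structure, shape)

    observed = np.atleast_1d(np.asarray(observed_extents, dtype=float))
    p = (1.0 + (null_max[None, :] >= observed[:, None]).sum(axis=1)) / (1.0 + n_permutations)
    return PermutationResult(null_max_extents=null_max, p_values=p,
                             n_permutations=n_permutations,
                             low_precision=n_permutations < 100)


def _max_extent(z_flat, mask, u, structure, shape) -> int:
    vol = np.zeros(shape, dtype=bool)
    vol[mask] = z_flat > u
    if not vol.any():
        return 0
    labels, n_lab = ndimage.label(vol, structure=structure)
    return int(np.bincount(labels.ravel())[1:].max())
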