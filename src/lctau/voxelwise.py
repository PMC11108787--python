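"""Mass-univariate regression of outcome maps with cluster-extent correction.

Implements the forward/reverse voxel-wise models, nuisance residualization,
the LC-by-amyloid interaction model, a Monte-Carlo cluster-extent threshold
(white-noise null smoothed at a configured FWHM; smoothness is taken from
config rather than estimated from residuals), cluster extraction at
26-connectivity, and the directional coefficient-distribution comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .core_io import BrainVolume
from .exceptions import (
    DegenerateClusterError,
    InsufficientDataError,
    SingularDesignError,
)

__all__ = [
    "VoxelModelResult",
    "ClusterSet",
    "DirectionalComparison",
    "fit_voxelwise",
    "residualize_against",
    "fit_interaction",
    "mc_cluster_threshold",
    "extract_clusters",
    "compare_directions",
    "partial_r_map",
]

_CDF_EPS = 1e-15
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VoxelModelResult:
    """Per-voxel OLS maps for one predictor of interest."""

    beta_map: BrainVolume
    t_map: BrainVolume
    z_map: BrainVolume
    df: int
    n_used: int
    model_spec: str
    mask: BrainVolume

    def partial_r(self) -> np.ndarray:
        """Partial correlation of the predictor, from t and df, in-mask."""
        return partial_r_map(self.t_map.data, self.df, self.mask)


@dataclass
class ClusterSet:
    label_map: BrainVolume
    sizes: list[int]
    voxel_z_threshold: float
    extent_threshold: int
    alpha: float = 0.05

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def cluster_mask(self, label: int) -> np.ndarray:
        return self.label_map.data == label


@dataclass
class DirectionalComparison:
    cluster_label: int
    n_voxels: int
    coeffs_forward: np.ndarray
    coeffs_reverse: np.ndarray
    mean_difference: float
    t_stat: float
    df: int
    p_value: float
    ci_low: float
    ci_high: float
    pearson_r: float


def _stack_outcomes(outcome_maps, mask_bool: np.ndarray) -> np.ndarray:
    """(n_subjects, n_mask_voxels) matrix from volumes or arrays."""
    rows = []
    for vol in outcome_maps:
        data = vol.data if isinstance(vol, BrainVolume) else np.asarray(vol)
        rows.append(data[mask_bool])
    return np.asarray(rows, dtype=float)


def _build_design(columns: list[np.ndarray], names: list[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(columns[0]))] + columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = []
        for j in range(1, X.shape[1]):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                bad.append(names[j - 1])
        raise SingularDesignError(
            f"rank-deficient design (rank {rank} < {X.shape[1]})",
            collinear_columns=bad,
        )
    return X

def _mass_ols(Y: np.ndarray, X: np.ndarray, j: int):
    """OLS of every column of Y on X; return beta_j, t_j, z_j, df."""
    n, p = X.shape
    df = n - p
    if df < 1:
        raise InsufficientDataError(f"n={n} too small for {p} parameters")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y                      # (p, n_vox)
    resid = Y - X @ B
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[j, j], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B[j] / se, np.inf * np.sign(B[j]))
    t = np.where(np.isnan(t), 0.0, t)
    cdf = np.clip(stats.t.cdf(t, df), _CDF_EPS, 1 - _CDF_EPS)
    z = stats.norm.ppf(cdf)
    return B[j], t, z, df


def _complete_cases(*arrays: np.ndarray) -> np.ndarray:
    ok = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        a = np.asarray(a, dtype=float)
        ok &= np.isfinite(a) if a.ndim == 1 else np.isfinite(a).all(axis=1)
    return ok


def _as_cov_matrix(covariates) -> tuple[np.ndarray | None, list[str]]:
    if covariates is None:
        return None, []
    try:  # DataFrame
        names = list(covariates.columns)
        return covariates.to_numpy(dtype=float), names
    except AttributeError:
        arr = np.asarray(covariates, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        return arr, [f"cov{i}" for i in range(arr.shape[1])]


def fit_voxelwise(outcome_maps, predictor, covariates=None,
                  mask: BrainVolume | None = None) -> VoxelModelResult:
    """Per-voxel OLS of the outcome on [1, predictor, covariates].

    Subjects with a missing predictor or covariate are dropped (complete
    cases per model); the t-map is for the predictor and the z-map is the
    normal quantile of its t CDF with clamping at 1e-15.
    """
    template = outcome_maps[0]
    if not isinstance(template, BrainVolume):
        raise TypeError("outcome_maps must be BrainVolume instances")
    if mask is None:
        mask = template.with_data(np.ones(template.shape))
    template.check_compatible(mask)
    mask_bool = mask.require_mask()

    predictor = np.asarray(predictor, dtype=float)
    cov, cov_names = _as_cov_matrix(covariates)
    keep = (_complete_cases(predictor) if cov is None
            else _complete_cases(predictor, cov))
    Y = _stack_outcomes(outcome_maps, mask_bool)[keep]
    names = ["predictor"] + cov_names
    X = _build_design([predictor[keep]] if cov is None
                      else [predictor[keep], cov[keep]], names)
    beta, t, z, df = _mass_ols(Y, X, j=1)

    def _vol(values: np.ndarray) -> BrainVolume:
        out = np.zeros(template.shape)
        out[mask_bool] = values
        return template.with_data(out)

    return VoxelModelResult(
        beta_map=_vol(beta), t_map=_vol(t), z_map=_vol(z),
        df=df, n_used=int(keep.sum()),
        model_spec="outcome ~ 1 + predictor"
                   + "".join(f" + {c}" for c in cov_names),
        mask=mask,
    )


def residualize_against(outcome_maps, nuisance) -> list[BrainVolume]:
    """Per-voxel residuals of the outcome on [1, nuisance].

    Residuals are orthogonal to the nuisance regressor at every voxel.
    """
    template = outcome_maps[0]
    mask_bool = np.ones(template.shape, dtype=bool)
    Y = _stack_outcomes(outcome_maps, mask_bool)
    nuisance = np.asarray(nuisance, dtype=float)
    X = np.column_stack([np.ones(len(nuisance)), nuisance])
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ B
    out = []
    for i in range(R.shape[0]):
        vol = np.zeros(template.shape)
        vol[mask_bool] = R[i]
        out.append(template.with_data(vol))
    return out


def fit_interaction(outcome_maps, predictor, moderator, covariates=None,
                    mask: BrainVolume | None = None) -> VoxelModelResult:
    """Interaction model; the returned maps are for the product term.

    Predictor and moderator are mean-centered (over complete cases) before
    the product is formed, so their main effects stay interpretable.
    """
    template = outcome_maps[0]
    if mask is None:
        mask = template.with_data(np.ones(template.shape))
    mask_bool = mask.require_mask()

    predictor = np.asarray(predictor, dtype=float)
    moderator = np.asarray(moderator, dtype=float)
    cov, cov_names = _as_cov_matrix(covariates)
    keep = (_complete_cases(predictor, moderator) if cov is None
            else _complete_cases(predictor, moderator, cov))
    x = predictor[keep] - predictor[keep].mean()
    m = moderator[keep] - moderator[keep].mean()
    cols = [x, m, x * m]
    names = ["predictor", "moderator", "predictor:moderator"]
    if cov is not None:
        cols.append(cov[keep])
        names += cov_names
    X = _build_design(cols, names)
    Y = _stack_outcomes(outcome_maps, mask_bool)[keep]
    beta, t, z, df = _mass_ols(Y, X, j=3)

    def _vol(values: np.ndarray) -> BrainVolume:
        out = np.zeros(template.shape)
        out[mask_bool] = values
        return template.with_data(out)

    return VoxelModelResult(
        beta_map=_vol(beta), t_map=_vol(t), z_map=_vol(z),
        df=df, n_used=int(keep.sum()),
        model_spec="outcome ~ 1 + x + m + x:m"
                   + "".join(f" + {c}" for c in cov_names),
        mask=mask,
    )


def _fwhm_to_sigma_vox(fwhm_mm: float, voxel_size: tuple) -> np.ndarray:
    factor = 2.0 * np.sqrt(2.0 * np.log(2.0))
    return np.asarray([fwhm_mm / factor / v for v in voxel_size])


def mc_cluster_threshold(mask: BrainVolume, smoothing_fwhm_mm: float = 8.0,
                         voxel_z_threshold: float = 1.64,
                         alpha: float = 0.05, n_iter: int = 10_000,
                         seed: int | np.random.Generator = 0,
                         return_distribution: bool = False):
    """Cluster-extent threshold from a smoothed white-noise Monte-Carlo null.

    Each iteration draws white Gaussian noise on the mask's bounding grid,
    smooths it at the stated FWHM, re-standardizes within the mask,
    thresholds at ``voxel_z_threshold`` and records the maximum
    26-connected cluster size. The returned extent is one more than the
    ``ceil((1-alpha) * n_iter)``-th order statistic of those maxima.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    mask_bool = mask.require_mask()
    voxel_size = mask.voxel_size_mm
    smooth = smoothing_fwhm_mm > 0
    if smooth and smoothing_fwhm_mm < min(voxel_size):
        warnings.warn(
            f"FWHM {smoothing_fwhm_mm} mm < voxel size {min(voxel_size)} mm;"
            " smoothing skipped",
            UserWarning,
        )
        smooth = False
    sigma = _fwhm_to_sigma_vox(smoothing_fwhm_mm, voxel_size)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    max_sizes = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        noise = rng.standard_normal(mask.shape)
        if smooth:
            noise = ndimage.gaussian_filter(noise, sigma=sigma)
        vals = noise[mask_bool]
        sd = vals.std()
        z = np.zeros(mask.shape)
        z[mask_bool] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        supra = (z > voxel_z_threshold) & mask_bool
        if supra.any():
            labels, n_lab = ndimage.label(supra, structure=_STRUCT_26)
            if n_lab:
                counts = np.bincount(labels[supra])
                max_sizes[it] = int(counts.max())
    order = np.sort(max_sizes)
    k = int(np.ceil((1.0 - alpha) * n_iter))
    extent = int(order[k - 1]) + 1
    if return_distribution:
        return extent, max_sizes
    return extent


def extract_clusters(z_map: BrainVolume, mask: BrainVolume,
                     voxel_z_threshold: float,
                     extent_threshold: int,
                     alpha: float = 0.05) -> ClusterSet:
    """26-connected components of {z > threshold}, small ones dropped.

    Surviving clusters are relabeled 1..k in descending size order.
    """
    z_map.check_compatible(mask)
    mask_bool = mask.require_mask()
    supra = (z_map.data > voxel_z_threshold) & mask_bool
    labels, n_lab = ndimage.label(supra, structure=_STRUCT_26)
    out = np.zeros(z_map.shape, dtype=int)
    sizes: list[int] = []
    if n_lab:
        counts = np.bincount(labels.ravel())[1:]
        keep = [(int(c), lab + 1) for lab, c in enumerate(counts)
                if c >= extent_threshold]
        keep.sort(key=lambda sc: (-sc[0], sc[1]))
        for new_lab, (size, old_lab) in enumerate(keep, start=1):
            out[labels == old_lab] = new_lab
            sizes.append(size)
    return ClusterSet(
        label_map=z_map.with_data(out), sizes=sizes,
        voxel_z_threshold=voxel_z_threshold,
        extent_threshold=int(extent_threshold), alpha=alpha,
    )


def partial_r_map(t_map_data: np.ndarray, df: int,
                  mask: BrainVolume) -> np.ndarray:
    """Partial correlation r = t / sqrt(t^2 + df) over in-mask voxels."""
    mask_bool = mask.require_mask()
    t = t_map_data[mask_bool]
    return t / np.sqrt(t * t + df)


def compare_directions(forward: VoxelModelResult,
                       reverse: VoxelModelResult,
                       clusters: ClusterSet,
                       alpha: float = 0.05) -> list[DirectionalComparison]:
    """Paired comparison of forward vs reverse partial correlations.

    Voxels are the forward-analysis surviving-cluster voxels; the
    coefficient compared is the predictor's partial correlation derived
    from each direction's t-map (unitless, hence comparable across models
    with differently scaled outcomes).
    """
    forward.z_map.check_compatible(reverse.z_map)
    if clusters.n_clusters == 0:
        raise DegenerateClusterError("cluster set is empty")
    results = []
    for label, size in enumerate(clusters.sizes, start=1):
        vox = clusters.cluster_mask(label)
        if size < 2:
            raise DegenerateClusterError(
                f"cluster {label} has {size} voxel(s); paired t undefined"
            )
        t_f = forward.t_map.data[vox]
        t_r = reverse.t_map.data[vox]
        r_f = t_f / np.sqrt(t_f * t_f + forward.df)
        r_r = t_r / np.sqrt(t_r * t_r + reverse.df)
        diff = r_f - r_r
        n = diff.size
        mean_diff = float(diff.mean())
        se = float(diff.std(ddof=1) / np.sqrt(n))
        if se > 0:
            t_stat = mean_diff / se
            p = float(2 * stats.t.sf(abs(t_stat), n - 1))
            half = stats.t.ppf(1 - alpha / 2, n - 1) * se
        else:
            t_stat = 0.0 if mean_diff == 0 else np.inf * np.sign(mean_diff)
            p = 1.0 if mean_diff == 0 else 0.0
            half = 0.0
        if np.std(r_f) > 0 and np.std(r_r) > 0:
            pear = float(np.corrcoef(r_f, r_r)[0, 1])
        else:
            pear = np.nan
        results.append(DirectionalComparison(
            cluster_label=label, n_voxels=n,
            coeffs_forward=r_f, coeffs_reverse=r_r,
            mean_difference=mean_diff, t_stat=float(t_stat), df=n - 1,
            p_value=p, ci_low=float(mean_diff - half),
            ci_high=float(mean_diff + half), pearson_r=pear,
        ))
    return results
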