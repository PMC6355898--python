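"""Voxelwise GLM fitting and group-level analyses.

Ordinary least squares per voxel, t contrasts, one-sample second-level
tests with centred covariates, probabilistic-atlas ROI construction and
summarization, quintile (binned-parameter) effect estimates, a
repeated-measures 2x2 ANCOVA for the hemisphere-by-region ROI designs,
and Monte-Carlo cluster-extent thresholding of smoothed null fields.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .design import DesignMatrix

__all__ = [
    "BoldDataset",
    "GlmFit",
    "ContrastResult",
    "RoiDefinition",
    "ClusterThreshold",
    "fit_glm",
    "contrast",
    "second_level",
    "mean_displacement",
    "cluster_threshold_montecarlo",
    "roi_build",
    "roi_effect",
    "quintile_effects",
    "anova_2x2",
]

logger = logging.getLogger(__name__)


@dataclass
class BoldDataset:
    """A 4-D functional image with brain mask and repetition time."""

    data: np.ndarray  # (x, y, z, volume)
    affine: np.ndarray  # 4x4 voxel-to-mm
    mask: np.ndarray  # boolean (x, y, z)
    tr: float

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, volume)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask grid must match image grid")
        self.mask = self.mask.astype(bool)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def masked_series(self) -> np.ndarray:
        """Time-by-voxel matrix of the in-mask series."""
        return self.data[self.mask].T


@dataclass
class GlmFit:
    betas: np.ndarray  # regressors x voxels
    residual_variance: np.ndarray  # voxels
    df: int
    design: DesignMatrix
    mask: np.ndarray
    xtx_inv: np.ndarray  # (X'X)^+ for contrast standard errors


@dataclass
class ContrastResult:
    effect: np.ndarray  # voxels
    t: np.ndarray
    weights: np.ndarray
    df: int


@dataclass
class RoiDefinition:
    name: str
    mask: np.ndarray  # boolean voxel mask
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = self.mask.astype(bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.name!r} is empty")


@dataclass
class ClusterThreshold:
    voxel_p: float
    smoothness_fwhm: float
    n_simulations: int
    min_cluster_size: int
    max_cluster_sizes: np.ndarray  # null distribution of largest clusters


def fit_glm(data: BoldDataset, design: DesignMatrix) -> GlmFit:
    """Ordinary least squares at every in-mask voxel.

    A rank-deficient design is fitted with the pseudo-inverse after a
    warning naming the dependent columns; degrees of freedom use the
    design's rank, not its column count.
    """
    X = design.matrix.to_numpy(dtype=float)
    if X.shape[0] != data.n_volumes:
        raise ValueError("design rows must equal the number of volumes")
    Y = data.masked_series()
    if not np.isfinite(Y).all():
        raise ValueError("masked voxels contain non-finite values")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        dep = [design.names[j] for j in range(X.shape[1])
               if abs(R[j, j]) < 1e-10 * abs(R).max()]
        warnings.warn(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"dependent columns: {dep}; using pseudo-inverse",
            stacklevel=2,
        )
    pinv = np.linalg.pinv(X)
    betas = pinv @ Y
    resid = Y - X @ betas
    df = data.n_volumes - rank
    resvar = (resid ** 2).sum(axis=0) / df
    return GlmFit(
        betas=betas,
        residual_variance=resvar,
        df=df,
        design=design,
        mask=data.mask,
        xtx_inv=pinv @ pinv.T,
    )


def contrast(fit: GlmFit, weights: np.ndarray) -> ContrastResult:
    """Effect w'beta and its t statistic with the fit's df."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (fit.betas.shape[0],):
        raise ValueError(
            f"weights length {w.shape} != n regressors {fit.betas.shape[0]}"
        )
    effect = w @ fit.betas
    var = fit.residual_variance * float(w @ fit.xtx_inv @ w)
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, np.where(effect == 0, 0.0, np.inf)
                     * np.sign(effect + (effect == 0)))
    return ContrastResult(effect=effect, t=t, weights=w, df=fit.df)


def second_level(
    maps: np.ndarray, covariates: pd.DataFrame | None = None
) -> dict[str, ContrastResult]:
    """One-sample t-test per voxel, optionally with centred covariates.

    ``maps`` is participants x voxels. Returns the intercept test under
    ``"intercept"`` plus one slope test per covariate. Voxels with zero
    residual variance get t = +/-inf (flagged, not NaN).
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    n = maps.shape[0]
    if n < 3:
        raise ValueError("second-level analysis needs >= 3 participants")
    X = np.ones((n, 1))
    names = ["intercept"]
    if covariates is not None and len(covariates.columns):
        C = covariates.to_numpy(dtype=float)
        if C.shape[0] != n:
            raise ValueError("one covariate row per participant required")
        C = C - C.mean(axis=0)
        X = np.column_stack([X, C])
        names += list(covariates.columns)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariates are collinear")
    pinv = np.linalg.pinv(X)
    betas = pinv @ maps
    resid = maps - X @ betas
    df = n - X.shape[1]
    resvar = (resid ** 2).sum(axis=0) / df
    xtx_inv = pinv @ pinv.T
    out = {}
    for j, name in enumerate(names):
        se = np.sqrt(resvar * xtx_inv[j, j])
        # zero residual variance (up to round-off) flags t as +/-inf
        degenerate = se <= 1e-10 * np.maximum(np.abs(betas[j]), 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(degenerate, np.sign(betas[j]) * np.inf,
                         betas[j] / np.where(se > 0, se, 1.0))
            t = np.where(degenerate & (betas[j] == 0), 0.0, t)
        w = np.zeros(X.shape[1])
        w[j] = 1.0
        out[name] = ContrastResult(effect=betas[j], t=t, weights=w, df=df)
    return out


def mean_displacement(motion_params: np.ndarray | pd.DataFrame) -> float:
    """Mean scan-to-scan displacement over the six motion parameters.

    For each parameter, the mean absolute change between successive
    volumes is computed; the six means are averaged.
    """
    M = np.asarray(motion_params, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a volumes x parameters table with >= 2 volumes")
    return float(np.mean(np.abs(np.diff(M, axis=0))))


def _fwhm_to_sigma(fwhm: float, voxel_size: float) -> float:
    return fwhm / voxel_size / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def cluster_threshold_montecarlo(
    mask: np.ndarray,
    smoothness_fwhm: float,
    voxel_p: float = 0.005,
    n_sim: int = 5000,
    seed: int | np.random.Generator = 0,
    voxel_size: float = 2.0,
    two_tailed: bool = False,
    connectivity: int = 26,
) -> ClusterThreshold:
    """Minimum cluster extent controlling family-wise error at p < .05.

    Each simulation draws Gaussian white noise on the mask grid,
    smooths it to the requested FWHM, standardizes it over the mask,
    thresholds at the one-tailed (default) voxel p, and records the
    largest suprathreshold cluster under 26-neighbour connectivity.
    The reported minimum size is the smallest extent k such that the
    proportion of null fields containing a cluster of at least k voxels
    is <= 0.05 (the 95th percentile of the max-cluster distribution,
    plus one).
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if smoothness_fwhm < voxel_size:
        raise ValueError("smoothness must be at least one voxel")
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives an unstable percentile", stacklevel=2)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sigma = _fwhm_to_sigma(smoothness_fwhm, voxel_size)
    zthr = stats.norm.isf(voxel_p / 2 if two_tailed else voxel_p)
    structure = (np.ones((3, 3, 3)) if connectivity == 26
                 else ndimage.generate_binary_structure(3, 1))
    max_sizes = np.zeros(n_sim, dtype=int)
    for s in range(n_sim):
        field_ = rng.standard_normal(mask.shape)
        if sigma > 1e-12:
            field_ = ndimage.gaussian_filter(field_, sigma)
        vals = field_[mask]
        z = (field_ - vals.mean()) / vals.std()
        supra = np.zeros(mask.shape, dtype=bool)
        supra[mask] = (np.abs(z[mask]) if two_tailed else z[mask]) > zthr
        if supra.any():
            labels, n_lab = ndimage.label(supra, structure=structure)
            if n_lab:
                max_sizes[s] = int(np.bincount(labels.ravel())[1:].max())
    # smallest k with P(max >= k) <= 0.05
    k = int(np.quantile(max_sizes, 0.95, method="higher")) + 1
    while k > 1 and np.mean(max_sizes >= k - 1) <= 0.05:
        k -= 1
    return ClusterThreshold(
        voxel_p=voxel_p,
        smoothness_fwhm=smoothness_fwhm,
        n_simulations=n_sim,
        min_cluster_size=max(k, 1),
        max_cluster_sizes=max_sizes,
    )


def roi_build(
    prob_atlas: np.ndarray,
    affine: np.ndarray,
    threshold: float = 0.30,
    medial_cut_mm: float | None = 30.0,
    name: str = "custom",
) -> RoiDefinition:
    """Threshold a probabilistic region image into an ROI mask.

    Voxels with probability strictly greater than ``threshold`` are
    kept; with a medial cut, voxels whose world-space |x| is below
    ``medial_cut_mm`` are removed (the pars orbitalis mask extends into
    medial prefrontal territory unrelated to language).
    """
    keep = prob_atlas > threshold
    if medial_cut_mm is not None:
        ii, jj, kk = np.indices(prob_atlas.shape)
        vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
        x_mm = (vox @ affine.T)[..., 0]
        keep &= np.abs(x_mm) >= medial_cut_mm
    return RoiDefinition(
        name=name,
        mask=keep,
        provenance={
            "threshold": threshold,
            "strict": True,
            "medial_cut_mm": medial_cut_mm,
        },
    )


def roi_effect(map_values: np.ndarray, roi: RoiDefinition,
               data_mask: np.ndarray | None = None) -> float:
    """Unweighted mean of a statistic map over the ROI voxels.

    ``map_values`` is either a full 3-D image or a flat in-mask vector
    accompanied by ``data_mask``.
    """
    if map_values.ndim == 1:
        if data_mask is None:
            raise ValueError("flat map needs data_mask")
        img = np.full(data_mask.shape, np.nan)
        img[data_mask.astype(bool)] = map_values
    else:
        img = map_values
    if img.shape != roi.mask.shape:
        raise ValueError("ROI grid does not match map grid")
    vals = img[roi.mask]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("ROI contains no defined voxels")
    return float(vals.mean())


def quintile_effects(
    param_values: np.ndarray,
    block_regressors: np.ndarray,
    data: np.ndarray,
    nuisance: np.ndarray | None = None,
    n_bins: int = 5,
) -> pd.DataFrame:
    """Effect estimates at binned levels of a block-level parameter.

    Blocks are ranked by the parameter (ties broken by stable block
    order) and split into ``n_bins`` near-equal sets, least to most.
    One regressor per bin (the sum of that bin's single-block
    regressors) is fitted jointly with any nuisance columns and an
    intercept; bin effects are reported relative to the overall
    speech-related activation (the count-weighted mean of the bin
    betas), so the weighted relative effects sum to zero.
    """
    v = np.asarray(param_values, dtype=float)
    n_blocks = len(v)
    if n_blocks < n_bins:
        raise ValueError(f"need >= {n_bins} blocks, got {n_blocks}")
    if block_regressors.shape[1] != n_blocks:
        raise ValueError("one regressor column per block required")
    order = np.argsort(v, kind="stable")
    edges = np.linspace(0, n_blocks, n_bins + 1).round().astype(int)
    bin_of = np.empty(n_blocks, dtype=int)
    for b in range(n_bins):
        bin_of[order[edges[b]:edges[b + 1]]] = b
    counts = np.bincount(bin_of, minlength=n_bins)
    Xbins = np.column_stack(
        [block_regressors[:, bin_of == b].sum(axis=1) for b in range(n_bins)]
    )
    X = [Xbins]
    if nuisance is not None:
        X.append(np.atleast_2d(np.asarray(nuisance, dtype=float).T).T)
    X.append(np.ones((block_regressors.shape[0], 1)))
    X = np.column_stack(X)
    y = np.asarray(data, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    betas = np.linalg.pinv(X) @ y
    bin_betas = betas[:n_bins].mean(axis=1)
    overall = np.average(bin_betas, weights=counts)
    return pd.DataFrame({
        "bin": np.arange(1, n_bins + 1),
        "n_blocks": counts,
        "effect": bin_betas,
        "relative_effect": bin_betas - overall,
    })


def anova_2x2(
    roi_effects: pd.DataFrame,
    covariate: np.ndarray | pd.Series | None = None,
    factor_a: str = "hemisphere",
    factor_b: str = "region",
) -> pd.DataFrame:
    """Repeated-measures 2x2 ANCOVA on per-participant ROI effects.

    ``roi_effects`` is long-format with columns ``participant``,
    ``factor_a``, ``factor_b`` and ``value``; every participant must
    contribute all four cells. Each within-participant effect (two main
    effects and the interaction) is a contrast across the four cells;
    it is tested by regressing the per-participant contrast scores on
    an intercept plus the centred between-participant covariate, giving
    F(1, n-2) with the covariate (or F(1, n-1) without).
    """
    needed = {"participant", factor_a, factor_b, "value"}
    if not needed.issubset(roi_effects.columns):
        raise ValueError(f"roi_effects needs columns {sorted(needed)}")
    wide = roi_effects.pivot_table(
        index="participant", columns=[factor_a, factor_b], values="value"
    )
    if wide.isna().any().any() or wide.shape[1] != 4:
        raise ValueError("each participant must have all four cells")
    wide = wide.sort_index(axis=1)
    (a1, b1), (_, b2) = wide.columns[0], wide.columns[1]
    a_levels = wide.columns.get_level_values(0)
    b_levels = wide.columns.get_level_values(1)
    ca = np.where(a_levels == a1, 1.0, -1.0) / 2.0
    cb = np.where(b_levels == b1, 1.0, -1.0) / 2.0
    contrasts = {
        factor_a: ca,
        factor_b: cb,
        f"{factor_a}:{factor_b}": ca * cb * 2.0,
    }
    n = wide.shape[0]
    X = np.ones((n, 1))
    if covariate is not None:
        c = np.asarray(covariate, dtype=float)
        if len(c) != n:
            raise ValueError("one covariate value per participant required")
        X = np.column_stack([X, c - c.mean()])
    df2 = n - X.shape[1]
    rows = []
    pinv = np.linalg.pinv(X)
    xtx_inv = pinv @ pinv.T
    for name, w in contrasts.items():
        y = wide.to_numpy() @ w
        beta = pinv @ y
        resid = y - X @ beta
        mse = float(resid @ resid) / df2
        se2 = mse * xtx_inv[0, 0]
        if se2 <= 1e-20 * max(beta[0] ** 2, 1e-300):
            F = 0.0 if abs(beta[0]) <= 1e-12 * np.abs(y).max() else np.inf
        else:
            F = float(beta[0] ** 2 / se2)
        p = float(stats.f.sf(F, 1, df2)) if np.isfinite(F) else 0.0
        rows.append({"effect": name, "F": F, "df1": 1, "df2": df2, "p": p})
    return pd.DataFrame(rows)
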