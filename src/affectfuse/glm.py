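"""Mass-univariate BOLD general linear model, from first principles.

Implements the canonical double-gamma haemodynamic response function,
causal regressor convolution, design-matrix construction with Legendre
drift, voxelwise ordinary least squares, extra-sum-of-squares F-contrasts,
family-wise error control (Bonferroni or Freedman-Lane max-statistic
permutation), the exclusion contrast C = A \\ B that separates
affect-related from reporting-related voxels, and cluster/local-maxima
tables of significant regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "HrfModel",
    "DesignMatrix",
    "GlmFit",
    "StatMap",
    "canonical_hrf",
    "convolve_regressor",
    "build_design",
    "fit_glm",
    "f_contrast",
    "fwe_threshold",
    "exclusion_contrast",
    "local_maxima_table",
]


@dataclass(frozen=True)
class HrfModel:
    """Canonical double-gamma HRF parameters (SPM-style defaults).

    The kernel is gamma_pdf(t; peak) - gamma_pdf(t; undershoot)/ratio,
    with gamma shape = delay/dispersion, peak-normalised to 1.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 6.0
    kernel_length: float = 32.0

    def __post_init__(self) -> None:
        for name in (
            "peak_delay",
            "undershoot_delay",
            "peak_dispersion",
            "undershoot_dispersion",
            "undershoot_ratio",
            "kernel_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"HRF parameter {name} must be positive")


def canonical_hrf(dt: float, model: HrfModel | None = None) -> np.ndarray:
    """Sample the canonical double-gamma HRF at spacing ``dt`` seconds."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    model = model or HrfModel()
    t = np.arange(0.0, model.kernel_length + dt / 2, dt)
    peak = stats.gamma.pdf(
        t, a=model.peak_delay / model.peak_dispersion, scale=model.peak_dispersion
    )
    under = stats.gamma.pdf(
        t,
        a=model.undershoot_delay / model.undershoot_dispersion,
        scale=model.undershoot_dispersion,
    )
    kernel = peak - under / model.undershoot_ratio
    peak_amp = kernel.max()
    if peak_amp <= 0:
        raise ValueError("HRF kernel has non-positive peak; check parameters")
    return kernel / peak_amp


def convolve_regressor(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal linear convolution truncated to the length of ``x``."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot convolve an empty regressor")
    if not np.all(np.isfinite(x)):
        raise ValueError("regressor contains non-finite values")
    return np.convolve(x, np.asarray(kernel, dtype=float))[: x.size]


@dataclass
class DesignMatrix:
    """Named design columns at the TR grid; effect columns come first."""

    matrix: np.ndarray
    names: list[str]
    effect_indices: list[int]

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("one name per design column required")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def contrast_for_effects(self) -> np.ndarray:
        """F-contrast rows selecting every effect-of-interest column."""
        c = np.zeros((len(self.effect_indices), self.n_columns))
        for row, idx in enumerate(self.effect_indices):
            c[row, idx] = 1.0
        return c


def _legendre_drift(n_volumes: int, order: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n_volumes)
    return np.stack(
        [np.polynomial.legendre.Legendre.basis(k)(x) for k in range(1, order + 1)],
        axis=1,
    ) if order >= 1 else np.zeros((n_volumes, 0))


def build_design(
    regressors: dict[str, np.ndarray],
    confounds: dict[str, np.ndarray] | None,
    n_volumes: int,
    drift_order: int = 3,
    hrf_kernel: np.ndarray | None = None,
    tr: float | None = None,
) -> DesignMatrix:
    """Assemble the GLM design matrix.

    Effects of interest are HRF-convolved (kernel built at TR if not
    given) and standardised to zero mean / unit SD for conditioning.
    Confounds are included as passed (only demeaned), so callers control
    whether a movement trajectory enters raw or convolved.  Legendre
    drift columns up to ``drift_order`` and an intercept complete the
    design.  Rank deficiency is an error naming the dependent columns.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    effect_indices: list[int] = []

    if regressors:
        if hrf_kernel is None:
            if tr is None:
                raise ValueError("need a TR or an explicit HRF kernel for effects")
            hrf_kernel = canonical_hrf(dt=tr)
        for name, series in regressors.items():
            series = np.asarray(series, dtype=float)
            if series.shape != (n_volumes,):
                raise ValueError(f"regressor {name!r} must have length {n_volumes}")
            conv = convolve_regressor(series, hrf_kernel)
            sd = conv.std()
            if sd == 0:
                raise ValueError(
                    f"regressor {name!r} is constant after convolution; "
                    "it cannot be standardised"
                )
            effect_indices.append(len(cols))
            cols.append((conv - conv.mean()) / sd)
            names.append(name)

    for name, series in (confounds or {}).items():
        series = np.asarray(series, dtype=float)
        if series.shape != (n_volumes,):
            raise ValueError(f"confound {name!r} must have length {n_volumes}")
        if np.ptp(series) == 0:
            raise ValueError(f"confound {name!r} is constant (all-zero column)")
        cols.append(series - series.mean())
        names.append(f"confound:{name}")

    drift = _legendre_drift(n_volumes, drift_order)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift:{k + 1}")
    cols.append(np.ones(n_volumes))
    names.append("intercept")

    matrix = np.column_stack(cols)
    if matrix.shape[1] >= n_volumes:
        raise ValueError("design has as many columns as volumes; cannot fit")
    rank = np.linalg.matrix_rank(matrix)
    if rank < matrix.shape[1]:
        # identify dependent columns from the QR diagonal
        q, rr = np.linalg.qr(matrix)
        diag = np.abs(np.diag(rr))
        tol = diag.max() * max(matrix.shape) * np.finfo(float).eps
        dependent = [names[i] for i in range(matrix.shape[1]) if diag[i] <= tol]
        raise ValueError(
            "design matrix is rank deficient; dependent columns: "
            + ", ".join(dependent or ["(undetermined)"])
        )
    return DesignMatrix(matrix=matrix, names=names, effect_indices=effect_indices)


@dataclass
class GlmFit:
    """Per-voxel OLS estimates: beta is columns x voxels."""

    design: DesignMatrix
    beta: np.ndarray
    sigma2: np.ndarray
    dof: int
    volume_shape: tuple[int, int, int] | None = None


def fit_glm(bold, design: DesignMatrix) -> GlmFit:
    """Voxelwise ordinary least squares.

    ``bold`` may be a BoldSeries or a voxels x time array.  Degrees of
    freedom are n_volumes - rank(X).
    """
    volume_shape = None
    if hasattr(bold, "flat") and hasattr(bold, "n_volumes"):
        volume_shape = bold.volume_shape
        y = bold.flat().T  # time x voxels
    else:
        y = np.asarray(bold, dtype=float).T
    if y.shape[0] != design.n_volumes:
        raise ValueError(
            f"BOLD has {y.shape[0]} volumes but design expects {design.n_volumes}"
        )
    bad = ~np.all(np.isfinite(y), axis=0)
    if np.any(bad):
        raise ValueError(f"non-finite voxel series at flat indices {np.where(bad)[0][:5]}")
    x = design.matrix
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = design.n_volumes - rank
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / dof
    # voxels fitted exactly (to rounding) are genuinely noiseless
    scale = (y**2).mean(axis=0)
    sigma2 = np.where(sigma2 <= 1e-20 * np.maximum(scale, 1e-300), 0.0, sigma2)
    return GlmFit(design=design, beta=beta, sigma2=sigma2, dof=dof, volume_shape=volume_shape)


@dataclass
class StatMap:
    """Per-voxel F and p values plus significance masks (sets A, B, C)."""

    f_values: np.ndarray
    p_values: np.ndarray
    dof: tuple[int, int]
    alpha: float | None = None
    correction: str | None = None
    mask: np.ndarray | None = None
    volume_shape: tuple[int, int, int] | None = None

    def volume(self, which: str = "f") -> np.ndarray:
        if self.volume_shape is None:
            raise ValueError("stat map has no attached volume shape")
        arr = {"f": self.f_values, "p": self.p_values}[which]
        return arr.reshape(self.volume_shape)


def f_contrast(fit: GlmFit, contrast: np.ndarray) -> StatMap:
    """Extra-sum-of-squares F test that contrast @ beta == 0.

    F = (C b)' [C (X'X)^-1 C']^{-1} (C b) / (q s^2) with q = rank(C),
    referred to an F(q, dof) distribution.
    """
    c = np.atleast_2d(np.asarray(contrast, dtype=float))
    x = fit.design.matrix
    if c.shape[1] != x.shape[1]:
        raise ValueError(
            f"contrast has {c.shape[1]} columns but design has {x.shape[1]}"
        )
    q = np.linalg.matrix_rank(c)
    if q == 0:
        raise ValueError("contrast has rank zero")
    xtx_inv = np.linalg.pinv(x.T @ x)
    middle = np.linalg.pinv(c @ xtx_inv @ c.T)
    cb = c @ fit.beta  # q x voxels
    quad = np.einsum("qv,qr,rv->v", cb, middle, cb)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = quad / (q * fit.sigma2)
    # degenerate noiseless voxels: zero effect -> F = 0, nonzero -> infinite
    f = np.where(fit.sigma2 > 0, f, np.where(quad <= 1e-12, 0.0, np.inf))
    p = stats.f.sf(f, q, fit.dof)
    return StatMap(
        f_values=f, p_values=p, dof=(q, fit.dof), volume_shape=fit.volume_shape
    )


def fwe_threshold(
    statmap: StatMap,
    alpha: float,
    method: str = "bonferroni",
    fit: GlmFit | None = None,
    bold=None,
    n_permutations: int = 500,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Family-wise-error-corrected significance mask.

    ``bonferroni``: reject where p < alpha / n_voxels.  ``permutation_maxT``
    rejects where F exceeds the (1 - alpha) quantile of the max-F null
    distribution obtained by Freedman-Lane permutation: residuals of the
    reduced (confounds-only) model are permuted, the reduced fit added
    back, and the F-contrast recomputed.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if method == "bonferroni":
        n_vox = statmap.p_values.size
        return statmap.p_values < alpha / n_vox
    if method == "permutation_maxT":
        if fit is None or bold is None:
            raise ValueError("permutation_maxT needs the GlmFit and the BOLD data")
        if n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if rng is None:
            raise ValueError("permutation_maxT needs a seeded generator")
        y = bold.flat().T if hasattr(bold, "n_volumes") else np.asarray(bold, dtype=float).T
        design = fit.design
        x = design.matrix
        keep = [i for i in range(x.shape[1]) if i not in design.effect_indices]
        x_red = x[:, keep]
        beta_red, *_ = np.linalg.lstsq(x_red, y, rcond=None)
        fitted_red = x_red @ beta_red
        resid_red = y - fitted_red
        contrast = design.contrast_for_effects()
        n = y.shape[0]
        max_f = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = rng.permutation(n)
            y_star = fitted_red + resid_red[perm]
            beta, _, rank, _ = np.linalg.lstsq(x, y_star, rcond=None)
            resid = y_star - x @ beta
            sigma2 = (resid**2).sum(axis=0) / fit.dof
            perm_fit = GlmFit(
                design=design, beta=beta, sigma2=sigma2, dof=fit.dof,
                volume_shape=fit.volume_shape,
            )
            max_f[b] = f_contrast(perm_fit, contrast).f_values.max()
        threshold = np.quantile(max_f, 1.0 - alpha)
        return statmap.f_values > threshold
    raise ValueError(f"unknown FWE method {method!r}")


def exclusion_contrast(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Set difference C = A \\ B on matching voxel grids, exactly."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks are on different voxel grids")
    return mask_a & ~mask_b


def local_maxima_table(
    f_volume: np.ndarray,
    p_volume: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    connectivity: int = 26,
) -> pd.DataFrame:
    """Cluster table: voxel count, peak mm coordinate, peak F, corrected p.

    Clusters are connected components of ``mask`` (26- or 6-neighbour);
    each row reports the cluster's peak-F voxel mapped through the affine.
    An empty mask yields an empty table.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be a 3-D voxel grid")
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    columns = ["voxels", "x_mm", "y_mm", "z_mm", "p_corrected", "f_peak"]
    labelled, n_clusters = ndimage.label(mask, structure=structure)
    rows = []
    n_vox_total = mask.size
    for k in range(1, n_clusters + 1):
        sel = labelled == k
        count = int(sel.sum())
        f_in = np.where(sel, f_volume, -np.inf)
        peak_idx = np.unravel_index(np.argmax(f_in), mask.shape)
        mm = affine @ np.array([*peak_idx, 1.0])
        p_corr = min(1.0, float(p_volume[peak_idx]) * n_vox_total)
        rows.append(
            {
                "voxels": count,
                "x_mm": float(mm[0]),
                "y_mm": float(mm[1]),
                "z_mm": float(mm[2]),
                "p_corrected": p_corr,
                "f_peak": float(f_volume[peak_idx]),
            }
        )
    frame = pd.DataFrame(rows, columns=columns)
    return frame.sort_values("f_peak", ascending=False, ignore_index=True) if rows else frame
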