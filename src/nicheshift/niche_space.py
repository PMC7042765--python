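"""Shared 2-D environmental space (PCA on pooled backgrounds) and kernel occupancy grids.

The niche of each range is quantified on a common R x R grid spanning the
first two principal components of the pooled, standardized background
environments of both ranges.  Occurrence and availability densities are
kernel-smoothed on that grid and the occupancy surface is the
availability-corrected density, normalized to unit mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PcaEnvModel", "NicheGrid", "fit_pca_env", "project", "shared_bounds", "build_grid"]

Bounds = tuple[tuple[float, float], tuple[float, float]]


@dataclass
class PcaEnvModel:
    """PCA of the pooled standardized background environments, first two axes retained.

    ``loadings`` has one column per retained axis; columns are orthonormal
    eigenvectors of the correlation matrix of the pooled background sample.
    ``explained_fraction`` are the corresponding variance fractions;
    ``explained_fraction_all`` covers every axis and sums to 1.
    """

    variables: list[str]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray
    explained_fraction: np.ndarray
    explained_fraction_all: np.ndarray

    @property
    def explained_2d(self) -> float:
        """Variance fraction captured jointly by the two retained axes."""
        return float(self.explained_fraction.sum())


@dataclass
class NicheGrid:
    """Kernel occupancy of one range on the shared environmental-space grid.

    Attributes
    ----------
    x, y : cell-center coordinates along the two PCA axes (length R each).
    o : occurrence kernel density at cell centers.
    e : availability (background) kernel density at cell centers.
    z : corrected occupancy o/e where e > 0 (else 0), normalized to sum 1.
    z_uncor : o normalized by its maximum, in [0, 1].
    bandwidth / bg_bandwidth : per-axis kernel widths of the occurrence and
        availability densities (each from Silverman's rule on its own sample
        unless overridden).
    """

    x: np.ndarray
    y: np.ndarray
    o: np.ndarray
    e: np.ndarray
    z: np.ndarray
    z_uncor: np.ndarray
    bandwidth: tuple[float, float]
    bg_bandwidth: tuple[float, float]
    kernel_cutoff: float | None

    @property
    def resolution(self) -> int:
        return self.x.size

    def occupancy(self, corrected: bool = True) -> np.ndarray:
        """Occupancy surface normalized to unit mass."""
        if corrected:
            return self.z
        s = self.z_uncor.sum()
        return self.z_uncor / s


def _as_matrix(env, variables: list[str] | None = None) -> np.ndarray:
    if isinstance(env, pd.DataFrame):
        if variables is not None:
            missing = set(variables) - set(env.columns)
            if missing:
                raise ValueError(f"missing variables: {sorted(missing)}")
            env = env[variables]
        return env.to_numpy(float)
    return np.asarray(env, float)


def fit_pca_env(background_env_native, background_env_invasive) -> PcaEnvModel:
    """Fit the environmental-space PCA on the pooled backgrounds of both ranges.

    Rows of both matrices (same column set) are pooled, z-scored, and the
    eigendecomposition of their correlation matrix taken; the two leading
    axes are retained.  Axis signs are fixed so the largest-magnitude loading
    of each axis is positive.
    """
    if isinstance(background_env_native, pd.DataFrame):
        variables = list(background_env_native.columns)
    else:
        variables = [f"v{i}" for i in range(np.asarray(background_env_native).shape[1])]
    a = _as_matrix(background_env_native, variables)
    b = _as_matrix(background_env_invasive, variables)
    if a.shape[1] != b.shape[1]:
        raise ValueError("both ranges must share the variable set")
    pooled = np.vstack([a, b])
    if pooled.shape[0] < 10:
        raise ValueError("need at least 10 pooled background rows")
    if pooled.shape[1] < 2:
        raise ValueError("need at least 2 variables for a 2-D environmental space")
    means = pooled.mean(axis=0)
    scales = pooled.std(axis=0, ddof=0)
    if np.any(scales == 0):
        raise ValueError("zero-variance variable in pooled background")
    zs = (pooled - means) / scales
    corr = (zs.T @ zs) / zs.shape[0]
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0, None)
    frac_all = evals / evals.sum()
    loadings = evecs[:, :2].copy()
    for j in range(2):  # deterministic sign convention
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    return PcaEnvModel(
        variables=variables,
        means=means,
        scales=scales,
        loadings=loadings,
        explained_fraction=frac_all[:2],
        explained_fraction_all=frac_all,
    )


def project(model: PcaEnvModel, env) -> np.ndarray:
    """Project environment rows into the 2-D PCA space (n x 2 scores)."""
    m = _as_matrix(env, model.variables)
    if m.shape[1] != len(model.variables):
        raise ValueError("column count does not match the fitted variable set")
    return ((m - model.means) / model.scales) @ model.loadings


def shared_bounds(*score_sets: np.ndarray) -> Bounds:
    """Pooled min/max per axis over any number of score sets (no margin)."""
    pooled = np.vstack(score_sets)
    return (
        (float(pooled[:, 0].min()), float(pooled[:, 0].max())),
        (float(pooled[:, 1].min()), float(pooled[:, 1].max())),
    )


def silverman_bandwidth(scores: np.ndarray) -> tuple[float, float]:
    """Per-axis Silverman/Scott rule for a 2-D sample: h_i = sigma_i * n^(-1/6)."""
    n = scores.shape[0]
    sd = scores.std(axis=0, ddof=1) if n > 1 else np.zeros(2)
    h = sd * n ** (-1.0 / 6.0)
    return float(h[0]), float(h[1])


def _axis_kernel(
    pts: np.ndarray, centers: np.ndarray, h: float, cutoff: float | None
) -> np.ndarray:
    # (n_points, R) truncated-Gaussian kernel weights along one axis
    d = (pts[:, None] - centers[None, :]) / h
    k = np.exp(-0.5 * d * d)
    if cutoff is not None:
        k[np.abs(d) > cutoff] = 0.0
    return k


def _kde_grid(
    scores: np.ndarray,
    xc: np.ndarray,
    yc: np.ndarray,
    bw: tuple[float, float],
    cutoff: float | None,
) -> np.ndarray:
    kx = _axis_kernel(scores[:, 0], xc, bw[0], cutoff)
    ky = _axis_kernel(scores[:, 1], yc, bw[1], cutoff)
    dens = kx.T @ ky
    dens /= scores.shape[0] * 2.0 * np.pi * bw[0] * bw[1]
    return dens


def build_grid(
    scores_occ: np.ndarray,
    scores_bg: np.ndarray,
    bounds: Bounds,
    R: int = 100,
    bandwidth: tuple[float, float] | None = None,
    bandwidth_multiplier: float = 1.0,
    kernel_cutoff: float | None = 4.0,
    bg_bandwidth: tuple[float, float] | None = None,
) -> NicheGrid:
    """Kernel occupancy grid of one range on the shared axis bounds.

    Both densities are product-Gaussian kernel estimates evaluated at the
    R x R cell centers.  The kernel has compact support: weights beyond
    ``kernel_cutoff`` bandwidths are exactly zero (pass ``None`` for the pure
    Gaussian), so the z > 0 envelope is a meaningful occupied set.  Each
    density gets Silverman's per-axis rule on its own sample (occurrences
    for o, background for e) unless overridden, so the availability surface
    does not depend on the occurrence sample; points outside the bounds are
    clamped to the boundary cell.

    Grid arrays are indexed ``[ix, iy]`` (axis 0 = first PCA axis).
    """
    scores_occ = np.asarray(scores_occ, float)
    scores_bg = np.asarray(scores_bg, float)
    if scores_occ.shape[0] == 0:
        raise ValueError("no occurrence scores: cannot build an occupancy grid")
    (x0, x1), (y0, y1) = bounds
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate axis bounds")
    xe = np.linspace(x0, x1, R + 1)
    ye = np.linspace(y0, y1, R + 1)
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])

    def clamp(s: np.ndarray) -> np.ndarray:
        out = s.copy()
        out[:, 0] = np.clip(out[:, 0], x0, x1)
        out[:, 1] = np.clip(out[:, 1], y0, y1)
        return out

    scores_occ = clamp(scores_occ)
    scores_bg = clamp(scores_bg)

    def default_bw(scores: np.ndarray) -> tuple[float, float]:
        hx, hy = silverman_bandwidth(scores)
        # degenerate spread: fall back to one cell width
        hx = hx if hx > 0 else (x1 - x0) / R
        hy = hy if hy > 0 else (y1 - y0) / R
        return (hx * bandwidth_multiplier, hy * bandwidth_multiplier)

    if bandwidth is None:
        bandwidth = default_bw(scores_occ)
    if bg_bandwidth is None:
        bg_bandwidth = default_bw(scores_bg)
    o = _kde_grid(scores_occ, xc, yc, bandwidth, kernel_cutoff)
    e = _kde_grid(scores_bg, xc, yc, bg_bandwidth, kernel_cutoff)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(e > 0, o / e, 0.0)
    total = z.sum()
    if total > 0:
        z = z / total
    omax = o.max()
    if omax <= 0:
        raise ValueError("occurrence density vanished everywhere (cutoff too small?)")
    return NicheGrid(
        x=xc,
        y=yc,
        o=o,
        e=e,
        z=z,
        z_uncor=o / omax,
        bandwidth=bandwidth,
        bg_bandwidth=bg_bandwidth,
        kernel_cutoff=kernel_cutoff,
    )
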