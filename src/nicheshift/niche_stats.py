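"""Niche overlap metrics, permutation tests, and the expansion/stability/unfilling decomposition.

Overlap is measured on normalized occupancy surfaces with Schoener's D,

    D = 1 - (1/2) * sum |z1 - z2|,

and the Hellinger-based index of Warren et al.,

    I = 1 - (1/2) * sum (sqrt(z1) - sqrt(z2))^2,

both in [0, 1] (0 = no overlap, 1 = identical niches).  Two permutation
tests ask complementary questions: the *equivalency* test pools and
re-splits the occurrences of the two ranges (are the niches
interchangeable?), and the *similarity* (background) test relocates one
range's occupancy surface at random within its available environment (is the
observed overlap larger than chance placement would produce?).  Niche change
is decomposed into expansion E, stability S and unfilling U following the
COUE framework.

The :class:`NicheComparison` model bundles the whole analysis: build it from
per-range occurrence and background environments, call :meth:`~NicheComparison.fit`,
and read the results object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .niche_space import (
    NicheGrid,
    PcaEnvModel,
    _kde_grid,
    build_grid,
    fit_pca_env,
    project,
    shared_bounds,
    silverman_bandwidth,
)

__all__ = [
    "OverlapResult",
    "PermutationTestResult",
    "NicheDynamics",
    "GridParams",
    "schoener_D",
    "warren_I",
    "overlap",
    "equivalency_test",
    "similarity_test",
    "niche_dynamics",
    "NicheComparison",
    "NicheComparisonResults",
]


@dataclass
class OverlapResult:
    D: float
    I: float


@dataclass
class PermutationTestResult:
    """Observed overlap, its permutation null, and p-values for one test."""

    observed: OverlapResult
    null_D: np.ndarray
    null_I: np.ndarray
    p_D: float
    p_I: float
    n_reps: int
    kind: str  # "equivalency" | "similarity"
    direction: str | None = None
    #: observed value outside the one-sided 95% bound of the null
    outside_ci_D: bool = False
    outside_ci_I: bool = False


@dataclass
class NicheDynamics:
    expansion: float
    stability: float
    unfilling: float
    quantile_threshold: float
    analogue_only: bool


@dataclass
class GridParams:
    """Occupancy-grid settings shared by every surface in one analysis."""

    R: int = 100
    bandwidth_multiplier: float = 1.0
    kernel_cutoff: float | None = 4.0
    corrected: bool = True  # use availability-corrected occupancy z (vs z_uncor)


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------


def _normalized(z: np.ndarray, name: str) -> np.ndarray:
    z = np.asarray(z, float)
    if np.any(z < 0):
        raise ValueError(f"{name}: occupancy grid has negative entries")
    s = z.sum()
    if s <= 0:
        raise ValueError(f"{name}: occupancy grid sums to zero")
    if not np.isclose(s, 1.0, atol=1e-6):
        import warnings

        warnings.warn(f"{name} not normalized (sum={s:.3g}); normalizing internally", stacklevel=3)
        z = z / s
    return z


def schoener_D(z1: np.ndarray, z2: np.ndarray) -> float:
    """Schoener's D between two normalized occupancy grids."""
    z1, z2 = np.asarray(z1, float), np.asarray(z2, float)
    if z1.shape != z2.shape:
        raise ValueError(f"grid shapes differ: {z1.shape} vs {z2.shape}")
    z1 = _normalized(z1, "z1")
    z2 = _normalized(z2, "z2")
    return float(1.0 - 0.5 * np.abs(z1 - z2).sum())


def warren_I(z1: np.ndarray, z2: np.ndarray) -> float:
    """Warren et al.'s Hellinger-based I between two normalized occupancy grids."""
    z1, z2 = np.asarray(z1, float), np.asarray(z2, float)
    if z1.shape != z2.shape:
        raise ValueError(f"grid shapes differ: {z1.shape} vs {z2.shape}")
    z1 = _normalized(z1, "z1")
    z2 = _normalized(z2, "z2")
    return float(1.0 - 0.5 * ((np.sqrt(z1) - np.sqrt(z2)) ** 2).sum())


def overlap(g1: NicheGrid | np.ndarray, g2: NicheGrid | np.ndarray, corrected: bool = True) -> OverlapResult:
    z1 = g1.occupancy(corrected) if isinstance(g1, NicheGrid) else g1
    z2 = g2.occupancy(corrected) if isinstance(g2, NicheGrid) else g2
    return OverlapResult(D=schoener_D(z1, z2), I=warren_I(z1, z2))


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------


def _occupancy_from_o(o: np.ndarray, e: np.ndarray, corrected: bool) -> np.ndarray:
    if corrected:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(e > 0, o / e, 0.0)
    else:
        z = o.copy()
    s = z.sum()
    if s <= 0:
        raise ValueError("occupancy grid vanished")
    return z / s


def equivalency_test(
    occ1: np.ndarray,
    occ2: np.ndarray,
    bg1: np.ndarray,
    bg2: np.ndarray,
    grid_params: GridParams | None = None,
    n_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> PermutationTestResult:
    """Niche equivalency permutation test.

    Occurrence scores of both ranges are pooled and randomly re-split into
    pseudo-sets of the original sizes; occupancy grids are rebuilt against
    the original (fixed) backgrounds and overlap recomputed, ``n_reps``
    times.  The p-value is lower-tailed, p = (#{null <= observed} + 1) /
    (n_reps + 1): equivalency is rejected when the observed overlap is
    smaller than random relabelling allows.  The availability densities and
    grid geometry are fixed across repetitions, while each pseudo-set's
    occurrence bandwidth is recomputed by the same rule as the observed
    one, so the overlap statistic is a pure function of the split and the
    permutation p-value is exact under exchangeability.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    gp = grid_params or GridParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    occ1, occ2 = np.asarray(occ1, float), np.asarray(occ2, float)
    bounds = shared_bounds(bg1, bg2)
    g1 = build_grid(occ1, bg1, bounds, gp.R, None, gp.bandwidth_multiplier, gp.kernel_cutoff)
    g2 = build_grid(occ2, bg2, bounds, gp.R, None, gp.bandwidth_multiplier, gp.kernel_cutoff)
    obs = overlap(g1, g2, gp.corrected)

    pooled = np.vstack([occ1, occ2])
    n1 = occ1.shape[0]
    null_D = np.empty(n_reps)
    null_I = np.empty(n_reps)

    def clamp(s):
        out = s.copy()
        out[:, 0] = np.clip(out[:, 0], *bounds[0])
        out[:, 1] = np.clip(out[:, 1], *bounds[1])
        return out

    from .niche_space import silverman_bandwidth

    def pseudo_bw(scores: np.ndarray, grid) -> tuple[float, float]:
        hx, hy = silverman_bandwidth(scores)
        hx = hx if hx > 0 else (bounds[0][1] - bounds[0][0]) / gp.R
        hy = hy if hy > 0 else (bounds[1][1] - bounds[1][0]) / gp.R
        return (hx * gp.bandwidth_multiplier, hy * gp.bandwidth_multiplier)

    for r in range(n_reps):
        perm = rng.permutation(pooled.shape[0])
        p1, p2 = clamp(pooled[perm[:n1]]), clamp(pooled[perm[n1:]])
        o1 = _kde_grid(p1, g1.x, g1.y, pseudo_bw(p1, g1), gp.kernel_cutoff)
        o2 = _kde_grid(p2, g2.x, g2.y, pseudo_bw(p2, g2), gp.kernel_cutoff)
        z1 = _occupancy_from_o(o1, g1.e, gp.corrected)
        z2 = _occupancy_from_o(o2, g2.e, gp.corrected)
        null_D[r] = schoener_D(z1, z2)
        null_I[r] = warren_I(z1, z2)

    p_D = (np.count_nonzero(null_D <= obs.D) + 1) / (n_reps + 1)
    p_I = (np.count_nonzero(null_I <= obs.I) + 1) / (n_reps + 1)
    return PermutationTestResult(
        observed=obs,
        null_D=null_D,
        null_I=null_I,
        p_D=float(p_D),
        p_I=float(p_I),
        n_reps=n_reps,
        kind="equivalency",
        outside_ci_D=bool(obs.D < np.quantile(null_D, 0.05)),
        outside_ci_I=bool(obs.I < np.quantile(null_I, 0.05)),
    )


def _grid_centroid(z: np.ndarray) -> tuple[float, float]:
    ix, iy = np.indices(z.shape)
    m = z.sum()
    return float((ix * z).sum() / m), float((iy * z).sum() / m)


def _shift_density(z: np.ndarray, di: int, dj: int, mode: str) -> np.ndarray:
    if mode == "wrap":
        return np.roll(np.roll(z, di, axis=0), dj, axis=1)
    out = np.zeros_like(z)
    R0, R1 = z.shape
    si0, si1 = max(0, di), min(R0, R0 + di)
    ti0, ti1 = max(0, -di), min(R0, R0 - di)
    sj0, sj1 = max(0, dj), min(R1, R1 + dj)
    tj0, tj1 = max(0, -dj), min(R1, R1 - dj)
    out[si0:si1, sj0:sj1] = z[ti0:ti1, tj0:tj1]
    return out


def similarity_test(
    source: NicheGrid,
    target: NicheGrid,
    n_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
    direction: str | None = None,
    grid_params: GridParams | None = None,
    mode: str = "wrap",
) -> PermutationTestResult:
    """Niche similarity (background) test.

    The target range's occupancy surface is relocated ``n_reps`` times: a
    random center is drawn uniformly from the target background's occupied
    environmental cells (e > 0) and the whole surface translated there
    (wrapped by default, or clipped with ``mode="clip"``), renormalized, and
    its overlap with the untouched source surface recomputed.  The p-value
    is upper-tailed, p = (#{null >= observed} + 1)/(n_reps + 1): a small p
    means the two niches are more similar than expected by chance.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    gp = grid_params or GridParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z_src = source.occupancy(gp.corrected)
    z_tgt = target.occupancy(gp.corrected)
    obs = OverlapResult(D=schoener_D(z_src, z_tgt), I=warren_I(z_src, z_tgt))

    cells = np.argwhere(target.e > 0)
    if cells.size == 0:
        raise ValueError("target background occupies no environmental cells")
    ci, cj = _grid_centroid(z_tgt)
    null_D = np.empty(n_reps)
    null_I = np.empty(n_reps)
    for r in range(n_reps):
        ti, tj = cells[rng.integers(cells.shape[0])]
        shifted = _shift_density(z_tgt, int(round(ti - ci)), int(round(tj - cj)), mode)
        s = shifted.sum()
        if s <= 0:  # clipped entirely off-grid; count as zero overlap
            null_D[r] = 0.0
            null_I[r] = 0.0
            continue
        shifted = shifted / s
        null_D[r] = schoener_D(z_src, shifted)
        null_I[r] = warren_I(z_src, shifted)

    p_D = (np.count_nonzero(null_D >= obs.D) + 1) / (n_reps + 1)
    p_I = (np.count_nonzero(null_I >= obs.I) + 1) / (n_reps + 1)
    return PermutationTestResult(
        observed=obs,
        null_D=null_D,
        null_I=null_I,
        p_D=float(p_D),
        p_I=float(p_I),
        n_reps=n_reps,
        kind="similarity",
        direction=direction,
        outside_ci_D=bool(obs.D > np.quantile(null_D, 0.95)),
        outside_ci_I=bool(obs.I > np.quantile(null_I, 0.95)),
    )


# ---------------------------------------------------------------------------
# niche dynamics (expansion / stability / unfilling)
# ---------------------------------------------------------------------------


def _occupied_set(z: np.ndarray, quantile_threshold: float) -> np.ndarray:
    """Occupied envelope: cells above the density level that trims the lowest
    ``quantile_threshold`` fraction of total occupancy mass (0 keeps every
    z > 0 cell)."""
    if quantile_threshold < 0 or quantile_threshold >= 1:
        raise ValueError("quantile_threshold must be in [0, 1)")
    if quantile_threshold == 0:
        return z > 0
    pos = np.sort(z[z > 0])
    if pos.size == 0:
        return z > 0
    cum = np.cumsum(pos) / pos.sum()
    level = pos[np.searchsorted(cum, quantile_threshold)]
    return z > level


def niche_dynamics(
    native: NicheGrid,
    invasive: NicheGrid,
    quantile_threshold: float = 0.05,
    analogue_only: bool = False,
    corrected: bool = True,
) -> NicheDynamics:
    """Decompose niche change into expansion E, stability S and unfilling U.

    Each range's occupied cell set is its occupancy envelope after trimming
    the lowest ``quantile_threshold`` fraction of occupancy mass (0 keeps
    every cell with z > 0); the default 5% removes the marginal densities
    the kernel smears far beyond the data.  Expansion is the
    occupancy mass of the invaded niche lying outside the native occupied
    set; stability is its complement (E + S = 1); unfilling is, symmetrically,
    the native mass outside the invaded occupied set.  ``analogue_only``
    restricts everything to cells available (e > 0) in both ranges.
    """
    if native.z.shape != invasive.z.shape:
        raise ValueError("grids must share geometry")
    z_nat = native.occupancy(corrected)
    z_inv = invasive.occupancy(corrected)
    occ_nat = _occupied_set(z_nat, quantile_threshold)
    occ_inv = _occupied_set(z_inv, quantile_threshold)
    domain = np.ones_like(occ_nat) if not analogue_only else (native.e > 0) & (invasive.e > 0)
    occ_nat &= domain
    occ_inv &= domain
    if not occ_nat.any() or not occ_inv.any():
        raise ValueError("empty occupied set; lower the threshold or check the grids")
    inv_total = z_inv[occ_inv].sum()
    nat_total = z_nat[occ_nat].sum()
    if inv_total <= 0 or nat_total <= 0:
        raise ValueError("occupancy mass vanished on the occupied set")
    E = z_inv[occ_inv & ~occ_nat].sum() / inv_total
    U = z_nat[occ_nat & ~occ_inv].sum() / nat_total
    return NicheDynamics(
        expansion=float(E),
        stability=float(1.0 - E),
        unfilling=float(U),
        quantile_threshold=quantile_threshold,
        analogue_only=analogue_only,
    )


# ---------------------------------------------------------------------------
# Model / Results front-end
# ---------------------------------------------------------------------------


class NicheComparison:
    """Full environmental-space niche comparison between two ranges.

    Parameters
    ----------
    native_occ_env, invasive_occ_env : DataFrame
        Predictor values at the occurrence points of each range.
    native_bg_env, invasive_bg_env : DataFrame
        Predictor values of the background (available environment) of each
        range; the PCA is fitted on these, pooled.
    grid_params : GridParams, optional
        Occupancy-grid settings (resolution, bandwidth multiplier, kernel
        cutoff, corrected/uncorrected surface).
    quantile_threshold, analogue_only :
        Settings of the expansion/stability/unfilling decomposition.

    Examples
    --------
    >>> model = NicheComparison(nat_occ.env, nat_bg.env, inv_occ.env, inv_bg.env)
    >>> res = model.fit(n_reps=99, seed=0)
    >>> print(res.summary())                          # doctest: +SKIP
    """

    def __init__(
        self,
        native_occ_env: pd.DataFrame,
        native_bg_env: pd.DataFrame,
        invasive_occ_env: pd.DataFrame,
        invasive_bg_env: pd.DataFrame,
        grid_params: GridParams | None = None,
        quantile_threshold: float = 0.05,
        analogue_only: bool = False,
    ) -> None:
        self.native_occ_env = native_occ_env
        self.native_bg_env = native_bg_env
        self.invasive_occ_env = invasive_occ_env
        self.invasive_bg_env = invasive_bg_env
        self.grid_params = grid_params or GridParams()
        self.quantile_threshold = quantile_threshold
        self.analogue_only = analogue_only

    def fit(self, n_reps: int = 1000, seed: int | None = None) -> "NicheComparisonResults":
        gp = self.grid_params
        rng = np.random.default_rng(seed)
        pca = fit_pca_env(self.native_bg_env, self.invasive_bg_env)
        s_occ1 = project(pca, self.native_occ_env)
        s_occ2 = project(pca, self.invasive_occ_env)
        s_bg1 = project(pca, self.native_bg_env)
        s_bg2 = project(pca, self.invasive_bg_env)
        bounds = shared_bounds(s_bg1, s_bg2)
        g1 = build_grid(s_occ1, s_bg1, bounds, gp.R, None, gp.bandwidth_multiplier, gp.kernel_cutoff)
        g2 = build_grid(s_occ2, s_bg2, bounds, gp.R, None, gp.bandwidth_multiplier, gp.kernel_cutoff)
        obs = overlap(g1, g2, gp.corrected)
        eq = equivalency_test(s_occ1, s_occ2, s_bg1, s_bg2, gp, n_reps, rng)
        sim_ni = similarity_test(g1, g2, n_reps, rng, "native->invasive", gp)
        sim_in = similarity_test(g2, g1, n_reps, rng, "invasive->native", gp)
        dyn = niche_dynamics(g1, g2, self.quantile_threshold, self.analogue_only, gp.corrected)
        return NicheComparisonResults(
            model=self,
            pca=pca,
            native_grid=g1,
            invasive_grid=g2,
            observed=obs,
            equivalency=eq,
            similarity_native_to_invasive=sim_ni,
            similarity_invasive_to_native=sim_in,
            dynamics=dyn,
        )


@dataclass
class NicheComparisonResults:
    """Fitted niche comparison: overlap, permutation tests, dynamics."""

    model: NicheComparison
    pca: PcaEnvModel
    native_grid: NicheGrid
    invasive_grid: NicheGrid
    observed: OverlapResult
    equivalency: PermutationTestResult
    similarity_native_to_invasive: PermutationTestResult
    similarity_invasive_to_native: PermutationTestResult
    dynamics: NicheDynamics
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        d, eq = self.observed, self.equivalency
        sni, sin_ = self.similarity_native_to_invasive, self.similarity_invasive_to_native
        dyn = self.dynamics
        lines = [
            "Niche comparison (environmental space, 2 PCA axes)",
            "=" * 54,
            f"PCA variance explained (2 axes): {100 * self.pca.explained_2d:.2f}%",
            f"Overlap:      D = {d.D:.4f}   I = {d.I:.4f}",
            f"Equivalency:  p(D) = {eq.p_D:.4f}   p(I) = {eq.p_I:.4f}   (n_reps={eq.n_reps})",
            f"Similarity native->invasive:  p(D) = {sni.p_D:.4f}   p(I) = {sni.p_I:.4f}",
            f"Similarity invasive->native:  p(D) = {sin_.p_D:.4f}   p(I) = {sin_.p_I:.4f}",
            f"Dynamics:     expansion = {dyn.expansion:.4f}   stability = {dyn.stability:.4f}"
            f"   unfilling = {dyn.unfilling:.4f}",
        ]
        return "\n".join(lines)

    def to_table(self) -> pd.DataFrame:
        """One-row table with the overlap/test/dynamics schema of the analysis."""
        eq, sni, sin_ = (
            self.equivalency,
            self.similarity_native_to_invasive,
            self.similarity_invasive_to_native,
        )
        return pd.DataFrame(
            [
                {
                    "D": self.observed.D,
                    "I": self.observed.I,
                    "equivalency_p_D": eq.p_D,
                    "equivalency_p_I": eq.p_I,
                    "similarity_native_to_invasive_p_D": sni.p_D,
                    "similarity_native_to_invasive_p_I": sni.p_I,
                    "similarity_invasive_to_native_p_D": sin_.p_D,
                    "similarity_invasive_to_native_p_I": sin_.p_I,
                    "expansion": self.dynamics.expansion,
                    "stability": self.dynamics.stability,
                    "unfilling": self.dynamics.unfilling,
                }
            ]
        )

    def to_json(self, path: str | Path | None = None, include_null: bool = False) -> dict:
        eq, sni, sin_ = (
            self.equivalency,
            self.similarity_native_to_invasive,
            self.similarity_invasive_to_native,
        )

        def test_dict(t: PermutationTestResult) -> dict:
            d = {
                "observed_D": t.observed.D,
                "observed_I": t.observed.I,
                "p_D": t.p_D,
                "p_I": t.p_I,
                "n_reps": t.n_reps,
                "kind": t.kind,
                "direction": t.direction,
                "outside_ci_D": t.outside_ci_D,
                "outside_ci_I": t.outside_ci_I,
            }
            if include_null:
                d["null_D"] = t.null_D.tolist()
                d["null_I"] = t.null_I.tolist()
            return d

        out = {
            "pca_explained_2d": self.pca.explained_2d,
            "overlap": {"D": self.observed.D, "I": self.observed.I},
            "equivalency": test_dict(eq),
            "similarity_native_to_invasive": test_dict(sni),
            "similarity_invasive_to_native": test_dict(sin_),
            "dynamics": {
                "expansion": self.dynamics.expansion,
                "stability": self.dynamics.stability,
                "unfilling": self.dynamics.unfilling,
                "quantile_threshold": self.dynamics.quantile_threshold,
                "analogue_only": self.dynamics.analogue_only,
            },
        }
        if path is not None:
            Path(path).write_text(json.dumps(out, indent=2))
        return out

    def plot(self, path: str | Path | None = None):
        """Occupancy surfaces of both ranges in the shared PCA space."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4.2), sharex=True, sharey=True)
        for ax, grid, label in (
            (axes[0], self.native_grid, "native"),
            (axes[1], self.invasive_grid, "invasive"),
        ):
            extent = (grid.x[0], grid.x[-1], grid.y[0], grid.y[-1])
            ax.imshow(
                grid.occupancy(self.model.grid_params.corrected).T,
                origin="lower",
                extent=extent,
                aspect="auto",
                cmap="viridis",
            )
            ax.contour(grid.x, grid.y, (grid.e > 0).T.astype(float), levels=[0.5], colors="w")
            ax.set_title(f"{label} occupancy")
            ax.set_xlabel("PC1")
        axes[0].set_ylabel("PC2")
        fig.suptitle(f"D = {self.observed.D:.3f}, I = {self.observed.I:.3f}")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=130)
            plt.close(fig)
        return fig
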