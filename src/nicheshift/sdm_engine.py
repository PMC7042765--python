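"""From-scratch maximum-entropy presence-background distribution model.

The model is the Gibbs distribution over background locations,

    p_lambda(x) = exp(lambda . f(x)) / Z,   Z = sum over background of exp(lambda . f),

whose coefficients minimize the L1-penalized negative mean log raw
probability of the presences,

    J(lambda) = -mean_pres[lambda . f] + log Z(lambda) + sum_j beta_j |lambda_j|,

a convex objective.  Features f are built from the predictors by the classic
maxent feature classes: linear (L), quadratic (Q), product (P), hinge (H,
forward and reverse at fixed knots) and threshold (T), all rescaled to
[0, 1] over the training range with clamping.  Per-feature penalties are
beta_j = RM * b_class / sqrt(n_presence) with class-level base constants in
:data:`DEFAULT_BASE_PENALTIES` and RM the user-facing regularization
multiplier.

Model selection follows the standard tuning protocol: a grid of feature-class
combinations x regularization multipliers, AICc computed on the full data,
spatial block cross-validated AUC as a secondary diagnostic, and the
lowest-AICc candidate within the dAICc < 2 set selected.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_BASE_PENALTIES",
    "DEFAULT_CLASS_COMBOS",
    "DEFAULT_RMS",
    "Feature",
    "FeatureSet",
    "MaxentModel",
    "MaxentResults",
    "BlockPartition",
    "TuningResult",
    "ConvergenceError",
    "build_features",
    "fit_maxent",
    "predict",
    "block_partition",
    "aicc",
    "tune",
]

#: Class-level base L1 penalties, patterned on published maxent defaults;
#: the effective penalty is beta_j = RM * base / sqrt(n_presence).
DEFAULT_BASE_PENALTIES: dict[str, float] = {"L": 1.0, "Q": 1.0, "P": 1.0, "H": 0.5, "T": 1.0}

DEFAULT_CLASS_COMBOS: tuple[str, ...] = ("L", "H", "LQ", "LQH", "LQHP", "LQHPT")
DEFAULT_RMS: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


class ConvergenceError(RuntimeError):
    """Solver failed to reach the KKT tolerance within the iteration cap."""

    def __init__(self, message: str, kkt_residual: float):
        super().__init__(message)
        self.kkt_residual = kkt_residual


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Feature:
    kind: str  # 'L' | 'Q' | 'P' | 'HF' | 'HR' | 'T'
    variables: tuple[str, ...]
    knot: float | None = None

    @property
    def penalty_class(self) -> str:
        return "H" if self.kind in ("HF", "HR") else self.kind


@dataclass
class FeatureSet:
    """Feature definitions plus the [0,1] rescaling constants of the training sample."""

    classes: str
    knots: int
    variables: list[str]
    var_min: np.ndarray
    var_max: np.ndarray
    features: list[Feature]

    @property
    def n_features(self) -> int:
        return len(self.features)

    def _rescale(self, env) -> np.ndarray:
        if isinstance(env, pd.DataFrame):
            env = env[self.variables].to_numpy(float)
        else:
            env = np.asarray(env, float)
        span = self.var_max - self.var_min
        span = np.where(span > 0, span, 1.0)
        u = (env - self.var_min) / span
        return np.clip(u, 0.0, 1.0)  # clamp out-of-range values to the training range

    def transform(self, env) -> np.ndarray:
        """(n, n_features) design matrix; every entry in [0, 1]."""
        u = self._rescale(env)
        col = {name: u[:, i] for i, name in enumerate(self.variables)}
        out = np.empty((u.shape[0], self.n_features))
        for j, ft in enumerate(self.features):
            if ft.kind == "L":
                out[:, j] = col[ft.variables[0]]
            elif ft.kind == "Q":
                out[:, j] = col[ft.variables[0]] ** 2
            elif ft.kind == "P":
                out[:, j] = col[ft.variables[0]] * col[ft.variables[1]]
            elif ft.kind == "HF":
                t = ft.knot
                out[:, j] = np.clip((col[ft.variables[0]] - t) / (1.0 - t), 0.0, 1.0)
            elif ft.kind == "HR":
                t = ft.knot
                out[:, j] = np.clip((t - col[ft.variables[0]]) / t, 0.0, 1.0)
            elif ft.kind == "T":
                out[:, j] = (col[ft.variables[0]] > ft.knot).astype(float)
            else:  # pragma: no cover
                raise ValueError(f"unknown feature kind {ft.kind}")
        return out

    def penalty_classes(self) -> np.ndarray:
        return np.array([ft.penalty_class for ft in self.features])


def build_features(env_sample, classes: str = "LQH", knots: int = 20) -> FeatureSet:
    """Construct the feature set for a class combination.

    ``env_sample`` (DataFrame) supplies the variable names and the per-variable
    min/max used for [0,1] rescaling.  Hinge and threshold knots are ``knots``
    evenly spaced interior points of the rescaled [0,1] interval.  Constant
    (zero-range) variables contribute no nonlinear features (warning).
    """
    classes = "".join(sorted(set(classes.upper()), key="LQHPT".index))
    bad = set(classes) - set("LQHPT")
    if bad:
        raise ValueError(f"unknown feature classes: {sorted(bad)}")
    if not classes:
        raise ValueError("at least one feature class is required")
    if isinstance(env_sample, pd.DataFrame):
        variables = list(env_sample.columns)
        m = env_sample.to_numpy(float)
    else:
        m = np.asarray(env_sample, float)
        variables = [f"v{i}" for i in range(m.shape[1])]
    vmin, vmax = m.min(axis=0), m.max(axis=0)
    constant = [v for v, lo, hi in zip(variables, vmin, vmax) if hi <= lo]
    if constant and set(classes) - {"L"}:
        warnings.warn(
            f"constant variables {constant}: nonlinear features dropped", stacklevel=2
        )
    varying = [v for v in variables if v not in constant]

    interior = np.linspace(0.0, 1.0, knots + 2)[1:-1]
    features: list[Feature] = []
    if "L" in classes:
        features += [Feature("L", (v,)) for v in variables]
    if "Q" in classes:
        features += [Feature("Q", (v,)) for v in varying]
    if "H" in classes:
        for v in varying:
            features += [Feature("HF", (v,), float(t)) for t in interior]
            features += [Feature("HR", (v,), float(t)) for t in interior]
    if "P" in classes:
        features += [Feature("P", (a, b)) for a, b in itertools.combinations(varying, 2)]
    if "T" in classes:
        for v in varying:
            features += [Feature("T", (v,), float(t)) for t in interior]
    return FeatureSet(classes, knots, variables, vmin, vmax, features)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _betas(feature_set: FeatureSet, rm: float, n_presence: int, base=None) -> np.ndarray:
    base = base or DEFAULT_BASE_PENALTIES
    cls = feature_set.penalty_classes()
    return rm * np.array([base[c] for c in cls]) / np.sqrt(n_presence)


def _objective(lam, Fp_mean, Fb, beta):
    lin = Fb @ lam
    return float(-(Fp_mean @ lam) + logsumexp(lin) + beta @ np.abs(lam))


def _smooth_grad(lam, Fp_mean, Fb):
    lin = Fb @ lam
    lin -= lin.max()
    w = np.exp(lin)
    w /= w.sum()
    return -Fp_mean + Fb.T @ w, w


def _kkt_residual(lam, grad, beta, zero_tol=1e-10):
    r = np.where(
        np.abs(lam) > zero_tol,
        np.abs(grad + np.sign(lam) * beta),
        np.maximum(0.0, np.abs(grad) - beta),
    )
    return float(r.max())


def _fista(Fp_mean, Fb, beta, tol, max_iter):
    """Accelerated proximal gradient (FISTA) with backtracking and restart."""
    n_feat = Fp_mean.size
    lam = np.zeros(n_feat)
    y = lam.copy()
    t = 1.0
    L = 1.0
    f_y_grad, _ = _smooth_grad(y, Fp_mean, Fb)
    residual = _kkt_residual(lam, f_y_grad, beta)
    if residual <= tol:
        return lam, residual, 0

    def smooth_val(v):
        return float(-(Fp_mean @ v) + logsumexp(Fb @ v))

    f_prev = _objective(lam, Fp_mean, Fb, beta)
    for it in range(1, max_iter + 1):
        g, _ = _smooth_grad(y, Fp_mean, Fb)
        fy = smooth_val(y)
        while True:  # backtracking line search on the smooth part
            step = 1.0 / L
            cand = np.sign(y - step * g) * np.maximum(np.abs(y - step * g) - step * beta, 0.0)
            diff = cand - y
            if smooth_val(cand) <= fy + g @ diff + 0.5 * L * (diff @ diff) + 1e-12:
                break
            L *= 2.0
            if L > 1e12:
                break
        f_cand = _objective(cand, Fp_mean, Fb, beta)
        if f_cand > f_prev:  # monotone restart
            y = lam.copy()
            t = 1.0
            L *= 2.0
            continue
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = cand + ((t - 1.0) / t_new) * (cand - lam)
        lam, t, f_prev = cand, t_new, f_cand
        L = max(L / 1.5, 1e-3)
        if it % 10 == 0 or it == max_iter:
            g_lam, _ = _smooth_grad(lam, Fp_mean, Fb)
            residual = _kkt_residual(lam, g_lam, beta)
            if residual <= tol:
                return lam, residual, it
    g_lam, _ = _smooth_grad(lam, Fp_mean, Fb)
    return lam, _kkt_residual(lam, g_lam, beta), max_iter


@dataclass
class MaxentResults:
    """Fitted maxent model: coefficients, normalizer, entropy, diagnostics."""

    feature_set: FeatureSet
    params: np.ndarray  # lambda, one per feature
    beta: np.ndarray  # per-feature L1 penalties
    rm: float
    log_Z: float  # log normalizer over the training background
    entropy: float  # H of the fitted raw distribution over training background
    n_presence: int
    n_background: int
    kkt_residual: float
    n_iter: int
    range_label: str | None = None
    _train_bg_env: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        """Number of nonzero coefficients (|lambda| > 1e-8)."""
        return int(np.count_nonzero(np.abs(self.params) > 1e-8))

    def predict(self, env, output: str = "cloglog") -> np.ndarray:
        return predict(self, env, output)

    def summary(self) -> str:
        fs = self.feature_set
        nz = np.flatnonzero(np.abs(self.params) > 1e-8)
        lines = [
            "Maximum-entropy presence-background model",
            "=" * 52,
            f"Range:               {self.range_label or '-'}",
            f"Feature classes:     {fs.classes} (knots={fs.knots}, {fs.n_features} features)",
            f"Regularization RM:   {self.rm}",
            f"Presences / bg:      {self.n_presence} / {self.n_background}",
            f"Nonzero coeffs k:    {self.k}",
            f"Entropy H:           {self.entropy:.4f}",
            f"KKT residual:        {self.kkt_residual:.2e}  ({self.n_iter} iterations)",
            "-" * 52,
            f"{'feature':<28}{'lambda':>12}{'beta':>10}",
        ]
        for j in nz:
            ft = fs.features[j]
            name = f"{ft.kind}({','.join(ft.variables)}" + (
                f"@{ft.knot:.3f})" if ft.knot is not None else ")"
            )
            lines.append(f"{name:<28}{self.params[j]:>12.4f}{self.beta[j]:>10.4f}")
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> dict:
        fs = self.feature_set
        out = {
            "classes": fs.classes,
            "knots": fs.knots,
            "variables": fs.variables,
            "var_min": fs.var_min.tolist(),
            "var_max": fs.var_max.tolist(),
            "features": [
                {"kind": f.kind, "variables": list(f.variables), "knot": f.knot}
                for f in fs.features
            ],
            "lambda": self.params.tolist(),
            "beta": self.beta.tolist(),
            "rm": self.rm,
            "log_Z": self.log_Z,
            "entropy": self.entropy,
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "range_label": self.range_label,
        }
        if path is not None:
            Path(path).write_text(json.dumps(out, indent=2))
        return out


class MaxentModel:
    """Maxent model specification: data plus feature/penalty settings.

    Statsmodels-style front end over :func:`fit_maxent`:

    >>> res = MaxentModel(pres_env, bg_env, classes="LQH", rm=1.0).fit()
    >>> res.predict(other_env, output="cloglog")        # doctest: +SKIP
    """

    def __init__(
        self,
        presence_env,
        background_env,
        classes: str = "LQH",
        knots: int = 20,
        rm: float = 1.0,
        feature_set: FeatureSet | None = None,
        base_penalties: dict[str, float] | None = None,
        range_label: str | None = None,
    ) -> None:
        self.presence_env = presence_env
        self.background_env = background_env
        self.rm = rm
        self.base_penalties = base_penalties
        self.range_label = range_label
        if feature_set is None:
            sample = (
                pd.concat([presence_env, background_env], ignore_index=True)
                if isinstance(presence_env, pd.DataFrame)
                else np.vstack([presence_env, background_env])
            )
            feature_set = build_features(sample, classes, knots)
        self.feature_set = feature_set

    def fit(self, tol: float = 1e-7, max_iter: int = 10_000) -> MaxentResults:
        return fit_maxent(
            self.presence_env,
            self.background_env,
            self.feature_set,
            rm=self.rm,
            base_penalties=self.base_penalties,
            tol=tol,
            max_iter=max_iter,
            range_label=self.range_label,
        )


def fit_maxent(
    presence_env,
    background_env,
    feature_set: FeatureSet,
    rm: float = 1.0,
    base_penalties: dict[str, float] | None = None,
    tol: float = 1e-7,
    max_iter: int = 10_000,
    seed: int | None = None,  # noqa: ARG001 - deterministic solver; kept for interface stability
    range_label: str | None = None,
    _Fp: np.ndarray | None = None,
    _Fb: np.ndarray | None = None,
) -> MaxentResults:
    """Fit the penalized maxent model by deterministic proximal gradient descent.

    Raises :class:`ConvergenceError` (carrying the final KKT residual) if the
    iteration cap is reached before the optimality tolerance.
    """
    Fp = feature_set.transform(presence_env) if _Fp is None else _Fp
    Fb = feature_set.transform(background_env) if _Fb is None else _Fb
    n_pres, n_bg = Fp.shape[0], Fb.shape[0]
    if n_pres < 2:
        raise ValueError("need at least 2 presences")
    if n_bg < 10:
        raise ValueError("need at least 10 background points")
    beta = _betas(feature_set, rm, n_pres, base_penalties)
    lam, residual, n_iter = _fista(Fp.mean(axis=0), Fb, beta, tol, max_iter)
    if residual > tol:
        raise ConvergenceError(
            f"maxent solver did not converge in {max_iter} iterations "
            f"(KKT residual {residual:.3e} > tol {tol:.1e})",
            residual,
        )
    lin = Fb @ lam
    log_Z = float(logsumexp(lin))
    logp = lin - log_Z
    entropy = float(-(np.exp(logp) @ logp))
    return MaxentResults(
        feature_set=feature_set,
        params=lam,
        beta=beta,
        rm=rm,
        log_Z=log_Z,
        entropy=entropy,
        n_presence=n_pres,
        n_background=n_bg,
        kkt_residual=residual,
        n_iter=n_iter,
        range_label=range_label,
        _train_bg_env=background_env if isinstance(background_env, pd.DataFrame) else None,
    )


def predict(model: MaxentResults, env, output: str = "cloglog") -> np.ndarray:
    """Suitability of new environments under a fitted model.

    ``raw`` is exp(lambda . f(x)) / Z_train (the Gibbs density relative to
    the training background); ``cloglog`` is 1 - exp(-exp(H) * raw), clipped
    to [0, 1].  Out-of-range predictor values are clamped to the training
    range by the feature transform.
    """
    if output not in ("raw", "cloglog"):
        raise ValueError("output must be 'raw' or 'cloglog'")
    F = model.feature_set.transform(env)
    raw = np.exp(F @ model.params - model.log_Z)
    if output == "raw":
        return raw
    return np.clip(1.0 - np.exp(-np.exp(model.entropy) * raw), 0.0, 1.0)


# ---------------------------------------------------------------------------
# spatial block partition, AICc, tuning
# ---------------------------------------------------------------------------


@dataclass
class BlockPartition:
    """Four-quadrant spatial split: median latitude, then per-half median longitude."""

    presence_block: np.ndarray
    background_block: np.ndarray
    lat_split: float
    lon_split_south: float
    lon_split_north: float


def block_partition(presence_coords: np.ndarray, background_coords: np.ndarray) -> BlockPartition:
    """Assign presences and background to 4 spatial blocks.

    Presences are split at their median latitude; each half is split at its
    own median longitude; background points are assigned by the same three
    boundaries.  Blocks are numbered 0..3 = (S,W), (S,E), (N,W), (N,E).
    """
    p = np.asarray(presence_coords, float)
    b = np.asarray(background_coords, float)
    if p.shape[0] < 4:
        raise ValueError("need at least 4 presences for a 4-block partition")
    if np.all(p == p[0]):
        raise ValueError("degenerate presence coordinates: all points identical")
    lat_split = float(np.median(p[:, 1]))
    south = p[:, 1] <= lat_split
    lon_s = float(np.median(p[south, 0])) if south.any() else np.nan
    lon_n = float(np.median(p[~south, 0])) if (~south).any() else np.nan

    def assign(coords: np.ndarray) -> np.ndarray:
        s = coords[:, 1] <= lat_split
        west = np.where(s, coords[:, 0] <= lon_s, coords[:, 0] <= lon_n)
        return np.where(s, 0, 2) + np.where(west, 0, 1)

    return BlockPartition(assign(p), assign(b), lat_split, lon_s, lon_n)


def aicc(model: MaxentResults, presence_env) -> tuple[int, float, float]:
    """(k, logL, AICc) of a fitted model.

    k counts coefficients with |lambda| > 1e-8; the log-likelihood evaluates
    each presence's raw probability renormalized over the training
    background.  AICc = 2k - 2 logL + 2k(k+1)/(n-k-1); if n <= k+1 the
    candidate is invalid and AICc is NaN.
    """
    k = model.k
    F = model.feature_set.transform(presence_env)
    logL = float((F @ model.params - model.log_Z).sum())
    n = F.shape[0]
    if n <= k + 1:
        return k, logL, float("nan")
    return k, logL, 2.0 * k - 2.0 * logL + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class TuningResult:
    """Candidate table of the feature-class x RM tuning grid and the selected row."""

    table: pd.DataFrame
    selected: int
    selected_model: MaxentResults

    @property
    def selected_row(self) -> pd.Series:
        return self.table.loc[self.selected]

    def summary(self) -> str:
        row = self.selected_row
        head = (
            f"Tuning grid: {len(self.table)} candidates; selected "
            f"{row['feature_classes']} @ RM={row['rm']} "
            f"(k={row['k']}, AICc={row['AICc']:.2f}, dAICc={row['delta_AICc']:.2f})"
        )
        return head + "\n" + self.table.to_string(index=False, float_format="%.3f")


def tune(
    presence_env,
    background_env,
    presence_coords: np.ndarray | None = None,
    background_coords: np.ndarray | None = None,
    class_combos: tuple[str, ...] = DEFAULT_CLASS_COMBOS,
    rms: tuple[float, ...] = DEFAULT_RMS,
    knots: int = 20,
    cv: bool = True,
    tol: float = 1e-5,
    max_iter: int = 10_000,
    base_penalties: dict[str, float] | None = None,
    range_label: str | None = None,
) -> TuningResult:
    """Fit the full feature-class x RM candidate grid and select by AICc.

    Every candidate is fitted on the full data for AICc; if ``cv`` and
    coordinates are given, 4-fold spatial-block test AUC is also computed.
    The selected candidate is the lowest-AICc model among those with
    dAICc < 2 (ties broken by fewer nonzero coefficients, then lower RM).
    """
    from .sdm_eval import auc  # local import to avoid a module cycle

    if isinstance(presence_env, pd.DataFrame):
        sample = pd.concat([presence_env, background_env], ignore_index=True)
    else:
        sample = np.vstack([presence_env, background_env])

    part = None
    if cv and presence_coords is not None and background_coords is not None:
        part = block_partition(presence_coords, background_coords)

    rows = []
    models: list[MaxentResults | None] = []
    for classes in class_combos:
        fs = build_features(sample, classes, knots)
        Fp = fs.transform(presence_env)
        Fb = fs.transform(background_env)
        cv_mats = None
        if part is not None:
            cv_mats = []
            for blk in range(4):
                tr_p = Fp[part.presence_block != blk]
                tr_b = Fb[part.background_block != blk]
                te_p = Fp[part.presence_block == blk]
                te_b = Fb[part.background_block == blk]
                cv_mats.append((tr_p, tr_b, te_p, te_b))
        for rm in sorted(rms, reverse=True):  # strongest shrinkage first
            try:
                res = fit_maxent(
                    presence_env,
                    background_env,
                    fs,
                    rm=rm,
                    base_penalties=base_penalties,
                    tol=tol,
                    max_iter=max_iter,
                    range_label=range_label,
                    _Fp=Fp,
                    _Fb=Fb,
                )
            except ConvergenceError as err:
                logger.warning("candidate %s RM=%s failed to converge: %s", classes, rm, err)
                rows.append(
                    dict(
                        feature_classes=classes,
                        rm=rm,
                        k=np.nan,
                        logL=np.nan,
                        AICc=np.nan,
                        mean_test_auc=np.nan,
                        valid=False,
                    )
                )
                models.append(None)
                continue
            k, logL, aic = aicc(res, presence_env)
            mean_auc = np.nan
            if cv_mats is not None:
                aucs = []
                for tr_p, tr_b, te_p, te_b in cv_mats:
                    if tr_p.shape[0] < 2 or te_p.shape[0] < 1 or te_b.shape[0] < 1:
                        continue
                    try:
                        cvres = fit_maxent(
                            tr_p, tr_b, fs, rm=rm, base_penalties=base_penalties,
                            tol=tol, max_iter=max_iter, _Fp=tr_p, _Fb=tr_b,
                        )
                    except ConvergenceError:
                        continue
                    sp = te_p @ cvres.params
                    sb = te_b @ cvres.params
                    aucs.append(auc(sp, sb))
                if aucs:
                    mean_auc = float(np.mean(aucs))
            rows.append(
                dict(
                    feature_classes=classes,
                    rm=rm,
                    k=k,
                    logL=logL,
                    AICc=aic,
                    mean_test_auc=mean_auc,
                    valid=bool(np.isfinite(aic)),
                )
            )
            models.append(res)

    table = pd.DataFrame(rows)
    valid = table["valid"] & np.isfinite(table["AICc"])
    if not valid.any():
        raise ValueError("all tuning candidates invalid (AICc undefined everywhere)")
    best = table.loc[valid, "AICc"].min()
    table["delta_AICc"] = table["AICc"] - best
    eligible = table.index[valid & (table["delta_AICc"] < 2.0)]
    order = table.loc[eligible].sort_values(["AICc", "k", "rm"]).index
    selected = int(order[0])
    sel_model = models[selected]
    assert sel_model is not None
    table = table[
        ["feature_classes", "rm", "k", "logL", "AICc", "delta_AICc", "mean_test_auc", "valid"]
    ]
    return TuningResult(table=table, selected=selected, selected_model=sel_model)
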