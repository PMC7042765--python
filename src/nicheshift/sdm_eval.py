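"""Suitability-model evaluation: AUC, continuous Boyce index, TSS, and the reciprocal report.

All three metrics treat the model's background sample as pseudo-absences.
AUC is the rank probability that a presence outscores a background point;
the continuous Boyce index (CBI) is the Spearman correlation between
suitability and the presence-to-expected frequency ratio across overlapping
suitability windows; TSS is max(sensitivity + specificity - 1) over
thresholds.  AUC and CBI/TSS are invariant under strictly monotone
transforms of the scores, so they can be computed on raw or cloglog output
interchangeably.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "auc",
    "boyce_index",
    "tss",
    "tss_at_threshold",
    "RangeData",
    "EvaluationReport",
    "reciprocal_report",
]


def auc(presence_scores, background_scores) -> float:
    """Rank-based AUC of presences vs background, ties counted 1/2."""
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if p.size == 0 or b.size == 0:
        raise ValueError("empty score vector")
    y = np.concatenate([np.ones(p.size), np.zeros(b.size)])
    s = np.concatenate([p, b])
    if np.all(s == s[0]):
        return 0.5
    return float(roc_auc_score(y, s))


def boyce_index(
    presence_scores,
    background_scores,
    n_windows: int = 101,
    window_width_fraction: float = 0.1,
) -> float:
    """Continuous Boyce index over overlapping suitability windows.

    Windows of width ``window_width_fraction`` x (score range) are slid
    across the pooled score range at ``n_windows`` positions.  Per window the
    predicted-to-expected ratio P/E = (fraction of presences) / (fraction of
    background) is computed; windows with no background are skipped.  CBI is
    the Spearman rank correlation between window midpoint and P/E, in
    [-1, 1].

    Raises
    ------
    ValueError
        If the score range is degenerate or fewer than 3 windows are valid.
    """
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if p.size == 0 or b.size == 0:
        raise ValueError("empty score vector")
    lo = min(p.min(), b.min())
    hi = max(p.max(), b.max())
    if not hi > lo:
        raise ValueError("degenerate score range: Boyce index undefined")
    w = window_width_fraction * (hi - lo)
    centers = np.linspace(lo + w / 2, hi - w / 2, n_windows)
    mids, ratios = [], []
    for c in centers:
        in_p = np.count_nonzero((p >= c - w / 2) & (p <= c + w / 2)) / p.size
        in_b = np.count_nonzero((b >= c - w / 2) & (b <= c + w / 2)) / b.size
        if in_b == 0:
            continue
        mids.append(c)
        ratios.append(in_p / in_b)
    if len(mids) < 3:
        raise ValueError("fewer than 3 valid windows: Boyce index undefined")
    rho = spearmanr(mids, ratios).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def _sens_spec(p: np.ndarray, b: np.ndarray, thresholds: np.ndarray):
    p_sorted = np.sort(p)
    b_sorted = np.sort(b)
    sens = 1.0 - np.searchsorted(p_sorted, thresholds, side="right") / p.size
    spec = np.searchsorted(b_sorted, thresholds, side="right") / b.size
    return sens, spec


def tss(presence_scores, background_scores) -> tuple[float, float]:
    """Max TSS over candidate thresholds, with the maximizing threshold.

    Background points are pseudo-absences; a point scores "presence" when
    its suitability is strictly above the threshold.  Candidate thresholds
    are the midpoints between consecutive distinct observed scores plus
    sentinels below and above the range, so the all-presence and all-absence
    classifications are included (TSS = 0 there).
    """
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if p.size == 0 or b.size == 0:
        raise ValueError("empty score vector")
    s = np.unique(np.concatenate([p, b]))
    mids = (s[:-1] + s[1:]) / 2 if s.size > 1 else np.empty(0)
    thresholds = np.concatenate([[s[0] - 1.0], mids, [s[-1] + 1.0]])
    sens, spec = _sens_spec(p, b, thresholds)
    score = sens + spec - 1.0
    i = int(np.argmax(score))
    return float(score[i]), float(thresholds[i])


def tss_at_threshold(presence_scores, background_scores, threshold: float) -> float:
    """TSS at a fixed (e.g. transferred) threshold."""
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    sens, spec = _sens_spec(p, b, np.array([threshold]))
    return float(sens[0] + spec[0] - 1.0)


# ---------------------------------------------------------------------------
# reciprocal report (Table-2 schema)
# ---------------------------------------------------------------------------


@dataclass
class RangeData:
    """Prepared inputs of one range for distribution modelling."""

    label: str
    presence_env: pd.DataFrame
    background_env: pd.DataFrame
    presence_coords: np.ndarray | None = None
    background_coords: np.ndarray | None = None


@dataclass
class EvaluationReport:
    """AUC / CBI / TSS for every train-range x eval-range combination.

    ``cells`` has one row per combination; ``tss`` uses the threshold
    maximized on the evaluation range, ``tss_transferred`` re-uses the
    threshold tuned on the model's own training range (the transferability
    variant, which can go negative on a failed transfer).
    """

    cells: pd.DataFrame

    def table(self, tss_policy: str = "optimized") -> pd.DataFrame:
        """Wide 3 x 4 layout: rows AUC / Boyce index / TSS, one column per combination."""
        tss_col = {"optimized": "tss", "transferred": "tss_transferred"}[tss_policy]
        cols = {}
        for _, row in self.cells.iterrows():
            cols[f"{row['train']} -> {row['eval']}"] = [
                row["auc"],
                row["cbi"],
                row[tss_col],
            ]
        return pd.DataFrame(cols, index=["AUC", "Boyce index", "TSS"])

    def to_csv(self, path: str | Path, tss_policy: str = "optimized") -> None:
        self.table(tss_policy).to_csv(path)

    def to_json(self, path: str | Path | None = None) -> dict:
        out = self.cells.to_dict(orient="records")
        if path is not None:
            Path(path).write_text(json.dumps(out, indent=2))
        return out


def _evaluate_pair(model, data: RangeData) -> dict:
    from .sdm_engine import predict

    sp = predict(model, data.presence_env, "cloglog")
    sb = predict(model, data.background_env, "cloglog")
    t, thr = tss(sp, sb)
    try:
        cbi = boyce_index(sp, sb)
    except ValueError as err:
        logger.warning("Boyce index undefined for eval range %s: %s", data.label, err)
        cbi = float("nan")
    return {
        "auc": auc(sp, sb),
        "cbi": cbi,
        "tss": t,
        "tss_threshold": thr,
        "n_presence": len(sp),
        "n_background": len(sb),
    }


def reciprocal_report(
    native: RangeData,
    invasive: RangeData,
    classes: str | dict[str, str] = "LQH",
    rm: float | dict[str, float] = 1.0,
    knots: int = 20,
    tol: float = 1e-5,
    max_iter: int = 10_000,
    base_penalties: dict[str, float] | None = None,
) -> EvaluationReport:
    """Fit one model per range and evaluate all four train x eval combinations.

    ``classes``/``rm`` are typically the settings selected by
    :func:`nicheshift.sdm_engine.tune`; pass a mapping ``{range_label: value}``
    to use each range's own tuned settings.  Each model predicts cloglog
    suitability for both ranges and is scored against the evaluation range's
    presences and background with AUC, CBI and TSS (both threshold
    policies).
    """
    from .sdm_engine import MaxentModel, predict

    def per_range(value, label):
        return value[label] if isinstance(value, dict) else value

    models = {
        d.label: MaxentModel(
            d.presence_env,
            d.background_env,
            classes=per_range(classes, d.label),
            knots=knots,
            rm=per_range(rm, d.label),
            base_penalties=base_penalties,
            range_label=d.label,
        ).fit(tol=tol, max_iter=max_iter)
        for d in (native, invasive)
    }
    data = {d.label: d for d in (native, invasive)}
    # training-range optimal thresholds, for the transferred-threshold TSS variant
    own_threshold = {}
    for label, model in models.items():
        d = data[label]
        own_threshold[label] = tss(
            predict(model, d.presence_env, "cloglog"),
            predict(model, d.background_env, "cloglog"),
        )[1]

    rows = []
    for train_label in (native.label, invasive.label):
        for eval_label in (native.label, invasive.label):
            model = models[train_label]
            d = data[eval_label]
            cell = _evaluate_pair(model, d)
            cell["tss_transferred"] = tss_at_threshold(
                predict(model, d.presence_env, "cloglog"),
                predict(model, d.background_env, "cloglog"),
                own_threshold[train_label],
            )
            rows.append({"train": train_label, "eval": eval_label, **cell})
    order = [
        (native.label, native.label),
        (native.label, invasive.label),
        (invasive.label, invasive.label),
        (invasive.label, native.label),
    ]
    cells = pd.DataFrame(rows)
    cells["__key"] = list(zip(cells["train"], cells["eval"]))
    cells = cells.set_index("__key").loc[order].reset_index(drop=True)
    return EvaluationReport(cells=cells)
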