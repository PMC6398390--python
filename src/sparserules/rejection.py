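"""Score calibration and the minimum-expected-cost accept/reject decision rule.

Raw ensemble scores f(x) are mapped to posterior probabilities
eta(x) = P(y = +1 | x) by isotonic regression (pool-adjacent-violators)
fitted on out-of-fold scores.  With misclassification cost 1 and rejection
cost d, the decision rule with smallest expected cost is

    +1  if eta > 1 - d
     0  (reject) if d <= eta <= 1 - d
    -1  if eta < d

so the rejection band [d, 1-d] shrinks to the single point {0.5} as
d -> 0.5.  An empirical operating mode is also provided that targets a
rejection *rate* directly by abstaining on the samples whose posterior is
closest to 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .optimizer import RuleModel, fit as _fit
from .rulespace import Dataset, InvalidConfigurationError

__all__ = [
    "CalibratedModel",
    "RejectionMetrics",
    "calibrate",
    "fit_isotonic_map",
    "decide",
    "decide_at_rejection_rate",
    "metrics",
    "accuracy_rejection_curve",
]

#: posterior clipping margin: outputs live in [CLIP, 1-CLIP]
CLIP = 1e-6


@dataclass
class IsotonicMap:
    """Monotone nondecreasing piecewise-linear score -> posterior map.

    Stored as breakpoints (x, y); evaluation linearly interpolates and
    extrapolates by constants beyond the fitted range.  Outputs are
    clipped to [CLIP, 1-CLIP].
    """

    x: np.ndarray
    y: np.ndarray

    def __call__(self, scores) -> np.ndarray:
        s = np.atleast_1d(np.asarray(scores, dtype=float))
        out = np.interp(s, self.x, self.y)
        return np.clip(out, CLIP, 1.0 - CLIP)


@dataclass
class CalibratedModel:
    """A fitted rule model together with its score -> posterior map."""

    base: RuleModel
    calibration_map: IsotonicMap
    folds: int = 5
    seed: int = 0

    def score(self, X) -> np.ndarray:
        return self.base.score(X)

    def predict_proba(self, X) -> np.ndarray:
        return self.calibration_map(self.base.score(X))

    def decide(self, X, d: float | None = None) -> np.ndarray:
        d = self.base.config.d if d is None else d
        return decide(self.predict_proba(X), d)


@dataclass
class RejectionMetrics:
    rejection_rate: float
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    n_classified: int
    n_rejected: int
    tp: int
    fp: int
    tn: int
    fn: int


def fit_isotonic_map(scores: np.ndarray, labels01: np.ndarray) -> IsotonicMap:
    """Pool-adjacent-violators fit of P(y=1 | score) with linear interpolation."""
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(np.asarray(scores, dtype=float), np.asarray(labels01, dtype=float))
    return IsotonicMap(x=np.asarray(iso.X_thresholds_), y=np.asarray(iso.y_thresholds_))


def calibrate(
    model: RuleModel, data: Dataset, folds: int = 5, seed: int = 0
) -> CalibratedModel:
    """Attach an out-of-fold isotonic calibration map to a fitted model.

    The rule model is refitted on each stratified fold-complement with the
    same configuration; held-out scores pooled over folds are regressed on
    the 0/1 labels by pool-adjacent-violators.  Calibrating on out-of-fold
    rather than training scores avoids the optimistic bias of the latter.
    """
    if folds < 2:
        raise InvalidConfigurationError("folds must be >= 2")
    counts = [int(np.sum(data.y == c)) for c in (-1, 1)]
    if min(counts) < folds:
        raise ValueError(
            f"cannot stratify {folds} folds: smallest class has {min(counts)} samples"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof_scores = np.empty(data.n)
    for tr, te in skf.split(data.X, data.y):
        sub = Dataset(
            X=data.X[tr], y=data.y[tr], feature_names=list(data.feature_names)
        )
        fold_model = _fit(sub, model.config)
        oof_scores[te] = fold_model.score(data.X[te])
    cal = fit_isotonic_map(oof_scores, (data.y == 1).astype(float))
    return CalibratedModel(base=model, calibration_map=cal, folds=folds, seed=seed)


def decide(eta, d: float):
    """Minimum-expected-cost decision: +1 / 0 (reject) / -1 from the posterior.

    Boundary values eta == d and eta == 1-d reject.
    """
    if not (0.0 < d <= 0.5):
        raise InvalidConfigurationError(f"rejection cost d must be in (0, 0.5], got {d}")
    e = np.atleast_1d(np.asarray(eta, dtype=float))
    if np.any((e < 0) | (e > 1)):
        raise ValueError("posterior eta must lie in [0, 1]")
    out = np.zeros(e.shape, dtype=int)
    out[e > 1.0 - d] = 1
    out[e < d] = -1
    return int(out[0]) if np.isscalar(eta) or np.asarray(eta).ndim == 0 else out


def decide_at_rejection_rate(etas, target_rr: float):
    """Abstain on the round(target_rr * n) samples with posterior closest to 0.5.

    The rejected count is the nearest-integer realization of the target
    rate (half rounds up), so the achieved rate is as close as possible to
    the requested one.  Remaining samples are classified by
    sign(eta - 0.5).  Ties in
    |eta - 0.5| are broken by sample order (stable sort), so classified
    subsets are nested along an increasing rejection-rate grid.

    Returns (decisions, achieved_rr, (band_lo, band_hi)) where the band is
    the interval of |eta - 0.5| distances that were rejected.
    """
    e = np.asarray(etas, dtype=float)
    if e.size == 0:
        raise ValueError("etas must be nonempty")
    if not (0.0 <= target_rr < 1.0):
        raise InvalidConfigurationError(f"target rejection rate must be in [0, 1), got {target_rr}")
    n = e.size
    n_rej = int(np.floor(target_rr * n + 0.5))
    dist = np.abs(e - 0.5)
    order = np.argsort(dist, kind="stable")
    decisions = np.where(e > 0.5, 1, -1)
    rejected = order[:n_rej]
    decisions[rejected] = 0
    band = (0.0, float(dist[rejected].max())) if n_rej else (0.0, 0.0)
    return decisions, n_rej / n, band


def metrics(decisions, y, etas=None) -> RejectionMetrics:
    """Confusion-matrix metrics on the classified (non-rejected) subset.

    AUC is computed rank-based (ties half-credit) from ``etas`` restricted
    to classified samples; NaN if etas are absent or one class is missing
    among classified samples.
    """
    dec = np.asarray(decisions, dtype=int)
    yy = np.asarray(y, dtype=int)
    if dec.shape != yy.shape:
        raise ValueError("decisions and y must have equal length")
    classified = dec != 0
    n_cls = int(classified.sum())
    if n_cls == 0:
        raise ValueError("all samples rejected; metrics undefined")
    d_c, y_c = dec[classified], yy[classified]
    tp = int(np.sum((d_c == 1) & (y_c == 1)))
    fp = int(np.sum((d_c == 1) & (y_c == -1)))
    tn = int(np.sum((d_c == -1) & (y_c == -1)))
    fn = int(np.sum((d_c == -1) & (y_c == 1)))
    sn = tp / (tp + fn) if tp + fn else float("nan")
    sp = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / n_cls
    auc = float("nan")
    if etas is not None:
        e_c = np.asarray(etas, dtype=float)[classified]
        if len(np.unique(y_c)) == 2:
            auc = float(roc_auc_score((y_c == 1).astype(int), e_c))
    return RejectionMetrics(
        rejection_rate=(dec.size - n_cls) / dec.size,
        accuracy=acc,
        sensitivity=sn,
        specificity=sp,
        auc=auc,
        n_classified=n_cls,
        n_rejected=dec.size - n_cls,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def accuracy_rejection_curve(etas, y, rr_grid):
    """Accuracy/AUC vs rejection rate table; classified subsets nest along the grid.

    Returns a pandas DataFrame with columns
    RR, ACC, AUC, n_classified, n_rejected, TP, FP, TN, FN.
    """
    import pandas as pd

    rows = []
    for rr in rr_grid:
        decisions, achieved, _band = decide_at_rejection_rate(etas, rr)
        m = metrics(decisions, y, etas)
        rows.append(
            {
                "RR": achieved,
                "ACC": m.accuracy,
                "AUC": m.auc,
                "n_classified": m.n_classified,
                "n_rejected": m.n_rejected,
                "TP": m.tp,
                "FP": m.fp,
                "TN": m.tn,
                "FN": m.fn,
            }
        )
    return pd.DataFrame(rows)
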