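"""Classification quality indicators, ROC, and external regression validation.

Classification indicators operate on confusion counts over the *predicted*
compounds only: models gated by an applicability domain (or a consensus rule
without quorum) may abstain, and the prediction rate PR = predicted/total
tracks the coverage that was traded for accuracy.

Two accuracy conventions circulate for such tables: the balanced form
(SP + SE)/2 and the standard form (TP + TN)/N over predicted compounds.
Both are computed; ``acc_standard`` is the headline value.  Reported
rounding is half-even at two decimals.

The external regression statistics go beyond R²/RMSE: Q²F3 references the
squared prediction error to the *training* variance, CCC (Lin's concordance
correlation) penalises location/scale bias, and rm² penalises the gap
between the ordinary and through-origin determination of observed on
predicted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import ACTIVE, INACTIVE

ABSTAIN = "abstain"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    n_total: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.tn, self.fp, self.fn)
        if any(c < 0 for c in counts):
            raise ValueError("confusion counts must be non-negative")
        if sum(counts) > self.n_total:
            raise ValueError("more predictions than offered compounds")

    @property
    def n_predicted(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(
    y_true: Sequence[str], y_pred: Sequence[str], n_total: int | None = None
) -> ConfusionCounts:
    """Confusion counts over non-abstaining predictions.

    ``y_pred`` entries may be ``"abstain"`` (or None), excluded from the
    counts but reflected in the prediction rate through ``n_total`` (defaults
    to the number of offered compounds).
    """
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors are not aligned")
    if n_total is None:
        n_total = len(y_true)
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if p is None or p == ABSTAIN:
            continue
        if t not in (ACTIVE, INACTIVE) or p not in (ACTIVE, INACTIVE):
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        if p == ACTIVE:
            tp += t == ACTIVE
            fp += t == INACTIVE
        else:
            tn += t == INACTIVE
            fn += t == ACTIVE
    return ConfusionCounts(tp, tn, fp, fn, n_total)


@dataclass(frozen=True)
class QualityReport:
    se: float
    sp: float
    acc_standard: float
    acc_balanced: float
    npv: float
    ppv: float
    mcc: float
    pr: float
    undefined: tuple[str, ...] = ()

    def rounded(self, decimals: int = 2) -> dict[str, float]:
        """Half-even rounding as used in printed report tables."""
        vals = {
            "SE": self.se,
            "SP": self.sp,
            "ACC": self.acc_standard,
            "ACC_balanced": self.acc_balanced,
            "NPV": self.npv,
            "PPV": self.ppv,
            "MCC": self.mcc,
            "PR": self.pr,
        }
        return {k: float(np.round(v, decimals)) for k, v in vals.items()}


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def quality_indicators(cc: ConfusionCounts) -> QualityReport:
    """SE, SP, accuracies, NPV, PPV, MCC and PR from confusion counts.

    Any indicator with a zero denominator is reported as 0 and listed in
    ``undefined`` (the usual MCC convention extended to the ratios so the
    report stays total).
    """
    undefined: list[str] = []
    tp, tn, fp, fn = cc.tp, cc.tn, cc.fp, cc.fn
    se = _ratio(tp, tp + fn, "SE", undefined)
    sp = _ratio(tn, tn + fp, "SP", undefined)
    acc_std = _ratio(tp + tn, cc.n_predicted, "ACC", undefined)
    acc_bal = (sp + se) / 2
    npv = _ratio(tn, tn + fn, "NPV", undefined)
    ppv = _ratio(tp, tp + fp, "PPV", undefined)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den == 0:
        undefined.append("MCC")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den)
    pr = _ratio(cc.n_predicted, cc.n_total, "PR", undefined)
    return QualityReport(se, sp, acc_std, acc_bal, npv, ppv, float(mcc), pr,
                         tuple(undefined))


def roc_curve(raw_scores: Sequence[float], y_true: Sequence[str]):
    """Staircase ROC over all score thresholds and its trapezoidal AUC.

    Returns ``(points, auc)`` with points an (k, 2) array of (FPR, TPR).
    """
    from sklearn import metrics as _skm

    y = np.array([1 if t == ACTIVE else 0 for t in y_true])
    if y.min() == y.max():
        raise ValueError("ROC needs at least one compound of each class")
    fpr, tpr, _ = _skm.roc_curve(y, np.asarray(raw_scores, dtype=float))
    return np.stack([fpr, tpr], axis=1), float(_skm.auc(fpr, tpr))


@dataclass(frozen=True)
class RegressionReport:
    r2: float
    rmse: float
    q2_f3: float
    ccc: float
    rm2: float
    r0_2: float
    undefined: tuple[str, ...] = ()


def regression_metrics(
    y_obs_ext: Sequence[float],
    y_pred_ext: Sequence[float],
    y_train: Sequence[float],
) -> RegressionReport:
    """External validation statistics of a regression model.

    * R² — squared Pearson correlation of observed vs predicted;
    * RMSE — root mean squared prediction error (pKi units);
    * Q²F3 = 1 − [Σ(obs−pred)²/n_ext] / [Σ(y_tr−ȳ_tr)²/n_tr];
    * CCC = 2·cov(obs,pred) / (var_obs + var_pred + (mean_obs − mean_pred)²);
    * rm² = R²·(1 − √(R² − R0²)) with R0² the through-origin determination of
      observed on predicted values.

    Zero variance in either vector leaves the correlation-based statistics
    undefined (reported 0 and flagged).
    """
    yo = np.asarray(y_obs_ext, dtype=float).ravel()
    yp = np.asarray(y_pred_ext, dtype=float).ravel()
    yt = np.asarray(y_train, dtype=float).ravel()
    if yo.shape != yp.shape:
        raise ValueError("observed/predicted vectors are not aligned")
    if yo.size == 0 or yt.size == 0:
        raise ValueError("empty input vectors")

    undefined: list[str] = []
    rmse = float(np.sqrt(np.mean((yo - yp) ** 2)))

    var_o = float(np.var(yo))  # population variances throughout
    var_p = float(np.var(yp))
    var_t = float(np.var(yt))

    if var_o == 0 or var_p == 0:
        undefined += ["R2", "CCC", "rm2"]
        r2 = ccc = rm2 = r0_2 = 0.0
    else:
        cov = float(np.mean((yo - yo.mean()) * (yp - yp.mean())))
        r2 = cov**2 / (var_o * var_p)
        ccc = 2 * cov / (var_o + var_p + (yo.mean() - yp.mean()) ** 2)
        # through-origin regression of observed on predicted
        k = float(np.sum(yo * yp) / np.sum(yp**2)) if np.sum(yp**2) > 0 else 0.0
        ss_res0 = float(np.sum((yo - k * yp) ** 2))
        ss_tot = float(np.sum((yo - yo.mean()) ** 2))
        r0_2 = 1.0 - ss_res0 / ss_tot
        rm2 = r2 * (1.0 - np.sqrt(max(r2 - r0_2, 0.0)))

    if var_t == 0:
        undefined.append("Q2F3")
        q2_f3 = 0.0
    else:
        q2_f3 = 1.0 - (np.mean((yo - yp) ** 2)) / var_t

    return RegressionReport(
        r2=float(r2),
        rmse=rmse,
        q2_f3=float(q2_f3),
        ccc=float(ccc),
        rm2=float(rm2),
        r0_2=float(r0_2),
        undefined=tuple(undefined),
    )
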