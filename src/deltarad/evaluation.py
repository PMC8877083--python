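"""Signature aggregation, fusion across modalities, and performance metrics.

A patient's signature per modality is the median of their test-set decision
values across repetitions. The fused signature averages the available
per-modality median signatures after standardizing each modality's signature
vector (raw SVM decision values from different models are not on a common
scale); patients missing a modality simply average over the ones they have.

AUC uses the rank (Mann-Whitney) formulation with ties counted 1/2; its 95% CI
comes from a stratified percentile bootstrap. Paired AUC comparison uses the
DeLong covariance-adjusted z-test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import ParameterError
from .model import SplitScheme, train_svm, zscore_apply, zscore_fit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def tnr(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclass
class MetricsReport:
    tag: str
    accuracy_mean: float
    accuracy_sd: float
    tpr_mean: float
    tpr_sd: float
    tnr_mean: float
    tnr_sd: float
    auc: float
    auc_ci: tuple[float, float]
    n_patients: int


def median_signature(records: pd.DataFrame, role: str = "test") -> pd.DataFrame:
    """Per-patient median score across repetitions, one column per modality.

    Patients never appearing in a test set for some modality come out NaN and
    are excluded from that modality's ROC.
    """
    sub = records[records["role"] == role]
    return sub.pivot_table(
        index="patient_id", columns="modality", values="score", aggfunc="median"
    )


def fuse(median_scores: pd.DataFrame, modalities=None, standardize: bool = True) -> pd.Series:
    """Average the available per-modality signatures into one score per patient.

    Each modality column is standardized (zero mean, unit SD over its non-missing
    patients) before averaging; a patient with a single available modality gets
    that modality's (standardized) score. Patients with no score are dropped.
    """
    df = median_scores if modalities is None else median_scores[list(modalities)]
    if standardize:
        df = (df - df.mean()) / df.std(ddof=0).replace(0.0, 1.0)
    fused = df.mean(axis=1, skipna=True)
    n_empty = int(fused.isna().sum())
    if n_empty:
        logger.info("dropping %d patients with no available signature", n_empty)
    return fused.dropna()


def roc_auc(
    labels, scores, n_boot: int = 2000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """AUC (rank formulation, ties = 1/2) with a stratified bootstrap 95% CI."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ParameterError("both classes required for ROC")
    auc = float(roc_auc_score(y, s))
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ip = rng.choice(pos, size=pos.size, replace=True)
        ineg = rng.choice(neg, size=neg.size, replace=True)
        idx = np.concatenate([ip, ineg])
        boots[i] = roc_auc_score(y[idx], s[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auc, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_placements(y: np.ndarray, s: np.ndarray):
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = pos.size, neg.size
    all_r = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    v10 = (all_r[:m] - r_pos) / n           # structural components per positive
    v01 = 1.0 - (all_r[m:] - r_neg) / m     # per negative
    auc = v10.mean()
    return auc, v10, v01


def compare_auc(scores_a, scores_b, labels) -> float:
    """Two-sided p-value of the paired DeLong test for AUC(a) == AUC(b).

    Both score vectors must refer to the same patients in the same order.
    Identical score vectors give p = 1.
    """
    y = np.asarray(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise ParameterError("paired comparison needs aligned score/label vectors")
    if len(np.unique(y)) < 2:
        raise ParameterError("both classes required")
    auc_a, v10a, v01a = _delong_placements(y, a)
    auc_b, v10b, v01b = _delong_placements(y, b)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 1e-15:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# comparator models
# ---------------------------------------------------------------------------

def recist_comparator(early_calls, final_labels) -> tuple[ConfusionMatrix, MetricsReport]:
    """Early radiological response call as a (training-free) predictor.

    ``early_calls`` and ``final_labels`` are aligned 0/1 vectors (1 = responder);
    missing calls (NaN) drop the patient with a log message.
    """
    calls = pd.Series(early_calls).astype(float)
    labels = pd.Series(final_labels).astype(float)
    ok = calls.notna() & labels.notna()
    if (~ok).any():
        logger.info("excluding %d patients with missing early calls", int((~ok).sum()))
    c = calls[ok].astype(int).to_numpy()
    y = labels[ok].astype(int).to_numpy()
    cm = ConfusionMatrix(
        tp=int(np.sum((c == 1) & (y == 1))),
        fn=int(np.sum((c == 0) & (y == 1))),
        fp=int(np.sum((c == 1) & (y == 0))),
        tn=int(np.sum((c == 0) & (y == 0))),
    )
    report = MetricsReport(
        tag="early_recist",
        accuracy_mean=cm.accuracy,
        accuracy_sd=0.0,
        tpr_mean=cm.tpr,
        tpr_sd=0.0,
        tnr_mean=cm.tnr,
        tnr_sd=0.0,
        auc=(cm.tpr + cm.tnr) / 2.0,  # ROC of a binary predictor
        auc_ci=(np.nan, np.nan),
        n_patients=int(ok.sum()),
    )
    return cm, report


def delta_volume_model(
    delta_volumes: pd.Series,
    labels: pd.Series,
    splits: SplitScheme,
    C: float = 1.0,
):
    """Single-feature comparator: the split scheme and SVM applied to delta volume.

    No preselection/PCA/SFFS is needed for one feature. Returns
    ``(records, metrics)`` in the same shape as the radiomic pipeline.
    """
    ids = delta_volumes.index.to_numpy()
    X = delta_volumes.to_numpy(dtype=float).reshape(-1, 1)
    y = labels.loc[delta_volumes.index].to_numpy()
    rec_rows, met_rows = [], []
    for rep, (tr, va, te) in enumerate(splits.repetitions):
        mean, sd = zscore_fit(X[tr])
        Ztr = zscore_apply(X[tr].copy(), mean, sd)
        svm = train_svm(Ztr, y[tr], C=C)
        for role, rows in (("validation", va), ("test", te)):
            if len(rows) == 0:
                continue
            Z = zscore_apply(X[rows].copy(), mean, sd)
            s = svm.decision_function(Z)
            pred = (s > 0).astype(int)
            for i, r in enumerate(rows):
                rec_rows.append(
                    {
                        "patient_id": ids[r],
                        "modality": "volume",
                        "repetition": rep,
                        "role": role,
                        "score": float(s[i]),
                        "predicted": int(pred[i]),
                    }
                )
            yy = y[rows]
            tp = int(np.sum((pred == 1) & (yy == 1)))
            fn = int(np.sum((pred == 0) & (yy == 1)))
            fp = int(np.sum((pred == 1) & (yy == 0)))
            tn = int(np.sum((pred == 0) & (yy == 0)))
            met_rows.append(
                {
                    "modality": "volume",
                    "repetition": rep,
                    "role": role,
                    "accuracy": (tp + tn) / len(yy),
                    "tpr": tp / (tp + fn) if tp + fn else np.nan,
                    "tnr": tn / (tn + fp) if tn + fp else np.nan,
                    "auc": float(roc_auc_score(yy, s))
                    if len(np.unique(yy)) == 2
                    else np.nan,
                    "tp": tp,
                    "fn": fn,
                    "fp": fp,
                    "tn": tn,
                }
            )
    return pd.DataFrame(rec_rows), pd.DataFrame(met_rows)


def aggregate_metrics(
    metrics: pd.DataFrame,
    labels: pd.Series,
    records: pd.DataFrame | None = None,
    tag: str = "",
    role: str = "test",
    seed: int = 0,
) -> MetricsReport:
    """Average per-repetition accuracy/TPR/TNR; AUC from per-patient median signatures."""
    sub = metrics[metrics["role"] == role]
    if records is not None:
        med = median_signature(records, role=role)
        col = med.columns[0]
        s = med[col].dropna()
        auc, ci = roc_auc(labels.loc[s.index].to_numpy(), s.to_numpy(), seed=seed)
        n = len(s)
    else:
        auc, ci, n = np.nan, (np.nan, np.nan), 0
    return MetricsReport(
        tag=tag,
        accuracy_mean=float(sub["accuracy"].mean()),
        accuracy_sd=float(sub["accuracy"].std(ddof=0)),
        tpr_mean=float(sub["tpr"].mean()),
        tpr_sd=float(sub["tpr"].std(ddof=0)),
        tnr_mean=float(sub["tnr"].mean()),
        tnr_sd=float(sub["tnr"].std(ddof=0)),
        auc=auc,
        auc_ci=ci,
        n_patients=n,
    )
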