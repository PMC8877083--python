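"""Signature model selection and classification.

Per modality and per repetition of a 100x stratified 55/25/20 split, the
pipeline is: stability whitelist -> train-set Z-score -> Wilcoxon rank-sum
preselection (p < 0.05) -> PCA keeping the components that reach 97%
cumulative variance (a semi-supervised PCA, since only outcome-associated
features enter it) -> sequential forward floating selection of components by
validation accuracy -> linear SVM. The continuous signature of a patient is
the signed SVM decision value (positive = responder).

All statistics (means, SDs, test p-values, PCA loadings, SVM weights) are
fitted on the training set only and applied unchanged to validation and test
rows.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .errors import ParameterError, SchemaError

logger = logging.getLogger(__name__)

FRACTIONS = (0.55, 0.25, 0.20)
N_REPETITIONS = 100
ALPHA = 0.05
VARIANCE_THRESHOLD = 0.97
FALLBACK_K = 5  # features kept when nothing passes the rank-sum screen


@dataclass(frozen=True)
class SplitScheme:
    """Repeated stratified train/validation/test partitions."""

    repetitions: tuple  # tuple of (train, val, test) integer index arrays
    fractions: tuple[float, float, float]
    seed: int

    def __len__(self):
        return len(self.repetitions)


def make_splits(
    labels,
    seed: int,
    n_reps: int = N_REPETITIONS,
    fractions: tuple[float, float, float] = FRACTIONS,
) -> SplitScheme:
    """Build stratified random 55/25/20 partitions, repeated ``n_reps`` times.

    Within each class the patient indices are shuffled and cut into
    round(f_train * n), round(f_val * n) and the remainder, so the responder
    proportion is equal across the three sets up to rounding.
    """
    y = np.asarray(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ParameterError("fractions must sum to 1")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ParameterError("need >=2 patients per class")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        tr, va, te = [], [], []
        for c in classes:
            idx = rng.permutation(np.flatnonzero(y == c))
            n_tr = int(round(fractions[0] * idx.size))
            n_va = int(round(fractions[1] * idx.size))
            # rounding on very small classes can starve the test set; keep >=1
            # member per class in the test set, shrinking validation first
            while idx.size - n_tr - n_va < 1:
                if n_va > 0:
                    n_va -= 1
                elif n_tr > 1:
                    n_tr -= 1
                else:
                    break
            tr.append(idx[:n_tr])
            va.append(idx[n_tr : n_tr + n_va])
            te.append(idx[n_tr + n_va :])
        reps.append(
            (
                np.sort(np.concatenate(tr)),
                np.sort(np.concatenate(va)),
                np.sort(np.concatenate(te)),
            )
        )
    return SplitScheme(repetitions=tuple(reps), fractions=tuple(fractions), seed=seed)


def zscore_fit(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and population SDs of the training matrix (zero SD kept as 0)."""
    if train.shape[0] < 2:
        raise ParameterError("need >=2 training rows")
    return train.mean(axis=0), train.std(axis=0)


def zscore_apply(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Standardize with train parameters; zero-SD columns map to 0."""
    out = X - mean
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return out


def apply_stability_whitelist(table: pd.DataFrame, whitelist) -> pd.DataFrame:
    """Column-subset a feature table to the acquisition-stable feature names.

    ``whitelist=None`` (no whitelist configured) is the identity.
    """
    if whitelist is None:
        return table
    names = list(whitelist)
    if len(set(names)) != len(names):
        raise SchemaError("duplicate names in whitelist")
    missing = [n for n in names if n not in table.columns]
    if missing:
        raise SchemaError(f"whitelist names absent from table: {missing[:5]}")
    return table[names]


def wilcoxon_preselect(
    X: np.ndarray, y: np.ndarray, alpha: float = ALPHA, fallback_k: int = FALLBACK_K
) -> np.ndarray:
    """Indices of features whose two-sample rank-sum test has p < alpha.

    Uses the Mann-Whitney U with normal approximation and tie correction. If
    no feature passes, falls back to the ``fallback_k`` smallest p-values so
    the downstream PCA is never empty.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ParameterError("training labels contain a single class")
    a, b = X[y == 1], X[y == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided", method="asymptotic")
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    keep = np.flatnonzero(p < alpha)
    if keep.size == 0:
        keep = np.sort(np.argsort(p, kind="stable")[:fallback_k])
        logger.info("rank-sum screen empty; falling back to %d smallest p", fallback_k)
    return keep


@dataclass
class PcaTransform:
    components: np.ndarray  # (k97, n_features) orthonormal rows
    mean: np.ndarray
    explained_variance_ratio: np.ndarray
    k97: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) @ self.components.T


def pca_fit(train: np.ndarray, var_threshold: float = VARIANCE_THRESHOLD) -> PcaTransform:
    """PCA of the training matrix, keeping the first k components whose
    cumulative explained-variance ratio reaches ``var_threshold``."""
    if train.shape[0] < 2 or train.shape[1] < 1:
        raise ParameterError("PCA needs >=2 rows and >=1 feature")
    pca = PCA(svd_solver="full")
    pca.fit(train)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    k97 = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    k97 = min(k97, len(evr))
    return PcaTransform(
        components=pca.components_[:k97].copy(),
        mean=pca.mean_.copy(),
        explained_variance_ratio=evr[:k97].copy(),
        k97=k97,
    )


def train_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> SVC:
    """Linear SVM; decision values are the continuous signatures
    (positive = responder, label threshold at 0)."""
    if len(np.unique(y)) < 2:
        raise ParameterError("training labels contain a single class")
    svm = SVC(kernel="linear", C=C)
    svm.fit(X, y)
    return svm


def score(svm: SVC, X: np.ndarray) -> np.ndarray:
    return svm.decision_function(X)


def _accuracy(svm: SVC, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(svm.predict(X) == y))


def sffs_select(
    train_Z: np.ndarray,
    val_Z: np.ndarray,
    y_train: np.ndarray,
    y_val: np.ndarray,
    max_k: int | None = None,
    C: float = 1.0,
) -> list[int]:
    """Sequential forward floating selection of principal components.

    Starting from the empty set, repeatedly adds the component that maximizes
    validation accuracy of an SVM trained on the training projections, then
    floats: removes components while removal strictly improves the best
    accuracy recorded for the smaller subset size. Ties break toward the
    lowest component index. Returns the visited subset with the highest
    validation accuracy (smallest size, then lexicographically smallest, on
    ties), as an ordered index list.
    """
    n_comp = train_Z.shape[1]
    if n_comp < 1:
        raise ParameterError("no components to select from")
    if max_k is None or max_k > n_comp:
        max_k = n_comp
    if val_Z.shape[0] == 0:
        # degenerate split (a class too small to populate validation): no
        # selection signal, keep every component
        logger.info("empty validation set; skipping component selection")
        return list(range(max_k))

    cache: dict[tuple[int, ...], float] = {}

    def evaluate(subset: tuple[int, ...]) -> float:
        if subset not in cache:
            svm = train_svm(train_Z[:, list(subset)], y_train, C=C)
            cache[subset] = _accuracy(svm, val_Z[:, list(subset)], y_val)
        return cache[subset]

    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    current: list[int] = []

    while len(current) < max_k:
        remaining = [c for c in range(n_comp) if c not in current]
        if not remaining:
            break
        accs = [evaluate(tuple(sorted(current + [c]))) for c in remaining]
        i_best = int(np.argmax(accs))  # argmax returns first max -> lowest index
        cand_acc = accs[i_best]
        k = len(current) + 1
        if k in best and cand_acc <= best[k][0]:
            break  # no addition improves
        current = current + [remaining[i_best]]
        best[k] = (cand_acc, tuple(current))
        # floating backward removals
        while len(current) > 2:
            sub_accs = [
                evaluate(tuple(sorted(s for s in current if s != r))) for r in current
            ]
            j = int(np.argmax(sub_accs))
            if sub_accs[j] > best[len(current) - 1][0]:
                removed = current[j]
                current = [s for s in current if s != removed]
                best[len(current)] = (sub_accs[j], tuple(current))
            else:
                break

    top = max(best.items(), key=lambda kv: (kv[1][0], -kv[0], tuple(-i for i in kv[1][1])))
    return list(top[1][1])


@dataclass
class FittedSignatureModel:
    """Everything fitted on one repetition's training set."""

    zscore_mean: np.ndarray
    zscore_sd: np.ndarray
    preselected: np.ndarray
    pca: PcaTransform
    sffs_components: list[int]
    svm_coef: np.ndarray
    svm_intercept: float
    svm: SVC = field(repr=False, default=None)


@dataclass
class PipelineConfig:
    alpha: float = ALPHA
    var_threshold: float = VARIANCE_THRESHOLD
    svm_C: float = 1.0
    max_k: int | None = None  # None -> k97 (no cap)
    whitelist: list[str] | None = None


def fit_one_repetition(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
) -> FittedSignatureModel:
    """Fit the whole selection + classification chain on one split.

    Missing values are imputed with the train-set feature mean before
    standardization (hence 0 after Z-scoring); nothing outside ``train_idx``
    and ``val_idx`` influences any fitted parameter.
    """
    Xtr_raw = X[train_idx]
    col_mean = np.nanmean(Xtr_raw, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)

    def prep(rows):
        M = X[rows].copy()
        nan = ~np.isfinite(M)
        if nan.any():
            M[nan] = np.broadcast_to(col_mean, M.shape)[nan]
        return M

    Xtr = prep(train_idx)
    mean, sd = zscore_fit(Xtr)
    Ztr = zscore_apply(Xtr, mean, sd)
    keep = wilcoxon_preselect(Ztr, y[train_idx], alpha=config.alpha)
    pca = pca_fit(Ztr[:, keep], var_threshold=config.var_threshold)
    Ttr = pca.transform(Ztr[:, keep])
    Zval = zscore_apply(prep(val_idx), mean, sd)
    Tval = pca.transform(Zval[:, keep])
    comps = sffs_select(
        Ttr, Tval, y[train_idx], y[val_idx], max_k=config.max_k, C=config.svm_C
    )
    svm = train_svm(Ttr[:, comps], y[train_idx], C=config.svm_C)
    return FittedSignatureModel(
        zscore_mean=mean,
        zscore_sd=sd,
        preselected=keep,
        pca=pca,
        sffs_components=comps,
        svm_coef=svm.coef_.copy(),
        svm_intercept=float(svm.intercept_[0]),
        svm=svm,
    )


def _signature_for(model: FittedSignatureModel, X: np.ndarray, rows: np.ndarray, col_mean):
    M = X[rows].copy()
    nan = ~np.isfinite(M)
    if nan.any():
        M[nan] = np.broadcast_to(col_mean, M.shape)[nan]
    Z = zscore_apply(M, model.zscore_mean, model.zscore_sd)
    T = model.pca.transform(Z[:, model.preselected])
    return score(model.svm, T[:, model.sffs_components])


def run_modality_pipeline(
    table: pd.DataFrame,
    labels: pd.Series,
    splits: SplitScheme,
    config: PipelineConfig = PipelineConfig(),
    modality: str = "",
):
    """Run the full per-repetition pipeline on one modality's delta table.

    Returns ``(records, metrics, models)``: per-patient per-repetition
    signature records for validation and test roles, per-repetition test/val
    metrics, and the fitted models.
    """
    table = apply_stability_whitelist(table, config.whitelist)
    ids = table.index.to_numpy()
    y = labels.loc[table.index].to_numpy()
    X = table.to_numpy(dtype=float)

    rec_rows = []
    met_rows = []
    models = []
    col_mean_cache = None
    for rep, (tr, va, te) in enumerate(splits.repetitions):
        model = fit_one_repetition(X, y, tr, va, config)
        col_mean = np.nanmean(X[tr], axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        for role, rows in (("validation", va), ("test", te)):
            if len(rows) == 0:
                continue
            s = _signature_for(model, X, rows, col_mean)
            pred = (s > 0).astype(int)
            for i, r in enumerate(rows):
                rec_rows.append(
                    {
                        "patient_id": ids[r],
                        "modality": modality,
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
            auc = float(roc_auc_score(yy, s)) if len(np.unique(yy)) == 2 else np.nan
            met_rows.append(
                {
                    "modality": modality,
                    "repetition": rep,
                    "role": role,
                    "accuracy": (tp + tn) / len(yy),
                    "tpr": tp / (tp + fn) if tp + fn else np.nan,
                    "tnr": tn / (tn + fp) if tn + fp else np.nan,
                    "auc": auc,
                    "tp": tp,
                    "fn": fn,
                    "fp": fp,
                    "tn": tn,
                }
            )
        models.append(model)
    records = pd.DataFrame(rec_rows)
    metrics = pd.DataFrame(met_rows)
    return records, metrics, models
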