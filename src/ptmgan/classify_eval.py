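"""Random-forest multiclass classification and its evaluation suite.

The classifier is a random forest (500 trees, sqrt(p) features per split by
default). Data are split 4/5 training / 1/5 independent test (stratified);
tenfold stratified cross-validation runs on the training 4/5. Inside every
fold the whole fitted context — PWM, correlation mask, GAN, scaler, forest —
sees training rows only, and evaluation rows are never synthetic.

Metrics: overall accuracy and error rate (E = 1 - Acc), the K-category
Matthews correlation coefficient, confusion entropy (CEN), per-class
one-vs-rest Acc/Sp/Sn/MCC/AUC with midrank AUC, the DeLong test for paired
AUC comparison, and scheme-grouped random-forest feature importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

from .encoders import SCHEME_ORDER, FeatureEncoder, FeatureMatrix, StructureTable
from .feature_filter import PccFilter
from .gan import GanConfig, augment_dataset


# ---------------------------------------------------------------------------
# splits

@dataclass
class SplitPlan:
    """Stratified 80/20 split plus stratified K folds over the 80%."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: list  # list of (fit_idx, val_idx) absolute row indices
    seed: int

    def __post_init__(self):
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test rows overlap")
        val_union = np.sort(np.concatenate([v for _, v in self.folds]))
        if not np.array_equal(val_union, np.sort(self.train_idx)):
            raise ValueError("folds do not partition the training rows")


def make_split(
    labels: np.ndarray, seed: int, n_folds: int = 10, test_fraction: float = 0.2
) -> SplitPlan:
    """Stratified independent split and CV plan; deterministic in ``seed``."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < max(n_folds, int(round(1 / test_fraction))):
        raise ValueError("a class is too small for stratified splitting")
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=seed
    )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [
        (train_idx[fit], train_idx[val])
        for fit, val in skf.split(train_idx, labels[train_idx])
    ]
    return SplitPlan(np.sort(train_idx), np.sort(test_idx), folds, seed)


# ---------------------------------------------------------------------------
# confusion-matrix metrics

def confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted (labels 1..K)."""
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[int(t) - 1, int(p) - 1] += 1
    return cm


def accuracy(cm: np.ndarray) -> float:
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def error_rate(cm: np.ndarray) -> float:
    return 1.0 - accuracy(cm)


def multiclass_mcc(cm: np.ndarray) -> float:
    """K-category correlation coefficient computed from the confusion matrix."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    t = cm.sum(axis=1)  # true-class margins
    p = cm.sum(axis=0)  # predicted-class margins
    num = total * np.trace(cm) - t @ p
    den = np.sqrt(total**2 - p @ p) * np.sqrt(total**2 - t @ t)
    if den == 0:
        warnings.warn("zero-variance margins; MCC defined as 0")
        return 0.0
    return float(np.clip(num / den, -1.0, 1.0))


def cen(cm: np.ndarray) -> float:
    """Confusion entropy of a K-class confusion matrix (K >= 2).

    For class j, misclassification probabilities
    ``P^j_{j,k} = C_{j,k} / sum_i (C_{j,i} + C_{i,j})`` (and symmetrically
    ``P^j_{k,j}``) feed a per-class entropy with logarithm base ``2(K-1)``
    over off-diagonal terms, weighted by the class mass
    ``w_j = sum_i (C_{j,i} + C_{i,j}) / (2 N)``.
    """
    cm = np.asarray(cm, dtype=float)
    K = cm.shape[0]
    if K < 2:
        raise ValueError("CEN needs at least two classes")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    base = 2.0 * (K - 1)
    value = 0.0
    for j in range(K):
        mass = cm[j, :].sum() + cm[:, j].sum()
        if mass == 0:
            continue
        w = mass / (2.0 * total)
        h = 0.0
        for k in range(K):
            if k == j:
                continue
            for pr in (cm[j, k] / mass, cm[k, j] / mass):
                if pr > 0:
                    h -= pr * np.log(pr) / np.log(base)
        value += w * h
    return float(value)


# ---------------------------------------------------------------------------
# ranks, AUC, DeLong

def _auc_midrank(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    truth = np.asarray(truth, dtype=bool)
    pos = truth.sum()
    neg = len(truth) - pos
    if pos == 0 or neg == 0:
        raise ValueError("AUC needs both positive and negative samples")
    ranks = rankdata(scores)
    return float((ranks[truth].sum() - pos * (pos + 1) / 2) / (pos * neg))


def per_class_metrics(
    cm: np.ndarray,
    scores: Optional[np.ndarray] = None,
    y_true: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """One-vs-rest Acc/Sp/Sn/MCC (and AUC when scores are given) per class.

    ``scores`` is the (n_samples, K) class-probability matrix aligned with
    ``y_true`` (labels 1..K); both may be omitted to get threshold metrics
    only.
    """
    cm = np.asarray(cm)
    K = cm.shape[0]
    total = cm.sum()
    rows = []
    for j in range(K):
        tp = cm[j, j]
        fn = cm[j, :].sum() - tp
        fp = cm[:, j].sum() - tp
        tn = total - tp - fn - fp
        sn = tp / (tp + fn) if tp + fn else 0.0
        sp = tn / (tn + fp) if tn + fp else 0.0
        acc = (tp + tn) / total
        den = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
        if den == 0:
            warnings.warn("degenerate one-vs-rest margins; MCC defined as 0")
            mcc = 0.0
        else:
            mcc = (tp * tn - fp * fn) / den
        row = {"class": j + 1, "Acc": acc, "Sp": sp, "Sn": sn, "MCC": mcc}
        if scores is not None:
            row["AUC"] = _auc_midrank(scores[:, j], np.asarray(y_true) == j + 1)
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")


def _delong_components(scores: np.ndarray, truth: np.ndarray):
    """Structural components (V10, V01) of the midrank AUC."""
    truth = np.asarray(truth, dtype=bool)
    pos_scores = scores[truth]
    neg_scores = scores[~truth]
    m, n = len(pos_scores), len(neg_scores)
    all_ranks = rankdata(scores)
    pos_ranks_local = rankdata(pos_scores)
    neg_ranks_local = rankdata(neg_scores)
    auc = (all_ranks[truth].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[truth] - pos_ranks_local) / n
    v01 = 1.0 - (all_ranks[~truth] - neg_ranks_local) / m
    return auc, v10, v01


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray, truth: np.ndarray):
    """Paired DeLong comparison of two correlated AUCs.

    Returns ``(auc_a, auc_b, p_value)`` with a two-sided normal p-value on
    the AUC difference. Identical scores give p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if not (len(scores_a) == len(scores_b) == len(truth)):
        raise ValueError("score vectors and truth must be aligned")
    if truth.all() or not truth.any():
        raise ValueError("truth must contain both classes")
    auc_a, v10_a, v01_a = _delong_components(scores_a, truth)
    auc_b, v10_b, v01_b = _delong_components(scores_b, truth)
    m, n = len(v10_a), len(v01_a)
    d10 = v10_a - v10_b
    d01 = v01_a - v01_b
    var = (np.var(d10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(d01, ddof=1) / n if n > 1 else 0.0
    )
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
    return float(auc_a), float(auc_b), p


# ---------------------------------------------------------------------------
# feature importance

def aggregate_importance(
    rf_model: RandomForestClassifier, provenance: pd.DataFrame
) -> tuple:
    """Sum impurity importances per encoding scheme; rank individual features.

    Returns ``(per_scheme, ranked)``: a Series of cumulative importance per
    scheme (descending) and a DataFrame of individual features with their
    scheme, tag and importance (descending).
    """
    imp = rf_model.feature_importances_
    if len(imp) != len(provenance):
        raise ValueError("provenance does not match the fitted feature count")
    ranked = provenance.assign(importance=imp).sort_values(
        "importance", ascending=False, kind="stable"
    )
    per_scheme = (
        ranked.groupby("scheme")["importance"].sum().sort_values(ascending=False)
    )
    return per_scheme, ranked.reset_index(drop=True)


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineOptions:
    """End-to-end options for one encode -> filter -> augment -> RF run."""

    schemes: Optional[tuple] = None
    structure: Optional[StructureTable] = None
    filter_mode: str = "feature-label"
    filter_threshold: float = 0.5
    augment: Optional[str] = None  # None | 'cgan' | 'cwgan'
    gan_config: GanConfig = field(default_factory=GanConfig)
    n_trees: int = 500
    max_features: str = "sqrt"
    n_folds: int = 10
    seed: int = 0


@dataclass
class FoldResult:
    """Outcome of one fitted fold: counts, scores and the fitted artifacts."""

    cm: np.ndarray
    scores: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    rf: RandomForestClassifier
    provenance: pd.DataFrame
    mask_kept: np.ndarray
    eval_synthetic: np.ndarray


def run_pipeline_fold(
    dataset,
    train_idx: np.ndarray,
    eval_idx: np.ndarray,
    options: Optional[PipelineOptions] = None,
) -> FoldResult:
    """Fit the whole pipeline on training rows, evaluate on held-out rows.

    PWM fitting, correlation screening, GAN training and forest fitting all
    see training rows only; synthetic rows are appended to the training side
    and never evaluated.
    """
    options = options or PipelineOptions()
    frags = dataset.fragments
    y = dataset.y
    K = dataset.class_set.n_classes
    train_frags = [frags[i] for i in train_idx]
    eval_frags = [frags[i] for i in eval_idx]
    y_train, y_eval = y[train_idx], y[eval_idx]

    schemes = options.schemes or SCHEME_ORDER
    enc = FeatureEncoder(schemes=schemes, structure=options.structure)
    fm_train = enc.fit(train_frags).transform(train_frags)
    fm_eval = enc.transform(eval_frags)

    filt = PccFilter(options.filter_mode, options.filter_threshold)
    fm_train = filt.fit_transform(fm_train, y_train)
    fm_eval = filt.transform(fm_eval)

    X_train, y_fit = fm_train.X, y_train
    synthetic_train = np.zeros(len(X_train), dtype=bool)
    if options.augment is not None:
        X_train, y_fit, synthetic_train, _ = augment_dataset(
            X_train, y_train, options.augment, options.gan_config
        )

    rf = RandomForestClassifier(
        n_estimators=options.n_trees,
        max_features=options.max_features,
        random_state=options.seed,
        n_jobs=1,
    )
    rf.fit(X_train, y_fit)
    proba = rf.predict_proba(fm_eval.X)
    # align score columns with class indices 1..K
    scores = np.zeros((len(eval_idx), K))
    for col, cls in enumerate(rf.classes_):
        scores[:, int(cls) - 1] = proba[:, col]
    y_pred = np.asarray(rf.classes_)[np.argmax(proba, axis=1)]
    cm = confusion(y_eval, y_pred, K)
    return FoldResult(
        cm=cm,
        scores=scores,
        y_true=y_eval,
        y_pred=y_pred,
        rf=rf,
        provenance=fm_train.provenance,
        mask_kept=filt.mask_.kept,
        eval_synthetic=np.zeros(len(eval_idx), dtype=bool),
    )


def metrics_report(cm: np.ndarray, scores=None, y_true=None) -> dict:
    """Bundle the overall metrics (and per-class table) into one dict."""
    report = {
        "Acc": accuracy(cm),
        "MCC": multiclass_mcc(cm),
        "CEN": cen(cm),
        "E": error_rate(cm),
    }
    report["per_class"] = per_class_metrics(cm, scores, y_true)
    return report
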