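"""Metrics, cross-validation harness and the strategy benchmark.

Sensitivity, specificity and accuracy are the standard confusion-matrix
ratios; for multi-class problems sensitivity and specificity are
macro-averaged over one-vs-rest tables (micro averaging available).  The
*good detection rate* (GDR) is reported as macro-averaged per-class recall
— an interpretation, clearly labelled as such.  All metrics are reported
as percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dbn_elm import BBNELMClassifier
from .de_hfcm_ewt import DEHFCMEWTFeatures
from .graph_features import DynamicGraphWeights, GraphEntropyFeatures
from .lmd_lssvm import (DimScaler, FCMEncoder, LMDFeatures,
                        LSSVMClassifier, TunedLSSVMClassifier)
from .manifold import LLC, LTSA, TrialSummaryFeatures
from .trials import TrialSet

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionSummary",
    "confusion_summary",
    "metrics",
    "gdr",
    "crossval",
    "baseline_classifiers",
    "run_benchmark",
]


@dataclass
class ConfusionSummary:
    """One-vs-rest TP/FP/TN/FN counts per class."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    n_classes: int


def confusion_summary(y_true, y_pred, n_classes: int | None = None) -> ConfusionSummary:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    tp = np.zeros(n_classes)
    fp = np.zeros(n_classes)
    tn = np.zeros(n_classes)
    fn = np.zeros(n_classes)
    total = len(y_true)
    for c in range(n_classes):
        tp[c] = np.sum((y_true == c) & (y_pred == c))
        fp[c] = np.sum((y_true != c) & (y_pred == c))
        fn[c] = np.sum((y_true == c) & (y_pred != c))
        tn[c] = total - tp[c] - fp[c] - fn[c]
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn, n_classes=n_classes)


def metrics(cs: ConfusionSummary, average: str = "macro") -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) in [0, 1].

    Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP), averaged over
    one-vs-rest classes; classes with an empty denominator are skipped
    (logged).  Accuracy is the overall fraction correct.
    """
    if average not in ("macro", "micro"):
        raise ValueError("average must be 'macro' or 'micro'")
    total = cs.tp.sum() + cs.fn.sum()
    accuracy = float(cs.tp.sum() / total) if total else float("nan")
    if average == "micro":
        sens = float(cs.tp.sum() / max(cs.tp.sum() + cs.fn.sum(), 1))
        spec = float(cs.tn.sum() / max(cs.tn.sum() + cs.fp.sum(), 1))
        return sens, spec, accuracy
    sens_terms, spec_terms = [], []
    for c in range(cs.n_classes):
        if cs.tp[c] + cs.fn[c] > 0:
            sens_terms.append(cs.tp[c] / (cs.tp[c] + cs.fn[c]))
        else:
            logger.info("class %d absent from y_true; sensitivity skipped", c)
        if cs.tn[c] + cs.fp[c] > 0:
            spec_terms.append(cs.tn[c] / (cs.tn[c] + cs.fp[c]))
    sens = float(np.mean(sens_terms)) if sens_terms else float("nan")
    spec = float(np.mean(spec_terms)) if spec_terms else float("nan")
    return sens, spec, accuracy


def gdr(y_true, y_pred) -> float:
    """Good detection rate as macro-averaged per-class recall, in percent.

    Classes absent from ``y_true`` are excluded (logged).
    """
    cs = confusion_summary(y_true, y_pred)
    sens, _, _ = metrics(cs)
    return 100.0 * sens


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def crossval(X: np.ndarray, y: np.ndarray, estimator, folds: int = 5,
             seed: int = 0) -> dict:
    """Stratified k-fold evaluation; returns mean and SD of sensitivity,
    specificity, accuracy and GDR (all in percent)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < folds]
    if len(small):
        raise ValueError(f"classes {small.tolist()} have fewer than "
                         f"{folds} members")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for tr, te in skf.split(X, y):
        model = clone(estimator).fit(X[tr], y[tr])
        y_hat = model.predict(X[te])
        cs = confusion_summary(y[te], y_hat, n_classes=len(classes))
        sens, spec, acc = metrics(cs)
        rows.append([100 * sens, 100 * spec, 100 * acc, gdr(y[te], y_hat)])
    arr = np.array(rows)
    keys = ["sen", "spe", "acc", "gdr"]
    out = {k: float(np.nanmean(arr[:, i])) for i, k in enumerate(keys)}
    out.update({f"{k}_sd": float(np.nanstd(arr[:, i]))
                for i, k in enumerate(keys)})
    return out


def baseline_classifiers(seed: int = 0) -> dict:
    """The four reference classifiers (standardized inputs)."""
    return {
        "svm": make_pipeline(StandardScaler(), SVC(C=10.0, kernel="rbf")),
        "adaboost": make_pipeline(StandardScaler(),
                                  AdaBoostClassifier(random_state=seed)),
        "nbc": make_pipeline(StandardScaler(), GaussianNB()),
        "knn": make_pipeline(StandardScaler(),
                             KNeighborsClassifier(n_neighbors=5)),
    }


# ---------------------------------------------------------------------------
# Benchmark
# ---------------------------------------------------------------------------

def _rows_strategy1(ts: TrialSet, folds, seed, window_s, decimate_to):
    rows = []
    extractors = [
        ("dynamic-graph", DynamicGraphWeights(window_s=window_s,
                                              decimate_to=decimate_to)),
        ("dynamic-graph+entropy", GraphEntropyFeatures(window_s=window_s,
                                                       decimate_to=decimate_to)),
    ]
    y = ts.labels
    for name, extractor in extractors:
        X = extractor.transform(ts)
        for clf_name, clf in baseline_classifiers(seed).items():
            res = crossval(X, y, clf, folds=folds, seed=seed)
            rows.append({"method": name, "classifier": clf_name, **res})
    return rows


def _rows_strategy2(ts: TrialSet, folds, seed, embed_dim, n_neighbors):
    # LTSA/LLC have no out-of-sample extension, so the label-free embedding
    # is computed on the full set and the classifier is cross-validated on
    # the embedded coordinates.
    rows = []
    y = ts.labels
    P = TrialSummaryFeatures().transform(ts)
    d = min(embed_dim, P.shape[1] - 1)
    reducers = [
        ("ltsa", LTSA(n_components=d, n_neighbors=n_neighbors)),
        ("llc", LLC(n_components=d, n_neighbors=n_neighbors,
                    n_models=4, local_dim=min(d, 5), random_state=seed)),
    ]
    clf = BBNELMClassifier(hidden_layers=(32, 16), epochs=10, bp_epochs=20,
                           random_state=seed)
    for name, reducer in reducers:
        Q = reducer.fit_transform(P)
        res = crossval(Q, y, clf, folds=folds, seed=seed)
        rows.append({"method": name, "classifier": "pso-bbn-elm", **res})
    return rows


def _rows_strategy3(ts: TrialSet, folds, seed, ablations, n_bands):
    rows = []
    y = ts.labels
    for ablation in ablations:
        X = DEHFCMEWTFeatures(n_bands=n_bands, ablation=ablation).transform(ts)
        for clf_name, clf in baseline_classifiers(seed).items():
            res = crossval(X, y, clf, folds=folds, seed=seed)
            rows.append({"method": ablation, "classifier": clf_name, **res})
    return rows


def _rows_strategy4(ts: TrialSet, folds, seed, n_clusters, tune_hybrid=False):
    rows = []
    y = ts.labels
    lmd_X = LMDFeatures().transform(ts)
    summary_X = TrialSummaryFeatures().transform(ts)
    variants = [
        ("lmd", lmd_X, False),
        ("fcm", summary_X, True),
        ("lmd-fcm", lmd_X, True),
    ]
    kernels = [
        ("lssvm-linear", LSSVMClassifier(kernel="linear", gamma_reg=100.0)),
        ("lssvm-poly", LSSVMClassifier(kernel="poly", degree=2,
                                       gamma_reg=100.0)),
        ("lssvm-hybrid",
         TunedLSSVMClassifier(random_state=seed) if tune_hybrid else
         LSSVMClassifier(kernel="hybrid", mix_weight=0.5, sigma2=1.0,
                         gamma_reg=100.0)),
    ]
    for name, X, use_fcm in variants:
        for clf_name, clf in kernels:
            steps = [StandardScaler()]
            if use_fcm:
                steps.append(FCMEncoder(n_clusters=n_clusters,
                                        random_state=seed))
            steps.append(DimScaler())
            steps.append(clf)
            res = crossval(X, y, make_pipeline(*steps), folds=folds, seed=seed)
            rows.append({"method": name, "classifier": clf_name, **res})
    return rows


def run_benchmark(ts: TrialSet, methods=("strategy1", "strategy2",
                                         "strategy3", "strategy4"),
                  folds: int = 5, seed: int = 0,
                  window_s: float = 0.25, decimate_to: float = 1000.0,
                  embed_dim: int = 10, n_neighbors: int = 15,
                  ablations=("full",), n_bands: int = 5,
                  n_clusters: int = 8, tune_hybrid: bool = False) -> pd.DataFrame:
    """Cross-validated benchmark of the requested strategies on a trial set.

    Returns one row per (feature method, classifier) with mean and SD of
    sensitivity, specificity, accuracy and GDR in percent.
    """
    valid = {"strategy1", "strategy2", "strategy3", "strategy4"}
    unknown = set(methods) - valid
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; "
                         f"valid keys: {sorted(valid)}")
    rows: list[dict] = []
    if "strategy1" in methods:
        rows += _rows_strategy1(ts, folds, seed, window_s, decimate_to)
    if "strategy2" in methods:
        rows += _rows_strategy2(ts, folds, seed, embed_dim, n_neighbors)
    if "strategy3" in methods:
        rows += _rows_strategy3(ts, folds, seed, ablations, n_bands)
    if "strategy4" in methods:
        rows += _rows_strategy4(ts, folds, seed, n_clusters,
                                tune_hybrid=tune_hybrid)
    columns = ["method", "classifier", "sen", "spe", "acc", "gdr",
               "sen_sd", "spe_sd", "acc_sd", "gdr_sd"]
    return pd.DataFrame(rows, columns=columns)
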