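"""Risk models: logistic regression with ROC/AUC, and the SVM protocol.

Two multivariable logistic models are compared:

* model 1 (clinical): sex, age, left-atrial diameter, GFR, mechanical
  ventilation time;
* model 2 (clinical + ECG): model 1 plus Pmax, Pstd and PWd.

Model discrimination is summarised by the AUC via the Mann–Whitney identity
(ties counted 1/2) with a 95% DeLong confidence interval.

The machine-learning protocol splits the cohort 7:3 inside the minority
(POAF) class, matches the majority training subsample to it (class-balanced
training), and evaluates either on everything left over (scheme A) or on a
class-balanced test subsample (scheme B).  An RBF-kernel SVM is tuned by
grid search over (C, gamma) with stratified five-fold cross-validation, and
accuracy / sensitivity / specificity come from the confusion matrix with the
POAF class positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ArgumentError, DataError, TemporalLeakageWarning

__all__ = [
    "LogisticModelResult",
    "SplitScheme",
    "SvmResult",
    "MODEL1_PREDICTORS",
    "MODEL2_PREDICTORS",
    "fit_logistic",
    "fit_reference_models",
    "roc_auc",
    "make_splits",
    "tune_svm",
    "train_svm",
    "evaluate_svm",
    "run_svm_protocol",
    "default_c_grid",
    "default_gamma_grid",
]

MODEL1_PREDICTORS = ["sex", "age", "la", "gfr", "mech_vent"]
MODEL2_PREDICTORS = MODEL1_PREDICTORS + ["pmax", "pstd", "pwd"]


@dataclass
class LogisticModelResult:
    """Fitted logistic model plus its ROC summary."""

    predictors: list[str]
    params: pd.Series
    conf_int: pd.DataFrame          # 95% CI per coefficient
    probabilities: np.ndarray       # per-patient predicted P(outcome=1)
    auc: float
    auc_ci: tuple[float, float]
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    separation_flag: bool = False


@dataclass
class SplitScheme:
    """Train/test index partition for the SVM protocol."""

    scheme: str
    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    train_counts: tuple[int, int]   # (class 0, class 1)
    test_counts: tuple[int, int]

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise DataError("train and test sets overlap")


@dataclass
class SvmResult:
    """Tuned hyperparameters and confusion-matrix metrics (POAF positive)."""

    c_penalty: float
    gamma: float
    cv_accuracy: float
    train_ac: float
    test_ac: float
    test_sen: float
    test_spe: float
    tn: int
    fp: int
    fn: int
    tp: int


# --------------------------------------------------------------------------
# Logistic models and ROC


def fit_logistic(table: pd.DataFrame, predictors: Sequence[str],
                 outcome: str = "poaf") -> LogisticModelResult:
    """Maximum-likelihood logistic regression with intercept.

    Raises on a non-binary outcome, a constant predictor, or a singular
    design; flags (but does not fail on) perfect separation, where the MLE
    diverges yet the ranking of predicted probabilities is still usable for
    ROC analysis.
    """
    y = table[outcome].to_numpy(dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ArgumentError("outcome must be binary with both classes present")
    X = table[list(predictors)].to_numpy(dtype=float)
    const = [p for p, col in zip(predictors, X.T) if np.ptp(col) == 0]
    if const:
        raise ArgumentError(f"constant predictor(s): {', '.join(const)}")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DataError(
            "singular design matrix; collinear predictors among: "
            + ", ".join(predictors))

    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception:  # e.g. PerfectSeparationError on older statsmodels
            separated = True
            fit = sm.Logit(y, design).fit_regularized(disp=0, alpha=1e-6,
                                                      maxiter=500)
        for w in caught:
            if "separation" in str(w.message).lower() or \
                    "converge" in str(w.message).lower():
                separated = True
    # Diverging coefficients also indicate separation.
    if np.max(np.abs(np.asarray(fit.params))) > 50:
        separated = True

    names = ["const", *predictors]
    params = pd.Series(np.asarray(fit.params), index=names)
    try:
        ci = pd.DataFrame(np.asarray(fit.conf_int()), index=names,
                          columns=["ci_low", "ci_high"])
    except Exception:
        ci = pd.DataFrame(np.nan, index=names, columns=["ci_low", "ci_high"])
    probs = np.asarray(fit.predict(design), dtype=float)
    auc, lo, hi = roc_auc(probs, y)
    fpr, tpr, _ = roc_curve(y, probs)
    return LogisticModelResult(
        predictors=list(predictors), params=params, conf_int=ci,
        probabilities=probs, auc=auc, auc_ci=(lo, hi),
        roc_fpr=fpr, roc_tpr=tpr, separation_flag=separated)


def fit_reference_models(table: pd.DataFrame, outcome: str = "poaf",
                         ) -> tuple[LogisticModelResult, LogisticModelResult]:
    """Fit the clinical model and the clinical+ECG model on one cohort.

    Emits a temporal-leakage warning: mechanical ventilation time is a
    postoperative quantity, so these models describe association, not a
    purely preoperative prediction.
    """
    warnings.warn(
        "mechanical ventilation time is postoperative; its use as a "
        "predictor leaks post-outcome information",
        TemporalLeakageWarning, stacklevel=2)
    m1 = fit_logistic(table, MODEL1_PREDICTORS, outcome)
    m2 = fit_logistic(table, MODEL2_PREDICTORS, outcome)
    return m1, m2


def _midrank(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata
    return rankdata(x, method="average")


def roc_auc(scores: np.ndarray, labels: np.ndarray,
            ) -> tuple[float, float, float]:
    """AUC by the Mann–Whitney identity, 95% CI by DeLong's method.

    AUC = P(score of a random positive > score of a random negative), ties
    counted 1/2.  The DeLong variance uses the placement values of each
    class; the CI is the normal approximation clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ArgumentError("both classes must be present")
    allv = np.concatenate([pos, neg])
    tz = _midrank(allv)
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n            # placements of positives
    v10 = 1.0 - (tz[m:] - ty) / m      # placements of negatives
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    half = 1.959963984540054 * np.sqrt(var)
    return float(auc), float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


# --------------------------------------------------------------------------
# SVM protocol


def make_splits(labels: np.ndarray, scheme: str = "A", seed: int = 0,
                train_fraction: float = 0.7) -> SplitScheme:
    """Class-balanced 7:3 train/test split, scheme A or B.

    The minority class (1) is split with floor(train_fraction · n1) cases in
    training and the remainder in test; the same number of class-0 cases is
    drawn for training.  Scheme A tests on every remaining patient; scheme B
    tests on a random class-0 subsample matched in size to the class-1 test
    set.  Deterministic under ``seed``.
    """
    scheme = scheme.upper()
    if scheme not in ("A", "B"):
        raise ArgumentError("scheme must be 'A' or 'B'")
    labels = np.asarray(labels, dtype=int)
    idx0 = np.flatnonzero(labels == 0)
    idx1 = np.flatnonzero(labels == 1)
    n1_train = int(np.floor(train_fraction * idx1.size))
    n1_test = idx1.size - n1_train
    if n1_train < 1 or n1_test < 1:
        raise ArgumentError("class 1 too small for the requested ratio")
    if idx0.size < n1_train + n1_test:
        raise ArgumentError("class 0 too small for a class-balanced split")
    rng = np.random.default_rng(seed)
    idx1 = rng.permutation(idx1)
    idx0 = rng.permutation(idx0)
    train1, test1 = idx1[:n1_train], idx1[n1_train:]
    train0, rest0 = idx0[:n1_train], idx0[n1_train:]
    test0 = rest0 if scheme == "A" else rest0[:n1_test]
    train = np.sort(np.concatenate([train0, train1]))
    test = np.sort(np.concatenate([test0, test1]))
    return SplitScheme(scheme=scheme, seed=seed, train_idx=train,
                       test_idx=test,
                       train_counts=(train0.size, train1.size),
                       test_counts=(test0.size, test1.size))


def default_c_grid() -> np.ndarray:
    """Log-spaced C in 10^[-2, 3], 6 points per decade."""
    return np.logspace(-2, 3, 31)


def default_gamma_grid() -> np.ndarray:
    """Log-spaced gamma in 10^[-3, 2], 6 points per decade."""
    return np.logspace(-3, 2, 31)


def _svm_pipeline(c: float, gamma: float) -> Pipeline:
    # Standardisation is fit on the training folds only (pipeline semantics).
    return Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(C=c, gamma=gamma, kernel="rbf")),
    ])


def tune_svm(train_x: np.ndarray, train_y: np.ndarray,
             c_grid: Sequence[float] | None = None,
             gamma_grid: Sequence[float] | None = None,
             k: int = 5, seed: int = 0) -> tuple[float, float, float]:
    """Grid-search (C, gamma) by stratified k-fold CV accuracy.

    Ties break toward smaller C, then smaller gamma (the grids are scanned
    in ascending order with a strict-improvement rule).  Returns
    (C, gamma, best CV accuracy); deterministic under ``seed``.
    """
    train_x = np.asarray(train_x, dtype=float)
    train_y = np.asarray(train_y, dtype=int)
    counts = np.bincount(train_y, minlength=2)
    if k > counts.min():
        raise ArgumentError(
            f"k={k} exceeds the smaller class count {counts.min()}")
    c_grid = np.sort(np.asarray(c_grid if c_grid is not None
                                else default_c_grid(), dtype=float))
    gamma_grid = np.sort(np.asarray(gamma_grid if gamma_grid is not None
                                    else default_gamma_grid(), dtype=float))
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(cv.split(train_x, train_y))
    best = (-np.inf, np.nan, np.nan)
    for c in c_grid:
        for g in gamma_grid:
            accs = []
            for tr, te in folds:
                pipe = _svm_pipeline(c, g)
                pipe.fit(train_x[tr], train_y[tr])
                accs.append(pipe.score(train_x[te], train_y[te]))
            acc = float(np.mean(accs))
            if acc > best[0] + 1e-12:
                best = (acc, c, g)
    return float(best[1]), float(best[2]), float(best[0])


def train_svm(train_x: np.ndarray, train_y: np.ndarray, c: float,
              gamma: float) -> Pipeline:
    """Fit the standardise+SVC pipeline on the full training set."""
    pipe = _svm_pipeline(c, gamma)
    pipe.fit(np.asarray(train_x, dtype=float), np.asarray(train_y, dtype=int))
    return pipe


def evaluate_svm(model: Pipeline, test_x: np.ndarray, test_y: np.ndarray,
                 ) -> dict[str, float]:
    """Confusion-matrix metrics on a test set, POAF (class 1) positive.

    Ac = (TP+TN)/N, Sen = TP/(TP+FN), Spe = TN/(TN+FP); single-class
    denominators yield NaN rather than an error.
    """
    test_y = np.asarray(test_y, dtype=int)
    if test_y.size == 0:
        raise ArgumentError("test set is empty")
    pred = model.predict(np.asarray(test_x, dtype=float))
    tn, fp, fn, tp = confusion_matrix(test_y, pred, labels=[0, 1]).ravel()
    ac = (tp + tn) / test_y.size
    sen = tp / (tp + fn) if (tp + fn) else np.nan
    spe = tn / (tn + fp) if (tn + fp) else np.nan
    return {"ac": float(ac), "sen": float(sen), "spe": float(spe),
            "tn": int(tn), "fp": int(fp), "fn": int(fn), "tp": int(tp)}


def run_svm_protocol(features: np.ndarray, labels: np.ndarray,
                     scheme: str = "A", seed: int = 0,
                     c_grid: Sequence[float] | None = None,
                     gamma_grid: Sequence[float] | None = None,
                     k: int = 5) -> SvmResult:
    """Split, tune, train and evaluate; one Table-3-style result row."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    split = make_splits(labels, scheme=scheme, seed=seed)
    xtr, ytr = features[split.train_idx], labels[split.train_idx]
    xte, yte = features[split.test_idx], labels[split.test_idx]
    c, gamma, cv_acc = tune_svm(xtr, ytr, c_grid, gamma_grid, k=k, seed=seed)
    model = train_svm(xtr, ytr, c, gamma)
    train_metrics = evaluate_svm(model, xtr, ytr)
    test_metrics = evaluate_svm(model, xte, yte)
    return SvmResult(
        c_penalty=c, gamma=gamma, cv_accuracy=cv_acc,
        train_ac=train_metrics["ac"],
        test_ac=test_metrics["ac"], test_sen=test_metrics["sen"],
        test_spe=test_metrics["spe"],
        tn=test_metrics["tn"], fp=test_metrics["fp"],
        fn=test_metrics["fn"], tp=test_metrics["tp"])
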