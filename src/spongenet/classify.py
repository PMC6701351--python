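"""Lymph-node-metastasis prediction harness.

Samples are labelled +1 (non-LNM) and -1 (LNM). Candidate descriptors (hub
genes from the coexpression network) are screened by Pearson correlation
with the label — descriptors with |r| < 0.1 are deleted, and an optional
second stage keeps only descriptors whose correlation test reaches p < 0.05.
Four standard classifiers (logistic regression, random forest, k nearest
neighbors, Gaussian naive Bayes) are then evaluated under three schemes:
stratified 5-fold cross-validation, ten random stratified 3:2 train/test
splits, and leave-one-out. AUC and precision are computed on the pooled
held-out predictions of each scheme, and calibration points come from the
pooled probabilities in ten equal-width bins.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, precision_score, roc_auc_score
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

NON_LNM, LNM = 1, -1            # the label convention: LNM is the positive class
SCHEMES = ("cv5", "random_split", "loo")
CLASSIFIERS = ("LR", "RF", "kNN", "NB")
DEFAULT_R_THRESHOLD = 0.1


@dataclasses.dataclass
class EvaluationReport:
    """Per-classifier x scheme metrics plus calibration-curve points."""

    auc: pd.DataFrame            # classifiers x schemes
    precision: pd.DataFrame
    accuracy: pd.DataFrame
    calibration: dict[tuple[str, str], pd.DataFrame]
    seed: int


def screen_features(
    values: pd.DataFrame,
    labels: Sequence[int],
    candidates: Sequence[str] | None = None,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    p_threshold: float | None = None,
) -> pd.DataFrame:
    """Correlation screen of descriptors against the +1/-1 LNM label.

    ``values`` is features x samples. Returns a table (feature, r, p, kept);
    a feature is kept when |r| >= r_threshold and, if ``p_threshold`` is
    given, additionally p < p_threshold. Constant descriptors are deleted
    with a warning (their correlation is undefined).
    """
    y = np.asarray(labels, dtype=float)
    feats = list(candidates) if candidates is not None else list(values.index)
    rows = []
    for f in feats:
        x = values.loc[f].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("descriptor %s is constant — deleted", f)
            rows.append((f, np.nan, np.nan, False))
            continue
        r, p = stats.pearsonr(x, y)
        kept = abs(r) >= r_threshold and (p_threshold is None or p < p_threshold)
        rows.append((f, float(r), float(p), bool(kept)))
    return pd.DataFrame(rows, columns=["feature", "r", "p", "kept"])


def naive_bayes_posterior(
    priors: Sequence[float],
    likelihoods: Sequence[float],
    evidence: float | None = None,
    floor: float = 1e-300,
) -> np.ndarray:
    """Bayes rule P(A|B) = P(B|A) P(A) / P(B) over a set of classes.

    ``evidence`` defaults to sum(prior * likelihood); a zero evidence is
    floored with a log entry so a posterior is always defined.
    """
    priors = np.asarray(priors, dtype=float)
    lik = np.asarray(likelihoods, dtype=float)
    if evidence is None:
        evidence = float((priors * lik).sum())
    if evidence <= 0:
        logger.warning("zero evidence density — floored at %g", floor)
        evidence = floor
    return priors * lik / evidence


def gaussian_class_posterior(
    x: Sequence[float],
    class_params: dict[int, tuple[Sequence[float], Sequence[float]]],
    priors: dict[int, float],
) -> dict[int, float]:
    """Naive-Bayes posterior for one sample with per-feature Gaussians.

    ``class_params[c] = (means, sds)``; features are treated as
    conditionally independent given the class.
    """
    x = np.asarray(x, dtype=float)
    classes = sorted(class_params)
    lik = []
    for c in classes:
        mu, sd = (np.asarray(v, dtype=float) for v in class_params[c])
        lik.append(float(np.prod(stats.norm.pdf(x, mu, sd))))
    post = naive_bayes_posterior([priors[c] for c in classes], lik)
    return dict(zip(classes, post))


def _make_classifiers(seed: int) -> dict[str, object]:
    return {
        "LR": make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, C=1.0)
        ),
        "RF": RandomForestClassifier(
            n_estimators=100, max_features="sqrt", random_state=seed
        ),
        "kNN": make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5)),
        "NB": GaussianNB(),
    }


def _splits(scheme: str, y: np.ndarray, seed: int):
    if scheme == "cv5":
        return StratifiedKFold(n_splits=5, shuffle=True, random_state=seed).split(
            np.zeros_like(y), y
        )
    if scheme == "random_split":
        return StratifiedShuffleSplit(
            n_splits=10, test_size=0.4, random_state=seed
        ).split(np.zeros_like(y), y)
    if scheme == "loo":
        return LeaveOneOut().split(np.zeros_like(y))
    raise ValueError(f"unknown scheme: {scheme}")


def evaluate(
    values: pd.DataFrame,
    labels: Sequence[int],
    signatures: Sequence[str] | None = None,
    schemes: Sequence[str] = SCHEMES,
    seed: int = 0,
    n_calibration_bins: int = 10,
) -> EvaluationReport:
    """Run all four classifiers under the requested validation schemes.

    ``values`` is features x samples; metrics are computed on predictions
    pooled over held-out folds (every sample is held out exactly once under
    cv5/loo; under random_split the pool concatenates the ten test sets).
    """
    X_all = values.loc[signatures].T.to_numpy(dtype=float) if signatures is not None \
        else values.T.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2 or min(np.bincount((y == LNM).astype(int))) < 2:
        raise ValueError("need >=2 samples in each class")

    auc = pd.DataFrame(index=list(CLASSIFIERS), columns=list(schemes), dtype=float)
    precision = auc.copy()
    accuracy = auc.copy()
    calibration: dict[tuple[str, str], pd.DataFrame] = {}

    for name in CLASSIFIERS:
        for scheme in schemes:
            pooled_p, pooled_pred, pooled_y = [], [], []
            for split_i, (tr, te) in enumerate(_splits(scheme, y, seed)):
                if len(np.unique(y[tr])) < 2:
                    raise ValueError(f"{scheme}: a training fold lost a class")
                clf = _make_classifiers(seed + split_i)[name]
                clf.fit(X_all[tr], y[tr])
                proba = clf.predict_proba(X_all[te])
                pos_col = list(clf.classes_).index(LNM)
                pooled_p.append(proba[:, pos_col])
                pooled_pred.append(clf.predict(X_all[te]))
                pooled_y.append(y[te])
            p = np.concatenate(pooled_p)
            pred = np.concatenate(pooled_pred)
            truth = np.concatenate(pooled_y)
            auc.loc[name, scheme] = roc_auc_score(truth == LNM, p)
            precision.loc[name, scheme] = precision_score(
                truth, pred, pos_label=LNM, zero_division=0
            )
            accuracy.loc[name, scheme] = accuracy_score(truth, pred)
            calibration[(name, scheme)] = calibration_points(
                p, truth == LNM, n_bins=n_calibration_bins
            )
    return EvaluationReport(auc, precision, accuracy, calibration, seed)


def calibration_points(
    probabilities: np.ndarray,
    outcomes: np.ndarray,
    n_bins: int = 10,
) -> pd.DataFrame:
    """(mean predicted, observed rate, count) per equal-width probability bin.

    Empty bins are skipped; a perfectly calibrated model tracks the identity
    line within binomial noise.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(probabilities, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        rows.append(
            (float(probabilities[mask].mean()), float(outcomes[mask].mean()),
             int(mask.sum()))
        )
    return pd.DataFrame(rows, columns=["mean_predicted", "observed_rate", "n"])


def report_to_frame(report: EvaluationReport) -> pd.DataFrame:
    """Long-format table: method x scheme x {auc, precision, accuracy}."""
    rows = []
    for name in report.auc.index:
        for scheme in report.auc.columns:
            rows.append(
                (name, scheme, report.auc.loc[name, scheme],
                 report.precision.loc[name, scheme],
                 report.accuracy.loc[name, scheme])
            )
    return pd.DataFrame(rows, columns=["method", "scheme", "auc", "precision", "accuracy"])
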