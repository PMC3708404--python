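"""Discriminative basis selection and leave-one-out classification.

Binary labels in {-1, +1} are attached to the per-sample coefficients of a
fitted coding.  Each basis gets a point-biserial correlation — the Pearson
correlation between its coefficient column and the label vector — and bases
are ranked by correlation magnitude: a strongly anti-correlated basis is
just as discriminative as a correlated one.  Classification keeps only the
top-ranked coefficients as features and evaluates with leave-one-out
cross-validation using a linear SVM or a k-nearest-neighbour classifier,
the protocol appropriate to ensembles of a few dozen volumes.

Two fold hygiene modes are provided for the end-to-end experiment: the
default refits the coding and the selection inside every fold so the
held-out sample never influences its own features (no leakage); a "pooled"
mode fits the coding and selection once on all samples and cross-validates
only the classifier, which is cheaper and matches how such pipelines are
often run in practice, at the cost of optimistic selection bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .gndpca import fit_gndpca, project_core
from .ltc import encode, fit_ltc

__all__ = [
    "LabeledCoefficients",
    "SelectionResult",
    "basis_label_correlation",
    "select_bases",
    "loo_classify",
    "classification_experiment",
]


@dataclass
class LabeledCoefficients:
    """Coefficient matrix (M x J) paired with binary labels in {-1, +1}."""

    coefficients: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_2d(np.asarray(self.coefficients, dtype=np.float64))
        self.labels = np.asarray(self.labels, dtype=np.float64).ravel()
        if self.coefficients.shape[0] != self.labels.size:
            raise ValueError(
                f"{self.coefficients.shape[0]} coefficient rows for {self.labels.size} labels"
            )
        if not set(np.unique(self.labels)) <= {-1.0, 1.0}:
            raise ValueError("labels must take values in {-1, +1}")
        if np.unique(self.labels).size < 2:
            raise ValueError("both classes must be present")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def n_bases(self) -> int:
        return self.coefficients.shape[1]


@dataclass
class SelectionResult:
    """Per-basis label correlations and the magnitude ranking."""

    correlations: np.ndarray   # signed point-biserial r per basis
    ranking: np.ndarray        # basis indices, |r| descending, ties by index
    selected: np.ndarray       # first k of the ranking


def _pearson(x: np.ndarray, y: np.ndarray, coupled_denominator: bool = False) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    if coupled_denominator:
        # variant with denominator sqrt(sum (x_i - xbar)^2 (y_i - ybar)^2);
        # kept for comparison only — it is not scale-invariant and is not a
        # correlation coefficient.
        denom = np.sqrt(np.sum(xc**2 * yc**2))
    else:
        denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0.0:
        raise ValueError("correlation undefined: constant column or single class")
    return float(np.sum(xc * yc) / denom)


def basis_label_correlation(
    lc: LabeledCoefficients, basis_index: int, coupled_denominator: bool = False
) -> float:
    """Point-biserial correlation of one coefficient column with the labels.

    This is the ordinary Pearson correlation specialized to a binary
    second variable; it lies in [-1, 1] and flips sign under a label flip.
    ``coupled_denominator`` switches to a nonstandard coupled-denominator variant
    retained for comparison.
    """
    if not 0 <= basis_index < lc.n_bases:
        raise ValueError(f"basis_index {basis_index} out of range [0, {lc.n_bases})")
    return _pearson(lc.coefficients[:, basis_index], lc.labels, coupled_denominator)


def select_bases(lc: LabeledCoefficients, k: int) -> SelectionResult:
    """Rank bases by |correlation| descending and keep the top k.

    Ties in magnitude resolve to the lower basis index.  A constant
    coefficient column gets correlation 0 (it carries no label signal)
    rather than raising, so selection works on degenerate columns too.
    """
    if not 1 <= k <= lc.n_bases:
        raise ValueError(f"k must be in [1, {lc.n_bases}], got {k}")
    corrs = np.empty(lc.n_bases)
    for j in range(lc.n_bases):
        try:
            corrs[j] = basis_label_correlation(lc, j)
        except ValueError:
            corrs[j] = 0.0
    ranking = np.argsort(-np.abs(corrs), kind="stable")
    return SelectionResult(correlations=corrs, ranking=ranking, selected=ranking[:k])


def _make_classifier(classifier: str, params: dict | None):
    params = dict(params or {})
    standardize = params.pop("standardize", True)
    if classifier == "svm":
        params.setdefault("kernel", "linear")
        params.setdefault("C", 1.0)
        clf = SVC(**params)
    elif classifier == "knn":
        params.setdefault("n_neighbors", 3)
        clf = KNeighborsClassifier(**params)
    else:
        raise ValueError(f"unknown classifier {classifier!r}; use 'svm' or 'knn'")
    if standardize:
        return make_pipeline(StandardScaler(), clf)
    return clf


def loo_classify(
    features: np.ndarray,
    labels: np.ndarray,
    classifier: str = "svm",
    params: dict | None = None,
) -> tuple[float, np.ndarray]:
    """Leave-one-out accuracy of a classifier on a feature matrix.

    Each sample is predicted by a classifier trained on the other M-1;
    features are z-scored on the training part of every fold (distance- and
    margin-based classifiers are sensitive to the decaying coefficient
    scales; disable with ``params={"standardize": False}``).  Returns the
    fraction correct and the per-sample predictions; a fold whose training
    set is single-class is skipped with a warning and its prediction is
    NaN, excluded from the accuracy denominator.
    """
    x = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if x.shape[0] == 1 and np.asarray(labels).size > 1:
        x = x.T
    y = np.asarray(labels, dtype=np.float64).ravel()
    if x.shape[0] != y.size:
        raise ValueError("features and labels disagree on the number of samples")
    if y.size < 2:
        raise ValueError("leave-one-out needs at least two samples")

    preds = np.full(y.size, np.nan)
    for i in range(y.size):
        train = np.arange(y.size) != i
        if np.unique(y[train]).size < 2:
            warnings.warn(f"fold {i} skipped: training set is single-class", UserWarning)
            continue
        clf = _make_classifier(classifier, params)
        clf.fit(x[train], y[train])
        preds[i] = clf.predict(x[i][None, :])[0]
    valid = ~np.isnan(preds)
    if not valid.any():
        raise ValueError("no valid leave-one-out fold (labels too degenerate)")
    accuracy = float(np.mean(preds[valid] == y[valid]))
    return accuracy, preds


def _ltc_fold_features(
    train_samples, test_sample, train_labels, max_bases, select_k, gndpca_opts
):
    """Fit the coding on the training fold, optionally select, encode all."""
    model = fit_ltc(train_samples, max_bases=max_bases, gndpca_opts=gndpca_opts)
    train_feats = model.coefficients
    test_feats = encode(model, test_sample)
    if select_k is not None:
        sel = select_bases(LabeledCoefficients(train_feats, train_labels), select_k)
        train_feats = train_feats[:, sel.selected]
        test_feats = test_feats[sel.selected]
    return train_feats, test_feats


def classification_experiment(
    samples: Sequence[np.ndarray],
    labels: Sequence[float],
    method: str,
    classifiers: Sequence[str] = ("svm", "knn"),
    fold_mode: str = "refit",
    max_bases: int = 50,
    select_k: int = 5,
    core_ranks: tuple[int, ...] | None = None,
    classifier_params: dict | None = None,
    gndpca_opts: dict | None = None,
) -> dict:
    """End-to-end leave-one-out benchmark for one feature-building method.

    ``method`` chooses the features: ``"ltc_all"`` (all coding
    coefficients), ``"ltc_selected"`` (the ``select_k`` most
    label-correlated coefficients) or ``"gndpca"`` (the flattened core
    tensor; ``core_ranks`` defaults to ``min(mode size, 20, 20, 3)``
    per mode, the core size used for full-resolution volumes scaled to the
    input).  ``fold_mode="refit"`` refits model and selection inside every
    fold; ``"pooled"`` fits once on all samples and cross-validates only
    the classifier.  Returns ``{"method", "fold_mode", "n_samples",
    results: {classifier: {"accuracy", "n_correct", "predictions"}}}``.
    """
    y = np.asarray(labels, dtype=np.float64).ravel()
    vols = [np.asarray(s, dtype=np.float64) for s in samples]
    if len(vols) != y.size:
        raise ValueError("samples and labels disagree on length")
    if method not in ("ltc_all", "ltc_selected", "gndpca"):
        raise ValueError(f"unknown method {method!r}")
    if fold_mode not in ("refit", "pooled"):
        raise ValueError(f"unknown fold_mode {fold_mode!r}")
    m = len(vols)
    shape = vols[0].shape
    if core_ranks is None:
        target = (20, 20, 3) if len(shape) == 3 else (20,) * len(shape)
        core_ranks = tuple(min(i, t) for i, t in zip(shape, target))
    sel_k = select_k if method == "ltc_selected" else None

    results: dict[str, dict] = {}
    if fold_mode == "pooled":
        if method == "gndpca":
            gmodel = fit_gndpca(vols, core_ranks=core_ranks, **(gndpca_opts or {}))
            feats = np.stack([project_core(gmodel, v).ravel() for v in vols])
        else:
            lmodel = fit_ltc(vols, max_bases=max_bases, gndpca_opts=gndpca_opts)
            feats = lmodel.coefficients
            if sel_k is not None:
                sel = select_bases(LabeledCoefficients(feats, y), sel_k)
                feats = feats[:, sel.selected]
        for clf_name in classifiers:
            acc, preds = loo_classify(feats, y, classifier=clf_name, params=classifier_params)
            results[clf_name] = {
                "accuracy": acc,
                "n_correct": int(np.nansum(preds == y)),
                "predictions": preds,
            }
    else:
        preds_by_clf = {c: np.full(m, np.nan) for c in classifiers}
        for i in range(m):
            train_idx = [j for j in range(m) if j != i]
            y_train = y[train_idx]
            if np.unique(y_train).size < 2:
                warnings.warn(f"fold {i} skipped: training set is single-class", UserWarning)
                continue
            train_vols = [vols[j] for j in train_idx]
            if method == "gndpca":
                gmodel = fit_gndpca(train_vols, core_ranks=core_ranks, **(gndpca_opts or {}))
                x_train = np.stack([project_core(gmodel, v).ravel() for v in train_vols])
                x_test = project_core(gmodel, vols[i]).ravel()
            else:
                x_train, x_test = _ltc_fold_features(
                    train_vols, vols[i], y_train, max_bases, sel_k, gndpca_opts
                )
            for clf_name in classifiers:
                clf = _make_classifier(clf_name, classifier_params)
                clf.fit(x_train, y_train)
                preds_by_clf[clf_name][i] = clf.predict(x_test[None, :])[0]
        for clf_name in classifiers:
            preds = preds_by_clf[clf_name]
            valid = ~np.isnan(preds)
            results[clf_name] = {
                "accuracy": float(np.mean(preds[valid] == y[valid])),
                "n_correct": int(np.nansum(preds == y)),
                "predictions": preds,
            }

    return {
        "method": method,
        "fold_mode": fold_mode,
        "n_samples": m,
        "results": results,
    }
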