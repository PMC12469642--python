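"""Discriminability evaluation: PCA scores + multinomial logistic regression.

Mirrors the published evaluation protocol: samples are projected onto the
first two principal components of the gene-centered log2 expression matrix
and a multinomial logistic regression is fit and evaluated *on the same
samples*. The reported accuracy is therefore a training-set (resubstitution)
measure of separability, not a prediction claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, confusion_matrix

from .io import SampleTable, ValidationError


@dataclass(frozen=True)
class ClassificationReport:
    pc_scores: np.ndarray                 # samples x n_components
    explained_variance_fractions: np.ndarray
    confusion: np.ndarray                 # 3 x 3, rows true, cols predicted
    accuracy: float
    labels: tuple[str, ...]
    feature_set_label: str


def pca_scores(
    logexpr: pd.DataFrame,
    genes: list[str] | None = None,
    n_components: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Project samples onto principal components of gene-centered log2
    expression.

    ``logexpr`` is genes x samples. Genes (features) are mean-centered; no
    unit-variance scaling. Components come from the SVD of the centered
    samples x genes matrix with a deterministic sign convention: the
    largest-magnitude gene loading of each component is made positive.
    Returns (scores, explained variance fractions).
    """
    sub = logexpr if genes is None else logexpr.loc[genes]
    X = sub.to_numpy(dtype=float).T           # samples x genes
    n_samples, n_genes = X.shape
    if n_components > min(n_samples - 1, n_genes):
        raise ValidationError(
            f"n_components={n_components} exceeds min(n_samples - 1, n_genes)"
        )
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(n_components):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U[:, :n_components] * s[:n_components]
    var = s ** 2
    fractions = var[:n_components] / var.sum() if var.sum() > 0 else var[:n_components]
    return scores, fractions


def fit_eval_logreg(
    scores: np.ndarray,
    samples: SampleTable,
    ridge_lambda: float = 1e-4,
    feature_set_label: str = "",
) -> ClassificationReport:
    """Multinomial logistic regression on PC scores, trained and evaluated
    on the same samples (a separability measure).

    A small ridge penalty (lambda = 1e-4 by default) keeps the fit finite on
    perfectly separable data.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(samples.conditions)
    classes = [c for c in samples.labels if c in set(labels)]
    if len(classes) < 2:
        raise ValidationError("classification needs at least 2 conditions present")
    model = LogisticRegression(
        C=1.0 / ridge_lambda, solver="lbfgs", max_iter=10000
    )
    model.fit(scores, labels)
    pred = model.predict(scores)
    conf = confusion_matrix(labels, pred, labels=list(samples.labels))
    acc = float(accuracy_score(labels, pred))
    # variance fractions belong to the PCA step; filled by evaluate_features
    return ClassificationReport(
        pc_scores=scores,
        explained_variance_fractions=np.array([]),
        confusion=conf,
        accuracy=acc,
        labels=tuple(samples.labels),
        feature_set_label=feature_set_label,
    )


def evaluate_features(
    logexpr: pd.DataFrame,
    samples: SampleTable,
    genes: list[str] | None = None,
    n_components: int = 2,
    ridge_lambda: float = 1e-4,
    feature_set_label: str = "",
) -> ClassificationReport:
    """PCA on the given gene subset, then logistic regression on the PCs."""
    scores, fractions = pca_scores(logexpr, genes=genes, n_components=n_components)
    report = fit_eval_logreg(
        scores, samples, ridge_lambda=ridge_lambda,
        feature_set_label=feature_set_label,
    )
    return ClassificationReport(
        pc_scores=report.pc_scores,
        explained_variance_fractions=fractions,
        confusion=report.confusion,
        accuracy=report.accuracy,
        labels=report.labels,
        feature_set_label=feature_set_label,
    )


def report_to_dict(report: ClassificationReport) -> dict:
    return {
        "feature_set": report.feature_set_label,
        "accuracy": report.accuracy,
        "labels": list(report.labels),
        "confusion": report.confusion.tolist(),
        "explained_variance_fractions":
            np.asarray(report.explained_variance_fractions).tolist(),
    }
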