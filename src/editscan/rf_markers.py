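"""Iterative random-forest marker-gene selection with LDA validation.

Workflow: restrict an expression matrix to male samples, drop genes below an
expression floor in every sample, move to natural-log scale, optionally
restrict to a curated panel, then repeatedly fit random forests (each with a
fresh sub-seed) and record which genes most frequently rank among the top
features by importance. The resulting panel is validated by leave-one-out
linear-discriminant classification and visualized through the first two
principal components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from editscan.errors import ValidationError
from editscan.pileup_io import ExpressionMatrix, GenePanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RFConfig:
    n_iterations: int = 10_000
    trees_per_forest: int = 500
    top_k_per_iteration: int = 10
    n_select: int = 40
    seed: int = 0
    importance: str = "gini"  # or "permutation"

    def __post_init__(self) -> None:
        for name in ("n_iterations", "trees_per_forest", "top_k_per_iteration", "n_select"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.importance not in ("gini", "permutation"):
            raise ValidationError(f"unknown importance {self.importance!r}")


@dataclass
class MarkerSelection:
    selection_freq: pd.Series  # gene -> fraction of iterations recorded
    selected: list[str]
    lda_accuracy: float | None = None
    pc_scores: pd.DataFrame | None = None


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x [PC1, PC2]
    degenerate_pc2: bool


def preprocess(expr: ExpressionMatrix, min_level: float = 1.0) -> ExpressionMatrix:
    """Male-only subset, low-expression filter, natural-log transform.

    Genes whose expression is below ``min_level`` in ALL retained samples are
    removed; remaining values become ln(value + 1) (the +1 offset maps FPKM
    zeros to zero instead of -inf).
    """
    males = expr.sample_meta.index[expr.sample_meta["sex"] == "M"]
    males = [s for s in expr.samples if s in set(males)]
    if not males:
        raise ValidationError("no male samples after sex filter")
    values = expr.values[males]
    meta = expr.sample_meta.loc[males]
    if meta["group"].nunique() < 2:
        raise ValidationError("a group is absent after male-only subsetting")
    keep = (values >= min_level).any(axis=1)
    values = np.log(values.loc[keep] + 1.0)
    return ExpressionMatrix(values=values, sample_meta=meta)


def restrict_to_panel(expr: ExpressionMatrix, panel: GenePanel) -> ExpressionMatrix:
    """Keep the (case-insensitive) intersection of matrix genes and panel."""
    keep = [g for g in expr.genes if g in panel]
    if not keep:
        raise ValidationError(
            f"panel {panel.name!r} has no genes in common with the matrix"
        )
    absent = [g for g in panel.genes if g.casefold() not in {x.casefold() for x in keep}]
    if absent:
        logger.info(
            "panel %s: %d genes absent from matrix: %s",
            panel.name,
            len(absent),
            ", ".join(sorted(absent)[:10]),
        )
    return ExpressionMatrix(values=expr.values.loc[keep], sample_meta=expr.sample_meta)


def _labels_from_meta(expr: ExpressionMatrix) -> np.ndarray:
    return expr.sample_meta.loc[expr.samples, "group"].to_numpy()


def iterative_rf_select(
    expr: ExpressionMatrix,
    labels: np.ndarray | None = None,
    config: RFConfig = RFConfig(),
) -> MarkerSelection:
    """Repeated random-forest fits; rank genes by how often they hit the top.

    Each iteration fits a fresh forest (new sub-seed drives its bootstrap and
    feature subsampling) and records the ``top_k_per_iteration`` genes by
    importance. ``selection_freq`` is recorded count / n_iterations; the
    ``n_select`` genes with the highest frequency are selected, ties broken
    lexicographically.
    """
    if labels is None:
        labels = _labels_from_meta(expr)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValidationError(f"exactly two classes required, got {list(classes)}")
    if counts.min() < 2:
        raise ValidationError("each class needs at least 2 samples")
    genes = list(expr.genes)
    top_k = config.top_k_per_iteration
    if top_k > len(genes):
        warnings.warn(
            f"top_k_per_iteration={top_k} exceeds gene count {len(genes)}; "
            "recording all genes each iteration",
            stacklevel=2,
        )
        top_k = len(genes)
    X = expr.values.to_numpy().T  # samples x genes
    y = labels
    ss = np.random.SeedSequence(config.seed)
    sub_seeds = ss.generate_state(2 * config.n_iterations, dtype=np.uint32)
    recorded = np.zeros(len(genes), dtype=np.int64)
    for it in range(config.n_iterations):
        clf = RandomForestClassifier(
            n_estimators=config.trees_per_forest,
            random_state=int(sub_seeds[2 * it]),
            n_jobs=1,
        )
        clf.fit(X, y)
        if config.importance == "gini":
            imp = clf.feature_importances_
        else:
            imp = permutation_importance(
                clf,
                X,
                y,
                n_repeats=5,
                random_state=int(sub_seeds[2 * it + 1]),
                n_jobs=1,
            ).importances_mean
        recorded[np.argsort(-imp, kind="stable")[:top_k]] += 1
    freq = pd.Series(recorded / config.n_iterations, index=genes, name="selection_freq")
    order = sorted(genes, key=lambda g: (-freq[g], g))
    return MarkerSelection(selection_freq=freq, selected=order[: config.n_select])


def _lda_predict(X_train, y_train, x_test, classes) -> object:
    """Two-class Fisher discriminant with ridge-regularized pooled covariance.

    Falls back to nearest-centroid (equivalently the training-majority class
    when centroids coincide) whenever a training class has a single sample or
    the covariance is degenerate.
    """
    n0 = int(np.sum(y_train == classes[0]))
    n1 = int(np.sum(y_train == classes[1]))
    mu0 = X_train[y_train == classes[0]].mean(axis=0)
    mu1 = X_train[y_train == classes[1]].mean(axis=0)
    d = X_train.shape[1]
    if n0 < 2 or n1 < 2:
        # nearest centroid fallback; ties to the majority training class
        d0 = np.linalg.norm(x_test - mu0)
        d1 = np.linalg.norm(x_test - mu1)
        if d0 == d1:
            return classes[0] if n0 >= n1 else classes[1]
        return classes[0] if d0 < d1 else classes[1]
    resid0 = X_train[y_train == classes[0]] - mu0
    resid1 = X_train[y_train == classes[1]] - mu1
    S = (resid0.T @ resid0 + resid1.T @ resid1) / (n0 + n1 - 2)
    trace = float(np.trace(S))
    if trace <= 0:
        return classes[0] if n0 >= n1 else classes[1]
    S = S + (1e-6 * trace / d) * np.eye(d)
    w = np.linalg.solve(S, mu1 - mu0)
    score = float(w @ (x_test - 0.5 * (mu0 + mu1)))
    threshold = float(np.log(n0 / n1))
    if score == threshold:
        return classes[0] if n0 >= n1 else classes[1]
    return classes[1] if score > threshold else classes[0]


def lda_validate(expr_selected: ExpressionMatrix, labels: np.ndarray | None = None) -> float:
    """Leave-one-out linear-discriminant classification accuracy."""
    if labels is None:
        labels = _labels_from_meta(expr_selected)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValidationError(f"exactly two classes required, got {list(classes)}")
    X = expr_selected.values.to_numpy().T
    n = X.shape[0]
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        pred = _lda_predict(X[mask], labels[mask], X[i], classes)
        correct += int(pred == labels[i])
    return correct / n


def pca_project(expr_selected: ExpressionMatrix) -> PCAResult:
    """First two principal-component scores per sample.

    Per-gene centering followed by SVD; each component's loading vector is
    oriented so its sum is non-negative. With fewer than two non-degenerate
    dimensions the second (or both) score column is zero and flagged.
    """
    X = expr_selected.values.to_numpy().T  # samples x genes
    if X.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    scores = np.zeros((X.shape[0], 2))
    for j in range(min(2, rank)):
        sign = 1.0 if Vt[j].sum() >= 0 else -1.0
        scores[:, j] = sign * U[:, j] * s[j]
    df = pd.DataFrame(scores, index=expr_selected.samples, columns=["PC1", "PC2"])
    return PCAResult(scores=df, degenerate_pc2=rank < 2)


def run_marker_pipeline(
    expr: ExpressionMatrix,
    panels: list[GenePanel],
    n_select: dict[str, int],
    config: RFConfig = RFConfig(),
) -> MarkerSelection:
    """Preprocess, select per panel, then validate the combined panel.

    ``n_select`` maps panel name to the number of genes to keep from that
    panel (e.g. 40 apoptosis + 10 proliferation). Selection frequencies from
    all panels are concatenated; LDA validation and PCA run on the union of
    selected genes.
    """
    pre = preprocess(expr)
    labels = _labels_from_meta(pre)
    freqs = []
    selected: list[str] = []
    for panel in panels:
        sub = restrict_to_panel(pre, panel)
        cfg = RFConfig(
            n_iterations=config.n_iterations,
            trees_per_forest=config.trees_per_forest,
            top_k_per_iteration=config.top_k_per_iteration,
            n_select=n_select.get(panel.name, config.n_select),
            seed=config.seed,
            importance=config.importance,
        )
        sel = iterative_rf_select(sub, labels, cfg)
        freqs.append(sel.selection_freq)
        selected.extend(g for g in sel.selected if g not in selected)
    combined = ExpressionMatrix(
        values=pre.values.loc[selected], sample_meta=pre.sample_meta
    )
    return MarkerSelection(
        selection_freq=pd.concat(freqs),
        selected=selected,
        lda_accuracy=lda_validate(combined, labels),
        pc_scores=pca_project(combined).scores,
    )
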