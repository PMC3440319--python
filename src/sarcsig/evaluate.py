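"""Signature evaluation: repeated stratified CV, distribution comparison,
PCA projection, and cross-cohort transfer.

The headline metric protocol is B repetitions (default 1,000) of stratified
k-fold (default 5) cross-validation.  Within each repetition the k held-out
folds' confusion counts are pooled into a single accuracy / sensitivity /
specificity triple (sensitivity = TP/(TP+FN) with the disease class
positive), giving a distribution of B values per metric.  Two signatures are
compared by a Welch t-test on their accuracy distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

from .discovery import RFEConfig, _rfe_to_size, _zscore_train_apply, train_linear_svm
from .expression import ExpressionMatrix, match_genes, standardize_genes

__all__ = [
    "CVConfig",
    "EvaluationReport",
    "PCAProjection",
    "repeated_stratified_cv",
    "compare_accuracy_distributions",
    "pca_projection",
    "cross_cohort_evaluate",
]


@dataclass(frozen=True)
class CVConfig:
    """Repetitions, folds, classifier cost, and evaluation mode.

    ``mode`` is ``"fixed_signature"`` (classifier weights retrained per
    split, gene list never re-selected) or ``"nested_rfe"`` (feature
    selection re-run inside every training split, honest but much slower).
    ``permute_labels`` draws a fresh label permutation per repetition —
    the permutation null for chance-level accuracy.
    """

    n_folds: int = 5
    n_repetitions: int = 1000
    cost: float = 1.0
    mode: str = "fixed_signature"
    permute_labels: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_signature", "nested_rfe"):
            raise ValueError("mode must be 'fixed_signature' or 'nested_rfe'")
        if self.n_folds < 2 or self.n_repetitions < 1:
            raise ValueError("need n_folds >= 2 and n_repetitions >= 1")


@dataclass
class EvaluationReport:
    """Metric distributions over repeated CV plus pooled confusion totals."""

    accuracy_samples: np.ndarray
    sensitivity_samples: np.ndarray
    specificity_samples: np.ndarray
    n_repetitions: int
    n_folds: int
    confusion_total: tuple  # (TP, FP, TN, FN) summed over all repetitions
    mode: str
    transfer_accuracy: float | None = None

    def summary(self) -> dict:
        return {
            "mean_accuracy": float(self.accuracy_samples.mean()),
            "sd_accuracy": float(self.accuracy_samples.std(ddof=1))
            if len(self.accuracy_samples) > 1
            else 0.0,
            "mean_sensitivity": float(self.sensitivity_samples.mean()),
            "mean_specificity": float(self.specificity_samples.mean()),
            "n_repetitions": self.n_repetitions,
            "n_folds": self.n_folds,
            "mode": self.mode,
        }


@dataclass(frozen=True)
class PCAProjection:
    """Top-2 principal-axis sample coordinates of a signature submatrix."""

    coordinates: pd.DataFrame  # samples x [PC1, PC2]
    eigenvalues: tuple
    total_variance: float


def repeated_stratified_cv(
    m: ExpressionMatrix,
    y: np.ndarray,
    genes: list[str],
    cfg: CVConfig | None = None,
) -> EvaluationReport:
    """Repeated stratified k-fold CV of a signature on one cohort.

    ``y`` holds +1 (disease) / -1 (control) labels aligned with
    ``m.sample_ids``.  Per repetition: one stratified partition; per fold,
    genes are standardized with training-fold statistics (frozen for the
    test fold), the linear SVM is trained on the signature submatrix, and
    held-out predictions accumulate into a pooled confusion.  Reproducible
    bit-for-bit from the seed.
    """
    cfg = cfg or CVConfig()
    y = np.asarray(y)
    class_counts = pd.Series(y).value_counts()
    if (class_counts < cfg.n_folds).any():
        raise ValueError(
            f"smallest class has {class_counts.min()} samples; "
            f"use k <= {class_counts.min()}"
        )
    if cfg.mode == "fixed_signature":
        sub = m.subset_genes(list(genes))
        X = sub.values.to_numpy().T  # samples x genes
    else:
        X = m.values.to_numpy().T
    rng = np.random.default_rng(cfg.seed)

    acc = np.empty(cfg.n_repetitions)
    sens = np.empty(cfg.n_repetitions)
    spec = np.empty(cfg.n_repetitions)
    tp_t = fp_t = tn_t = fn_t = 0
    for rep in range(cfg.n_repetitions):
        y_rep = rng.permutation(y) if cfg.permute_labels else y
        skf = StratifiedKFold(
            n_splits=cfg.n_folds,
            shuffle=True,
            random_state=int(rng.integers(2**31)),
        )
        tp = fp = tn = fn = 0
        for tr, te in skf.split(X, y_rep):
            if cfg.mode == "nested_rfe":
                cols = _nested_gene_indices(m, y_rep[tr], tr, len(genes), cfg, rng)
            else:
                cols = slice(None)
            Xtr, Xte = _zscore_train_apply(X[tr][:, cols], X[te][:, cols])
            model = train_linear_svm(Xtr, y_rep[tr], cfg.cost)
            pred = model.predict(Xte)
            truth = y_rep[te]
            tp += int(((pred == 1) & (truth == 1)).sum())
            fp += int(((pred == 1) & (truth == -1)).sum())
            tn += int(((pred == -1) & (truth == -1)).sum())
            fn += int(((pred == -1) & (truth == 1)).sum())
        acc[rep] = (tp + tn) / (tp + tn + fp + fn)
        sens[rep] = tp / (tp + fn) if tp + fn else np.nan
        spec[rep] = tn / (tn + fp) if tn + fp else np.nan
        tp_t, fp_t, tn_t, fn_t = tp_t + tp, fp_t + fp, tn_t + tn, fn_t + fn

    return EvaluationReport(
        accuracy_samples=acc,
        sensitivity_samples=sens,
        specificity_samples=spec,
        n_repetitions=cfg.n_repetitions,
        n_folds=cfg.n_folds,
        confusion_total=(tp_t, fp_t, tn_t, fn_t),
        mode=cfg.mode,
    )


def _nested_gene_indices(m, y_tr, tr, target_size, cfg, rng):
    """Re-select a same-size gene set inside one training split."""
    sub = ExpressionMatrix(m.values.iloc[:, tr])
    sel = _rfe_to_size(
        sub,
        y_tr,
        target_size,
        RFEConfig(cost=cfg.cost, seed=int(rng.integers(2**31))),
    )
    idx = {g: i for i, g in enumerate(m.gene_ids)}
    return [idx[g] for g in sel]


def compare_accuracy_distributions(
    a: EvaluationReport, b: EvaluationReport
) -> tuple[float, float, float]:
    """Welch two-sample t-test on the accuracy distributions of two reports.

    Returns (t_statistic, p_value, mean_difference = mean(a) - mean(b)).
    If both distributions are degenerate (zero variance), p is 1.0 for equal
    means and 0.0 otherwise, with a warning.
    """
    xa, xb = a.accuracy_samples, b.accuracy_samples
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("both reports need >= 2 accuracy samples")
    mean_diff = float(xa.mean() - xb.mean())
    if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
        warnings.warn("degenerate zero-variance accuracy distributions", stacklevel=2)
        equal = np.isclose(mean_diff, 0.0)
        return (0.0 if equal else np.inf * np.sign(mean_diff), 1.0 if equal else 0.0, mean_diff)
    t, p = stats.ttest_ind(xa, xb, equal_var=False)
    return float(t), float(p), mean_diff


def pca_projection(
    m: ExpressionMatrix, genes: list[str] | None = None
) -> PCAProjection:
    """Project samples onto the top-2 principal axes of the signature genes.

    The submatrix is gene-standardized first so every signature gene
    contributes on equal scale.  Sign convention: the loading with the
    largest magnitude on each axis is positive.  Requires >= 3 samples and
    >= 2 genes.
    """
    sub = m if genes is None else m.subset_genes(list(genes))
    if sub.n_genes < 2:
        raise ValueError("pca_projection requires >= 2 genes")
    if sub.n_samples < 3:
        raise ValueError("pca_projection requires >= 3 samples")
    X = standardize_genes(sub).values.to_numpy().T  # samples x genes
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    total_var = float(X.var(axis=0, ddof=1).sum())
    return PCAProjection(
        coordinates=pd.DataFrame(
            coords, index=sub.sample_ids, columns=["PC1", "PC2"]
        ),
        eigenvalues=tuple(float(v) for v in pca.explained_variance_),
        total_variance=total_var,
    )


def cross_cohort_evaluate(
    signature_genes: list[str],
    train: tuple[ExpressionMatrix, np.ndarray],
    test: tuple[ExpressionMatrix, np.ndarray],
    cfg: CVConfig | None = None,
) -> EvaluationReport:
    """Evaluate a signature discovered on one cohort inside another cohort.

    Cohorts are matched by gene symbol and gene-standardized independently
    (the cohorts may come from different platforms, so only within-cohort
    relative expression is comparable).  A classifier trained on the
    training cohort's signature submatrix yields a direct transfer accuracy
    (``report.transfer_accuracy``); the report's metric distributions come
    from fixed-signature repeated CV inside the test cohort, mirroring the
    independent-validation design.  Signature genes absent from the test
    cohort are logged and dropped; fewer than half present is an error.
    """
    cfg = cfg or CVConfig()
    m_train, y_train = train
    m_test, y_test = test
    present = [g for g in signature_genes if g in set(m_test.gene_ids)]
    missing = [g for g in signature_genes if g not in set(m_test.gene_ids)]
    if len(present) < max(1, len(signature_genes) / 2):
        raise ValueError(
            f"test cohort shares only {len(present)}/{len(signature_genes)} "
            f"signature genes; missing: {missing}"
        )
    if missing:
        warnings.warn(
            f"signature gene(s) absent from test cohort, proceeding without: "
            f"{missing}",
            stacklevel=2,
        )
    shared = [g for g in present if g in set(m_train.gene_ids)]
    tr_sub, te_sub, _ = match_genes(
        m_train.subset_genes(shared), m_test.subset_genes(shared)
    )
    tr_z = standardize_genes(tr_sub)
    te_z = standardize_genes(te_sub)
    model = train_linear_svm(tr_z.values.to_numpy().T, np.asarray(y_train), cfg.cost)
    transfer_acc = float(
        (model.predict(te_z.values.to_numpy().T) == np.asarray(y_test)).mean()
    )
    report = repeated_stratified_cv(te_z, np.asarray(y_test), shared, cfg)
    report.transfer_accuracy = transfer_acc
    return report
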