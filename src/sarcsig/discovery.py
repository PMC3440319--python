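"""Gene-signature discovery: linear SVM recursive feature elimination.

A soft-margin linear support-vector machine is trained on all pooled samples;
genes are scored by the squared hyperplane weight w_g^2 and the
lowest-scoring fraction is eliminated each round (single-gene steps once the
active set is small).  Each round's repeated cross-validated accuracy
distribution is recorded, and the final signature is the smallest round
whose mean accuracy is within one standard error of the best round
(the one-SE parsimony rule).  Per-gene "weights" in the reported signature
are selection frequencies over resampled RFE runs: the fraction of stratified
bootstrap replicates in which the gene survives to the signature size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .expression import ExpressionMatrix

__all__ = [
    "LinearModelState",
    "RFEConfig",
    "RFETrace",
    "Signature",
    "train_linear_svm",
    "rank_features",
    "rfe",
    "select_parsimonious_signature",
    "selection_frequency_weights",
]


@dataclass(frozen=True)
class LinearModelState:
    """Trained linear classifier: prediction = sign(w . x + b)."""

    w: np.ndarray
    b: float
    cost: float
    genes: tuple = ()

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision(X) >= 0, 1, -1)


@dataclass(frozen=True)
class RFEConfig:
    """Schedule and CV settings of the elimination loop.

    ``drop_fraction`` of active genes are removed per round (ceil, minimum
    one) until ``single_step_below`` genes remain, after which genes leave
    one at a time — coarse early steps for speed, fine late steps where the
    accuracy-versus-size curve matters.
    """

    cost: float = 1.0
    drop_fraction: float = 0.1
    single_step_below: int = 50
    cv_folds: int = 5
    cv_repeats_per_round: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.drop_fraction < 1:
            raise ValueError("drop_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class RFETrace:
    """Per-round record of the elimination run.

    ``rounds`` is a list of dicts with keys size, active_genes,
    cv_accuracy_samples, mean_accuracy, se_accuracy.  ``rounds_survived``
    counts, per input gene, how many rounds the gene stayed active.
    """

    rounds: list = field(default_factory=list)
    input_genes: tuple = ()
    rounds_survived: dict = field(default_factory=dict)
    config: RFEConfig | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "round": i,
                    "size": r["size"],
                    "mean_accuracy": r["mean_accuracy"],
                    "se_accuracy": r["se_accuracy"],
                }
                for i, r in enumerate(self.rounds)
            ]
        )


@dataclass(frozen=True)
class Signature:
    """Ordered gene list with selection-frequency weights and a trained model.

    ``weights`` (non-increasing, in [0, 1]) define the gene order when
    present; ``model`` is the linear classifier refit on all samples using
    exactly these genes.
    """

    genes: tuple
    weights: tuple | None
    model: LinearModelState | None

    @property
    def size(self) -> int:
        return len(self.genes)


def train_linear_svm(X: np.ndarray, y: np.ndarray, cost: float = 1.0) -> LinearModelState:
    """Fit a soft-margin linear SVM; returns the hyperplane (w, b).

    X is samples x genes (gene-standardized), y in {-1, +1}.  The sign
    convention is decision > 0 => class +1.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    # tight tolerance: keeps the fit effectively at the exact optimum, so
    # symmetries (label flip => w negation) hold to ~1e-9
    clf = SVC(kernel="linear", C=cost, tol=1e-8)
    clf.fit(X, y)
    w = clf.coef_[0].copy()
    b = float(clf.intercept_[0])
    # sklearn orients the decision toward classes_[1]; flip if that is -1
    if clf.classes_[1] != max(clf.classes_):
        w, b = -w, -b
    return LinearModelState(w=w, b=b, cost=cost)


def rank_features(model: LinearModelState) -> np.ndarray:
    """Importance score per gene: squared hyperplane weight w_g^2."""
    return model.w**2


def _zscore_train_apply(train: np.ndarray, *others: np.ndarray):
    """Column z-score using train statistics; constant columns pass as zeros."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return tuple((a - mu) / sd for a in (train, *others))


def _cv_accuracy_samples(
    X: np.ndarray,
    y: np.ndarray,
    cost: float,
    k: int,
    repeats: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pooled-fold accuracy for each of ``repeats`` stratified k-fold draws."""
    accs = np.empty(repeats)
    for r in range(repeats):
        skf = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=int(rng.integers(2**31))
        )
        correct = total = 0
        for tr, te in skf.split(X, y):
            Xtr, Xte = _zscore_train_apply(X[tr], X[te])
            model = train_linear_svm(Xtr, y[tr], cost)
            correct += int((model.predict(Xte) == y[te]).sum())
            total += len(te)
        accs[r] = correct / total
    return accs


def _elimination_count(n_active: int, cfg: RFEConfig) -> int:
    if n_active <= cfg.single_step_below:
        return 1
    return max(1, int(np.ceil(cfg.drop_fraction * n_active)))


def rfe(
    m: ExpressionMatrix,
    y: np.ndarray,
    cfg: RFEConfig | None = None,
    track_cv: bool = True,
) -> RFETrace:
    """Run recursive feature elimination down to a single gene.

    Each round trains the SVM on all pooled samples (gene-standardized),
    ranks genes by w^2, records the round's repeated-CV accuracy distribution
    (unless ``track_cv`` is False, used by the resampling weight machinery),
    and removes the lowest-ranked genes.  Ties in w^2 break by input gene
    order.  Deterministic for a fixed seed.
    """
    cfg = cfg or RFEConfig()
    if m.n_genes < 2:
        raise ValueError("rfe requires >= 2 genes")
    rng = np.random.default_rng(cfg.seed)
    genes = np.array(m.gene_ids)
    X_all = m.values.to_numpy().T  # samples x genes
    y = np.asarray(y)
    active = np.arange(len(genes))
    trace = RFETrace(input_genes=tuple(genes), config=cfg)
    survived = dict.fromkeys(genes, 0)

    while True:
        Xa = X_all[:, active]
        (Xz,) = _zscore_train_apply(Xa)
        model = train_linear_svm(Xz, y, cfg.cost)
        scores = rank_features(model)
        record = {
            "size": len(active),
            "active_genes": tuple(genes[active]),
        }
        if track_cv:
            accs = _cv_accuracy_samples(
                Xa, y, cfg.cost, cfg.cv_folds, cfg.cv_repeats_per_round, rng
            )
            record["cv_accuracy_samples"] = accs
            record["mean_accuracy"] = float(accs.mean())
            record["se_accuracy"] = (
                float(accs.std(ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0
            )
        trace.rounds.append(record)
        for g in genes[active]:
            survived[g] += 1
        if len(active) == 1:
            break
        k_drop = _elimination_count(len(active), cfg)
        # ascending score, ties by position in the active list (= input order)
        order = np.lexsort((np.arange(len(active)), scores))
        active = np.delete(active, np.sort(order[:k_drop]))

    trace.rounds_survived = survived
    return trace


def select_parsimonious_signature(
    trace: RFETrace,
    m: ExpressionMatrix | None = None,
    y: np.ndarray | None = None,
) -> Signature:
    """One-SE parsimony rule over the RFE trace.

    Let A* be the best round's mean CV accuracy and SE* its standard error;
    the signature is the smallest round size whose mean accuracy is at least
    A* - SE*.  If ``m`` and ``y`` are given the linear model is refit on all
    samples restricted to the chosen genes.
    """
    if not trace.rounds:
        raise ValueError("empty RFE trace")
    if "mean_accuracy" not in trace.rounds[0]:
        raise ValueError("trace lacks CV accuracy (run rfe with track_cv=True)")
    means = np.array([r["mean_accuracy"] for r in trace.rounds])
    best = int(np.argmax(means))
    threshold = means[best] - trace.rounds[best]["se_accuracy"]
    eligible = [r for r in trace.rounds if r["mean_accuracy"] >= threshold]
    chosen = min(eligible, key=lambda r: r["size"])
    genes = tuple(chosen["active_genes"])
    model = None
    if m is not None and y is not None:
        sub = m.subset_genes(list(genes))
        (Xz,) = _zscore_train_apply(sub.values.to_numpy().T)
        model = train_linear_svm(Xz, np.asarray(y), trace.config.cost if trace.config else 1.0)
        model = LinearModelState(model.w, model.b, model.cost, genes=genes)
    return Signature(genes=genes, weights=None, model=model)


def selection_frequency_weights(
    m: ExpressionMatrix,
    y: np.ndarray,
    target_size: int,
    n_resamples: int = 100,
    cfg: RFEConfig | None = None,
    seed: int = 0,
) -> pd.Series:
    """Gene weights = fraction of resampled RFE runs reaching the final set.

    Each resample is a stratified bootstrap of the samples (class sizes
    preserved); RFE runs without CV tracking until ``target_size`` genes
    remain, and each surviving gene's counter increments.  Genes with
    positive weight are returned sorted non-increasing (ties by input gene
    order).
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    cfg = cfg or RFEConfig()
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    counts = dict.fromkeys(m.gene_ids, 0)
    sample_idx = np.arange(m.n_samples)
    for _ in range(n_resamples):
        boot = np.concatenate(
            [
                rng.choice(sample_idx[y == cls], size=(y == cls).sum(), replace=True)
                for cls in np.unique(y)
            ]
        )
        mb = ExpressionMatrix(
            m.values.iloc[:, boot].set_axis(
                [f"s{i}" for i in range(len(boot))], axis=1
            )
        )
        sub_cfg = RFEConfig(
            cost=cfg.cost,
            drop_fraction=cfg.drop_fraction,
            single_step_below=cfg.single_step_below,
            cv_folds=cfg.cv_folds,
            cv_repeats_per_round=cfg.cv_repeats_per_round,
            seed=int(rng.integers(2**31)),
        )
        trace = _rfe_to_size(mb, y[boot], target_size, sub_cfg)
        for g in trace:
            counts[g] += 1
    weights = pd.Series(counts, name="weight") / n_resamples
    weights = weights[weights > 0]
    # non-increasing weight, ties by input gene order
    order = sorted(
        weights.index, key=lambda g: (-weights[g], m.gene_ids.index(g))
    )
    return weights.loc[order]


def _rfe_to_size(
    m: ExpressionMatrix, y: np.ndarray, target_size: int, cfg: RFEConfig
) -> tuple:
    """Elimination loop stopping at ``target_size`` genes, no CV tracking."""
    genes = np.array(m.gene_ids)
    X_all = m.values.to_numpy().T
    active = np.arange(len(genes))
    while len(active) > target_size:
        (Xz,) = _zscore_train_apply(X_all[:, active])
        try:
            model = train_linear_svm(Xz, y, cfg.cost)
        except ValueError:
            warnings.warn("degenerate resample (single class); skipped", stacklevel=2)
            break
        scores = rank_features(model)
        k_drop = min(
            _elimination_count(len(active), cfg), len(active) - target_size
        )
        order = np.lexsort((np.arange(len(active)), scores))
        active = np.delete(active, np.sort(order[:k_drop]))
    return tuple(genes[active])


def planted_recovery(
    selected_genes, planted_genes
) -> tuple[float, float]:
    """Precision and recall of a selected gene set against planted truth."""
    sel, pla = set(selected_genes), set(planted_genes)
    tp = len(sel & pla)
    precision = tp / len(sel) if sel else 0.0
    recall = tp / len(pla) if pla else 0.0
    return precision, recall


def weights_separate_planted(
    weights: pd.Series, planted_genes, all_genes
) -> float:
    """Mann-Whitney p that planted genes out-weight noise genes.

    Genes absent from ``weights`` count as weight 0.
    """
    full = pd.Series(0.0, index=pd.Index(all_genes))
    full.loc[weights.index] = weights
    planted = set(planted_genes)
    w_planted = full[[g in planted for g in full.index]]
    w_noise = full[[g not in planted for g in full.index]]
    return float(
        stats.mannwhitneyu(w_planted, w_noise, alternative="greater").pvalue
    )
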