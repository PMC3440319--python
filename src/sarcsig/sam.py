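"""Two-class unpaired SAM: permutation d-statistic with q-value FDR control.

The moderated statistic for gene g is

    d_g = (mean2_g - mean1_g) / (s_g + s0)

where s_g = sqrt[(1/n1 + 1/n2) * (SS1_g + SS2_g) / (n1 + n2 - 2)] is the
gene-specific standard error (SS = within-group sum of squared deviations)
and s0 is a small "fudge" constant that damps the statistic for genes with
tiny variance.  With s0 = 0, d reduces exactly to the classical
pooled-variance two-sample t statistic.

Significance is assessed against a permutation null: group labels are
shuffled, d recomputed with the same s0, and per-gene q-values estimated from
median null exceedance counts with a pi0 correction.  A gene is deemed
differentially expressed when q < 0.05 and its fold change exceeds 1.4 in
either direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "DEConfig",
    "sam_d_statistic",
    "estimate_s0",
    "permutation_null",
    "compute_q_values",
    "fold_changes",
    "select_differential",
    "union_analysis_set",
    "differential_expression",
]


@dataclass(frozen=True)
class DEConfig:
    """Knobs of the differential-expression stage.

    ``fc_threshold`` / ``q_threshold`` implement the selection rule
    (fold change > 1.4 in either direction and q < 0.05).  ``pi0_mode``
    chooses between the IQR-based pi0 estimate and the conservative pi0 = 1.
    """

    s0_mode: str = "auto"  # "auto" | "fixed"
    s0_value: float = 0.0
    n_permutations: int = 200
    fc_threshold: float = 1.4
    q_threshold: float = 0.05
    pi0_mode: str = "estimate"  # "estimate" | "one"
    exceedance_mode: str = "mean"  # "mean" | "median"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must lie in (0, 1)")
        if self.s0_mode not in ("auto", "fixed"):
            raise ValueError("s0_mode must be 'auto' or 'fixed'")
        if self.pi0_mode not in ("estimate", "one"):
            raise ValueError("pi0_mode must be 'estimate' or 'one'")
        if self.exceedance_mode not in ("mean", "median"):
            raise ValueError("exceedance_mode must be 'mean' or 'median'")


def _group_stats(X: np.ndarray, mask2: np.ndarray):
    """Vectorized per-gene group means and within-group SS.

    X is genes x samples; mask2 is an (n_arrangements, n_samples) boolean
    matrix marking group-2 membership per arrangement.  Returns arrays of
    shape (genes, n_arrangements).
    """
    M = mask2.astype(float).T  # samples x arrangements
    n2 = mask2.sum(axis=1).astype(float)
    n1 = mask2.shape[1] - n2
    total = X.sum(axis=1, keepdims=True)
    total_sq = (X**2).sum(axis=1, keepdims=True)
    sum2 = X @ M
    sumsq2 = (X**2) @ M
    mean2 = sum2 / n2
    mean1 = (total - sum2) / n1
    ss2 = sumsq2 - n2 * mean2**2
    ss1 = (total_sq - sumsq2) - n1 * mean1**2
    # clip tiny negatives from cancellation
    ss1 = np.maximum(ss1, 0.0)
    ss2 = np.maximum(ss2, 0.0)
    pooled = (ss1 + ss2) / (n1 + n2 - 2)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * pooled)
    return mean1, mean2, s


def _as_mask(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    uniq = np.unique(y)
    if len(uniq) != 2:
        raise ValueError(f"labels must define exactly two groups, got {uniq}")
    mask2 = y == uniq.max()
    if mask2.sum() < 2 or (~mask2).sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    return mask2


def sam_d_statistic(
    m: ExpressionMatrix | np.ndarray, y: np.ndarray, s0: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (d, s) for the two-group split given by binary labels ``y``.

    Group 2 is the numerically larger label (convention: +1 = case), so
    d > 0 means higher expression in cases.  Genes with s + s0 = 0 get
    d = 0 with a warning.
    """
    X = m.values.to_numpy() if isinstance(m, ExpressionMatrix) else np.asarray(m, float)
    mask2 = _as_mask(y)
    mean1, mean2, s = _group_stats(X, mask2[None, :])
    s = s[:, 0]
    denom = s + s0
    degenerate = denom == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero s + s0; d set to 0",
            stacklevel=2,
        )
    d = np.where(degenerate, 0.0, (mean2[:, 0] - mean1[:, 0]) / np.where(degenerate, 1.0, denom))
    return d, s


def estimate_s0(
    m: ExpressionMatrix | np.ndarray, y: np.ndarray, n_bins: int | None = None
) -> float:
    """Choose the fudge constant s0 by the standard SAM recipe.

    Candidate s0 values are the percentiles {0, 5, ..., 100} of the s_g
    distribution; the winner minimizes the coefficient of variation of the
    median absolute d across quantile bins of s_g, stabilizing |d| against
    the variance-mean trend.  With fewer than 100 genes the recipe is
    unstable and the median of s_g is returned with a warning.
    """
    X = m.values.to_numpy() if isinstance(m, ExpressionMatrix) else np.asarray(m, float)
    mask2 = _as_mask(y)
    mean1, mean2, s = _group_stats(X, mask2[None, :])
    r = (mean2 - mean1)[:, 0]
    s = s[:, 0]
    n_genes = len(s)
    if n_genes < 100:
        warnings.warn("fewer than 100 genes; falling back to s0 = median(s)", stacklevel=2)
        return float(np.median(s))
    if n_bins is None:
        n_bins = int(np.clip(n_genes // 25, 2, 100))
    # quantile bins of s (stable even with ties)
    order = np.argsort(s, kind="stable")
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = (np.arange(n_genes) * n_bins) // n_genes
    candidates = np.percentile(s, np.arange(0, 101, 5))
    best_s0, best_cv = float(candidates[0]), np.inf
    for s0 in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = r / (s + s0)
        med = np.array(
            [np.median(np.abs(d[bin_of == b])) for b in range(n_bins)]
        )
        med = med[np.isfinite(med)]
        mean_med = med.mean()
        if mean_med == 0:
            continue
        cv = med.std(ddof=1) / mean_med
        if cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _arrangement_count(n: int, n2: int) -> int:
    return comb(n, n2)


def permutation_null(
    m: ExpressionMatrix | np.ndarray,
    y: np.ndarray,
    s0: float,
    n_permutations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Null d matrix (n_permutations_used x genes) from label shuffles.

    When the number of distinct label arrangements C(n, n2) is at most
    ``n_permutations`` the enumeration is exhaustive (every arrangement used
    exactly once); otherwise arrangements are drawn uniformly at random with
    the given seed.  The same s0 is reused in every round.  Each arrangement
    is evaluated through the same code path as :func:`sam_d_statistic`, so
    exhaustive enumeration is bitwise-reproducible against a direct
    recomputation.
    """
    X = m.values.to_numpy() if isinstance(m, ExpressionMatrix) else np.asarray(m, float)
    mask2 = _as_mask(y)
    n = len(mask2)
    n2 = int(mask2.sum())
    total = _arrangement_count(n, n2)
    if total <= n_permutations:
        masks = np.zeros((total, n), dtype=bool)
        for i, pos in enumerate(combinations(range(n), n2)):
            masks[i, list(pos)] = True
    else:
        rng = np.random.default_rng(seed)
        masks = np.zeros((n_permutations, n), dtype=bool)
        for i in range(n_permutations):
            masks[i, rng.choice(n, size=n2, replace=False)] = True
    out = np.empty((masks.shape[0], X.shape[0]))
    for i in range(masks.shape[0]):
        mean1, mean2, s = _group_stats(X, masks[i : i + 1])
        denom = s[:, 0] + s0
        degenerate = denom == 0
        out[i] = np.where(
            degenerate,
            0.0,
            (mean2[:, 0] - mean1[:, 0]) / np.where(degenerate, 1.0, denom),
        )
    return out  # arrangements x genes


def compute_q_values(
    d_observed: np.ndarray,
    d_null: np.ndarray,
    pi0_mode: str = "estimate",
    exceedance_mode: str = "mean",
) -> np.ndarray:
    """Per-gene q-values from observed d and a permutation null matrix.

    For the threshold at |d_g|, the estimated FDR is

        pi0 * E_p #{null |d| >= |d_g|} / #{observed |d| >= |d_g|}

    where E_p aggregates the per-permutation null exceedance counts: the
    mean (default — the expected number of falsely called genes, which keeps
    the procedure calibrated on pure-null data) or the median
    (``exceedance_mode="median"``, anti-conservative in the extreme tail
    where the median count collapses to zero).  pi0 = 2 * (fraction of
    observed d inside the interquartile range of the pooled null d), clipped
    to [0, 1] (or pi0 = 1 in conservative mode).  The q-value of gene g is
    the minimum estimated FDR over all thresholds at which g would be
    called, which enforces monotonicity: q is non-increasing in |d|.  Ties
    in |d| break by gene input order.
    """
    d_observed = np.asarray(d_observed, float)
    d_null = np.asarray(d_null, float)
    if d_null.size == 0:
        raise ValueError("null matrix is empty")
    n_genes = len(d_observed)
    abs_obs = np.abs(d_observed)

    if pi0_mode == "one":
        pi0 = 1.0
    else:
        pooled = d_null.ravel()
        q25, q75 = np.percentile(pooled, [25, 75])
        frac_in_iqr = np.mean((d_observed >= q25) & (d_observed <= q75))
        pi0 = float(np.clip(2.0 * frac_in_iqr, 0.0, 1.0))

    # significance order: descending |d|, ties by input order
    order = np.lexsort((np.arange(n_genes), -abs_obs))
    obs_count = np.empty(n_genes)
    obs_count[order] = np.arange(1, n_genes + 1)

    # median over permutations of per-permutation null exceedance counts
    sorted_null = np.sort(np.abs(d_null), axis=1)
    counts = d_null.shape[1] - np.vstack(
        [np.searchsorted(row, abs_obs, side="left") for row in sorted_null]
    )
    if exceedance_mode == "median":
        null_agg = np.median(counts, axis=0)
    elif exceedance_mode == "mean":
        null_agg = counts.mean(axis=0)
    else:
        raise ValueError("exceedance_mode must be 'mean' or 'median'")

    fdr = pi0 * null_agg / obs_count
    # running min from the least significant end of the ordering upward
    fdr_sorted = fdr[order]
    q_sorted = np.minimum.accumulate(fdr_sorted[::-1])[::-1]
    q = np.empty(n_genes)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def fold_changes(
    m: ExpressionMatrix | np.ndarray, y: np.ndarray, log2_input: bool = True
) -> np.ndarray:
    """Per-gene case/control fold change as a ratio of geometric means.

    FC = 2^(case log2 mean - control log2 mean); FC < 1 denotes
    down-regulation in cases.  Linear-scale input is log2-transformed first.
    """
    X = m.values.to_numpy() if isinstance(m, ExpressionMatrix) else np.asarray(m, float)
    if not log2_input:
        if (X <= 0).any():
            raise ValueError("linear-scale input must be positive")
        X = np.log2(X)
    mask2 = _as_mask(y)
    diff = X[:, mask2].mean(axis=1) - X[:, ~mask2].mean(axis=1)
    return 2.0**diff


def select_differential(result: pd.DataFrame, cfg: DEConfig | None = None) -> pd.DataFrame:
    """Apply the selection rule: q < q_threshold and max(FC, 1/FC) > fc_threshold.

    Both inequalities are strict.  Adds/overwrites boolean ``selected`` and
    ``direction`` ("up"/"down" by FC vs 1) columns; returns the same frame.
    """
    cfg = cfg or DEConfig()
    fc = result["fold_change"].to_numpy()
    q = result["q_value"].to_numpy()
    sym_fc = np.maximum(fc, 1.0 / fc)
    result = result.copy()
    result["selected"] = (q < cfg.q_threshold) & (sym_fc > cfg.fc_threshold)
    result["direction"] = np.where(fc >= 1.0, "up", "down")
    return result


def union_analysis_set(*gene_lists) -> list[str]:
    """Order-preserving union of gene lists (first-seen order)."""
    seen: dict[str, None] = {}
    for lst in gene_lists:
        for g in lst:
            seen.setdefault(g, None)
    return list(seen)


def differential_expression(
    m: ExpressionMatrix,
    y: np.ndarray,
    cfg: DEConfig | None = None,
) -> pd.DataFrame:
    """Full SAM analysis for one binary contrast.

    ``y`` holds binary labels aligned with ``m.sample_ids`` (+1 = case).
    Returns a per-gene DataFrame with columns d, s, fold_change, q_value,
    selected, direction, indexed by gene symbol.
    """
    cfg = cfg or DEConfig()
    if cfg.s0_mode == "fixed":
        s0 = cfg.s0_value
    else:
        s0 = estimate_s0(m, y)
    d, s = sam_d_statistic(m, y, s0)
    null = permutation_null(m, y, s0, cfg.n_permutations, cfg.seed)
    q = compute_q_values(d, null, cfg.pi0_mode, cfg.exceedance_mode)
    fc = fold_changes(m, y, log2_input=True)
    out = pd.DataFrame(
        {"d": d, "s": s, "fold_change": fc, "q_value": q},
        index=pd.Index(m.gene_ids, name="gene"),
    )
    out.attrs["s0"] = s0
    out.attrs["n_permutations_used"] = null.shape[0]
    return select_differential(out, cfg)
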