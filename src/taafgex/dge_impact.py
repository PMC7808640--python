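"""Downstream impact of inference accuracy on differential expression (DE).

The question: when DE analysis is run on *inferred* expression instead of the
measured ground truth, how faithfully are the ground-truth DE calls and
significance rankings reproduced?  The pipeline: derive a two-class phenotype
(either given, or *artificial* — two large clusters from hierarchical
clustering of expression); call DE genes per class with a pluggable backend
(default: Welch's t-test with Benjamini-Hochberg adjustment, flagging
adjusted p < 0.01); score inferred-vs-truth calls with accuracy, F_beta
(0.5, 1, 2) and Matthews correlation; measure rank agreement of the top
candidates; and repeat over many balanced subsamples of realistic DGE study
sizes, comparing methods with paired Wilcoxon signed-rank tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .evaluation import paired_tests

__all__ = [
    "DGEEvalResult",
    "artificial_phenotypes",
    "call_de",
    "welch_t_backend",
    "confusion_scores",
    "rank_agreement",
    "subsample_experiment",
]

DEBackend = Callable[[np.ndarray, np.ndarray], np.ndarray]
"""A DE backend maps (class-A matrix, class-B matrix) -> per-gene raw p-values."""


@dataclass
class DGEEvalResult:
    """Scores for one method on one balanced subsample."""

    method: str
    sample_size: int
    repetition: int
    accuracy: float
    f_half: float
    f1: float
    f2: float
    mcc: float
    rank_mae_top100: float
    rank_mae_p05: float


# ---------------------------------------------------------------------------
# Artificial phenotypes by clustering
# ---------------------------------------------------------------------------


def artificial_phenotypes(
    expression: np.ndarray,
    n_samples: int = 2000,
    min_cluster: int = 300,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Two-class labels from hierarchical clustering of a random subset.

    Runs agglomerative clustering (Ward linkage, Euclidean distance) on
    ``n_samples`` randomly chosen rows and returns, at the shallowest cut
    where the two largest clusters both exceed ``min_cluster``, the row
    indices of those clusters' members and their binary labels.  Samples in
    neither cluster are excluded.

    Returns ``(row_indices, labels)`` with labels in {0, 1}.
    """
    expression = np.asarray(expression, dtype=float)
    total = expression.shape[0]
    if total < n_samples:
        raise ValueError(f"need >= {n_samples} samples, got {total}")
    if min_cluster > n_samples // 2:
        raise ValueError("min_cluster cannot exceed half the clustered samples")
    rng = np.random.default_rng(seed)
    subset = np.sort(rng.choice(total, size=n_samples, replace=False))
    z = linkage(expression[subset], method="ward", metric="euclidean")
    for k in range(2, n_samples + 1):  # shallowest cut first
        assignment = fcluster(z, t=k, criterion="maxclust")
        ids, counts = np.unique(assignment, return_counts=True)
        if len(ids) < 2:
            continue
        top2 = ids[np.argsort(counts)[::-1][:2]]
        c1, c2 = (int(np.sum(assignment == c)) for c in top2)
        if c1 >= min_cluster and c2 >= min_cluster:
            keep = np.isin(assignment, top2)
            labels = (assignment[keep] == top2[1]).astype(int)
            return subset[keep], labels
    raise ValueError(
        f"no cut yields two clusters with >= {min_cluster} samples each"
    )


# ---------------------------------------------------------------------------
# DE calling
# ---------------------------------------------------------------------------


def welch_t_backend(class_a: np.ndarray, class_b: np.ndarray) -> np.ndarray:
    """Per-gene Welch two-sample t-test p-values (the default backend)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(class_a, class_b, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both classes with equal means -> undefined t -> p = 1
    return np.where(np.isnan(p), 1.0, p)


def call_de(
    expression: np.ndarray,
    labels: Sequence,
    alpha_adj: float = 0.01,
    backend: DEBackend = welch_t_backend,
) -> pd.DataFrame:
    """Per-gene DE test with Benjamini-Hochberg adjustment.

    Returns a DataFrame with columns ``p``, ``p_adj`` and ``de`` (adjusted
    p < ``alpha_adj``), one row per gene in column order.  The test backend
    is pluggable, so a moderated/empirical-Bayes caller can be substituted.
    """
    expression = np.asarray(expression, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != expression.shape[0]:
        raise ValueError("labels length must match the sample count")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    a = expression[labels == classes[0]]
    b = expression[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 samples")
    p = backend(a, b)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"p": p, "p_adj": p_adj, "de": p_adj < alpha_adj})


# ---------------------------------------------------------------------------
# Confusion scores and rank agreement
# ---------------------------------------------------------------------------


def _f_beta(precision: float, recall: float, beta: float) -> float:
    denom = beta**2 * precision + recall
    if denom == 0:
        return 0.0
    return (1 + beta**2) * precision * recall / denom


def confusion_scores(
    truth_flags: Sequence[bool], predicted_flags: Sequence[bool]
) -> Dict[str, float]:
    """Accuracy, F_0.5, F_1, F_2 and MCC of predicted vs truth DE flags.

    Degenerate denominators (no positives anywhere, a zero MCC denominator)
    yield a score of 0 with a warning rather than an error.
    """
    t = np.asarray(truth_flags, dtype=bool)
    p = np.asarray(predicted_flags, dtype=bool)
    if t.shape != p.shape:
        raise ValueError("flag vectors must have equal length")
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    n = tp + fp + fn + tn
    accuracy = (tp + tn) / n if n else 0.0
    degenerate = False
    if tp + fp == 0 or tp + fn == 0:
        degenerate = True
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
    else:
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
    mcc_denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_denom == 0:
        degenerate = True
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(mcc_denom)
    if degenerate:
        warnings.warn("degenerate confusion matrix; affected scores set to 0")
    return {
        "accuracy": accuracy,
        "f_half": _f_beta(precision, recall, 0.5),
        "f1": _f_beta(precision, recall, 1.0),
        "f2": _f_beta(precision, recall, 2.0),
        "mcc": float(mcc),
    }


def _ranks(p_values: np.ndarray, gene_ids: Sequence[str]) -> Dict[str, int]:
    """1-based ranks by ascending p-value, ties broken by gene id."""
    order = sorted(range(len(gene_ids)), key=lambda i: (p_values[i], gene_ids[i]))
    return {gene_ids[i]: r + 1 for r, i in enumerate(order)}


def rank_agreement(
    truth_p: np.ndarray,
    inferred_p: np.ndarray,
    gene_ids: Sequence[str],
    selection: str = "top-k",
    k: int = 100,
    alpha: float = 0.05,
) -> float:
    """Mean absolute rank displacement of the truth-selected DE candidates.

    Candidates are chosen on the TRUTH ordering: either the ``k``
    most significant genes (``selection="top-k"``) or all genes with truth
    p < ``alpha`` (``selection="p-threshold"``).  For each candidate the
    absolute difference between its truth rank and its rank in the inferred
    ordering is averaged.  An empty candidate set returns NaN with a warning.
    """
    truth_p = np.asarray(truth_p, dtype=float)
    inferred_p = np.asarray(inferred_p, dtype=float)
    gene_ids = list(gene_ids)
    if not (len(truth_p) == len(inferred_p) == len(gene_ids)):
        raise ValueError("p-value vectors and gene ids must share one length")
    truth_rank = _ranks(truth_p, gene_ids)
    inferred_rank = _ranks(inferred_p, gene_ids)
    if selection == "top-k":
        candidates = [g for g, r in truth_rank.items() if r <= k]
    elif selection == "p-threshold":
        candidates = [g for g, pv in zip(gene_ids, truth_p) if pv < alpha]
    else:
        raise ValueError("selection must be 'top-k' or 'p-threshold'")
    if not candidates:
        warnings.warn("empty candidate set; rank agreement undefined (NaN)")
        return float("nan")
    diffs = [abs(truth_rank[g] - inferred_rank[g]) for g in candidates]
    return float(np.mean(diffs))


# ---------------------------------------------------------------------------
# Repeated balanced subsampling
# ---------------------------------------------------------------------------


def subsample_experiment(
    truth_expression: np.ndarray,
    inferred: Mapping[str, np.ndarray],
    labels: Sequence,
    gene_ids: Sequence[str],
    sizes: Sequence[int] = (12, 60),
    repetitions: int = 200,
    alpha_adj: float = 0.01,
    seed: int = 0,
    backend: DEBackend = welch_t_backend,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Repeated balanced-subsample DE evaluation across sample sizes.

    For each size and repetition a balanced subsample (size/2 per class) is
    drawn; DE is called on the ground truth and on every inferred matrix
    restricted to the same samples; the truth calls serve as the reference
    for confusion scores and rank agreement.  Sizes a class cannot support
    are skipped with a warning.

    Returns ``(results, wilcoxon)``: a long-format results table (method,
    size, repetition, metric columns) and, for every method pair, paired
    Wilcoxon p-values per size and metric.
    """
    truth_expression = np.asarray(truth_expression, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    idx_a = np.flatnonzero(labels == classes[0])
    idx_b = np.flatnonzero(labels == classes[1])
    rng = np.random.default_rng(seed)
    metric_names = [
        "accuracy", "f_half", "f1", "f2", "mcc", "rank_mae_top100", "rank_mae_p05",
    ]

    rows: List[dict] = []
    for size in sizes:
        half = size // 2
        if half < 2 or half > min(len(idx_a), len(idx_b)):
            warnings.warn(f"sample size {size} unsupported by class sizes; skipped")
            continue
        for rep in range(repetitions):
            sub = np.concatenate(
                [
                    rng.choice(idx_a, size=half, replace=False),
                    rng.choice(idx_b, size=half, replace=False),
                ]
            )
            sub_labels = labels[sub]
            truth_tab = call_de(
                truth_expression[sub], sub_labels, alpha_adj, backend
            )
            truth_flags = truth_tab["de"].to_numpy()
            for method, matrix in inferred.items():
                tab = call_de(
                    np.asarray(matrix, dtype=float)[sub], sub_labels, alpha_adj, backend
                )
                scores = confusion_scores(truth_flags, tab["de"].to_numpy())
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    top100 = rank_agreement(
                        truth_tab["p"].to_numpy(), tab["p"].to_numpy(), gene_ids,
                        selection="top-k", k=100,
                    )
                    p05 = rank_agreement(
                        truth_tab["p"].to_numpy(), tab["p"].to_numpy(), gene_ids,
                        selection="p-threshold", alpha=0.05,
                    )
                rows.append(
                    {
                        "method": method,
                        "sample_size": size,
                        "repetition": rep,
                        **scores,
                        "rank_mae_top100": top100,
                        "rank_mae_p05": p05,
                    }
                )
    results = pd.DataFrame(rows)

    # paired Wilcoxon tests between every method pair, per size and metric
    test_rows: List[dict] = []
    methods = sorted(inferred)
    if not results.empty:
        for size in results["sample_size"].unique():
            at_size = results[results["sample_size"] == size]
            by_method = {
                m: at_size[at_size["method"] == m].sort_values("repetition")
                for m in methods
            }
            for i, m1 in enumerate(methods):
                for m2 in methods[i + 1 :]:
                    for metric in metric_names:
                        a = by_method[m1][metric].to_numpy()
                        b = by_method[m2][metric].to_numpy()
                        ok = np.isfinite(a) & np.isfinite(b)
                        if ok.sum() < 2 or np.all(a[ok] == b[ok]):
                            p = 1.0
                        else:
                            with warnings.catch_warnings():
                                warnings.simplefilter("ignore")
                                _, p = paired_tests(a[ok], b[ok])
                        test_rows.append(
                            {
                                "sample_size": size,
                                "metric": metric,
                                "method_1": m1,
                                "method_2": m2,
                                "wilcoxon_p": p,
                            }
                        )
    return results, pd.DataFrame(test_rows)
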