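"""Per-gene expert ensembles over a pool of trained architectures.

For every target gene, the ensemble picks the single model (the *expert*)
with the lowest per-gene mean absolute error on a *selection* half of the
validation data, and only that expert predicts the gene.  Candidate pools of
up to four architectures are enumerated and ranked by MMAE on a disjoint
*evaluation* half, so selection and ranking never see the same samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .evaluation import mae_per_sample, mmae

__all__ = [
    "ExpertMap",
    "per_gene_errors",
    "per_gene_expert_selection",
    "ensemble_predict",
    "enumerate_and_select",
]


@dataclass
class ExpertMap:
    """gene id -> expert model id, over a declared model pool."""

    experts: Dict[str, str]
    pool: frozenset

    def __post_init__(self) -> None:
        stray = set(self.experts.values()) - set(self.pool)
        if stray:
            raise ValueError(f"experts outside the pool: {sorted(stray)}")

    def to_tsv(self) -> str:
        lines = [f"{g}\t{m}" for g, m in sorted(self.experts.items())]
        return "\n".join(lines) + "\n"


def per_gene_errors(
    truth: np.ndarray, prediction: np.ndarray, gene_ids: Sequence[str]
) -> Dict[str, float]:
    """Per-gene mean absolute error over samples."""
    truth = np.asarray(truth, dtype=float)
    prediction = np.asarray(prediction, dtype=float)
    if truth.shape != prediction.shape:
        raise ValueError("shape mismatch between truth and prediction")
    if truth.shape[1] != len(gene_ids):
        raise ValueError("gene_ids length must match the column count")
    errs = np.mean(np.abs(truth - prediction), axis=0)
    return dict(zip(gene_ids, errs))


def per_gene_expert_selection(
    per_gene_err: Mapping[str, Mapping[str, float]]
) -> ExpertMap:
    """Assign each gene the model with minimal selection-half error.

    ``per_gene_err`` maps model id -> {gene id -> MAE}.  All models must
    cover the same gene set.  Exact ties go to the lexicographically smallest
    model id.
    """
    if not per_gene_err:
        raise ValueError("empty model pool")
    model_ids = sorted(per_gene_err)
    gene_sets = {m: frozenset(per_gene_err[m]) for m in model_ids}
    reference = gene_sets[model_ids[0]]
    for m, gs in gene_sets.items():
        if gs != reference:
            raise ValueError(f"model {m!r} reports a different gene set")
    experts = {
        g: min(model_ids, key=lambda m: (per_gene_err[m][g], m)) for g in reference
    }
    return ExpertMap(experts=experts, pool=frozenset(model_ids))


def ensemble_predict(
    expert_map: ExpertMap,
    model_predictions: Mapping[str, np.ndarray],
    gene_ids: Sequence[str],
) -> np.ndarray:
    """Column g of the output is copied from g's expert's prediction.

    ``gene_ids`` fixes the column order of both the inputs and the output.
    """
    missing = {expert_map.experts[g] for g in gene_ids} - set(model_predictions)
    if missing:
        raise ValueError(f"missing predictions for models: {sorted(missing)}")
    col = {g: j for j, g in enumerate(gene_ids)}
    first = next(iter(model_predictions.values()))
    out = np.empty((first.shape[0], len(gene_ids)))
    for g in gene_ids:
        out[:, col[g]] = model_predictions[expert_map.experts[g]][:, col[g]]
    return out


def enumerate_and_select(
    truth_selection: np.ndarray,
    truth_evaluation: np.ndarray,
    predictions_selection: Mapping[str, np.ndarray],
    predictions_evaluation: Mapping[str, np.ndarray],
    gene_ids: Sequence[str],
    max_size: int = 4,
) -> Tuple[frozenset, ExpertMap, List[Tuple[frozenset, float]]]:
    """Enumerate all non-empty pools of <= max_size models; pick the best.

    Each candidate pool's expert map is built on the selection half; pools
    are ranked by ensemble MMAE on the evaluation half.  Returns the winning
    pool, its expert map, and the full (pool, evaluation MMAE) ranking sorted
    ascending, ties broken by pool size then sorted model ids.
    """
    model_ids = sorted(predictions_selection)
    if not model_ids:
        raise ValueError("empty model pool")
    if set(predictions_evaluation) != set(model_ids):
        raise ValueError("selection and evaluation predictions cover different models")
    if truth_selection.shape == truth_evaluation.shape and np.array_equal(
        truth_selection, truth_evaluation
    ):
        raise ValueError("selection and evaluation halves must be disjoint")

    sel_errors = {
        m: per_gene_errors(truth_selection, predictions_selection[m], gene_ids)
        for m in model_ids
    }
    ranking: List[Tuple[frozenset, float]] = []
    maps: Dict[frozenset, ExpertMap] = {}
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(model_ids, size):
            pool = frozenset(combo)
            emap = per_gene_expert_selection({m: sel_errors[m] for m in combo})
            pred = ensemble_predict(
                emap, {m: predictions_evaluation[m] for m in combo}, gene_ids
            )
            score = mmae(mae_per_sample(truth_evaluation, pred))
            ranking.append((pool, score))
            maps[pool] = emap
    ranking.sort(key=lambda t: (t[1], len(t[0]), tuple(sorted(t[0]))))
    best_pool = ranking[0][0]
    return best_pool, maps[best_pool], ranking
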