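"""Model-comparison statistics: samplewise MAE, bootstrap CIs, paired tests.

Samples are treated as the independent replication unit.  For model m and
sample s, MAE_m(s) is the mean over genes of |y(g,s) - yhat_m(g,s)|; MMAE_m
averages that over samples.  Two models are compared through the samplewise
mean difference of absolute errors MDAE_{m1,m2}(s) and its average MMDAE
(negative values favor m1), with percentile-bootstrap confidence intervals
over samples and paired Student's t / Wilcoxon signed-rank tests on the
samplewise MAEs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats

__all__ = [
    "SamplewiseErrors",
    "ComparisonReport",
    "mae_per_sample",
    "mmae",
    "mdae_per_sample",
    "mmdae",
    "bootstrap_ci",
    "paired_tests",
    "compare_models",
]


@dataclass
class SamplewiseErrors:
    model_id: str
    mae: np.ndarray  # per-sample MAE over genes

    def __post_init__(self) -> None:
        self.mae = np.asarray(self.mae, dtype=float)
        if np.any(self.mae < 0):
            raise ValueError("per-sample MAE entries must be nonnegative")


@dataclass
class ComparisonReport:
    """MMDAE point estimate with bootstrap CI and paired-test p-values."""

    model_1: str
    model_2: str
    mmdae: float
    ci_low: float
    ci_high: float
    t_test_p: float
    wilcoxon_p: float
    n_bootstrap: int
    seed: int

    def to_tsv_row(self) -> str:
        return (
            f"{self.model_1}\t{self.model_2}\t{self.mmdae:.6f}\t"
            f"{self.ci_low:.6f}\t{self.ci_high:.6f}\t"
            f"{self.t_test_p:.3g}\t{self.wilcoxon_p:.3g}"
        )


def _check_shapes(truth: np.ndarray, *preds: np.ndarray) -> Tuple[np.ndarray, ...]:
    truth = np.asarray(truth, dtype=float)
    out = [truth]
    for p in preds:
        p = np.asarray(p, dtype=float)
        if p.shape != truth.shape:
            raise ValueError(f"shape mismatch: {p.shape} vs truth {truth.shape}")
        out.append(p)
    return tuple(out)


def mae_per_sample(truth: np.ndarray, prediction: np.ndarray) -> np.ndarray:
    """MAE_m(s): mean over genes of the absolute prediction error, per sample."""
    truth, prediction = _check_shapes(truth, prediction)
    return np.mean(np.abs(truth - prediction), axis=1)


def mmae(per_sample_mae: np.ndarray) -> float:
    """MMAE_m: the mean of the samplewise MAEs."""
    per_sample_mae = np.asarray(per_sample_mae, dtype=float)
    if per_sample_mae.size == 0:
        raise ValueError("empty per-sample MAE vector")
    return float(np.mean(per_sample_mae))


def mdae_per_sample(
    truth: np.ndarray, pred_m1: np.ndarray, pred_m2: np.ndarray
) -> np.ndarray:
    """MDAE_{m1,m2}(s): samplewise mean difference of absolute errors.

    Identically equals mae_per_sample(m1) - mae_per_sample(m2).
    """
    truth, pred_m1, pred_m2 = _check_shapes(truth, pred_m1, pred_m2)
    return np.mean(np.abs(truth - pred_m1) - np.abs(truth - pred_m2), axis=1)


def mmdae(per_sample_mdae: np.ndarray) -> float:
    """MMDAE_{m1,m2}: mean samplewise MDAE; negative favors model 1."""
    return mmae(per_sample_mdae)


def bootstrap_ci(
    per_sample_values: np.ndarray,
    n_bootstrap: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> Tuple[float, float]:
    """Percentile bootstrap CI for the mean, resampling samples with
    replacement.  Deterministic under the seed."""
    values = np.asarray(per_sample_values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    rng = np.random.default_rng(seed)
    n = values.size
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(means, [alpha, 1.0 - alpha])
    return float(low), float(high)


def paired_tests(mae_m1: np.ndarray, mae_m2: np.ndarray) -> Tuple[float, float]:
    """Two-sided paired Student's t and Wilcoxon signed-rank p-values on the
    samplewise MAE differences.

    Degenerate cases: all differences zero -> both p = 1 with a warning;
    zero variance of nonzero differences -> t-test p = 0 with a warning.
    The Wilcoxon test drops zero differences, uses the exact distribution for
    n <= 25 without ties, and the continuity-corrected normal approximation
    otherwise.
    """
    d = np.asarray(mae_m1, dtype=float) - np.asarray(mae_m2, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired observations")
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p-values set to 1")
        return 1.0, 1.0
    # treat differences constant to rounding as zero-variance
    if np.std(d) <= 1e-12 * abs(np.mean(d)):
        warnings.warn(
            "paired differences have zero variance but nonzero mean; t-test p = 0"
        )
        t_p = 0.0
    else:
        t_p = float(stats.ttest_rel(mae_m1, mae_m2).pvalue)
    nz = d[d != 0]
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not has_ties) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w_p = float(
            stats.wilcoxon(nz, zero_method="wilcox", correction=True, method=method).pvalue
        )
    return t_p, w_p


def compare_models(
    truth: np.ndarray,
    pred_m1: np.ndarray,
    pred_m2: np.ndarray,
    model_1: str = "m1",
    model_2: str = "m2",
    n_bootstrap: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> ComparisonReport:
    """Full pairwise comparison: MMDAE, bootstrap CI and paired tests."""
    mdae = mdae_per_sample(truth, pred_m1, pred_m2)
    point = mmdae(mdae)
    ci_low, ci_high = bootstrap_ci(mdae, n_bootstrap=n_bootstrap, level=level, seed=seed)
    t_p, w_p = paired_tests(
        mae_per_sample(truth, pred_m1), mae_per_sample(truth, pred_m2)
    )
    return ComparisonReport(
        model_1=model_1,
        model_2=model_2,
        mmdae=point,
        ci_low=ci_low,
        ci_high=ci_high,
        t_test_p=t_p,
        wilcoxon_p=w_p,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )
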