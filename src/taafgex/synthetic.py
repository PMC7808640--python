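"""Seeded synthetic landmark -> target expression generator.

Emulates the structure of a large microarray expression compendium at desk
scale: a low-dimensional latent state per sample, a *landmark* gene block
that is linear in the latents (so the landmarks carry the signal), and a
*target* gene block that is a per-gene scaled-and-shifted nonlinear function
of the latents.  The per-gene output scales and offsets create exactly the
range mismatch that a TAAF's amplitude (alpha) and output shift (delta) can
absorb while a fixed sigmoidal unit cannot.  Samples belong to series
(experiment groups) with additive block intercepts, making series-aware
splitting measurably different from random splitting, and an optional
two-class phenotype plants a known set of differentially expressed target
genes.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .data_io import ExpressionDataset

__all__ = ["GeneratorConfig", "GroundTruth", "generate_expression", "generate_phenotype_dataset"]


@dataclass(frozen=True)
class GeneratorConfig:
    n_samples: int = 2000
    n_landmarks: int = 50
    n_targets: int = 200
    n_latent: int = 8
    nonlinearity: str = "mixed"  # "tanh" | "sigmoid" | "mixed"
    noise_sd: float = 0.3
    target_scale_range: Tuple[float, float] = (0.5, 3.0)
    target_offset_range: float = 2.0
    n_series: int = 20
    series_effect_sd: float = 0.0
    n_de_genes: int = 10
    de_effect_size: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_landmarks", "n_targets", "n_latent", "n_series"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.noise_sd < 0 or self.series_effect_sd < 0:
            raise ValueError("noise sds must be nonnegative")
        if self.nonlinearity not in ("tanh", "sigmoid", "mixed"):
            raise ValueError("nonlinearity must be 'tanh', 'sigmoid' or 'mixed'")
        lo, hi = self.target_scale_range
        if not (0 < lo <= hi):
            raise ValueError("target_scale_range must be a positive interval")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_targets:
            raise ValueError("n_de_genes must lie in [0, n_targets]")


@dataclass
class GroundTruth:
    """The generating maps, kept so noiseless targets are recomputable."""

    latents: np.ndarray  # n_samples x n_latent
    landmark_map: np.ndarray  # n_latent x n_landmarks
    target_weights: np.ndarray  # n_latent x n_targets
    target_kind: List[str]  # per-target nonlinearity
    target_scale: np.ndarray
    target_offset: np.ndarray
    series_of_sample: List[str]
    series_intercept: dict
    de_flags: Optional[np.ndarray] = None  # per-target bool
    de_shift: Optional[np.ndarray] = None  # per-sample x per-target added shift

    def noiseless_targets(self, latents: Optional[np.ndarray] = None) -> np.ndarray:
        """Per-gene scaled nonlinear map of the latents, before noise and
        series effects (DE class shifts included when present)."""
        z = self.latents if latents is None else latents
        proj = z @ self.target_weights
        out = np.empty_like(proj)
        for j, kind in enumerate(self.target_kind):
            f = np.tanh if kind == "tanh" else (lambda v: 1.0 / (1.0 + np.exp(-v)))
            out[:, j] = f(proj[:, j])
        out = out * self.target_scale + self.target_offset
        if self.de_shift is not None and latents is None:
            out = out + self.de_shift
        return out


def _target_kinds(config: GeneratorConfig) -> List[str]:
    if config.nonlinearity == "mixed":
        return ["tanh" if j % 2 == 0 else "sigmoid" for j in range(config.n_targets)]
    return [config.nonlinearity] * config.n_targets


def _generate(
    config: GeneratorConfig, phenotype: bool
) -> Tuple[ExpressionDataset, GroundTruth]:
    rng = np.random.default_rng(config.seed)
    n_s, n_l, n_t, n_z = (
        config.n_samples,
        config.n_landmarks,
        config.n_targets,
        config.n_latent,
    )
    latents = rng.standard_normal((n_s, n_z))
    landmark_map = rng.standard_normal((n_z, n_l)) / np.sqrt(n_z)
    target_weights = rng.standard_normal((n_z, n_t)) / np.sqrt(n_z)
    kinds = _target_kinds(config)
    lo, hi = config.target_scale_range
    scales = rng.uniform(lo, hi, size=n_t)
    offsets = rng.uniform(-config.target_offset_range, config.target_offset_range, size=n_t)

    series_names = [f"SER{k:03d}" for k in range(config.n_series)]
    series_of_sample = [series_names[i % config.n_series] for i in range(n_s)]
    series_intercept = {
        name: float(rng.normal(0.0, config.series_effect_sd)) for name in series_names
    }

    phenotype_labels: Optional[List[str]] = None
    de_flags: Optional[np.ndarray] = None
    de_shift: Optional[np.ndarray] = None
    if phenotype:
        phenotype_labels = ["A" if i < n_s // 2 else "B" for i in range(n_s)]
        de_flags = np.zeros(n_t, dtype=bool)
        de_idx = rng.choice(n_t, size=config.n_de_genes, replace=False)
        if config.de_effect_size != 0.0:
            de_flags[de_idx] = True
        de_shift = np.zeros((n_s, n_t))
        is_b = np.array([lab == "B" for lab in phenotype_labels])
        de_shift[np.ix_(is_b, de_idx)] = config.de_effect_size

    truth = GroundTruth(
        latents=latents,
        landmark_map=landmark_map,
        target_weights=target_weights,
        target_kind=kinds,
        target_scale=scales,
        target_offset=offsets,
        series_of_sample=series_of_sample,
        series_intercept=series_intercept,
        de_flags=de_flags,
        de_shift=de_shift,
    )

    landmarks = latents @ landmark_map
    targets = truth.noiseless_targets()
    if config.noise_sd > 0:
        landmarks = landmarks + rng.normal(0.0, config.noise_sd, size=landmarks.shape)
        targets = targets + rng.normal(0.0, config.noise_sd, size=targets.shape)
    block = np.array([series_intercept[s] for s in series_of_sample])[:, None]
    values = np.hstack([landmarks, targets]) + block

    dataset = ExpressionDataset(
        values=values,
        sample_ids=[f"S{i:05d}" for i in range(n_s)],
        gene_ids=[f"L{j:04d}" for j in range(n_l)] + [f"T{j:04d}" for j in range(n_t)],
        gene_role=["landmark"] * n_l + ["target"] * n_t,
        series_label=series_of_sample,
        phenotype=phenotype_labels,
    )
    return dataset, truth


def generate_expression(config: GeneratorConfig) -> Tuple[ExpressionDataset, GroundTruth]:
    """Landmark + target expression with series structure; no phenotype."""
    return _generate(config, phenotype=False)


def generate_phenotype_dataset(
    config: GeneratorConfig,
) -> Tuple[ExpressionDataset, np.ndarray]:
    """Two-class dataset in which class B's designated DE target genes are
    shifted by ``de_effect_size``.  Returns (dataset, per-target DE flags)."""
    dataset, truth = _generate(config, phenotype=True)
    return dataset, truth.de_flags


def write_ground_truth_sidecar(truth: GroundTruth, gene_ids: List[str], path) -> None:
    """Tab-delimited sidecar: target gene id, is_de, scale, offset."""
    from pathlib import Path

    lines = ["gene_id\tis_de\tscale\toffset"]
    flags = (
        truth.de_flags
        if truth.de_flags is not None
        else np.zeros(len(truth.target_scale), dtype=bool)
    )
    for gid, f, s, o in zip(gene_ids, flags, truth.target_scale, truth.target_offset):
        lines.append(f"{gid}\t{int(f)}\t{s:.10g}\t{o:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")
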