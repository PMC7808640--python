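"""D-GEX-family feed-forward networks with fixed or TAAF activations.

The architecture family: one to three fully connected hidden layers of equal
width mapping landmark-gene expression to target-gene expression, 25% dropout
on hidden activations, and an output layer that is either linear (one neuron
per target) or itself a TAAF layer.  Hidden units either use a plain inner
activation (tanh / logistic sigmoid) with a conventional bias, or a TAAF —
in which case gamma plays the role of the bias and no separate bias exists.

Because the full target-gene set is large in the motivating application, the
targets can be split into two random halves served by two half-networks whose
predictions are concatenated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .activations import (
    FULL_MASK,
    InnerActivation,
    TAAFParameters,
    get_inner,
    init_taaf,
    taaf_value,
)

__all__ = [
    "ArchitectureSpec",
    "Layer",
    "NetworkParameters",
    "build_network",
    "forward",
    "parameter_count",
    "capacity_matched_width",
    "split_target_genes",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ArchitectureSpec:
    """Description of one member of the network family."""

    input_dim: int
    output_dim: int
    n_hidden_layers: int = 1
    width: int = 3000
    dropout_rate: float = 0.25
    inner_kind: str = "tanh"
    hidden_mode: str = "fixed"  # "fixed" | "taaf"
    output_mode: str = "linear"  # "linear" | "taaf"
    adaptivity_mask: FrozenSet[str] = field(default_factory=lambda: FULL_MASK)

    def __post_init__(self) -> None:
        if self.n_hidden_layers not in (1, 2, 3):
            raise ValueError("n_hidden_layers must be 1, 2 or 3")
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.hidden_mode not in ("fixed", "taaf"):
            raise ValueError("hidden_mode must be 'fixed' or 'taaf'")
        if self.output_mode not in ("linear", "taaf"):
            raise ValueError("output_mode must be 'linear' or 'taaf'")
        if self.input_dim < 1 or self.output_dim < 1:
            raise ValueError("input_dim and output_dim must be >= 1")
        get_inner(self.inner_kind)  # validates the kind
        object.__setattr__(self, "adaptivity_mask", frozenset(self.adaptivity_mask))

    def layer_dims(self) -> List[Tuple[int, int]]:
        dims = [self.input_dim] + [self.width] * self.n_hidden_layers + [self.output_dim]
        return list(zip(dims[:-1], dims[1:]))


@dataclass
class Layer:
    """One dense layer: weights plus either a bias vector or TAAF parameters."""

    weights: np.ndarray  # fan_in x fan_out
    bias: Optional[np.ndarray] = None
    taaf: Optional[TAAFParameters] = None

    def __post_init__(self) -> None:
        if (self.bias is None) == (self.taaf is None):
            raise ValueError("a layer has exactly one of bias or TAAF parameters")


@dataclass
class NetworkParameters:
    """Concrete weights for one ArchitectureSpec, plus provenance."""

    architecture: ArchitectureSpec
    layers: List[Layer]
    rng_seed: int
    target_ids: Optional[List[str]] = None  # genes served, for half-networks

    def copy(self) -> "NetworkParameters":
        return NetworkParameters(
            architecture=self.architecture,
            layers=[
                Layer(
                    weights=l.weights.copy(),
                    bias=None if l.bias is None else l.bias.copy(),
                    taaf=None if l.taaf is None else l.taaf.copy(),
                )
                for l in self.layers
            ],
            rng_seed=self.rng_seed,
            target_ids=None if self.target_ids is None else list(self.target_ids),
        )


def build_network(spec: ArchitectureSpec, seed: int) -> NetworkParameters:
    """Initialize a network: normalized (fan-in + fan-out scaled uniform)
    weights, zero biases, TAAF parameters at (1, 1, 0, 0).

    Deterministic given (spec, seed).
    """
    rng = np.random.default_rng(seed)
    layers: List[Layer] = []
    dims = spec.layer_dims()
    n_layers = len(dims)
    for k, (fan_in, fan_out) in enumerate(dims):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        is_output = k == n_layers - 1
        mode = spec.output_mode if is_output else spec.hidden_mode
        if (is_output and mode == "taaf") or (not is_output and mode == "taaf"):
            layers.append(Layer(weights=w, taaf=init_taaf(fan_out, spec.adaptivity_mask)))
        else:
            layers.append(Layer(weights=w, bias=np.zeros(fan_out)))
    return NetworkParameters(architecture=spec, layers=layers, rng_seed=seed)


def _apply_layer(
    x: np.ndarray, layer: Layer, inner: InnerActivation, activate: bool
) -> np.ndarray:
    z = x @ layer.weights
    if layer.taaf is not None:
        return taaf_value(z, layer.taaf, inner)
    z = z + layer.bias
    return inner.value(z) if activate else z


def forward(
    network: NetworkParameters,
    landmarks: np.ndarray,
    training: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Forward pass; returns the samples x output_dim prediction matrix.

    During training, inverted dropout at the spec's rate is applied to every
    hidden activation (never to inputs or the output layer), so evaluation
    needs no rescaling and is deterministic.
    """
    spec = network.architecture
    x = np.asarray(landmarks, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != spec.input_dim:
        raise ValueError(
            f"landmark matrix has {x.shape[1]} columns, expected {spec.input_dim}"
        )
    inner = get_inner(spec.inner_kind)
    rng = np.random.default_rng(seed) if training else None
    keep = 1.0 - spec.dropout_rate
    for k, layer in enumerate(network.layers):
        is_output = k == len(network.layers) - 1
        x = _apply_layer(x, layer, inner, activate=not is_output)
        if not is_output and training and spec.dropout_rate > 0:
            mask = rng.random(x.shape) < keep
            x = x * mask / keep
    return x


def parameter_count(spec: ArchitectureSpec, trainable_only: bool = False) -> int:
    """Exact stored-parameter count.

    Conventions: a fixed-activation or linear unit costs fan_in weights plus
    one bias; a TAAF unit costs fan_in weights plus its four TAAF parameters
    and no bias.  With ``trainable_only``, frozen TAAF parameters (outside the
    adaptivity mask) are excluded.
    """
    taaf_cost = len(spec.adaptivity_mask) if trainable_only else 4
    total = 0
    dims = spec.layer_dims()
    for k, (fan_in, fan_out) in enumerate(dims):
        is_output = k == len(dims) - 1
        mode = spec.output_mode if is_output else spec.hidden_mode
        per_unit = fan_in + (taaf_cost if mode == "taaf" else 1)
        total += per_unit * fan_out
    return total


def capacity_matched_width(
    reference: ArchitectureSpec, template: ArchitectureSpec, trainable_only: bool = False
) -> int:
    """Largest width W such that the template at W has no more parameters
    than the reference, while W+1 would exceed it.

    Used to shrink a TAAF network until its total parameter count matches a
    fixed-activation reference of the same depth.
    """
    for name in ("n_hidden_layers", "input_dim", "output_dim"):
        if getattr(reference, name) != getattr(template, name):
            raise ValueError(f"reference and template must share {name}")
    budget = parameter_count(reference, trainable_only)

    def count_at(w: int) -> int:
        spec = ArchitectureSpec(
            **{**asdict(template), "width": w, "adaptivity_mask": template.adaptivity_mask}
        )
        return parameter_count(spec, trainable_only)

    if count_at(1) > budget:
        raise ValueError("no width >= 1 fits within the reference parameter budget")
    lo, hi = 1, max(reference.width, 1)
    while count_at(hi) <= budget:
        hi *= 2
    while hi - lo > 1:  # invariant: count_at(lo) <= budget < count_at(hi)
        mid = (lo + hi) // 2
        if count_at(mid) <= budget:
            lo = mid
        else:
            hi = mid
    return lo


def split_target_genes(
    gene_ids: Sequence[str], seed: int
) -> Tuple[List[str], List[str]]:
    """Split target genes into two random halves (sizes differ by at most 1),
    one per half-network.  Deterministic under the seed; operates on sorted
    ids so the split is order independent."""
    ids = sorted(str(g) for g in gene_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 genes to split")
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    half = (len(ids) + 1) // 2
    return ids[:half], ids[half:]


# ---------------------------------------------------------------------------
# Checkpoints: a single .npz archive with documented key names
# ---------------------------------------------------------------------------


def save_checkpoint(network: NetworkParameters, path: str | Path) -> None:
    """Write a network to a single archive.

    Keys: ``spec/json`` (architecture as JSON), ``layer_k/weights``,
    ``layer_k/bias`` or ``layer_k/taaf/{alpha,beta,gamma,delta}``,
    ``meta/seed``, ``meta/format_version``, ``meta/target_ids``.
    """
    spec_dict = asdict(network.architecture)
    spec_dict["adaptivity_mask"] = sorted(spec_dict["adaptivity_mask"])
    arrays: dict[str, np.ndarray] = {
        "spec/json": np.array(json.dumps(spec_dict)),
        "meta/seed": np.array(network.rng_seed),
        "meta/format_version": np.array(CHECKPOINT_FORMAT_VERSION),
    }
    if network.target_ids is not None:
        arrays["meta/target_ids"] = np.array(network.target_ids)
    for k, layer in enumerate(network.layers):
        arrays[f"layer_{k}/weights"] = layer.weights
        if layer.bias is not None:
            arrays[f"layer_{k}/bias"] = layer.bias
        else:
            t = layer.taaf
            arrays[f"layer_{k}/taaf/alpha"] = t.alpha
            arrays[f"layer_{k}/taaf/beta"] = t.beta
            arrays[f"layer_{k}/taaf/gamma"] = t.gamma
            arrays[f"layer_{k}/taaf/delta"] = t.delta
            arrays[f"layer_{k}/taaf/mask"] = np.array(sorted(t.adaptivity_mask))
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> NetworkParameters:
    """Read a network checkpoint written by :func:`save_checkpoint`."""
    with np.load(path, allow_pickle=False) as archive:
        version = int(archive["meta/format_version"])
        if version != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format version {version}")
        spec_dict = json.loads(str(archive["spec/json"]))
        spec_dict["adaptivity_mask"] = frozenset(spec_dict["adaptivity_mask"])
        spec = ArchitectureSpec(**spec_dict)
        layers: List[Layer] = []
        for k in range(spec.n_hidden_layers + 1):
            w = archive[f"layer_{k}/weights"]
            if f"layer_{k}/bias" in archive:
                layers.append(Layer(weights=w, bias=archive[f"layer_{k}/bias"]))
            else:
                taaf = TAAFParameters(
                    alpha=archive[f"layer_{k}/taaf/alpha"],
                    beta=archive[f"layer_{k}/taaf/beta"],
                    gamma=archive[f"layer_{k}/taaf/gamma"],
                    delta=archive[f"layer_{k}/taaf/delta"],
                    adaptivity_mask=frozenset(
                        str(m) for m in archive[f"layer_{k}/taaf/mask"]
                    ),
                )
                layers.append(Layer(weights=w, taaf=taaf))
        target_ids = (
            [str(g) for g in archive["meta/target_ids"]]
            if "meta/target_ids" in archive
            else None
        )
        return NetworkParameters(
            architecture=spec,
            layers=layers,
            rng_seed=int(archive["meta/seed"]),
            target_ids=target_ids,
        )
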