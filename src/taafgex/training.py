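"""Training protocol: mini-batch Nadam, epoch loop, best-epoch selection.

Optimization follows the Nadam recipe (Adam with Nesterov momentum): the
momentum schedule is psi(t) = beta1 * (1 - 0.5 * 0.96**(t * schedule_decay))
applied per update step, with bias-corrected first and second moments.
Defaults: learning rate 5e-4, beta1 0.9, beta2 0.999, schedule decay 0.004,
batch size 256, 600 epochs.

The training loss defaults to mean squared error; every *reported* metric is
MAE-based (see :mod:`taafgex.evaluation`), and validation MMAE drives
best-epoch selection — the model returned is the snapshot from the epoch with
the lowest validation MMAE, not the final epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .activations import TAAFParameters, get_inner, init_taaf, taaf_partials, taaf_value
from .data_io import ExpressionDataset
from .evaluation import mae_per_sample, mmae
from .model import NetworkParameters, forward

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "TrainingDivergenceError",
    "train",
    "predict_full_profile",
    "fit_taaf_unit",
]


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int, loss: float):
        super().__init__(f"non-finite training loss {loss!r} at epoch {epoch}")
        self.epoch = epoch


@dataclass
class TrainingConfig:
    learning_rate: float = 0.0005
    beta1: float = 0.9
    beta2: float = 0.999
    schedule_decay: float = 0.004
    batch_size: int = 256
    n_epochs: int = 600
    loss_kind: str = "squared-error"  # or "absolute-error"
    seed: int = 0
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("beta1 and beta2 must lie in (0, 1)")
        if self.batch_size < 1 or self.n_epochs < 1:
            raise ValueError("batch_size and n_epochs must be >= 1")
        if self.loss_kind not in ("squared-error", "absolute-error"):
            raise ValueError("loss_kind must be 'squared-error' or 'absolute-error'")


@dataclass
class TrainingHistory:
    train_loss: List[float] = field(default_factory=list)
    val_mmae: List[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        """Argmin of validation MMAE, first occurrence on ties (0-based)."""
        if not self.val_mmae:
            raise ValueError("empty history")
        arr = np.asarray(self.val_mmae)
        return int(np.argmin(arr))

    def to_tsv(self) -> str:
        lines = ["epoch\ttrain_loss\tval_mmae"]
        for e, (tl, vm) in enumerate(zip(self.train_loss, self.val_mmae)):
            lines.append(f"{e}\t{tl:.10g}\t{vm:.10g}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Nadam
# ---------------------------------------------------------------------------


class _Nadam:
    """Nadam with the 0.96**(t*eta) momentum schedule, one state per array."""

    def __init__(self, params: List[np.ndarray], config: TrainingConfig):
        self.cfg = config
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.m_schedule = 1.0
        self.t = 0

    def step(self, params: List[np.ndarray], grads: List[Optional[np.ndarray]]) -> None:
        cfg = self.cfg
        self.t += 1
        t = self.t
        mu_t = cfg.beta1 * (1.0 - 0.5 * 0.96 ** (t * cfg.schedule_decay))
        mu_t1 = cfg.beta1 * (1.0 - 0.5 * 0.96 ** ((t + 1) * cfg.schedule_decay))
        m_schedule_new = self.m_schedule * mu_t
        m_schedule_next = m_schedule_new * mu_t1
        self.m_schedule = m_schedule_new
        for i, (p, g) in enumerate(zip(params, grads)):
            if g is None:  # frozen parameter
                continue
            g_prime = g / (1.0 - m_schedule_new)
            self.m[i] = cfg.beta1 * self.m[i] + (1.0 - cfg.beta1) * g
            m_prime = self.m[i] / (1.0 - m_schedule_next)
            self.v[i] = cfg.beta2 * self.v[i] + (1.0 - cfg.beta2) * g * g
            v_prime = self.v[i] / (1.0 - cfg.beta2**t)
            m_bar = (1.0 - mu_t) * g_prime + mu_t1 * m_prime
            p -= cfg.learning_rate * m_bar / (np.sqrt(v_prime) + cfg.epsilon)


# ---------------------------------------------------------------------------
# Parameter registry and backprop
# ---------------------------------------------------------------------------

_TAAF_NAMES = ("alpha", "beta", "gamma", "delta")


def _collect_params(network: NetworkParameters) -> Tuple[List[np.ndarray], List[bool]]:
    """Flatten network parameters into (arrays, trainable flags).

    Order per layer: weights, then bias or (alpha, beta, gamma, delta).
    TAAF parameters outside the adaptivity mask are marked frozen.
    """
    arrays: List[np.ndarray] = []
    trainable: List[bool] = []
    for layer in network.layers:
        arrays.append(layer.weights)
        trainable.append(True)
        if layer.bias is not None:
            arrays.append(layer.bias)
            trainable.append(True)
        else:
            t = layer.taaf
            for name in _TAAF_NAMES:
                arrays.append(getattr(t, name))
                trainable.append(name in t.adaptivity_mask)
    return arrays, trainable


def _forward_backward(
    network: NetworkParameters,
    x: np.ndarray,
    y: np.ndarray,
    loss_kind: str,
    dropout_rng: Optional[np.random.Generator],
) -> Tuple[float, List[np.ndarray]]:
    """One mini-batch pass; returns (loss, gradients in registry order)."""
    spec = network.architecture
    inner = get_inner(spec.inner_kind)
    keep = 1.0 - spec.dropout_rate
    n_layers = len(network.layers)

    # forward with caches
    acts = [x]  # layer inputs
    caches: List[dict] = []
    h = x
    for k, layer in enumerate(network.layers):
        is_output = k == n_layers - 1
        z = h @ layer.weights
        cache: dict = {"input": h, "z": z}
        if layer.taaf is not None:
            t = layer.taaf
            u = t.beta * z + t.gamma
            cache["u"] = u
            cache["fu"] = inner.value(u)
            cache["fpu"] = inner.derivative(u)
            a = t.alpha * cache["fu"] + t.delta
        elif is_output:  # linear output
            a = z + layer.bias
        else:
            u = z + layer.bias
            cache["u"] = u
            cache["fpu"] = inner.derivative(u)
            a = inner.value(u)
        if not is_output and dropout_rng is not None and spec.dropout_rate > 0:
            mask = dropout_rng.random(a.shape) < keep
            cache["dropout"] = mask
            a = a * mask / keep
        caches.append(cache)
        h = a
        acts.append(h)

    pred = h
    resid = pred - y
    denom = resid.size
    if loss_kind == "squared-error":
        loss = float(np.mean(resid**2))
        g = 2.0 * resid / denom
    else:
        loss = float(np.mean(np.abs(resid)))
        g = np.sign(resid) / denom

    # backward
    grads: List[List[np.ndarray]] = [[] for _ in network.layers]
    for k in range(n_layers - 1, -1, -1):
        layer = network.layers[k]
        cache = caches[k]
        is_output = k == n_layers - 1
        if not is_output and "dropout" in cache:
            g = g * cache["dropout"] / keep
        if layer.taaf is not None:
            t = layer.taaf
            fu, fpu, z = cache["fu"], cache["fpu"], cache["z"]
            g_alpha = np.sum(g * fu, axis=0)
            g_beta = np.sum(g * t.alpha * z * fpu, axis=0)
            g_gamma = np.sum(g * t.alpha * fpu, axis=0)
            g_delta = np.sum(g, axis=0)
            g_z = g * t.alpha * t.beta * fpu
            g_w = cache["input"].T @ g_z
            grads[k] = [g_w, g_alpha, g_beta, g_gamma, g_delta]
        elif is_output:  # linear output
            g_z = g
            grads[k] = [cache["input"].T @ g_z, np.sum(g_z, axis=0)]
        else:
            g_z = g * cache["fpu"]
            grads[k] = [cache["input"].T @ g_z, np.sum(g_z, axis=0)]
        g = g_z @ layer.weights.T

    flat: List[np.ndarray] = []
    for layer_grads in grads:
        flat.extend(layer_grads)
    return loss, flat


def _align_columns(
    network: NetworkParameters, dataset: ExpressionDataset
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Landmark and target blocks column-aligned with the network."""
    landmarks = dataset.landmarks()
    if landmarks.shape[1] != network.architecture.input_dim:
        raise ValueError(
            f"dataset has {landmarks.shape[1]} landmarks, network expects "
            f"{network.architecture.input_dim}"
        )
    target_ids = network.target_ids or dataset.target_ids
    missing = set(target_ids) - set(dataset.target_ids)
    if missing:
        raise ValueError(f"dataset lacks target genes: {sorted(missing)[:5]} ...")
    if len(target_ids) != network.architecture.output_dim:
        raise ValueError(
            f"network serves {network.architecture.output_dim} targets but "
            f"{len(target_ids)} target ids resolved"
        )
    return landmarks, dataset.target_columns(target_ids), list(target_ids)


def train(
    network: NetworkParameters,
    train_data: ExpressionDataset,
    val_data: ExpressionDataset,
    config: TrainingConfig,
) -> Tuple[NetworkParameters, TrainingHistory]:
    """Train with mini-batch Nadam; return the best validation snapshot.

    Sample order is reshuffled every epoch under the config seed.  After each
    epoch the validation MMAE is computed (dropout off) and the parameters
    are snapshotted whenever it improves; the returned network is the best
    snapshot, with the full per-epoch history alongside.
    """
    network = network.copy()
    x_train, y_train, target_ids = _align_columns(network, train_data)
    x_val, y_val, _ = _align_columns(network, val_data)
    if network.target_ids is None:
        network.target_ids = target_ids

    params, trainable = _collect_params(network)
    optimizer = _Nadam(params, config)
    rng = np.random.default_rng(config.seed)
    history = TrainingHistory()
    best: Optional[NetworkParameters] = None
    best_val = math.inf
    n = x_train.shape[0]

    for epoch in range(config.n_epochs):
        order = rng.permutation(n)
        dropout_rng = np.random.default_rng(rng.integers(2**31))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = _forward_backward(
                network, x_train[idx], y_train[idx], config.loss_kind, dropout_rng
            )
            if not np.isfinite(loss):
                raise TrainingDivergenceError(epoch, loss)
            masked = [g if t else None for g, t in zip(grads, trainable)]
            optimizer.step(params, masked)
            epoch_loss += loss
            n_batches += 1
        history.train_loss.append(epoch_loss / n_batches)

        val_pred = forward(network, x_val, training=False)
        val_score = mmae(mae_per_sample(y_val, val_pred))
        history.val_mmae.append(val_score)
        if val_score < best_val:
            best_val = val_score
            best = network.copy()

    return best, history


def predict_full_profile(
    half_networks: Sequence[NetworkParameters],
    landmarks: np.ndarray,
    target_order: Optional[Sequence[str]] = None,
) -> Tuple[np.ndarray, List[str]]:
    """Concatenate half-network predictions into one full target profile.

    The half-networks' target-id sets must partition the full target set.
    Columns are ordered by ``target_order`` when given, else by sorted gene
    id (the canonical order).  Returns (matrix, ordered target ids).
    """
    if any(net.target_ids is None for net in half_networks):
        raise ValueError("every half-network must declare its target_ids")
    id_sets = [set(net.target_ids) for net in half_networks]
    union: set = set()
    total = 0
    for s in id_sets:
        union |= s
        total += len(s)
    if total != len(union):
        raise ValueError("half-network target sets overlap")
    order = list(target_order) if target_order is not None else sorted(union)
    if set(order) != union:
        raise ValueError("target_order does not match the union of half-network targets")

    col_owner: Dict[str, Tuple[int, int]] = {}
    for m, net in enumerate(half_networks):
        for j, g in enumerate(net.target_ids):
            col_owner[g] = (m, j)
    preds = [forward(net, landmarks, training=False) for net in half_networks]
    out = np.empty((preds[0].shape[0], len(order)))
    for c, g in enumerate(order):
        m, j = col_owner[g]
        out[:, c] = preds[m][:, j]
    return out, order


def fit_taaf_unit(
    y: np.ndarray,
    targets: np.ndarray,
    inner_kind: str = "tanh",
    mask=("alpha", "beta", "gamma", "delta"),
    config: Optional[TrainingConfig] = None,
) -> TAAFParameters:
    """Fit one TAAF unit g(y) = alpha*f(beta*y + gamma) + delta to data.

    The pre-activation ``y`` is taken as given (input weight fixed at 1), so
    only the four TAAF parameters are optimized, by mini-batch Nadam on the
    configured loss.  Used for parameter-recovery studies; note the sign
    ambiguity of odd inner functions: for tanh, (a, b, g, d) and
    (-a, -b, -g, d) are the same function.
    """
    cfg = config or TrainingConfig(learning_rate=0.02, n_epochs=400, batch_size=256)
    y = np.asarray(y, dtype=float).ravel()
    targets = np.asarray(targets, dtype=float).ravel()
    if y.shape != targets.shape:
        raise ValueError("y and targets must have the same length")
    inner = get_inner(inner_kind)
    params = init_taaf(1, mask)
    arrays = [params.alpha, params.beta, params.gamma, params.delta]
    trainable = [name in params.adaptivity_mask for name in _TAAF_NAMES]
    optimizer = _Nadam(arrays, cfg)
    rng = np.random.default_rng(cfg.seed)
    n = len(y)
    for _ in range(cfg.n_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            yb = y[idx][:, None]
            tb = targets[idx][:, None]
            pred = taaf_value(yb, params, inner)
            resid = pred - tb
            if cfg.loss_kind == "squared-error":
                g = 2.0 * resid / resid.size
            else:
                g = np.sign(resid) / resid.size
            _, d_alpha, d_beta, d_gamma, d_delta = taaf_partials(yb, params, inner)
            grads = [
                np.sum(g * d, axis=0)
                for d in (d_alpha, d_beta, d_gamma, d_delta)
            ]
            masked = [gr if t else None for gr, t in zip(grads, trainable)]
            optimizer.step(arrays, masked)
    return params
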