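"""Transformative adaptive activation functions (TAAFs).

A TAAF wraps an *inner* activation function ``f`` with four per-neuron
parameters::

    g(f, y) = alpha * f(beta * y + gamma) + delta

``alpha`` scales the amplitude, ``beta`` the slope, ``gamma`` translates the
input (and doubles as the neuron's bias — TAAF units carry no separate bias
term), and ``delta`` translates the output.  At initialization
``(alpha, beta, gamma, delta) = (1, 1, 0, 0)``, so a freshly initialized TAAF
is exactly its inner function.  All four parameters are trained by
back-propagation like ordinary weights; constrained variants freeze any
subset of them at their initial values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, FrozenSet, Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "InnerActivation",
    "TAAFParameters",
    "TAAF_PARAM_NAMES",
    "FULL_MASK",
    "get_inner",
    "taaf_value",
    "taaf_partials",
    "init_taaf",
    "enumerate_constrained_variants",
    "equivalent_sigmoid_params",
]

TAAF_PARAM_NAMES: Tuple[str, str, str, str] = ("alpha", "beta", "gamma", "delta")
FULL_MASK: FrozenSet[str] = frozenset(TAAF_PARAM_NAMES)


@dataclass(frozen=True)
class InnerActivation:
    """A base activation function and its derivative.

    Supported kinds: ``"tanh"`` (hyperbolic tangent), ``"sigmoid"``
    (logistic sigmoid) and ``"identity"``.
    """

    kind: str
    value: Callable[[np.ndarray], np.ndarray]
    derivative: Callable[[np.ndarray], np.ndarray]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # scipy.special.expit without the import; numerically stable either way
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _sigmoid_deriv(x: np.ndarray) -> np.ndarray:
    s = _sigmoid(x)
    return s * (1.0 - s)


_INNER: dict[str, InnerActivation] = {
    "tanh": InnerActivation("tanh", np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
    "sigmoid": InnerActivation("sigmoid", _sigmoid, _sigmoid_deriv),
    "identity": InnerActivation(
        "identity",
        lambda x: np.asarray(x, dtype=float),
        lambda x: np.ones_like(np.asarray(x, dtype=float)),
    ),
}


def get_inner(kind: str) -> InnerActivation:
    """Look up an inner activation by kind name."""
    try:
        return _INNER[kind]
    except KeyError:
        raise ValueError(
            f"unknown inner activation {kind!r}; expected one of {sorted(_INNER)}"
        ) from None


def _normalize_mask(mask: Iterable[str]) -> FrozenSet[str]:
    mask = frozenset(mask)
    unknown = mask - FULL_MASK
    if unknown:
        raise ValueError(f"unknown TAAF parameter names in mask: {sorted(unknown)}")
    return mask


@dataclass
class TAAFParameters:
    """Per-unit TAAF parameter vectors plus the trainable-subset mask.

    All four vectors share one length (the number of units).  Parameters
    outside ``adaptivity_mask`` are frozen: training must never change them.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    adaptivity_mask: FrozenSet[str] = field(default_factory=lambda: FULL_MASK)

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.delta = np.atleast_1d(np.asarray(self.delta, dtype=float))
        n = len(self.alpha)
        if not (len(self.beta) == len(self.gamma) == len(self.delta) == n):
            raise ValueError("alpha, beta, gamma, delta must have identical length")
        self.adaptivity_mask = _normalize_mask(self.adaptivity_mask)

    @property
    def n_units(self) -> int:
        return len(self.alpha)

    def copy(self) -> "TAAFParameters":
        return TAAFParameters(
            self.alpha.copy(),
            self.beta.copy(),
            self.gamma.copy(),
            self.delta.copy(),
            self.adaptivity_mask,
        )


def init_taaf(n_units: int, mask: Iterable[str] = FULL_MASK) -> TAAFParameters:
    """Fresh TAAF parameters: alpha = beta = 1 and gamma = delta = 0 per unit.

    ``mask`` selects which of the four parameters are trainable; the empty
    mask yields a frozen TAAF that stays identical to its inner function.
    """
    if n_units < 1:
        raise ValueError(f"n_units must be >= 1, got {n_units}")
    return TAAFParameters(
        alpha=np.ones(n_units),
        beta=np.ones(n_units),
        gamma=np.zeros(n_units),
        delta=np.zeros(n_units),
        adaptivity_mask=_normalize_mask(mask),
    )


def _check_length(y: np.ndarray, params: TAAFParameters) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != params.n_units:
        raise ValueError(
            f"pre-activation trailing dimension {y.shape[-1]} does not match "
            f"{params.n_units} TAAF units"
        )
    return y


def taaf_value(
    y: np.ndarray, params: TAAFParameters, inner: InnerActivation
) -> np.ndarray:
    """Evaluate ``alpha * f(beta * y + gamma) + delta`` elementwise per unit.

    ``y`` may carry a leading batch dimension; parameters broadcast along it.
    Non-finite parameters propagate into the output (no clamping).
    """
    y = _check_length(y, params)
    return params.alpha * inner.value(params.beta * y + params.gamma) + params.delta


def taaf_partials(
    y: np.ndarray, params: TAAFParameters, inner: InnerActivation
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Analytic partial derivatives of the TAAF output.

    Returns ``(d/dy, d/dalpha, d/dbeta, d/dgamma, d/ddelta)``, each with the
    shape of ``y``:

    * d/dy     = alpha * beta * f'(beta*y + gamma)
    * d/dalpha = f(beta*y + gamma)
    * d/dbeta  = alpha * y * f'(beta*y + gamma)
    * d/dgamma = alpha * f'(beta*y + gamma)
    * d/ddelta = 1
    """
    y = _check_length(y, params)
    u = params.beta * y + params.gamma
    fu = inner.value(u)
    fpu = inner.derivative(u)
    d_y = params.alpha * params.beta * fpu
    d_alpha = fu
    d_beta = params.alpha * y * fpu
    d_gamma = params.alpha * fpu
    d_delta = np.ones_like(y)
    return d_y, d_alpha, d_beta, d_gamma, d_delta


def enumerate_constrained_variants() -> List[FrozenSet[str]]:
    """All 16 subsets of {alpha, beta, gamma, delta} as adaptivity masks.

    Ordered by subset size, then lexicographically in the canonical
    (alpha, beta, gamma, delta) parameter order, so ablation tables are
    reproducible.  The empty subset is the plain inner activation; the full
    subset is the unconstrained TAAF.
    """
    order = {name: i for i, name in enumerate(TAAF_PARAM_NAMES)}
    masks: List[FrozenSet[str]] = []
    for size in range(5):
        combos = sorted(
            itertools.combinations(TAAF_PARAM_NAMES, size),
            key=lambda c: tuple(order[n] for n in c),
        )
        masks.extend(frozenset(c) for c in combos)
    return masks


def equivalent_sigmoid_params(tanh_params: TAAFParameters) -> TAAFParameters:
    """Re-express a tanh-inner TAAF as a pointwise-equal sigmoid-inner TAAF.

    Because ``tanh(u) = 2*sigmoid(2u) - 1``,

        alpha*tanh(beta*y + gamma) + delta
          = 2*alpha*sigmoid(2*beta*y + 2*gamma) + (delta - alpha),

    i.e. the mapped parameters are ``(2a, 2b, 2g, d - a)``.  In particular the
    plain logistic sigmoid is the tanh-TAAF ``(1/2, 1/2, 0, 1/2)``.
    """
    return TAAFParameters(
        alpha=2.0 * tanh_params.alpha,
        beta=2.0 * tanh_params.beta,
        gamma=2.0 * tanh_params.gamma,
        delta=tanh_params.delta - tanh_params.alpha,
        adaptivity_mask=tanh_params.adaptivity_mask,
    )
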