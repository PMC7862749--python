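"""The zero-inflated generalized Dirichlet (ZIGD) distribution.

A generalized Dirichlet (GD) composition of length V is built by
stick-breaking over V-1 independent Beta(a, b) variables Q_1..Q_{V-1}
(Connor-Mosimann construction):

    beta_1 = Q_1,   beta_i = Q_i * prod_{l<i} (1 - Q_l),
    beta_V = prod_{l<V} (1 - Q_l).

The ZIGD adds a zero-inflation probability pi to each stick variable: Q_i is
exactly 0 with probability pi, else a Beta(a, b) draw.  A zeroed stick gives
an exactly-zero composition component -- a *structural* zero, a taxon truly
absent from the subcommunity -- flagged by the indicator delta_i = I(beta_i = 0).
The last component is never zero-inflated: it absorbs the residual stick mass
and is therefore always strictly positive.

The ZIGD is not exchangeable in component order; the taxon order of the input
count matrix is the stick order and is fixed for a run.

Hyperparameters are symmetric scalars, except that ``b`` may be given
per stick position: with ``a = eta`` and ``b_i = eta * (V - i)`` the GD
(pi = 0) reduces exactly to the symmetric Dirichlet(eta), which is the
nesting point used by the reduction checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import as_generator

__all__ = [
    "ZIGDParams",
    "CompositionWithZeros",
    "sample_zi_betas",
    "stick_break",
    "sample_zigd",
    "dirichlet_nesting_b",
]


def _b_vector(b: float | np.ndarray, V: int) -> np.ndarray:
    """Broadcast a scalar/vector b to a length-(V-1) positive float array."""
    arr = np.asarray(b, dtype=float)
    if arr.ndim == 0:
        arr = np.full(V - 1, float(arr))
    if arr.shape != (V - 1,):
        raise ValueError(f"b must be a scalar or a length-{V - 1} vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("b must be positive and finite")
    return arr


def dirichlet_nesting_b(eta: float, V: int) -> np.ndarray:
    """Per-position b at which GD(a=eta, b) equals the symmetric Dirichlet(eta).

    For a Dirichlet(alpha_1..alpha_V) the equivalent GD has a_i = alpha_i and
    b_i = alpha_{i+1} + ... + alpha_V; symmetric eta gives b_i = eta * (V - i)
    (1-indexed i = 1..V-1).
    """
    return eta * np.arange(V - 1, 0, -1, dtype=float)


@dataclass(frozen=True)
class ZIGDParams:
    """ZIGD hyperparameters: zero-inflation pi, beta shapes (a, b), length V."""

    pi: float
    a: float
    b: float | np.ndarray
    V: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi must be in [0, 1], got {self.pi}")
        if not self.a > 0:
            raise ValueError(f"a must be positive, got {self.a}")
        if not isinstance(self.V, (int, np.integer)) or self.V < 2:
            raise ValueError(f"V must be an integer >= 2, got {self.V}")
        # validates b and freezes the broadcast vector
        object.__setattr__(self, "_b_vec", _b_vector(self.b, self.V))

    @property
    def b_vector(self) -> np.ndarray:
        return self._b_vec  # type: ignore[attr-defined]


@dataclass
class CompositionWithZeros:
    """A point on the simplex with exact structural zeros.

    Invariants: beta sums to 1; beta[i] == 0 exactly when delta[i] == 1
    (exact zeros, never small floats); the last component is never zero.
    """

    beta: np.ndarray
    delta: np.ndarray

    @property
    def support(self) -> np.ndarray:
        """Ordered index set U of in-support positions (delta == 0)."""
        return np.flatnonzero(self.delta == 0)

    @property
    def n_support(self) -> int:
        return int(np.sum(self.delta == 0))


def sample_zi_betas(params: ZIGDParams, rng: int | np.random.Generator | None = None) -> np.ndarray:
    """Draw the V-1 zero-inflated stick variables Q.

    Each Q_i is exactly 0 with probability pi, otherwise Beta(a, b_i).
    """
    rng = as_generator(rng)
    q = rng.beta(params.a, params.b_vector)
    # Beta variates are in (0, 1) a.s.; clip defensively so downstream
    # stick-breaking never sees Q == 1.
    np.clip(q, 0.0, np.nextafter(1.0, 0.0), out=q)
    zeroed = rng.random(params.V - 1) < params.pi
    q[zeroed] = 0.0
    return q


def stick_break(Q: np.ndarray) -> CompositionWithZeros:
    """Map stick variables Q (length V-1, in [0, 1)) to a composition.

    beta_i = Q_i * prod_{l<i}(1 - Q_l); the last component takes the residual
    stick and is always strictly positive.  beta_i is exactly 0 iff Q_i is 0.
    Deterministic given (Q, order): the map is order-sensitive by design.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 1 or Q.size < 1:
        raise ValueError("Q must be a 1-d vector of length >= 1")
    if np.any(Q < 0) or np.any(Q >= 1) or not np.all(np.isfinite(Q)):
        raise ValueError("all Q_i must lie in [0, 1)")
    V = Q.size + 1
    tiny = np.nextafter(0.0, 1.0)
    beta = np.zeros(V)
    remaining = 1.0
    for i, q in enumerate(Q):
        b = q * remaining
        # a positive stick must give a positive component: zero is reserved
        # for structural zeros (q == 0), so guard against underflow
        beta[i] = b if (b > 0.0 or q == 0.0) else tiny
        remaining *= 1.0 - q
    beta[V - 1] = max(remaining, tiny)  # residual stick, > 0 since all Q < 1
    delta = np.zeros(V, dtype=np.int8)
    delta[: V - 1][Q == 0.0] = 1
    return CompositionWithZeros(beta=beta, delta=delta)


def sample_zigd(params: ZIGDParams, rng: int | np.random.Generator | None = None) -> CompositionWithZeros:
    """Draw one ZIGD(pi, a, b) composition of length V."""
    rng = as_generator(rng)
    return stick_break(sample_zi_betas(params, rng))
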