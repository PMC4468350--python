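"""The Cartesian parameterization of a model's stochastic cone.

The stochastic rate matrices of an ``n``-dimensional model form a
polyhedral cone; its fixed-trace section is a bounded polytope.  The
Cartesian map sends the hypercube ``[-1, 1]^(n-1)`` one-to-one onto the
trace −12 section:

1. form the perturbation direction ``P' = sum_i b_i B_i`` over the
   non-``A`` generators (with ``A2`` substituted for ``A1`` so all are
   trace-free),
2. rescale it so its most negative off-diagonal entry is −1:
   ``P = P' / (-min offdiag P')``,
3. set the saturation ``s = max_i |b_i|`` and return ``Q = A + s*P``.

At ``s = 1`` the result sits on the boundary of stochasticity with at
least one vanishing off-diagonal rate.  The map is continuous (not
smooth) and its inverse is continuous, which is what makes bounded
hill-climbing over the hypercube safe.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .basis import basis_matrix
from .rates import OFFDIAG_MASK, in_model_span, is_stochastic
from .registry import ModelDefinition

__all__ = [
    "CartesianParams",
    "direction_basis",
    "cartesian_to_rate",
    "rate_to_cartesian",
    "sample_stochastic",
    "enumerate_rays",
    "raysum_sample",
]

_DEGENERATE_TOL = 1e-13


@dataclass(frozen=True)
class CartesianParams:
    """A point of the hypercube ``[-1, 1]^(n-1)`` for one model."""

    model: ModelDefinition
    b: np.ndarray

    def __post_init__(self):
        b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if b.shape != (self.model.dimension - 1,):
            raise ValueError(
                f"model {self.model.name} takes {self.model.dimension - 1} "
                f"Cartesian parameters, got shape {b.shape}")
        if np.abs(b).max(initial=0.0) > 1.0 + 1e-12:
            raise ValueError("Cartesian parameters must lie in [-1, 1]")
        object.__setattr__(self, "b", b)

    @property
    def saturation(self) -> float:
        """Distance from the Jukes–Cantor center toward the boundary."""
        return float(np.abs(self.b).max(initial=0.0))


def direction_basis(model: ModelDefinition) -> list[np.ndarray]:
    """The model's non-``A`` generators with ``A2`` replacing ``A1``.

    All returned matrices are trace-free and have off-diagonal entries
    summing to zero, so only the ``A`` weight carries trace.
    """
    names = model.basis_names
    if "A" not in names:
        raise ValueError(
            f"model {model.name} lacks the A generator; the Cartesian "
            "parameterization does not apply")
    out = []
    for n in names:
        if n == "A":
            continue
        out.append(basis_matrix("A2" if n == "A1" else n, model.pairing))
    return out


def cartesian_to_rate(params: CartesianParams) -> np.ndarray:
    """Map hypercube parameters to a stochastic member with trace −12."""
    model, b = params.model, params.b
    A = basis_matrix("A")
    if model.dimension == 1:
        return A.copy()
    mats = direction_basis(model)
    P1 = np.tensordot(b, np.array(mats), axes=1)
    m = P1[OFFDIAG_MASK].min()
    if m >= -_DEGENERATE_TOL:
        # b = 0 (independent generators make P' = 0 impossible otherwise)
        assert np.abs(b).max() < 1e-6, "nonzero b produced a zero direction"
        return A.copy()
    s = np.abs(b).max()
    return A + (s / -m) * P1


def rate_to_cartesian(Q: np.ndarray, model: ModelDefinition,
                      tol: float = 1e-9) -> CartesianParams:
    """Invert the Cartesian map for a trace −12 stochastic member.

    With ``R = Q - A`` expressed in the direction basis as coordinates
    ``c``, the forward map gives ``c = (s / -min offdiag P') * b``; since
    the minimum off-diagonal of ``R`` equals ``-s`` this inverts to
    ``b = c * (-min offdiag R) / max_j |c_j|``.
    """
    Q = np.asarray(Q, dtype=float)
    if not is_stochastic(Q, tol=1e-7):
        raise ValueError("matrix is not stochastic")
    if abs(np.trace(Q) + 12.0) > 1e-7:
        raise ValueError("normalize to trace -12 before inverting")
    ok, resid = in_model_span(Q, model, tol)
    if not ok:
        raise ValueError(
            f"matrix is not in model {model.name} (residual {resid:.2e})")
    if model.dimension == 1:
        return CartesianParams(model, np.zeros(0))
    A = basis_matrix("A")
    R = (Q - A).ravel()
    mats = np.array([m.ravel() for m in direction_basis(model)])
    c, *_ = np.linalg.lstsq(mats.T, R, rcond=None)
    cmax = np.abs(c).max()
    if cmax < 1e-12:
        return CartesianParams(model, np.zeros(model.dimension - 1))
    min_off = (Q - A)[OFFDIAG_MASK].min()
    b = c * (-min_off / cmax)
    return CartesianParams(model, np.clip(b, -1.0, 1.0))


def sample_stochastic(model: ModelDefinition, trace: float = -4.0,
                      n: int = 1, seed: int | np.random.Generator = 0
                      ) -> list[np.ndarray]:
    """Random stochastic members at a predetermined trace.

    Uniform sampling of the Cartesian hypercube pushed through
    :func:`cartesian_to_rate`, then rescaled from trace −12 to `trace`.
    """
    if trace >= 0:
        raise ValueError("trace must be negative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    scale = trace / -12.0
    out = []
    for _ in range(n):
        b = rng.uniform(-1.0, 1.0, model.dimension - 1)
        out.append(cartesian_to_rate(CartesianParams(model, b)) * scale)
    return out


def enumerate_rays(model: ModelDefinition, dedup_tol: float = 1e-8
                   ) -> list[np.ndarray]:
    """Extreme rays of the model's stochastic cone, normalized to trace −4.

    The cone in weight space is cut out by the 12 off-diagonal
    nonnegativity constraints.  Every extreme ray of an ``n``-dimensional
    cone has an active set of rank ``n-1``, so enumerating all
    ``(n-1)``-subsets of the constraints, solving for the line they
    annihilate, and keeping the feasible directions is exhaustive.
    Duplicates (rays whose active sets exceed ``n-1`` constraints) are
    merged after normalizing to unit maximum off-diagonal entry.

    The number of rays equals the second number of the model's name for
    every catalogued structure.
    """
    # 2.2a has no A generator; rays only need the plain basis
    use_a2 = "A" in model.basis_names and "A1" in model.basis_names
    mats = model.basis_matrices(use_a2=use_a2)
    n = len(mats)
    offdiag = [(i, j) for i in range(4) for j in range(4) if i != j]
    C = np.array([[M[i, j] for M in mats] for (i, j) in offdiag])
    if n == 1:
        rays_w = [np.ones(1)]
    else:
        rays_w = []
        for idx in itertools.combinations(range(12), n - 1):
            sub = C[list(idx)]
            if np.linalg.matrix_rank(sub, tol=1e-9) != n - 1:
                continue
            v = np.linalg.svd(sub)[2][-1]
            for w in (v, -v):
                vals = C @ w
                if vals.min() >= -1e-9 and vals.max() > 1e-9:
                    w = w / np.abs(vals).max()
                    if not any(np.allclose(w, r, atol=dedup_tol)
                               for r in rays_w):
                        rays_w.append(w)
    out = []
    for w in rays_w:
        Q = np.tensordot(w, np.array(mats), axes=1)
        out.append(Q * (-4.0 / np.trace(Q)))
    return out


def raysum_sample(model: ModelDefinition, seed: int | np.random.Generator = 0,
                  rays: list[np.ndarray] | None = None,
                  weights=None) -> np.ndarray:
    """A nonnegative combination of the model's extreme rays.

    Always stochastic and in the model; the representation is redundant
    whenever the ray count exceeds the dimension.  With `weights` omitted
    they are drawn uniformly from [0, 1].
    """
    if rays is None:
        rays = enumerate_rays(model)
    if weights is None:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        weights = rng.uniform(0.0, 1.0, len(rays))
    weights = np.asarray(weights, dtype=float)
    if weights.min() < 0:
        raise ValueError("ray weights must be nonnegative")
    return np.tensordot(weights, np.array(rays), axes=1)
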