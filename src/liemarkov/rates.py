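"""Rate-matrix construction and queries.

Rate matrices are plain 4x4 ``numpy`` arrays in canonical A,G,C,T order
with columns summing to zero.  A matrix is *stochastic* when all its
off-diagonal entries are nonnegative; the scale convention used
throughout the package is trace −4, which corresponds to one expected
substitution per site per unit time when the equilibrium is flat.
"""

from __future__ import annotations

import io

import numpy as np

from .basis import BASE_ORDER, basis_matrix, reorder
from .registry import ModelDefinition

__all__ = [
    "OFFDIAG_MASK",
    "from_weights",
    "weights_a1_to_a2",
    "weights_a2_to_a1",
    "raysum_to_rate_56b",
    "is_stochastic",
    "in_model_span",
    "normalize",
    "equilibrium_frequencies",
    "expected_rate",
    "write_matrix_text",
    "read_matrix_text",
]

#: boolean mask selecting the 12 off-diagonal entries.
OFFDIAG_MASK = ~np.eye(4, dtype=bool)

STOCHASTIC_TOL = 1e-9


def from_weights(model: ModelDefinition, weights, use_a2: bool = False) -> np.ndarray:
    """Linear combination ``Q = sum_i w_i B_i`` of the model's generators.

    `weights` follows the order of ``model.basis_names``; with
    ``use_a2=True`` the weight for the ``A1`` slot is interpreted as the
    weight of ``A2 = 3*A1 - A`` instead.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (model.dimension,):
        raise ValueError(
            f"model {model.name} needs {model.dimension} weights, "
            f"got shape {weights.shape}")
    mats = model.basis_matrices(use_a2=use_a2)
    return np.tensordot(weights, np.array(mats), axes=1)


def weights_a1_to_a2(model: ModelDefinition, weights) -> np.ndarray:
    """Convert weights on (A, A1, ...) to weights on (A, A2, ...).

    From ``A2 = 3*A1 - A``: ``a1*A1 = (a1/3)*A2 + (a1/3)*A``, so the A
    weight gains ``a1/3`` and the A2 weight is ``a1/3``.
    """
    w = np.array(weights, dtype=float)
    names = model.basis_names
    if "A1" not in names or "A" not in names:
        return w
    ia, i1 = names.index("A"), names.index("A1")
    out = w.copy()
    out[ia] = w[ia] + w[i1] / 3.0
    out[i1] = w[i1] / 3.0
    return out


def weights_a2_to_a1(model: ModelDefinition, weights) -> np.ndarray:
    """Inverse of :func:`weights_a1_to_a2`."""
    w = np.array(weights, dtype=float)
    names = model.basis_names
    if "A1" not in names or "A" not in names:
        return w
    ia, i1 = names.index("A"), names.index("A1")
    out = w.copy()
    out[i1] = 3.0 * w[i1]
    out[ia] = w[ia] - w[i1]
    return out


def raysum_to_rate_56b(alpha: float, beta: float, rho_a: float, rho_g: float,
                       rho_c: float, rho_t: float) -> np.ndarray:
    """Model 5.6b as a K2ST part plus an F81 part.

    ``alpha`` is the transition rate, ``beta`` the transversion rate and
    ``rho_x`` the extra rate into base ``x`` regardless of origin.  All
    six parameters must be nonnegative, which makes the result stochastic
    by construction; the parameterization is redundant by one degree of
    freedom (adding ``delta`` to ``alpha`` and ``beta`` while subtracting
    it from every ``rho`` leaves the matrix unchanged).
    """
    params = (alpha, beta, rho_a, rho_g, rho_c, rho_t)
    if min(params) < 0:
        raise ValueError("ray-sum parameters must all be nonnegative")
    rho = np.array([rho_a, rho_g, rho_c, rho_t])
    Q = np.full((4, 4), beta) + rho[:, None]
    transitions = [(0, 1), (1, 0), (2, 3), (3, 2)]
    for i, j in transitions:
        Q[i, j] = alpha + rho[i]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=0))
    return Q


def is_stochastic(Q: np.ndarray, tol: float = STOCHASTIC_TOL) -> bool:
    """All off-diagonal entries nonnegative (within `tol`)."""
    return bool(Q[OFFDIAG_MASK].min() >= -tol)


def in_model_span(Q: np.ndarray, model: ModelDefinition,
                  tol: float = STOCHASTIC_TOL) -> tuple[bool, float]:
    """Least-squares membership test; returns (flag, residual)."""
    span = model.span()
    v = np.asarray(Q, dtype=float).ravel()
    resid = float(np.linalg.norm(v - span.T @ (span @ v)))
    return resid < tol, resid


def normalize(Q: np.ndarray, target_trace: float = -4.0) -> np.ndarray:
    """Rescale to the requested trace (default −4)."""
    tr = np.trace(Q)
    if tr >= 0:
        raise ValueError(f"cannot normalize: trace {tr} is not negative")
    return Q * (target_trace / tr)


def equilibrium_frequencies(Q: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Stationary distribution: the null right eigenvector of ``Q``.

    Computed from the singular value decomposition, which is exact for a
    4x4 matrix up to rounding.  Requires an (essentially) unique null
    vector with consistent sign; a reducible or degenerate generator is
    rejected.
    """
    Q = np.asarray(Q, dtype=float)
    if np.abs(Q.sum(axis=0)).max() > 1e-8:
        raise ValueError("columns of a rate matrix must sum to zero")
    _, s, vt = np.linalg.svd(Q)
    if s[-2] < 1e-12:
        raise ValueError("rate matrix has a degenerate (multi-dimensional) "
                         "null space; equilibrium is not unique")
    pi = vt[-1]
    if pi.sum() < 0:
        pi = -pi
    if pi.min() < -tol * max(1.0, np.abs(Q).max()):
        raise ValueError("principal null vector has mixed signs; the "
                         "generator is reducible or nonstochastic")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def expected_rate(Q: np.ndarray) -> float:
    """Expected substitutions per site per unit time at equilibrium.

    ``-sum_i pi_i Q_ii``; equals ``-trace/4`` exactly when the
    equilibrium is flat.
    """
    pi = equilibrium_frequencies(Q)
    return float(-(pi * np.diag(Q)).sum())


_HEADER = "# liemarkov rate matrix; base order {order}; columns sum to zero"


def write_matrix_text(Q: np.ndarray, path=None, base_order: str = "ACGT",
                      transpose: bool = False) -> str:
    """Serialize a rate matrix as plain text with a convention header.

    The default external base order is alphabetical ACGT; pass
    ``transpose=True`` to emit the rows-sum-to-zero convention (noted in
    the header).  Entries are written in full precision so the round trip
    through :func:`read_matrix_text` is bit-exact.
    """
    M = reorder(np.asarray(Q, dtype=float), base_order)
    conv = "rows sum to zero" if transpose else "columns sum to zero"
    if transpose:
        M = M.T
    lines = [_HEADER.format(order=base_order).replace(
        "columns sum to zero", conv)]
    for row in M:
        lines.append(" ".join(repr(float(x)) for x in row))
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_matrix_text(source) -> np.ndarray:
    """Parse :func:`write_matrix_text` output back to canonical A,G,C,T."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = source
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    header = lines[0]
    if not header.startswith("#"):
        raise ValueError("missing convention header")
    order = header.split("base order")[1].split(";")[0].strip()
    transpose = "rows sum to zero" in header
    M = np.array([[float(x) for x in ln.split()] for ln in lines[1:]])
    if M.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix, got {M.shape}")
    if transpose:
        M = M.T
    inv = [order.index(b) for b in BASE_ORDER]
    return M[np.ix_(inv, inv)]


def paml_export(Q: np.ndarray) -> np.ndarray:
    """Re-express in the T,C,A,G order used by PAML."""
    return reorder(Q, "TCAG")


def paml_import(M: np.ndarray) -> np.ndarray:
    """Canonicalize a T,C,A,G-ordered matrix to A,G,C,T."""
    idx = ["TCAG".index(b) for b in BASE_ORDER]
    return np.asarray(M)[np.ix_(idx, idx)]
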