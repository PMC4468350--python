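"""Basis generators of the RY/WS/MK Lie Markov model hierarchy.

Every rate matrix of a Lie Markov model in this hierarchy is a linear
combination of a fixed set of twelve 4x4 generators (plus ``A2``, an
alternative to ``A1``).  The canonical base order is A, G, C, T — purines
first — with the *column* convention: entry ``Q[i, j]`` is the
instantaneous rate from base ``j`` to base ``i``, so every column sums to
zero.  Under this order the distinguished pairing is purine/pyrimidine
(RY); relabelling the rows and columns in the order A,T,C,G or A,C,G,T
produces the Watson–Crick (WS) and amino/keto (MK) variants of every
asymmetric model.

Generator summary (weights are written in lowercase, e.g. ``e1`` for
``E1``):

* ``A`` — the Jukes–Cantor generator: all off-diagonal rates equal.
* ``A1`` — transitions (A<->G, C<->T) relative to transversions;
  ``A2 = 3*A1 - A`` is the trace-free version used wherever an
  orthogonal-to-``A`` basis is convenient.
* ``B``, ``C`` — transversion sign patterns distinguishing the two
  transversion classes.
* ``D`` — purine rows against pyrimidine rows; the only generators that
  are not doubly stochastic are ``D``, ``E1`` and ``E2``, and they are
  exactly the ones that move the equilibrium base frequencies off 1/4.
* ``D1`` — purine transitions against pyrimidine transitions.
* ``E1``, ``E2`` — within-pair row differences (A vs G, C vs T).
* ``F1``, ``F2``, ``G1``, ``G2`` — doubly stochastic within/between-pair
  asymmetries completing the twelve-dimensional general Markov space.
"""

from __future__ import annotations

import enum

import numpy as np

__all__ = [
    "BASE_ORDER",
    "BASIS_LABELS",
    "Pairing",
    "basis_matrix",
    "pairing_permutation",
    "permute_matrix",
    "reorder",
]

#: canonical internal base order (purines first).
BASE_ORDER = ("A", "G", "C", "T")

_A = np.ones((4, 4)) - 4.0 * np.eye(4)
_A1 = np.array(
    [[-1, 1, 0, 0],
     [1, -1, 0, 0],
     [0, 0, -1, 1],
     [0, 0, 1, -1]], dtype=float)
_B = np.array(
    [[0, 0, 1, -1],
     [0, 0, -1, 1],
     [1, -1, 0, 0],
     [-1, 1, 0, 0]], dtype=float)
_C = np.array(
    [[0, 0, 1, -1],
     [0, 0, -1, 1],
     [-1, 1, 0, 0],
     [1, -1, 0, 0]], dtype=float)
_D = np.array(
    [[1, 1, 1, 1],
     [1, 1, 1, 1],
     [-1, -1, -1, -1],
     [-1, -1, -1, -1]], dtype=float)
_D1 = np.array(
    [[-1, 1, 0, 0],
     [1, -1, 0, 0],
     [0, 0, 1, -1],
     [0, 0, -1, 1]], dtype=float)
_E1 = np.array(
    [[1, 1, 1, 1],
     [-1, -1, -1, -1],
     [0, 0, 0, 0],
     [0, 0, 0, 0]], dtype=float)
_E2 = np.array(
    [[0, 0, 0, 0],
     [0, 0, 0, 0],
     [1, 1, 1, 1],
     [-1, -1, -1, -1]], dtype=float)
_F1 = np.array(
    [[1, 1, -1, -1],
     [-1, -1, 1, 1],
     [0, 0, 0, 0],
     [0, 0, 0, 0]], dtype=float)
_F2 = np.array(
    [[0, 0, 0, 0],
     [0, 0, 0, 0],
     [-1, -1, 1, 1],
     [1, 1, -1, -1]], dtype=float)
_G1 = np.array(
    [[0, 0, 1, -1],
     [0, 0, 1, -1],
     [0, 0, -1, 1],
     [0, 0, -1, 1]], dtype=float)
_G2 = np.array(
    [[-1, 1, 0, 0],
     [-1, 1, 0, 0],
     [1, -1, 0, 0],
     [1, -1, 0, 0]], dtype=float)

_CANONICAL = {
    "A": _A, "A1": _A1, "A2": 3.0 * _A1 - _A,
    "B": _B, "C": _C, "D": _D, "D1": _D1,
    "E1": _E1, "E2": _E2, "F1": _F1, "F2": _F2,
    "G1": _G1, "G2": _G2,
}

#: the twelve generator labels plus the alternative ``A2``.
BASIS_LABELS = tuple(_CANONICAL)


class Pairing(enum.Enum):
    """Which pairing of bases a model structure distinguishes.

    ``RY`` distinguishes purines/pyrimidines (AG | CT), ``WS`` the
    Watson–Crick weak/strong pairs (AT | CG), ``MK`` amino/keto
    (AC | GT).  ``FULLY_SYMMETRIC`` marks the six structures whose rate
    matrix spans coincide under all three pairings.
    """

    RY = "RY"
    WS = "WS"
    MK = "MK"
    FULLY_SYMMETRIC = "SYM"

    @property
    def base_order(self) -> tuple[str, ...]:
        """The base relabelling that realizes this pairing."""
        return {
            Pairing.RY: ("A", "G", "C", "T"),
            Pairing.WS: ("A", "T", "C", "G"),
            Pairing.MK: ("A", "C", "G", "T"),
            Pairing.FULLY_SYMMETRIC: ("A", "G", "C", "T"),
        }[self]


def pairing_permutation(pairing: Pairing) -> np.ndarray:
    """Index permutation realizing `pairing`, as positions in A,G,C,T.

    ``p[k]`` is the canonical index of the base written in slot ``k`` of
    the pairing's base order.  Each permutation is an involution:
    applying it twice to rows and columns restores the matrix.
    """
    return np.array([BASE_ORDER.index(b) for b in pairing.base_order])


def permute_matrix(matrix: np.ndarray, pairing: Pairing) -> np.ndarray:
    """Relabel rows/columns of a canonical-pattern matrix per `pairing`."""
    p = pairing_permutation(pairing)
    out = np.empty_like(matrix)
    out[np.ix_(p, p)] = matrix
    return out


def basis_matrix(name: str, pairing: Pairing = Pairing.RY) -> np.ndarray:
    """Return basis generator `name` under `pairing`, in canonical A,G,C,T
    coordinates.

    The generator's sign pattern is defined against the pairing's base
    order and then expressed in canonical coordinates, so e.g. the WS
    variant of ``A1`` boosts the A<->T and C<->G interchanges.
    """
    try:
        mat = _CANONICAL[name]
    except KeyError:
        raise KeyError(
            f"unknown basis matrix {name!r}; valid labels are "
            f"{', '.join(BASIS_LABELS)}"
        ) from None
    return permute_matrix(mat, pairing)


def reorder(matrix: np.ndarray, order: str | tuple[str, ...]) -> np.ndarray:
    """Re-express a canonical A,G,C,T matrix in another base order.

    ``order`` may be a string like ``"ACGT"`` or ``"TCAG"`` (the PAML
    convention).  Returns ``M`` with ``M[i, j]`` the rate from
    ``order[j]`` to ``order[i]``.
    """
    idx = [BASE_ORDER.index(b) for b in order]
    if sorted(idx) != [0, 1, 2, 3]:
        raise ValueError(f"base order must be a permutation of AGCT, got {order!r}")
    return matrix[np.ix_(idx, idx)]
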