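"""The classical reversible comparison panel.

The original ModelTest panel holds 14 time-reversible models.  Five of
them are also Lie Markov models (JC = 1.1, K80 = RY2.2b, K81 = 3.3a,
TrNef = RY3.3c, F81 = 4.4a) and resolve to registry entries; the other
nine (HKY, TrN, K81uf, TIMef, TIM, TVMef, TVM, SYM, GTR) are provided
here as exchangeability x frequency parameterizations.

A reversible model is specified by a symmetric exchangeability matrix
``S`` and equilibrium frequencies ``pi``; with the column convention the
rate from ``j`` to ``i`` is ``Q[i, j] = S[i, j] * pi[i]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .registry import get_model

__all__ = [
    "ReversibleSpec",
    "REVERSIBLE_PANEL",
    "SHARED_WITH_LIE",
    "reversible_panel_models",
    "reversible_rate_matrix",
]

# the six unordered base pairs in canonical A,G,C,T indexing;
# (0,1) and (2,3) are the transitions
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class ReversibleSpec:
    """One GTR-family model.

    ``classes`` assigns each of the six base pairs (AG, AC, AT, GC, GT,
    CT in canonical order) to an exchangeability class; class 0 is fixed
    at rate 1 and the others are free.  ``free_frequencies`` marks the
    models with three frequency degrees of freedom (otherwise flat).
    """

    name: str
    classes: tuple[int, int, int, int, int, int]
    free_frequencies: bool

    @property
    def n_exchange_free(self) -> int:
        return max(self.classes)

    @property
    def k_free(self) -> int:
        return self.n_exchange_free + (3 if self.free_frequencies else 0)


# pair order:                 AG AC AT GC GT CT
_CLASSES = {
    "HKY":   (1, 0, 0, 0, 0, 1),   # transitions vs transversions
    "TrN":   (1, 0, 0, 0, 0, 2),   # the two transitions differ
    "K81uf": (1, 0, 2, 2, 0, 1),   # K3ST exchangeabilities, free pi
    "TIMef": (1, 0, 2, 2, 0, 3),
    "TIM":   (1, 0, 2, 2, 0, 3),
    "TVMef": (1, 2, 3, 4, 0, 1),   # transversions all free, AG=CT
    "TVM":   (1, 2, 3, 4, 0, 1),
    "SYM":   (1, 2, 3, 4, 0, 5),
    "GTR":   (1, 2, 3, 4, 0, 5),
}
_FREE_PI = {"HKY", "TrN", "K81uf", "TIM", "TVM", "GTR"}

#: the nine panel models beyond the Lie Markov hierarchy.
REVERSIBLE_PANEL: dict[str, ReversibleSpec] = {
    name: ReversibleSpec(name, cls, name in _FREE_PI)
    for name, cls in _CLASSES.items()
}

#: ModelTest models that coincide with Lie Markov models.
SHARED_WITH_LIE = {
    "JC": "1.1", "K80": "RY2.2b", "K81": "3.3a",
    "TrNef": "RY3.3c", "F81": "4.4a",
}


def reversible_panel_models() -> list[ReversibleSpec]:
    """The nine extra reversible models, in panel order."""
    return list(REVERSIBLE_PANEL.values())


def shared_panel_models():
    """The five ModelTest models resolved to Lie Markov registry entries."""
    return {name: get_model(struct) for name, struct in SHARED_WITH_LIE.items()}


def reversible_rate_matrix(spec: ReversibleSpec, exchange_rates=(),
                           frequencies=None,
                           target_trace: float = -4.0) -> np.ndarray:
    """Build the rate matrix for `spec`.

    `exchange_rates` supplies the free class rates (class 0 is pinned at
    1); `frequencies` the equilibrium distribution (flat when the spec
    has no frequency freedom).  The result is normalized to
    `target_trace` (pass ``None`` to skip).
    """
    rates = np.concatenate([[1.0], np.asarray(exchange_rates, dtype=float)])
    if len(rates) != spec.n_exchange_free + 1:
        raise ValueError(
            f"{spec.name} takes {spec.n_exchange_free} free exchange "
            f"rates, got {len(rates) - 1}")
    if rates.min() <= 0:
        raise ValueError("exchange rates must be positive")
    if frequencies is None:
        if spec.free_frequencies:
            raise ValueError(f"{spec.name} requires equilibrium frequencies")
        pi = np.full(4, 0.25)
    else:
        pi = np.asarray(frequencies, dtype=float)
        if pi.min() <= 0 or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("frequencies must be positive and sum to 1")
        if not spec.free_frequencies and np.abs(pi - 0.25).max() > 1e-12:
            raise ValueError(f"{spec.name} has flat equilibrium frequencies")
    S = np.zeros((4, 4))
    for (i, j), cls in zip(_PAIRS, spec.classes):
        S[i, j] = S[j, i] = rates[cls]
    Q = S * pi[:, None]
    np.fill_diagonal(Q, -Q.sum(axis=0))
    if target_trace is not None:
        Q = Q * (target_trace / np.trace(Q))
    return Q
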