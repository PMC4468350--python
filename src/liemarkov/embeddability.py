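"""Multiplicative-closure diagnostics.

A model is multiplicatively closed when the product of two of its Markov
matrices is again the exponential of a model rate matrix.  The practical
test takes stochastic ``Q1``, ``Q2``, forms the "average" generator
``Q' = log(exp(Q1) exp(Q2))`` with the principal matrix logarithm, and
asks whether ``Q'`` is (i) real, (ii) stochastic and (iii) inside the
model's span.  For a Lie Markov model failure mode (iii) cannot occur;
modes (i) and (ii) — jointly called *nonembeddability* — do occur once
the factors are saturated enough, and the Monte Carlo experiments here
measure how deep a phylogeny must be before that matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .cartesian import sample_stochastic
from .rates import OFFDIAG_MASK, in_model_span
from .registry import ModelDefinition

__all__ = [
    "EmbeddabilityResult",
    "product_rate",
    "nonembeddable_fraction",
    "threshold_trace",
    "difference_dependence",
]

COMPLEX_TOL = 1e-8     # imaginary dust threshold on the principal log
STOCHASTIC_TOL = 1e-9  # off-diagonal negativity threshold


@dataclass
class EmbeddabilityResult:
    """Classification of one ``(Q1, Q2)`` product."""

    Q1: np.ndarray
    Q2: np.ndarray
    Qprime: np.ndarray  # possibly complex
    classification: str  # stochastic_in_model | real_nonstochastic |
    #                      complex | not_in_model
    residual: float | None = None

    @property
    def nonembeddable(self) -> bool:
        return self.classification in ("complex", "real_nonstochastic")


def _expm(Q: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eig(Q)
    try:
        M = (V * np.exp(w)) @ np.linalg.inv(V)
    except np.linalg.LinAlgError:
        return scipy.linalg.expm(Q)
    if not np.isfinite(M).all() or np.abs(M.imag).max() > 1e-10:
        return scipy.linalg.expm(Q)
    return M.real


def _logm(M: np.ndarray) -> np.ndarray:
    """Principal matrix logarithm with an eigendecomposition fast path."""
    w, V = np.linalg.eig(M)
    if np.abs(w).min() < 1e-300:
        raise np.linalg.LinAlgError("singular product matrix")
    cond = np.linalg.cond(V)
    if cond < 1e6:
        L = (V * np.log(w.astype(complex))) @ np.linalg.inv(V)
        # accept the fast path only if it reproduces M
        err = np.abs((V * w) @ np.linalg.inv(V) - M).max()
        if err < 1e-10:
            return L
    return scipy.linalg.logm(M)


def product_rate(Q1: np.ndarray, Q2: np.ndarray,
                 model: ModelDefinition | None = None) -> EmbeddabilityResult:
    """Average generator of the two-epoch process ``exp(Q1) exp(Q2)``.

    Classification: ``complex`` when the principal logarithm has a
    material imaginary part, ``real_nonstochastic`` when real with a
    negative off-diagonal rate, ``not_in_model`` when real and stochastic
    but outside the span (never observed for Lie Markov models), else
    ``stochastic_in_model``.
    """
    M = _expm(Q1) @ _expm(Q2)
    try:
        L = _logm(M)
    except (np.linalg.LinAlgError, ValueError):
        return EmbeddabilityResult(Q1, Q2, np.full((4, 4), np.nan + 0j),
                                   "complex")
    if np.iscomplexobj(L) and np.abs(L.imag).max() > COMPLEX_TOL:
        return EmbeddabilityResult(Q1, Q2, L, "complex")
    L = L.real if np.iscomplexobj(L) else L
    if L[OFFDIAG_MASK].min() < -STOCHASTIC_TOL:
        return EmbeddabilityResult(Q1, Q2, L, "real_nonstochastic")
    residual = None
    if model is not None:
        ok, residual = in_model_span(L, model, tol=1e-8)
        if not ok:
            return EmbeddabilityResult(Q1, Q2, L, "not_in_model", residual)
    return EmbeddabilityResult(Q1, Q2, L, "stochastic_in_model", residual)


def nonembeddable_fraction(model: ModelDefinition, trace: float,
                           n: int = 2000, seed: int = 0,
                           check_span: bool = False) -> float:
    """Fraction of random same-trace pairs with complex or nonstochastic
    average generator.

    Pairs are drawn by uniform Cartesian-hypercube sampling rescaled to
    `trace`.  Real stochastic averages falling outside the span would be
    counted separately (they are a sanity check, expected never to
    happen), not as nonembeddable.
    """
    rng = np.random.default_rng(seed)
    Qs = sample_stochastic(model, trace, 2 * n, rng)
    bad = 0
    for i in range(n):
        res = product_rate(Qs[2 * i], Qs[2 * i + 1],
                           model if check_span else None)
        if res.classification == "not_in_model":
            raise AssertionError(
                f"average generator left the span of {model.name} "
                f"(residual {res.residual:.2e})")
        bad += res.nonembeddable
    return bad / n


def threshold_trace(model: ModelDefinition, target_fraction: float = 0.05,
                    n: int = 2000, seed: int = 0,
                    trace_bounds: tuple[float, float] = (-0.05, -60.0),
                    iterations: int = 9) -> dict:
    """Trace at which the nonembeddable fraction crosses `target_fraction`.

    Bisection on |trace|; each evaluation uses a fresh `n`-pair Monte
    Carlo estimate.  Returns the crossing trace with a binomial
    half-width converted through the local slope, or status ``"never"``
    if the deepest trace probed stays below the target (matching the
    models whose products are always embeddable).
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must be in (0, 1)")
    lo, hi = trace_bounds  # lo: shallow (fraction ~ 0), hi: deep
    rng = np.random.default_rng(seed)

    def frac(tr):
        return nonembeddable_fraction(model, tr, n=n,
                                      seed=int(rng.integers(2 ** 31)))

    f_hi = frac(hi)
    if f_hi < target_fraction:
        return {"model": model.name, "status": "never", "trace": None,
                "fraction_at_bound": f_hi, "bound": hi}
    evals = []
    for _ in range(iterations):
        mid = -np.sqrt(lo * hi)  # geometric bisection in |trace|
        f_mid = frac(mid)
        evals.append((mid, f_mid))
        if f_mid < target_fraction:
            lo = mid
        else:
            hi = mid
    trace = -np.sqrt(lo * hi)
    # crude CI: binomial SE at the target divided by the local slope
    se = np.sqrt(target_fraction * (1 - target_fraction) / n)
    evals.sort()
    slopes = [abs((f2 - f1) / (t2 - t1))
              for (t1, f1), (t2, f2) in zip(evals, evals[1:]) if t2 != t1]
    slope = max(np.median(slopes) if slopes else 0.0, 1e-4)
    return {"model": model.name, "status": "crossed", "trace": float(trace),
            "ci_halfwidth": float(se / slope), "n": n}


def _rms_offdiag(Q: np.ndarray) -> float:
    return float(np.sqrt(np.mean(Q[OFFDIAG_MASK] ** 2)))


def difference_dependence(models=("6.6", "8.8", "8.10b", "10.12"),
                          n_pairs: int = 1000, seed: int = 0,
                          pairing=None) -> dict:
    """How much embeddability depends on the difference |Q1 − Q2|.

    For each model, at a trace giving roughly 50% nonembeddability,
    draws `n_pairs` pairs and standardizes the difference in mean RMS
    off-diagonal distance between nonembeddable and embeddable pairs by
    the pooled standard deviation.
    """
    from .registry import get_model

    rng = np.random.default_rng(seed)
    per_model = {}
    for name in models:
        model = name if isinstance(name, ModelDefinition) else get_model(name)
        tr = _find_half_trace(model, n=400,
                              seed=int(rng.integers(2 ** 31)))
        Qs = sample_stochastic(model, tr, 2 * n_pairs,
                               np.random.default_rng(int(rng.integers(2 ** 31))))
        diffs = np.empty(n_pairs)
        flags = np.empty(n_pairs, dtype=bool)
        for i in range(n_pairs):
            Q1, Q2 = Qs[2 * i], Qs[2 * i + 1]
            diffs[i] = _rms_offdiag(Q1 - Q2)
            flags[i] = product_rate(Q1, Q2).nonembeddable
        d1, d0 = diffs[flags], diffs[~flags]
        if len(d1) < 2 or len(d0) < 2:
            raise RuntimeError(
                f"could not balance embeddable/nonembeddable groups for "
                f"{model.name} at trace {tr}")
        pooled = np.sqrt(((len(d1) - 1) * d1.var(ddof=1)
                          + (len(d0) - 1) * d0.var(ddof=1))
                         / (len(d1) + len(d0) - 2))
        per_model[model.name] = {
            "trace": tr, "fraction": float(flags.mean()),
            "effect_sd": float((d1.mean() - d0.mean()) / pooled)}
    mean_effect = float(np.mean([v["effect_sd"] for v in per_model.values()]))
    return {"per_model": per_model, "mean_effect_sd": mean_effect}


def _find_half_trace(model: ModelDefinition, n: int = 400, seed: int = 0,
                     bounds: tuple[float, float] = (-4.0, -120.0),
                     iterations: int = 7) -> float:
    """Trace with nonembeddable fraction closest to 50% (clamped at the
    deep bound if 50% is never reached)."""
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    f_hi = nonembeddable_fraction(model, hi, n=n,
                                  seed=int(rng.integers(2 ** 31)))
    if f_hi < 0.5:
        return hi
    for _ in range(iterations):
        mid = -np.sqrt(lo * hi)
        f = nonembeddable_fraction(model, mid, n=n,
                                   seed=int(rng.integers(2 ** 31)))
        if f < 0.5:
            lo = mid
        else:
            hi = mid
    return float(-np.sqrt(lo * hi))
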