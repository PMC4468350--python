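"""Pruning-algorithm likelihoods, hill-climbing fits and model scans.

The evaluation pipeline: build an NJ tree from Jukes–Cantor distances,
midpoint-root it, then for each candidate model maximize the pruning
likelihood over the model's Cartesian parameters, the branch lengths and
any rate-heterogeneity parameters, and rank models by BIC (and AICc).

Conventions:

* The rate matrix is always normalized to trace −4; the overall rate
  scale is folded into the branch lengths.
* The root distribution is the equilibrium distribution of the fitted
  rate matrix (root placement therefore matters for the nonreversible
  models).
* Free parameters ``k`` = (model dimension − 1) + branch count + rate
  heterogeneity parameters.  The branch count is 2T−2 for nonreversible
  models on a rooted binary tree with T leaves, and 2T−3 for reversible
  ones (the two root-adjacent branch lengths are only jointly
  identifiable); the convention used is recorded on every fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.optimize import minimize_scalar
from scipy.special import gammainc, gammaincinv

from .alignment import Alignment
from .cartesian import CartesianParams, cartesian_to_rate
from .rates import equilibrium_frequencies, is_stochastic
from .registry import ModelDefinition, get_model, is_time_reversible
from .reversible import (REVERSIBLE_PANEL, ReversibleSpec,
                         reversible_rate_matrix)
from .trees import Phylogeny

__all__ = [
    "RateHeterogeneity",
    "FitResult",
    "log_likelihood",
    "log_likelihood_rate_matrix",
    "fit_model",
    "model_scan",
]

_LNL_FLOOR = -1e18  # sentinel for invalid parameter points

HETEROGENEITY_KINDS = ("single", "I", "G", "IG")


@dataclass(frozen=True)
class RateHeterogeneity:
    """Across-site rate variation: none, +I, +G(8) or +I+G.

    The variable-rate categories always have mean rate 1 (the invariant
    fraction sits at rate 0 on top of that); the overall time scale is
    carried by the branch lengths.
    """

    kind: str = "single"
    p_invariant: float = 0.0
    gamma_shape: float = 1.0
    n_categories: int = 8

    def __post_init__(self):
        if self.kind not in HETEROGENEITY_KINDS:
            raise ValueError(
                f"heterogeneity kind must be one of {HETEROGENEITY_KINDS}, "
                f"got {self.kind!r}")
        if self.kind in ("I", "IG") and not 0.0 <= self.p_invariant < 1.0:
            raise ValueError("p_invariant must lie in [0, 1)")
        if self.kind in ("G", "IG") and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.n_categories < 1:
            raise ValueError("need at least one rate category")

    @property
    def n_free(self) -> int:
        return {"single": 0, "I": 1, "G": 1, "IG": 2}[self.kind]

    def categories(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, probabilities) of the discrete rate mixture."""
        if self.kind == "single":
            return np.array([1.0]), np.array([1.0])
        if self.kind == "I":
            return (np.array([0.0, 1.0]),
                    np.array([self.p_invariant, 1.0 - self.p_invariant]))
        g = _gamma_category_rates(self.gamma_shape, self.n_categories)
        probs = np.full(self.n_categories, 1.0 / self.n_categories)
        if self.kind == "G":
            return g, probs
        return (np.concatenate([[0.0], g]),
                np.concatenate([[self.p_invariant],
                                (1.0 - self.p_invariant) * probs]))


def _gamma_category_rates(shape: float, k: int) -> np.ndarray:
    """Equal-probability discretization of Gamma(shape, mean 1).

    Category rate = conditional mean of the quantile band, computed in
    closed form from the regularized incomplete gamma function; the
    rates average to 1 exactly (renormalized against rounding).
    """
    edges = gammaincinv(shape, np.linspace(0.0, 1.0, k + 1))
    # E[X; X < t] for mean-1 Gamma(shape) equals gammainc(shape+1, shape*t)
    # with t in rate-x units; edges are already in shape*x units
    mass = gammainc(shape + 1.0, edges)
    rates = k * np.diff(mass)
    return rates / rates.mean()


class _Propagator:
    """Branch transition matrices ``exp(Q*t*r)`` from one eigendecomposition.

    Falls back to ``scipy.linalg.expm`` per branch when the
    eigendecomposition is unreliable (defective or ill-conditioned Q).
    """

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self._ok = False
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            if np.linalg.cond(V) < 1e8:
                self.w, self.V, self.Vinv = w, V, Vinv
                M = (V * np.exp(w)) @ Vinv
                self._ok = bool(np.isfinite(M).all()
                                and np.abs(M.imag).max() < 1e-9)
        except np.linalg.LinAlgError:
            pass

    def __call__(self, t: float) -> np.ndarray:
        if t == 0.0:
            return np.eye(4)
        if self._ok:
            M = (self.V * np.exp(self.w * t)) @ self.Vinv
            return M.real
        return scipy.linalg.expm(self.Q * t)


def _leaf_partials(patterns: np.ndarray) -> np.ndarray:
    """(n_leaves, n_patterns, 4) indicator partials from bitmask codes."""
    bits = np.array([1, 2, 4, 8], dtype=np.uint8)
    return ((patterns[:, :, None] & bits) > 0).astype(float)


def log_likelihood_rate_matrix(aln: Alignment, tree: Phylogeny,
                               Q: np.ndarray,
                               heterogeneity: RateHeterogeneity
                               = RateHeterogeneity()) -> float:
    """Pruning log-likelihood for an explicit rate matrix.

    ``Q`` must be stochastic (any negative trace; branch lengths are
    interpreted against ``Q`` as given).  The root is weighted by the
    equilibrium distribution of ``Q``; heterogeneity categories share
    that distribution.
    """
    if not is_stochastic(Q, tol=1e-7):
        raise ValueError("rate matrix is not stochastic")
    if set(aln.taxa) != set(tree.taxa):
        raise ValueError("alignment and tree name different taxa")
    pi = equilibrium_frequencies(Q)
    patterns, counts = aln.patterns()
    # alignment rows in tree-leaf order
    row = [aln.taxa.index(t) for t in tree.taxa]
    leaf_p = _leaf_partials(patterns[row])
    rates, probs = heterogeneity.categories()
    prop = _Propagator(Q)
    n_pat = patterns.shape[1]
    site_lik = np.zeros(n_pat)
    for r, wgt in zip(rates, probs):
        if wgt == 0.0:
            continue
        partial = np.empty((tree.n_nodes, n_pat, 4))
        partial[:tree.n_leaves] = leaf_p
        for node in tree.postorder:
            kids = tree.children[node]
            if not kids:
                continue
            acc = np.ones((n_pat, 4))
            for k in kids:
                M = prop(tree.lengths[k] * r)
                # column convention: M[x, y] = P(end x | start y), so the
                # message to the parent state y is sum_x partial[x] M[x, y]
                acc *= partial[k] @ M
            partial[node] = acc
        site_lik += wgt * (partial[tree.root] @ pi)
    if site_lik.min() <= 0.0:
        return _LNL_FLOOR
    return float(counts @ np.log(site_lik))


def log_likelihood(aln: Alignment, tree: Phylogeny,
                   model: ModelDefinition | str, b,
                   heterogeneity: RateHeterogeneity = RateHeterogeneity()
                   ) -> float:
    """Pruning log-likelihood of a Lie Markov model at Cartesian ``b``.

    The rate matrix is the Cartesian image rescaled to trace −4, so the
    branch lengths of `tree` are expected substitutions per site at a
    flat equilibrium.
    """
    if isinstance(model, str):
        model = get_model(model)
    Q = cartesian_to_rate(CartesianParams(model, np.asarray(b, dtype=float)))
    return log_likelihood_rate_matrix(aln, tree, Q * (1.0 / 3.0),
                                      heterogeneity)


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    model_name: str
    heterogeneity_kind: str
    lnL: float
    parameters: dict
    branch_lengths: np.ndarray
    tree: Phylogeny
    k: int
    n_sites: int
    reversible: bool
    k_convention: str
    seed: int
    restarts: int
    converged: bool
    restart_log: list = field(default_factory=list)

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n_sites) - 2.0 * self.lnL

    @property
    def aicc(self) -> float:
        n, k = self.n_sites, self.k
        if n - k - 1 <= 0:
            return math.inf
        return 2.0 * k - 2.0 * self.lnL + 2.0 * k * (k + 1) / (n - k - 1)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "heterogeneity": self.heterogeneity_kind,
            "lnL": self.lnL,
            "k": self.k,
            "n_sites": self.n_sites,
            "BIC": self.bic,
            "AICc": self.aicc,
            "reversible": self.reversible,
            "k_convention": self.k_convention,
            "parameters": {key: (val.tolist()
                                 if isinstance(val, np.ndarray) else val)
                           for key, val in self.parameters.items()},
            "branch_lengths": self.branch_lengths.tolist(),
            "newick": self.tree.to_newick(),
            "seed": self.seed,
            "restarts": self.restarts,
            "converged": self.converged,
        }


class _Objective:
    """Flattened parameter vector -> lnL, for one model family.

    Layout: [model block | branch lengths | heterogeneity block].
    The model block is the Cartesian ``b`` for a Lie Markov model, or
    free exchange rates followed by three free frequency weights (the T
    weight pinned at 1) for a reversible-panel model.
    """

    def __init__(self, aln: Alignment, tree: Phylogeny,
                 model: ModelDefinition | ReversibleSpec, het_kind: str):
        self.aln = aln
        self.tree = tree
        self.model = model
        self.het_kind = het_kind
        self.is_lie = isinstance(model, ModelDefinition)
        if self.is_lie:
            n_model = model.dimension - 1
            self.bounds = [(-0.999, 0.999)] * n_model
        else:
            n_model = model.n_exchange_free
            self.bounds = [(1e-3, 50.0)] * n_model
            if model.free_frequencies:
                n_model += 3
                self.bounds += [(1e-3, 50.0)] * 3
        self.n_model = n_model
        self.n_branch = tree.n_branches
        self.bounds += [(1e-8, 20.0)] * self.n_branch
        self.het_slots = []
        if het_kind in ("I", "IG"):
            self.het_slots.append("p_invariant")
            self.bounds.append((0.0, 0.95))
        if het_kind in ("G", "IG"):
            self.het_slots.append("gamma_shape")
            self.bounds.append((0.02, 200.0))
        self.n_params = len(self.bounds)

    def split(self, x: np.ndarray):
        model_part = x[:self.n_model]
        lengths = x[self.n_model:self.n_model + self.n_branch]
        het_part = x[self.n_model + self.n_branch:]
        return model_part, lengths, het_part

    def heterogeneity(self, het_part) -> RateHeterogeneity:
        kwargs = dict(zip(self.het_slots, het_part))
        return RateHeterogeneity(self.het_kind, **kwargs)

    def rate_matrix(self, model_part) -> np.ndarray:
        if self.is_lie:
            Q = cartesian_to_rate(CartesianParams(self.model,
                                                  np.asarray(model_part)))
            return Q / 3.0  # trace −12 section rescaled to trace −4
        nx = self.model.n_exchange_free
        rates = model_part[:nx]
        if self.model.free_frequencies:
            w = np.concatenate([model_part[nx:nx + 3], [1.0]])
            pi = w / w.sum()
        else:
            pi = None
        return reversible_rate_matrix(self.model, rates, pi)

    def __call__(self, x: np.ndarray) -> float:
        model_part, lengths, het_part = self.split(x)
        try:
            Q = self.rate_matrix(model_part)
            het = self.heterogeneity(het_part)
            tree = self.tree.with_branch_lengths(lengths)
            return log_likelihood_rate_matrix(self.aln, tree, Q, het)
        except (ValueError, np.linalg.LinAlgError):
            return _LNL_FLOOR

    def initial(self, rng: np.random.Generator, perturb: bool) -> np.ndarray:
        x = np.empty(self.n_params)
        if self.is_lie:
            x[:self.n_model] = (rng.uniform(-0.5, 0.5, self.n_model)
                                if perturb else 0.0)
        else:
            x[:self.n_model] = 1.0
            if perturb:
                x[:self.n_model] *= rng.uniform(0.5, 2.0, self.n_model)
        t0 = np.clip(self.tree.branch_lengths_vector(), 1e-4, 20.0)
        if perturb:
            t0 = np.clip(t0 * rng.uniform(0.5, 2.0, self.n_branch),
                         1e-8, 20.0)
        x[self.n_model:self.n_model + self.n_branch] = t0
        het0 = {"p_invariant": 0.1, "gamma_shape": 1.0}
        for j, slot in enumerate(self.het_slots):
            x[self.n_model + self.n_branch + j] = het0[slot]
        return x


def _coordinate_ascent(obj: _Objective, x0: np.ndarray,
                       tol: float = 1e-6, max_cycles: int = 40
                       ) -> tuple[np.ndarray, float, bool]:
    """Bounded coordinate-cycling line search (hill climbing)."""
    x = x0.copy()
    best = obj(x)
    converged = False
    for _ in range(max_cycles):
        start = best
        for i in range(obj.n_params):
            lo, hi = obj.bounds[i]
            xi_old = x[i]

            def neg(v, i=i):
                x[i] = v
                return -obj(x)

            res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-7})
            if -res.fun > best:
                best = -res.fun
                x[i] = res.x
            else:
                x[i] = xi_old  # the line search left x[i] at its last trial
        if best - start < tol:
            converged = True
            break
    return x, best, converged


def fit_model(aln: Alignment, tree: Phylogeny,
              model: ModelDefinition | ReversibleSpec | str,
              heterogeneity: str = "single", seed: int = 0,
              restarts: int = 3, tol: float = 1e-6) -> FitResult:
    """Maximum-likelihood fit of one model on a fixed topology.

    Hill climbing (bounded coordinate-cycling line search) over the
    model parameters, all branch lengths and the heterogeneity
    parameters, from `restarts` starting points (the first from the
    input branch lengths and a neutral model, the rest randomized by
    `seed`).  The topology is never changed.
    """
    if isinstance(model, str):
        model = (REVERSIBLE_PANEL[model] if model in REVERSIBLE_PANEL
                 else get_model(model))
    tree.require_rooted("likelihood fitting")
    obj = _Objective(aln, tree, model, heterogeneity)
    rng = np.random.default_rng(seed)
    best_x, best_lnl, best_conv = None, -np.inf, False
    log = []
    for r in range(max(1, restarts)):
        x0 = obj.initial(rng, perturb=(r > 0))
        x, lnl, conv = _coordinate_ascent(obj, x0, tol=tol)
        log.append({"restart": r, "lnL": lnl, "converged": conv})
        if lnl > best_lnl:
            best_x, best_lnl, best_conv = x, lnl, conv
    model_part, lengths, het_part = obj.split(best_x)
    if obj.is_lie:
        reversible = is_time_reversible(model)
        params = {"b": np.asarray(model_part).copy()}
        name = model.name
        n_model_free = model.dimension - 1  # trace pinned at −4
    else:
        reversible = True
        nx = model.n_exchange_free
        params = {"exchange_rates": np.asarray(model_part[:nx]).copy()}
        if model.free_frequencies:
            w = np.concatenate([model_part[nx:nx + 3], [1.0]])
            params["frequencies"] = w / w.sum()
        name = model.name
        n_model_free = model.k_free  # already excludes the fixed trace
    for slot, val in zip(obj.het_slots, het_part):
        params[slot] = float(val)
    n_branch_ident = (tree.n_branches - 1) if reversible else tree.n_branches
    k = n_model_free + n_branch_ident + len(obj.het_slots)
    conv_note = (
        f"k = {n_model_free} model parameters (trace fixed at -4) + "
        f"{n_branch_ident} branch lengths "
        f"({'2T-3, root-adjacent pair merged (reversible)' if reversible else '2T-2 (nonreversible)'}) "
        f"+ {len(obj.het_slots)} heterogeneity")
    return FitResult(
        model_name=name, heterogeneity_kind=heterogeneity, lnL=best_lnl,
        parameters=params, branch_lengths=np.asarray(lengths).copy(),
        tree=tree.with_branch_lengths(lengths), k=k, n_sites=aln.n_sites,
        reversible=reversible, k_convention=conv_note, seed=seed,
        restarts=max(1, restarts), converged=best_conv, restart_log=log)


def model_scan(aln: Alignment, tree: Phylogeny, models,
               heterogeneities=("single",), seed: int = 0,
               restarts: int = 3, progress=None):
    """Fit every (model, heterogeneity) combination and rank by BIC.

    Returns a pandas DataFrame sorted by BIC with ΔBIC/ΔAICc columns
    (zero for the respective best model) and the fitted FitResult
    objects attached in ``df.attrs["fits"]``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    fits = []
    for name in models:
        for het in heterogeneities:
            fit = fit_model(aln, tree, name, heterogeneity=het,
                            seed=int(rng.integers(2 ** 31)),
                            restarts=restarts)
            fits.append(fit)
            if progress is not None:
                progress(fit)
    rows = [{
        "model": f.model_name, "heterogeneity": f.heterogeneity_kind,
        "lnL": f.lnL, "k": f.k, "BIC": f.bic, "AICc": f.aicc,
    } for f in fits]
    df = pd.DataFrame(rows)
    df["dBIC"] = df["BIC"] - df["BIC"].min()
    df["dAICc"] = df["AICc"] - df["AICc"].min()
    df = df.sort_values("BIC", kind="stable").reset_index(drop=True)
    df.attrs["fits"] = fits
    return df
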