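"""Alignment simulation under any registered model on any rooted tree.

Sites evolve independently: the root state is drawn from the model's
equilibrium distribution, and each branch applies the column-stochastic
transition matrix ``M = exp(Q * t * r)`` with the per-site rate ``r``
drawn from the heterogeneity mixture (an invariant site has ``r = 0``
and so copies the root state everywhere).

Reproducibility: all randomness comes from a counter-based Philox
stream; the per-node/per-site uniform variates are drawn as one array up
front, so the output is invariant to the order in which nodes or taxa
are visited and is byte-identical across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import Alignment, write_alignment
from .cartesian import CartesianParams, cartesian_to_rate
from .likelihood import RateHeterogeneity, _Propagator
from .rates import equilibrium_frequencies, is_stochastic, normalize
from .registry import ModelDefinition, get_model
from .trees import Phylogeny, write_tree

__all__ = [
    "SimulationSpec",
    "simulate_alignment",
    "random_tree",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to simulate one alignment, seed included."""

    tree: Phylogeny
    model: ModelDefinition | str
    b: tuple = ()
    trace: float = -4.0
    heterogeneity: RateHeterogeneity = field(
        default_factory=RateHeterogeneity)
    n_sites: int = 1000
    seed: int = 0
    p_missing: float = 0.0

    def resolved_model(self) -> ModelDefinition:
        return (get_model(self.model) if isinstance(self.model, str)
                else self.model)

    def rate_matrix(self) -> np.ndarray:
        model = self.resolved_model()
        Q = cartesian_to_rate(
            CartesianParams(model, np.asarray(self.b, dtype=float)))
        return normalize(Q, self.trace)


def _draw(cum: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Categorical draws: `cum` is (4, n) column-cumulative probabilities."""
    return (cum < u[None, :]).sum(axis=0).clip(0, 3)


def simulate_alignment(spec: SimulationSpec) -> Alignment:
    """Simulate one alignment under `spec` (see module docstring)."""
    Q = spec.rate_matrix()
    if not is_stochastic(Q, tol=1e-9):
        raise ValueError("simulation rate matrix is not stochastic")
    tree = spec.tree
    n_sites = int(spec.n_sites)
    if n_sites < 1:
        raise ValueError("n_sites must be positive")
    pi = equilibrium_frequencies(Q)
    rng = np.random.Generator(np.random.Philox(spec.seed))
    # one uniform per (node, site), plus one per site for the rate
    # category and one per (leaf, site) for optional missingness
    u_state = rng.random((tree.n_nodes, n_sites))
    u_rate = rng.random(n_sites)
    u_miss = rng.random((tree.n_leaves, n_sites))

    rates, probs = spec.heterogeneity.categories()
    cat = (np.cumsum(probs)[:, None] < u_rate[None, :]).sum(axis=0)
    cat = cat.clip(0, len(rates) - 1)

    states = np.empty((tree.n_nodes, n_sites), dtype=np.int64)
    states[tree.root] = _draw(np.cumsum(pi)[:, None] * np.ones(n_sites),
                              u_state[tree.root])
    prop = _Propagator(Q)
    preorder = tree.postorder[::-1]
    for c, r in enumerate(rates):
        sites = np.nonzero(cat == c)[0]
        if sites.size == 0:
            continue
        for node in preorder:
            p = tree.parent[node]
            if p < 0:
                continue
            M = prop(tree.lengths[node] * r)
            M = np.clip(M, 0.0, None)
            M = M / M.sum(axis=0, keepdims=True)
            cum = np.cumsum(M, axis=0)
            states[node, sites] = _draw(cum[:, states[p, sites]],
                                        u_state[node, sites])
    codes = np.uint8(1) << states[:tree.n_leaves].astype(np.uint8)
    if spec.p_missing > 0.0:
        codes = np.where(u_miss < spec.p_missing, np.uint8(15), codes)
    return Alignment(list(tree.taxa), codes)


def random_tree(n_taxa: int, seed: int = 0, depth: float = 0.5,
                prefix: str = "t") -> Phylogeny:
    """A random rooted binary tree with exponential-ish branch lengths.

    Taxa are joined in random order; branch lengths are uniform in
    (0.2, 1.8) x `depth` / log2(n_taxa), giving trees of roughly the
    requested root-to-tip depth.
    """
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.Generator(np.random.Philox(seed))
    scale = depth / max(1.0, np.log2(n_taxa))
    items = [f"{prefix}{i + 1}" for i in range(n_taxa)]
    subtrees = list(items)
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        li, lj = rng.uniform(0.2, 1.8, 2) * scale
        merged = f"({subtrees[i]}:{li:.6f},{subtrees[j]}:{lj:.6f})"
        subtrees = ([s for k, s in enumerate(subtrees) if k not in (i, j)]
                    + [merged])
    return Phylogeny.from_newick(subtrees[0] + ";")


#: fixture definitions: name -> (model, b, heterogeneity, taxa, sites).
#: The models span all equilibrium-frequency classes (0-3 degrees of
#: freedom), reversible and nonreversible structures, and every
#: heterogeneity kind, at sizes small enough to keep text fixtures tiny.
_FIXTURES = {
    "jc_small": ("1.1", (), RateHeterogeneity(), 4, 1000),
    "k2st_titv": ("RY2.2b", (0.6,), RateHeterogeneity(), 4, 1000),
    "ebf1_3.4": ("3.4", (0.3, 0.4), RateHeterogeneity(), 6, 1500),
    "ebf2_ry5.7a": ("RY5.7a", (0.4, -0.2, 0.3, 0.1),
                    RateHeterogeneity(), 6, 1500),
    "ebf3_ry5.6b": ("RY5.6b", (0.5, 0.3, 0.25, -0.35),
                    RateHeterogeneity(), 8, 2000),
    "gamma_ry2.2b": ("RY2.2b", (0.5,),
                     RateHeterogeneity("G", gamma_shape=0.6), 6, 2000),
    "invar_3.3a": ("3.3a", (0.4, -0.3),
                   RateHeterogeneity("I", p_invariant=0.3), 6, 2000),
    "ig_ry8.8": ("RY8.8", (0.3, 0.2, -0.2, 0.25, 0.15, -0.1, 0.05),
                 RateHeterogeneity("IG", p_invariant=0.2, gamma_shape=0.8),
                 8, 2000),
    "gm_12.12": ("12.12", (0.2, -0.15, 0.1, 0.25, -0.2, 0.15,
                           0.1, -0.05, 0.2, -0.1, 0.05),
                 RateHeterogeneity(), 6, 1500),
}


def make_fixture_suite(seed: int, out_dir) -> dict:
    """Write the deterministic fixture bundle and return its manifest.

    Each fixture gets ``<name>.fasta`` and ``<name>.nwk``; the manifest
    (also written as ``manifest.json``) records the generating model,
    Cartesian parameters, heterogeneity, seeds and tree so recovery
    tests can check fitted values against the truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "fixtures": {}}
    for k, (name, (model, b, het, n_taxa, n_sites)) in enumerate(
            _FIXTURES.items()):
        tree = random_tree(n_taxa, seed=seed * 1000 + k)
        spec = SimulationSpec(tree=tree, model=model, b=tuple(b),
                              heterogeneity=het, n_sites=n_sites,
                              seed=seed * 1000 + 500 + k)
        aln = simulate_alignment(spec)
        write_alignment(aln, out / f"{name}.fasta")
        write_tree(tree, out / f"{name}.nwk")
        manifest["fixtures"][name] = {
            "model": model,
            "b": list(b),
            "trace": spec.trace,
            "heterogeneity": {
                "kind": het.kind,
                "p_invariant": het.p_invariant,
                "gamma_shape": het.gamma_shape,
            },
            "n_taxa": n_taxa,
            "n_sites": n_sites,
            "tree_seed": seed * 1000 + k,
            "sim_seed": seed * 1000 + 500 + k,
            "alignment": f"{name}.fasta",
            "tree": f"{name}.nwk",
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
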