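"""The catalogue of Lie Markov model structures and their properties.

A model *structure* (e.g. ``"5.6b"``) is a named subset of the basis
generators; combined with a pairing (RY, WS or MK) it yields a concrete
model whose rate matrices are the linear span of the permuted generators.
The number before the point in the name is the model dimension, the
number after it the count of extreme rays of its stochastic cone.

Structural properties — Lie closure, nesting, equilibrium-frequency
degrees of freedom, time reversibility — all derive from the basis sets
and are computed here.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np

from .basis import Pairing, basis_matrix

__all__ = [
    "ModelDefinition",
    "MODEL_STRUCTURES",
    "SYMMETRIC_STRUCTURES",
    "STRUCTURE_ALIASES",
    "build_model",
    "get_model",
    "list_models",
    "list_structures",
    "verify_lie_closure",
    "model_span",
    "spans_equal",
    "is_nested",
    "ebf_degrees_of_freedom",
    "is_time_reversible",
    "distinct_pairing_structures",
    "catalogue",
    "nesting_graph_dot",
]

#: basis sets of the 37 catalogued structures, keyed by structure name.
MODEL_STRUCTURES: dict[str, tuple[str, ...]] = {
    "1.1": ("A",),
    "2.2b": ("A", "A1"),
    "3.3a": ("A", "A1", "B"),
    "3.3b": ("A", "A1", "C"),
    "3.3c": ("A", "A1", "D1"),
    "3.4": ("A", "A1", "D"),
    "4.4a": ("A", "D", "E1", "E2"),
    "4.4b": ("A", "A1", "D", "D1"),
    "4.5a": ("A", "A1", "B", "D"),
    "4.5b": ("A", "A1", "C", "D"),
    "5.6a": ("A", "A1", "B", "C", "D1"),
    "5.6b": ("A", "A1", "D", "E1", "E2"),
    "5.7a": ("A", "A1", "B", "E1", "E2"),
    "5.7b": ("A", "A1", "B", "F1", "F2"),
    "5.7c": ("A", "A1", "B", "G1", "G2"),
    "5.11a": ("A", "A1", "D1", "E1", "E2"),
    "5.11b": ("A", "A1", "D1", "F1", "F2"),
    "5.11c": ("A", "A1", "D1", "G1", "G2"),
    "5.16": ("A", "A1", "D", "G1", "G2"),
    "6.6": ("A", "A1", "B", "C", "D", "D1"),
    "6.7a": ("A", "A1", "B", "D", "E1", "E2"),
    "6.7b": ("A", "A1", "C", "D", "E1", "E2"),
    "6.8a": ("A", "A1", "D", "D1", "E1", "E2"),
    "6.8b": ("A", "A1", "D", "D1", "G1", "G2"),
    "6.17a": ("A", "A1", "B", "D", "G1", "G2"),
    "6.17b": ("A", "A1", "C", "D", "G1", "G2"),
    "8.8": ("A", "A1", "D", "D1", "E1", "E2", "F1", "F2"),
    "8.10a": ("A", "A1", "B", "C", "D", "D1", "E1", "E2"),
    "8.10b": ("A", "A1", "B", "C", "D", "D1", "G1", "G2"),
    "8.16": ("A", "A1", "D", "D1", "E1", "E2", "G1", "G2"),
    "8.17": ("A", "A1", "B", "D", "E1", "E2", "G1", "G2"),
    "8.18": ("A", "A1", "B", "D", "E1", "E2", "F1", "F2"),
    "9.20a": ("A", "A1", "B", "C", "D1", "E1", "E2", "F1", "F2"),
    "9.20b": ("A", "A1", "B", "C", "D1", "F1", "F2", "G1", "G2"),
    "10.12": ("A", "A1", "B", "C", "D", "D1", "E1", "E2", "F1", "F2"),
    "10.34": ("A", "A1", "B", "C", "D", "D1", "E1", "E2", "G1", "G2"),
    "12.12": ("A", "A1", "B", "C", "D", "D1",
              "E1", "E2", "F1", "F2", "G1", "G2"),
}

#: hidden structure: forbids transversions entirely, so it is excluded
#: from catalogues but remains constructible for testing.
_HIDDEN_STRUCTURES: dict[str, tuple[str, ...]] = {"2.2a": ("A1", "D1")}

#: structures whose RY/WS/MK spans coincide (never get a pairing prefix).
SYMMETRIC_STRUCTURES = ("1.1", "3.3a", "4.4a", "6.7a", "9.20b", "12.12")

#: classical names: structure -> (alias, pairing it applies to).
STRUCTURE_ALIASES: dict[str, tuple[str, Pairing]] = {
    "1.1": ("JC", Pairing.FULLY_SYMMETRIC),
    "2.2b": ("K2ST", Pairing.RY),
    "3.3a": ("K3ST", Pairing.FULLY_SYMMETRIC),
    "3.3c": ("TrNef", Pairing.RY),
    "4.4a": ("F81", Pairing.FULLY_SYMMETRIC),
    "6.6": ("SSM", Pairing.WS),
    "9.20b": ("DS", Pairing.FULLY_SYMMETRIC),
    "12.12": ("GM", Pairing.FULLY_SYMMETRIC),
}

_SPAN_TOL = 1e-9


@dataclass(frozen=True)
class ModelDefinition:
    """A structure + pairing, with its basis generators resolved.

    ``basis_names`` lists the generators as catalogued (using ``A1``);
    ``use_a2`` re-expresses the same span with ``A2 = 3*A1 - A`` so that
    every non-``A`` generator is trace-free, which the Cartesian
    parameterization requires.
    """

    structure_name: str
    pairing: Pairing
    basis_names: tuple[str, ...]
    dimension: int
    ray_count: int
    alias: str | None = None
    hidden: bool = False
    _span: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def name(self) -> str:
        if self.pairing is Pairing.FULLY_SYMMETRIC:
            return self.structure_name
        return f"{self.pairing.value}{self.structure_name}"

    def basis_matrices(self, use_a2: bool = False) -> list[np.ndarray]:
        """The generators in canonical A,G,C,T coordinates."""
        names = self.basis_names
        if use_a2:
            if "A" not in names:
                raise ValueError(
                    f"model {self.name} has no A generator; A2 cannot "
                    "substitute for A1")
            names = tuple("A2" if n == "A1" else n for n in names)
        return [basis_matrix(n, self.pairing) for n in names]

    def span(self) -> np.ndarray:
        """Orthonormal row basis of the vectorized rate-matrix span."""
        if self._span is None:
            mats = np.array([m.ravel() for m in self.basis_matrices()])
            q = np.linalg.qr(mats.T)[0].T
            object.__setattr__(self, "_span", q)
        return self._span


def _parse_name(structure_name: str) -> tuple[int, int]:
    m = re.fullmatch(r"(\d+)\.(\d+)[a-c]?", structure_name)
    if not m:
        raise KeyError(f"malformed model structure name {structure_name!r}")
    return int(m.group(1)), int(m.group(2))


def build_model(structure_name: str, pairing: Pairing | str = Pairing.RY,
                allow_hidden: bool = False) -> ModelDefinition:
    """Construct the `ModelDefinition` for `structure_name` under `pairing`.

    The six fully symmetric structures ignore the requested pairing.
    Structure ``"2.2a"`` is rejected unless ``allow_hidden`` is set: the
    hierarchy omits it because it forbids transversions entirely.
    """
    if isinstance(pairing, str):
        pairing = Pairing(pairing.upper()) if pairing.upper() != "SYM" \
            else Pairing.FULLY_SYMMETRIC
    hidden = False
    if structure_name in _HIDDEN_STRUCTURES:
        if not allow_hidden:
            raise KeyError(
                "model 2.2a is omitted from the hierarchy: it forbids "
                "transversions entirely and is of no phylogenetic "
                "interest (pass allow_hidden=True to construct it anyway)")
        basis_names = _HIDDEN_STRUCTURES[structure_name]
        hidden = True
    elif structure_name in MODEL_STRUCTURES:
        basis_names = MODEL_STRUCTURES[structure_name]
    else:
        raise KeyError(
            f"unknown model structure {structure_name!r}; valid names: "
            f"{', '.join(MODEL_STRUCTURES)}")
    if structure_name in SYMMETRIC_STRUCTURES:
        pairing = Pairing.FULLY_SYMMETRIC
    elif pairing is Pairing.FULLY_SYMMETRIC:
        raise ValueError(
            f"structure {structure_name} is not fully symmetric; choose "
            "an RY, WS or MK pairing")
    dim, rays = _parse_name(structure_name)
    alias = None
    al = STRUCTURE_ALIASES.get(structure_name)
    if al is not None and (al[1] is pairing or al[1] is Pairing.FULLY_SYMMETRIC):
        alias = al[0]
    if len(basis_names) != dim:
        raise AssertionError("catalogue inconsistency")  # pragma: no cover
    return ModelDefinition(structure_name, pairing, basis_names,
                           dim, rays, alias, hidden)


#: ModelTest spellings for models that already exist in the hierarchy
#: under another classical name (K80 = K2ST, K81 = K3ST).
_MODELTEST_SPELLINGS = {"K80": "K2ST", "K81": "K3ST"}


def get_model(name: str) -> ModelDefinition:
    """Resolve a prefixed model name like ``"RY5.6b"``, ``"6.7a"`` or a
    classical alias like ``"K2ST"``."""
    name = _MODELTEST_SPELLINGS.get(name.upper(), name)
    for struct, (alias, pairing) in STRUCTURE_ALIASES.items():
        if name.upper() == alias.upper():
            return build_model(struct, pairing)
    m = re.fullmatch(r"(RY|WS|MK)?(\d+\.\d+[a-c]?)", name)
    if not m:
        raise KeyError(f"cannot parse model name {name!r}")
    prefix, struct = m.groups()
    if struct in SYMMETRIC_STRUCTURES:
        return build_model(struct, Pairing.FULLY_SYMMETRIC)
    return build_model(struct, Pairing(prefix) if prefix else Pairing.RY)


#: names of the nine reversible models the classical ModelTest panel adds
#: beyond the Lie Markov hierarchy.
MODELTEST_EXTRA = ("HKY", "TrN", "K81uf", "TIMef", "TIM",
                   "TVMef", "TVM", "SYM", "GTR")


def list_structures() -> list[str]:
    """The 37 catalogued structure names."""
    return list(MODEL_STRUCTURES)


def list_models(include_pairing_variants: bool = True,
                include_modeltest: bool = False) -> list[str]:
    """Model catalogue names.

    Without variants: the 37 structures.  With variants: the 6 fully
    symmetric structures plus 31 x 3 pairing variants = 99.  Adding the
    reversible ModelTest panel contributes 9 more for 108.
    """
    if not include_pairing_variants:
        names = list(MODEL_STRUCTURES)
    else:
        names = []
        for struct in MODEL_STRUCTURES:
            if struct in SYMMETRIC_STRUCTURES:
                names.append(struct)
            else:
                names.extend(f"{p.value}{struct}"
                             for p in (Pairing.RY, Pairing.WS, Pairing.MK))
    if include_modeltest:
        names.extend(MODELTEST_EXTRA)
    return names


def verify_lie_closure(model: ModelDefinition, tol: float = 1e-10) -> dict:
    """Check the model span is closed under the matrix commutator.

    For every generator pair the commutator ``XY - YX`` is projected onto
    the span; the report carries the maximum residual and the worst pair.
    A residual above ``tol`` would indicate a mis-transcribed generator.
    """
    mats = model.basis_matrices()
    span = model.span()
    worst = (0.0, None)
    for (i, X), (j, Y) in itertools.combinations(enumerate(mats), 2):
        comm = (X @ Y - Y @ X).ravel()
        resid = float(np.linalg.norm(comm - span.T @ (span @ comm)))
        if resid > worst[0]:
            worst = (resid, (model.basis_names[i], model.basis_names[j]))
    return {"model": model.name, "max_residual": worst[0],
            "worst_pair": worst[1], "closed": worst[0] < tol}


def model_span(model: ModelDefinition) -> np.ndarray:
    """Orthonormal basis (rows) of the model's vectorized span."""
    return model.span()


def _rank(rows: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(rows, tol=_SPAN_TOL))


def spans_equal(a: ModelDefinition, b: ModelDefinition) -> bool:
    if a.dimension != b.dimension:
        return False
    return _rank(np.vstack([a.span(), b.span()])) == a.dimension


def is_nested(inner: ModelDefinition, outer: ModelDefinition) -> bool:
    """True iff every rate matrix of `inner` lies in `outer`'s span.

    Both spans are expressed in canonical coordinates first, so
    cross-pairing nestings (e.g. an RY model inside a WS supermodel via a
    fully symmetric intermediate) are detected.
    """
    stacked = np.vstack([inner.span(), outer.span()])
    return _rank(stacked) == outer.dimension


def ebf_degrees_of_freedom(model: ModelDefinition) -> int:
    """Degrees of freedom of the equilibrium base frequencies (0-3).

    ``D`` contributes the between-pair degree of freedom, ``E1``/``E2``
    the two within-pair ones; models with none of the three are doubly
    stochastic and pin the equilibrium at 1/4 per base.
    """
    names = set(model.basis_names)
    has_d = "D" in names
    has_e = "E1" in names or "E2" in names
    return 3 if (has_d and has_e) else 1 if has_d else 2 if has_e else 0


def is_time_reversible(model: ModelDefinition, n_samples: int = 30,
                       tol: float = 1e-8, seed: int = 0) -> bool:
    """Detailed-balance check on randomly sampled stochastic members.

    With the column convention, detailed balance reads
    ``pi_j * Q[i, j] == pi_i * Q[j, i]``; equivalently the flux matrix
    ``Q * pi`` (columns scaled by the equilibrium) is symmetric.
    """
    from .cartesian import sample_stochastic
    from .rates import equilibrium_frequencies

    for Q in sample_stochastic(model, trace=-4.0, n=n_samples, seed=seed):
        pi = equilibrium_frequencies(Q)
        flux = Q * pi[np.newaxis, :]
        if np.abs(flux - flux.T).max() > tol:
            return False
    return True


def distinct_pairing_structures() -> list[str]:
    """Structures whose RY, WS and MK spans are pairwise distinct (31)."""
    out = []
    for struct in MODEL_STRUCTURES:
        ms = [build_model(struct, p) if struct not in SYMMETRIC_STRUCTURES
              else None for p in (Pairing.RY, Pairing.WS, Pairing.MK)]
        if ms[0] is None:
            continue
        if (not spans_equal(ms[0], ms[1]) and not spans_equal(ms[0], ms[2])
                and not spans_equal(ms[1], ms[2])):
            out.append(struct)
    return out


def catalogue(include_pairing_variants: bool = True):
    """Machine-readable catalogue as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for name in list_models(include_pairing_variants):
        m = get_model(name)
        rows.append({
            "name": m.name,
            "structure": m.structure_name,
            "pairing": m.pairing.value,
            "basis": ",".join(m.basis_names),
            "dimension": m.dimension,
            "rays": m.ray_count,
            "ebf_df": ebf_degrees_of_freedom(m),
            "reversible": is_time_reversible(m),
            "alias": m.alias or "",
        })
    return pd.DataFrame(rows)


def _covering_edges(models: list[ModelDefinition]) -> list[tuple[str, str]]:
    """Transitive reduction of the nesting partial order on spans."""
    n = len(models)
    leq = np.zeros((n, n), dtype=bool)
    for i, a in enumerate(models):
        for j, b in enumerate(models):
            if i != j and a.dimension < b.dimension and is_nested(a, b):
                leq[i, j] = True
    edges = []
    for i in range(n):
        for j in range(n):
            if leq[i, j] and not any(leq[i, k] and leq[k, j] for k in range(n)):
                edges.append((models[i].name, models[j].name))
    return edges


def nesting_graph_dot(pairing: Pairing = Pairing.RY) -> str:
    """Nesting hierarchy for one pairing family, in DOT format.

    Nodes are the 6 fully symmetric structures plus the 31 asymmetric
    structures under `pairing`; edges are covering nesting relations.
    """
    models = []
    for struct in MODEL_STRUCTURES:
        if struct in SYMMETRIC_STRUCTURES:
            models.append(build_model(struct, Pairing.FULLY_SYMMETRIC))
        else:
            models.append(build_model(struct, pairing))
    lines = ["digraph nesting {", "  rankdir=BT;"]
    for m in models:
        label = m.name + (f"\\n({m.alias})" if m.alias else "")
        lines.append(f'  "{m.name}" [label="{label}"];')
    for lo, hi in _covering_edges(models):
        lines.append(f'  "{lo}" -> "{hi}";')
    lines.append("}")
    return "\n".join(lines)
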