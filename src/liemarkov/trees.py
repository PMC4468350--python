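"""Phylogenies as flat arrays, plus distance-based tree building.

A :class:`Phylogeny` stores a rooted tree over node indices: leaves come
first (in taxon order), internal nodes after, the root last.  The
likelihood and simulation code only ever touches the ``parent``,
``lengths`` and ``postorder`` arrays.

Newick text is parsed and written through ``dendropy``; neighbor joining
and midpoint rooting are delegated to it as well.  Branch lengths are in
expected substitutions per site under the trace −4 rate normalization.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .alignment import Alignment

__all__ = [
    "Phylogeny",
    "read_tree",
    "write_tree",
    "jc_distance_matrix",
    "nj_tree",
    "tree_diameter",
]


@dataclass
class Phylogeny:
    """A rooted phylogeny with branch lengths.

    Node ``i < n_leaves`` is the leaf ``taxa[i]``; the root is the last
    node.  ``lengths[i]`` is the branch above node ``i`` (zero for the
    root); ``postorder`` lists every node before its parent.
    """

    taxa: list[str]
    parent: np.ndarray
    lengths: np.ndarray
    children: list[list[int]] = field(repr=False)
    postorder: np.ndarray = field(repr=False)

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    @property
    def is_binary_rooted(self) -> bool:
        """Every internal node, the root included, has exactly two children."""
        return all(len(self.children[i]) == 2
                   for i in range(self.n_leaves, self.n_nodes))

    def branch_lengths_vector(self) -> np.ndarray:
        """Lengths of all non-root branches, indexed by child node."""
        return self.lengths[:-1].copy()

    def with_branch_lengths(self, lengths) -> "Phylogeny":
        """Copy of the tree with the non-root branch lengths replaced."""
        lengths = np.asarray(lengths, dtype=float)
        if lengths.shape != (self.n_branches,):
            raise ValueError(
                f"expected {self.n_branches} branch lengths, "
                f"got shape {lengths.shape}")
        if lengths.min() < 0:
            raise ValueError("branch lengths must be nonnegative")
        full = np.append(lengths, 0.0)
        return Phylogeny(self.taxa, self.parent.copy(), full,
                         [c[:] for c in self.children],
                         self.postorder.copy())

    # -- conversions ---------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        leaves = list(tree.leaf_node_iter())
        taxa = [lf.taxon.label for lf in leaves]
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon labels in tree")
        if len(taxa) < 2:
            raise ValueError("tree needs at least two leaves")
        index = {id(lf): i for i, lf in enumerate(leaves)}
        internals = [nd for nd in tree.postorder_node_iter()
                     if not nd.is_leaf()]
        # dendropy postorder visits the seed (root) last already
        for k, nd in enumerate(internals):
            index[id(nd)] = len(taxa) + k
        n = len(taxa) + len(internals)
        parent = np.full(n, -1, dtype=int)
        lengths = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        for nd in tree.postorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                lengths[i] = (nd.edge.length
                              if nd.edge.length is not None else 0.0)
        post = np.array([index[id(nd)]
                         for nd in tree.postorder_node_iter()], dtype=int)
        if lengths.min() < 0:
            raise ValueError("tree has negative branch lengths")
        return cls(taxa, parent, lengths, children, post)

    def to_dendropy(self) -> dendropy.Tree:
        ns = dendropy.TaxonNamespace(self.taxa)
        tree = dendropy.Tree(taxon_namespace=ns)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i, label in enumerate(self.taxa):
            nodes[i].taxon = ns.get_taxon(label)
        for i in range(self.n_nodes - 1):
            nodes[self.parent[i]].add_child(nodes[i])
            nodes[i].edge.length = float(self.lengths[i])
        tree.seed_node = nodes[self.root]
        tree.is_rooted = True
        return tree

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=text, schema="newick",
                                     preserve_underscores=True)
        except Exception as exc:
            raise ValueError(f"could not parse newick tree: {exc}") from exc
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True,
            unquoted_underscores=True).strip()

    # -- operations ----------------------------------------------------

    def require_rooted(self, context: str = "this operation") -> None:
        """Raise if the tree is not strictly bifurcating at every node.

        A trifurcating root is the newick signature of an unrooted tree;
        root placement matters for nonreversible models, so the caller
        must choose a root (``midpoint_root`` is the package default).
        """
        if not self.is_binary_rooted:
            raise ValueError(
                f"{context} needs a rooted binary tree, but this tree has "
                "a multifurcation (an unrooted tree read from newick "
                "shows up as a trifurcating root); root it first, e.g. "
                "with Phylogeny.midpoint_root()")

    def midpoint_root(self) -> "Phylogeny":
        """Reroot at the midpoint of the longest leaf-to-leaf path."""
        tree = self.to_dendropy()
        tree.reroot_at_midpoint(update_bipartitions=False)
        # drop any unifurcation the reroot may leave behind
        tree.suppress_unifurcations()
        return Phylogeny.from_dendropy(tree)

    def node_depths(self) -> np.ndarray:
        """Path length from the root down to each node."""
        depth = np.zeros(self.n_nodes)
        for i in self.postorder[::-1]:
            if self.parent[i] >= 0:
                depth[i] = depth[self.parent[i]] + self.lengths[i]
        return depth


def read_tree(path) -> Phylogeny:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return Phylogeny.from_newick(path.read_text())


def write_tree(tree: Phylogeny, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def jc_distance_matrix(aln: Alignment) -> np.ndarray:
    """Pairwise Jukes–Cantor distances ``d = -(3/4) ln(1 - 4p/3)``.

    ``p`` is the mismatch proportion over sites where both sequences
    have an unambiguous call.  ``p >= 3/4`` means the pair is saturated
    beyond what the correction can invert and raises rather than being
    silently capped.
    """
    n = aln.n_taxa
    codes = aln.codes
    plain = np.isin(codes, (1, 2, 4, 8))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            use = plain[i] & plain[j]
            if not use.any():
                raise ValueError(
                    f"no comparable sites between {aln.taxa[i]} "
                    f"and {aln.taxa[j]}")
            p = np.mean(codes[i, use] != codes[j, use])
            if p >= 0.75:
                raise ValueError(
                    f"sequences {aln.taxa[i]} and {aln.taxa[j]} are "
                    f"saturated (mismatch proportion {p:.3f} >= 3/4); "
                    "the distance correction diverges")
            D[i, j] = D[j, i] = -0.75 * np.log1p(-4.0 * p / 3.0)
    return D


def nj_tree(aln: Alignment, distances: np.ndarray | None = None,
            midpoint: bool = True) -> Phylogeny:
    """Neighbor-joining tree from Jukes–Cantor distances.

    The NJ tree is unrooted; by default it is midpoint-rooted so the
    result is directly usable for likelihood work.  Negative NJ branch
    lengths (a known small-sample artifact) are clamped to zero.
    """
    if aln.n_taxa < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    if distances is None:
        distances = jc_distance_matrix(aln)
    buf = io.StringIO()
    buf.write("," + ",".join(aln.taxa) + "\n")
    for i, t in enumerate(aln.taxa):
        buf.write(t + "," + ",".join(repr(float(x)) for x in distances[i])
                  + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    phylo = Phylogeny.from_dendropy(tree)
    return phylo.midpoint_root() if midpoint else phylo


def tree_diameter(tree: Phylogeny) -> float:
    """Longest leaf-to-leaf path length, in substitutions per site.

    Multiplied by the rate-matrix trace this bounds the trace of the
    end-to-end average generator, which is the quantity the
    embeddability thresholds are stated in.
    """
    # farthest-leaf distance below each node; combine the two best
    # children at every internal node
    best = np.where(np.arange(tree.n_nodes) < tree.n_leaves, 0.0, -np.inf)
    diameter = 0.0
    for i in tree.postorder:
        kids = tree.children[i]
        if not kids:
            continue
        downs = sorted((best[k] + tree.lengths[k] for k in kids),
                       reverse=True)
        best[i] = downs[0]
        if len(downs) > 1:
            diameter = max(diameter, downs[0] + downs[1])
    return float(diameter)
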