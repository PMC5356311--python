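"""Rooted phylogenies with branch lengths, as flat indexed arrays.

Newick parsing/writing goes through dendropy; the pruning and reconstruction
code works on a plain array representation (parent pointers, postorder) that
is cheap to traverse.  Branch lengths are expected numbers of substitutions
per site.  An unrooted tree (multifurcating root) is refused unless the
caller designates an outgroup to root on — the pipeline never guesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np


class TreeError(ValueError):
    """Raised for malformed or inconsistent trees."""


@dataclass
class PhyloTree:
    """Rooted tree: node i has parent ``parent[i]`` and edge length ``blen[i]``.

    The root has parent -1 and blen 0.  Leaves carry the taxon names; internal
    nodes are auto-labelled ``N1..Nk`` in postorder (the root is the last) when
    the Newick source does not name them.
    """

    names: list[str]
    parent: np.ndarray          # int, -1 at root
    blen: np.ndarray            # float, 0.0 at root
    children: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.names)
        self.parent = np.asarray(self.parent, dtype=int)
        self.blen = np.asarray(self.blen, dtype=float)
        if not self.children:
            self.children = [[] for _ in range(n)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    self.children[p].append(i)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        if np.any(self.blen < 0):
            raise TreeError("negative branch length")
        leaf_names = [self.names[i] for i in self.leaf_indices()]
        if len(leaf_names) != len(set(leaf_names)):
            dupes = sorted({x for x in leaf_names if leaf_names.count(x) > 1})
            raise TreeError(f"duplicate leaf names: {dupes}")

    # -- structure queries ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def leaf_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaf_indices()]

    def internal_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.is_leaf(i)]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise TreeError(f"no node named '{name}'") from None

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def descendant_leaves(self, i: int) -> list[int]:
        """Leaf indices below node i (i itself if a leaf)."""
        out, stack = [], [i]
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                out.append(v)
            else:
                stack.extend(self.children[v])
        return out

    def total_length(self) -> float:
        return float(self.blen.sum())

    # -- editing -------------------------------------------------------------

    def with_branch_lengths(self, blen: np.ndarray) -> "PhyloTree":
        return PhyloTree(list(self.names), self.parent.copy(),
                         np.asarray(blen, dtype=float).copy())

    def reroot_at(self, name: str) -> "PhyloTree":
        """Re-orient the tree so the named internal node becomes the root.

        Edges on the path from the node to the old root are reversed, keeping
        their lengths; for a reversible substitution model the likelihood is
        unchanged.  The old root is kept as an ordinary (possibly
        single-child) node.
        """
        new_root = self.index(name)
        parent = self.parent.copy()
        blen = self.blen.copy()
        # collect path new_root -> old root, then flip each edge
        path = [new_root]
        while parent[path[-1]] >= 0:
            path.append(int(parent[path[-1]]))
        for child, par in zip(path, path[1:]):
            parent[par] = child
            blen[par] = self.blen[child]
        parent[new_root] = -1
        blen[new_root] = 0.0
        return PhyloTree(list(self.names), parent, blen)

    # -- newick I/O ----------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            if self.is_leaf(i):
                body = self.names[i]
            else:
                body = "(" + ",".join(fmt(c) for c in self.children[i]) + ")" + self.names[i]
            if self.parent[i] >= 0:
                body += f":{self.blen[i]:.10g}"
            return body

        return fmt(self.root) + ";"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    names: list[str] = []
    parent: list[int] = []
    blen: list[float] = []
    index: dict[int, int] = {}
    auto = 0
    nodes = list(dtree.preorder_node_iter())
    n_internal = sum(1 for nd in nodes if not nd.is_leaf())
    # postorder numbering of internal labels so the root is N<k>
    post_rank = {id(nd): r for r, nd in enumerate(
        nd for nd in dtree.postorder_node_iter() if not nd.is_leaf())}
    for nd in nodes:
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError("leaf without a name")
            name = nd.taxon.label
        elif nd.label:
            name = nd.label
        else:
            name = f"N{post_rank[id(nd)] + 1}"
            auto += 1
        idx = len(names)
        index[id(nd)] = idx
        names.append(name)
        if nd.parent_node is None:
            parent.append(-1)
            blen.append(0.0)
        else:
            if nd.edge.length is None:
                raise TreeError(f"branch above '{name}' has no length; "
                                "lengths are required (no silent default)")
            parent.append(index[id(nd.parent_node)])
            blen.append(float(nd.edge.length))
    del auto, n_internal
    if len(set(names)) != len(names):
        # internal auto-labels may collide with given labels
        raise TreeError("duplicate node names after labelling")
    return PhyloTree(names, np.array(parent), np.array(blen))


def read_tree(path: str | Path, root_on: str | None = None) -> PhyloTree:
    """Read a single Newick tree with branch lengths.

    If the root is multifurcating the tree is treated as unrooted and
    ``root_on`` (a leaf name) is required: the tree is rooted at the midpoint
    of that leaf's terminal branch.
    """
    return _read_newick(Path(path).read_text(), root_on)


def tree_from_string(newick: str, root_on: str | None = None) -> PhyloTree:
    return _read_newick(newick, root_on)


def _read_newick(newick: str, root_on: str | None) -> PhyloTree:
    try:
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse Newick: {exc}") from exc
    seed_children = len(dtree.seed_node.child_nodes())
    if seed_children > 2:
        if root_on is None:
            raise TreeError(
                "tree appears unrooted (multifurcating root); pass "
                "root_on=<leaf name> (CLI: --root-on) to place the root")
        target = None
        for nd in dtree.leaf_node_iter():
            if nd.taxon is not None and nd.taxon.label == root_on:
                target = nd
                break
        if target is None:
            raise TreeError(f"root_on leaf '{root_on}' not found in tree")
        if target.edge.length is None:
            raise TreeError(f"branch above '{root_on}' has no length")
        half = target.edge.length / 2.0
        dtree.reroot_at_edge(target.edge, length1=half, length2=half,
                             update_bipartitions=False)
    return _from_dendropy(dtree)
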