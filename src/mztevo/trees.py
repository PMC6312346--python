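"""Rooted phylogenies as flat postorder arrays.

Newick parsing and writing are delegated to dendropy; internally the tree is
held as parent/child index arrays in deterministic postorder, which is what
the pruning, simulation and parsimony routines iterate over.  Internal nodes
are named ``N{postorder_index}`` unless the newick supplies labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


@dataclass
class Tree:
    """A rooted tree indexed in postorder (root last).

    Attributes
    ----------
    labels : list of str
        Node labels, tips carry taxon names; internal nodes ``N<i>``.
    parent : np.ndarray of int
        Parent index per node; root has parent -1.
    children : list of list of int
        Child indices per node (empty for tips).
    blen : np.ndarray of float
        Length of the branch above each node; 0 for the root.
    """

    labels: list[str]
    parent: np.ndarray
    children: list[list[int]]
    blen: np.ndarray
    tip_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.tip_index = {
            self.labels[i]: i for i in range(self.n_nodes) if not self.children[i]
        }

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tips(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips]

    @property
    def internal(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def preorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def height(self) -> float:
        """Maximum root-to-tip path length."""
        depth = np.zeros(self.n_nodes)
        for v in self.preorder():
            if v != self.root:
                depth[v] = depth[self.parent[v]] + self.blen[v]
        return float(depth[self.tips].max())

    def patristic_distances(self) -> np.ndarray:
        """Pairwise tip-to-tip path lengths, ordered as ``self.tips``."""
        depth = np.zeros(self.n_nodes)
        for v in self.preorder():
            if v != self.root:
                depth[v] = depth[self.parent[v]] + self.blen[v]
        tips = self.tips
        n = len(tips)
        # ancestor sets per tip for MRCA lookup
        anc: list[dict[int, float]] = []
        for t in tips:
            path = {}
            v = t
            while v != -1:
                path[v] = depth[v]
                v = self.parent[v]
            anc.append(path)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                common = max(
                    (d for v, d in anc[i].items() if v in anc[j]), default=0.0
                )
                out[i, j] = out[j, i] = depth[tips[i]] + depth[tips[j]] - 2 * common
        return out


def _from_dendropy(dtree: dendropy.Tree) -> Tree:
    nodes = list(dtree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    labels: list[str] = []
    parent = np.full(len(nodes), -1, dtype=int)
    children: list[list[int]] = [[] for _ in nodes]
    blen = np.zeros(len(nodes))
    for i, nd in enumerate(nodes):
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError("tip without a label")
            labels.append(nd.taxon.label.replace(" ", "_"))
        else:
            lbl = nd.label or f"N{i}"
            labels.append(lbl)
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            children[parent[i]].append(i)
            if nd.edge.length is None:
                raise TreeError(f"branch above {labels[-1]!r} has no length")
            if nd.edge.length < 0:
                raise TreeError(f"negative branch length above {labels[-1]!r}")
            blen[i] = float(nd.edge.length)
    tips = [labels[i] for i in range(len(nodes)) if not children[i]]
    if len(set(tips)) != len(tips):
        raise TreeError("duplicate tip labels")
    root = len(nodes) - 1
    if len(children[root]) > 2:
        raise TreeError(
            f"root has {len(children[root])} children; a rooted (binary-rooted) "
            "tree is required"
        )
    return Tree(labels=labels, parent=parent, children=children, blen=blen)


def read_tree(source: str, species: list[str] | None = None, *, path: bool | None = None) -> Tree:
    """Parse a rooted newick tree from a file path or a newick string.

    Strings containing ``(`` are treated as newick data, anything else as a
    path.  ``species``, when given, must all be present among the tip labels.
    """
    is_path = not source.lstrip().startswith("(") if path is None else path
    try:
        if is_path:
            dtree = dendropy.Tree.get(path=source, schema="newick")
        else:
            dtree = dendropy.Tree.get(data=source, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse newick: {exc}") from exc
    tree = _from_dendropy(dtree)
    if species is not None:
        missing = set(species) - set(tree.tip_labels)
        if missing:
            raise TreeError(f"species not found among tree tips: {sorted(missing)}")
    return tree


def to_newick(tree: Tree, internal_labels: bool = True) -> str:
    def render(v: int) -> str:
        if tree.is_tip(v):
            core = tree.labels[v]
        else:
            inner = ",".join(render(c) for c in tree.children[v])
            lbl = tree.labels[v] if internal_labels else ""
            core = f"({inner}){lbl}"
        if v == tree.root:
            return core
        return f"{core}:{tree.blen[v]:.10g}"

    return render(tree.root) + ";"


def write_tree(tree: Tree, path: str, internal_labels: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(to_newick(tree, internal_labels=internal_labels) + "\n")
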