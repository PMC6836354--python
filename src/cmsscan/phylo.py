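"""Distance-based phylogenetics for candidate-gene homolog sets.

p-distances (proportion of differing alignment columns, gaps counted as
differences) feed a Saitou-Nei neighbor-joining builder with deterministic
lowest-index tie-breaking.  Trees serialize to newick with 6-decimal branch
lengths; negative NJ branch estimates are clamped to zero and flagged.
Topology, not branch-length inference, is the deliverable: homolog trees
only need to show which lineage a chimeric ORF groups with.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .align_core import PROTEIN_SCHEME, ScoringScheme, global_align


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    taxa: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.shape != (len(self.taxa), len(self.taxa)):
            raise PhyloError("distance matrix shape does not match taxa")
        if not np.allclose(d, d.T):
            raise PhyloError("distance matrix must be symmetric")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise PhyloError("distances must be finite and non-negative")
        if np.any(np.diag(d) != 0):
            raise PhyloError("diagonal must be zero")
        self.distances = d


@dataclass
class TreeNode:
    name: str = ""
    branch_length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        return [leaf for c in self.children for leaf in c.leaves()]


@dataclass
class PhyloTree:
    root: TreeNode
    negative_branches_clamped: int = 0

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                body = node.name
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")" + node.name
            if node.branch_length is not None:
                body += f":{node.branch_length:.6f}"
            return body

        return fmt(self.root) + ";"

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions (as the smaller-side leaf sets are
        not canonical on unrooted trees, both sides are normalized)."""
        all_leaves = frozenset(self.root.leaves())
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                out.add(min(below, all_leaves - below, key=sorted))
            return below

        walk(self.root)
        return out


def parse_newick(text: str) -> PhyloTree:
    """Parse the newick serialization produced by :meth:`PhyloTree.to_newick`."""
    tokens = re.findall(
        r"[(),;]|:[0-9.eE+-]+|[^(),;:]+(?::[0-9.eE+-]+)?", text.replace(" ", "")
    )
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if tokens[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if tokens[pos] == ",":
                    pos += 1
                    continue
                break
            if tokens[pos] != ")":
                raise PhyloError("unbalanced newick parentheses")
            pos += 1
        if pos < len(tokens) and tokens[pos] not in "(),;":
            label = tokens[pos]
            pos += 1
            if label.startswith(":"):
                node.branch_length = float(label[1:])
            elif ":" in label:
                name, bl = label.split(":")
                node.name = name
                node.branch_length = float(bl)
            else:
                node.name = label
        return node

    root = parse_node()
    if pos >= len(tokens) or tokens[pos] != ";":
        raise PhyloError("newick must end with ';'")
    return PhyloTree(root=root)


def p_distance(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Proportion of differing columns after global alignment."""
    res = global_align(a, b, scheme or PROTEIN_SCHEME)
    return (res.mismatches + res.gap_columns) / res.aligned_length


def pairwise_distances(
    seqs: dict[str, str] | list[tuple[str, str]],
    model: str = "p-distance",
    scheme: ScoringScheme | None = None,
) -> DistanceMatrix:
    """All-pairs p-distance matrix of named sequences (>= 3 required)."""
    if model != "p-distance":
        raise PhyloError(f"unknown distance model {model!r}")
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if len(items) < 3:
        raise PhyloError("need at least 3 sequences for a distance matrix")
    taxa = [name for name, _ in items]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(items[i][1], items[j][1], scheme)
    return DistanceMatrix(taxa=taxa, distances=d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with lowest-index tie-breaking.

    Produces an unrooted tree represented with a trifurcating root (the
    last three remaining nodes).  For n=3 the closed-form three-point
    branch lengths are returned directly.
    """
    n = len(dm.taxa)
    if n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    d = dm.distances.copy()
    nodes = [TreeNode(name=t) for t in dm.taxa]
    active = list(range(n))
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among minima
        flat = np.argmin(q)
        bi, bj = divmod(int(flat), m)
        if bi > bj:
            bi, bj = bj, bi
        i, j = active[bi], active[bj]
        dij = d[i, j]
        li = 0.5 * dij + (r[bi] - r[bj]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        nodes[i].branch_length = clamp(li)
        nodes[j].branch_length = clamp(lj)
        parent.children = [nodes[i], nodes[j]]
        # distances from the new node to the others
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        d = np.column_stack([d, np.append(new_row, 0.0)])
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    # join the final three nodes at a trifurcating root
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    nodes[a].branch_length = clamp(0.5 * (dab + dac - dbc))
    nodes[b].branch_length = clamp(0.5 * (dab + dbc - dac))
    nodes[c].branch_length = clamp(0.5 * (dac + dbc - dab))
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root=root, negative_branches_clamped=clamped)
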