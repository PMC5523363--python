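"""Rooted ultrametric trees: newick I/O, UPGMA, monophyly checks.

An ultrametric (clock-like) tree stores a height above the tips for every
node: tips sit at height 0 and every root-to-tip path has equal length.
Such trees are the substrate of the mixed Yule-coalescent delimitation
model, where node heights are proxies for event times.

Newick parsing and serialization are delegated to dendropy; the internal
representation is a minimal height-annotated node structure convenient
for interval extraction and threshold sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

#: Relative tolerance for ultrametricity validation.
ULTRAMETRIC_RTOL = 1e-6


@dataclass
class Node:
    """Tree node; ``label`` is set for tips, ``height`` is above the tips."""

    height: float
    label: str | None = None
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)


class UltrametricTree:
    """Rooted tree with tip heights 0 and parent height >= child height."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self._validate()

    # -- traversal ---------------------------------------------------------

    def preorder(self):
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_tips(self) -> int:
        return len(self.leaves())

    @property
    def height(self) -> float:
        return self.root.height

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        scale = max(self.root.height, 1e-300)
        for n in self.preorder():
            if n.is_leaf:
                if n.label is None:
                    raise ValueError("unlabelled tip")
                if abs(n.height) > ULTRAMETRIC_RTOL * scale:
                    raise ValueError(f"tip {n.label} at height {n.height} != 0")
                n.height = 0.0
            else:
                for c in n.children:
                    if n.height < c.height - ULTRAMETRIC_RTOL * scale:
                        raise ValueError(
                            f"parent height {n.height} < child height {c.height}"
                        )
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")

    # -- manipulation ------------------------------------------------------

    def scaled(self, factor: float) -> "UltrametricTree":
        """Copy with every node height multiplied by ``factor``."""

        def rec(n: Node) -> Node:
            m = Node(height=n.height * factor, label=n.label)
            for c in n.children:
                m.add(rec(c))
            return m

        return UltrametricTree(rec(self.root))

    def drop_tips(self, labels) -> "UltrametricTree":
        """Copy without the listed tips, suppressing unifurcations."""
        drop = set(labels)

        def rec(n: Node) -> Node | None:
            if n.is_leaf:
                return None if n.label in drop else Node(n.height, n.label)
            kept = [c for c in (rec(c) for c in n.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                return kept[0]
            m = Node(n.height)
            for c in kept:
                m.add(c)
            return m

        root = rec(self.root)
        if root is None or root.is_leaf:
            raise ValueError("fewer than 2 tips left after dropping")
        return UltrametricTree(root)

    # -- newick ------------------------------------------------------------

    def to_newick(self) -> str:
        def rec(n: Node) -> str:
            if n.is_leaf:
                core = n.label
            else:
                core = "(" + ",".join(rec(c) for c in n.children) + ")"
            if n.parent is None:
                return core
            return f"{core}:{n.parent.height - n.height:.10g}"

        return rec(self.root) + ";"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def parse_newick(text: str, strict: bool = True) -> UltrametricTree:
    """Parse a newick string with branch lengths into an ultrametric tree.

    Node heights are derived from branch lengths measured down from the
    root.  In strict mode a tree whose tips are not equidistant from the
    root (beyond a relative tolerance of 1e-6) is rejected; in lenient
    mode tip heights are coerced to zero.
    """
    dt = dendropy.Tree.get(
        data=text, schema="newick", rooting="force-rooted",
        suppress_internal_node_taxa=True,
    )
    # depth from root
    depth: dict[dendropy.Node, float] = {}
    for nd in dt.preorder_node_iter():
        el = nd.edge.length
        if nd.parent_node is None:
            depth[nd] = 0.0
        else:
            if el is None:
                raise ValueError("newick is missing branch lengths")
            depth[nd] = depth[nd.parent_node] + float(el)
    tip_depths = [depth[nd] for nd in dt.leaf_node_iter()]
    h_root = max(tip_depths)
    if h_root <= 0:
        raise ValueError("tree has zero height")
    spread = (max(tip_depths) - min(tip_depths)) / h_root
    if strict and spread > ULTRAMETRIC_RTOL:
        raise ValueError(
            f"tree is not ultrametric (relative tip-depth spread {spread:.3g})"
        )

    def rec(nd: dendropy.Node) -> Node:
        if nd.is_leaf():
            if nd.taxon is None:
                raise ValueError("unlabelled tip in newick")
            return Node(height=0.0, label=nd.taxon.label.replace(" ", "_"))
        m = Node(height=h_root - depth[nd])
        for c in nd.child_nodes():
            m.add(rec(c))
        return m

    return UltrametricTree(rec(dt.seed_node))


def read_newick(path: str | Path, strict: bool = True) -> UltrametricTree:
    return parse_newick(Path(path).read_text(), strict=strict)


def upgma_tree(dm, height_separation: float = 0.0) -> UltrametricTree:
    """UPGMA agglomeration of a distance matrix into an ultrametric tree.

    At each step the pair of clusters with the smallest average distance
    is merged at height = half that distance.  Serves as a deterministic
    strict-clock tree builder; the output always satisfies the
    ultrametric invariants.  Missing (nan) entries are an error.

    ``height_separation`` > 0 forces every pair of internal node heights
    at least that far apart (merges are bumped upward deterministically
    in merge order).  Identical or near-identical sequences otherwise
    produce zero-length branches, which the branching-process likelihood
    downstream cannot accommodate; a separation at the scale of one
    substitution's worth of height mimics the strictly positive node
    times a probabilistic clock tree assigns them.
    """
    d = np.asarray(dm.d, dtype=float)
    ids = list(dm.ids)
    if np.isnan(d).any():
        raise ValueError("distance matrix has undefined entries")
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 tips")
    nodes: dict[int, Node] = {i: Node(0.0, ids[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    used_heights: list[float] = []
    work = d.copy()
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        best = (np.inf, None)
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                if work[i, j] < best[0]:
                    best = (work[i, j], (i, j))
        dist, (i, j) = best
        h = max(dist / 2.0, nodes[i].height, nodes[j].height)
        if height_separation > 0:
            h = max(
                h,
                nodes[i].height + height_separation,
                nodes[j].height + height_separation,
            )
            bumped = True
            while bumped:
                bumped = False
                for prev in used_heights:
                    new = prev + height_separation
                    if abs(h - prev) < height_separation * (1 - 1e-9) and new > h:
                        h = new
                        bumped = True
            used_heights.append(h)
        parent = Node(h)
        parent.add(nodes[i])
        parent.add(nodes[j])
        # average linkage update
        work = np.pad(work, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            v = (sizes[i] * work[i, k] + sizes[j] * work[j, k]) / (
                sizes[i] + sizes[j]
            )
            work[nxt, k] = work[k, nxt] = v
        nodes[nxt] = parent
        sizes[nxt] = sizes[i] + sizes[j]
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    return UltrametricTree(nodes[active[0]])


def check_reciprocal_monophyly(
    tree: UltrametricTree, partition: dict[str, str]
) -> dict[str, bool]:
    """Per-label monophyly verdicts.

    A label is monophyletic iff the most recent common ancestor of its
    tips subtends no tip of any other label; single-tip labels are
    monophyletic by convention.
    """
    leaves = tree.leaves()
    missing = [n.label for n in leaves if n.label not in partition]
    if missing:
        raise ValueError(f"tips without a label: {missing}")
    # leaf set under every node, by postorder accumulation
    below: dict[int, set[str]] = {}
    for n in tree.postorder():
        if n.is_leaf:
            below[id(n)] = {n.label}
        else:
            acc = set()
            for c in n.children:
                acc |= below[id(c)]
            below[id(n)] = acc
    verdicts: dict[str, bool] = {}
    for label in sorted(set(partition[n.label] for n in leaves)):
        tips = {n.label for n in leaves if partition[n.label] == label}
        if len(tips) == 1:
            verdicts[label] = True
            continue
        # MRCA = smallest node whose leaf set contains all tips
        mrca_set = None
        for n in tree.preorder():
            s = below[id(n)]
            if tips <= s and (mrca_set is None or len(s) < len(mrca_set)):
                mrca_set = s
        verdicts[label] = mrca_set == tips
    return verdicts
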