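"""Fitch parsimony: tree length, heuristic search, character optimization.

Characters are unordered nucleotide states; missing data and IUPAC
ambiguity act as wildcards (state sets).  Tree length is the minimum
number of state changes summed over sites (Fitch's small-parsimony
count).  The heuristic search uses random stepwise addition followed by
nearest-neighbor-interchange refinement, keeping every distinct
topology at the best length found.

Character optimization classifies each change on each branch:

* a change is *unambiguous* if it falls on that branch in every
  most-parsimonious ancestral reconstruction (MPR) — computed exactly by
  dynamic programming (up/down Sankoff passes), not by picking one
  reconstruction;
* a site is *non-homoplasious* if its tree-wide minimum change count
  equals the theoretical minimum (number of distinct observed states
  minus one), i.e. it shows no convergence or reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import Alignment

# state bitmasks
_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7,
    "N": 15, "-": 15, "?": 15,
}
_STATES = "ACGT"
_INF = 10 ** 6


@dataclass
class CharacterMatrix:
    """tips x sites matrix of state bitmasks (A=1, C=2, G=4, T=8)."""

    ids: list[str]
    masks: np.ndarray  # uint8, shape (n_tips, n_sites)

    @classmethod
    def from_alignment(cls, aln: Alignment) -> "CharacterMatrix":
        masks = np.array(
            [[_MASK[b] for b in s.bases] for s in aln.seqs], dtype=np.uint8
        )
        return cls(ids=list(aln.ids), masks=masks)

    @property
    def n_sites(self) -> int:
        return self.masks.shape[1]

    def condensed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(unique site-pattern columns, weights, site->pattern index)."""
        pats, inverse, counts = np.unique(
            self.masks, axis=1, return_inverse=True, return_counts=True
        )
        return pats, counts, inverse


class PNode:
    """Mutable unweighted tree node for parsimony search."""

    __slots__ = ("label", "children", "parent")

    def __init__(self, label: str | None = None):
        self.label = label
        self.children: list[PNode] = []
        self.parent: PNode | None = None

    def add(self, child: "PNode") -> None:
        child.parent = self
        self.children.append(child)

    def remove(self, child: "PNode") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        out, stack = [], [self]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def leaves(self) -> list["PNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "PNode":
        m = PNode(self.label)
        for c in self.children:
            m.add(c.copy())
        return m

    def canonical(self) -> str:
        if self.is_leaf:
            return self.label
        return "(" + ",".join(sorted(c.canonical() for c in self.children)) + ")"

    def to_newick(self) -> str:
        return self.canonical() + ";"


def tree_from_ultrametric(root) -> PNode:
    """Topology-only copy of a height-annotated tree node."""

    def rec(n) -> PNode:
        m = PNode(getattr(n, "label", None))
        for c in n.children:
            m.add(rec(c))
        return m

    return rec(root.root if hasattr(root, "root") else root)


def _leaf_mask_rows(
    root: PNode, matrix: CharacterMatrix, cols: np.ndarray
) -> dict[int, np.ndarray]:
    row_of = {t: i for i, t in enumerate(matrix.ids)}
    out = {}
    for leaf in root.leaves():
        if leaf.label not in row_of:
            raise ValueError(f"tip {leaf.label!r} not in character matrix")
        out[id(leaf)] = cols[row_of[leaf.label]]
    return out


def fitch_length(tree, matrix: CharacterMatrix) -> int:
    """Minimum number of changes over all sites (Fitch count).

    ``tree`` may be a :class:`PNode` root or any object with a ``root``
    attribute of nested ``children``/``label`` nodes; heights are
    ignored.  Missing/ambiguous states are wildcards.  Raises if tree
    tips and matrix rows mismatch.
    """
    root = tree if isinstance(tree, PNode) else tree_from_ultrametric(tree)
    tips = sorted(n.label for n in root.leaves())
    if tips != sorted(matrix.ids):
        raise ValueError("tree tips do not match character matrix rows")
    pats, weights, _ = matrix.condensed()
    leaf_rows = _leaf_mask_rows(root, matrix, pats)
    return int(_fitch_steps(root, leaf_rows, weights))


def _fitch_steps(root: PNode, leaf_rows, weights) -> int:
    state: dict[int, np.ndarray] = {}
    steps = np.zeros(len(weights), dtype=np.int64)
    for n in root.postorder():
        if n.is_leaf:
            state[id(n)] = leaf_rows[id(n)]
            continue
        acc = state.pop(id(n.children[0]))
        for c in n.children[1:]:
            other = state.pop(id(c))
            inter = acc & other
            union = acc | other
            hit = inter == 0
            steps += hit * 1
            acc = np.where(hit, union, inter)
        state[id(n)] = acc
    return int((steps * weights).sum())


# ---------------------------------------------------------------------------
# heuristic search


def _tree_length(root: PNode, leaf_rows, weights) -> int:
    return _fitch_steps(root, leaf_rows, weights)


def _random_addition_tree(labels: list[str], rng: np.random.Generator,
                          matrix: CharacterMatrix, pats, weights) -> PNode:
    order = list(rng.permutation(labels))
    root = PNode()
    root.add(PNode(order[0]))
    root.add(PNode(order[1]))
    row_of = {t: i for i, t in enumerate(matrix.ids)}
    for lab in order[2:]:
        best = (np.inf, None)
        edges = [n for n in root.postorder() if n.parent is not None]
        for target in edges:
            parent = target.parent
            mid, leaf = PNode(), PNode(lab)
            parent.children[parent.children.index(target)] = mid
            mid.parent = parent
            mid.add(target)
            mid.add(leaf)
            leaf_rows = {
                id(n): pats[row_of[n.label]] for n in root.leaves()
            }
            length = _fitch_steps(root, leaf_rows, weights)
            if length < best[0]:
                best = (length, target)
            # undo
            mid.remove(target)
            parent.children[parent.children.index(mid)] = target
            target.parent = parent
        target = best[1]
        parent = target.parent
        mid, leaf = PNode(), PNode(lab)
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add(target)
        mid.add(leaf)
    return root


def _nni_neighbors(root: PNode):
    """Yield (apply, undo) closures for every NNI move on the tree."""
    for v in list(root.postorder()):
        if v.is_leaf or v.parent is None:
            continue
        u = v.parent
        siblings = [s for s in u.children if s is not v]
        for s in siblings:
            for c in list(v.children):
                yield _make_swap(u, s, v, c)


def _make_swap(u: PNode, s: PNode, v: PNode, c: PNode):
    def apply():
        u.children[u.children.index(s)] = c
        v.children[v.children.index(c)] = s
        s.parent, c.parent = v, u

    def undo():
        u.children[u.children.index(c)] = s
        v.children[v.children.index(s)] = c
        s.parent, c.parent = u, v

    return apply, undo


@dataclass
class SearchResult:
    best_length: int
    trees: list[PNode]

    def newicks(self) -> list[str]:
        return [t.to_newick() for t in self.trees]


def heuristic_search(
    matrix: CharacterMatrix,
    outgroup: str | None = None,
    reps: int = 100,
    seed: int = 0,
) -> SearchResult:
    """Random-addition + NNI heuristic search for most-parsimonious trees.

    Runs ``reps`` independent random-addition replicates (seeded), each
    refined by NNI to a local optimum; returns every distinct topology
    at the overall best length, rooted on ``outgroup`` for reporting
    (distinctness is judged on the outgroup-rooted canonical form).
    Requires >= 4 tips.
    """
    labels = list(matrix.ids)
    if len(labels) < 4:
        raise ValueError("heuristic search needs at least 4 tips")
    if outgroup is not None and outgroup not in labels:
        raise ValueError(f"outgroup {outgroup!r} not among tips")
    pats, weights, _ = matrix.condensed()
    row_of = {t: i for i, t in enumerate(matrix.ids)}

    def rows_for(root: PNode):
        return {id(n): pats[row_of[n.label]] for n in root.leaves()}

    best_len = np.inf
    best: dict[str, PNode] = {}
    for rep in range(reps):
        rng = np.random.default_rng((seed, rep))
        root = _random_addition_tree(labels, rng, matrix, pats, weights)
        length = _fitch_steps(root, rows_for(root), weights)
        improved = True
        while improved:
            improved = False
            for apply, undo in _nni_neighbors(root):
                apply()
                cand = _fitch_steps(root, rows_for(root), weights)
                if cand < length:
                    length = cand
                    improved = True
                else:
                    undo()
        if length < best_len:
            best_len, best = length, {}
        if length == best_len:
            rooted = (
                reroot_on_outgroup(root, outgroup) if outgroup else root.copy()
            )
            best.setdefault(rooted.canonical(), rooted)
    return SearchResult(best_length=int(best_len), trees=list(best.values()))


def reroot_on_outgroup(root: PNode, outgroup: str) -> PNode:
    """Copy of the tree rooted on the edge subtending the outgroup tip."""
    root = root.copy()
    og = next(n for n in root.postorder() if n.label == outgroup)
    if og.parent is None:
        raise ValueError("outgroup cannot be the root")
    # build the rerooted tree: new root with og and the rest
    rest = _hang_from(og.parent, exclude=og)
    new_root = PNode()
    new_root.add(PNode(outgroup))
    new_root.add(rest)
    return new_root


def _hang_from(node: PNode, exclude: PNode) -> PNode:
    """Subtree of everything reachable from ``node`` except ``exclude``."""
    kept = [c.copy() for c in node.children if c is not exclude]
    up = node.parent
    if up is not None:
        kept.append(_hang_from(up, exclude=node))
    if len(kept) == 1:
        return kept[0]
    m = PNode()
    for c in kept:
        m.add(c)
    return m


# ---------------------------------------------------------------------------
# character optimization (exact MPR classification)


@dataclass
class BranchChange:
    """One classified change: site (0-based), branch given by the tip set
    below it, optimal parent/child state sets, and flags."""

    site: int
    clade: frozenset
    from_states: str
    to_states: str
    unambiguous: bool
    homoplasious: bool


@dataclass
class CharacterOptimization:
    """Per-branch classified changes plus per-site change counts."""

    changes: list[BranchChange]
    site_min_changes: np.ndarray
    site_theoretical_min: np.ndarray
    tree_length: int

    def unambiguous_changes(self, clade=None, homoplasious=None):
        out = [c for c in self.changes if c.unambiguous]
        if clade is not None:
            clade = frozenset(clade)
            out = [c for c in out if c.clade == clade]
        if homoplasious is not None:
            out = [c for c in out if c.homoplasious == homoplasious]
        return out


def root_branch_clade(root: PNode, below: dict[int, frozenset]) -> frozenset:
    """Deterministic clade key for the unrooted branch at the root."""
    c1, c2 = root.children
    return min(
        (below[id(c1)], below[id(c2)]),
        key=lambda s: (len(s), tuple(sorted(s))),
    )


def _sankoff_tables(root: PNode, leaf_masks: dict[int, int]):
    """Down/up DP tables of subtree costs per node and state (unit costs)."""
    nodes = list(root.postorder())
    down: dict[int, np.ndarray] = {}
    for n in nodes:
        if n.is_leaf:
            m = leaf_masks[id(n)]
            down[id(n)] = np.array(
                [0 if (m >> s) & 1 else _INF for s in range(4)]
            )
        else:
            acc = np.zeros(4, dtype=np.int64)
            for c in n.children:
                dc = down[id(c)]
                acc = acc + np.minimum(dc, dc.min() + 1)
            down[id(n)] = acc
    up: dict[int, np.ndarray] = {id(root): np.zeros(4, dtype=np.int64)}
    # preorder up-pass
    stack = [root]
    while stack:
        u = stack.pop()
        for v in u.children:
            # cost of everything outside v's subtree given v's state
            sib = np.zeros(4, dtype=np.int64)
            for w in u.children:
                if w is v:
                    continue
                dw = down[id(w)]
                sib = sib + np.minimum(dw, dw.min() + 1)
            base = up[id(u)] + sib  # per state of u
            up[id(v)] = np.array(
                [
                    min(base[su] + (0 if su == sv else 1) for su in range(4))
                    for sv in range(4)
                ]
            )
            stack.append(v)
    return down, up


def optimize_characters(tree, matrix: CharacterMatrix) -> CharacterOptimization:
    """Classify every change on every branch across all MPRs.

    For each site and branch, the change is reported *unambiguous* iff
    forcing equal states across the branch costs strictly more than the
    site's minimum (so every MPR changes there); the reported state sets
    are those achieved in some MPR with a change on the branch.  A site
    is *homoplasious* iff its minimum change count exceeds (distinct
    observed unambiguous states - 1).
    """
    root = tree if isinstance(tree, PNode) else tree_from_ultrametric(tree)
    tips = sorted(n.label for n in root.leaves())
    if tips != sorted(matrix.ids):
        raise ValueError("tree tips do not match character matrix rows")
    row_of = {t: i for i, t in enumerate(matrix.ids)}
    pats, weights, inverse = matrix.condensed()
    below: dict[int, frozenset] = {}
    for n in root.postorder():
        below[id(n)] = (
            frozenset([n.label])
            if n.is_leaf
            else frozenset().union(*(below[id(c)] for c in n.children))
        )
    # the root's two child edges form a single unrooted branch: a change
    # there is reported once, under the root-branch clade key
    merged_root = len(root.children) == 2
    branches = [
        n for n in root.postorder()
        if n.parent is not None and not (merged_root and n.parent is root)
    ]

    n_pat = pats.shape[1]
    pat_min = np.zeros(n_pat, dtype=np.int64)
    pat_theo = np.zeros(n_pat, dtype=np.int64)
    pat_changes: list[list] = [[] for _ in range(n_pat)]
    for j in range(n_pat):
        leaf_masks = {
            id(n): int(pats[row_of[n.label], j]) for n in root.leaves()
        }
        observed = set()
        for m in leaf_masks.values():
            if bin(m).count("1") == 1:
                observed.add(m)
        theo = max(len(observed) - 1, 0)
        down, up = _sankoff_tables(root, leaf_masks)
        total = int(min(down[id(root)][s] + up[id(root)][s] for s in range(4)))
        pat_min[j] = total
        pat_theo[j] = theo
        if total == 0:
            continue
        homopl = total > theo
        if merged_root:
            c1, c2 = root.children
            d1, d2 = down[id(c1)], down[id(c2)]
            no_change = int(min(d1[s] + d2[s] for s in range(4)))
            if no_change > 0:  # some MPR may change across the root branch
                pairs = [
                    (s1, s2)
                    for s1 in range(4)
                    for s2 in range(4)
                    if s1 != s2 and d1[s1] + d2[s2] + 1 == total
                ]
                if pairs:
                    froms = "".join(sorted({_STATES[a] for a, _ in pairs}))
                    tos = "".join(sorted({_STATES[b] for _, b in pairs}))
                    pat_changes[j].append(
                        BranchChange(
                            site=-1, clade=root_branch_clade(root, below),
                            from_states=froms, to_states=tos,
                            unambiguous=no_change > total, homoplasious=homopl,
                        )
                    )
        for v in branches:
            u = v.parent
            sib = np.zeros(4, dtype=np.int64)
            for w in u.children:
                if w is v:
                    continue
                dw = down[id(w)]
                sib = sib + np.minimum(dw, dw.min() + 1)
            outside = up[id(u)] + sib  # cost excluding v's subtree, per u-state
            dv = down[id(v)]
            no_change = int(min(outside[s] + dv[s] for s in range(4)))
            unamb = no_change > total
            # optimal changing state pairs on this branch
            pairs = [
                (su, sv)
                for su in range(4)
                for sv in range(4)
                if su != sv and outside[su] + 1 + dv[sv] == total
            ]
            if not pairs:
                continue  # no MPR changes on this branch
            froms = "".join(sorted({_STATES[a] for a, _ in pairs}))
            tos = "".join(sorted({_STATES[b] for _, b in pairs}))
            pat_changes[j].append(
                BranchChange(
                    site=-1, clade=below[id(v)], from_states=froms,
                    to_states=tos, unambiguous=unamb, homoplasious=homopl,
                )
            )

    changes: list[BranchChange] = []
    site_min = pat_min[inverse]
    site_theo = pat_theo[inverse]
    for site, j in enumerate(inverse):
        for bc in pat_changes[j]:
            changes.append(
                BranchChange(
                    site=site, clade=bc.clade, from_states=bc.from_states,
                    to_states=bc.to_states, unambiguous=bc.unambiguous,
                    homoplasious=bc.homoplasious,
                )
            )
    return CharacterOptimization(
        changes=changes,
        site_min_changes=site_min,
        site_theoretical_min=site_theo,
        tree_length=int((pat_min * weights).sum()),
    )


def collapse_unsupported(root: PNode, matrix: CharacterMatrix) -> PNode:
    """Copy with internal branches carrying no unambiguous change collapsed.

    Mirrors hard-collapsing of zero-length branches before counting
    distinct most-parsimonious topologies.
    """
    root = root.copy()
    opt = optimize_characters(root, matrix)
    supported = {c.clade for c in opt.changes if c.unambiguous}
    below: dict[int, frozenset] = {}
    for n in root.postorder():
        below[id(n)] = (
            frozenset([n.label])
            if n.is_leaf
            else frozenset().union(*(below[id(c)] for c in n.children))
        )
    for n in list(root.postorder()):
        if n.is_leaf or n.parent is None:
            continue
        key = below[id(n)]
        if n.parent is root and len(root.children) == 2:
            key = root_branch_clade(root, below)
        if key not in supported:
            p = n.parent
            idx = p.children.index(n)
            p.children[idx:idx + 1] = n.children
            for c in n.children:
                c.parent = p
    return root
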