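"""Independent brute-force oracles for small-parsimony checks.

Enumerates every ancestral state assignment (and every allowed state of
ambiguous tips) directly, with no dynamic programming, so it is an
independent check of the Fitch/Sankoff implementations.
"""

import numpy as np


def enumerate_optimal_labelings(root, tip_masks):
    """(min cost, per-edge 'change in every optimum' flags, opt count).

    ``tip_masks``: label -> state bitmask (A=1,C=2,G=4,T=8).  Edges are
    keyed by the frozenset of tip labels below the child.  Only
    feasible assignments (tip state within its mask) are enumerated.
    """
    nodes = list(_postorder(root))
    below = {}
    for n in nodes:
        below[id(n)] = (
            frozenset([n.label])
            if not n.children
            else frozenset().union(*(below[id(c)] for c in n.children))
        )
    free = []
    fixed = {}
    for n in nodes:
        if n.children:
            free.append(n)
        else:
            m = tip_masks[n.label]
            states = [s for s in range(4) if (m >> s) & 1]
            if len(states) == 1:
                fixed[id(n)] = states[0]
            else:
                free.append(n)
    k = len(free)
    idx = {id(n): i for i, n in enumerate(free)}
    grids = np.meshgrid(*([np.arange(4)] * k), indexing="ij")
    A = np.stack([g.ravel() for g in grids], axis=1) if k else np.zeros((1, 0), int)
    valid = np.ones(len(A), dtype=bool)
    for n in free:
        if not n.children:
            m = tip_masks[n.label]
            allowed = np.array([(m >> s) & 1 for s in range(4)], bool)
            valid &= allowed[A[:, idx[id(n)]]]
    A = A[valid]

    def states_of(n):
        if id(n) in fixed:
            return np.full(len(A), fixed[id(n)])
        return A[:, idx[id(n)]]

    # the root's two child edges count as one unrooted branch, keyed by
    # the smaller (then lexicographically first) of the two clades
    merged_root = len(root.children) == 2
    edges = [
        (n.parent, n)
        for n in nodes
        if n.parent is not None and not (merged_root and n.parent is root)
    ]
    cost = np.zeros(len(A), dtype=np.int64)
    mism = {}
    for u, v in edges:
        m = states_of(u) != states_of(v)
        mism[below[id(v)]] = m
        cost += m
    if merged_root:
        c1, c2 = root.children
        m = states_of(c1) != states_of(c2)
        key = min(
            (below[id(c1)], below[id(c2)]),
            key=lambda s: (len(s), tuple(sorted(s))),
        )
        mism[key] = m
        cost += m
    best = int(cost.min())
    opt = cost == best
    always_changes = {
        clade: bool(m[opt].all()) for clade, m in mism.items()
    }
    return best, always_changes, int(opt.sum())


def _postorder(root):
    out, stack = [], [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return reversed(out)


def random_case(rng, n_tips, n_sites, missing_rate=0.15):
    """Random rooted binary topology + state masks per tip and site."""
    from gmycdelim.parsimony import PNode

    nodes = [PNode(f"t{i}") for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        p = PNode()
        p.add(a)
        p.add(b)
        nodes = [x for x in nodes if x is not a and x is not b] + [p]
    root = nodes[0]
    masks = np.zeros((n_tips, n_sites), dtype=np.uint8)
    for i in range(n_tips):
        for j in range(n_sites):
            if rng.random() < missing_rate:
                masks[i, j] = 15
            else:
                masks[i, j] = 1 << int(rng.integers(4))
    return root, masks
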