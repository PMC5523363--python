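"""Single-threshold general mixed Yule-coalescent (GMYC) species delimitation.

Given an ultrametric gene tree, the model places a time threshold T on the
tree: branching events older than T are speciation events of a
generalized pure-birth (Yule) process, branching events younger than T
are coalescences within the independent population processes of the
lineages that cross T (the "entities").  Between successive branching
events the waiting time x_i is exponential with total rate

    rho_i = b1 * n_s,i**p1  +  sum_k b2 * (n_k,i * (n_k,i - 1))**p2

where n_s,i counts lineages on the speciation process during interval i
(below the threshold this is the constant number of entities, since the
species lineages persist to the present) and n_k,i counts the lineages
of coalescent group k.  The log-likelihood is

    logL = sum_i [ ln rho_i - rho_i * x_i ]

over the waiting intervals, each of which ends (rootward) in a branching
event.  The scaling exponents p1, p2 generalize the strict Yule (p=1)
and Kingman coalescent (p=1) rates, absorbing e.g. population growth or
decline; a single (b2, p2) pair is shared across all coalescent groups.
The alternative model therefore has 5 free parameters (b1, p1, b2, p2,
T) against the null's 2 (one coalescent process spanning the whole
tree), giving 3 degrees of freedom for the likelihood-ratio test of
"one species" against "many".

The maximum-likelihood threshold is found by an exhaustive sweep over
candidate thresholds at midpoints between consecutive distinct node
heights (tips included, so the all-singleton pure-Yule configuration is
a candidate).  Entities with two or more sampled tips are reported as
clusters, the rest as singletons; the solutions within 2 log-likelihood
units of the maximum form an approximate confidence set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .trees import Node, UltrametricTree

# parameter box constraints for the rate scales b and exponents p
P_LO, P_HI = 0.0, 3.0
B_LO, B_HI = 1e-10, 1e6

#: relative jitter separating tied node heights (avoids zero-length intervals)
HEIGHT_JITTER = 1e-9

#: default degrees of freedom of the likelihood-ratio test
LRT_DF = 3

#: width of the approximate confidence set, in log-likelihood units
CONFIDENCE_WINDOW = 2.0


def chi2_survival(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if not (isinstance(df, (int, np.integer)) and df >= 1):
        raise ValueError(f"df must be a positive integer, got {df!r}")
    if x < 0:
        raise ValueError("statistic must be non-negative")
    return float(chi2.sf(x, df))


# ---------------------------------------------------------------------------
# waiting-interval extraction


@dataclass
class WaitingIntervalSeries:
    """Per-interval sufficient statistics of the branching process.

    One entry per waiting interval, ordered root -> tips; every interval
    ends (rootward) in the branching event at its top.  ``n_s`` is 0 in
    a pure-coalescent (null) series.  ``group_vals``/``group_idx``
    flatten the per-interval coalescent group sizes as n_k*(n_k-1)
    values (groups of size 1 contribute nothing) with their interval
    index, for vectorized likelihood evaluation.
    """

    x: np.ndarray
    n_s: np.ndarray
    group_vals: np.ndarray
    group_idx: np.ndarray
    n_intervals: int = field(init=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.n_s = np.asarray(self.n_s, dtype=float)
        self.group_vals = np.asarray(self.group_vals, dtype=float)
        self.group_idx = np.asarray(self.group_idx, dtype=np.intp)
        self.n_intervals = len(self.x)
        if (self.x < 0).any():
            raise ValueError("negative interval duration")

    def coalescent_sum(self, p2: float) -> np.ndarray:
        """sum_k (n_k(n_k-1))**p2, per interval."""
        if not len(self.group_vals):
            return np.zeros(self.n_intervals)
        return np.bincount(
            self.group_idx,
            weights=self.group_vals ** p2,
            minlength=self.n_intervals,
        )


def strict_heights(tree: UltrametricTree) -> dict[int, float]:
    """id(node) -> height, with tied internal heights made distinct.

    Ties (polytomies resolved at equal heights, identical sequences) are
    separated by a deterministic jitter of 1e-9 x root height, children
    staying below parents, so every waiting interval has positive
    duration; the likelihood perturbation is below reporting precision.
    """
    depth: dict[int, int] = {}
    for n in tree.preorder():
        depth[id(n)] = 0 if n.parent is None else depth[id(n.parent)] + 1
    order = sorted(
        tree.internal_nodes(), key=lambda n: (n.height, -depth[id(n)])
    )
    eps = HEIGHT_JITTER * max(tree.height, 1e-300)
    out: dict[int, float] = {id(n): 0.0 for n in tree.leaves()}
    prev = 0.0
    for n in order:
        h = max(n.height, prev + eps)
        out[id(n)] = h
        prev = h
    return out


def _entity_roots(
    tree: UltrametricTree, heights: dict[int, float], threshold: float
) -> list[Node]:
    """Nodes whose edge to the parent crosses the threshold height."""
    if heights[id(tree.root)] <= threshold:
        return [tree.root]
    out = []
    for n in tree.preorder():
        if n.parent is None:
            continue
        if heights[id(n)] <= threshold < heights[id(n.parent)]:
            out.append(n)
    return out


def waiting_intervals(
    tree: UltrametricTree, threshold: float | None = None
) -> WaitingIntervalSeries:
    """Waiting-interval statistics of the tree under a threshold placement.

    With ``threshold=None`` every branching event belongs to a single
    coalescent process (the one-species null).  Otherwise lineages above
    the threshold follow the speciation process and each
    threshold-crossing lineage founds its own coalescent group.
    Requires >= 3 tips.
    """
    if tree.n_tips < 3:
        raise ValueError("GMYC intervals require at least 3 tips")
    heights = strict_heights(tree)
    ev_h = sorted(
        (heights[id(n)] for n in tree.internal_nodes()), reverse=True
    )
    edges = [
        (heights[id(n.parent)], heights[id(n)], n)
        for n in tree.preorder()
        if n.parent is not None
    ]
    if threshold is None:
        m = 0
        entity_of: dict[int, int] = {}
    else:
        roots = _entity_roots(tree, heights, threshold)
        m = len(roots)
        entity_of = {}
        for k, r in enumerate(roots):
            stack = [r]
            while stack:
                n = stack.pop()
                entity_of[id(n)] = k
                stack.extend(n.children)

    x, n_s, gvals, gidx = [], [], [], []
    K = len(ev_h)
    for i in range(K):
        top = ev_h[i]
        bot = ev_h[i + 1] if i + 1 < K else 0.0
        mid = 0.5 * (top + bot)
        crossing = [c for (pt, pb, c) in edges if pb <= mid < pt]
        coal: dict[int, int] = {}
        if threshold is None:
            spec = 0
            coal[0] = len(crossing)
        elif mid >= threshold:
            spec = len(crossing)
        else:
            spec = m  # one persisting species lineage per entity
            for c in crossing:
                e = entity_of[id(c)]
                coal[e] = coal.get(e, 0) + 1
        x.append(top - bot)
        n_s.append(spec)
        for cnt in coal.values():
            if cnt >= 2:
                gvals.append(cnt * (cnt - 1))
                gidx.append(i)
    return WaitingIntervalSeries(
        np.array(x), np.array(n_s, dtype=float),
        np.array(gvals, dtype=float), np.array(gidx, dtype=np.intp),
    )


# ---------------------------------------------------------------------------
# likelihood


def interval_loglik(
    series: WaitingIntervalSeries,
    b1: float = 0.0,
    p1: float = 1.0,
    b2: float = 1.0,
    p2: float = 1.0,
) -> float:
    """Log-likelihood of the waiting-interval series at given rates.

    ``b1``/``b2`` scale the speciation and coalescent processes and must
    be positive wherever the corresponding process is active (``b1`` may
    be 0 for a pure-coalescent series).  Raises on a non-positive rate
    for an active process.
    """
    has_yule = bool((series.n_s > 0).any())
    has_coal = len(series.group_vals) > 0
    if has_yule and b1 <= 0:
        raise ValueError("non-positive speciation rate scale")
    if has_coal and b2 <= 0:
        raise ValueError("non-positive coalescent rate scale")
    rho = np.zeros(series.n_intervals)
    if has_yule and b1 > 0:
        rho = rho + b1 * np.where(series.n_s > 0, series.n_s, 1.0) ** p1 * (
            series.n_s > 0
        )
    if has_coal:
        rho = rho + b2 * series.coalescent_sum(p2)
    if (rho <= 0).any():
        return -np.inf
    return float(np.sum(np.log(rho) - rho * series.x))


@dataclass
class NullFit:
    """Fitted single-coalescent (one-species) model."""

    b: float
    p: float
    loglik: float
    converged: bool = True


def fit_null(tree: UltrametricTree) -> NullFit:
    """Maximum-likelihood single-coalescent fit (the one-species null).

    For a fixed exponent p the rate scale b has the closed-form ML
    solution b = m / sum_i C_i x_i with C_i = (n_i(n_i-1))**p, so only a
    1-D bounded search over p is needed.
    """
    series = waiting_intervals(tree, threshold=None)
    return _fit_single_coalescent(series)


def _fit_single_coalescent(series: WaitingIntervalSeries) -> NullFit:
    m = series.n_intervals
    vals = series.group_vals  # one group per interval in the null series

    def negprof(p: float) -> float:
        c = series.coalescent_sum(p)
        denom = float(np.sum(c * series.x))
        if denom <= 0:
            return np.inf
        b = min(max(m / denom, B_LO), B_HI)
        return -float(np.sum(np.log(b * c)) - b * denom)

    res = minimize_scalar(negprof, bounds=(P_LO, P_HI), method="bounded")
    p = float(res.x)
    denom = float(np.sum(series.coalescent_sum(p) * series.x))
    b = min(max(m / denom, B_LO), B_HI)
    return NullFit(
        b=b, p=p, loglik=-float(res.fun), converged=bool(res.success)
    )


def _pure_birth_profile(series: WaitingIntervalSeries) -> tuple[float, float, float]:
    """ML (b1, p1, logL) for a series with no active coalescent groups."""
    m = series.n_intervals

    def negprof(p: float) -> float:
        a = series.n_s ** p
        denom = float(np.sum(a * series.x))
        if denom <= 0:
            return np.inf
        b = min(max(m / denom, B_LO), B_HI)
        return -float(np.sum(np.log(b * a)) - b * denom)

    res = minimize_scalar(negprof, bounds=(P_LO, P_HI), method="bounded")
    p = float(res.x)
    denom = float(np.sum(series.n_s ** p * series.x))
    b = min(max(m / denom, B_LO), B_HI)
    return b, p, -float(res.fun)


def _fit_mixed(series: WaitingIntervalSeries) -> tuple[np.ndarray, float]:
    """Maximize the mixed likelihood over (b1, p1, b2, p2).

    Derivative-free Nelder-Mead on (ln b1, p1, ln b2, p2) from 5
    deterministic moment-matched starts; returns (params, logL).
    """
    yule_mask = series.n_s > 0
    xdur = series.x
    m = series.n_intervals
    # precomputed logs: rates are b*exp(p*log n) per interval/group
    log_ns = np.log(np.where(yule_mask, series.n_s, 1.0))
    has_groups = len(series.group_vals) > 0
    log_gv = np.log(series.group_vals) if has_groups else None
    gidx = series.group_idx
    lb_lo, lb_hi = float(np.log(B_LO)), float(np.log(B_HI))

    def negll(v: np.ndarray) -> float:
        lb1, p1, lb2, p2 = v
        if not (P_LO <= p1 <= P_HI and P_LO <= p2 <= P_HI):
            return np.inf
        lb1 = min(max(lb1, lb_lo), lb_hi)
        lb2 = min(max(lb2, lb_lo), lb_hi)
        rho = np.exp(lb1 + p1 * log_ns) * yule_mask
        if has_groups:
            rho = rho + np.exp(lb2) * np.bincount(
                gidx, weights=np.exp(p2 * log_gv), minlength=m
            )
        # every interval carries an active process, so rho > 0
        return float(rho @ xdur - np.log(rho).sum())

    def moment_b(p1: float, p2: float) -> tuple[float, float]:
        a = np.where(yule_mask, series.n_s, 1.0) ** p1 * yule_mask
        c = series.coalescent_sum(p2)
        # split events evenly by which process dominates the interval
        da = float(np.sum(a * xdur))
        dc = float(np.sum(c * xdur))
        tot = series.n_intervals
        b1 = tot / (2 * da) if da > 0 else 1.0
        b2 = tot / (2 * dc) if dc > 0 else 1.0
        return (min(max(b1, B_LO), B_HI), min(max(b2, B_LO), B_HI))

    starts = []
    for p1, p2 in ((1.0, 1.0), (0.5, 1.0), (1.0, 0.5), (1.5, 1.5), (0.2, 0.2)):
        b1, b2 = moment_b(p1, p2)
        starts.append(np.array([np.log(b1), p1, np.log(b2), p2]))
    best_v, best_f = None, np.inf
    for s in starts:
        res = minimize(
            negll, s, method="Nelder-Mead",
            options={"maxfev": 300, "xatol": 1e-5, "fatol": 1e-8},
        )
        if res.fun < best_f:
            best_f, best_v = float(res.fun), res.x
    lb1, p1, lb2, p2 = best_v
    params = np.array([np.exp(lb1), p1, np.exp(lb2), p2])
    return params, -best_f


# ---------------------------------------------------------------------------
# clusters and the threshold sweep


@dataclass
class ClusterResult:
    """Tip partition induced by a threshold."""

    partition: dict[str, int]
    n_entities: int
    n_clusters: int
    n_singletons: int


def extract_clusters(
    tree: UltrametricTree, threshold: float
) -> ClusterResult:
    """Partition the tips by the lineages crossing the threshold.

    Each crossing lineage is one entity; entities with >= 2 tips are
    clusters, the rest singletons.  A threshold at or above the root
    yields a single entity holding every tip.
    """
    heights = strict_heights(tree)
    roots = _entity_roots(tree, heights, threshold)
    partition: dict[str, int] = {}
    n_clusters = n_singletons = 0
    for k, r in enumerate(roots):
        tips = []
        stack = [r]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                tips.append(n.label)
            stack.extend(n.children)
        for t in tips:
            partition[t] = k
        if len(tips) >= 2:
            n_clusters += 1
        else:
            n_singletons += 1
    return ClusterResult(
        partition=partition,
        n_entities=len(roots),
        n_clusters=n_clusters,
        n_singletons=n_singletons,
    )


@dataclass
class ThresholdCandidate:
    threshold: float
    loglik: float
    n_entities: int
    n_clusters: int
    params: np.ndarray | None


@dataclass
class GMYCFit:
    """Full single-threshold GMYC fit.

    ``loglik_null``/``loglik_alt`` are the maximized log-likelihoods of
    the one-species and threshold models; ``lr`` their likelihood-ratio
    statistic and ``p_value`` its chi-square upper tail at ``df``
    degrees of freedom.  ``confidence_set`` holds every candidate
    threshold within 2 log-likelihood units of the maximum.
    """

    null: NullFit
    threshold: float
    params: np.ndarray | None
    loglik_alt: float
    profile: list[ThresholdCandidate]
    clusters: ClusterResult
    df: int = LRT_DF
    confidence_window: float = CONFIDENCE_WINDOW

    @property
    def loglik_null(self) -> float:
        return self.null.loglik

    @property
    def lr(self) -> float:
        return max(2.0 * (self.loglik_alt - self.loglik_null), 0.0)

    @property
    def p_value(self) -> float:
        return chi2_survival(self.lr, self.df)

    @property
    def confidence_set(self) -> list[ThresholdCandidate]:
        return [
            c for c in self.profile
            if c.loglik >= self.loglik_alt - self.confidence_window
        ]

    def summary(self) -> dict:
        return {
            "loglik_null": self.loglik_null,
            "loglik_alt": self.loglik_alt,
            "lr": self.lr,
            "df": self.df,
            "p_value": self.p_value,
            "threshold": self.threshold,
            "n_entities": self.clusters.n_entities,
            "n_clusters": self.clusters.n_clusters,
            "n_singletons": self.clusters.n_singletons,
            "confidence_set_clusters": sorted(
                {c.n_clusters for c in self.confidence_set}
            ),
            "confidence_set_entities": sorted(
                {c.n_entities for c in self.confidence_set}
            ),
        }


def candidate_thresholds(tree: UltrametricTree) -> list[float]:
    """Midpoints between consecutive distinct node heights (tips at 0).

    The lowest candidate sits below every branching event (an
    all-singleton, pure-Yule configuration); a threshold above the root
    (the null configuration) is handled separately by the sweep.
    """
    heights = strict_heights(tree)
    hs = sorted({0.0} | {heights[id(n)] for n in tree.internal_nodes()})
    return [0.5 * (a + b) for a, b in zip(hs[:-1], hs[1:])]


def fit_gmyc(
    tree: UltrametricTree,
    df: int = LRT_DF,
    confidence_window: float = CONFIDENCE_WINDOW,
) -> GMYCFit:
    """Fit the single-threshold GMYC model by exhaustive threshold sweep.

    Every candidate threshold is scored by maximizing the mixed
    likelihood over (b1, p1, b2, p2); the above-root (one-entity)
    configuration reduces exactly to the null model and is scored with
    the null's maximized log-likelihood, so ``loglik_alt >=
    loglik_null`` always holds.  Ties in log-likelihood are broken
    toward the solution with fewer clusters.
    """
    null = fit_null(tree)
    heights = strict_heights(tree)
    profile: list[ThresholdCandidate] = []
    # the null-like candidate: threshold above the root
    above = heights[id(tree.root)] * 1.01 + 1e-12
    profile.append(
        ThresholdCandidate(
            threshold=above, loglik=null.loglik, n_entities=1,
            n_clusters=1, params=None,
        )
    )
    for t in candidate_thresholds(tree):
        series = waiting_intervals(tree, threshold=t)
        cl = extract_clusters(tree, t)
        if len(series.group_vals) == 0:
            b1, p1, ll = _pure_birth_profile(series)
            params = np.array([b1, p1, np.nan, np.nan])
        else:
            params, ll = _fit_mixed(series)
        profile.append(
            ThresholdCandidate(
                threshold=t, loglik=ll, n_entities=cl.n_entities,
                n_clusters=cl.n_clusters, params=params,
            )
        )
    # best logL; ties (within 1e-9) broken toward the coarser partition
    best_ll = max(c.loglik for c in profile)
    near = [c for c in profile if c.loglik >= best_ll - 1e-9]
    best = min(near, key=lambda c: (c.n_entities, -c.threshold))
    clusters = extract_clusters(tree, best.threshold)
    return GMYCFit(
        null=null,
        threshold=best.threshold,
        params=best.params,
        loglik_alt=best.loglik,
        profile=profile,
        clusters=clusters,
        df=df,
        confidence_window=confidence_window,
    )
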