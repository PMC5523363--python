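"""Synthetic data with the statistical structure the pipeline assumes.

Three generative layers mirror the delimitation model itself:

1. a Yule (pure-birth) species tree — exponential waiting times with
   rate (speciation rate) x (current species count);
2. a neutral coalescent gene tree within the species tree — within each
   species branch, k lineages merge at rate k(k-1)/2 per
   ``coalescent_size`` time units, and lineage sets join at species-tree
   nodes;
3. Kimura 2-parameter sequence evolution along the gene tree, with
   transitions kappa-fold faster than each transversion and total rate
   ``substitution_rate`` expected substitutions/site/time.

The study-like fixture emulates a three-species CO1 barcoding data set:
unbalanced species sizes (19/7/4 plus one outgroup), 825 sites, deep
between-species splits against shallow within-species variation (so
between-species distances land near 0.07-0.13 and within-species ones
below ~0.02), and one short 147-site fragment stored as missing data.
All randomness flows through a single integer seed; a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import AlignedSeq, Alignment
from .trees import Node, UltrametricTree


@dataclass
class ScenarioConfig:
    """Simulation scenario; defaults emulate the three-species study."""

    n_species: int = 3
    tips_per_species: tuple[int, ...] = (19, 7, 4)
    speciation_rate: float = 0.1      # events / time unit
    coalescent_size: float = 0.5      # mean pair-coalescence time within species
    substitution_rate: float = 0.003  # expected substitutions / site / time
    kappa: float = 4.0                # transition : transversion rate ratio
    sites: int = 825
    # (tip label, sites kept from the 5' end); the rest becomes missing
    missing_fragment: tuple[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.sites < 1:
            raise ValueError("species count and sites must be positive")
        if isinstance(self.tips_per_species, int):
            self.tips_per_species = (self.tips_per_species,) * self.n_species
        if len(self.tips_per_species) != self.n_species:
            raise ValueError("tips_per_species length != n_species")
        if min(self.tips_per_species) < 1:
            raise ValueError("each species needs at least one tip")
        for v in (self.speciation_rate, self.coalescent_size,
                  self.substitution_rate, self.kappa):
            if v <= 0:
                raise ValueError("rates and sizes must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_species_tree(
    cfg: ScenarioConfig, rng: np.random.Generator | None = None
) -> UltrametricTree:
    """Yule species tree conditioned on the requested species count.

    Splits occur at rate lambda*k with k current species; after the
    (n-1)-th split one further Exp(lambda*n) waiting time separates the
    last split from the present, so terminal branches are positive.
    Species tips are labelled sp1..spN.  Requires >= 2 species.
    """
    if cfg.n_species < 2:
        raise ValueError("need at least 2 species")
    rng = cfg.rng() if rng is None else rng
    lam = cfg.speciation_rate
    # forward times of splits, origin at 0
    t = 0.0
    split_times = []
    for k in range(1, cfg.n_species):
        t += rng.exponential(1.0 / (lam * k))
        split_times.append(t)
    present = t + rng.exponential(1.0 / (lam * cfg.n_species))
    # grow the topology: a uniformly chosen lineage splits at each event
    root = Node(height=present - split_times[0])
    active = [Node(0.0), Node(0.0)]
    root.add(active[0])
    root.add(active[1])
    for st in split_times[1:]:
        n = active.pop(int(rng.integers(len(active))))
        n.height = present - st
        a, b = Node(0.0), Node(0.0)
        n.add(a)
        n.add(b)
        active.extend([a, b])
    for i, n in enumerate(active, start=1):
        n.height = 0.0
        n.label = f"sp{i}"
    return UltrametricTree(root)


def _preorder(root: Node):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(n.children))


def simulate_gene_tree(
    species_tree: UltrametricTree,
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> tuple[UltrametricTree, dict[str, str]]:
    """Neutral coalescent gene tree within the species tree.

    Within every species-tree branch, k gene lineages coalesce at rate
    k(k-1)/2 / coalescent_size; unmerged lineages are passed up to the
    parent population at species-tree nodes and coalescence completes
    above the root.  Tips are labelled ``<species>_<i>``; the returned
    map sends tip label -> species label.
    """
    rng = cfg.rng() if rng is None else rng
    ne = cfg.coalescent_size
    sp_tips = {n.label: n for n in species_tree.leaves()}
    counts = dict(zip(sorted(sp_tips), cfg.tips_per_species))
    labels: dict[str, str] = {}

    def coalesce(lineages: list[Node], t0: float, t1: float) -> list[Node]:
        """Run the coalescent from height t0 up to t1 (inf allowed)."""
        t = t0
        lineages = list(lineages)
        while len(lineages) > 1:
            k = len(lineages)
            t_next = t + rng.exponential(ne / (k * (k - 1) / 2))
            if t_next >= t1:
                return lineages
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[i], lineages[j]
            parent = Node(height=t_next)
            parent.add(a)
            parent.add(b)
            lineages = [
                x for x in lineages if x is not a and x is not b
            ] + [parent]
            t = t_next
        return lineages

    # post-order over the species tree, carrying lineage lists upward
    pending: dict[int, list[Node]] = {}
    order = list(_preorder(species_tree.root))[::-1]
    for sp_node in order:
        if sp_node.is_leaf:
            sp = sp_node.label
            lineages = []
            for i in range(1, counts[sp] + 1):
                tip = Node(height=0.0, label=f"{sp}_{i}")
                labels[tip.label] = sp
                lineages.append(tip)
            start = 0.0
        else:
            lineages = []
            for c in sp_node.children:
                lineages.extend(pending.pop(id(c)))
            start = sp_node.height
        top = (
            sp_node.parent.height if sp_node.parent is not None else np.inf
        )
        pending[id(sp_node)] = coalesce(lineages, start, top)
    (root_lineages,) = (pending[id(species_tree.root)],)
    assert len(root_lineages) == 1
    return UltrametricTree(root_lineages[0]), labels


def simulate_scenario(cfg: ScenarioConfig) -> Fixture:
    """Full generative chain for an arbitrary scenario.

    Yule species tree conditioned on the configured species count, a
    coalescent gene tree within it, and K2P sequences along the gene
    tree; one RNG seeded from ``cfg.seed`` drives all three layers.
    """
    rng = cfg.rng()
    sp_tree = simulate_species_tree(cfg, rng)
    gene_tree, labels = simulate_gene_tree(sp_tree, cfg, rng)
    aln = simulate_sequences(gene_tree, cfg, rng, labels=labels)
    return Fixture(
        alignment=aln, labels=labels, gene_tree=gene_tree,
        species_tree=sp_tree, config=cfg, outgroup=None,
    )


def scenario_from_file(path: str | Path) -> ScenarioConfig:
    """Read a ScenarioConfig from a simple key: value (YAML) file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "tips_per_species" in data and isinstance(data["tips_per_species"], list):
        data["tips_per_species"] = tuple(data["tips_per_species"])
    if "missing_fragment" in data and data["missing_fragment"] is not None:
        tip, keep = data["missing_fragment"]
        data["missing_fragment"] = (str(tip), int(keep))
    return ScenarioConfig(**data)


def simulate_coalescent_tree(
    n_tips: int,
    coalescent_size: float = 1.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> UltrametricTree:
    """Neutral coalescent tree of one panmictic population.

    k lineages merge at rate k(k-1)/2 per ``coalescent_size`` time
    units; the null scenario of the delimitation test.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed) if rng is None else rng
    lineages: list[Node] = [
        Node(0.0, f"t{i}") for i in range(1, n_tips + 1)
    ]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(coalescent_size / (k * (k - 1) / 2))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        parent = Node(height=t)
        parent.add(a)
        parent.add(b)
        lineages = [x for x in lineages if x is not a and x is not b]
        lineages.append(parent)
    return UltrametricTree(lineages[0])


# K2P transition-probability pieces: partner index under transition is
# code ^ 2 with the ordering A=0, C=1, G=2, T=3
_BASES = "ACGT"


def _k2p_probs(t: float, mu: float, kappa: float):
    """(p_same, p_transition, p_each_transversion) after time t."""
    beta = mu / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_tv = 0.25 - 0.25 * e1            # each of the two transversions
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_same = 1.0 - p_ts - 2.0 * p_tv
    return p_same, p_ts, p_tv


def simulate_sequences(
    gene_tree: UltrametricTree,
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
    labels: dict[str, str] | None = None,
) -> Alignment:
    """Evolve sequences along the gene tree under the K2P model.

    The root sequence is uniform over A,C,G,T; each branch applies the
    closed-form K2P transition probabilities for its duration.  A
    configured missing fragment keeps only the first k sites of the
    named tip, replacing the rest with N (the alignment stays
    rectangular).
    """
    rng = cfg.rng() if rng is None else rng
    seqs: dict[str, np.ndarray] = {}
    codes: dict[int, np.ndarray] = {
        id(gene_tree.root): rng.integers(0, 4, size=cfg.sites)
    }
    for n in gene_tree.preorder():
        if n.parent is None:
            continue
        t = n.parent.height - n.height
        p_same, p_ts, p_tv = _k2p_probs(t, cfg.substitution_rate, cfg.kappa)
        parent = codes[id(n.parent)]
        u = rng.random(cfg.sites)
        child = parent.copy()
        ts_partner = parent ^ 2
        # transversion partners: the two states of the opposite class
        tv1 = parent ^ 1
        tv2 = parent ^ 3
        child = np.where(u < p_ts, ts_partner, child)
        child = np.where((u >= p_ts) & (u < p_ts + p_tv), tv1, child)
        child = np.where(
            (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv), tv2, child
        )
        codes[id(n)] = child
        if n.is_leaf:
            seqs[n.label] = child
    records = []
    for tip in gene_tree.tip_labels:
        bases = "".join(_BASES[c] for c in seqs[tip])
        if cfg.missing_fragment and cfg.missing_fragment[0] == tip:
            keep = int(cfg.missing_fragment[1])
            bases = bases[:keep] + "N" * (cfg.sites - keep)
        records.append(
            AlignedSeq(
                id=tip, bases=bases,
                species=None if labels is None else labels.get(tip),
            )
        )
    return Alignment(records)


# ---------------------------------------------------------------------------
# the study-like fixture


#: fixed species-tree node heights of the fixture (time units): the two
#: shallow-split species diverge at 12, the large species joins at 18,
#: the outgroup at 21.  With substitution_rate 0.003 the expected K2P
#: distances are ~0.072 / ~0.108 / ~0.126 between species and below
#: ~0.01 within (coalescent_size 0.5), i.e. a clear barcode gap.
FIXTURE_DEPTHS = {"inner": 12.0, "ingroup": 18.0, "root": 21.0}
FIXTURE_SPECIES = ("ovatus", "anatolicus", "sanctus")
FIXTURE_SIZES = (19, 7, 4)
FIXTURE_OUTGROUP = "aubei"


@dataclass
class Fixture:
    """Simulated study-like data set with its generating truth."""

    alignment: Alignment
    labels: dict[str, str]
    gene_tree: UltrametricTree
    species_tree: UltrametricTree
    config: ScenarioConfig
    outgroup: str | None

    @property
    def ingroup_species(self) -> tuple[str, ...]:
        return FIXTURE_SPECIES

    def truth(self) -> dict:
        ingroup = set(self.labels.values())
        if self.outgroup is not None:
            ingroup.discard(self.outgroup)
        return {
            "n_species": len(ingroup),
            "partition": self.labels,
            "outgroup": self.outgroup,
            "seed": self.config.seed,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "alignment.fasta", "w") as fh:
            for s in self.alignment.seqs:
                fh.write(f">{s.id}\n{s.bases}\n")
        with open(outdir / "labels.tsv", "w") as fh:
            for tip, sp in self.labels.items():
                fh.write(f"{tip}\t{sp}\n")
        (outdir / "truth.json").write_text(
            json.dumps(self.truth(), indent=2) + "\n"
        )
        self.gene_tree.write(outdir / "gene_tree.nwk")


def fixture_species_tree(include_outgroup: bool = True) -> UltrametricTree:
    """The fixed fixture species tree (heights in time units)."""
    d = FIXTURE_DEPTHS
    ov = Node(0.0, "ovatus")
    an = Node(0.0, "anatolicus")
    sa = Node(0.0, "sanctus")
    inner = Node(d["inner"])
    inner.add(an)
    inner.add(sa)
    ing = Node(d["ingroup"])
    ing.add(ov)
    ing.add(inner)
    if not include_outgroup:
        return UltrametricTree(ing)
    root = Node(d["root"])
    root.add(ing)
    root.add(Node(0.0, FIXTURE_OUTGROUP))
    return UltrametricTree(root)


def paper_like_fixture(
    seed: int = 0,
    include_outgroup: bool = True,
    short_fragment: bool = True,
) -> Fixture:
    """Simulated data emulating the study's structure and Table-like ranges.

    Three ingroup species with 19/7/4 tips (plus one outgroup tip when
    ``include_outgroup``), 825 sites, kappa=4, and — when
    ``short_fragment`` — one sanctus tip truncated to its first 147
    sites, mirroring the study's short museum-specimen fragment.
    """
    species = FIXTURE_SPECIES + (
        (FIXTURE_OUTGROUP,) if include_outgroup else ()
    )
    counts = dict(zip(species, FIXTURE_SIZES + ((1,) if include_outgroup else ())))
    # tips_per_species follows the sorted species-label order used by
    # simulate_gene_tree
    cfg = ScenarioConfig(
        n_species=len(species),
        tips_per_species=tuple(counts[s] for s in sorted(counts)),
        coalescent_size=0.5,
        substitution_rate=0.003,
        kappa=4.0,
        sites=825,
        missing_fragment=("sanctus_4", 147) if short_fragment else None,
        seed=seed,
    )
    sp_tree = fixture_species_tree(include_outgroup)
    rng = cfg.rng()
    gene_tree, labels = simulate_gene_tree(sp_tree, cfg, rng)
    aln = simulate_sequences(gene_tree, cfg, rng, labels=labels)
    return Fixture(
        alignment=aln,
        labels=labels,
        gene_tree=gene_tree,
        species_tree=sp_tree,
        config=cfg,
        outgroup=FIXTURE_OUTGROUP if include_outgroup else None,
    )
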