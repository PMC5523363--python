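"""Kimura 2-parameter distances with pairwise deletion.

The K2P model distinguishes transitions (A<->G, C<->T) from transversions.
With P and Q the transition and transversion proportions over the sites
comparable in a pair,

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

substitutions per site.  Distances are computed with pairwise deletion:
only sites where both sequences have an unambiguous base enter P and Q.
Sequences whose overlap with the rest of the alignment falls below a
minimum number of shared sites are dropped from the matrix (short
fragments produce unstable distance estimates), and the drop is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import AlignedSeq, Alignment

#: Default minimum pairwise overlap (sites) for a distance to be computed.
DEFAULT_MIN_OVERLAP = 300

# purine/pyrimidine classes of the A,C,G,T codes (0..3)
_IS_PURINE = np.array([True, False, True, False])


class InsufficientOverlapError(ValueError):
    """Raised when a pair shares fewer comparable sites than required."""


def transition_transversion_counts(
    a: AlignedSeq, b: AlignedSeq
) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) for a pair."""
    ok = (a.codes >= 0) & (b.codes >= 0)
    ca, cb = a.codes[ok], b.codes[ok]
    diff = ca != cb
    same_class = _IS_PURINE[ca] == _IS_PURINE[cb]
    ts = int((diff & same_class).sum())
    tv = int((diff & ~same_class).sum())
    return int(ok.sum()), ts, tv


def k2p_distance(
    a: AlignedSeq, b: AlignedSeq, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> float:
    """K2P distance between two aligned sequences (substitutions/site).

    Returns ``nan`` when the correction is undefined (log of a
    non-positive argument, i.e. saturation).  Raises
    :class:`InsufficientOverlapError` when fewer than ``min_overlap``
    comparable sites remain after pairwise deletion.
    """
    n, ts, tv = transition_transversion_counts(a, b)
    if n < min_overlap:
        raise InsufficientOverlapError(
            f"{a.id} vs {b.id}: {n} comparable sites < min_overlap={min_overlap}"
        )
    p, q = ts / n, tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return d if d > 0.0 else 0.0


@dataclass
class DistanceMatrix:
    """Square symmetric matrix of pairwise distances.

    ``excluded`` lists tips dropped for insufficient overlap; ``d`` may
    contain ``nan`` where the K2P correction was undefined.
    """

    ids: list[str]
    d: np.ndarray
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def get(self, i: str, j: str) -> float:
        return float(self.d[self.ids.index(i), self.ids.index(j)])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f")


def distance_matrix(
    aln: Alignment, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> DistanceMatrix:
    """All-pairs K2P matrix with pairwise deletion.

    A sequence is retained only if it reaches ``min_overlap`` comparable
    sites with *every* other retained sequence; short fragments are
    excluded and reported in ``excluded``.  Raises ``ValueError`` if
    fewer than two sequences survive.
    """
    # a sequence with < min_overlap unambiguous sites can never pass
    retained = [s for s in aln.seqs if s.n_unambiguous >= min_overlap]
    excluded = [s.id for s in aln.seqs if s.n_unambiguous < min_overlap]
    # iterate: drop any sequence still failing against some retained partner
    changed = True
    while changed:
        changed = False
        for s in list(retained):
            for t in retained:
                if t.id == s.id:
                    continue
                ok = int(((s.codes >= 0) & (t.codes >= 0)).sum())
                if ok < min_overlap:
                    retained.remove(s)
                    excluded.append(s.id)
                    changed = True
                    break
            if changed:
                break
    if len(retained) < 2:
        raise ValueError(
            f"fewer than 2 sequences retained at min_overlap={min_overlap}"
        )
    n = len(retained)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_distance(
                retained[i], retained[j], min_overlap=min_overlap
            )
    return DistanceMatrix([s.id for s in retained], d, excluded)


@dataclass
class SpeciesRangeSummary:
    """Per-species-pair (min, max) distance ranges, Table-style.

    ``ranges[(sp_a, sp_b)]`` with ``sp_a == sp_b`` covers within-species
    pairs; the value is ``None`` for singleton species (no within pair).
    """

    species: list[str]
    ranges: dict[tuple[str, str], tuple[float, float] | None]

    def within_max(self) -> float:
        vals = [
            r[1]
            for (a, b), r in self.ranges.items()
            if a == b and r is not None
        ]
        return max(vals) if vals else math.nan

    def between_min(self) -> float:
        vals = [r[0] for (a, b), r in self.ranges.items() if a != b and r]
        return min(vals) if vals else math.nan

    def to_frame(self) -> pd.DataFrame:
        """Lower-triangular 'min-max' table mirroring the usual layout."""
        sp = self.species
        out = pd.DataFrame("/", index=sp, columns=sp)
        for i, a in enumerate(sp):
            for j, b in enumerate(sp):
                if j > i:
                    continue
                r = self.ranges.get((b, a)) or self.ranges.get((a, b))
                out.loc[a, b] = (
                    "-" if r is None else f"{r[0]:.3f}-{r[1]:.3f}"
                )
        return out


def species_range_summary(
    dm: DistanceMatrix, partition: dict[str, str]
) -> SpeciesRangeSummary:
    """Min–max distance per species pair and within each species.

    Every retained tip must be labelled; nan distances are ignored in the
    ranges.  Raises ``ValueError`` on an unlabelled tip.
    """
    missing = [t for t in dm.ids if t not in partition]
    if missing:
        raise ValueError(f"unlabelled tips: {missing}")
    species = sorted({partition[t] for t in dm.ids})
    buckets: dict[tuple[str, str], list[float]] = {}
    for i, ti in enumerate(dm.ids):
        for j in range(i + 1, len(dm.ids)):
            v = dm.d[i, j]
            if math.isnan(v):
                continue
            key = tuple(sorted((partition[ti], partition[dm.ids[j]])))
            buckets.setdefault(key, []).append(float(v))
    ranges: dict[tuple[str, str], tuple[float, float] | None] = {}
    for ia, a in enumerate(species):
        for b in species[ia:]:
            vals = buckets.get((a, b))
            ranges[(a, b)] = (min(vals), max(vals)) if vals else None
    return SpeciesRangeSummary(species, ranges)
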