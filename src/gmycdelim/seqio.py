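"""Aligned-sequence I/O and missing-data bookkeeping.

Alignments are equal-length DNA sequences over {A,C,G,T}, IUPAC ambiguity
codes, N, '-' and '?'.  For distance computation every symbol other than an
unambiguous A/C/G/T is treated uniformly as missing data, and pairwise
statistics are computed with pairwise deletion: each pair of sequences is
compared only over the sites where *both* carry an unambiguous base.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

#: Unambiguous nucleotide states.
CANONICAL = "ACGT"

#: Everything a well-formed record may contain.
_ALLOWED = set("ACGTRYSWKMBDHVN-?")

# byte codes for fast vector comparisons
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(CANONICAL):
    _CODE[ord(_b)] = _i


@dataclass
class AlignedSeq:
    """One aligned sequence: specimen id, optional species label, bases."""

    id: str
    bases: str
    species: str | None = None
    codes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        bad = set(self.bases) - _ALLOWED
        if bad:
            raise ValueError(f"{self.id}: invalid symbols {sorted(bad)!r}")
        self.codes = _CODE[np.frombuffer(self.bases.encode(), dtype=np.uint8)]

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def n_unambiguous(self) -> int:
        """Number of sites with an unambiguous A/C/G/T call."""
        return int((self.codes >= 0).sum())


@dataclass
class Alignment:
    """Equal-length collection of :class:`AlignedSeq`."""

    seqs: list[AlignedSeq]

    def __post_init__(self) -> None:
        if not self.seqs:
            raise ValueError("alignment is empty")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        ids = [s.id for s in self.seqs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dup}")
        if len(self.seqs[0]) == 0:
            raise ValueError("alignment length is zero")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.seqs]

    def __len__(self) -> int:
        return len(self.seqs)

    def __getitem__(self, key: int | str) -> AlignedSeq:
        if isinstance(key, str):
            for s in self.seqs:
                if s.id == key:
                    return s
            raise KeyError(key)
        return self.seqs[key]

    def species_partition(self) -> dict[str, str]:
        """tip id -> species label, for the labelled subset."""
        return {s.id: s.species for s in self.seqs if s.species is not None}


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column tab-separated tip->species table."""
    labels: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"label row needs two columns: {row!r}")
            labels[row[0].strip()] = row[1].strip()
    return labels


def read_alignment(
    path: str | Path, labels: dict[str, str] | str | Path | None = None
) -> Alignment:
    """Read an aligned FASTA file, attaching species labels where given.

    Raises ``ValueError`` on unequal lengths or duplicate ids.
    """
    if labels is not None and not isinstance(labels, dict):
        labels = read_labels(labels)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seqs = [
        AlignedSeq(
            id=r.id,
            bases=str(r.seq),
            species=(labels or {}).get(r.id),
        )
        for r in records
    ]
    return Alignment(seqs)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in aln.seqs:
            fh.write(f">{s.id}\n{s.bases}\n")


def comparable_sites(a: AlignedSeq, b: AlignedSeq) -> int:
    """Count sites where both sequences carry an unambiguous A/C/G/T base.

    Symmetric; equals the alignment length when both sequences are fully
    unambiguous.
    """
    return int(((a.codes >= 0) & (b.codes >= 0)).sum())
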