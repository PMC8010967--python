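"""Peptide-fragment assembly for lysine-modification datasets.

A *fragment* is a lysine-centered window of ``2*xi + 1`` residues (default
``xi = 8``, window length 17) cut from a protein sequence around an annotated
modification site. This module reads FASTA sequences plus a site-annotation
table, extracts windows, removes redundant (homologous) windows, merges
annotations from multiple sources, and assembles the final single-label
multi-class dataset.

Site coordinates are 1-based in all interfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .aadata import AMINO_ACIDS

logger = logging.getLogger(__name__)

_CANONICAL = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class Fragment:
    """A lysine-centered peptide window with provenance.

    Parameters
    ----------
    protein_id : str
        Identifier of the source protein.
    site : int
        1-based index of the central lysine in the source protein.
    sequence : str
        The window itself; odd length, canonical residues only, central ``K``.
    labels : frozenset of str
        Modification-type names annotated at this site (non-empty).
    """

    protein_id: str
    site: int
    sequence: str
    labels: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if len(self.sequence) % 2 != 1:
            raise ValueError(f"fragment length must be odd, got {len(self.sequence)}")
        mid = len(self.sequence) // 2
        if self.sequence[mid] != "K":
            raise ValueError(
                f"central residue must be K, got {self.sequence[mid]!r} "
                f"({self.protein_id}:{self.site})"
            )
        if not self.labels:
            raise ValueError("fragment must carry at least one label")
        object.__setattr__(self, "labels", frozenset(self.labels))


@dataclass(frozen=True)
class ClassSet:
    """Ordered (lexicographic) modification classes with sample counts."""

    names: tuple
    counts: tuple

    def __post_init__(self):
        if tuple(sorted(self.names)) != tuple(self.names):
            raise ValueError("class names must be in lexicographic order")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        """1-based class index of ``name``."""
        return self.names.index(name) + 1


@dataclass
class Dataset:
    """Single-label fragment collection ready for encoding.

    ``y[i]`` is the 1-based class index of ``fragments[i]`` in ``class_set``.
    """

    fragments: list
    class_set: ClassSet
    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        if len(self.fragments) != len(self.y):
            raise ValueError("label vector length mismatch")
        if len(self.y) and not (self.y.min() >= 1 and self.y.max() <= self.class_set.n_classes):
            raise ValueError("class indices out of range")

    def __len__(self) -> int:
        return len(self.fragments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": [f.protein_id for f in self.fragments],
                "position": [f.site for f in self.fragments],
                "sequence": [f.sequence for f in self.fragments],
                "class_index": self.y,
                "class_name": [self.class_set.names[i - 1] for i in self.y],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Dataset":
        df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
        names = tuple(sorted(df["class_name"].unique()))
        counts = tuple(int((df["class_name"] == n).sum()) for n in names)
        class_set = ClassSet(names, counts)
        frags = [
            Fragment(r.protein_id, int(r.position), r.sequence, frozenset([r.class_name]))
            for r in df.itertuples()
        ]
        y = np.array([class_set.index_of(n) for n in df["class_name"]], dtype=int)
        return cls(frags, class_set, y)


def read_fasta(path) -> dict:
    """Read a (possibly line-wrapped, multi-record) FASTA into ``{id: sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_sites_tsv(path) -> pd.DataFrame:
    """Read a site-annotation table with columns protein_id, position, modification."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position", "modification"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    return df


def extract_fragments(
    proteins: Mapping[str, str],
    sites: pd.DataFrame,
    xi: int = 8,
) -> list:
    """Cut a ``2*xi + 1`` window around every annotated lysine.

    Records are rejected (with a logged warning) when the protein ID is
    unknown, the annotated residue is not ``K``, either flank is shorter than
    ``xi`` (no padding), or the window contains a non-canonical letter.
    """
    if xi < 1:
        raise ValueError("xi must be >= 1")
    out = []
    for rec in sites.itertuples():
        pid, pos, mod = str(rec.protein_id), int(rec.position), str(rec.modification)
        seq = proteins.get(pid)
        if seq is None:
            logger.warning("unknown protein ID %s; record rejected", pid)
            continue
        if pos < 1 or pos > len(seq) or seq[pos - 1] != "K":
            logger.warning("site %s:%d is not a lysine; record rejected", pid, pos)
            continue
        if pos - xi < 1 or pos + xi > len(seq):
            continue  # flank shorter than xi: dropped, no padding
        window = seq[pos - xi - 1 : pos + xi]
        if not _CANONICAL.issuperset(window):
            logger.warning(
                "non-canonical residue in window %s:%d; fragment dropped", pid, pos
            )
            continue
        out.append(Fragment(pid, pos, window, frozenset([mod])))
    return out


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of positions at which two equal-length sequences agree."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def remove_redundant(fragments: Sequence[Fragment], threshold: float = 0.40) -> list:
    """Greedy keep-first redundancy reduction.

    Scanning in input order, a fragment is dropped iff its identity to any
    already-retained fragment is ``>= threshold``. Input order is file order,
    so runs are reproducible.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if not fragments:
        return []
    L = len(fragments[0].sequence)
    kept: list = []
    kept_arr = np.empty((0, L), dtype="S1")
    for frag in fragments:
        row = np.frombuffer(frag.sequence.encode(), dtype="S1")
        if kept_arr.shape[0]:
            ident = (kept_arr == row).mean(axis=1)
            if (ident >= threshold).any():
                continue
        kept.append(frag)
        kept_arr = np.vstack([kept_arr, row])
    return kept


def merge_labels(fragments: Iterable[Fragment]) -> list:
    """Collapse records sharing (protein_id, site, sequence); union label sets."""
    merged: dict = {}
    order: list = []
    for frag in fragments:
        key = (frag.protein_id, frag.site, frag.sequence)
        if key in merged:
            merged[key] = merged[key] | frag.labels
        else:
            merged[key] = frag.labels
            order.append(key)
    return [Fragment(pid, site, seq, merged[(pid, site, seq)]) for pid, site, seq in order]


def filter_classes(
    fragments: Sequence[Fragment],
    min_count: int = 500,
    single_label_only: bool = True,
) -> Dataset:
    """Keep single-label records of classes with at least ``min_count`` records.

    Multi-label records are excluded first (when ``single_label_only``); class
    sizes are then counted over the remaining records and undersized classes
    deleted. Class order in the result is lexicographic.
    """
    if single_label_only:
        candidates = [f for f in fragments if len(f.labels) == 1]
    else:
        candidates = list(fragments)
    tallies: dict = {}
    for f in candidates:
        lab = next(iter(f.labels))
        tallies[lab] = tallies.get(lab, 0) + 1
    surviving = sorted(name for name, n in tallies.items() if n >= min_count)
    if not surviving:
        raise ValueError("no modification class reaches the minimum count")
    kept = [f for f in candidates if next(iter(f.labels)) in surviving]
    counts = tuple(tallies[name] for name in surviving)
    class_set = ClassSet(tuple(surviving), counts)
    y = np.array([class_set.index_of(next(iter(f.labels))) for f in kept], dtype=int)
    return Dataset(kept, class_set, y)
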