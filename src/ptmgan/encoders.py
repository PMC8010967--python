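"""Feature encoding: eight sequence schemes plus a structural block.

Each 17-residue fragment is turned into a fixed-length numeric vector by
concatenating, in order:

========================  ==========================  ======
scheme                    content                     dims
========================  ==========================  ======
AAindex                   14 z-scored properties/res  238
CKSAAP                    k-spaced pair frequencies,
                          k in {0, 1, 2}              1200
PWM                       positional residue freq.    17
ReducedAlphabet           8-group one-hot/residue     136
FoldAmyloid               windowed packing density    17
BE                        20-way one-hot/residue      340
PC-PseAAC                 parallel-correlation PseAAC 36
SC-PseAAC                 series-correlation PseAAC   52
Structure                 19 channels/residue         323
========================  ==========================  ======

Total: 2359 (2036 without the structural block). Every column carries
provenance ``(scheme, tag)`` with a human-readable tag such as the pair
``"Y**A"``, the window offset ``"+4"``, or the channel ``"Q3-H@-2"``.

The PWM is the only scheme with fitted state; it must be fitted on training
fragments only. :class:`FeatureEncoder` bundles fitting and transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .aadata import (
    AMINO_ACIDS,
    DEFAULT_AAINDEX_PROPERTIES,
    FOLDAMYLOID_CUTOFF,
    FOLDAMYLOID_PACKING,
    PSEAAC_PC_PROPERTIES,
    PSEAAC_SC_PROPERTIES,
    REDUCED_ALPHABET_GROUPS,
)

L_DEFAULT = 17
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Fixed concatenation order of the nine schemes.
SCHEME_ORDER = (
    "AAindex",
    "CKSAAP",
    "PWM",
    "ReducedAlphabet",
    "FoldAmyloid",
    "BE",
    "PC-PseAAC",
    "SC-PseAAC",
    "Structure",
)

#: Column order of the 19 per-residue structural channels.
STRUCTURE_CHANNELS = (
    "ASA",
    "Q3-H", "Q3-E", "Q3-C",
    "Q8-G", "Q8-H", "Q8-I", "Q8-B", "Q8-E", "Q8-T", "Q8-S", "Q8-C",
    "phi", "psi", "theta", "tau",
    "HSEa-up", "HSEa-down",
    "CN",
)


@dataclass
class FeatureBlock:
    """One scheme's slice of the feature vector, with per-column tags."""

    scheme: str
    values: np.ndarray
    tags: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.tags):
            raise ValueError("values/tags length mismatch")


@dataclass
class PWMatrix:
    """20 x L positional residue-frequency table fitted on training fragments."""

    freqs: np.ndarray  # (20, L)
    n_fitted: int

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape[0] != 20:
            raise ValueError("PWM must have 20 residue rows")
        colsums = self.freqs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("PWM position columns must sum to 1")


def make_property_table(properties: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Assemble a z-scored residue-by-property table.

    Each property map must cover exactly the 20 canonical residues; values are
    standardized across the 20 residues (population sigma).
    """
    cols = {}
    for name, mapping in properties.items():
        if set(mapping) != set(AMINO_ACIDS):
            raise ValueError(f"property {name!r} does not cover the canonical residues")
        v = np.array([mapping[aa] for aa in AMINO_ACIDS], dtype=float)
        sd = v.std()
        if sd == 0:
            raise ValueError(f"property {name!r} is constant")
        cols[name] = (v - v.mean()) / sd
    return pd.DataFrame(cols, index=list(AMINO_ACIDS))


DEFAULT_PROPERTY_TABLE = make_property_table(DEFAULT_AAINDEX_PROPERTIES)


def _check_fragment(seq: str, L: int = L_DEFAULT) -> None:
    if len(seq) != L:
        raise ValueError(f"expected fragment of length {L}, got {len(seq)}")
    unknown = set(seq) - set(AMINO_ACIDS)
    if unknown:
        raise ValueError(f"unknown residues {sorted(unknown)} in fragment")


def _offset_tag(p: int, L: int) -> str:
    """Window offset of 1-based position p relative to the central residue."""
    off = p - (L // 2 + 1)
    return f"{off:+d}" if off else "0"


def encode_aaindex(
    seq: str, property_table: pd.DataFrame = DEFAULT_PROPERTY_TABLE
) -> FeatureBlock:
    """Per-residue physicochemical profile: 14 z-scored scales, position-major."""
    _check_fragment(seq)
    if property_table.shape[1] != 14:
        raise ValueError("AAindex encoding expects exactly 14 properties")
    vals = property_table.loc[list(seq)].to_numpy().ravel()
    tags = [
        f"{prop}@{_offset_tag(p + 1, len(seq))}"
        for p in range(len(seq))
        for prop in property_table.columns
    ]
    return FeatureBlock("AAindex", vals, tags)


def encode_cksaap(seq: str, k_set: Sequence[int] = (0, 1, 2)) -> FeatureBlock:
    """Composition of k-spaced amino-acid pairs.

    For each gap ``k`` the ordered pair ``(seq[i], seq[i+k+1])`` is counted over
    all ``L - 1 - k`` positions and normalized by that count, so each 400-long
    k-block is a frequency distribution summing to 1. Pair index is
    alphabetical, blocks are k-major.
    """
    L = len(seq)
    vals = np.zeros(400 * len(k_set))
    tags: list = []
    for ki, k in enumerate(k_set):
        if k >= L - 1:
            raise ValueError(f"gap k={k} too large for fragment of length {L}")
        n_pairs = L - 1 - k
        block = np.zeros(400)
        for i in range(n_pairs):
            a, b = seq[i], seq[i + k + 1]
            block[_AA_INDEX[a] * 20 + _AA_INDEX[b]] += 1
        vals[ki * 400 : (ki + 1) * 400] = block / n_pairs
        gap = "*" * k
        tags.extend(f"{a}{gap}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS)
    return FeatureBlock("CKSAAP", vals, tags)


def fit_pwm(fragments: Sequence, L: int = L_DEFAULT) -> PWMatrix:
    """Positional residue frequencies pooled over training fragments.

    ``freqs[a, p]`` is the fraction of training fragments carrying residue
    ``a`` at window position ``p`` (no pseudocount).
    """
    seqs = [f.sequence if hasattr(f, "sequence") else f for f in fragments]
    if not seqs:
        raise ValueError("cannot fit a PWM on an empty training set")
    counts = np.zeros((20, L))
    for s in seqs:
        _check_fragment(s, L)
        for p, aa in enumerate(s):
            counts[_AA_INDEX[aa], p] += 1
    return PWMatrix(counts / len(seqs), n_fitted=len(seqs))


def encode_pwm(seq: str, pwm: PWMatrix) -> FeatureBlock:
    """Per-position training frequency of the fragment's own residues."""
    L = pwm.freqs.shape[1]
    _check_fragment(seq, L)
    vals = np.array([pwm.freqs[_AA_INDEX[aa], p] for p, aa in enumerate(seq)])
    tags = [_offset_tag(p + 1, L) for p in range(L)]
    return FeatureBlock("PWM", vals, tags)


_REDUCED_MAP = {
    aa: gi
    for gi, (_, members) in enumerate(REDUCED_ALPHABET_GROUPS.items())
    for aa in members
}
_REDUCED_NAMES = tuple(REDUCED_ALPHABET_GROUPS)


def encode_reduced_alphabet(seq: str) -> FeatureBlock:
    """Residue one-hot over the eight physicochemical groups, position-major."""
    _check_fragment(seq)
    L = len(seq)
    vals = np.zeros(8 * L)
    tags = [
        f"{g}@{_offset_tag(p + 1, L)}" for p in range(L) for g in _REDUCED_NAMES
    ]
    for p, aa in enumerate(seq):
        vals[p * 8 + _REDUCED_MAP[aa]] = 1.0
    return FeatureBlock("ReducedAlphabet", vals, tags)


def encode_foldamyloid(
    seq: str,
    scale: Mapping[str, float] = FOLDAMYLOID_PACKING,
    window: int = 5,
    cutoff: float = FOLDAMYLOID_CUTOFF,
    binary: bool = False,
) -> FeatureBlock:
    """Amyloidogenicity profile from expected residue packing density.

    Per-residue score is the mean of the packing scale over a centered window
    (truncated at the fragment ends). In binary mode positions whose score
    reaches ``cutoff`` are flagged 1 (amyloid-prone) and others 0.
    """
    _check_fragment(seq)
    L = len(seq)
    raw = np.array([scale[aa] for aa in seq])
    half = window // 2
    smoothed = np.array(
        [raw[max(0, i - half) : min(L, i + half + 1)].mean() for i in range(L)]
    )
    vals = (smoothed >= cutoff).astype(float) if binary else smoothed
    tags = [_offset_tag(p + 1, L) for p in range(L)]
    return FeatureBlock("FoldAmyloid", vals, tags)


def encode_binary(seq: str) -> FeatureBlock:
    """Plain 20-way one-hot (binary encoding, BE), position-major."""
    _check_fragment(seq)
    L = len(seq)
    vals = np.zeros(20 * L)
    tags = [f"{aa}@{_offset_tag(p + 1, L)}" for p in range(L) for aa in AMINO_ACIDS]
    for p, aa in enumerate(seq):
        vals[p * 20 + _AA_INDEX[aa]] = 1.0
    return FeatureBlock("BE", vals, tags)


def _pseaac_shared(seq: str, lam: int) -> np.ndarray:
    L = len(seq)
    _check_fragment(seq)
    if lam >= L:
        raise ValueError("lambda must be smaller than the fragment length")
    counts = np.zeros(20)
    for aa in seq:
        counts[_AA_INDEX[aa]] += 1
    return counts / L


def encode_pc_pseaac(
    seq: str,
    lam: int = 16,
    w: float = 0.05,
    property_table: pd.DataFrame = DEFAULT_PROPERTY_TABLE,
    properties: Sequence[str] = PSEAAC_PC_PROPERTIES,
) -> FeatureBlock:
    """Parallel-correlation pseudo amino-acid composition (20 + lambda dims).

    The order-correlation factor for lag ``k`` averages, over all residue pairs
    ``(i, i+k)``, the mean squared property difference across the pooled
    property set; composition and correlation components are jointly normalized
    so the vector sums to 1.
    """
    freqs = _pseaac_shared(seq, lam)
    H = property_table.loc[list(seq), list(properties)].to_numpy()  # (L, n_props)
    L = len(seq)
    theta = np.empty(lam)
    for k in range(1, lam + 1):
        diffs = H[k:] - H[:-k]
        theta[k - 1] = np.mean(diffs**2)
    denom = freqs.sum() + w * theta.sum()
    vals = np.concatenate([freqs / denom, w * theta / denom])
    tags = [f"comp-{aa}" for aa in AMINO_ACIDS] + [
        f"theta-{k}" for k in range(1, lam + 1)
    ]
    return FeatureBlock("PC-PseAAC", vals, tags)


def encode_sc_pseaac(
    seq: str,
    lam: int = 16,
    w: float = 0.05,
    property_table: pd.DataFrame = DEFAULT_PROPERTY_TABLE,
    properties: Sequence[str] = PSEAAC_SC_PROPERTIES,
) -> FeatureBlock:
    """Series-correlation pseudo amino-acid composition (20 + 2*lambda dims).

    One correlation factor per (lag, property) pair: the mean over ``i`` of
    ``H_g(R_i) * H_g(R_{i+k})``; interleaved lag-major as
    ``tau_1 = (k=1, g=1), tau_2 = (k=1, g=2), tau_3 = (k=2, g=1), ...``.
    """
    freqs = _pseaac_shared(seq, lam)
    H = property_table.loc[list(seq), list(properties)].to_numpy()
    n_props = len(properties)
    tau = np.empty(lam * n_props)
    for k in range(1, lam + 1):
        prods = H[:-k] * H[k:]  # (L-k, n_props)
        tau[(k - 1) * n_props : k * n_props] = prods.mean(axis=0)
    denom = freqs.sum() + w * tau.sum()
    vals = np.concatenate([freqs / denom, w * tau / denom])
    tags = [f"comp-{aa}" for aa in AMINO_ACIDS] + [
        f"tau-{k}-{g}" for k in range(1, lam + 1) for g in properties
    ]
    return FeatureBlock("SC-PseAAC", vals, tags)


class StructureTable:
    """Per-residue structural descriptors keyed by (protein_id, position).

    Wraps a table with columns ``protein_id``, ``position`` and the 19
    channels in :data:`STRUCTURE_CHANNELS` (solvent accessibility, 3- and
    8-state secondary-structure probabilities, backbone angles, half-sphere
    exposures, contact number) as produced by a per-residue structure
    predictor.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = set(("protein_id", "position") + STRUCTURE_CHANNELS) - set(frame.columns)
        if missing:
            raise ValueError(f"structure table missing columns: {sorted(missing)}")
        self._frame = frame
        self._lookup = {
            (str(pid), int(pos)): i
            for i, (pid, pos) in enumerate(zip(frame["protein_id"], frame["position"]))
        }
        self._values = frame[list(STRUCTURE_CHANNELS)].to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, path) -> "StructureTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"protein_id": str}))

    def to_tsv(self, path) -> None:
        self._frame.to_csv(path, sep="\t", index=False)

    def row(self, protein_id: str, position: int) -> np.ndarray:
        try:
            return self._values[self._lookup[(str(protein_id), int(position))]]
        except KeyError:
            raise KeyError(
                f"no structural row for protein {protein_id!r} position {position}"
            ) from None


def encode_structure(fragment, structure: StructureTable) -> FeatureBlock:
    """Concatenate the 19 structural channels of each window residue."""
    seq = fragment.sequence
    L = len(seq)
    xi = L // 2
    rows = []
    for off in range(-xi, xi + 1):
        rows.append(structure.row(fragment.protein_id, fragment.site + off))
    vals = np.concatenate(rows)
    tags = [
        f"{ch}@{_offset_tag(p + 1, L)}" for p in range(L) for ch in STRUCTURE_CHANNELS
    ]
    return FeatureBlock("Structure", vals, tags)


@dataclass
class FeatureMatrix:
    """Samples-by-features table with per-column scheme provenance."""

    X: np.ndarray
    provenance: pd.DataFrame  # columns: scheme, tag

    def __post_init__(self):
        if self.X.shape[1] != len(self.provenance):
            raise ValueError("provenance does not cover the feature columns")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.X[:, idx], self.provenance.iloc[idx].reset_index(drop=True))


@dataclass
class FeatureEncoder:
    """Fitted encoding context mapping fragments to feature vectors.

    Only the PWM has fitted state; :meth:`fit` must see training fragments
    only. Scheme toggles drop whole blocks (e.g. ``structure=None`` omits the
    structural block, giving 2036 dims).
    """

    schemes: tuple = SCHEME_ORDER
    structure: Optional[StructureTable] = None
    property_table: pd.DataFrame = field(default_factory=lambda: DEFAULT_PROPERTY_TABLE)
    foldamyloid_binary: bool = False
    pwm_: Optional[PWMatrix] = None

    def __post_init__(self):
        unknown = set(self.schemes) - set(SCHEME_ORDER)
        if unknown:
            raise ValueError(f"unknown schemes: {sorted(unknown)}")
        # concatenation order is fixed regardless of the order given
        self.schemes = tuple(s for s in SCHEME_ORDER if s in self.schemes)
        if "Structure" in self.schemes and self.structure is None:
            self.schemes = tuple(s for s in self.schemes if s != "Structure")

    def fit(self, fragments: Sequence) -> "FeatureEncoder":
        if "PWM" in self.schemes:
            self.pwm_ = fit_pwm(fragments)
        return self

    def encode_one(self, fragment) -> list:
        """Encode a single fragment to an ordered list of FeatureBlocks."""
        seq = fragment.sequence if hasattr(fragment, "sequence") else fragment
        blocks = []
        for scheme in self.schemes:
            if scheme == "AAindex":
                blocks.append(encode_aaindex(seq, self.property_table))
            elif scheme == "CKSAAP":
                blocks.append(encode_cksaap(seq))
            elif scheme == "PWM":
                if self.pwm_ is None:
                    raise RuntimeError("PWM scheme requested but encoder is not fitted")
                blocks.append(encode_pwm(seq, self.pwm_))
            elif scheme == "ReducedAlphabet":
                blocks.append(encode_reduced_alphabet(seq))
            elif scheme == "FoldAmyloid":
                blocks.append(
                    encode_foldamyloid(seq, binary=self.foldamyloid_binary)
                )
            elif scheme == "BE":
                blocks.append(encode_binary(seq))
            elif scheme == "PC-PseAAC":
                blocks.append(encode_pc_pseaac(seq, property_table=self.property_table))
            elif scheme == "SC-PseAAC":
                blocks.append(encode_sc_pseaac(seq, property_table=self.property_table))
            elif scheme == "Structure":
                blocks.append(encode_structure(fragment, self.structure))
        return blocks

    def transform(self, fragments: Sequence) -> FeatureMatrix:
        rows = []
        prov = None
        for frag in fragments:
            blocks = self.encode_one(frag)
            rows.append(np.concatenate([b.values for b in blocks]))
            if prov is None:
                prov = pd.DataFrame(
                    {
                        "scheme": np.concatenate(
                            [[b.scheme] * len(b.tags) for b in blocks]
                        ),
                        "tag": np.concatenate([b.tags for b in blocks]),
                    }
                )
        if prov is None:
            raise ValueError("no fragments to encode")
        return FeatureMatrix(np.vstack(rows), prov)

    def fit_transform(self, fragments: Sequence) -> FeatureMatrix:
        return self.fit(fragments).transform(fragments)


def encode_all(fragment, pwm: PWMatrix, structure: Optional[StructureTable] = None):
    """One-shot full encoding of a fragment; returns (vector, provenance)."""
    enc = FeatureEncoder(structure=structure, pwm_=pwm)
    blocks = enc.encode_one(fragment)
    vec = np.concatenate([b.values for b in blocks])
    prov = pd.DataFrame(
        {
            "scheme": np.concatenate([[b.scheme] * len(b.tags) for b in blocks]),
            "tag": np.concatenate([b.tags for b in blocks]),
        }
    )
    return vec, prov
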