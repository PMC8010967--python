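"""Seeded synthetic inputs emulating a CPLM-style modification-site corpus.

Every stage of the pipeline is testable without downloads: the generator
writes the exact file dialects the package consumes (multi-record FASTA, a
protein/position/modification site table, and a 19-channel per-residue
structure table).

Each synthetic protein embeds one annotated central lysine. Flank residues
are drawn from a class-specific position-specific distribution that
interpolates — by ``motif_strength`` — between the uniform residue
distribution and a degenerate distribution on the class's preferred residue
at the informative window offsets (defaults -4, -1, +2, +4, +7). Structural
channels are drawn from class-shifted Gaussians (secondary-structure
probability groups via softmax of Gaussian logits, so each group sums to 1),
with the shift scaled by ``struct_effect``. Everything is reproducible from
the seed; identical seeds give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aadata import AMINO_ACIDS
from .encoders import STRUCTURE_CHANNELS, StructureTable
from .fragments import Dataset, extract_fragments, filter_classes, merge_labels

#: The seven post-filter class counts of the CPLM-derived lysine-modification
#: corpus (alphabetical: Ace, Glyca, Malon, Meth, Succ, Sumo, Ubiq).
CPLM_CLASS_COUNTS = {
    "Ace": 3114,
    "Glyca": 1399,
    "Malon": 1224,
    "Meth": 1147,
    "Succ": 1645,
    "Sumo": 1174,
    "Ubiq": 3185,
}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic corpus."""

    class_counts: dict
    motif_strength: float = 0.5
    struct_effect: float = 1.0
    noise: float = 1.0
    xi: int = 8
    informative_offsets: tuple = (-4, -1, 2, 4, 7)
    seed: int = 0

    def __post_init__(self):
        if any(c < 1 for c in self.class_counts.values()):
            raise ValueError("class counts must be >= 1")
        if not 0.0 <= self.motif_strength <= 1.0:
            raise ValueError("motif strength must lie in [0, 1]")
        if any(abs(o) > self.xi or o == 0 for o in self.informative_offsets):
            raise ValueError("informative offsets must be non-zero and within the window")


@dataclass
class Fixture:
    """In-memory synthetic corpus; ``write`` emits the on-disk dialects."""

    spec: FixtureSpec
    proteins: dict
    sites: pd.DataFrame
    structure: pd.DataFrame

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteins.fasta",
            "sites": outdir / "sites.tsv",
            "structure": outdir / "structure.tsv",
        }
        with open(paths["fasta"], "w") as fh:
            for pid, seq in self.proteins.items():
                fh.write(f">{pid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        self.sites.to_csv(paths["sites"], sep="\t", index=False)
        self.structure.to_csv(
            paths["structure"], sep="\t", index=False, float_format="%.5f"
        )
        return paths

    def structure_table(self) -> StructureTable:
        return StructureTable(self.structure)


def _preferred_residue(class_idx: int, offset: int) -> str:
    """Deterministic class/position preferred residue (never the central K)."""
    alphabet = AMINO_ACIDS.replace("K", "")
    return alphabet[(7 * class_idx + 3 * abs(offset) + (offset > 0)) % len(alphabet)]


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Draw a full synthetic corpus from a spec (deterministic in the seed)."""
    rng = np.random.default_rng(spec.seed)
    names = sorted(spec.class_counts)
    aas = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    xi = spec.xi
    margin = 3  # spare residues beyond the window on each side
    plen = 2 * (xi + margin) + 1
    site = xi + margin + 1  # 1-based central lysine

    proteins: dict = {}
    site_rows = []
    struct_rows = []
    n_ch = len(STRUCTURE_CHANNELS)
    for ci, name in enumerate(names):
        # class-specific Gaussian mean shift per structural channel
        shift = spec.struct_effect * np.sin(0.7 * (ci + 1) * np.arange(1, n_ch + 1))
        for s in range(spec.class_counts[name]):
            pid = f"SYN_{name}_{s:05d}"
            residues = aas[rng.integers(0, 20, size=plen)]
            residues[site - 1] = "K"
            for off in spec.informative_offsets:
                if rng.random() < spec.motif_strength:
                    residues[site - 1 + off] = _preferred_residue(ci, off)
            seq = "".join(residues)
            proteins[pid] = seq
            site_rows.append((pid, site, name))
            base = rng.standard_normal((plen, n_ch)) * spec.noise + shift
            block = np.empty((plen, n_ch))
            block[:, 0] = 0.5 + 0.15 * base[:, 0]  # ASA
            q3 = np.exp(base[:, 1:4])
            block[:, 1:4] = q3 / q3.sum(axis=1, keepdims=True)
            q8 = np.exp(base[:, 4:12])
            block[:, 4:12] = q8 / q8.sum(axis=1, keepdims=True)
            block[:, 12:16] = 30.0 * base[:, 12:16]  # phi, psi, theta, tau (degrees)
            block[:, 16:18] = 20.0 + 3.0 * base[:, 16:18]  # HSEa up/down
            block[:, 18] = 30.0 + 4.0 * base[:, 18]  # contact number
            for pos in range(plen):
                struct_rows.append((pid, pos + 1, *block[pos]))

    sites = pd.DataFrame(site_rows, columns=["protein_id", "position", "modification"])
    structure = pd.DataFrame(
        struct_rows, columns=["protein_id", "position", *STRUCTURE_CHANNELS]
    )
    return Fixture(spec, proteins, sites, structure)


def fixture_dataset(spec: FixtureSpec) -> tuple:
    """Generate a fixture and run it through fragment assembly.

    Returns ``(dataset, structure_table)`` ready for encoding; every planted
    site survives extraction because proteins carry full flanks.
    """
    fx = generate_fixture(spec)
    frags = extract_fragments(fx.proteins, fx.sites, xi=spec.xi)
    frags = merge_labels(frags)
    ds = filter_classes(frags, min_count=1)
    return ds, fx.structure_table()


def cplm_counts_fixture(seed: int = 0, **overrides) -> FixtureSpec:
    """Spec with exactly the seven published post-filter class counts."""
    return FixtureSpec(class_counts=dict(CPLM_CLASS_COUNTS), seed=seed, **overrides)
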