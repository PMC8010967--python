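"""Packaged amino-acid property scales.

All tables cover exactly the 20 canonical residues (one-letter codes, alphabetical
order ``ACDEFGHIKLMNPQRSTVWY``). The encoder layer z-scores scales across the 20
residues before use, so only the relative ordering of each scale matters downstream.
The default AAindex-style selection below is configurable: any mapping of
``{name: {aa: value}}`` with full canonical coverage can be passed to
:func:`ptmgan.encoders.make_property_table`.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Kyte & Doolittle hydropathy
HYDROPHOBICITY = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4, "H": -3.2,
    "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5,
    "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

# Hopp & Woods hydrophilicity
HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0, "H": -0.5,
    "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2,
    "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}

# Side-chain mass (Da), the scale conventionally used in pseudo amino-acid composition
SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0, "H": 82.0,
    "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0,
    "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}

# Isoelectric point of the free amino acid
ISOELECTRIC_POINT = {
    "A": 6.00, "C": 5.07, "D": 2.77, "E": 3.22, "F": 5.48, "G": 5.97, "H": 7.59,
    "I": 6.02, "K": 9.74, "L": 5.98, "M": 5.74, "N": 5.41, "P": 6.30, "Q": 5.65,
    "R": 10.76, "S": 5.68, "T": 5.60, "V": 5.96, "W": 5.89, "Y": 5.66,
}

# Zamyatnin residue volume (A^3)
SIDE_CHAIN_VOLUME = {
    "A": 88.6, "C": 108.5, "D": 111.1, "E": 138.4, "F": 189.9, "G": 60.1,
    "H": 153.2, "I": 166.7, "K": 168.6, "L": 166.7, "M": 162.9, "N": 114.1,
    "P": 112.7, "Q": 143.8, "R": 173.4, "S": 89.0, "T": 116.1, "V": 140.0,
    "W": 227.8, "Y": 193.6,
}

# Grantham polarity
POLARITY = {
    "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2, "G": 9.0, "H": 10.4,
    "I": 5.2, "K": 11.3, "L": 4.9, "M": 5.7, "N": 11.6, "P": 8.0, "Q": 10.5,
    "R": 10.5, "S": 9.2, "T": 8.6, "V": 5.9, "W": 5.4, "Y": 6.2,
}

# Charton & Charton polarizability
POLARIZABILITY = {
    "A": 0.046, "C": 0.128, "D": 0.105, "E": 0.151, "F": 0.290, "G": 0.000,
    "H": 0.230, "I": 0.186, "K": 0.219, "L": 0.186, "M": 0.221, "N": 0.134,
    "P": 0.131, "Q": 0.180, "R": 0.291, "S": 0.062, "T": 0.108, "V": 0.140,
    "W": 0.409, "Y": 0.298,
}

# Theoretical maximum accessible surface area (A^2), Tien et al.
MAX_ASA = {
    "A": 129.0, "C": 167.0, "D": 193.0, "E": 223.0, "F": 240.0, "G": 104.0,
    "H": 224.0, "I": 197.0, "K": 236.0, "L": 201.0, "M": 224.0, "N": 195.0,
    "P": 159.0, "Q": 225.0, "R": 274.0, "S": 155.0, "T": 172.0, "V": 174.0,
    "W": 285.0, "Y": 263.0,
}

# Bhaskaran & Ponnuswamy average flexibility
FLEXIBILITY = {
    "A": 0.357, "C": 0.346, "D": 0.511, "E": 0.497, "F": 0.314, "G": 0.544,
    "H": 0.323, "I": 0.462, "K": 0.466, "L": 0.365, "M": 0.295, "N": 0.463,
    "P": 0.509, "Q": 0.493, "R": 0.529, "S": 0.507, "T": 0.444, "V": 0.386,
    "W": 0.305, "Y": 0.420,
}

# Net charge at physiological pH (His fractional)
NET_CHARGE = {
    "A": 0.0, "C": 0.0, "D": -1.0, "E": -1.0, "F": 0.0, "G": 0.0, "H": 0.1,
    "I": 0.0, "K": 1.0, "L": 0.0, "M": 0.0, "N": 0.0, "P": 0.0, "Q": 0.0,
    "R": 1.0, "S": 0.0, "T": 0.0, "V": 0.0, "W": 0.0, "Y": 0.0,
}

# pKa of the alpha-carboxyl group
PK_COOH = {
    "A": 2.34, "C": 1.96, "D": 1.88, "E": 2.19, "F": 1.83, "G": 2.34, "H": 1.82,
    "I": 2.36, "K": 2.18, "L": 2.36, "M": 2.28, "N": 2.02, "P": 1.99, "Q": 2.17,
    "R": 2.17, "S": 2.21, "T": 2.09, "V": 2.32, "W": 2.38, "Y": 2.20,
}

# pKa of the alpha-amino group
PK_NH2 = {
    "A": 9.69, "C": 10.28, "D": 9.60, "E": 9.67, "F": 9.13, "G": 9.60, "H": 9.17,
    "I": 9.60, "K": 8.95, "L": 9.60, "M": 9.21, "N": 8.80, "P": 10.60, "Q": 9.13,
    "R": 9.04, "S": 9.15, "T": 9.10, "V": 9.62, "W": 9.39, "Y": 9.11,
}

# Janin transfer free energy (interior propensity)
BURIEDNESS = {
    "A": 0.3, "C": 0.9, "D": -0.6, "E": -0.7, "F": 0.5, "G": 0.3, "H": -0.1,
    "I": 0.7, "K": -1.8, "L": 0.5, "M": 0.4, "N": -0.5, "P": -0.3, "Q": -0.7,
    "R": -1.4, "S": -0.1, "T": -0.2, "V": 0.6, "W": 0.3, "Y": -0.4,
}

# Jones side-chain refractivity
REFRACTIVITY = {
    "A": 4.34, "C": 35.77, "D": 12.00, "E": 17.26, "F": 29.40, "G": 0.00,
    "H": 21.81, "I": 19.06, "K": 21.29, "L": 18.78, "M": 21.64, "N": 13.28,
    "P": 10.93, "Q": 17.56, "R": 26.66, "S": 6.35, "T": 11.01, "V": 13.92,
    "W": 42.53, "Y": 31.53,
}

#: Default 14-property selection for the AAindex-style per-residue encoding.
DEFAULT_AAINDEX_PROPERTIES = {
    "hydrophobicity": HYDROPHOBICITY,
    "hydrophilicity": HYDROPHILICITY,
    "mass": SIDE_CHAIN_MASS,
    "isoelectric_point": ISOELECTRIC_POINT,
    "volume": SIDE_CHAIN_VOLUME,
    "polarity": POLARITY,
    "polarizability": POLARIZABILITY,
    "max_asa": MAX_ASA,
    "flexibility": FLEXIBILITY,
    "net_charge": NET_CHARGE,
    "pk_cooh": PK_COOH,
    "pk_nh2": PK_NH2,
    "buriedness": BURIEDNESS,
    "refractivity": REFRACTIVITY,
}

# Per-residue expected packing density used by the amyloidogenicity score.
# Residues with value above the cutoff are the packing-dense (amyloid-prone) ones.
FOLDAMYLOID_PACKING = {
    "A": 20.21, "C": 22.64, "D": 18.22, "E": 18.30, "F": 22.46, "G": 19.04,
    "H": 20.47, "I": 22.53, "K": 17.69, "L": 22.06, "M": 21.80, "N": 18.52,
    "P": 17.43, "Q": 18.98, "R": 18.91, "S": 19.23, "T": 19.85, "V": 22.57,
    "W": 22.08, "Y": 21.72,
}
FOLDAMYLOID_CUTOFF = 21.4

#: Reduced 8-letter alphabet: physicochemical residue groups.
REDUCED_ALPHABET_GROUPS = {
    "acid": "DE",
    "basic": "HKR",
    "aromatic": "FWY",
    "amide": "NQ",
    "small_hydroxyl": "ST",
    "sulfur": "CM",
    "aliphatic_1": "AGP",
    "aliphatic_2": "ILV",
}

#: Property triple used by parallel-correlation pseudo amino-acid composition.
PSEAAC_PC_PROPERTIES = ("hydrophilicity", "hydrophobicity", "mass")
#: Property pair used by series-correlation pseudo amino-acid composition.
PSEAAC_SC_PROPERTIES = ("hydrophilicity", "hydrophobicity")
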