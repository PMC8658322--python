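"""Physicochemical lookup tables used by the sequence encoders.

Two families of tables live here:

* the 13 three-group partitions of the 20 standard residues used by the
  composition/transition/distribution (CTD) descriptors, in the convention
  popularised by the iFeature toolkit (Dubchak-style groupings under
  hydrophobicity scales, van der Waals volume, polarity, polarizability,
  charge, secondary structure and solvent accessibility);
* Chou's per-residue property values (hydrophobicity, hydrophilicity,
  side-chain mass) that drive the pseudo-amino-acid composition
  correlation terms.

Every partition covers the 20 residues exactly once; this is asserted at
import time so a corrupted table can never silently skew a descriptor.
"""

from __future__ import annotations

import numpy as np

#: Fixed residue order used everywhere (alphabetical one-letter codes).
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

# ---------------------------------------------------------------------------
# CTD: 13 properties, each splitting the alphabet into 3 disjoint groups.
# Order of properties and of groups is fixed so feature vectors are
# bit-reproducible.
# ---------------------------------------------------------------------------

CTD_PROPERTIES: list[str] = [
    "hydrophobicity_PRAM900101",
    "hydrophobicity_ARGP820101",
    "hydrophobicity_ZIMJ680101",
    "hydrophobicity_PONP930101",
    "hydrophobicity_CASG920101",
    "hydrophobicity_ENGD860101",
    "hydrophobicity_FASG890101",
    "normwaalsvolume",
    "polarity",
    "polarizability",
    "charge",
    "secondarystruct",
    "solventaccess",
]

CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity_PRAM900101": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "hydrophobicity_ARGP820101": ("QSTNGDE", "RAHCKMV", "LYPFIW"),
    "hydrophobicity_ZIMJ680101": ("QNGSWTDERA", "HMCKV", "LPFYI"),
    "hydrophobicity_PONP930101": ("KPDESNQT", "GRHA", "YMFWLCVI"),
    "hydrophobicity_CASG920101": ("KDEQPSRNTG", "AHYMLV", "FIWC"),
    "hydrophobicity_ENGD860101": ("RDKENQHYP", "SGTAW", "CVLIMF"),
    "hydrophobicity_FASG890101": ("KERSQD", "NTPG", "AYHWVMFLIC"),
    "normwaalsvolume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}


def ctd_group_index(prop: str) -> np.ndarray:
    """Map each alphabet position to its group number (0, 1 or 2)."""
    idx = np.full(20, -1, dtype=np.int64)
    for g, members in enumerate(CTD_GROUPS[prop]):
        for aa in members:
            idx[AA_INDEX[aa]] = g
    return idx


def _check_partitions() -> None:
    for prop, groups in CTD_GROUPS.items():
        joined = "".join(groups)
        if sorted(joined) != sorted(ALPHABET):
            raise AssertionError(f"CTD groups for {prop} are not a partition")


_check_partitions()

# ---------------------------------------------------------------------------
# Chou property values for PAAC / APAAC (raw, unstandardized).
# Order follows ALPHABET.
# ---------------------------------------------------------------------------

_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}

_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}

_SIDECHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}


def _standardize(table: dict[str, float]) -> np.ndarray:
    v = np.array([table[aa] for aa in ALPHABET], dtype=float)
    return (v - v.mean()) / v.std()  # population std, Chou's convention


#: Standardized property rows, shape (3, 20): hydrophobicity,
#: hydrophilicity, side-chain mass. PAAC correlates over all three.
PAAC_PROPERTIES: np.ndarray = np.vstack(
    [_standardize(t) for t in (_HYDROPHOBICITY, _HYDROPHILICITY, _SIDECHAIN_MASS)]
)

#: Standardized property rows, shape (2, 20): hydrophobicity and
#: hydrophilicity. APAAC builds amphiphilic correlation terms from these.
APAAC_PROPERTIES: np.ndarray = PAAC_PROPERTIES[:2]
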