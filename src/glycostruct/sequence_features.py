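"""Per-position sequence-derived features.

Four AAindex scales (hydrophobicity, flexibility, polarity, beta-turn
propensity), a 14-property physicochemical table, PSSM log-odds columns and
a PSSM-frequency conservation score. Unknown residues ('X', used for window
padding beyond the chain termini) evaluate to neutral values: the scale mean
for lookups, a uniform column (score 0) for conservation.
"""

from __future__ import annotations

import numpy as np

from .types import AA_ORDER, PSSMProfile

_LOG2_20 = np.log2(20.0)


def _scale(d: dict[str, float]) -> dict[str, float]:
    assert sorted(d) == sorted(AA_ORDER)
    return d


# AAindex CIDH920105: normalized average hydrophobicity scales (Cid et al., 1992).
HYDROPHOBICITY = _scale({
    "A": 0.02, "R": -0.42, "N": -0.77, "D": -1.04, "C": 0.77,
    "Q": -1.10, "E": -1.14, "G": -0.80, "H": 0.26, "I": 1.81,
    "L": 1.14, "K": -0.41, "M": 1.00, "F": 1.35, "P": -0.09,
    "S": -0.97, "T": -0.77, "W": 1.71, "Y": 1.11, "V": 1.13,
})

# AAindex BHAR880101: average flexibility indices (Bhaskaran & Ponnuswamy, 1988).
FLEXIBILITY = _scale({
    "A": 0.357, "R": 0.529, "N": 0.463, "D": 0.511, "C": 0.346,
    "Q": 0.493, "E": 0.497, "G": 0.544, "H": 0.323, "I": 0.462,
    "L": 0.365, "K": 0.466, "M": 0.295, "F": 0.314, "P": 0.509,
    "S": 0.507, "T": 0.444, "W": 0.305, "Y": 0.420, "V": 0.386,
})

# AAindex RADA880108: mean polarity (Radzicka & Wolfenden, 1988).
POLARITY = _scale({
    "A": -0.06, "R": -0.84, "N": -0.48, "D": -0.80, "C": 1.36,
    "Q": -0.73, "E": -0.77, "G": -0.41, "H": 0.49, "I": 1.31,
    "L": 1.21, "K": -1.18, "M": 1.27, "F": 1.27, "P": 0.0,
    "S": -0.50, "T": -0.27, "W": 0.88, "Y": 0.33, "V": 1.09,
})

# AAindex BEGF750103: conformational parameter of beta-turn (Beghin & Dirkx, 1975).
BETA_TURN = _scale({
    "A": 0.70, "R": 0.34, "N": 1.42, "D": 0.98, "C": 0.65,
    "Q": 0.75, "E": 0.27, "G": 1.41, "H": 0.63, "I": 0.78,
    "L": 0.40, "K": 1.28, "M": 0.67, "F": 0.67, "P": 1.10,
    "S": 1.41, "T": 1.09, "W": 0.45, "Y": 1.61, "V": 0.71,
})

#: The four AAindex scales, keyed by the feature name used in encoded vectors.
AA_SCALES: dict[str, dict[str, float]] = {
    "Normalized average hydrophobicity scales": HYDROPHOBICITY,
    "Average flexibility indices": FLEXIBILITY,
    "Mean polarity": POLARITY,
    "Conformational parameter of beta-turn": BETA_TURN,
}

#: Names and per-amino-acid values of the 14 physicochemical properties, in
#: fixed encoding order. pK values and pI from standard biochemistry tables
#: (pKR = 0 where the side chain is not ionizable); hydropathy (Kyte &
#: Doolittle); % occurrence (UniProtKB composition); % buried (Chothia);
#: average volume (Zamyatnin); accessible surface area (Miller, Gly-X-Gly);
#: van der Waals volume; polarity (Grantham); side-chain polarity (1 polar /
#: 0 non-polar); alpha-helix and beta-strand conformational preferences
#: (Chou & Fasman).
PHYSCHEM_PROPERTIES = (
    "pK1", "pK2", "pKR", "pI", "Hydropathy index", "Percentage occurrence",
    "Percentage buried", "Average volume", "Accessible surface area",
    "Van der Waals volume", "Polarity ranking", "Side-chain polarity",
    "Alpha-helix preference", "Beta-strand preference",
)

_PHYSCHEM: dict[str, tuple[float, ...]] = {
    #      pK1    pK2    pKR    pI   hyd   occ    bur   vol    asa   vdw   pol  scp  Pa    Pb
    "A": (2.34, 9.69, 0.00, 6.00, 1.8, 8.25, 38.0, 88.6, 113.0, 67.0, 8.1, 0, 1.42, 0.83),
    "R": (2.17, 9.04, 12.48, 10.76, -4.5, 5.53, 1.0, 173.4, 241.0, 148.0, 10.5, 1, 0.98, 0.93),
    "N": (2.02, 8.80, 0.00, 5.41, -3.5, 4.06, 12.0, 114.1, 158.0, 96.0, 11.6, 1, 0.67, 0.89),
    "D": (1.88, 9.60, 3.65, 2.77, -3.5, 5.45, 15.0, 111.1, 151.0, 91.0, 13.0, 1, 1.01, 0.54),
    "C": (1.96, 10.28, 8.18, 5.07, 2.5, 1.37, 45.0, 108.5, 140.0, 86.0, 5.5, 1, 0.70, 1.19),
    "Q": (2.17, 9.13, 0.00, 5.65, -3.5, 3.93, 7.0, 143.8, 189.0, 114.0, 10.5, 1, 1.11, 1.10),
    "E": (2.19, 9.67, 4.25, 3.22, -3.5, 6.75, 18.0, 138.4, 183.0, 109.0, 12.3, 1, 1.51, 0.37),
    "G": (2.34, 9.60, 0.00, 5.97, -0.4, 7.07, 36.0, 60.1, 85.0, 48.0, 9.0, 0, 0.57, 0.75),
    "H": (1.82, 9.17, 6.00, 7.59, -3.2, 2.27, 17.0, 153.2, 194.0, 118.0, 10.4, 1, 1.00, 0.87),
    "I": (2.36, 9.60, 0.00, 6.02, 4.5, 5.96, 60.0, 166.7, 182.0, 124.0, 5.2, 0, 1.08, 1.60),
    "L": (2.36, 9.60, 0.00, 5.98, 3.8, 9.66, 45.0, 166.7, 180.0, 124.0, 4.9, 0, 1.21, 1.30),
    "K": (2.18, 8.95, 10.53, 9.74, -3.9, 5.84, 3.0, 168.6, 211.0, 135.0, 11.3, 1, 1.16, 0.74),
    "M": (2.28, 9.21, 0.00, 5.74, 1.9, 2.42, 40.0, 162.9, 204.0, 124.0, 5.7, 0, 1.45, 1.05),
    "F": (1.83, 9.13, 0.00, 5.48, 2.8, 3.86, 50.0, 189.9, 218.0, 135.0, 5.2, 0, 1.13, 1.38),
    "P": (1.99, 10.60, 0.00, 6.30, -1.6, 4.70, 18.0, 112.7, 143.0, 90.0, 8.0, 0, 0.57, 0.55),
    "S": (2.21, 9.15, 0.00, 5.68, -0.8, 6.56, 22.0, 89.0, 122.0, 73.0, 9.2, 1, 0.77, 0.75),
    "T": (2.09, 9.10, 0.00, 5.60, -0.7, 5.34, 23.0, 116.1, 146.0, 93.0, 8.6, 1, 0.83, 1.19),
    "W": (2.83, 9.39, 0.00, 5.89, -0.9, 1.08, 27.0, 227.8, 259.0, 163.0, 5.4, 0, 1.08, 1.37),
    "Y": (2.20, 9.11, 10.07, 5.66, -1.3, 2.92, 15.0, 193.6, 229.0, 141.0, 6.2, 1, 0.69, 1.47),
    "V": (2.32, 9.62, 0.00, 5.96, 4.2, 6.87, 54.0, 140.0, 160.0, 105.0, 5.9, 0, 1.06, 1.70),
}

_PHYSCHEM_MEAN = tuple(
    float(np.mean([_PHYSCHEM[a][k] for a in AA_ORDER]))
    for k in range(len(PHYSCHEM_PROPERTIES))
)


def aaindex_value(scale: dict[str, float] | str, aa: str) -> float:
    """Look up an AAindex scale value; 'X' returns the mean of the scale."""
    if isinstance(scale, str):
        scale = AA_SCALES[scale]
    if aa == "X":
        return float(np.mean(list(scale.values())))
    if aa not in scale:
        raise KeyError(f"unknown amino acid {aa!r}")
    return scale[aa]


def physchem_vector(aa: str) -> np.ndarray:
    """The 14 physicochemical property values of a residue, in the fixed
    order of :data:`PHYSCHEM_PROPERTIES`; 'X' gives per-property means."""
    if aa == "X":
        return np.asarray(_PHYSCHEM_MEAN, dtype=float)
    if aa not in _PHYSCHEM:
        raise KeyError(f"unknown amino acid {aa!r}")
    return np.asarray(_PHYSCHEM[aa], dtype=float)


def pssm_column(profile: PSSMProfile, i: int) -> np.ndarray:
    """The 20 log-odds values at position ``i`` in canonical column order."""
    if not 0 <= i < profile.length:
        raise IndexError(f"position {i} out of range [0, {profile.length})")
    return profile.logodds[i].copy()


def conservation_score(profile: PSSMProfile, i: int) -> float:
    """Residue conservation as normalized information content.

    ``1 - H_i / log2(20)`` with ``H_i`` the Shannon entropy (bits) of the
    position's frequency column; 0 for a uniform column, 1 for one-hot.
    """
    if not 0 <= i < profile.length:
        raise IndexError(f"position {i} out of range [0, {profile.length})")
    p = profile.freqs[i]
    nz = p[p > 0]
    h = -float(np.sum(nz * np.log2(nz)))
    return 1.0 - h / _LOG2_20
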