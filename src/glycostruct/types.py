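"""Core in-memory containers: atoms, residues, chains, PSSM profiles and sites."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed amino-acid column order of ASCII PSSM files.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Backbone atom names; everything else in a residue counts as side chain.
MAINCHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class Atom:
    """A single atom of a parsed structure.

    Coordinates are in Angstrom, ``b_factor`` in Angstrom^2, ``occupancy``
    a fraction in [0, 1]. ``is_mainchain`` is true for N, CA, C, O, OXT.
    """

    name: str
    element: str
    coords: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be 3 finite numbers")
        if self.b_factor < 0:
            raise ValueError(f"atom {self.name}: negative B-factor")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy outside [0, 1]")

    @property
    def is_mainchain(self) -> bool:
        return self.name in MAINCHAIN_ATOMS


@dataclass
class Residue:
    """One residue of a chain, indexed both internally and by author numbering.

    ``seq_index`` is the 0-based position in the observed chain;
    ``author_number`` is the PDB author residue number plus insertion code
    (kept as a string, e.g. ``"42"`` or ``"42A"``) and is used only for
    joining against external per-residue tables, never for ordering.
    """

    chain_id: str
    seq_index: int
    author_number: str
    aa: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.aa not in AA_ORDER and self.aa != "X":
            raise ValueError(f"residue {self.author_number}: bad amino acid {self.aa!r}")

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """A single parsed protein chain."""

    structure_id: str
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def atom_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """All atom coordinates stacked (n_atoms, 3) plus the residue index
        of each atom (n_atoms,)."""
        coords = []
        owner = []
        for r in self.residues:
            for a in r.atoms:
                coords.append(a.coords)
                owner.append(r.seq_index)
        return np.asarray(coords, dtype=float), np.asarray(owner, dtype=int)

    def validate(self) -> None:
        for i, r in enumerate(self.residues):
            if r.seq_index != i:
                raise ValueError("seq_index values must be 0..len-1 contiguous")
            if not r.atoms:
                raise ValueError(f"residue {r.author_number} has no atoms")


@dataclass
class PSSMProfile:
    """Per-position log-odds and frequencies from an iterative profile search.

    ``freqs`` rows are renormalised to sum to 1; all-zero rows (which profile
    tools emit for some positions) become uniform.
    """

    logodds: np.ndarray
    freqs: np.ndarray
    aa_order: str = AA_ORDER

    def __post_init__(self) -> None:
        self.logodds = np.asarray(self.logodds, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.logodds.ndim != 2 or self.logodds.shape[1] != 20:
            raise ValueError("logodds must be L x 20")
        if self.freqs.shape != self.logodds.shape:
            raise ValueError("freqs shape must match logodds")
        if np.any(self.freqs < 0):
            raise ValueError("frequencies must be non-negative")
        sums = self.freqs.sum(axis=1)
        zero = sums <= 0
        self.freqs[zero] = 1.0 / 20.0
        sums[zero] = 1.0
        self.freqs = self.freqs / sums[:, None]

    @property
    def length(self) -> int:
        return self.logodds.shape[0]


@dataclass
class SiteRecord:
    """A candidate glycosylation site.

    ``label`` is 1 (experimentally positive), 0 (negative) or None (unknown,
    excluded from training). ``sequon`` flags the Asn-X-Ser/Thr (X != Pro)
    consensus motif and is meaningful for N-linked sites only.
    """

    structure_id: str
    chain: str
    seq_index: int
    aa: str
    glyco_type: str
    label: int | None = None
    sequon: bool = False

    def __post_init__(self) -> None:
        if self.glyco_type not in ("N", "O"):
            raise ValueError(f"glyco_type must be 'N' or 'O', got {self.glyco_type!r}")
        if self.glyco_type == "N" and self.aa != "N":
            raise ValueError("N-linked site must be an Asn residue")
        if self.glyco_type == "O" and self.aa not in ("S", "T"):
            raise ValueError("O-linked site must be a Ser or Thr residue")

    @property
    def site_id(self) -> tuple[str, str, int]:
        return (self.structure_id, self.chain, self.seq_index)
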