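"""Readers and writers for structures and external per-residue feature files.

PDB parsing is delegated to Bio.PDB; DSSP output files are parsed with
Biopython's DSSP dictionary reader. The ASCII PSSM and NACCESS ``.rsa``
formats have no reader in the scientific Python stack, so they are parsed
here directly.
"""

from __future__ import annotations

import importlib
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from .types import AA_ORDER, Atom, PSSMProfile, Residue, StructureModel

log = logging.getLogger(__name__)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Common nonstandard residues with an accepted parent amino acid.
_NONSTANDARD = {
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y", "CSO": "C", "MLY": "K", "M3L": "K",
}


class ParseError(ValueError):
    """Raised when an input file does not follow its expected format."""


def _pick_altloc(atoms):
    """Highest occupancy wins; ties break lexicographically by altloc id."""
    return min(atoms, key=lambda a: (-a.get_occupancy(), a.get_altloc()))


def parse_pdb(path: str | Path, chain: str, structure_id: str | None = None) -> StructureModel:
    """Parse one chain of a PDB file into a :class:`StructureModel`.

    Only standard-residue ATOM records of the requested chain are kept
    (plus common modified residues such as MSE, mapped to their parent amino
    acid); waters, other heteroatoms and hydrogens are excluded. For
    alternate locations the highest-occupancy conformer is retained (ties
    resolved to the lexicographically first altloc id). Multi-model files
    contribute only their first model.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sid = structure_id if structure_id is not None else path.stem
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(sid, str(path))
    try:
        model0 = next(iter(structure))
    except StopIteration:
        raise ParseError(f"{path}: no models found") from None
    if chain not in [c.id for c in model0]:
        raise KeyError(f"chain not found: {chain!r} in {path}")
    residues: list[Residue] = []
    for res in model0[chain]:
        resname = res.get_resname().strip()
        if resname in _THREE_TO_ONE:
            aa = _THREE_TO_ONE[resname]
        elif resname in _NONSTANDARD:
            aa = _NONSTANDARD[resname]
            log.warning("%s %s%s: nonstandard residue %s mapped to %s",
                        sid, chain, res.id[1], resname, aa)
        else:
            if resname != "HOH":
                log.warning("%s %s%s: skipping unknown residue %s",
                            sid, chain, res.id[1], resname)
            continue
        atoms: list[Atom] = []
        for atom in res:
            if atom.is_disordered():
                atom = _pick_altloc(atom.disordered_get_list())
            element = (atom.element or "").strip().upper() or atom.get_name()[0]
            if element in ("H", "D"):
                continue
            atoms.append(Atom(
                name=atom.get_name(),
                element=element,
                coords=np.asarray(atom.get_coord(), dtype=float),
                b_factor=max(float(atom.get_bfactor() or 0.0), 0.0),
                occupancy=min(max(float(atom.get_occupancy() or 1.0), 0.0), 1.0),
                altloc=atom.get_altloc().strip(),
            ))
        if not atoms:
            continue
        hetflag, resnum, icode = res.id
        residues.append(Residue(
            chain_id=chain,
            seq_index=len(residues),
            author_number=f"{resnum}{icode.strip()}",
            aa=aa,
            atoms=atoms,
        ))
    if not residues:
        raise ParseError(f"empty chain: no standard residues in chain {chain!r} of {path}")
    model = StructureModel(structure_id=sid, chain_id=chain, residues=residues)
    model.validate()
    return model


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a :class:`StructureModel` as minimal single-chain PDB text."""
    lines = []
    serial = 1
    for res in model.residues:
        resname = next(k for k, v in _THREE_TO_ONE.items() if v == res.aa) \
            if res.aa != "X" else "UNK"
        num = res.author_number
        icode = " "
        if num and num[-1].isalpha():
            icode = num[-1]
            num = num[:-1]
        for atom in res.atoms:
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            x, y, z = atom.coords
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{resname:>3s} {res.chain_id}"
                f"{int(num):4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}          "
                f"{atom.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pssm_ascii(path: str | Path) -> PSSMProfile:
    """Read a standard ASCII PSSM (header, then one row per residue with 20
    integer log-odds columns followed by 20 percentage columns).

    Frequencies are the percentages divided by 100; the amino-acid column
    order is taken from the file's header line and mapped onto the canonical
    order ``ARNDCQEGHILKMFPSTWYV``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_order: str | None = None
    logodds, percents = [], []
    for lineno, line in enumerate(lines, start=1):
        toks = line.split()
        if not toks:
            continue
        if header_order is None:
            if len(toks) >= 40 and all(len(t) == 1 and t.isalpha() for t in toks[:40]):
                header_order = "".join(toks[:20])
            elif len(toks) >= 20 and all(len(t) == 1 and t.isalpha() for t in toks[:20]):
                header_order = "".join(toks[:20])
            continue
        if not toks[0].lstrip("-").isdigit():
            continue  # footer (lambda/K statistics)
        if len(toks) < 42:
            raise ParseError(f"{path} line {lineno}: expected >= 42 columns, got {len(toks)}")
        try:
            logodds.append([float(t) for t in toks[2:22]])
            percents.append([float(t) for t in toks[22:42]])
        except ValueError as exc:
            raise ParseError(f"{path} line {lineno}: non-numeric PSSM entry") from exc
    if header_order is None or not logodds:
        raise ParseError(f"{path}: no PSSM header/rows found")
    if sorted(header_order) != sorted(AA_ORDER):
        raise ParseError(f"{path}: unexpected amino-acid header {header_order!r}")
    perm = [header_order.index(a) for a in AA_ORDER]
    lo = np.asarray(logodds, dtype=float)[:, perm]
    fr = np.asarray(percents, dtype=float)[:, perm] / 100.0
    return PSSMProfile(logodds=lo, freqs=fr)


def read_dssp(path: str | Path) -> dict[tuple[str, str], dict[str, float | None]]:
    """Read a DSSP output file into per-residue records.

    Returns a map ``(chain, author_number) -> {"acc", "phi", "psi"}``.
    Angles printed as 360.0 (the DSSP convention for undefined) become None.
    """
    dssp_mod = importlib.import_module("Bio.PDB.DSSP")
    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dssp, keys = dssp_mod.make_dssp_dict(str(path))
    except Exception as exc:  # Biopython raises assorted errors on bad files
        raise ParseError(f"{path}: not a DSSP file ({exc})") from exc
    if not keys:
        raise ParseError(f"{path}: DSSP header not found or no residue records")
    out: dict[tuple[str, str], dict[str, float | None]] = {}
    for chainid, res_id in keys:
        aa, ss, acc, phi, psi = dssp[(chainid, res_id)][:5]
        _, resnum, icode = res_id
        key = (chainid, f"{resnum}{icode.strip()}")
        out[key] = {
            "acc": float(acc),
            "phi": None if phi == 360.0 else float(phi),
            "psi": None if psi == 360.0 else float(psi),
        }
    return out


#: Order of the five absolute accessibility classes in a .rsa RES line.
RSA_CLASSES = ("acc_all", "acc_sidechain", "acc_mainchain", "acc_nonpolar_sc", "acc_polar_sc")


def read_rsa(path: str | Path) -> dict[tuple[str, str], dict[str, float]]:
    """Read a NACCESS ``.rsa`` file.

    Each ``RES`` line carries ABS/REL pairs for five accessibility classes
    (all atoms, total side chain, main chain, non-polar side chain, polar
    side chain); only the absolute values are kept.
    """
    path = Path(path)
    out: dict[tuple[str, str], dict[str, float]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith("RES"):
            continue
        toks = line.split()
        if len(toks) < 14:
            raise ParseError(f"{path} line {lineno}: truncated RES line")
        chain = toks[2]
        author = toks[3]
        try:
            abs_vals = [float(toks[4 + 2 * k]) for k in range(5)]
        except ValueError as exc:
            raise ParseError(f"{path} line {lineno}: non-numeric accessibility") from exc
        out[(chain, author)] = dict(zip(RSA_CLASSES, abs_vals))
    if not out:
        raise ParseError(f"{path}: no RES lines found")
    return out


def read_residue_scores(path: str | Path) -> dict[tuple[str, str], float]:
    """Read a whitespace-delimited per-residue score table
    (chain, author residue number, score), e.g. precomputed epitope
    log-odds. Scores may be negative."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["chain", "residue", "score"],
                         dtype={"chain": str, "residue": str})
    except Exception as exc:
        raise ParseError(f"{path}: cannot read score table ({exc})") from exc
    if not np.issubdtype(df["score"].dtype, np.number):
        raise ParseError(f"{path}: non-numeric score column")
    keys = list(zip(df["chain"], df["residue"]))
    if len(set(keys)) != len(keys):
        raise ParseError(f"{path}: duplicate residue in score table")
    return {k: float(s) for k, s in zip(keys, df["score"])}
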