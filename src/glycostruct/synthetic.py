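"""Synthetic desk-scale inputs with known ground truth.

Idealized 3-D chains (helix, extended strand, or a collapsed jittered-
lattice globule whose interior residues are buried), synthetic PSSM
profiles sharpened around the true sequence, and site labels planted by an
explicit rule (sequon required and/or structure-window-averaged all-atom
accessibility above a threshold, with optional label noise). Everything is
deterministic under its seed, and the planted label is an exact function of
the generated inputs when the noise rate is zero, so any imperfect recovery
downstream is attributable to the learner rather than the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import extract_candidate_sites
from .structural_features import (
    SASAConfig,
    residue_struct_features,
    shrake_rupley_sasa,
)
from .structure_io import write_pdb
from .types import AA_ORDER, Atom, PSSMProfile, Residue, SiteRecord, StructureModel
from .windows import structure_window

# Ideal backbone internal coordinates (Angstrom / degrees).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O, _A_N_CA_CB = 111.0, 116.6, 121.7, 120.5, 110.5
_OMEGA = 180.0
_TORSIONS = {"helix": (-57.0, -47.0), "extended": (-120.0, 130.0)}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place an atom at the given internal coordinates relative to a-b-c."""
    ang, dih = np.deg2rad(angle), np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(ang),
                  bond * np.sin(ang) * np.cos(dih),
                  bond * np.sin(ang) * np.sin(dih)])
    return c + d[0] * bc + d[1] * m + d[2] * n


@dataclass
class PlantRule:
    """Ground-truth labeling rule for synthetic sites.

    A site is positive iff (the sequon holds, when required) and its
    structure-window-averaged all-atom accessibility exceeds
    ``sasa_threshold`` (Angstrom^2); the label is then flipped with
    probability ``noise_rate``.
    """

    glyco_type: str = "N"
    sasa_threshold: float = 30.0
    require_sequon: bool = True
    noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")


@dataclass
class SyntheticDatasetSpec:
    """Size and shape of a synthetic dataset."""

    n_proteins: int = 200
    length_range: tuple[int, int] = (40, 80)
    geometry: str = "globule"
    lattice_spacing: float = 3.4
    pssm_concentration: float = 10.0
    n_seq_motifs: int = 2
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.length_range[0] < 4:
            raise ValueError("need at least one protein of length >= 4")


def _backbone_chain(n: int, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """N/CA/C coordinates for an ideal chain at fixed (phi, psi)."""
    N0 = np.array([0.0, 0.0, 0.0])
    CA0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    C0 = CA0 + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    res = [{"N": N0, "CA": CA0, "C": C0}]
    for i in range(1, n):
        prev = res[-1]
        Ni = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        CAi = _place(prev["CA"], prev["C"], Ni, _B_N_CA, _A_C_N_CA, _OMEGA)
        Ci = _place(prev["C"], Ni, CAi, _B_CA_C, _A_N_CA_C, phi)
        res.append({"N": Ni, "CA": CAi, "C": Ci})
    return res


def _globule_ca_positions(n: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """CA positions of n residues on a jittered lattice ball, ordered along
    a serpentine path so the chain stays local."""
    m = int(np.ceil(n ** (1 / 3))) + 2
    pts = []
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            for k in range(-m, m + 1):
                pts.append((i, j, k))
    pts = np.asarray(pts, dtype=float)
    r = np.linalg.norm(pts, axis=1)
    keep = np.argsort(r, kind="stable")[:n]
    cells = pts[keep]
    # serpentine order: snake through z-layers, then y-rows, then x
    order = sorted(range(n), key=lambda t: (
        cells[t, 2],
        cells[t, 1] * (1 if cells[t, 2] % 2 == 0 else -1),
        cells[t, 0] * (1 if cells[t, 1] % 2 == 0 else -1),
    ))
    ca = cells[order] * spacing
    ca += rng.uniform(-0.25, 0.25, size=ca.shape) * spacing / 3.4
    return ca


def build_ideal_structure(sequence: str, geometry: str = "helix",
                          seed: int | None = None,
                          lattice_spacing: float = 3.4,
                          structure_id: str = "SYNT",
                          chain_id: str = "A") -> StructureModel:
    """Build an idealized single-chain model for a sequence.

    ``helix`` and ``extended`` modes place the backbone at ideal torsions
    (helix targets phi = -57, psi = -47); ``globule`` mode packs residues on
    a jittered lattice ball so interior residues are solvent-inaccessible.
    Every residue gets N/CA/C/O plus one pseudo side-chain (CB-like) atom
    (except Gly); B-factors are drawn from a seeded gamma distribution.
    """
    if not sequence or any(a not in AA_ORDER for a in sequence):
        raise ValueError("sequence must be non-empty standard amino-acid letters")
    rng = np.random.default_rng(seed)
    n = len(sequence)

    if geometry in _TORSIONS:
        phi, psi = _TORSIONS[geometry]
        bb = _backbone_chain(n, phi, psi)
    elif geometry == "globule":
        ca = _globule_ca_positions(n, lattice_spacing, rng)
        bb = []
        for i in range(n):
            prev_ca = ca[i - 1] if i > 0 else ca[i] - np.array([1.0, 0, 0])
            next_ca = ca[i + 1] if i < n - 1 else ca[i] + np.array([1.0, 0, 0])
            u_in = ca[i] - prev_ca
            u_in /= np.linalg.norm(u_in)
            u_out = next_ca - ca[i]
            u_out /= np.linalg.norm(u_out)
            bb.append({"N": ca[i] - 1.2 * u_in, "CA": ca[i].copy(),
                       "C": ca[i] + 1.2 * u_out})
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    residues: list[Residue] = []
    for i, aa in enumerate(sequence):
        Ni, CAi, Ci = bb[i]["N"], bb[i]["CA"], bb[i]["C"]
        atoms = [
            Atom("N", "N", Ni, 0.0, 1.0),
            Atom("CA", "C", CAi, 0.0, 1.0),
            Atom("C", "C", Ci, 0.0, 1.0),
        ]
        if geometry in _TORSIONS:
            psi_i = _TORSIONS[geometry][1] if i < n - 1 else 180.0
            O = _place(Ni, CAi, Ci, _B_C_O, _A_CA_C_O, psi_i + 180.0)
        else:
            perp = np.cross(Ci - Ni, np.array([0.13, 0.77, 0.62]))
            nrm = np.linalg.norm(perp)
            perp = perp / nrm if nrm > 1e-6 else np.array([0.0, 0.0, 1.0])
            O = Ci + _B_C_O * perp
        atoms.append(Atom("O", "O", O, 0.0, 1.0))
        if aa != "G":
            if geometry in _TORSIONS:
                CB = _place(Ci, Ni, CAi, _B_CA_CB, _A_N_CA_CB, -120.0)
            else:
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                CB = CAi + _B_CA_CB * d
            atoms.append(Atom("CB", "C", CB, 0.0, 1.0))
        for a in atoms:
            a.b_factor = float(rng.gamma(shape=4.0, scale=5.0))
        residues.append(Residue(chain_id=chain_id, seq_index=i,
                                author_number=str(i + 1), aa=aa, atoms=atoms))
    return StructureModel(structure_id=structure_id, chain_id=chain_id,
                          residues=residues)


def synth_pssm(sequence: str, concentration: float = 10.0,
               seed: int | None = None) -> PSSMProfile:
    """Synthetic PSSM sharpened around the true sequence.

    Per position the frequency row is a mixture lam * onehot(true residue)
    + (1 - lam) * near-uniform noise with lam = c/(1+c); large concentration
    c gives one-hot rows (conservation -> 1), small c near-uniform rows
    (conservation -> 0). Log-odds are round(2*log2(p/0.05)) clipped to
    [-10, 10], against a uniform background.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    lam = concentration / (1.0 + concentration)
    L = len(sequence)
    freqs = np.empty((L, 20))
    for i, aa in enumerate(sequence):
        onehot = np.zeros(20)
        onehot[AA_ORDER.index(aa)] = 1.0
        noise = rng.dirichlet(np.full(20, 50.0))
        freqs[i] = lam * onehot + (1.0 - lam) * noise
    p = np.clip(freqs, 1e-6, None)
    logodds = np.clip(np.round(2.0 * np.log2(p / 0.05)), -10, 10)
    return PSSMProfile(logodds=logodds, freqs=freqs)


_BASE_COMPOSITION = {"N": 0.09, "S": 0.08, "T": 0.08, "P": 0.04}


def _sample_sequence(length: int, rng: np.random.Generator, n_motifs: int) -> str:
    probs = np.empty(20)
    rest = 1.0 - sum(_BASE_COMPOSITION.values())
    others = [a for a in AA_ORDER if a not in _BASE_COMPOSITION]
    for i, a in enumerate(AA_ORDER):
        probs[i] = _BASE_COMPOSITION.get(a, rest / len(others))
    seq = list(rng.choice(list(AA_ORDER), size=length, p=probs / probs.sum()))
    non_pro = [a for a in AA_ORDER if a != "P"]
    for _ in range(n_motifs):
        pos = int(rng.integers(0, length - 2))
        seq[pos] = "N"
        seq[pos + 1] = str(rng.choice(non_pro))
        seq[pos + 2] = "S" if rng.random() < 0.5 else "T"
    return "".join(seq)


def generate_dataset(spec: SyntheticDatasetSpec | None = None,
                     rule: PlantRule | None = None,
                     radius: float = 10.0,
                     precompute_features: bool = True,
                     ) -> tuple[list[dict], list[SiteRecord]]:
    """Generate structures, PSSMs and planted-label site records.

    Returns ``(proteins, sites)`` where each protein dict holds ``model``,
    ``pssm`` and (when ``precompute_features``) ``struct_feats``, the exact
    inputs the encoding pipeline consumes. The planted label of a candidate
    is rule-determined from the sequon flag and the structure-window-
    averaged all-atom accessibility, then flipped with the rule's noise
    rate.
    """
    spec = spec or SyntheticDatasetSpec()
    rule = rule or PlantRule()
    master = np.random.default_rng(spec.seed)
    noise_rng = np.random.default_rng(rule.seed + 1)
    cfg = SASAConfig()
    proteins: list[dict] = []
    sites: list[SiteRecord] = []
    for p in range(spec.n_proteins):
        prot_seed = int(master.integers(2**31 - 1))
        rng = np.random.default_rng(prot_seed)
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = _sample_sequence(length, rng, spec.n_seq_motifs)
        sid = f"SYN{p:04d}"
        model = build_ideal_structure(seq, spec.geometry, seed=prot_seed + 1,
                                      lattice_spacing=spec.lattice_spacing,
                                      structure_id=sid)
        pssm = synth_pssm(seq, spec.pssm_concentration, seed=prot_seed + 2)
        atom_sasa = shrake_rupley_sasa(model, cfg)
        prot = {"structure_id": sid, "model": model, "pssm": pssm}
        if precompute_features:
            prot["struct_feats"] = residue_struct_features(model, cfg, atom_sasa=atom_sasa)
            acc_all = prot["struct_feats"]["Absolute accessibility of all-atoms"].to_numpy()
        else:
            from .structural_features import accessibility_classes
            acc_all = accessibility_classes(model, atom_sasa)[
                "Absolute accessibility of all-atoms"].to_numpy()
        proteins.append(prot)
        for site in extract_candidate_sites(model, rule.glyco_type):
            members = sorted(structure_window(model, site.seq_index, radius))
            win_acc = float(np.mean(acc_all[members]))
            ok = site.sequon if rule.require_sequon else True
            label = int(ok and win_acc > rule.sasa_threshold)
            if noise_rng.random() < rule.noise_rate:
                label = 1 - label
            site.label = label
            sites.append(site)
    return proteins, sites


def planted_label(model: StructureModel, struct_feats, seq_index: int,
                  rule: PlantRule, radius: float = 10.0) -> int:
    """The noise-free planted label of a candidate site (oracle for
    identifiability checks)."""
    from .dataset import check_sequon

    members = sorted(structure_window(model, seq_index, radius))
    acc = struct_feats["Absolute accessibility of all-atoms"].to_numpy()
    win_acc = float(np.mean(acc[members]))
    ok = check_sequon(model.sequence, seq_index) if rule.require_sequon else True
    return int(ok and win_acc > rule.sasa_threshold)


def write_dataset(proteins: list[dict], sites: list[SiteRecord],
                  outdir: str | Path) -> None:
    """Write a generated dataset as standard files: one PDB and one ASCII
    PSSM per protein plus a site annotation TSV (positives only)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for prot in proteins:
        model = prot["model"]
        write_pdb(model, outdir / f"{model.structure_id}.pdb")
        write_pssm_ascii(prot["pssm"], model.sequence,
                         outdir / f"{model.structure_id}.pssm")
    lines = ["structure_id\tchain\tseq_index\tglyco_type"]
    for s in sites:
        if s.label == 1:
            lines.append(f"{s.structure_id}\t{s.chain}\t{s.seq_index}\t{s.glyco_type}")
    (outdir / "annotations.tsv").write_text("\n".join(lines) + "\n")


def write_pssm_ascii(pssm: PSSMProfile, sequence: str, path: str | Path) -> None:
    """Write a profile in the standard ASCII PSSM layout."""
    header = "  ".join(AA_ORDER) + "   " + "  ".join(AA_ORDER)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down",
        "            " + header,
    ]
    for i, aa in enumerate(sequence):
        lo = " ".join(f"{int(v):3d}" for v in pssm.logodds[i])
        pct = " ".join(f"{int(round(v * 100)):3d}" for v in pssm.freqs[i])
        lines.append(f"{i + 1:5d} {aa}  {lo}  {pct}  0.00 0.00")
    Path(path).write_text("\n".join(lines) + "\n")
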