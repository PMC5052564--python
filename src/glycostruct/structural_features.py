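"""Per-residue structural feature channels.

Fourteen channels per residue: five absolute solvent-accessibility classes,
three secondary-structure values (water-accessible surface, phi, psi),
an epitope log-odds score, four depth-index statistics, and the mean atomic
B-factor. Missing values (chain-terminal dihedrals, residues without CA)
are carried as NaN and excluded channel-wise from structure-window averages.

Solvent accessibility is computed by Shrake-Rupley point sampling with a
3 Angstrom probe (matching the accessibility convention of the study design
this package follows) and NACCESS-style van der Waals radii; values from
real external tool output (DSSP, NACCESS, epitope score tables) can be
injected verbatim and override the internal computations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .types import Residue, StructureModel

log = logging.getLogger(__name__)

#: NACCESS-style van der Waals radii (Angstrom); hydrogens are stripped at parse.
DEFAULT_VDW_RADII = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.90, "SE": 1.90}
_FALLBACK_VDW = 1.8

#: The 14 structural feature channels, in fixed encoding order.
STRUCT_CHANNELS = (
    "Absolute accessibility of all-atoms",
    "Absolute accessibility of total side-chain",
    "Absolute accessibility of main chain",
    "Absolute accessibility of non-polar side-chain",
    "Absolute accessibility of polar side-chain",
    "ACC",
    "Phi",
    "Psi",
    "Log-odds ratio",
    "Average depth index",
    "Standard deviation of depth index",
    "Side-chain average depth index",
    "Standard deviation of side-chain depth index",
    "B factor",
)

# Internal epitope log-odds propensity scale (synthetic, in-house): a
# smoothed surface/epitope propensity with hydrophilic, flexible residues
# high and buried hydrophobics low. It only approximates the shape of
# published epitope log-odds statistics; verbatim external scores injected
# through structure_io.read_residue_scores always take precedence.
EPITOPE_PROPENSITY = {
    "A": -0.50, "R": 0.40, "N": 0.80, "D": 0.60, "C": -0.80,
    "Q": 0.30, "E": 0.50, "G": 0.70, "H": 0.00, "I": -1.20,
    "L": -1.10, "K": 0.90, "M": -0.70, "F": -0.90, "P": 1.00,
    "S": 0.60, "T": 0.50, "W": -0.60, "Y": -0.10, "V": -1.00,
    "X": 0.0,
}


@dataclass
class SASAConfig:
    """Parameters of the Shrake-Rupley accessibility calculation."""

    probe_radius: float = 3.0
    n_sphere_points: int = 960
    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_sphere_points < 92:
            raise ValueError("n_sphere_points must be >= 92")


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` near-uniform deterministic points on the unit sphere."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _intrinsic_frame(coords: np.ndarray) -> np.ndarray:
    """A rotation matrix tied to the structure's principal axes.

    Expressing the sampling sphere in this frame makes the point-sampled
    SASA covariant under rigid motion of the coordinates (up to floating-
    point error), instead of weakly anisotropic in the lab frame. Signs are
    fixed deterministically; degenerate principal axes fall back to the
    identity for symmetric point sets.
    """
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    try:
        w, v = np.linalg.eigh(cov)
    except np.linalg.LinAlgError:
        return np.eye(3)
    # orient each axis by the sign of the third moment along it: a
    # rotation-covariant convention, unlike lab-frame component signs
    for k in range(3):
        proj = centered @ v[:, k]
        m3 = float(np.sum(proj**3))
        if m3 < 0:
            v[:, k] = -v[:, k]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return v


def _atom_radii(model: StructureModel, cfg: SASAConfig) -> np.ndarray:
    radii = []
    for res in model.residues:
        for a in res.atoms:
            r = cfg.vdw_radii.get(a.element)
            if r is None:
                log.warning("no vdW radius for element %r; using %.2f", a.element, _FALLBACK_VDW)
                r = _FALLBACK_VDW
            radii.append(r)
    return np.asarray(radii, dtype=float)


def shrake_rupley_sasa(model: StructureModel, cfg: SASAConfig | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Angstrom^2).

    Each atom's expanded sphere (vdW + probe radius) is sampled with a
    deterministic golden-spiral point set; a point is buried when it lies
    inside any other atom's expanded sphere. SASA is the accessible point
    fraction times the expanded-sphere area.
    """
    cfg = cfg or SASAConfig()
    coords, _ = model.atom_coords()
    if coords.size == 0:
        raise ValueError("empty model")
    radii = _atom_radii(model, cfg) + cfg.probe_radius
    n_pts = cfg.n_sphere_points
    unit = golden_spiral_points(n_pts) @ _intrinsic_frame(coords).T
    tree = cKDTree(coords)
    max_r = radii.max()
    sasa = np.empty(len(coords))
    for i in range(len(coords)):
        neigh = tree.query_ball_point(coords[i], radii[i] + max_r)
        dvec = coords[neigh] - coords[i]
        dist = np.linalg.norm(dvec, axis=1)
        rj = radii[neigh]
        # keep only neighbours whose expanded sphere can reach ours
        keep = (dist < radii[i] + rj) & (dist > 1e-12)
        order = np.argsort(dist[keep] - rj[keep])  # most-occluding first
        nvec, nr = dvec[keep][order], rj[keep][order]
        pts = radii[i] * unit
        alive = np.ones(n_pts, dtype=bool)
        for v, r in zip(nvec, nr):
            idx = np.flatnonzero(alive)
            if idx.size == 0:
                break
            d2 = ((pts[idx] - v) ** 2).sum(axis=1)
            alive[idx[d2 < r * r]] = False
        sasa[i] = 4.0 * np.pi * radii[i] ** 2 * (alive.sum() / n_pts)
    return sasa


def accessibility_classes(model: StructureModel, atom_sasa: np.ndarray) -> pd.DataFrame:
    """Aggregate per-atom SASA into five absolute per-residue classes:
    all atoms, total side chain, main chain, non-polar (C/S) side chain and
    polar (N/O) side chain."""
    rows = []
    k = 0
    for res in model.residues:
        tot = main = side = nonpolar = polar = 0.0
        for a in res.atoms:
            s = float(atom_sasa[k]); k += 1
            tot += s
            if a.is_mainchain:
                main += s
            else:
                side += s
                if a.element in ("C", "S", "SE"):
                    nonpolar += s
                elif a.element in ("N", "O"):
                    polar += s
        rows.append((tot, side, main, nonpolar, polar))
    if k != len(atom_sasa):
        raise ValueError("atom_sasa does not cover all atoms")
    return pd.DataFrame(rows, columns=list(STRUCT_CHANNELS[:5]),
                        index=range(len(model.residues)))


def _dihedral(p0, p1, p2, p3) -> float | None:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    nb1 = np.linalg.norm(b1)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9 or nb1 < 1e-9:
        return None  # collinear: dihedral undefined
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1 / nb1)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(model: StructureModel) -> pd.DataFrame:
    """Backbone phi/psi angles in degrees (NaN at termini or where backbone
    atoms are missing or degenerate)."""
    n = len(model.residues)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)

    def bb(i, name):
        a = model.residues[i].get_atom(name)
        return None if a is None else a.coords

    for i in range(n):
        Ni, CAi, Ci = bb(i, "N"), bb(i, "CA"), bb(i, "C")
        if i > 0 and all(v is not None for v in (bb(i - 1, "C"), Ni, CAi, Ci)):
            d = _dihedral(bb(i - 1, "C"), Ni, CAi, Ci)
            phi[i] = np.nan if d is None else d
        if i < n - 1 and all(v is not None for v in (Ni, CAi, Ci, bb(i + 1, "N"))):
            d = _dihedral(Ni, CAi, Ci, bb(i + 1, "N"))
            psi[i] = np.nan if d is None else d
    return pd.DataFrame({"Phi": phi, "Psi": psi}, index=range(n))


def depth_index(model: StructureModel, atom_sasa: np.ndarray) -> pd.DataFrame:
    """Depth-index statistics per residue.

    An atom's depth (dpx) is 0 when it is solvent accessible (SASA > 0) and
    otherwise its Euclidean distance to the nearest accessible atom. Four
    statistics per residue: mean and population SD over all atoms, and over
    side-chain atoms (0 when a residue has no side chain).
    """
    coords, owner = model.atom_coords()
    exposed = atom_sasa > 0
    if not exposed.any():
        raise ValueError("no surface: structure has zero accessible atoms")
    dpx = np.zeros(len(coords))
    buried = ~exposed
    if buried.any():
        tree = cKDTree(coords[exposed])
        d, _ = tree.query(coords[buried])
        dpx[buried] = d
    rows = []
    k = 0
    for res in model.residues:
        vals, side_vals = [], []
        for a in res.atoms:
            vals.append(dpx[k])
            if not a.is_mainchain:
                side_vals.append(dpx[k])
            k += 1
        va = np.asarray(vals)
        vs = np.asarray(side_vals)
        rows.append((
            float(va.mean()), float(va.std()),
            float(vs.mean()) if vs.size else 0.0,
            float(vs.std()) if vs.size else 0.0,
        ))
    return pd.DataFrame(rows, columns=list(STRUCT_CHANNELS[9:13]),
                        index=range(len(model.residues)))


def epitope_log_odds(model: StructureModel, neighbor_radius: float = 10.0,
                     lam: float = 0.1,
                     scores: dict[tuple[str, str], float] | None = None) -> np.ndarray:
    """Per-residue epitope log-odds.

    If ``scores`` (a precomputed external table keyed by (chain,
    author_number)) is given, those values are used verbatim. Otherwise an
    internal approximation smooths the embedded epitope propensity scale
    over CA neighbourhoods: mean propensity of residues whose CA lies within
    ``neighbor_radius`` of the target's CA, minus ``lam`` times the number
    of such neighbours (excluding the target) — a contact-number penalty
    that lowers buried residues.
    """
    n = len(model.residues)
    out = np.full(n, np.nan)
    if scores is not None:
        for i, res in enumerate(model.residues):
            key = (res.chain_id, res.author_number)
            if key in scores:
                out[i] = scores[key]
        return out
    ca = np.full((n, 3), np.nan)
    for i, res in enumerate(model.residues):
        a = res.get_atom("CA")
        if a is None:
            log.warning("residue %s has no CA; epitope log-odds skipped", res.author_number)
        else:
            ca[i] = a.coords
    ok = ~np.isnan(ca[:, 0])
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return out
    tree = cKDTree(ca[idx])
    prop = np.asarray([EPITOPE_PROPENSITY.get(model.residues[i].aa, 0.0) for i in idx])
    for pos, i in enumerate(idx):
        neigh = tree.query_ball_point(ca[i], neighbor_radius)
        out[i] = prop[neigh].mean() - lam * (len(neigh) - 1)
    return out


def residue_b_factor(residue: Residue) -> float:
    """Mean B-factor over a residue's atoms."""
    if not residue.atoms:
        raise ValueError(f"residue {residue.author_number} has no atoms")
    return float(np.mean([a.b_factor for a in residue.atoms]))


def residue_struct_features(
    model: StructureModel,
    cfg: SASAConfig | None = None,
    *,
    dssp: dict[tuple[str, str], dict[str, float | None]] | None = None,
    rsa: dict[tuple[str, str], dict[str, float]] | None = None,
    scores: dict[tuple[str, str], float] | None = None,
    atom_sasa: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the 14 structural channels for every residue of a chain.

    The ACC channel (water-accessible surface in the external secondary-
    structure tool's convention) is proxied by the residue all-atom SASA
    unless a DSSP table is injected, in which case DSSP acc/phi/psi override
    the internal values; an injected ``.rsa`` table overrides the five
    accessibility classes, and an injected score table the log-odds channel.
    Missing values are NaN.
    """
    cfg = cfg or SASAConfig()
    if atom_sasa is None:
        atom_sasa = shrake_rupley_sasa(model, cfg)
    acc = accessibility_classes(model, atom_sasa)
    dih = backbone_dihedrals(model)
    dpx = depth_index(model, atom_sasa)
    logodds = epitope_log_odds(model, scores=scores)
    bfac = [residue_b_factor(r) for r in model.residues]

    df = pd.concat([acc, dih, dpx], axis=1)
    df["ACC"] = acc["Absolute accessibility of all-atoms"].to_numpy()
    df["Log-odds ratio"] = logodds
    df["B factor"] = bfac

    for i, res in enumerate(model.residues):
        key = (res.chain_id, res.author_number)
        if rsa is not None and key in rsa:
            vals = rsa[key]
            df.loc[i, "Absolute accessibility of all-atoms"] = vals["acc_all"]
            df.loc[i, "Absolute accessibility of total side-chain"] = vals["acc_sidechain"]
            df.loc[i, "Absolute accessibility of main chain"] = vals["acc_mainchain"]
            df.loc[i, "Absolute accessibility of non-polar side-chain"] = vals["acc_nonpolar_sc"]
            df.loc[i, "Absolute accessibility of polar side-chain"] = vals["acc_polar_sc"]
        if dssp is not None and key in dssp:
            rec = dssp[key]
            df.loc[i, "ACC"] = rec["acc"]
            df.loc[i, "Phi"] = np.nan if rec["phi"] is None else rec["phi"]
            df.loc[i, "Psi"] = np.nan if rec["psi"] is None else rec["psi"]
    return df[list(STRUCT_CHANNELS)]
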