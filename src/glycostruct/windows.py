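"""Encode candidate sites as fixed-length named feature vectors.

Sequence context uses a sliding window of 2N+1 = 15 residues (the site at
position P8); PSSM log-odds over the window are flattened to PSSM_P1 ..
PSSM_P300. Structural context uses a sphere of radius R = 10 Angstrom: every
residue with any atom strictly closer than R to any atom of the target is a
window member, and the 14 structural channels are averaged over members
(NaN excluded channel-wise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .sequence_features import (
    AA_SCALES,
    PHYSCHEM_PROPERTIES,
    aaindex_value,
    conservation_score,
    physchem_vector,
)
from .structural_features import STRUCT_CHANNELS
from .types import PSSMProfile, SiteRecord, StructureModel


@dataclass
class WindowConfig:
    """Window geometry: sequence half-window N (window length 2N+1) and
    structure-sphere radius R in Angstrom."""

    half_window: int = 7
    radius: float = 10.0
    include_target: bool = True

    def __post_init__(self) -> None:
        if self.half_window < 0:
            raise ValueError("half_window must be >= 0")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def window_length(self) -> int:
        return 2 * self.half_window + 1


def sequence_window(sequence: str, i: int, half_window: int) -> str:
    """The 2N+1 residue window centered at ``i``, padded with 'X' beyond
    the termini."""
    if not 0 <= i < len(sequence):
        raise IndexError(f"site index {i} out of range")
    out = []
    for k in range(i - half_window, i + half_window + 1):
        out.append(sequence[k] if 0 <= k < len(sequence) else "X")
    return "".join(out)


def pssm_flat_index(p: int, a: int, window_length: int = 15) -> int:
    """Flatten (window position ``p`` in 1..2N+1, amino-acid column ``a`` in
    1..20) to the 1-based PSSM feature index: (p-1)*20 + a."""
    if not 1 <= p <= window_length:
        raise ValueError(f"window position {p} out of range 1..{window_length}")
    if not 1 <= a <= 20:
        raise ValueError(f"amino-acid column {a} out of range 1..20")
    return (p - 1) * 20 + a


def sequence_feature_names(cfg: WindowConfig | None = None) -> list[str]:
    """Feature names of the sequence block, in encoding order."""
    cfg = cfg or WindowConfig()
    w = cfg.window_length
    names = [f"PSSM_P{k}" for k in range(1, 20 * w + 1)]
    for scale_name in AA_SCALES:
        names += [f"{scale_name}_P{p}" for p in range(1, w + 1)]
    names += [f"Conservation score_P{p}" for p in range(1, w + 1)]
    center = cfg.half_window + 1
    names += [f"{prop}_P{center}" for prop in PHYSCHEM_PROPERTIES]
    return names


def encode_sequence_features(
    sequence: str, pssm: PSSMProfile, i: int, cfg: WindowConfig | None = None
) -> tuple[list[str], np.ndarray]:
    """Sequence-derived sub-vector for the site at ``i``.

    Concatenates, in fixed order: flattened PSSM log-odds over the window
    (20 per position), the four AAindex scales per position, the
    conservation score per position, and the 14 physicochemical properties
    of the central residue. Padded positions take neutral values (zero
    PSSM columns, scale means, conservation 0).
    """
    cfg = cfg or WindowConfig()
    if pssm.length != len(sequence):
        raise ValueError(
            f"sequence length {len(sequence)} != PSSM length {pssm.length}")
    window = sequence_window(sequence, i, cfg.half_window)
    positions = range(i - cfg.half_window, i + cfg.half_window + 1)
    in_range = [0 <= k < len(sequence) for k in positions]

    vals: list[float] = []
    for k, ok in zip(positions, in_range):
        vals.extend(pssm.logodds[k] if ok else np.zeros(20))
    for scale_name in AA_SCALES:
        vals.extend(aaindex_value(scale_name, aa) for aa in window)
    for k, ok in zip(positions, in_range):
        vals.append(conservation_score(pssm, k) if ok else 0.0)
    vals.extend(physchem_vector(sequence[i]))
    return sequence_feature_names(cfg), np.asarray(vals, dtype=float)


def structure_window(model: StructureModel, target: int, radius: float,
                     include_target: bool = True) -> set[int]:
    """Residues with any atom strictly closer than ``radius`` to any atom of
    the target residue (the target itself included by default)."""
    if not 0 <= target < len(model.residues):
        raise IndexError(f"target residue {target} out of range")
    coords, owner = model.atom_coords()
    t_coords = np.asarray([a.coords for a in model.residues[target].atoms])
    tree = cKDTree(coords)
    members: set[int] = set()
    for tc in t_coords:
        for j in tree.query_ball_point(tc, radius):
            if np.linalg.norm(coords[j] - tc) < radius:  # strict "<"
                members.add(int(owner[j]))
    members.discard(target)
    if include_target:
        members.add(target)
    return members


def encode_structural_features(
    model: StructureModel, struct_feats: pd.DataFrame, target: int,
    cfg: WindowConfig | None = None,
) -> tuple[list[str], np.ndarray]:
    """Structure-window average of the 14 channels for the target residue.

    Channels are averaged over window members with NaN excluded per channel;
    a channel missing for every member yields 0.
    """
    cfg = cfg or WindowConfig()
    members = sorted(structure_window(model, target, cfg.radius, cfg.include_target))
    block = struct_feats.loc[members, list(STRUCT_CHANNELS)].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(block, axis=0)
    means = np.nan_to_num(means, nan=0.0)
    return [f"{c}_P1" for c in STRUCT_CHANNELS], means


def encode_site(
    model: StructureModel, pssm: PSSMProfile, struct_feats: pd.DataFrame,
    site: SiteRecord, cfg: WindowConfig | None = None,
) -> tuple[list[str], np.ndarray]:
    """Full named feature vector for one site: sequence block then the 14
    structure-window-averaged channels."""
    cfg = cfg or WindowConfig()
    seq_names, seq_vals = encode_sequence_features(model.sequence, pssm, site.seq_index, cfg)
    str_names, str_vals = encode_structural_features(model, struct_feats, site.seq_index, cfg)
    return seq_names + str_names, np.concatenate([seq_vals, str_vals])


def encode_sites(
    proteins: list[dict], sites: list[SiteRecord], cfg: WindowConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Encode many sites into a feature matrix.

    ``proteins`` is a list of dicts with keys ``model`` (StructureModel),
    ``pssm`` (PSSMProfile) and optionally ``struct_feats`` (precomputed
    DataFrame; computed on demand otherwise). Returns a feature DataFrame
    indexed by (structure_id, chain, seq_index) and the aligned label
    series (NaN for unknown labels).
    """
    from .structural_features import residue_struct_features

    cfg = cfg or WindowConfig()
    by_id = {p["model"].structure_id: p for p in proteins}
    rows, labels, index = [], [], []
    names: list[str] | None = None
    for site in sites:
        p = by_id[site.structure_id]
        if "struct_feats" not in p:
            p["struct_feats"] = residue_struct_features(p["model"])
        n, v = encode_site(p["model"], p["pssm"], p["struct_feats"], site, cfg)
        if names is None:
            names = n
        rows.append(v)
        labels.append(np.nan if site.label is None else float(site.label))
        index.append(site.site_id)
    if not rows:
        return pd.DataFrame(), pd.Series(dtype=float)
    idx = pd.MultiIndex.from_tuples(index, names=["structure_id", "chain", "seq_index"])
    X = pd.DataFrame(rows, columns=names, index=idx)
    y = pd.Series(labels, index=idx, name="label")
    return X, y
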