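"""Solvent accessibility, dihedrals, depth index, epitope scores, B-factors."""

import numpy as np
import pandas as pd
import pytest

from glycostruct import (
    SASAConfig,
    accessibility_classes,
    backbone_dihedrals,
    depth_index,
    epitope_log_odds,
    residue_b_factor,
    residue_struct_features,
    shrake_rupley_sasa,
)
from glycostruct.structural_features import EPITOPE_PROPENSITY, STRUCT_CHANNELS, golden_spiral_points
from glycostruct.types import Atom, Residue, StructureModel


def single_atom_model(element="C", name="CA"):
    atom = Atom(name, element, np.zeros(3))
    return StructureModel("one", "A", [Residue("A", 0, "1", "A", [atom])])


def model_from_atoms(atom_specs, aa="A"):
    """atom_specs: list of residues, each a list of (name, element, xyz[, b])."""
    residues = []
    for i, spec in enumerate(atom_specs):
        atoms = [Atom(s[0], s[1], np.asarray(s[2], float),
                      s[3] if len(s) > 3 else 0.0) for s in spec]
        residues.append(Residue("A", i, str(i + 1), aa, atoms))
    return StructureModel("fix", "A", residues)


def latlong_grid_sasa(center, radius, other_centers, other_radii,
                      n_theta=100, n_phi=200):
    """Brute-force SASA of one sphere by solid-angle-weighted lat-long grid
    occupancy (independent of the spiral point sampling)."""
    thetas = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    phis = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    acc = tot = 0.0
    others = np.asarray(other_centers, float)
    r2 = np.asarray(other_radii, float) ** 2
    for t in thetas:
        w = np.sin(t)
        dirs = np.column_stack([
            np.sin(t) * np.cos(phis), np.sin(t) * np.sin(phis),
            np.full(n_phi, np.cos(t))])
        pts = center + radius * dirs
        if len(others):
            d2 = ((pts[:, None, :] - others[None]) ** 2).sum(-1)
            free = ~(d2 < r2[None, :]).any(axis=1)
        else:
            free = np.ones(n_phi, bool)
        acc += w * free.sum()
        tot += w * n_phi
    return 4.0 * np.pi * radius**2 * acc / tot


class TestShrakeRupley:
    def test_isolated_atom_matches_analytic_sphere(self):
        sasa = shrake_rupley_sasa(single_atom_model())
        analytic = 4.0 * np.pi * (1.87 + 3.0) ** 2
        assert sasa[0] == pytest.approx(analytic, rel=0.02)

    def test_distant_atoms_get_full_spheres(self):
        m = model_from_atoms([
            [("CA", "C", (0, 0, 0))],
            [("CA", "C", (30.0, 0, 0))],  # > 2*(1.87+3.0)
        ])
        sasa = shrake_rupley_sasa(m)
        analytic = 4.0 * np.pi * (1.87 + 3.0) ** 2
        assert np.allclose(sasa, analytic, rtol=0.02)

    def test_caged_atom_agrees_with_grid_oracle(self):
        """Central atom inside a two-shell cage: point-sampled SASA matches
        the independent lat-long occupancy oracle within 5% of sphere area."""
        shells = []
        for shell_r, n in ((4.0, 30), (7.0, 60)):
            shells.append(shell_r * golden_spiral_points(n))
        blockers = np.vstack(shells)
        specs = [[("CA", "C", (0.0, 0.0, 0.0))]]
        specs += [[("CA", "C", tuple(c))] for c in blockers]
        m = model_from_atoms(specs)
        sasa = shrake_rupley_sasa(m)
        r_exp = 1.87 + 3.0
        oracle = latlong_grid_sasa(np.zeros(3), r_exp, blockers,
                                   np.full(len(blockers), r_exp))
        sphere = 4.0 * np.pi * r_exp**2
        assert abs(sasa[0] - oracle) <= 0.05 * sphere
        assert sasa[0] <= 0.02 * sphere  # cage encloses the centre

    def test_partial_burial_agrees_with_grid_oracle(self):
        blockers = np.array([[4.0, 0, 0], [0, 4.0, 0], [0, 0, 4.0]])
        specs = [[("CA", "C", (0.0, 0.0, 0.0))]]
        specs += [[("CA", "C", tuple(c))] for c in blockers]
        m = model_from_atoms(specs)
        sasa = shrake_rupley_sasa(m)
        r_exp = 1.87 + 3.0
        oracle = latlong_grid_sasa(np.zeros(3), r_exp, blockers,
                                   np.full(3, r_exp))
        assert abs(sasa[0] - oracle) <= 0.05 * 4.0 * np.pi * r_exp**2

    def test_sasa_conservation_and_monotonicity(self, globule60):
        sasa = shrake_rupley_sasa(globule60)
        acc = accessibility_classes(globule60, sasa)
        assert acc["Absolute accessibility of all-atoms"].sum() == \
            pytest.approx(sasa.sum(), rel=1e-6)

    def test_adding_atom_never_increases_sasa(self):
        m1 = model_from_atoms([[("CA", "C", (0, 0, 0))], [("CA", "C", (4, 0, 0))]])
        m2 = model_from_atoms([[("CA", "C", (0, 0, 0))], [("CA", "C", (4, 0, 0))],
                               [("CA", "C", (2.0, 2.0, 0))]])
        s1 = shrake_rupley_sasa(m1)
        s2 = shrake_rupley_sasa(m2)
        assert np.all(s2[:2] <= s1 + 1e-9)

    def test_doubling_points_converges(self, helix20):
        s1 = shrake_rupley_sasa(helix20, SASAConfig(n_sphere_points=960))
        s2 = shrake_rupley_sasa(helix20, SASAConfig(n_sphere_points=1920))
        sphere = 4.0 * np.pi * 4.87**2
        assert np.abs(s1 - s2).max() < 0.03 * sphere  # per-atom discretization
        assert abs(s1.sum() - s2.sum()) / s2.sum() < 0.01  # total converged

    def test_agrees_with_independent_shrake_rupley(self, globule60):
        """Cross-check against biotite's Shrake-Rupley with matched radii."""
        biotite_struc = pytest.importorskip("biotite.structure")
        import biotite.structure as struc

        coords, _ = globule60.atom_coords()
        n = len(coords)
        arr = struc.AtomArray(n)
        arr.coord = coords.astype(np.float32)
        k = 0
        for res in globule60.residues:
            for a in res.atoms:
                arr.element[k] = a.element
                arr.res_id[k] = res.seq_index + 1
                arr.atom_name[k] = a.name
                arr.res_name[k] = "ALA"
                arr.chain_id[k] = "A"
                k += 1
        radii = np.array([{"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85}[e]
                          for e in arr.element], dtype=np.float32)
        ref = struc.sasa(arr, probe_radius=3.0, vdw_radii=radii, point_number=960)
        mine = shrake_rupley_sasa(globule60)
        # identical algorithm, different point sets: small per-atom scatter
        assert np.abs(mine - ref).max() < 0.05 * 4 * np.pi * 4.87**2
        assert abs(mine.sum() - ref.sum()) / ref.sum() < 0.02

    def test_empty_model_raises(self):
        with pytest.raises(ValueError):
            shrake_rupley_sasa(StructureModel("x", "A", []))


class TestAccessibilityClasses:
    def test_hand_computed_sums(self):
        m = model_from_atoms([[
            ("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)),
            ("C", "C", (2.5, 1, 0)), ("O", "O", (2.4, 2.2, 0)),
            ("CB", "C", (2, -1, 1)),
        ]])
        sasa = np.array([5.0, 10.0, 0.0, 3.0, 7.0])
        acc = accessibility_classes(m, sasa).iloc[0]
        assert acc["Absolute accessibility of all-atoms"] == 25.0
        assert acc["Absolute accessibility of main chain"] == 18.0
        assert acc["Absolute accessibility of total side-chain"] == 7.0
        assert acc["Absolute accessibility of non-polar side-chain"] == 7.0
        assert acc["Absolute accessibility of polar side-chain"] == 0.0

    def test_glycine_has_zero_side_chain(self):
        m = model_from_atoms([[("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)),
                               ("C", "C", (2.5, 1, 0)), ("O", "O", (2.4, 2.2, 0))]],
                             aa="G")
        acc = accessibility_classes(m, np.array([1.0, 2, 3, 4])).iloc[0]
        assert acc["Absolute accessibility of total side-chain"] == 0.0
        assert acc["Absolute accessibility of non-polar side-chain"] == 0.0

    def test_polar_plus_nonpolar_bounded_by_side_chain(self, globule60):
        sasa = shrake_rupley_sasa(globule60)
        acc = accessibility_classes(globule60, sasa)
        assert np.all(
            acc["Absolute accessibility of non-polar side-chain"]
            + acc["Absolute accessibility of polar side-chain"]
            <= acc["Absolute accessibility of total side-chain"] + 1e-9)


class TestDihedrals:
    def test_ideal_helix_angles(self, helix20):
        d = backbone_dihedrals(helix20)
        interior = d.iloc[1:-1]
        assert np.allclose(interior["Phi"], -57.0, atol=2.0)
        assert np.allclose(interior["Psi"], -47.0, atol=2.0)

    def test_termini_missing(self, helix20):
        d = backbone_dihedrals(helix20)
        assert np.isnan(d["Phi"].iloc[0])
        assert np.isnan(d["Psi"].iloc[-1])

    def test_collinear_atoms_give_missing(self):
        m = model_from_atoms([
            [("N", "N", (0, 0, 0)), ("CA", "C", (1, 0, 0)), ("C", "C", (2, 0, 0))],
            [("N", "N", (3, 0, 0)), ("CA", "C", (4, 0, 0)), ("C", "C", (5, 0, 0))],
        ])
        d = backbone_dihedrals(m)
        assert np.isnan(d["Psi"].iloc[0])
        assert np.isnan(d["Phi"].iloc[1])


class TestDepthIndex:
    def test_fully_exposed_residue_is_zero(self):
        m = model_from_atoms([[("CA", "C", (0, 0, 0)), ("CB", "C", (3, 0, 0))]])
        sasa = np.array([10.0, 12.0])
        d = depth_index(m, sasa).iloc[0]
        assert (d == 0).all()

    def test_single_buried_atom_distance(self):
        m = model_from_atoms([[
            ("N", "N", (0, 0, 0)), ("CA", "C", (2.5, 0, 0)),
        ]])
        sasa = np.array([4.0, 0.0])  # CA buried, N exposed at 2.5 A
        d = depth_index(m, sasa).iloc[0]
        assert d["Average depth index"] == pytest.approx(2.5 / 2)
        assert d["Standard deviation of depth index"] == pytest.approx(1.25)

    def test_matches_all_pairs_oracle(self, globule60):
        sub = StructureModel("sub", "A", [
            Residue("A", i, str(i + 1), r.aa,
                    [Atom(a.name, a.element, a.coords, a.b_factor) for a in r.atoms])
            for i, r in enumerate(globule60.residues[:10])])
        sasa = shrake_rupley_sasa(sub)
        coords, owner = sub.atom_coords()
        exposed = sasa > 0
        oracle = np.zeros(len(coords))
        for i in range(len(coords)):
            if not exposed[i]:
                oracle[i] = min(np.linalg.norm(coords[i] - coords[j])
                                for j in range(len(coords)) if exposed[j])
        got = depth_index(sub, sasa)
        mean_oracle = [oracle[owner == r].mean() for r in range(len(sub.residues))]
        assert np.allclose(got["Average depth index"], mean_oracle, atol=1e-9)

    def test_no_surface_raises(self):
        m = model_from_atoms([[("CA", "C", (0, 0, 0))]])
        with pytest.raises(ValueError, match="no surface"):
            depth_index(m, np.array([0.0]))


class TestEpitopeLogOdds:
    def test_isolated_residue_scores_own_propensity(self):
        m = model_from_atoms([[("CA", "C", (0, 0, 0))]], aa="K")
        v = epitope_log_odds(m)
        assert v[0] == pytest.approx(EPITOPE_PROPENSITY["K"])

    def test_pair_mean_minus_contact_penalty(self):
        m = StructureModel("p", "A", [
            Residue("A", 0, "1", "K", [Atom("CA", "C", (0, 0, 0))]),
            Residue("A", 1, "2", "I", [Atom("CA", "C", (5.0, 0, 0))]),
        ])
        v = epitope_log_odds(m, neighbor_radius=10.0, lam=0.1)
        expected = (EPITOPE_PROPENSITY["K"] + EPITOPE_PROPENSITY["I"]) / 2 - 0.1
        assert np.allclose(v, expected)

    def test_injected_scores_override(self):
        m = model_from_atoms([[("CA", "C", (0, 0, 0))]], aa="K")
        v = epitope_log_odds(m, scores={("A", "1"): -9.596})
        assert v[0] == pytest.approx(-9.596)


class TestResidueBFactor:
    def test_mean_of_two(self):
        r = Residue("A", 0, "1", "A", [Atom("N", "N", (0, 0, 0), 10.0),
                                       Atom("CA", "C", (1.5, 0, 0), 20.0)])
        assert residue_b_factor(r) == pytest.approx(15.0)

    def test_single_atom(self):
        r = Residue("A", 0, "1", "A", [Atom("CA", "C", (0, 0, 0), 7.5)])
        assert residue_b_factor(r) == pytest.approx(7.5)


class TestAssembly:
    def test_fourteen_named_channels(self, globule60):
        df = residue_struct_features(globule60)
        assert list(df.columns) == list(STRUCT_CHANNELS)
        assert len(df) == len(globule60.residues)

    def test_injected_tables_override_verbatim(self, globule60):
        keys = [(r.chain_id, r.author_number) for r in globule60.residues]
        rsa = {k: {"acc_all": 11.0, "acc_sidechain": 5.0, "acc_mainchain": 6.0,
                   "acc_nonpolar_sc": 3.0, "acc_polar_sc": 2.0} for k in keys}
        dssp = {k: {"acc": 42.0, "phi": -60.0, "psi": -45.0} for k in keys}
        scores = {k: -9.5 for k in keys}
        df = residue_struct_features(globule60, dssp=dssp, rsa=rsa, scores=scores)
        assert (df["Absolute accessibility of all-atoms"] == 11.0).all()
        assert (df["ACC"] == 42.0).all()
        assert (df["Phi"] == -60.0).all()
        assert (df["Log-odds ratio"] == -9.5).all()

    def test_acc_proxy_defaults_to_all_atom_sasa(self, globule60):
        df = residue_struct_features(globule60)
        assert np.allclose(df["ACC"], df["Absolute accessibility of all-atoms"])
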