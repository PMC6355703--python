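"""Gasteiger charges and interaction fingerprints."""
import numpy as np
import pytest

from modedock import fingerprint as fpm
from modedock import structio as st
from modedock import synthetic as syn
from modedock._geometry import quat_to_matrix

from conftest import toy_structure


def water(offset=(0.0, 0.0, 0.0)):
    o = np.asarray(offset, dtype=float)
    coords = np.array([[0, 0, 0], [0.9572, 0, 0], [-0.24, 0.9266, 0]]) + o
    return st.Structure(
        coords=coords, names=["O", "H1", "H2"], elements=["O", "H", "H"],
        res_names=["HOH"] * 3, res_numbers=[1] * 3, chain_ids=["W"] * 3, hetero=[True] * 3,
    )


class TestGasteiger:
    def test_neutral_molecule_sums_to_zero(self):
        w = water()
        cs = fpm.gasteiger_charges(w)
        assert cs.total == pytest.approx(0.0, abs=1e-6)
        assert cs.charges[0] < 0 < cs.charges[1]  # O negative, H positive

    def test_symmetric_hydrogens_equal(self):
        # symmetric O-H bonds: both hydrogens see the same environment
        coords = np.array([[0, 0, 0], [0.9572, 0, 0], [-0.9572, 0, 0]])
        w = st.Structure(
            coords=coords, names=["O", "H1", "H2"], elements=["O", "H", "H"],
            res_names=["HOH"] * 3, res_numbers=[1] * 3, chain_ids=["W"] * 3,
        )
        cs = fpm.gasteiger_charges(w)
        assert cs.charges[1] == pytest.approx(cs.charges[2], abs=1e-6)

    def test_charged_molecule_conserves_formal_charge(self, helix_peptide):
        cs = fpm.gasteiger_charges(helix_peptide)
        assert cs.total == pytest.approx(float(helix_peptide.formal_charges.sum()), abs=1e-4)

    def test_damping_shrinks_transfers_geometrically(self):
        """Per-iteration max charge shift decreases like the (1/2)^n damping."""
        w = syn.build_peptide("AA", conformation="extended", amidated=False)
        adj = fpm._connectivity(w)
        from modedock import _chem

        types = [_chem.gasteiger_type(str(w.elements[i]), len(adj[i])) for i in range(w.n_atoms)]
        params = np.array([_chem.GASTEIGER_PARAMS[t] for t in types])
        a, b, c = params[:, 0], params[:, 1], params[:, 2]
        chi_plus = np.where(np.array([t == "H" for t in types]), _chem.GASTEIGER_CHI_PLUS_H, a + b + c)
        q = w.formal_charges.astype(float).copy()
        damp, shifts = 1.0, []
        for _ in range(8):
            damp *= 0.5
            chi = a + b * q + c * q * q
            dq = np.zeros(len(q))
            for i in range(len(q)):
                for j in adj[i]:
                    if j < i:
                        continue
                    hi, lo = (i, j) if chi[i] > chi[j] else (j, i)
                    t = (chi[hi] - chi[lo]) / chi_plus[lo] * damp
                    dq[lo] += t
                    dq[hi] -= t
            q += dq
            shifts.append(np.abs(dq).max())
        assert all(s2 < s1 for s1, s2 in zip(shifts, shifts[1:]))
        assert shifts[-1] < 1e-2
        cs = fpm.gasteiger_charges(w)
        assert cs.converged
        assert np.allclose(cs.charges, q, atol=1e-12)

    def test_unparameterised_element_rejected(self):
        s = st.Structure(
            coords=[[0, 0, 0]], names=["FE"], elements=["FE"], res_names=["HEM"],
            res_numbers=[1], chain_ids=["A"], hetero=[True],
        )
        with pytest.raises(TypeError):
            fpm.gasteiger_charges(s)


class TestAnalyzePose:
    def test_distant_molecules_all_zero(self):
        a, b, _ = syn.make_interaction_complex({"salt_bridges": 1}, seed=0)
        far = b.with_coords(b.coords + [0.0, 200.0, 0.0])
        fp = fpm.analyze_pose(a, far)
        assert fp.hbonds == fp.salt_bridges == fp.cation_pi == 0
        assert fp.pi_stacking == fp.t_stacking == fp.hydrophobic_contacts == 0
        assert fp.summed_electrostatic == 0.0

    def test_salt_bridge_with_negative_energy(self):
        a, b, _ = syn.make_interaction_complex({"salt_bridges": 1}, seed=0)
        fp = fpm.analyze_pose(a, b)
        assert fp.salt_bridges == 1
        assert fp.summed_electrostatic < 0

    @pytest.mark.parametrize(
        "request_counts",
        [
            {"hbonds": 6, "salt_bridges": 2},
            {"cation_pi": 1},
            {"pi_stacking": 1},
            {"t_stacking": 1},
            {"hydrophobic_contacts": 3},
            {"hbonds": 2, "salt_bridges": 1, "cation_pi": 1, "hydrophobic_contacts": 2},
            {},
        ],
    )
    def test_constructed_complex_recovered_exactly(self, request_counts):
        a, b, expected = syn.make_interaction_complex(request_counts, seed=11)
        fp = fpm.analyze_pose(a, b)
        for attr in ("hbonds", "salt_bridges", "cation_pi", "pi_stacking", "t_stacking", "hydrophobic_contacts"):
            assert getattr(fp, attr) == getattr(expected, attr), attr
        assert fp.summed_electrostatic == pytest.approx(expected.summed_electrostatic, abs=1e-9)

    def test_perpendicular_and_parallel_benzene(self):
        from modedock.synthetic import _ring

        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")

        def phe(center, normal, chain, phase=0.0):
            pts = _ring(center, normal, phase)
            return st.Structure(
                coords=pts, names=list(names), elements=["C"] * 6, res_names=["PHE"] * 6,
                res_numbers=[1] * 6, chain_ids=[chain] * 6,
                partial_charges=np.zeros(6),
            )

        perp = fpm.analyze_pose(phe([0, 0, 0], [0, 0, 1], "A"), phe([0, 0, 4.8], [0, 1, 0], "B"))
        assert perp.t_stacking == 1 and perp.pi_stacking == 0
        par = fpm.analyze_pose(phe([0, 0, 0], [0, 0, 1], "A"), phe([0, 0, 3.8], [0, 0, 1], "B", phase=30))
        assert par.pi_stacking == 1 and par.t_stacking == 0

    def test_two_apolar_carbons_hydrophobic(self):
        a = toy_structure([[0, 0, 0]], res_names=["LEU"], names=["CD1"], chain="A", charges=np.zeros(1))
        b = toy_structure([[3.8, 0, 0]], res_names=["LEU"], names=["CD1"], chain="B", charges=np.zeros(1))
        fp = fpm.analyze_pose(a, b)
        assert fp.hydrophobic_contacts == 1

    def test_symmetric_in_roles(self):
        a, b, _ = syn.make_interaction_complex(
            {"hbonds": 1, "salt_bridges": 1, "hydrophobic_contacts": 2}, seed=4
        )
        fwd = fpm.analyze_pose(a, b)
        rev = fpm.analyze_pose(b, a)
        for attr in ("salt_bridges", "cation_pi", "pi_stacking", "t_stacking", "hydrophobic_contacts", "hbonds"):
            assert getattr(fwd, attr) == getattr(rev, attr), attr
        assert fwd.summed_electrostatic == pytest.approx(rev.summed_electrostatic, abs=1e-9)

    def test_counts_non_increasing_when_cutoffs_tighten(self):
        a, b, _ = syn.make_interaction_complex(
            {"hbonds": 2, "salt_bridges": 1, "cation_pi": 1, "hydrophobic_contacts": 3}, seed=2
        )
        loose = fpm.analyze_pose(a, b)
        tight = fpm.analyze_pose(
            a, b,
            fpm.FingerprintParams(
                hbond_dist=2.5, salt_bridge_dist=3.0, cation_pi_dist=4.0,
                pi_stack_dist=5.0, t_stack_dist=4.0, hydrophobic_dist=3.0, elec_dist=3.0,
            ),
        )
        for attr in ("hbonds", "salt_bridges", "cation_pi", "pi_stacking", "t_stacking", "hydrophobic_contacts"):
            assert getattr(tight, attr) <= getattr(loose, attr), attr

    def test_energy_invariant_under_rigid_transform(self):
        a, b, _ = syn.make_interaction_complex({"salt_bridges": 2, "hbonds": 1}, seed=6)
        rng = np.random.default_rng(9)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        rot = quat_to_matrix(q)
        shift = np.array([4.0, -8.0, 2.5])
        a2 = a.with_coords(a.coords @ rot.T + shift)
        b2 = b.with_coords(b.coords @ rot.T + shift)
        f1 = fpm.analyze_pose(a, b)
        f2 = fpm.analyze_pose(a2, b2)
        assert f1.summed_electrostatic == pytest.approx(f2.summed_electrostatic, abs=1e-9)
        assert f1.salt_bridges == f2.salt_bridges and f1.hbonds == f2.hbonds

    def test_missing_charges_is_state_error(self):
        a = toy_structure([[0, 0, 0]], chain="A")
        b = toy_structure([[5, 0, 0]], chain="B")
        with pytest.raises(RuntimeError):
            fpm.analyze_pose(a, b)


class TestSiteEngagement:
    def test_no_contacts_empty_maps(self):
        a, b, _ = syn.make_interaction_complex({}, seed=0)
        fp = fpm.analyze_pose(a, b)
        sites = [
            st.BindingSite(
                selection=st.Selection(frozenset(a.unique_residues()), "all"),
                defining_ligand=st.Selection(frozenset()), site_name="N-site",
            )
        ]
        out = fpm.site_engagement(fp, sites)
        assert out["N-site"] == {} and out["other"] == {}

    def test_single_site_residue_attributed(self):
        a, b, _ = syn.make_interaction_complex({"salt_bridges": 1, "hydrophobic_contacts": 1}, seed=1)
        fp = fpm.analyze_pose(a, b)
        arg_res = [k for k in a.unique_residues() if str(a.res_names[a.residue_mask([k])>0][0] if False else "x")]
        # the ARG station is residue 1 of molecule A
        arg_key = a.unique_residues()[0]
        sites = [
            st.BindingSite(
                selection=st.Selection(frozenset({arg_key}), "N"), site_name="N-site",
                defining_ligand=st.Selection(frozenset()),
            )
        ]
        out = fpm.site_engagement(fp, sites)
        assert arg_key in out["N-site"]
        assert "salt_bridge" in out["N-site"][arg_key]
        # completeness: everything interacting is in a site or "other"
        reported = set(out["N-site"]) | set(out["other"])
        assert reported == set(fp.contacts_by_residue)


class TestStericOverlap:
    def test_disjoint_structures_empty(self):
        a = toy_structure([[0, 0, 0]], chain="A")
        b = toy_structure([[20.0, 0, 0]], chain="B")
        rep = fpm.steric_overlap(a, b)
        assert rep.n_clashes == 0 and rep.overlap_volume == 0.0

    def test_full_overlap_equals_sphere_volume(self):
        a = toy_structure([[0, 0, 0]], chain="A")
        b = toy_structure([[0, 0, 0]], chain="B")
        rep = fpm.steric_overlap(a, b, grid_spacing=0.15)
        sphere = 4.0 / 3.0 * np.pi * 1.7 ** 3
        assert rep.overlap_volume == pytest.approx(sphere, rel=0.02)
        assert rep.n_clashes == 1

    def test_partial_overlap_matches_mc_oracle(self):
        d = 1.5
        a = toy_structure([[0, 0, 0]], chain="A")
        b = toy_structure([[d, 0, 0]], chain="B")
        rep = fpm.steric_overlap(a, b, grid_spacing=0.15)
        rng = np.random.default_rng(21)
        lo, hi = np.array([-1.7, -1.7, -1.7]), np.array([d + 1.7, 1.7, 1.7])
        pts = rng.uniform(lo, hi, size=(1_000_000, 3))
        inside = (np.linalg.norm(pts, axis=1) < 1.7) & (np.linalg.norm(pts - [d, 0, 0], axis=1) < 1.7)
        mc = inside.mean() * np.prod(hi - lo)
        assert rep.overlap_volume == pytest.approx(mc, rel=0.02)
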