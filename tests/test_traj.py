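"""Trajectory analytics: RMSD/RMSF, H-bonds, secondary structure, clustering."""
import numpy as np
import pytest

from modedock import structio as st
from modedock import synthetic as syn
from modedock import traj as tj

from conftest import random_rotation, toy_structure
from test_structio import quaternion_superpose


def polar_frame(d_pos, a_pos, h_pos=None):
    """Tiny two-residue system with a serine donor and glutamine acceptor."""
    names = ["CB", "OG", "OE1", "CD"]
    elements = ["C", "O", "O", "C"]
    res_names = ["SER", "SER", "GLN", "GLN"]
    res_numbers = [1, 1, 2, 2]
    coords = [np.asarray(d_pos) - [0, 1.43, 0], d_pos, a_pos, np.asarray(a_pos) + [0, 1.23, 0]]
    if h_pos is not None:
        names.append("HG")
        elements.append("H")
        res_names.append("SER")
        res_numbers.append(1)
        coords.append(h_pos)
    return st.Structure(
        coords=np.array(coords, dtype=float), names=names, elements=elements,
        res_names=res_names, res_numbers=res_numbers, chain_ids=["A"] * len(names),
    )


class TestKabschRmsd:
    def test_identical_frames_zero(self, helix_peptide):
        assert tj.kabsch_rmsd(helix_peptide.coords, helix_peptide.coords) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_invariance(self, helix_peptide):
        rng = np.random.default_rng(1)
        rot = random_rotation(rng)
        moved = helix_peptide.coords @ rot.T + [3.0, 4.0, -7.0]
        assert tj.kabsch_rmsd(helix_peptide.coords, moved) < 1e-9

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(-5, 5, (12, 3))
        b = a + rng.normal(0, 0.5, a.shape)
        assert tj.kabsch_rmsd(a, b) == pytest.approx(quaternion_superpose(a, b), abs=1e-9)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tj.kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRmsf:
    def test_static_trajectory_all_zero(self, helix_peptide):
        t = tj.Trajectory(helix_peptide, np.stack([helix_peptide.coords] * 5))
        keys, rmsf = tj.rmsf_profile(t)
        assert np.allclose(rmsf, 0.0, atol=1e-12)

    def test_single_frame_rejected(self, helix_peptide):
        t = tj.Trajectory(helix_peptide, helix_peptide.coords[None])
        with pytest.raises(ValueError):
            tj.rmsf_profile(t)

    def test_alternating_displacement_closed_form(self):
        # a heavy, superposition-neutral scaffold plus one CA flickering +-d:
        # the scaffold pins the alignment so RMSF(CA) = d exactly
        base = np.array(
            [[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10], [10, 10, 0], [10, 0, 10], [5, 5, 5]],
            dtype=float,
        )
        s = st.Structure(
            coords=base, names=["CA"] * 7, elements=["C"] * 7, res_names=["GLY"] * 7,
            res_numbers=list(range(1, 8)), chain_ids=["A"] * 7,
        )
        d = 0.4
        frames = []
        for f in range(20):
            c = base.copy()
            c[6, 0] += d if f % 2 == 0 else -d
            frames.append(c)
        t = tj.Trajectory(s, np.stack(frames))
        scaffold = st.Selection(frozenset({("A", i, "") for i in range(1, 7)}))
        keys, rmsf = tj.rmsf_profile(t, subset=scaffold)
        # oracle: direct per-atom formula on raw coordinates (alignment is
        # the identity because the scaffold never moves)
        stack = np.stack(frames)
        mean = stack.mean(axis=0)
        direct = np.sqrt(((stack - mean) ** 2).sum(axis=2).mean(axis=0))
        assert np.allclose(rmsf, direct, atol=1e-9)
        assert rmsf[6] == pytest.approx(d, abs=1e-9)


class TestDetectHbonds:
    def test_collinear_bond_detected(self):
        bonds = tj.detect_hbonds(*self._frame(2.9))
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9)
        assert bonds[0].angle_deviation <= 1e-9

    def test_distance_boundary(self):
        assert len(tj.detect_hbonds(*self._frame(3.1))) == 0
        assert len(tj.detect_hbonds(*self._frame(3.0))) == 1  # inclusive

    @pytest.mark.parametrize("theta,expected", [(25.0, 0), (15.0, 1)])
    def test_angle_boundary(self, theta, expected):
        # acceptor placed so the D-H...A deviation AT the hydrogen is theta
        h = np.array([0.96, 0.0, 0.0])
        a = h + 2.0 * np.array([np.cos(np.radians(theta)), np.sin(np.radians(theta)), 0.0])
        assert np.linalg.norm(a) <= 3.0  # distance criterion stays satisfied
        s = polar_frame([0, 0, 0], a, h_pos=h)
        assert len(tj.detect_hbonds(s.coords, s)) == expected

    @staticmethod
    def _frame(d):
        return (lambda s: (s.coords, s))(polar_frame([0, 0, 0], [d, 0, 0]))

    def test_matches_brute_force_on_peptide(self, helix_peptide):
        bonds = tj.detect_hbonds(helix_peptide.coords, helix_peptide)
        # brute-force oracle: all donor/acceptor template pairs, explicit H
        from modedock import _chem

        donors, acceptors = [], []
        keys = helix_peptide.residue_keys()
        for i in range(helix_peptide.n_atoms):
            rn, an = str(helix_peptide.res_names[i]), str(helix_peptide.names[i])
            if rn in _chem.PROTEIN_RESIDUES and an == "N" and rn != "PRO":
                donors.append(i)
            elif an in _chem.SIDECHAIN_DONORS.get(rn, {}):
                donors.append(i)
            if an in ("O", "OXT") or an in _chem.SIDECHAIN_ACCEPTORS.get(rn, set()):
                acceptors.append(i)
        expected = set()
        for di in donors:
            hs = [
                j for j in range(helix_peptide.n_atoms)
                if helix_peptide.elements[j] == "H" and keys[j] == keys[di]
                and np.linalg.norm(helix_peptide.coords[j] - helix_peptide.coords[di]) < 1.25
            ]
            for ai in acceptors:
                if keys[ai] == keys[di]:
                    continue
                d = np.linalg.norm(helix_peptide.coords[ai] - helix_peptide.coords[di])
                if d > 3.0:
                    continue
                devs = []
                for h in hs:
                    u = helix_peptide.coords[h] - helix_peptide.coords[di]
                    v = helix_peptide.coords[ai] - helix_peptide.coords[h]
                    cos = u @ v / np.linalg.norm(u) / np.linalg.norm(v)
                    devs.append(np.degrees(np.arccos(np.clip(cos, -1, 1))))
                if hs and min(devs) <= 20.0:
                    expected.add((keys[di], keys[ai]))
        got = {((b.donor[0], b.donor[1], b.donor[2]), (b.acceptor[0], b.acceptor[1], b.acceptor[2]))
               for b in bonds if b.hydrogen is not None}
        # restrict comparison to explicit-hydrogen bonds (the oracle has no
        # ideal-placement branch)
        assert expected <= got

    def test_inter_scope_far_selections_empty(self, helix_peptide):
        far = helix_peptide.with_coords(helix_peptide.coords + [100.0, 0, 0])
        far.chain_ids = np.full(far.n_atoms, "B", dtype=far.chain_ids.dtype)
        merged = helix_peptide.concat(far)
        sel_a = st.Selection(frozenset(k for k in merged.unique_residues() if k[0] == "A"))
        sel_b = st.Selection(frozenset(k for k in merged.unique_residues() if k[0] == "B"))
        bonds = tj.detect_hbonds(merged.coords, merged, scope="inter", groups=(sel_a, sel_b))
        assert bonds == []


@pytest.fixture(scope="module")
def controlled(extended_peptide):
    bonds = {
        (("A", 15, "N"), ("A", 5, "O")): 54.5,
        (("A", 7, "N"), ("A", 13, "O")): 100.0,
        (("A", 3, "N"), ("A", 11, "O")): 5.0,
    }
    return syn.make_traj_with_occupancy(extended_peptide, bonds, n_frames=200, noise=0.12, seed=3)


class TestOccupancy:
    def test_exact_target_recovery(self, controlled):
        rows = tj.hbond_occupancy(controlled, min_occupancy=10.0)
        by_label = {(r.donor_label, r.acceptor_label): r.occupancy for r in rows}
        assert by_label[("LEU15-Main-N", "THR5-Main-O")] == pytest.approx(54.5)
        assert by_label[("THR7-Main-N", "THR13-Main-O")] == pytest.approx(100.0)

    def test_low_occupancy_filtered(self, controlled):
        rows = tj.hbond_occupancy(controlled, min_occupancy=10.0)
        assert not any("3-Main-N" in r.donor_label.split("-")[0] + "-" + r.donor_label.split("-")[1] for r in rows)
        rows_all = tj.hbond_occupancy(controlled, min_occupancy=0.0)
        labels = {r.donor_label for r in rows_all}
        assert "SER3-Main-N" in labels

    def test_rows_sorted_by_donor_residue(self, controlled):
        rows = tj.hbond_occupancy(controlled, min_occupancy=10.0)
        nums = [int("".join(c for c in r.donor_label.split("-")[0] if c.isdigit())) for r in rows]
        assert nums == sorted(nums)

    def test_bit_reproducible(self, controlled):
        a = tj.hbond_occupancy(controlled, min_occupancy=10.0)
        b = tj.hbond_occupancy(controlled, min_occupancy=10.0)
        assert a == b


class TestSecondaryStructure:
    def test_ideal_helix_interior_h(self):
        p = syn.build_peptide("RSSQTITHGNGNTYLY", conformation="helix")
        labels = tj.assign_secondary_structure(p.coords, p).labels
        assert set(labels[2:-2]) == {"H"}

    def test_extended_single_strand_no_e(self):
        p = syn.build_peptide("RSSQTITHGNGNTYLY", conformation="extended")
        labels = tj.assign_secondary_structure(p.coords, p).labels
        assert "E" not in labels and "B" not in labels
        assert set(labels) <= {"C", "T"}

    def test_hairpin_strands_in_register(self):
        p = syn.build_peptide("RSSTSLLHGNGNTYLT", conformation="hairpin")
        labels = tj.assign_secondary_structure(p.coords, p).labels
        # the SLL (5-7) and TYL (13-15) stretches pair as the beta-sheet
        assert all(labels[i] == "E" for i in (4, 5, 6))
        assert all(labels[i] == "E" for i in (12, 13, 14))

    def test_rigid_invariance(self):
        p = syn.build_peptide("RSSTSLLHGNGNTYLT", conformation="hairpin")
        rng = np.random.default_rng(0)
        rot = random_rotation(rng)
        moved = p.coords @ rot.T + [11.0, -3.0, 8.0]
        assert tj.assign_secondary_structure(moved, p).labels == tj.assign_secondary_structure(p.coords, p).labels

    def test_missing_backbone_rejected(self, helix_peptide):
        broken = helix_peptide.subset(helix_peptide.names != "O")
        with pytest.raises(TypeError):
            tj.assign_secondary_structure(broken.coords, broken)


def daura_reference(rmsd_matrix, cutoff):
    """Brute-force Daura clustering oracle on a precomputed RMSD matrix."""
    n = len(rmsd_matrix)
    alive = set(range(n))
    assignments = {}
    centers = []
    cid = 0
    while alive:
        best, best_n = None, -1
        for i in sorted(alive):
            nn = sum(1 for j in alive if rmsd_matrix[i][j] <= cutoff)
            if nn > best_n:
                best, best_n = i, nn
        members = [j for j in sorted(alive) if rmsd_matrix[best][j] <= cutoff]
        for j in members:
            assignments[j] = cid
        centers.append(best)
        alive -= set(members)
        cid += 1
    return assignments, centers


class TestGromosCluster:
    def _two_basin_traj(self, peptide, n=12, seed=5):
        rng = np.random.default_rng(seed)
        shifted = peptide.coords.copy()
        shifted[: len(shifted) // 2] += [0, 0, 8.0]  # a genuinely different conformation
        frames = []
        for f in range(n):
            base = peptide.coords if f % 2 == 0 else shifted
            frames.append(base + rng.normal(0, 0.05, base.shape))
        return tj.Trajectory(peptide, np.stack(frames))

    def test_identical_frames_single_cluster(self, helix_peptide):
        t = tj.Trajectory(helix_peptide, np.stack([helix_peptide.coords] * 6))
        res = tj.gromos_cluster(t, cutoff=1.0)
        assert res.n_clusters == 1
        assert set(res.assignments) == {0}

    def test_two_basins(self, helix_peptide):
        t = self._two_basin_traj(helix_peptide)
        res = tj.gromos_cluster(t, cutoff=1.0)
        assert res.n_clusters == 2
        even = res.assignments[0]
        assert all(res.assignments[f] == even for f in range(0, 12, 2))
        assert all(res.assignments[f] != even for f in range(1, 12, 2))

    def test_matches_reference_implementation(self, helix_peptide):
        rng = np.random.default_rng(17)
        frames = np.stack([
            helix_peptide.coords + rng.normal(0, 0.45, helix_peptide.coords.shape)
            for _ in range(30)
        ])
        t = tj.Trajectory(helix_peptide, frames)
        cutoff = 0.52
        res = tj.gromos_cluster(t, cutoff=cutoff)
        bb = np.isin(helix_peptide.names, ["N", "CA", "C", "O"])
        mat = [
            [tj.kabsch_rmsd(frames[i][bb], frames[j][bb]) for j in range(30)]
            for i in range(30)
        ]
        ref_assign, ref_centers = daura_reference(mat, cutoff)
        assert res.centers == ref_centers
        assert [res.assignments[f] for f in range(30)] == [ref_assign[f] for f in range(30)]

    def test_partition_property(self, helix_peptide):
        t = self._two_basin_traj(helix_peptide, n=10)
        res = tj.gromos_cluster(t, cutoff=1.0)
        assert sorted(np.unique(res.assignments)) == list(range(res.n_clusters))
        for cid, center in enumerate(res.centers):
            assert res.assignments[center] == cid
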