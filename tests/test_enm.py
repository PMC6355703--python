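"""Elastic-network modes, opening-mode identification and displacement."""
import numpy as np
import pytest

from modedock import enm
from modedock import structio as st

from conftest import random_rotation, toy_structure


def ca_nodes(coords, masses=None, chain=None):
    n = len(coords)
    return st.Structure(
        coords=np.asarray(coords, dtype=float),
        names=["CA"] * n,
        elements=["C"] * n,
        res_names=["GLY"] * n,
        res_numbers=list(range(1, n + 1)),
        chain_ids=chain or ["A"] * n,
        masses=masses,
    )


def numerical_hessian_eigenvalues(coords, masses, cutoff=15.0, gamma=1.0, h=1e-5):
    """Independent oracle: finite-difference Hessian of the pairwise
    harmonic network energy, mass-weighted and diagonalised."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if np.linalg.norm(coords[i] - coords[j]) <= cutoff
    ]
    ref = {p: np.linalg.norm(coords[p[0]] - coords[p[1]]) for p in pairs}

    def energy(x):
        x = x.reshape(n, 3)
        e = 0.0
        for (i, j), r0 in ref.items():
            e += 0.5 * gamma * (np.linalg.norm(x[i] - x[j]) - r0) ** 2
        return e

    x0 = coords.ravel()
    dim = 3 * n
    hess = np.zeros((dim, dim))
    e0 = energy(x0)
    for a in range(dim):
        for b in range(a, dim):
            xa = x0.copy(); xa[a] += h; xa[b] += h
            xb = x0.copy(); xb[a] += h; xb[b] -= h
            xc = x0.copy(); xc[a] -= h; xc[b] += h
            xd = x0.copy(); xd[a] -= h; xd[b] -= h
            val = (energy(xa) - energy(xb) - energy(xc) + energy(xd)) / (4 * h * h)
            hess[a, b] = hess[b, a] = val
    im = np.repeat(1.0 / np.sqrt(masses), 3)
    return np.linalg.eigvalsh(hess * im[:, None] * im[None, :])


class TestBuildAnm:
    def test_connected_network_has_six_zero_modes(self, hinge):
        structure, _ = hinge
        modes = enm.build_anm(structure)
        thresh = 1e-8 * modes.eigenvalues[-1]
        assert int((modes.eigenvalues < thresh).sum()) == 6

    def test_eigenvectors_orthonormal(self, hinge):
        structure, _ = hinge
        modes = enm.build_anm(structure)
        gram = modes.eigenvectors.T @ modes.eigenvectors
        assert np.allclose(gram, np.eye(modes.n_modes), atol=1e-8)
        assert np.all(modes.eigenvalues >= 0)

    def test_diatomic_closed_form(self):
        # two nodes, one spring gamma: one internal mode at 2*gamma/m,
        # polarised along the bond axis
        m, gamma = 12.0, 2.5
        s = ca_nodes([[0, 0, 0], [3.8, 0, 0]], masses=np.full(2, m))
        modes = enm.build_anm(s, spring_constant=gamma)
        assert modes.eigenvalues[-1] == pytest.approx(2 * gamma / m, rel=1e-12)
        assert int((modes.eigenvalues < 1e-12).sum()) == 5  # 3 trans + 2 rot
        field = modes.cartesian_field(5)
        direction = field / np.linalg.norm(field, axis=1, keepdims=True)
        assert np.allclose(np.abs(direction[:, 0]), 1.0, atol=1e-9)

    def test_triangle_closed_form(self):
        # equilateral triangle: internal eigenvalues {3g/2m, 3g/2m, 3g/m}
        m, gamma = 12.0, 1.0
        h = 3.8 * np.sqrt(3.0) / 2.0
        s = ca_nodes([[0, 0, 0], [3.8, 0, 0], [1.9, h, 0]], masses=np.full(3, m))
        modes = enm.build_anm(s, spring_constant=gamma)
        internal = modes.eigenvalues[6:]
        assert internal == pytest.approx(
            [1.5 * gamma / m, 1.5 * gamma / m, 3.0 * gamma / m], rel=1e-9
        )

    def test_matches_numerical_hessian(self, hinge):
        structure, _ = hinge
        sub = structure.subset(np.arange(structure.n_atoms) < 14)  # keep the oracle cheap
        modes = enm.build_anm(sub, cutoff=12.0)
        oracle = numerical_hessian_eigenvalues(sub.coords, modes.masses, cutoff=12.0)
        mine = modes.eigenvalues
        keep = oracle > 1e-8 * oracle.max()
        assert np.allclose(mine[keep], oracle[keep], rtol=1e-6, atol=1e-9)

    def test_disconnected_network_reports_component(self):
        s = ca_nodes([[0, 0, 0], [3.8, 0, 0], [0, 3.8, 0], [100, 0, 0], [103.8, 0, 0], [100, 3.8, 0]])
        with pytest.raises(enm.ConnectivityError, match="3 node"):
            enm.build_anm(s)


class TestOpeningMode:
    def test_hinge_counter_rotation_identified(self, hinge, hinge_partition):
        structure, true_mode = hinge
        modes = enm.build_anm(structure)
        score = enm.identify_opening_mode(modes, hinge_partition)
        assert score.counter_rotation > 0.8
        assert score.mode_index == 6  # the softest internal mode IS the twist
        mw = (true_mode * np.sqrt(modes.masses)[:, None]).ravel()
        mw /= np.linalg.norm(mw)
        overlap = abs(modes.eigenvectors[:, score.mode_index] @ mw)
        assert overlap > 0.8

    def test_invariant_under_rigid_transform(self, hinge, hinge_partition):
        structure, _ = hinge
        rng = np.random.default_rng(2)
        rot = random_rotation(rng)
        moved = structure.with_coords(structure.coords @ rot.T + [10.0, -4.0, 2.0])
        score_a = enm.identify_opening_mode(enm.build_anm(structure), hinge_partition)
        score_b = enm.identify_opening_mode(enm.build_anm(moved), hinge_partition)
        assert score_a.mode_index == score_b.mode_index
        assert score_a.counter_rotation == pytest.approx(score_b.counter_rotation, abs=1e-6)

    def test_no_internal_modes_rejected(self, hinge_partition):
        s = ca_nodes([[0, 0, 0], [3.8, 0, 0], [1.9, 3.3, 0]], chain=["A", "A", "B"])
        modes = enm.build_anm(s)
        # drop internal columns to emulate a rigid-only mode set
        modes.eigenvalues = modes.eigenvalues[:6]
        modes.eigenvectors = modes.eigenvectors[:, :6]
        sel_a = st.Selection(frozenset({("A", 1, ""), ("A", 2, "")}))
        sel_b = st.Selection(frozenset({("B", 3, "")}))
        with pytest.raises(ValueError):
            enm.identify_opening_mode(modes, (sel_a, sel_b))


@pytest.fixture(scope="module")
def modeset(hinge):
    structure, _ = hinge
    return structure, enm.build_anm(structure)


class TestDisplacement:
    def test_seven_conformers_default_amplitudes(self, modeset):
        structure, modes = modeset
        ens = enm.displace_along_mode(structure, modes, 6)
        assert len(ens) == 7
        assert list(ens.amplitudes) == [0, 1, 2, 3, 4, 5, 6]

    def test_zero_amplitude_bit_identical(self, modeset):
        structure, modes = modeset
        ens = enm.displace_along_mode(structure, modes, 6, amplitudes=[0, 2])
        assert np.array_equal(ens.conformers[0].coords, structure.coords)

    @pytest.mark.parametrize("mode_index", [6, 7, 10])
    def test_amplitude_equals_mass_weighted_rmsd(self, modeset, mode_index):
        structure, modes = modeset
        amps = [0.0, 1.0, 3.5, 6.0]
        ens = enm.displace_along_mode(structure, modes, mode_index, amplitudes=amps)
        m = modes.masses
        for a, conf in zip(amps, ens.conformers):
            d = conf.coords - structure.coords
            rmsd = np.sqrt((m * (d ** 2).sum(axis=1)).sum() / m.sum())
            assert rmsd == pytest.approx(a, abs=1e-6)

    def test_rigid_mode_rejected(self, modeset):
        structure, modes = modeset
        with pytest.raises(ValueError):
            enm.displace_along_mode(structure, modes, 3)

    def test_sign_site_picks_more_exposed_direction(self, modeset):
        from modedock.sasa import shrake_rupley, site_sasa

        structure, modes = modeset
        residues = structure.unique_residues()
        keys = frozenset(
            k for k in residues
            if abs(structure.coords[structure.residue_mask([k])][0, 0]) < 10
        )
        site = st.BindingSite(
            selection=st.Selection(keys, "mid"),
            defining_ligand=st.Selection(frozenset()),
            site_name="mid",
        )
        ens = enm.displace_along_mode(structure, modes, 7, amplitudes=[0, 4], sign_site=site)
        # both candidate directions, reconstructed from the plain (+) ensemble
        plus_conf = enm.displace_along_mode(structure, modes, 7, amplitudes=[4]).conformers[0]
        minus_conf = structure.with_coords(2 * structure.coords - plus_conf.coords)
        exposures = {
            +1: site_sasa(plus_conf, site.selection, shrake_rupley(plus_conf)),
            -1: site_sasa(minus_conf, site.selection, shrake_rupley(minus_conf)),
        }
        got = site_sasa(ens.conformers[1], site.selection, shrake_rupley(ens.conformers[1]))
        assert got == pytest.approx(max(exposures.values()))
        assert ens.direction_sign == max(exposures, key=exposures.get)


class TestClashScan:
    def test_clean_base_has_no_clashes(self, hinge):
        structure, _ = hinge
        modes = enm.build_anm(structure)
        ens = enm.displace_along_mode(structure, modes, 6, amplitudes=[0])
        assert enm.clash_scan(ens)[0] == 0

    def test_constructed_clash_counted(self):
        s = toy_structure([[0, 0, 0], [0.5, 0, 0]], res_numbers=[1, 10])
        ens = enm.DisplacedEnsemble(base=s, mode_index=6, amplitudes=np.array([0.0]), conformers=[s])
        assert enm.clash_scan(ens)[0] == 1

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(0, 18, (100, 3))
        s = toy_structure(coords, res_numbers=list(range(1, 101)))
        ens = enm.DisplacedEnsemble(base=s, mode_index=6, amplitudes=np.array([0.0]), conformers=[s])
        threshold = 0.6
        expected = 0
        for i in range(100):
            for j in range(i + 1, 100):
                if abs(i - j) <= 2:
                    continue
                d = np.linalg.norm(coords[i] - coords[j])
                if d < threshold * (s.vdw_radii[i] + s.vdw_radii[j]):
                    expected += 1
        assert enm.clash_scan(ens, threshold=threshold)[0] == expected
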