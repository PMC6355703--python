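"""Elastic-network normal modes and mode-directed conformer generation.

A C-alpha anisotropic network model (uniform springs within a distance
cutoff, residue masses on the nodes) stands in for all-atom normal mode
analysis: the low-frequency, collective motions that matter here — the
counter-rotation "opening" of the two tubulin monomers — live in the part
of the spectrum that the elastic network reproduces well.

The opening mode is identified *functionally*: for each low-frequency
internal mode the displacement field is fitted by one rigid rotation per
monomer and scored by how anti-parallel the two rotation axes are, rather
than by any fixed mode index. Conformers are generated by mass-weighted
displacement along the selected mode, the amplitude being the mass-weighted
RMS C-alpha displacement in Angstrom.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structio import BindingSite, Selection, Structure

__all__ = [
    "ModeSet",
    "DisplacedEnsemble",
    "OpeningScore",
    "build_anm",
    "identify_opening_mode",
    "displace_along_mode",
    "clash_scan",
    "ConnectivityError",
]

N_RIGID = 6  # zero modes of a connected 3-D network


class ConnectivityError(ValueError):
    """The elastic network is not connected at the chosen cutoff."""


@dataclass
class ModeSet:
    """Mass-weighted normal modes of a C-alpha elastic network.

    ``eigenvectors[:, k]`` is the k-th mass-weighted mode (3N vector,
    orthonormal); eigenvalues ascend and carry spring-constant/mass units.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    node_keys: list
    masses: np.ndarray
    cutoff: float
    spring_constant: float
    node_coords: Optional[np.ndarray] = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_keys)

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    def internal_indices(self) -> np.ndarray:
        return np.arange(N_RIGID, self.n_modes)

    def cartesian_field(self, mode_index: int) -> np.ndarray:
        """Cartesian displacement field (N, 3) of one mode: w_i / sqrt(m_i)."""
        w = self.eigenvectors[:, mode_index].reshape(-1, 3)
        return w / np.sqrt(self.masses)[:, None]


@dataclass
class DisplacedEnsemble:
    """Conformers displaced along one mode at stated amplitudes (A)."""

    base: Structure
    mode_index: int
    amplitudes: np.ndarray
    conformers: list
    direction_sign: int = +1

    def __len__(self):
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)


@dataclass(frozen=True)
class OpeningScore:
    """Counter-rotation diagnostics of one internal mode.

    ``internal_index`` counts internal modes from 0; ``raw_index`` counts
    all modes including the six rigid-body zero modes (so the two encodings
    of a historical 'mode 8' are both recoverable).
    """

    mode_index: int  # raw index into the ModeSet
    counter_rotation: float
    collectivity: float

    @property
    def raw_index(self) -> int:
        return self.mode_index

    @property
    def internal_index(self) -> int:
        return self.mode_index - N_RIGID


def _ca_nodes(structure: Structure):
    mask = structure.names == "CA"
    if mask.sum() < 2:
        raise ValueError("need at least 2 C-alpha nodes for an elastic network")
    idx = np.flatnonzero(mask)
    keys = [structure.residue_keys()[i] for i in idx]
    # node mass = total residue mass (all atoms of that residue)
    reskeys = structure.residue_keys()
    mass_by_res: dict = {}
    for k, m in zip(reskeys, structure.masses):
        mass_by_res[k] = mass_by_res.get(k, 0.0) + float(m)
    masses = np.array([mass_by_res[k] for k in keys])
    return idx, keys, structure.coords[mask], masses


def build_anm(structure: Structure, cutoff: float = 15.0, spring_constant: float = 1.0) -> ModeSet:
    """Anisotropic network model on the C-alpha nodes.

    Builds the mass-weighted Hessian of the pairwise harmonic potential
    (uniform spring ``spring_constant`` for node pairs within ``cutoff``)
    and fully diagonalises it. Dense solver up to 3N = 6000; above that the
    lowest 50 modes are computed with a sparse shift-invert solver.
    """
    from scipy.spatial import cKDTree

    _, keys, coords, masses = _ca_nodes(structure)
    n = len(coords)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    # connectivity check
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    if len(pairs):
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        adj = coo_matrix((n, n))
    ncomp, labels = connected_components(adj, directed=False)
    if ncomp > 1:
        sizes = np.bincount(labels)
        smallest = int(sizes.min())
        raise ConnectivityError(
            f"elastic network disconnected at cutoff {cutoff} A: "
            f"{ncomp} components, smallest has {smallest} node(s)"
        )

    hess = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        d = coords[j] - coords[i]
        r2 = float(d @ d)
        block = -spring_constant * np.outer(d, d) / r2
        hess[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] += block
        hess[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] += block
        hess[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hess[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block

    inv_sqrt_m = np.repeat(1.0 / np.sqrt(masses), 3)
    hess_mw = hess * inv_sqrt_m[:, None] * inv_sqrt_m[None, :]
    hess_mw = 0.5 * (hess_mw + hess_mw.T)

    if 3 * n <= 6000:
        vals, vecs = np.linalg.eigh(hess_mw)
    else:  # pragma: no cover - exercised only on large receptors
        from scipy.sparse.linalg import eigsh

        k = min(50, 3 * n - 1)
        vals, vecs = eigsh(hess_mw, k=k, sigma=0.0, which="LM", tol=1e-10)
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]

    vals = np.where(np.abs(vals) < 1e-10 * max(np.abs(vals).max(), 1.0), 0.0, vals)
    vals = np.clip(vals, 0.0, None)
    return ModeSet(
        eigenvalues=vals,
        eigenvectors=vecs,
        node_keys=keys,
        masses=masses,
        cutoff=float(cutoff),
        spring_constant=float(spring_constant),
        node_coords=coords.copy(),
    )


def _fit_rotation(rel: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Least-squares angular velocity omega with disp ~ t + omega x rel.

    ``rel`` must be centroid-relative; the optimal rigid translation is then
    the mean displacement, which is removed before fitting the rotation.
    """
    disp = disp - disp.mean(axis=0)
    a = np.zeros((3, 3))
    b = np.zeros(3)
    for r, d in zip(rel, disp):
        a += np.dot(r, r) * np.eye(3) - np.outer(r, r)
        b += np.cross(r, d)
    # rel sets spanning < 3 dimensions leave a singular system
    return np.linalg.lstsq(a, b, rcond=None)[0]


def _collectivity(field: np.ndarray) -> float:
    amp2 = (field ** 2).sum(axis=1)
    total = amp2.sum()
    if total <= 0:
        return 0.0
    p = amp2 / total
    p = p[p > 0]
    return float(np.exp(-(p * np.log(p)).sum()) / len(amp2))


def identify_opening_mode(
    modes: ModeSet, partition, k: int = 20
) -> OpeningScore:
    """Pick the internal mode that best counter-rotates the two partitions.

    For each of the lowest ``k`` internal modes a rigid rotation is fitted
    to the displacement field of each partition member; the mode's
    counter-rotation score is ``-cos(angle between the two rotation axes)``
    weighted by the agreement of the rotation magnitudes. Ties break toward
    the lower eigenvalue (the iteration order).
    """
    sel_a, sel_b = partition
    keys = modes.node_keys
    in_a = np.array([kk in sel_a.members for kk in keys])
    in_b = np.array([kk in sel_b.members for kk in keys])
    covered = (in_a | in_b).sum()
    if covered < 0.9 * modes.n_nodes:
        raise ValueError("partition must cover at least 90% of the network nodes")
    internal = modes.internal_indices()
    if len(internal) == 0:
        raise ValueError("mode set has no internal modes")
    coords_a_idx, coords_b_idx = np.flatnonzero(in_a), np.flatnonzero(in_b)
    if len(coords_a_idx) < 3 or len(coords_b_idx) < 3:
        raise ValueError("each partition member needs at least 3 nodes")

    # node coordinates are not stored in the ModeSet; rotations are fitted
    # about each lobe's mass centre using the node masses as weights
    best: Optional[OpeningScore] = None
    node_coords = modes.node_coords
    if node_coords is None:
        raise ValueError("ModeSet lacks node coordinates; build it with build_anm")
    for raw in internal[:k]:
        field = modes.cartesian_field(int(raw))
        score = _counter_rotation(node_coords, field, coords_a_idx, coords_b_idx)
        cand = OpeningScore(
            mode_index=int(raw),
            counter_rotation=score,
            collectivity=_collectivity(field),
        )
        # near-degenerate scores (anti-symmetric bends of a symmetric body
        # tie with the torsion) resolve toward the lower eigenvalue, which
        # is the iteration order
        if best is None or cand.counter_rotation > best.counter_rotation + 0.02:
            best = cand
    return best


def _counter_rotation(coords, field, idx_a, idx_b) -> float:
    wa = _fit_rotation(coords[idx_a] - coords[idx_a].mean(0), field[idx_a])
    wb = _fit_rotation(coords[idx_b] - coords[idx_b].mean(0), field[idx_b])
    na, nb = np.linalg.norm(wa), np.linalg.norm(wb)
    if na < 1e-12 or nb < 1e-12:
        return 0.0
    cos = float(wa @ wb / (na * nb))
    weight = 2.0 * na * nb / (na * na + nb * nb)
    return -cos * weight


def displace_along_mode(
    structure: Structure,
    modes: ModeSet,
    mode_index: int,
    amplitudes: Sequence[float] = (0, 1, 2, 3, 4, 5, 6),
    sign_site: Optional[BindingSite] = None,
) -> DisplacedEnsemble:
    """Generate conformers along one internal mode.

    The Cartesian node displacement is ``s * w_i / sqrt(m_i)`` with the
    scale ``s`` fixed so the mass-weighted RMS C-alpha displacement equals
    the requested amplitude; all non-C-alpha atoms of a residue ride
    rigidly on their C-alpha. When ``sign_site`` is given the displacement
    sign with the larger site SASA at maximum amplitude is chosen (the
    "open" direction).
    """
    amplitudes = np.asarray(list(amplitudes), dtype=float)
    if np.any(amplitudes < 0):
        raise ValueError("amplitudes must be non-negative")
    if mode_index < N_RIGID or mode_index >= modes.n_modes:
        raise ValueError(
            f"mode {mode_index} is a rigid-body mode or out of range; "
            f"internal modes start at index {N_RIGID}"
        )
    field = modes.cartesian_field(mode_index)  # unit mass-weighted norm
    total_mass = modes.masses.sum()
    # per-node displacement at unit amplitude: s = a * sqrt(total node mass)
    unit = field * np.sqrt(total_mass)

    # map node displacements onto all atoms of each residue
    key_to_node = {k: i for i, k in enumerate(modes.node_keys)}
    reskeys = structure.residue_keys()
    atom_node = np.array([key_to_node.get(k, -1) for k in reskeys])
    if np.any(atom_node < 0):
        missing = {k for k, i in zip(reskeys, atom_node) if i < 0}
        raise ValueError(f"residues without a network node: {sorted(missing)[:5]}")
    atom_unit = unit[atom_node]

    sign = +1
    if sign_site is not None:
        from .sasa import shrake_rupley, site_sasa

        amax = amplitudes.max()
        exposures = {}
        for s in (+1, -1):
            conf = structure.with_coords(structure.coords + s * amax * atom_unit)
            exposures[s] = site_sasa(conf, sign_site.selection, shrake_rupley(conf))
        sign = +1 if exposures[+1] >= exposures[-1] else -1

    conformers = []
    for a in amplitudes:
        if a == 0.0:
            conformers.append(structure.copy())
        else:
            conformers.append(
                structure.with_coords(
                    structure.coords + sign * a * atom_unit,
                    metadata=f"{structure.metadata}+mode{mode_index}@{a:g}A",
                )
            )
    return DisplacedEnsemble(
        base=structure,
        mode_index=int(mode_index),
        amplitudes=amplitudes,
        conformers=conformers,
        direction_sign=sign,
    )


def clash_scan(ensemble: DisplacedEnsemble, threshold: float = 0.6) -> np.ndarray:
    """Per-conformer count of non-bonded heavy-atom clashes.

    A clash is a pair closer than ``threshold x (r_i + r_j)`` with the two
    atoms more than 2 residues apart in sequence (or in different chains).
    """
    from scipy.spatial import cKDTree

    counts = []
    for conf in ensemble.conformers:
        heavy = conf.elements != "H"
        coords = conf.coords[heavy]
        radii = conf.vdw_radii[heavy]
        chains = conf.chain_ids[heavy]
        resnum = conf.res_numbers[heavy]
        rmax = threshold * 2.0 * radii.max()
        pairs = cKDTree(coords).query_pairs(rmax, output_type="ndarray")
        if len(pairs) == 0:
            counts.append(0)
            continue
        i, j = pairs[:, 0], pairs[:, 1]
        d = np.linalg.norm(coords[i] - coords[j], axis=1)
        near_seq = (chains[i] == chains[j]) & (np.abs(resnum[i] - resnum[j]) <= 2)
        clash = (d < threshold * (radii[i] + radii[j])) & ~near_seq
        counts.append(int(clash.sum()))
    return np.array(counts, dtype=int)
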