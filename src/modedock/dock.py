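"""Blind rigid-body docking by FFT correlation.

Katchalski-Katzir-style shape complementarity on a Cartesian lattice: the
receptor grid carries a thin favourable surface layer (value 1) and an
imaginary core penalty; the ligand grid marks occupied voxels. For every
orientation in a deterministic quasi-uniform rotation set, the correlation
over all translations is evaluated with one 3-D FFT; an optional second
channel correlates splatted partial charges so complementary electrostatics
reward a pose. Local score maxima are pooled over rotations, de-duplicated
by ligand RMSD and the top scorers retained.

This is a classical, desk-scale stand-in for polar-Fourier docking codes:
pose locations and interaction patterns are comparable, absolute scores are
not.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._geometry import matrix_to_quat, quat_to_matrix, super_fibonacci_rotations
from .structio import Structure

__all__ = ["DockGrid", "Pose", "DockRun", "make_grids", "dock_rigid", "pose_coordinates"]


@dataclass
class DockGrid:
    """Discretised structure for FFT correlation."""

    origin: np.ndarray
    spacing: float
    dims: tuple
    shape_channel: np.ndarray  # complex for receptors, real 0/1 for ligands
    charge_channel: Optional[np.ndarray] = None
    role: str = "receptor"


@dataclass
class Pose:
    """Rigid placement of a ligand conformer with score components.

    ``rotation`` (unit quaternion, about the ligand centroid) is applied
    first, then ``translation`` (of the centroid).
    """

    rotation: np.ndarray
    translation: np.ndarray
    shape_score: float
    elec_score: float
    total_score: float
    receptor_id: str = ""
    ligand_id: str = ""

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        n = np.linalg.norm(self.rotation)
        if abs(n - 1.0) > 1e-9:
            self.rotation = self.rotation / n
        self.translation = np.asarray(self.translation, dtype=float)


@dataclass
class DockRun:
    """Retained poses (descending total score) plus the run parameters."""

    poses: list
    params: dict
    seed: int = 0

    def __len__(self):
        return len(self.poses)

    @property
    def best(self) -> Pose:
        return self.poses[0]


def _occupancy(structure: Structure, origin, dims, spacing) -> np.ndarray:
    occ = np.zeros(dims, dtype=bool)
    heavy = structure.elements != "H"
    for c, r in zip(structure.coords[heavy], structure.vdw_radii[heavy]):
        lo = np.maximum(np.floor((c - r - origin) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((c + r - origin) / spacing).astype(int) + 1, dims)
        if np.any(lo >= hi):
            continue
        ax = [origin[d] + spacing * np.arange(lo[d], hi[d]) - c[d] for d in range(3)]
        d2 = ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
        occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 < r * r
    return occ


def _potential_field(
    structure: Structure, origin, dims, spacing, rcut: float = 8.0, rmin: float = 1.0
) -> np.ndarray:
    """Truncated Coulomb potential of the structure's partial charges,
    sampled at voxel centres: phi(x) = sum q_j / max(|x - x_j|, rmin) for
    |x - x_j| <= rcut. Units: e / Angstrom."""
    grid = np.zeros(dims)
    q = structure.partial_charges
    if np.all(np.isnan(q)):
        return grid
    for c, qi in zip(structure.coords, q):
        if np.isnan(qi) or qi == 0.0:
            continue
        lo = np.maximum(np.floor((c - rcut - origin) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((c + rcut - origin) / spacing).astype(int) + 1, dims)
        if np.any(lo >= hi):
            continue
        ax = [origin[d] + spacing * np.arange(lo[d], hi[d]) - c[d] for d in range(3)]
        r = np.sqrt(
            ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
        )
        contrib = qi / np.clip(r, rmin, None)
        contrib[r > rcut] = 0.0
        grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += contrib
    return grid


def _splat_charges(structure: Structure, origin, dims, spacing) -> np.ndarray:
    """Trilinear deposition of partial charges onto the lattice."""
    grid = np.zeros(dims)
    q = structure.partial_charges
    if np.all(np.isnan(q)):
        return grid
    for c, qi in zip(structure.coords, q):
        if np.isnan(qi) or qi == 0.0:
            continue
        f = (c - origin) / spacing
        i0 = np.floor(f).astype(int)
        t = f - i0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    idx = i0 + (dx, dy, dz)
                    if np.any(idx < 0) or np.any(idx >= dims):
                        continue
                    w = (
                        (t[0] if dx else 1 - t[0])
                        * (t[1] if dy else 1 - t[1])
                        * (t[2] if dz else 1 - t[2])
                    )
                    grid[tuple(idx)] += qi * w
    return grid


def make_grids(
    structure: Structure,
    spacing: float = 1.0,
    role: str = "receptor",
    interior_weight: float = -15.0,
    surface_thickness: float = 1.5,
    origin=None,
    dims=None,
    margin: float = 2.0,
) -> DockGrid:
    """Discretise a structure for correlation docking.

    Receptor: surface voxels (within ``surface_thickness`` of the outside)
    get value 1, interior voxels ``interior_weight * 1j`` (overlap penalty),
    exterior 0. Ligand: occupied voxels get value 1. Charges, if present,
    are splatted onto a separate channel.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if structure.n_atoms == 0:
        raise ValueError("structure is empty")
    heavy = structure.elements != "H"
    coords = structure.coords[heavy]
    rmax = structure.vdw_radii[heavy].max()
    if origin is None:
        origin = coords.min(axis=0) - rmax - margin
    origin = np.asarray(origin, dtype=float)
    if dims is None:
        hi = coords.max(axis=0) + rmax + margin
        dims = tuple(np.ceil((hi - origin) / spacing).astype(int) + 1)
    dims = tuple(int(d) for d in dims)
    occ = _occupancy(structure, origin, dims, spacing)
    if role == "receptor":
        from scipy import ndimage

        # favourable layer = envelope dilated outward by surface_thickness
        # minus the core, so a ligand at touching distance scores while
        # interpenetration runs into the imaginary core penalty
        it = max(1, int(round(surface_thickness / spacing)))
        core = ndimage.binary_erosion(occ, iterations=1)
        halo = ndimage.binary_dilation(occ, iterations=it)
        shape = np.where(halo & ~core, 1.0, 0.0).astype(complex)
        shape += np.where(core, 1.0, 0.0) * (interior_weight * 1j)
    elif role == "ligand":
        shape = occ.astype(float)
    else:
        raise ValueError("role must be 'receptor' or 'ligand'")
    # receptor carries its Coulomb potential; the ligand carries splatted
    # charges, so their correlation approximates the interaction energy
    charge = (
        _potential_field(structure, origin, dims, spacing)
        if role == "receptor"
        else _splat_charges(structure, origin, dims, spacing)
    )
    return DockGrid(
        origin=origin,
        spacing=float(spacing),
        dims=dims,
        shape_channel=shape,
        charge_channel=charge,
        role=role,
    )


def correlate_grids(receptor: DockGrid, ligand: DockGrid, fft_dims=None):
    """Correlation score lattice c(t) = sum_x L(x) * R(x + t).

    Returns ``(score, elec, fft_dims)`` where ``score[t] = Re(c) + Im(c)``
    (surface contacts minus core-overlap penalty; the receptor core carries
    a negative imaginary weight) and ``elec[t]`` is minus the charge-channel
    correlation (positive = attractive). Translations index the lattice
    offset of the ligand grid relative to the receptor grid (wrapped).
    """
    from scipy import fft as sfft

    if fft_dims is None:
        fft_dims = tuple(
            sfft.next_fast_len(receptor.dims[d] + ligand.dims[d]) for d in range(3)
        )
    fr = sfft.fftn(receptor.shape_channel, s=fft_dims)
    fl = sfft.fftn(ligand.shape_channel.astype(complex), s=fft_dims)
    corr = sfft.ifftn(np.conj(fl) * fr)
    score = corr.real + corr.imag
    elec = np.zeros(fft_dims)
    if receptor.charge_channel is not None and ligand.charge_channel is not None and \
            np.any(receptor.charge_channel) and np.any(ligand.charge_channel):
        fqr = sfft.fftn(receptor.charge_channel, s=fft_dims)
        fql = sfft.fftn(ligand.charge_channel, s=fft_dims)
        elec = -sfft.ifftn(np.conj(fql) * fqr).real
    return score, elec, fft_dims


def brute_force_correlation(receptor: DockGrid, ligand: DockGrid, fft_dims):
    """Direct triple-loop correlation; the independent check of the FFT path."""
    score = np.zeros(fft_dims)
    lig = ligand.shape_channel
    rec = receptor.shape_channel
    nz = np.argwhere(lig != 0)
    for t0 in range(fft_dims[0]):
        for t1 in range(fft_dims[1]):
            for t2 in range(fft_dims[2]):
                acc = 0.0 + 0.0j
                for (x0, x1, x2) in nz:
                    r0 = (x0 + t0) % fft_dims[0]
                    r1 = (x1 + t1) % fft_dims[1]
                    r2 = (x2 + t2) % fft_dims[2]
                    if r0 < rec.shape[0] and r1 < rec.shape[1] and r2 < rec.shape[2]:
                        acc += lig[x0, x1, x2] * rec[r0, r1, r2]
                score[t0, t1, t2] = acc.real + acc.imag
    return score


def dock_rigid(
    receptor: Structure,
    ligand: Structure,
    rotation_step: float = 24.0,
    spacing: float = 1.0,
    retain: int = 350,
    seed: int = 0,
    elec_weight: float = 0.25,
    interior_weight: float = -15.0,
    surface_thickness: float = 1.5,
    peaks_per_rotation: int = 8,
    dedup_rmsd: float = 3.0,
) -> DockRun:
    """Blind rigid-body FFT docking over a deterministic rotation set.

    ``rotation_step`` (degrees) sets the angular resolution of the SO(3)
    covering; the identity rotation is always included. Candidate poses are
    local correlation maxima, de-duplicated at ``dedup_rmsd`` ligand RMSD;
    the top ``retain`` by total score (shape + ``elec_weight`` x electro-
    static) are kept. Fully deterministic; ``seed`` is recorded and only
    perturbs degenerate tie-breaking.
    """
    from scipy import ndimage

    if receptor.n_atoms == 0 or ligand.n_atoms == 0:
        raise ValueError("receptor and ligand must be non-empty")
    rec_grid = make_grids(
        receptor,
        spacing=spacing,
        role="receptor",
        interior_weight=interior_weight,
        surface_thickness=surface_thickness,
    )
    lig_heavy = ligand.subset(ligand.elements != "H")
    diameter = np.linalg.norm(
        lig_heavy.coords.max(axis=0) - lig_heavy.coords.min(axis=0)
    ) + 2 * lig_heavy.vdw_radii.max()
    rec_extent = max(rec_grid.dims) * spacing
    if diameter > rec_extent + 2 * diameter:  # pragma: no cover - sanity bound
        raise ValueError("ligand larger than the receptor grid")

    step_rad = np.radians(rotation_step)
    n_rot = max(1, int(np.ceil(8.0 * np.pi ** 2 / step_rad ** 3)))
    quats = super_fibonacci_rotations(n_rot)

    centroid = ligand.coords.mean(axis=0)
    candidates = []  # (total, shape, elec, quat_index, translation)
    rng = np.random.default_rng(seed)
    tiebreak = rng.random(1)  # recorded-only; correlation path is deterministic

    for qi, q in enumerate(quats):
        rot = quat_to_matrix(q)
        rcoords = (ligand.coords - centroid) @ rot.T + centroid
        rlig = ligand.with_coords(rcoords)
        lig_grid = make_grids(rlig, spacing=spacing, role="ligand", margin=1.0)
        score, elec, fft_dims = correlate_grids(rec_grid, lig_grid)
        # normalise by the rotation's rasterised ligand volume: voxel counts
        # vary with orientation and would otherwise bias the rotation search
        n_vox = float(lig_grid.shape_channel.sum())
        if n_vox == 0:
            continue
        total = (score + elec_weight * elec) / n_vox
        score = score / n_vox
        elec = elec / n_vox
        local_max = total == ndimage.maximum_filter(total, size=3, mode="wrap")
        flat = np.flatnonzero(local_max & (total > 0))
        if len(flat) == 0:
            continue
        order = flat[np.argsort(total.ravel()[flat])[::-1][:peaks_per_rotation]]
        for f in order:
            t = np.array(np.unravel_index(f, fft_dims))
            # wrapped translation -> signed lattice offset
            t_signed = np.where(t > np.array(fft_dims) // 2, t - np.array(fft_dims), t)
            delta = rec_grid.origin - lig_grid.origin + t_signed * spacing
            # rounding removes FFT float noise so exact ties break by
            # rotation-set order (identity first), deterministically
            candidates.append(
                (
                    round(float(total.ravel()[f]), 6),
                    round(float(score.ravel()[f]), 6),
                    round(float(elec.ravel()[f]), 6),
                    qi,
                    delta,
                )
            )

    candidates.sort(key=lambda c: (-c[0], c[3], tuple(np.round(c[4], 6))))
    # de-duplicate by ligand-coordinate RMSD between candidate placements
    kept = []
    kept_coords = []
    probe = ligand.coords - centroid
    for total, shape_s, elec_s, qi, delta in candidates:
        rot = quat_to_matrix(quats[qi])
        coords = probe @ rot.T + centroid + delta
        dup = False
        for kc in kept_coords:
            if np.sqrt(((coords - kc) ** 2).sum(axis=1).mean()) < dedup_rmsd:
                dup = True
                break
        if dup:
            continue
        kept.append((total, shape_s, elec_s, qi, delta))
        kept_coords.append(coords)
        if len(kept) >= retain:
            break

    poses = []
    for total, shape_s, elec_s, qi, delta in kept:
        rot = quat_to_matrix(quats[qi])
        # pose convention: x -> R x + t (rotation about the origin)
        trans = centroid + delta - rot @ centroid
        poses.append(
            Pose(
                rotation=matrix_to_quat(rot),
                translation=trans,
                shape_score=shape_s,
                elec_score=elec_s,
                total_score=total,
                receptor_id=receptor.metadata,
                ligand_id=ligand.metadata,
            )
        )
    params = {
        "rotation_step": rotation_step,
        "n_rotations": int(n_rot),
        "spacing": spacing,
        "retain": retain,
        "elec_weight": elec_weight,
        "interior_weight": interior_weight,
        "surface_thickness": surface_thickness,
        "dedup_rmsd": dedup_rmsd,
    }
    return DockRun(poses=poses, params=params, seed=seed)


def pose_coordinates(pose: Pose, ligand: Structure) -> Structure:
    """Apply a pose (rotation about the origin, then translation) to the
    ligand; metadata records the provenance."""
    rot = quat_to_matrix(pose.rotation)
    coords = ligand.coords @ rot.T + pose.translation
    return ligand.with_coords(
        coords, metadata=f"{ligand.metadata}|pose(score={pose.total_score:.2f})"
    )
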