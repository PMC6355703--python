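"""Solvent-accessible surface area (Shrake-Rupley) and grid molecular volume.

The SASA sampler uses a deterministic Fibonacci-spiral point set (no RNG)
on each expanded atom sphere; a point is accessible when it lies outside
every other occluder's expanded sphere. Heavy atoms only by default, with
Bondi-style radii from the bundled element table; het groups are excluded
as occluders unless requested, since site exposure here is a proxy for
docking accessibility of the residues that normally contact the ligand.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import BindingSite, Selection, Structure

__all__ = ["SasaResult", "shrake_rupley", "site_sasa", "molecular_volume"]


@dataclass
class SasaResult:
    """Per-atom accessible areas (A^2) over the atoms that were included."""

    atom_indices: np.ndarray  # indices into the source structure
    areas: np.ndarray  # same length; A^2
    probe_radius: float
    n_points: int
    radii_set: str = "bondi"

    def per_atom(self, structure: Structure) -> dict:
        """atom key -> area for the included atoms."""
        out = {}
        for i, a in zip(self.atom_indices, self.areas):
            out[
                (
                    str(structure.chain_ids[i]),
                    int(structure.res_numbers[i]),
                    str(structure.insertion_codes[i]),
                    str(structure.names[i]),
                )
            ] = float(a)
        return out

    @property
    def total(self) -> float:
        return float(self.areas.sum())


def _sphere_points(n: int) -> np.ndarray:
    from ._geometry import fibonacci_sphere

    return fibonacci_sphere(n)


def shrake_rupley(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    include_het: bool = False,
    include_hydrogens: bool = False,
) -> SasaResult:
    """Shrake-Rupley SASA with a deterministic spiral point set.

    Areas are computed for (and occluded by) heavy atoms; het-group atoms
    participate only when ``include_het`` is set, hydrogens only when
    ``include_hydrogens`` is set.
    """
    from scipy.spatial import cKDTree

    if structure.n_atoms == 0:
        raise ValueError("structure is empty")
    if n_points < 12:
        raise ValueError("n_points must be >= 12")
    include = np.ones(structure.n_atoms, dtype=bool)
    if not include_hydrogens:
        include &= structure.elements != "H"
    if not include_het:
        include &= ~structure.hetero
    idx = np.flatnonzero(include)
    if len(idx) == 0:
        raise ValueError("no atoms left after filtering")
    coords = structure.coords[idx]
    radii = structure.vdw_radii[idx] + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = 2.0 * radii.max()
    areas = np.empty(len(idx))
    for a in range(len(idx)):
        pts = coords[a] + radii[a] * unit
        neigh = [b for b in tree.query_ball_point(coords[a], rmax) if b != a]
        accessible = np.ones(n_points, dtype=bool)
        if neigh:
            neigh = np.array(neigh)
            close = neigh[
                np.linalg.norm(coords[neigh] - coords[a], axis=1) < radii[a] + radii[neigh]
            ]
            for b in close:
                accessible &= np.linalg.norm(pts - coords[b], axis=1) >= radii[b]
                if not accessible.any():
                    break
        areas[a] = 4.0 * np.pi * radii[a] ** 2 * accessible.sum() / n_points
    return SasaResult(
        atom_indices=idx, areas=areas, probe_radius=float(probe), n_points=int(n_points)
    )


def site_sasa(structure: Structure, site, sasa: SasaResult = None) -> float:
    """Summed accessible area (A^2) over all atoms of the site's residues."""
    selection = site.selection if isinstance(site, BindingSite) else site
    if not selection:
        raise ValueError("site selection is empty")
    if sasa is None:
        sasa = shrake_rupley(structure)
    members = set(selection.members)
    reskeys = structure.residue_keys()
    total = 0.0
    for i, area in zip(sasa.atom_indices, sasa.areas):
        if reskeys[i] in members:
            total += float(area)
    return total


def molecular_volume(structure: Structure, grid_spacing: float = 0.3) -> float:
    """Van der Waals volume (A^3) by grid voxelisation.

    A voxel counts when its centre lies inside any heavy-atom sphere.
    """
    occupied, _, _ = _voxelize(structure, grid_spacing)
    return float(occupied.sum()) * grid_spacing ** 3


def _voxelize(structure: Structure, h: float, origin=None, dims=None):
    """Boolean occupancy lattice of the heavy-atom vdW spheres.

    Returns ``(occupied, origin, dims)``; voxel (i,j,k) has its centre at
    ``origin + (i,j,k) * h`` and counts when inside any atom sphere. Marking
    is done atom-by-atom over each sphere's bounding sub-box (vectorised).
    """
    if structure.n_atoms == 0:
        raise ValueError("structure is empty")
    if h <= 0:
        raise ValueError("grid_spacing must be positive")
    heavy = structure.elements != "H"
    coords = structure.coords[heavy]
    radii = structure.vdw_radii[heavy]
    rmax = radii.max()
    if origin is None:
        origin = coords.min(axis=0) - rmax - h
    origin = np.asarray(origin, dtype=float)
    if dims is None:
        hi = coords.max(axis=0) + rmax + h
        dims = np.ceil((hi - origin) / h).astype(int) + 1
    dims = np.asarray(dims, dtype=int)
    occ = np.zeros(dims, dtype=bool)
    for c, r in zip(coords, radii):
        lo_i = np.maximum(np.floor((c - r - origin) / h).astype(int), 0)
        hi_i = np.minimum(np.ceil((c + r - origin) / h).astype(int) + 1, dims)
        if np.any(lo_i >= hi_i):
            continue
        ax = [origin[d] + h * np.arange(lo_i[d], hi_i[d]) - c[d] for d in range(3)]
        d2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        occ[lo_i[0] : hi_i[0], lo_i[1] : hi_i[1], lo_i[2] : hi_i[2]] |= d2 < r * r
    return occ, origin, dims
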