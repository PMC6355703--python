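"""Trajectory analytics: superposition RMSD/RMSF, hydrogen-bond detection
and occupancy tables, DSSP-style secondary structure, and GROMOS (Daura)
conformational clustering.

Trajectories enter as multi-model PDB files (or arrays); the molecular
dynamics that produced them is outside this package's scope. There is no
randomness anywhere in this module: identical inputs give bit-identical
tables.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _chem
from ._geometry import kabsch
from .structio import Selection, Structure, read_models, selection_atom_mask

__all__ = [
    "Trajectory",
    "HBond",
    "OccupancyRow",
    "ClusterResult",
    "SSString",
    "kabsch_rmsd",
    "rmsf_profile",
    "detect_hbonds",
    "hbond_occupancy",
    "assign_secondary_structure",
    "gromos_cluster",
]


@dataclass
class Trajectory:
    """Frames (F, N, 3) over a fixed topology."""

    topology: Structure
    frames: np.ndarray
    frame_interval: Optional[float] = None  # ps

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (F, N, 3) array")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError("every frame must match the topology's atom count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @classmethod
    def from_pdb(cls, path, frame_interval: Optional[float] = None) -> "Trajectory":
        models = read_models(path)
        return cls(
            topology=models[0],
            frames=np.stack([m.coords for m in models]),
            frame_interval=frame_interval,
        )


@dataclass(frozen=True)
class HBond:
    """A detected hydrogen bond (atom keys are (chain, resnum, icode, name))."""

    donor: tuple
    hydrogen: Optional[tuple]
    acceptor: tuple
    distance: float
    angle_deviation: float


@dataclass(frozen=True)
class OccupancyRow:
    """One occupancy-table row: RES<n>-Main|Side-<atom> labels + occupancy %."""

    donor_label: str
    acceptor_label: str
    occupancy: float


@dataclass
class ClusterResult:
    """Daura clustering output: a partition of frames plus ordered centers."""

    assignments: np.ndarray  # frame -> cluster id (discovery order)
    centers: list  # frame index of each cluster's center
    cutoff: float
    atom_subset: Optional[Selection]

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class SSString:
    """Per-residue secondary structure labels (H, G, E, B, T, C)."""

    labels: str
    residue_keys: tuple

    def __str__(self):
        return self.labels


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------


def _subset_indices(topology: Structure, subset: Optional[Selection]) -> np.ndarray:
    if subset is None:
        return np.arange(topology.n_atoms)
    mask = selection_atom_mask(topology, subset)
    return np.flatnonzero(mask)


def kabsch_rmsd(frame_a, frame_b, topology=None, subset=None) -> float:
    """RMSD after optimal superposition over the subset atoms."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if topology is not None and subset is not None:
        idx = _subset_indices(topology, subset)
        a, b = a[idx], b[idx]
    if a.shape != b.shape:
        raise ValueError("frames must have matching atom counts")
    return kabsch(a, b)[2]


def rmsf_profile(traj: Trajectory, subset: Optional[Selection] = None):
    """Per-residue C-alpha root-mean-square fluctuation.

    Every frame is superposed onto the first frame over the subset atoms
    (the alignment reference; all atoms by default) before deviations from
    the mean structure are accumulated. Returns ``(residue_keys, rmsf)``
    over all C-alpha atoms.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = _subset_indices(traj.topology, subset)
    ref = traj.frames[0]
    aligned = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        rot, trans, _ = kabsch(traj.frames[f][idx], ref[idx])
        aligned[f] = traj.frames[f] @ rot.T + trans
    mean = aligned.mean(axis=0)
    per_atom = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))
    ca = np.flatnonzero(traj.topology.names == "CA")
    keys = [traj.topology.residue_keys()[i] for i in ca]
    return keys, per_atom[ca]


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------


def _donor_entries(topology: Structure):
    """(atom index, n_H, rotatable) for every template donor heavy atom."""
    out = []
    reskeys = topology.residue_keys()
    first_res = {}
    for i, k in enumerate(reskeys):
        first_res.setdefault(k[0], k)
    for i in range(topology.n_atoms):
        rname = str(topology.res_names[i])
        aname = str(topology.names[i])
        if rname in _chem.PROTEIN_RESIDUES and aname == "N":
            if rname == "PRO":
                continue
            nh = 3 if reskeys[i] == first_res.get(reskeys[i][0]) else 1
            out.append((i, nh, False))
        else:
            tmpl = _chem.SIDECHAIN_DONORS.get(rname, {})
            if aname in tmpl:
                nh, rot = tmpl[aname]
                out.append((i, nh, rot))
    return out


def _acceptor_indices(topology: Structure):
    out = []
    for i in range(topology.n_atoms):
        rname = str(topology.res_names[i])
        aname = str(topology.names[i])
        if rname in _chem.PROTEIN_RESIDUES or rname == "NH2":
            if aname in ("O", "OXT", "OT1", "OT2"):
                out.append(i)
            elif aname in _chem.SIDECHAIN_ACCEPTORS.get(rname, set()):
                out.append(i)
        elif rname not in _chem.PROTEIN_RESIDUES and topology.hetero[i] and \
                topology.elements[i] in ("O", "N"):
            # het groups: any N/O is a candidate acceptor
            out.append(i)
    return np.array(out, dtype=int)


def _bonded_hydrogens(topology: Structure, coords: np.ndarray):
    """donor index -> list of hydrogen indices (distance criterion)."""
    from scipy.spatial import cKDTree

    hmask = topology.elements == "H"
    hs = np.flatnonzero(hmask)
    if len(hs) == 0:
        return {}
    tree = cKDTree(coords[hs])
    out: dict = {}
    heavies = np.flatnonzero(~hmask)
    for i in heavies:
        near = tree.query_ball_point(coords[i], 1.25)
        if near:
            out[i] = [int(hs[j]) for j in near]
    return out


def _atom_key(topology: Structure, i: int):
    return (
        str(topology.chain_ids[i]),
        int(topology.res_numbers[i]),
        str(topology.insertion_codes[i]),
        str(topology.names[i]),
    )


def detect_hbonds(
    frame: np.ndarray,
    topology: Structure,
    dist_cutoff: float = 3.0,
    angle_cutoff: float = 20.0,
    scope: str = "intra",
    groups=None,
) -> list:
    """Geometric hydrogen bonds in one frame.

    A bond is reported when the donor-acceptor heavy-atom distance is
    <= ``dist_cutoff`` AND the deviation from donor-H-acceptor linearity is
    <= ``angle_cutoff`` degrees. Explicit hydrogens are used when bonded to
    the donor; otherwise rotatable donors (hydroxyl, thiol, ammonium) are
    taken to point their hydrogen at the acceptor, and fixed sp2 donors get
    hydrogens constructed from ideal planar geometry.

    ``scope`` is "intra" (all pairs, different residues) or "inter" with
    ``groups=(selection_a, selection_b)``: only bonds crossing the two
    selections are reported.
    """
    from scipy.spatial import cKDTree

    coords = np.asarray(frame, dtype=float)
    unknown = {
        str(rn)
        for rn, het in zip(topology.res_names, topology.hetero)
        if str(rn) not in _chem.PROTEIN_RESIDUES and str(rn) != "NH2" and not het
    }
    if unknown:
        raise TypeError(f"no donor/acceptor template for residue(s): {sorted(unknown)}")
    donors = _donor_entries(topology)
    acceptors = _acceptor_indices(topology)
    if not donors or len(acceptors) == 0:
        return []
    hyd = _bonded_hydrogens(topology, coords)
    neighbors = {i: [] for i, _, _ in donors}
    # heavy-atom bonded neighbours of each donor (for ideal H construction)
    heavy = np.flatnonzero(topology.elements != "H")
    htree = cKDTree(coords[heavy])
    for i, _, _ in donors:
        for j in htree.query_ball_point(coords[i], 1.8):
            jj = int(heavy[j])
            if jj != i:
                neighbors[i].append(jj)

    reskeys = topology.residue_keys()
    if scope == "inter":
        if groups is None:
            raise ValueError("scope='inter' needs groups=(sel_a, sel_b)")
        in_a = {k for k in groups[0].members}
        in_b = {k for k in groups[1].members}
    atree = cKDTree(coords[acceptors])
    bonds = []
    for di, nh, rot in donors:
        for jj in atree.query_ball_point(coords[di], dist_cutoff):
            ai = int(acceptors[jj])
            if reskeys[ai] == reskeys[di]:
                continue
            if scope == "inter":
                cross = (reskeys[di] in in_a and reskeys[ai] in in_b) or (
                    reskeys[di] in in_b and reskeys[ai] in in_a
                )
                if not cross:
                    continue
            d = float(np.linalg.norm(coords[ai] - coords[di]))
            dev, hidx = _angle_deviation(coords, topology, di, ai, hyd, neighbors, rot)
            if dev <= angle_cutoff:
                bonds.append(
                    HBond(
                        donor=_atom_key(topology, di),
                        hydrogen=_atom_key(topology, hidx) if hidx is not None else None,
                        acceptor=_atom_key(topology, ai),
                        distance=d,
                        angle_deviation=dev,
                    )
                )
    return bonds


def _angle_deviation(coords, topology, di, ai, hyd, neighbors, rotatable):
    """Deviation from D-H...A linearity (deg) and the hydrogen index used."""
    hs = hyd.get(di, [])
    if hs:
        best, best_h = 1e9, None
        for h in hs:
            u = coords[h] - coords[di]
            v = coords[ai] - coords[h]
            cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            dev = float(np.degrees(np.arccos(np.clip(cosv, -1, 1))))
            if dev < best:
                best, best_h = dev, h
        return best, best_h
    if rotatable:
        return 0.0, None
    # ideal planar hydrogen(s) from the heavy neighbours
    nbrs = neighbors.get(di, [])
    if not nbrs:
        return 0.0, None
    dpos = coords[di]
    if len(nbrs) >= 2:
        u1 = dpos - coords[nbrs[0]]
        u2 = dpos - coords[nbrs[1]]
        hdir = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
        hdirs = [hdir / np.linalg.norm(hdir)]
    else:
        b = coords[nbrs[0]]
        axis = dpos - b
        axis /= np.linalg.norm(axis)
        # plane reference: any neighbour of the antecedent
        ref = None
        for k in neighbors.get(nbrs[0], []):
            if k != di:
                ref = coords[k]
                break
        if ref is None:
            ref = b + np.array([0.0, 0.0, 1.0])
        perp = ref - b - np.dot(ref - b, axis) * axis
        nperp = np.linalg.norm(perp)
        perp = perp / nperp if nperp > 1e-8 else np.array([1.0, 0.0, 0.0])
        ang = np.radians(60.0)
        hdirs = [
            np.cos(ang) * axis + np.sin(ang) * perp,
            np.cos(ang) * axis - np.sin(ang) * perp,
        ]
    best = 1e9
    for hd in hdirs:
        hpos = dpos + 1.01 * hd
        u = hpos - dpos
        v = coords[ai] - hpos
        cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        best = min(best, float(np.degrees(np.arccos(np.clip(cosv, -1, 1)))))
    return best, None


def _hb_label(topology: Structure, key) -> str:
    chain, num, icode, name = key
    idx = topology.atom_index(chain, num, name, icode)
    rname = str(topology.res_names[idx])
    kind = "Main" if name in _chem.MAINCHAIN_POLAR else "Side"
    return f"{rname}{num}-{kind}-{name}"


def hbond_occupancy(
    traj: Trajectory,
    dist_cutoff: float = 3.0,
    angle_cutoff: float = 20.0,
    min_occupancy: float = 10.0,
    scope: str = "intra",
    groups=None,
) -> list:
    """Per donor-acceptor pair occupancy (% of frames bonded).

    Rows with occupancy >= ``min_occupancy`` are returned, sorted by donor
    residue number then descending occupancy.
    """
    counts: dict = {}
    for f in range(traj.n_frames):
        for hb in detect_hbonds(
            traj.frames[f], traj.topology, dist_cutoff, angle_cutoff, scope, groups
        ):
            counts[(hb.donor, hb.acceptor)] = counts.get((hb.donor, hb.acceptor), 0) + 1
    rows = []
    for (dkey, akey), c in counts.items():
        occ = 100.0 * c / traj.n_frames
        if occ >= min_occupancy:
            rows.append(
                OccupancyRow(
                    donor_label=_hb_label(traj.topology, dkey),
                    acceptor_label=_hb_label(traj.topology, akey),
                    occupancy=occ,
                )
            )
    rows.sort(key=lambda r: (int("".join(ch for ch in r.donor_label.split("-")[0] if ch.isdigit())), -r.occupancy, r.donor_label, r.acceptor_label))
    return rows


# ---------------------------------------------------------------------------
# Secondary structure (DSSP-style)
# ---------------------------------------------------------------------------


def _backbone_table(topology: Structure):
    """Ordered protein residues with their backbone atom indices."""
    residues = []
    reskeys = topology.residue_keys()
    order = []
    by_res: dict = {}
    for i in range(topology.n_atoms):
        if str(topology.res_names[i]) not in _chem.PROTEIN_RESIDUES:
            continue
        k = reskeys[i]
        if k not in by_res:
            by_res[k] = {}
            order.append(k)
        by_res[k][str(topology.names[i])] = i
    for k in order:
        atoms = by_res[k]
        missing = {"N", "CA", "C", "O"} - set(atoms)
        if missing:
            raise TypeError(f"residue {k} missing backbone atom(s) {sorted(missing)}")
        residues.append((k, atoms))
    return residues


def assign_secondary_structure(frame: np.ndarray, topology: Structure) -> SSString:
    """DSSP-style assignment from backbone H-bond patterns.

    Backbone N-H...O=C bonds are scored with the classical DSSP
    electrostatic model (amide hydrogens placed by ideal geometry when
    absent); n-turns, bridges and ladders then yield H (alpha), G (3-10),
    E (strand), B (isolated bridge), T (turn) and C (coil), with the usual
    H > E > G > T precedence.
    """
    coords = np.asarray(frame, dtype=float)
    residues = _backbone_table(topology)
    n = len(residues)
    if n == 0:
        raise TypeError("no complete protein residues")
    chains = [k[0] for k, _ in residues]

    # amide H: explicit if present, else ideal in the peptide plane
    hyd = _bonded_hydrogens(topology, coords)
    hpos = np.full((n, 3), np.nan)
    for i, (k, atoms) in enumerate(residues):
        if str(topology.res_names[atoms["N"]]) == "PRO":
            continue
        hs = hyd.get(atoms["N"], [])
        if hs:
            hpos[i] = coords[hs[0]]
        elif i > 0 and chains[i - 1] == chains[i]:
            _, prev = residues[i - 1]
            nn = coords[atoms["N"]]
            u1 = nn - coords[prev["C"]]
            u2 = nn - coords[atoms["CA"]]
            d = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
            hpos[i] = nn + 1.01 * d / np.linalg.norm(d)

    # DSSP electrostatic criterion: E < -0.5 kcal/mol
    def hbond(i, j) -> bool:
        """CO of residue i accepts from NH of residue j."""
        if i < 0 or j < 0 or i >= n or j >= n or abs(i - j) < 2:
            return False
        if np.isnan(hpos[j, 0]):
            return False
        _, ai = residues[i]
        _, aj = residues[j]
        c, o = coords[ai["C"]], coords[ai["O"]]
        nn, h = coords[aj["N"]], hpos[j]
        r_on = np.linalg.norm(o - nn)
        r_ch = np.linalg.norm(c - h)
        r_oh = np.linalg.norm(o - h)
        r_cn = np.linalg.norm(c - nn)
        if min(r_on, r_ch, r_oh, r_cn) < 0.5:
            return False
        e = 0.084 * 332.0 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
        return e < -0.5

    turn = {3: np.zeros(n, bool), 4: np.zeros(n, bool), 5: np.zeros(n, bool)}
    for t in (3, 4, 5):
        for i in range(n - t):
            if chains[i] == chains[i + t] and hbond(i, i + t):
                turn[t][i] = True

    para = np.zeros((n, n), bool)
    anti = np.zeros((n, n), bool)
    for i in range(n):
        for j in range(i + 3, n):
            if (hbond(i - 1, j) and hbond(j, i + 1)) or (hbond(j - 1, i) and hbond(i, j + 1)):
                para[i, j] = para[j, i] = True
            if (hbond(i, j) and hbond(j, i)) or (hbond(i - 1, j + 1) and hbond(j - 1, i + 1)):
                anti[i, j] = anti[j, i] = True

    labels = np.full(n, "C", dtype="U1")
    # alpha helix: two consecutive 4-turns
    for i in range(1, n):
        if turn[4][i - 1] and turn[4][i]:
            labels[i : min(i + 4, n)] = "H"
    # strands: bridges extendable into ladders
    bridge = para | anti
    for i in range(n):
        partners = np.flatnonzero(bridge[i])
        if len(partners) == 0:
            continue
        ladder = False
        for j in partners:
            jn = j - 1 if anti[i, j] else j + 1
            jp = j + 1 if anti[i, j] else j - 1
            if i + 1 < n and 0 <= jn < n and bridge[i + 1, jn]:
                ladder = True
            if i - 1 >= 0 and 0 <= jp < n and bridge[i - 1, jp]:
                ladder = True
        if labels[i] == "C":
            labels[i] = "E" if ladder else "B"
    # 3-10 helix: two consecutive 3-turns
    for i in range(1, n):
        if turn[3][i - 1] and turn[3][i]:
            for k in range(i, min(i + 3, n)):
                if labels[k] == "C":
                    labels[k] = "G"
    # turns: interior of any n-turn
    for t in (3, 4, 5):
        for i in np.flatnonzero(turn[t]):
            for k in range(i + 1, min(i + t, n)):
                if labels[k] == "C":
                    labels[k] = "T"
    return SSString(labels="".join(labels), residue_keys=tuple(k for k, _ in residues))


# ---------------------------------------------------------------------------
# GROMOS / Daura clustering
# ---------------------------------------------------------------------------


def backbone_selection(topology: Structure) -> Selection:
    """Backbone (N, CA, C, O) residues-with-atoms helper used as the default
    clustering subset."""
    keys = {
        k
        for k, nm in zip(topology.residue_keys(), topology.names)
        if nm in ("N", "CA", "C", "O")
    }
    return Selection(frozenset(keys), label="backbone")


def _pairwise_rmsd(traj: Trajectory, atom_idx: np.ndarray) -> np.ndarray:
    f = traj.n_frames
    sub = traj.frames[:, atom_idx, :]
    mat = np.zeros((f, f))
    for i in range(f):
        for j in range(i + 1, f):
            mat[i, j] = mat[j, i] = kabsch(sub[i], sub[j])[2]
    return mat


def gromos_cluster(
    traj: Trajectory, cutoff: float, subset: Optional[Selection] = None,
    backbone_only: bool = True,
) -> ClusterResult:
    """Daura neighbour-counting clustering at an RMSD cutoff.

    Repeatedly extracts the frame with the most neighbours within ``cutoff``
    (ties to the lower frame index) as a cluster center, assigns it and its
    neighbours, removes them, and repeats. RMSDs are over the backbone atoms
    of the subset by default.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    idx = _subset_indices(traj.topology, subset)
    if backbone_only:
        bb = np.isin(traj.topology.names, ["N", "CA", "C", "O"]) & \
            np.isin(traj.topology.res_names, list(_chem.PROTEIN_RESIDUES))
        bb_idx = np.flatnonzero(bb)
        chosen = bb_idx[np.isin(bb_idx, idx)]
        idx = chosen if len(chosen) >= 3 else idx
    mat = _pairwise_rmsd(traj, idx)
    f = traj.n_frames
    alive = np.ones(f, dtype=bool)
    assignments = np.full(f, -1, dtype=int)
    centers = []
    cid = 0
    within = mat <= cutoff
    while alive.any():
        counts = (within & alive[None, :] & alive[:, None]).sum(axis=1)
        counts[~alive] = -1
        center = int(np.argmax(counts))  # argmax takes the first (lowest) index on ties
        members = np.flatnonzero(within[center] & alive)
        assignments[members] = cid
        centers.append(center)
        alive[members] = False
        cid += 1
    return ClusterResult(
        assignments=assignments, centers=centers, cutoff=float(cutoff), atom_subset=subset
    )
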