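"""Synthetic structure and trajectory generators.

Every downstream analysis stage (mode identification, H-bond occupancy,
clustering, docking, fingerprinting) has a generator here that produces an
input with *known* ground truth: an ideal-geometry peptide, a two-lobe hinge
body with an analytic counter-rotation field, a trajectory with controlled
hydrogen-bond occupancies, a receptor/ligand pair with a constructed true
docking placement, and a pair of molecules with a prescribed interaction
fingerprint. All generators are seed-deterministic.

The four V(L) CDR1 peptides studied experimentally ship as named presets,
plus the R1A point variant of the active peptide used in the comparative
docking demo.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _chem
from ._geometry import kabsch, place_atom
from .structio import Selection, Structure

__all__ = [
    "PEPTIDE_PRESETS",
    "FixtureSpec",
    "build_fixture",
    "build_peptide",
    "make_hinge_dimer",
    "make_traj_with_occupancy",
    "make_cavity_complex",
    "make_interaction_complex",
    "ConstructionError",
]


class ConstructionError(ValueError):
    """A requested synthetic construction is geometrically unsatisfiable."""


#: One-letter sequences of the synthetic V(L) CDR1 peptides (all amidated at
#: the C-terminus) and the R1A variant of the active peptide.
PEPTIDE_PRESETS = {
    "rb44l1": "RSSQTITHGNGNTYLY",
    "rb29l1": "RSSTSLLHGNGNTYLT",
    "c36l1": "KSSQSVFYSSNNKNYLA",
    "scr44": "SIGTYSTRNYQHNLTG",
    "rb44l1_r1a": "ASSQTITHGNGNTYLY",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request; identical spec + seed => identical output."""

    kind: str  # hinge_dimer | occupancy_traj | cavity_complex | peptide
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def build_fixture(spec: FixtureSpec):
    """Dispatch a :class:`FixtureSpec` to its generator."""
    kind = spec.kind
    p = dict(spec.parameters)
    if kind == "peptide":
        return build_peptide(**p)
    if kind == "hinge_dimer":
        return make_hinge_dimer(seed=spec.seed, **p)
    if kind == "occupancy_traj":
        return make_traj_with_occupancy(seed=spec.seed, **p)
    if kind == "cavity_complex":
        return make_cavity_complex(seed=spec.seed, **p)
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# Ideal-geometry peptide builder
# ---------------------------------------------------------------------------

# Engh-Huber-style ideal backbone geometry (lengths in Angstrom, angles deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.010
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.0, 116.2, 121.7, 120.1

_RECIPES = {
    "extended": (-139.0, 135.0),
    "helix": (-57.0, -47.0),
}
# Strand / loop dihedrals for the two-stranded beta-hairpin build: slightly
# twisted antiparallel strands plus a 4-residue loop, calibrated once so the
# two strands fall into backbone H-bond register on a 16-mer.
_HAIRPIN_STRAND = (-128.74, 124.53)
_HAIRPIN_LOOP = [(166.82, -15.20), (-84.94, 173.26), (-50.78, 72.81), (120.73, -169.83)]


import functools


@functools.lru_cache(maxsize=64)
def _residue_template(res_name: str):
    import biotite.structure.info as info

    try:
        return info.residue(res_name)
    except KeyError as exc:
        raise ValueError(f"unknown residue {res_name!r}") from exc


def _dihedral_plan(n: int, conformation) -> list:
    """Per-residue (phi, psi) list for a named or explicit conformation."""
    if isinstance(conformation, (list, tuple)) and conformation and \
            isinstance(conformation[0], (list, tuple)) and not isinstance(conformation[0], str):
        plan = [tuple(map(float, d)) for d in conformation]
        if len(plan) != n:
            raise ValueError("explicit dihedral list must match sequence length")
        return plan
    turn_at: Optional[int] = None
    name = conformation
    if isinstance(conformation, (list, tuple)):
        name, turn_at = conformation[0], int(conformation[1])
    elif isinstance(conformation, str) and ":" in conformation:
        name, turn = conformation.split(":")
        turn_at = int(turn)
    if name in _RECIPES:
        return [_RECIPES[name]] * n
    if name == "hairpin":
        if turn_at is None:
            turn_at = n // 2
        if not 2 <= turn_at <= n - len(_HAIRPIN_LOOP):
            raise ValueError("hairpin turn position out of range")
        plan = [_HAIRPIN_STRAND] * n
        for k, d in enumerate(_HAIRPIN_LOOP):  # loop at residues turn_at..turn_at+3
            plan[turn_at - 1 + k] = d
        return plan
    raise ValueError(f"unknown conformation {conformation!r}")


def build_peptide(sequence: str, conformation="extended", amidated: bool = True) -> Structure:
    """Build an all-atom peptide at ideal geometry.

    Backbone atoms are chained with ideal bond lengths/angles at the
    requested (phi, psi) dihedrals (omega fixed at 180); side chains are
    taken from idealised residue geometry and carried on the local backbone
    frame. The N-terminus is protonated (+1); the C-terminus is an amide cap
    (NH2 residue) when ``amidated`` (the experimental peptides are all
    amidated) else a charged carboxylate.

    ``conformation``: "extended", "helix", "hairpin[:turn_at]" or an explicit
    per-residue list of (phi, psi) pairs.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty peptide sequence")
    try:
        res3 = [_chem.ONE_TO_THREE[c] for c in sequence]
    except KeyError as exc:
        raise ValueError(f"unknown residue letter {exc.args[0]!r}") from exc
    n = len(res3)
    plan = _dihedral_plan(n, conformation)

    # backbone trace
    bb = np.zeros((n, 3, 3))  # residue x (N, CA, C) x xyz
    bb[0, 0] = (0.0, 0.0, 0.0)
    bb[0, 1] = (_B_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - _A_N_CA_C)
    bb[0, 2] = bb[0, 1] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        psi_prev = plan[i - 1][1]
        phi = plan[i][0]
        bb[i, 0] = place_atom(bb[i - 1, 0], bb[i - 1, 1], bb[i - 1, 2], _B_C_N, _A_CA_C_N, psi_prev)
        bb[i, 1] = place_atom(bb[i - 1, 1], bb[i - 1, 2], bb[i, 0], _B_N_CA, _A_C_N_CA, 180.0)
        bb[i, 2] = place_atom(bb[i - 1, 2], bb[i, 0], bb[i, 1], _B_CA_C, _A_N_CA_C, phi)

    names, elements, resnames, resnums, coords, formals = [], [], [], [], [], []

    def add(name, element, rname, rnum, pos, formal=0):
        names.append(name)
        elements.append(element)
        resnames.append(rname)
        resnums.append(rnum)
        coords.append(np.asarray(pos, dtype=float))
        formals.append(formal)

    strip = {"O", "OXT", "HXT", "H", "H2", "H3"}
    for i, rname in enumerate(res3):
        rnum = i + 1
        tmpl = _residue_template(rname)
        t_idx = {nm: k for k, nm in enumerate(tmpl.atom_name)}
        t_bb = np.array([tmpl.coord[t_idx["N"]], tmpl.coord[t_idx["CA"]], tmpl.coord[t_idx["C"]]])
        rot, trans, _ = kabsch(t_bb, bb[i])
        placed = tmpl.coord @ rot.T + trans
        add("N", "N", rname, rnum, bb[i, 0], formal=+1 if i == 0 else 0)
        add("CA", "C", rname, rnum, bb[i, 1])
        add("C", "C", rname, rnum, bb[i, 2])
        psi = plan[i][1]
        add("O", "O", rname, rnum, place_atom(bb[i, 0], bb[i, 1], bb[i, 2], _B_C_O, _A_CA_C_O, psi + 180.0))
        if i == 0:
            nh = 2 if rname == "PRO" else 3
            for k, tors in enumerate((60.0, 180.0, 300.0)[:nh]):
                add(f"H{k + 1}", "H", rname, rnum, place_atom(bb[0, 2], bb[0, 1], bb[0, 0], 1.033, 109.5, tors))
        elif rname != "PRO":
            # amide H anti to the preceding carbonyl O (trans peptide plane)
            o_prev = coords[[j for j, (nm, rn) in enumerate(zip(names, resnums)) if nm == "O" and rn == i][0]]
            add("H", "H", rname, rnum, place_atom(o_prev, bb[i - 1, 2], bb[i, 0], _B_N_H, 119.0, 180.0))
        for k, nm in enumerate(tmpl.atom_name):
            if nm in ("N", "CA", "C") or nm in strip:
                continue
            formal = 0
            fc = _chem.FORMAL_CHARGE_ATOM.get(rname)
            if fc is not None and nm == fc[0]:
                formal = fc[1]
            add(nm, str(tmpl.element[k]).upper(), rname, rnum, placed[k], formal)

    last = n - 1
    psi_last = plan[last][1]
    if amidated:
        ncap = place_atom(bb[last, 0], bb[last, 1], bb[last, 2], 1.335, _A_CA_C_N, psi_last)
        add("N", "N", "NH2", n + 1, ncap)
        add("HN1", "H", "NH2", n + 1, place_atom(bb[last, 1], bb[last, 2], ncap, _B_N_H, 119.0, 180.0))
        add("HN2", "H", "NH2", n + 1, place_atom(bb[last, 1], bb[last, 2], ncap, _B_N_H, 121.0, 0.0))
    else:
        add("OXT", "O", res3[last], n, place_atom(bb[last, 0], bb[last, 1], bb[last, 2], _B_C_O, _A_CA_C_O, psi_last), formal=-1)

    return Structure(
        coords=np.array(coords),
        names=names,
        elements=elements,
        res_names=resnames,
        res_numbers=resnums,
        chain_ids=["A"] * len(names),
        formal_charges=formals,
        metadata=f"peptide:{sequence}",
    )


def preset_peptide(name: str, conformation="extended") -> Structure:
    """Build one of the named peptide presets (see :data:`PEPTIDE_PRESETS`)."""
    try:
        seq = PEPTIDE_PRESETS[name.lower()]
    except KeyError as exc:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PEPTIDE_PRESETS)}") from exc
    return build_peptide(seq, conformation=conformation)


# ---------------------------------------------------------------------------
# Hinge dimer with analytic counter-rotation mode
# ---------------------------------------------------------------------------


def _packed_lobe(n_nodes: int, rng: np.random.Generator, radius: float, min_dist: float = 3.8):
    """Deterministic compact blob of pseudo-C-alpha nodes (rejection packing)."""
    pts = [np.zeros(3)]
    attempts = 0
    while len(pts) < n_nodes:
        cand = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(cand) > radius:
            continue
        d = np.linalg.norm(np.array(pts) - cand, axis=1)
        if d.min() >= min_dist and d.min() <= 2.5 * min_dist:
            pts.append(cand)
        attempts += 1
        if attempts > 200000:
            raise ConstructionError("cannot pack lobe; lower nodes_per_lobe or raise radius")
    return np.array(pts)


def make_hinge_dimer(nodes_per_lobe: int = 20, hinge_width: int = 2, seed: int = 0):
    """Two compact pseudo-C-alpha lobes joined by a thin axial hinge.

    Returns ``(structure, true_mode)`` where ``true_mode`` is the analytic
    counter-rotation displacement field (the two lobes twisting in opposite
    senses about the inter-lobe axis), normalised in the mass-weighted
    metric. Lobe A is chain A, lobe B chain B; hinge nodes are split between
    the chains. The lobes are separated beyond the default elastic-network
    cutoff so they couple only through the hinge, which makes the
    counter-rotation the softest internal motion.
    """
    if nodes_per_lobe < 10:
        raise ValueError("nodes_per_lobe must be >= 10")
    if hinge_width < 1:
        raise ValueError("hinge_width must be >= 1")
    rng = np.random.default_rng(seed)
    # radius keeps ~3.8 A packing density at any lobe size; the 11 A surface
    # gap leaves a few direct lobe-lobe springs at the 15 A default cutoff,
    # which removes floppy mechanisms while keeping the twist soft
    radius = (13.7 * nodes_per_lobe) ** (1.0 / 3.0)
    surf_gap = 11.0
    gap = 2.0 * radius + surf_gap
    lobe_a = _packed_lobe(nodes_per_lobe, rng, radius) + [-gap / 2.0, 0.0, 0.0]
    lobe_b = _packed_lobe(nodes_per_lobe, rng, radius) + [+gap / 2.0, 0.0, 0.0]
    # hinge: hinge_width nodes zig-zagged off-axis between the lobes
    m = hinge_width
    hx = np.linspace(-surf_gap / 4.0, surf_gap / 4.0, m) if m > 1 else np.array([0.0])
    jitter = 1.2 * np.where(np.arange(m) % 2 == 0, 1.0, -1.0)
    hinge = np.column_stack([hx, jitter, np.zeros(m)])
    coords = np.vstack([lobe_a, hinge[: m // 2 + m % 2], hinge[m // 2 + m % 2:], lobe_b])
    n = len(coords)
    chain = (["A"] * (nodes_per_lobe + m // 2 + m % 2)) + (["B"] * (nodes_per_lobe + m // 2))
    structure = Structure(
        coords=coords,
        names=["CA"] * n,
        elements=["C"] * n,
        res_names=["GLY"] * n,
        res_numbers=list(range(1, n + 1)),
        chain_ids=chain,
        masses=np.full(n, 110.0),  # average residue mass
        # alternating partial charges so electrostatic rescoring of docked
        # peptides is exercised on this fixture; irrelevant to the modes
        partial_charges=np.where(np.arange(n) % 2 == 0, 0.25, -0.25),
        metadata=f"hinge_dimer(seed={seed})",
    )
    axis = np.array([1.0, 0.0, 0.0])
    rel = coords - coords.mean(axis=0)
    field = np.cross(axis, rel)
    sign = np.where(coords[:, 0] < 0, 1.0, -1.0)
    field *= sign[:, None]
    mw = field * np.sqrt(structure.masses)[:, None]
    field /= np.linalg.norm(mw) / np.sqrt(structure.masses.mean())
    return structure, field


# ---------------------------------------------------------------------------
# Trajectories with controlled H-bond occupancy
# ---------------------------------------------------------------------------


def _atom_key_index(structure: Structure, key):
    if len(key) == 3:
        chain, num, name = key
        icode = ""
    else:
        chain, num, icode, name = key
    return structure.atom_index(chain, num, name, icode)


def make_traj_with_occupancy(
    peptide: Structure,
    bonds: dict,
    n_frames: int,
    noise: float = 0.15,
    seed: int = 0,
    dist_on: float = 2.85,
    dist_off: float = 8.0,
):
    """Multi-frame trajectory in which each listed donor/acceptor pair
    satisfies the 3.0 A / 20 deg H-bond criterion in exactly
    ``round(target * n_frames / 100)`` frames.

    ``bonds`` maps ``(donor_key, acceptor_key)`` -> target occupancy (%),
    keys being ``(chain, resnum, atom_name)`` tuples. In "on" frames the
    acceptor residue is rigidly placed so the acceptor atom lies on the
    donor-hydrogen axis at ``dist_on``; in "off" frames it is retracted to
    ``dist_off``. Gaussian noise (sigma = ``noise``) is applied everywhere
    except to atoms of residues defining a controlled bond in its on-frames.
    """
    from .traj import Trajectory

    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    reskeys = peptide.residue_keys()
    plans = []
    used_acceptor_residues = set()
    for (dkey, akey), target in bonds.items():
        if not 0.0 <= target <= 100.0:
            raise ValueError("occupancy targets must be in [0, 100]")
        di = _atom_key_index(peptide, dkey)
        ai = _atom_key_index(peptide, akey)
        dres, ares = reskeys[di], reskeys[ai]
        if dres == ares:
            raise ConstructionError("donor and acceptor must be in different residues")
        if ares in used_acceptor_residues:
            raise ConstructionError("each controlled bond needs its own acceptor residue")
        used_acceptor_residues.add(ares)
        dname, aname = peptide.names[di], peptide.names[ai]
        d_ok = dname in _chem.MAINCHAIN_POLAR or \
            aname_in(_chem.SIDECHAIN_DONORS.get(str(peptide.res_names[di]), {}), dname)
        a_ok = aname in ("O", "OXT", "OT1", "OT2") or \
            aname_in(_chem.SIDECHAIN_ACCEPTORS.get(str(peptide.res_names[ai]), set()), aname)
        if not (d_ok and a_ok):
            raise ConstructionError(
                f"pair {dkey} -> {akey} is not a donor/acceptor pair by the residue templates"
            )
        # direction: along donor->H if an explicit hydrogen is bonded, else
        # along the current donor->acceptor axis (rotatable donor)
        h_dir = None
        for j in range(peptide.n_atoms):
            if (
                peptide.elements[j] == "H"
                and reskeys[j] == dres
                and np.linalg.norm(peptide.coords[j] - peptide.coords[di]) < 1.25
            ):
                h_dir = peptide.coords[j] - peptide.coords[di]
                break
        if h_dir is None:
            h_dir = peptide.coords[ai] - peptide.coords[di]
        nrm = np.linalg.norm(h_dir)
        if nrm < 1e-9:
            raise ConstructionError("degenerate donor geometry")
        u = h_dir / nrm
        n_on = int(round(target * n_frames / 100.0))
        on_frames = set(rng.permutation(n_frames)[:n_on].tolist())
        acc_mask = peptide.residue_mask([ares])
        don_mask = peptide.residue_mask([dres])
        plans.append((di, ai, u, on_frames, acc_mask, don_mask))

    frames = np.empty((n_frames, peptide.n_atoms, 3))
    base = peptide.coords
    for f in range(n_frames):
        coords = base.copy()
        frozen = np.zeros(peptide.n_atoms, dtype=bool)
        for di, ai, u, on_frames, acc_mask, don_mask in plans:
            target_pos = base[di] + u * (dist_on if f in on_frames else dist_off)
            coords[acc_mask] = base[acc_mask] + (target_pos - base[ai])
            if f in on_frames:
                frozen |= acc_mask | don_mask
        if noise > 0:
            jitter = rng.normal(0.0, noise, size=(peptide.n_atoms, 3))
            jitter[frozen] = 0.0
            # keep off-frame retractions safely outside the criterion
            for di, ai, u, on_frames, acc_mask, don_mask in plans:
                if f not in on_frames:
                    jitter[acc_mask] = np.clip(jitter[acc_mask], -1.0, 1.0)
            coords += jitter
        frames[f] = coords
    return Trajectory(topology=peptide, frames=frames)


def aname_in(template, name) -> bool:
    return str(name) in template


# ---------------------------------------------------------------------------
# Cavity complex with known docking placement
# ---------------------------------------------------------------------------


def make_cavity_complex(ligand_shape: str = "blob", seed: int = 0):
    """Receptor cage with a complementary cavity plus the ligand that
    carved it. Returns ``(receptor, ligand, true_pose)``; the true pose is
    the identity rotation at the carving translation, clash-free by
    construction.

    The ligand is a chiral arrangement of pseudo-atoms (three unequal
    orthogonal arms plus an off-axis knob) so no wrong orientation fits the
    pocket; the receptor is a closely wrapped shell (convex outside, snug
    concave inside, narrow mouth above the topmost ligand atom) and carries
    charges complementary to the ligand's so the electrostatic channel
    reinforces the true orientation. Recovery is designed for docking at
    1.0 A spacing with a rotation step of <= 30 degrees.
    """
    from .dock import Pose

    rng = np.random.default_rng(seed)
    if ligand_shape != "blob":
        raise ValueError(f"unknown ligand shape {ligand_shape!r}")
    lig_local = np.array(
        [
            [0.0, 0.0, 0.0],
            [2.8, 0.0, 0.0],
            [5.6, 0.0, 0.0],
            [8.4, 0.0, 0.0],
            [0.0, 2.8, 0.0],
            [0.0, 5.6, 0.0],
            [0.0, 0.0, 2.8],
            [2.8, 2.8, 0.0],
        ]
    )
    lig_local = lig_local + rng.normal(0.0, 0.08, size=lig_local.shape)
    lig_local -= lig_local.mean(axis=0)
    true_translation = np.array([0.0, 0.0, -7.0])
    lig_true = lig_local + true_translation

    carve, shell, lspace = 2.7, 4.5, 1.8
    xs = np.arange(-16.0, 16.1, lspace)
    ys = np.arange(-14.0, 14.1, lspace)
    zs = np.arange(-18.0, 4.1, lspace)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    from scipy.spatial import cKDTree

    dmin, nearest = cKDTree(lig_true).query(grid, k=1)
    keep = (dmin > carve) & (dmin < carve + shell)
    # narrow exit channel above the topmost ligand atom
    top = lig_true[np.argmax(lig_true[:, 2])]
    dxy = np.linalg.norm(grid[:, :2] - top[:2], axis=1)
    keep &= ~((dxy <= 2.2) & (grid[:, 2] > top[2]))
    rec_coords = grid[keep]
    lig_q = np.where(np.arange(len(lig_local)) % 2 == 0, 1.0, -1.0)
    rec_q = np.where(dmin[keep] < carve + 2.2, -lig_q[nearest[keep]] / 2.0, 0.0)

    def pseudo(coords, chain, metadata, charges):
        m = len(coords)
        return Structure(
            coords=coords,
            names=[f"C{i+1}" for i in range(m)],
            elements=["C"] * m,
            res_names=["UNK"] * m,
            res_numbers=list(range(1, m + 1)),
            chain_ids=[chain] * m,
            hetero=[True] * m,
            partial_charges=charges,
            metadata=metadata,
        )

    receptor = pseudo(rec_coords, "R", f"cavity_receptor(seed={seed})", rec_q)
    ligand = pseudo(lig_local, "L", f"cavity_ligand(seed={seed})", lig_q)
    true_pose = Pose(
        rotation=np.array([1.0, 0.0, 0.0, 0.0]),
        translation=true_translation,
        shape_score=np.nan,
        elec_score=0.0,
        total_score=np.nan,
        receptor_id=receptor.metadata,
        ligand_id=ligand.metadata,
    )
    return receptor, ligand, true_pose


# ---------------------------------------------------------------------------
# Complexes with a prescribed interaction fingerprint
# ---------------------------------------------------------------------------

_RING_R = 1.39  # benzene C-C ring radius


def _ring(center, normal, phase=0.0):
    normal = np.asarray(normal, float)
    normal /= np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, a)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    ang = np.radians(np.arange(6) * 60.0 + phase)
    return np.asarray(center) + _RING_R * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))


def make_interaction_complex(classes: dict, seed: int = 0):
    """Two molecules whose interaction fingerprint equals the request.

    ``classes`` maps interaction names (hbonds, salt_bridges, cation_pi,
    pi_stacking, t_stacking, hydrophobic_contacts) to requested counts.
    Each unit is an isolated "station" of minimal chemical fragments spaced
    far apart so classes do not cross-contaminate; the one unavoidable
    coupling (T-stacked rings are close enough for ring-carbon hydrophobic
    contacts) is accounted for in the returned expectation. Partial charges
    are assigned directly by the generator (charged groups only).
    """
    from .fingerprint import InteractionFingerprint

    known = {"hbonds", "salt_bridges", "cation_pi", "pi_stacking", "t_stacking", "hydrophobic_contacts"}
    bad = set(classes) - known
    if bad:
        raise ConstructionError(f"unknown interaction classes: {sorted(bad)}")
    counts = {k: int(classes.get(k, 0)) for k in known}
    if any(v < 0 for v in counts.values()):
        raise ConstructionError("interaction counts must be >= 0")

    rng = np.random.default_rng(seed)
    a_atoms, b_atoms = [], []  # (name, element, resname, resnum, xyz, charge)
    a_res, b_res = [0], [0]

    def addA(name, el, rn, pos, q=0.0):
        a_atoms.append((name, el, rn, a_res[0], np.asarray(pos, float), q))

    def addB(name, el, rn, pos, q=0.0):
        b_atoms.append((name, el, rn, b_res[0], np.asarray(pos, float), q))

    x = 0.0
    extra_hydrophobic = 0
    step = 16.0

    for _ in range(counts["hbonds"]):
        a_res[0] += 1
        b_res[0] += 1
        # SER hydroxyl donor (rotatable, no explicit H) -> GLN carbonyl acceptor
        addA("CB", "C", "SER", [x, -1.45, 0.0])
        addA("OG", "O", "SER", [x, 0.0, 0.0])
        addB("OE1", "O", "GLN", [x, 2.85, 0.0])
        addB("CD", "C", "GLN", [x, 4.08, 0.0])
        addB("NE2", "N", "GLN", [x, 4.75, 1.15])
        x += step

    for _ in range(counts["salt_bridges"]):
        a_res[0] += 1
        b_res[0] += 1
        # edge-on guanidinium vs carboxylate: centroids 3.9 A apart, every
        # N...O pair > 3.0 A so no H-bond is implied
        addA("CZ", "C", "ARG", [x, 0.0, 0.0], q=0.25)
        for nm, ang in (("NE", 90.0), ("NH1", 210.0), ("NH2", 330.0)):
            pos = [x, 1.33 * np.cos(np.radians(ang)), 1.33 * np.sin(np.radians(ang))]
            addA(nm, "N", "ARG", pos, q=0.25)
        addB("CD", "C", "GLU", [x + 5.15, 0.0, 0.0])
        addB("OE1", "O", "GLU", [x + 3.9, 1.11, 0.0], q=-0.5)
        addB("OE2", "O", "GLU", [x + 3.9, -1.11, 0.0], q=-0.5)
        x += step

    for _ in range(counts["cation_pi"]):
        a_res[0] += 1
        b_res[0] += 1
        addA("CE", "C", "LYS", [x, 0.0, 5.95])
        addA("NZ", "N", "LYS", [x, 0.0, 4.5], q=0.6)
        ring = _ring([x, 0.0, 0.0], [0.0, 0.0, 1.0])
        for nm, pos in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), ring):
            addB(nm, "C", "PHE", pos)
        x += step

    for _ in range(counts["pi_stacking"]):
        a_res[0] += 1
        b_res[0] += 1
        for nm, pos in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), _ring([x, 0.0, 0.0], [0, 0, 1])):
            addA(nm, "C", "PHE", pos)
        for nm, pos in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), _ring([x, 0.0, 5.5], [0, 0, 1], phase=30.0)):
            addB(nm, "C", "PHE", pos)
        x += step

    for _ in range(counts["t_stacking"]):
        a_res[0] += 1
        b_res[0] += 1
        ra = _ring([x, 0.0, 0.0], [0, 0, 1])
        rb = _ring([x, 0.0, 4.8], [0, 1, 0])
        for nm, pos in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), ra):
            addA(nm, "C", "PHE", pos)
        for nm, pos in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), rb):
            addB(nm, "C", "PHE", pos)
        d = np.linalg.norm(ra[:, None, :] - rb[None, :, :], axis=2)
        extra_hydrophobic += int((d <= 4.0).sum())
        x += step

    for _ in range(counts["hydrophobic_contacts"]):
        a_res[0] += 1
        b_res[0] += 1
        addA("CD1", "C", "LEU", [x, 0.0, 0.0])
        addB("CD1", "C", "LEU", [x, 3.8, 0.0])
        x += step

    def mk(atoms, chain, metadata):
        if not atoms:
            atoms = [("C1", "C", "UNK", 1, np.array([500.0 + 100 * (chain == "B"), 0.0, 0.0]), 0.0)]
        return Structure(
            coords=np.array([a[4] for a in atoms]),
            names=[a[0] for a in atoms],
            elements=[a[1] for a in atoms],
            res_names=[a[2] for a in atoms],
            res_numbers=[a[3] for a in atoms],
            chain_ids=[chain] * len(atoms),
            partial_charges=np.array([a[5] for a in atoms]),
            metadata=metadata,
        )

    mol_a = mk(a_atoms, "A", f"interaction_complex_A(seed={seed})")
    mol_b = mk(b_atoms, "B", f"interaction_complex_B(seed={seed})")

    # expected electrostatic energy by direct pair summation (<= 4 A pairs)
    energy = 0.0
    for _, _, _, _, pa, qa in a_atoms:
        for _, _, _, _, pb, qb in b_atoms:
            r = float(np.linalg.norm(pa - pb))
            if r <= 4.0 and qa != 0.0 and qb != 0.0:
                energy += 332.06 * qa * qb / r
    expected = InteractionFingerprint(
        hbonds=counts["hbonds"],
        salt_bridges=counts["salt_bridges"],
        cation_pi=counts["cation_pi"],
        pi_stacking=counts["pi_stacking"],
        t_stacking=counts["t_stacking"],
        hydrophobic_contacts=counts["hydrophobic_contacts"] + extra_hydrophobic,
        summed_electrostatic=energy,
        contacts_by_residue={},
    )
    return mol_a, mol_b, expected
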