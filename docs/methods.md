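# Methods

This note records the models implemented in `modedock`, their assumptions,
the parameters that matter, and the choices made where the design was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Elastic-network normal modes

The receptor is reduced to its Cα atoms; nodes carry the *total residue
mass* (so a pseudo-atom fixture with uniform 110 amu nodes and an all-atom
protein are treated identically). Pairs within a cutoff (default **15 Å**,
a standard choice for Cα anisotropic network models) are joined by uniform
harmonic springs (spring constant default 1.0, arbitrary units — only
eigenvalue *ratios* and eigenvectors matter here). The mass-weighted
Hessian is assembled analytically and fully diagonalised (dense up to
3N = 6000; sparse shift-invert for the lowest 50 modes above that,
tolerance 1e-10). A connected network has exactly six near-zero
(rigid-body) eigenvalues; disconnection is an error that names the smallest
component rather than a silent large-gap spectrum.

This Cα network is a deliberate surrogate for all-atom force-field normal
modes: the low-frequency, highly collective motions — the inter-domain
opening targeted here — are the part of the spectrum such networks
reproduce well, while high-frequency local modes are not meaningful in this
model and are never used.

### Opening-mode identification

Because mode *numbering* is model-dependent, the opening mode is selected
functionally rather than by index. For each of the lowest K = 20 internal
modes, the Cartesian displacement field `w_i/√m_i` restricted to each of
the two domains (a residue partition covering ≥ 90 % of nodes) is fitted by
an instantaneous rigid motion `d ≈ t + ω × r` (translation = mean
displacement; ω from the 3×3 normal equations). The score is

    counter_rotation = −cos∠(ω_A, ω_B) · 2|ω_A||ω_B| / (|ω_A|² + |ω_B|²)

which is +1 exactly when the domains rotate equally about anti-parallel
axes. Scores within 0.02 of each other are treated as ties and resolved
toward the lower eigenvalue: anti-symmetric bending pairs of a symmetric
dumbbell tie with the torsion at the numerical level, and the softest
candidate is the physically meaningful pick. The returned `OpeningScore`
exposes both the raw index (rigid-body modes included) and the internal
index, since the literature counts either way. A Bruschweiler-style
collectivity `exp(−Σ p ln p)/N` is reported alongside.

### Mode-directed conformers

Displacement along mode *k* at amplitude *a*:
`Δx_i = s·w_i/√m_i`, with `s = a·√(Σm_i)` so that the **mass-weighted RMS
Cα displacement equals the amplitude exactly** (this is the assumed meaning
of the displacement scale; it is enforced to 1e-6 Å by tests). The
amplitude schedule defaults to 0–6 Å in 1 Å steps — seven conformers. All
non-Cα atoms of a residue translate rigidly with their Cα, preserving
internal residue geometry; no re-minimisation is attempted. Instead
`clash_scan` counts heavy-atom pairs (> 2 residues apart in sequence)
closer than 0.6 × the summed vdW radii, so displacement artifacts are
visible rather than silently relaxed. When a binding site is supplied, the
displacement sign with the larger site SASA at maximum amplitude is defined
as the *open* direction.

## Solvent-accessible surface area and volume

Shrake–Rupley with a **deterministic Fibonacci-spiral point set** (no RNG
anywhere; default 960 points, probe 1.4 Å, Bondi-type radii from the
bundled element table). Heavy atoms only; het groups are excluded as
occluders by default because site exposure is used as a docking-
accessibility proxy for the residues that normally contact the ligand —
both switches (`include_het`, `include_hydrogens`) are exposed. Site SASA
is the plain sum over all atoms of the site's residues, so whole-structure
selections reproduce the total exactly.

Molecular volume is grid voxelisation (default 0.3 Å): a voxel counts when
its centre lies inside any heavy-atom sphere. Tests hold it to 2 % against
closed forms and a seeded Monte-Carlo oracle; accuracy at a given spacing
is alignment-dependent, so sub-percent work should use ≤ 0.15 Å.

## Trajectory analytics

Trajectories are multi-model PDB files or arrays over a fixed topology; the
molecular dynamics that produces real trajectories is out of scope, and the
published per-bond occupancies and cluster counts that depend on
unpublished trajectories are *not* reproduction targets. Instead the
generator (`make_traj_with_occupancy`) constructs trajectories where each
listed donor–acceptor pair satisfies the criterion in an exact number of
frames, and the analytics must recover those numbers exactly.

* **H-bonds**: donor–acceptor heavy-atom distance ≤ 3.0 Å (the
  donor–acceptor reading of the distance criterion is assumed and
  configurable) AND deviation from D–H⋯A linearity at the hydrogen ≤ 20°.
  Explicit hydrogens are used when present; otherwise rotatable donors
  (hydroxyl, thiol, ammonium) are granted a hydrogen pointing at the
  acceptor (deviation 0), and fixed sp² donors get ideally constructed
  planar hydrogens. Donor/acceptor typing comes from per-residue template
  tables covering the 20 amino acids plus the C-terminal amide cap (the
  studied peptides are amidated); het-group N/O atoms are generic
  acceptors.
* **Occupancy tables** use the `RES<n>-Main|Side-<atom>` labelling
  convention (Main = backbone N/O including terminal oxygens), a ≥ 10 %
  reporting threshold, and donor-residue-number ordering. No RNG: tables
  are bit-reproducible.
* **Secondary structure** is DSSP-style: backbone H-bonds by the classical
  electrostatic criterion (E < −0.5 kcal/mol, ideal amide H when absent),
  then n-turns, bridges and ladders give H/G/E/B/T/C with H > E > G > T
  precedence. The hairpin builder's dihedral recipe was calibrated once so
  a 16-mer folds with its two strands in H-bond register, then frozen.
* **Clustering** is the Daura neighbour-counting algorithm over backbone
  RMSD (cutoff per run, 2.0 Å typical; ties to the lower frame index),
  tested for exact agreement with an independent brute-force reference.

## Rigid docking

Classical Cartesian FFT correlation docking. The receptor lattice carries a
favourable band — the envelope dilated outward by `surface_thickness`
(default 1.5 Å) minus a 1-voxel-eroded core — so a ligand at touching
distance scores while interpenetration meets the imaginary core penalty
(weight −15). The ligand lattice is its occupancy. Orientations come from a
deterministic super-Fibonacci covering of SO(3) whose size is chosen from
the rotation step (default 24°; identity always included). Scores are
**normalised by the rotation's rasterised ligand voxel count**, making
orientations comparable (unnormalised counts vary with rasterisation and
bias the search), and rounded to 6 decimals so exact ties break
deterministically by rotation-set order. A second channel correlates the
receptor's truncated Coulomb potential (cutoff 8 Å, inner clamp 1 Å)
against splatted ligand charges; its weight defaults to 0.25. Local maxima
are pooled over rotations, de-duplicated at 3 Å ligand RMSD (a declared
choice; the reference tool's pose-clustering radius is unpublished), and
the top 350 kept, mirroring the typical solution count of the blind-search
workflow this replaces. Absolute scores of that workflow's engine are not
reproduction targets; poses are re-scored by the fingerprint module.

## Interaction fingerprints

Gasteiger–Marsili PEOE charges: atom types from element + coordination
number (bonds by covalent-radius distance detection, exact for the
ideal-geometry and crystallographic structures handled here), initial
charges = pH-7 formal charges (Arg/Lys +1, Asp/Glu −1, free N-terminus +1,
amidated C-terminus neutral, His neutral), transfers damped by (1/2)ⁿ for
8 iterations. Charge is conserved exactly by construction.

Interaction criteria (all configurable; defaults follow the rescoring
literature since the source workflow does not print its cutoffs): H-bonds
as above; salt bridge = oppositely charged group centroids ≤ 4.0 Å;
cation-π = cationic centroid to aromatic ring centroid ≤ 6.0 Å; π-stacking
= ring centroids ≤ 7.5 Å with interplanar angle ≤ 30°; T-stacking =
centroids ≤ 5.0 Å with angle 60–90°; hydrophobic contact = apolar-carbon
pair (carbon with no N/O/S neighbour) ≤ 4.0 Å; summed electrostatics =
332.06·Σq_iq_j/r over inter-molecular pairs ≤ 4.0 Å, no dielectric,
negative favourable. Only inter-molecular pairs count. Steric overlap
reports clashing pairs (0.6 × summed vdW radii) and the voxel-intersection
volume of the two envelopes.

## Synthetic fixtures: what they do and do not establish

Every generator is seed-deterministic and emits standard PDB.

* **Hinge dimer**: two ~3.8 Å-packed pseudo-Cα lobes (radius scaled to keep
  packing density constant), surfaces 11 Å apart so a few direct springs
  prevent floppy mechanisms, joined by `hinge_width` zig-zag off-axis
  nodes. By construction its softest internal mode is the lobe
  counter-rotation (overlap with the analytic field > 0.8 for default-scale
  lobes); nodes carry alternating ±0.25 charges so electrostatic rescoring
  is exercised. It validates mode identification and displacement, *not*
  any protein energetics: it has no side chains, no polar atoms, and its
  H-bond/salt-bridge fingerprint rows are structurally zero.
* **Occupancy trajectories**: controlled bonds are switched by rigidly
  placing the acceptor residue on the donor–hydrogen axis (2.85 Å "on",
  8 Å "off"); Gaussian noise (σ = 0.15 Å default) never touches atoms of a
  controlled bond in its on-frames and cannot create a listed bond
  spuriously. Recovery is therefore exact by construction — a green test
  establishes the detector and bookkeeping, not anything about real
  hydrogen-bond dynamics.
* **Cavity complex**: a chiral pseudo-ligand (three unequal orthogonal arms
  plus a knob) inside a closely wrapped receptor cage with a narrow mouth
  and complementary wall charges. Designed for recovery at 1 Å spacing and
  ≤ 30° rotation steps; with a perfectly complementary pocket several
  placements can saturate the shape score, and the deterministic tie-break
  plus the electrostatic channel make the true placement the unique
  winner.
* **Interaction complexes**: isolated minimal-fragment "stations" per
  requested interaction, spaced 16 Å apart; geometries chosen so classes do
  not cross-contaminate (e.g. salt-bridge stations keep every N⋯O pair
  above the H-bond cutoff). The one unavoidable coupling — T-stacked rings
  are close enough for ring-carbon hydrophobic contacts — is counted into
  the expectation by direct distance arithmetic.

## Numerical choices and degenerate inputs

Inclusive (≤) boundaries on every distance criterion. Kabsch superposition
rejects < 3 pairs and collinear sets; proper rotations only. Eigenvalues
below 1e-10 × max are clamped to zero. The diatomic two-node network is
accepted (its 2γ/m internal mode is a closed-form test anchor) even though
the six-zero-mode invariant presumes a non-collinear 3-D network. PDB
altloc handling keeps the highest occupancy (ties by identifier order);
element inference from atom names failing is an error, never a default.

## Known limitations

* The elastic network cannot reproduce all-atom mode energies or orderings;
  only the functional (counter-rotation) selection makes results
  transferable, and on a real receptor the selected raw index need not
  match any published mode number.
* Rigid side-chain transport means large amplitudes can create clashes that
  a minimised structure would relax; `clash_scan` reports them but nothing
  repairs them.
* Docking scores are surface-contact fractions, not energies; they rank
  poses within a run and are not comparable across receptors of different
  size, which is why fingerprint rescoring follows.
* PEOE here covers H/C/N/O/S/P and halogens; metal centres are rejected
  rather than guessed.
* SASA values depend on the radii set and hydrogen handling at the few-
  percent level; comparisons across programs should expect ~10 %
  differences, which is the tolerance used for crystal-structure site
  areas.
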